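# Methods

This note records the models, parameter choices and numerical conventions
behind `ceparch`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinate and sequence conventions

All residue coordinates are 1-based and inclusive at both ends. Sequences
are uppercase over the 20 standard residues plus `X`; `X` is excluded from
every composition denominator and from pI. Lowercase FASTA input is
uppercased silently; any other character is a parse error.

## Theoretical pI

The net charge model is the standard per-group Henderson–Hasselbalch sum
over ionizable side chains (Asp, Glu, Cys, Tyr acidic; His, Lys, Arg
basic) plus both termini. Q(pH) is strictly decreasing, so the pI is the
unique root on [0, 14]; it is found by bisection to |Q| < 1e-4, which
locates the root to well under 0.01 pH units (verified against a dense
pH-grid sign-change oracle). The default pKa set is the Bjellqvist table
(N-term 7.5, C-term 3.55, D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0,
R 12.0); an EMBOSS-style alternative is selectable by name. His is counted
as basic — and therefore charged — throughout, which is required for the
propeptide residue-class statistics (basic = Arg, Lys, His) to be
reproducible. No titration-curve refinements, Cys oxidation states or
post-translational modifications are modeled.

## Composition classifiers

* **Propeptide type.** A structure-derived disorder fraction dominates
  when available (≥ 0.5 → ID). Otherwise a three-criterion vote is taken,
  with two votes calling ID: Pro fraction ≥ 0.05, acidic-minus-basic
  excess ≥ 0.05, and length ≤ 147 aa. The cutoffs sit between the
  reference class statistics (ID propeptides: ~20 % charged split 15:5
  acidic:basic, ~7 % Pro, 48–147 aa; structured propeptides: ~24 % charged
  split 11:13, ~3 % Pro, 145–172 aa); the exact values are package
  decisions, and every call reports which criteria fired together with the
  reference ranges.
* **W charge class.** Acidic iff pI < 5.5, basic iff pI > 9.0, else
  intermediate.
* **SlpA check.** Pass iff Lys ≥ 0.17 and acidic ≤ 0.05 and pI > 10; each
  failed criterion is returned as a reason.

## Motifs and the AN-domain validator

The canonical sortase motif is `LP.TG`. The variant pattern
`[LMF][PA].[TA][GAN]` is the smallest position-set pattern covering the
five variant anchors observed in CEP homologs (LAKTA, LPDTA, FPTTN,
MPQAG, LPTTN) plus known sortase substrate tolerances (L→M, P→A, T→A);
position 4 is restricted to {T, A} to limit false positives. Exact
canonical matches are never classed as variants. The cleavage motif
`KVY[YH][PA][TN]D` annotates its scissile bond before the final Asp.

A validated anchor domain requires: motif start within the C-terminal 70
residues; a downstream contiguous 15-residue window with mean
Kyte–Doolittle hydropathy ≥ 1.0 (contiguous window, not a sliding
average); and ≥ 2 Lys/Arg among the final 10 residues. All five
thresholds are configuration values. When several hits validate, the most
C-terminal one defines the AN start.

## Tandem repeats

Candidate periods come from recurrence distances of exact k-mers
(k = min(5, min_unit)); each candidate grows block-wise around its seed
while every new period-length copy keeps ≥ `min_identity` (default 0.5)
identity to the running column-majority consensus, with partial terminal
blocks attached the same way and counted as their aligned fraction of a
copy (hence fractional copy numbers such as 3.7). Overlaps are resolved
greedily by copies × identity; a hit whose unit divides a competitor's and
whose region covers ≥ 90 % of it at within-0.05 identity is preferred, so
perfect (u × n) repeats report unit u rather than a multiple. Consensus
column ties break to the lexicographically smallest residue for
determinism.

## Alignment, distances and trees

Pairwise global alignment is Needleman–Wunsch/Gotoh with affine gaps
(BLOSUM62, gap open −11, gap extend −1; a length-L gap costs
open + (L−1)·extend), delegated to Biopython's `PairwiseAligner` with the
first optimal traceback taken. Percent identity is counted over columns
where neither row is gapped. The protein Jukes–Cantor correction uses the
20-state generalization by default (4-state selectable), with a
saturation error at p ≥ (s−1)/s.

Neighbor joining is the standard Saitou–Nei agglomeration on the
Q-criterion, ties broken lexicographically by cluster label; branch
lengths come from the standard formulas, and negative lengths are clamped
to zero with the deficit moved to the sister edge (raw mode available).
The unrooted result is reported rooted at the final join. Bootstrap
resamples alignment columns with replacement under a seeded generator;
the support of an internal edge is the percentage of replicate NJ trees
containing the same leaf bipartition, reported on the point-estimate tree.
Multiple alignment, needed only to feed the distance/bootstrap machinery,
is a light progressive scheme over an NJ guide tree that merges profiles
via their majority-consensus strings; fidelity to production MSA tools is
explicitly not a goal. Tree-cut clustering removes edges whose
depth-from-root exceeds the threshold and returns the resulting leaf
components; the threshold is exposed because no canonical cluster-cut
value exists for this family.

## Structures

Only Cα atoms are modeled; pLDDT (0–100) is read from the B-factor column
following the structure-prediction convention, via gemmi (PDB and mmCIF;
first model, one chain). Disorder segments are maximal runs of
consecutive residues with pLDDT < 50 and length ≥ 20 — the literature
supports the < 50 reading for long runs without fixing a minimum length;
20 was chosen as the shortest W-like linker scale and lives in the
configuration. Kabsch superposition enforces a proper rotation by sign
correction of the smallest singular direction. The catalytic-triad search
returns all Asp < His < Ser triples (sequence order) whose Cα distances
lie within ±2.0 Å of 7.5 / 8.4 / 10 Å, sorted by total deviation. Domain
span is the extent along the first principal axis, in nm. Fold grouping
builds a pairwise RMSD matrix from alignment-paired superpositions and
cuts an average-linkage dendrogram at 3.5 Å by default.

## The annotator

Boundaries of the structured core (PRE, PRO, PR1, PA, PR2, Fn, H) derive
from profile databases and manual structural inspection in practice and
are accepted as *inputs*; the annotator computes what sequence and
structure actually encode: anchor motifs with the tripartite validation,
SlpA composition on the region trailing the disordered W, the W region
itself (from the pLDDT track when a model is given, otherwise a
composition heuristic: charged+polar+Pro+Gly+Ala ≥ 0.8 and
aromatic+Cys+Met ≤ 0.02 on the region between the last core domain and
the attachment), tandem repeats within W, the propeptide class and the
catalytic triad. An attachment domain is only accepted when a W region
ends within 5 residues of it, mirroring the observation that W occurs
exactly where an attachment domain follows; absence of evidence leaves
optional domains absent rather than failing. The validated profile is
grammar-checked; PR1 and PR2 print as a single `PR` token when no PA
intervenes.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of (parameters, seed). Per-domain
residues draw from categorical recipes matching the class statistics
above (ID propeptide: 20 % charged at 15:5, 7 % Pro, no Cys; structured:
~24 % at 11:13, 3 % Pro; W: a 9-letter low-complexity alphabet free of
aromatics/Cys/Met with acidic or basic bias; SlpA: 25 % Lys, no Asp/Glu;
AN: chosen motif + hydrophobic run + Lys/Arg tail); unconstrained
positions are uniform over the 20 residues, a simplicity choice recorded
here so natural frequencies can be swapped in. Two deliberate
disambiguations keep ground truth identifiable: the hydrophobic anchor
run draws from {L, I, V, F} only, so no variant-motif 5-mer can arise
inside it (position 2 requires P/A), and the protease-domain background
excludes free D/H/S so the explicitly planted triad is the unique
geometric solution within the protease subdomains. Toy structures are
compact clouds scaled exactly to their span targets (default 4 nm) with
pLDDT in [80, 95], extended chains with pLDDT in [20, 45] for disordered
segments, and the planted triad at exact 7.5/8.4/10 Å geometry; they
exercise geometry code and are not protein-like beyond those contracts.
Families evolve by the exact 20-state equal-rates transition kernel (a
site substitutes with probability 1 − e^(−d·s/(s−1)), drawing uniformly
over all s states), so observed mismatch proportions invert through the
Jukes–Cantor formula and compose across branches; there are no indels.

Consequently, passing tests show that each stage recovers its own
generative ground truth under realistic composition statistics — they do
not show robustness to homology-driven composition drift, indel-rich W
regions, partially disordered propeptides, or prediction-model artifacts
in real pLDDT tracks.

## Problem sizes

The default suite and the acceptance script run at desk scale: 100
random pairs for the alignment oracle (lengths ≤ 6), 200 additive
matrices of 4–6 taxa, 100 planted rigid transforms, a 72-run architecture
battery over the 8 layout templates (6 structure-assisted + 3
sequence-only seeds each), 50 repeat-recovery seeds, 20 W-boundary runs,
and 100 six-taxon families of 1000 sites. These sizes give binomial
standard errors of a few percent on the reported rates.

## Known limitations

* Core-domain boundaries are not predicted de novo; the annotator is an
  evidence integrator, not a domain segmenter.
* The manual Roman-numeral cluster assignment of the family's phylogeny
  is not auto-derived; `cut_clusters` exposes a threshold surrogate.
* The progressive MSA is a guide-tree consensus merge, adequate for
  distances and bootstrap on closely related rows, not for production
  alignments.
* The sequence-only W heuristic requires the attachment domain to be
  detected first; a W-like region with no downstream anchor is left
  unlabeled.
* SlpA window search in sequence-only mode scans trailing windows of
  100–150 aa and can misplace the W/SlpA boundary by a few residues when
  the lysine gradient is shallow.
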