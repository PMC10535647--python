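"""Synthetic stand-in for the qualitative domain architectures of the 21
structurally modeled CEP homologs.

The per-protein domain compositions below are reconstructed from textual
descriptions of the homolog set (cluster membership, presence/absence of
PA, H, W, AN and SlpA domains, and B-region Fn counts); the original
per-residue boundaries are not reproduced, so nominal lengths are used.
This fixture exercises architecture counting, not boundary accuracy.
"""

_CORE_PA = ["PRE", "PRO", "PR1", "PA", "PR2"]
_CORE_NOPA = ["PRE", "PRO", "PR1", "PR2"]


def _fns(n):
    return [f"FN{i}" for i in range(1, n + 1)]


# protein name -> ordered domain kinds
ARCHITECTURES_21 = {
    # cluster XIII: the minimal subtilisin layout
    "Subtilisin": _CORE_NOPA,
    # cluster I: A-region only, W with anchor
    "ScpA": _CORE_PA + _fns(3) + ["W", "AN"],
    # cluster II: two B-region Fn domains plus a helical stalk
    "PrtS_4F44": _CORE_PA + _fns(5) + ["H", "W", "AN"],
    # cluster III: four B-region Fn domains, no helical domain
    "ScpC": _CORE_PA + _fns(7) + ["W", "AN"],
    # cluster IX: SlpA-anchored with a short helix bundle
    "PrtH": _CORE_PA + _fns(6) + ["H", "W", "SLPA"],
    # cluster X: five homologs sharing the eight-Fn + H + W + AN layout
    "PrtP_SK11": _CORE_PA + _fns(8) + ["H", "W", "AN"],
    "PrtP_Wg2": _CORE_PA + _fns(8) + ["H", "W", "AN"],
    "PrtP_MS22337": _CORE_PA + _fns(8) + ["H", "W", "AN"],
    "PrtP_MS22333": _CORE_PA + _fns(8) + ["H", "W", "AN"],
    "PrtP_NFICC96Q": _CORE_PA + _fns(8) + ["H", "W", "AN"],
    # cluster XI: no PA insert, SlpA-anchored, long W
    "PrtH2": _CORE_NOPA + _fns(7) + ["W", "SLPA"],
    # cluster XII: no PA insert, covalent anchor
    "PrtR": _CORE_NOPA + _fns(6) + ["W", "AN"],
    "PrtP_NFICC80": _CORE_NOPA + _fns(6) + ["W", "AN"],
    "PrtP_NFICC200": _CORE_NOPA + _fns(6) + ["W", "AN"],
    # cluster VI: seven B-region Fn domains, SlpA-anchored
    "PrtB": _CORE_PA + _fns(10) + ["W", "SLPA"],
    "PrtL": _CORE_PA + _fns(10) + ["W", "SLPA"],
    # clusters V / VII / VIII: one shared architecture
    "PrtP_NFICC96W": _CORE_PA + _fns(5) + ["W", "AN"],
    "PrtP_NFICC103": _CORE_PA + _fns(5) + ["W", "AN"],
    "PrtP_NFICC120": _CORE_PA + _fns(5) + ["W", "AN"],
    "PrtP_NFICC546": _CORE_PA + _fns(5) + ["W", "AN"],
    # cluster IV: Fn tail with neither W nor attachment domain
    "PrtP_NFICC96H": _CORE_PA + _fns(8),
}

#: nominal segment lengths used to lay the kinds out as regions
NOMINAL_LENGTHS = {
    "PRE": 30, "PRO": 150, "PR1": 250, "PA": 150, "PR2": 120,
    "H": 200, "W": 90, "AN": 45, "SLPA": 125,
}
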