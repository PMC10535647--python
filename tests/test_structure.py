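import numpy as np
import pytest

from ceparch.seq_io import Region
from ceparch.structure import (
    EmptyModelError,
    StructureModel,
    cluster_domain_structures,
    disorder_fraction,
    disorder_segments,
    domain_span,
    find_catalytic_triad,
    kabsch_superpose,
    quality_bands,
    read_structure,
    superpose_by_alignment,
    write_pdb,
)


def make_model(plddt, coords=None, aa=None, start=1):
    n = len(plddt)
    rng = np.random.default_rng(0)
    return StructureModel(
        id="m",
        resi=np.arange(start, start + n),
        aa=tuple(aa) if aa else tuple("A") * n,
        coords=coords if coords is not None else rng.normal(size=(n, 3)),
        plddt=np.asarray(plddt, dtype=float),
    )


def random_rotation(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestReadStructure:
    def test_minimal_pdb_coordinates(self, tmp_pdb):
        path = tmp_pdb([
            ("MET", 1, (1.0, 2.0, 3.0), 95.0),
            ("LYS", 2, (4.0, 5.0, 6.0), 91.2),
            ("GLY", 3, (7.0, 8.0, 9.0), 40.0),
        ])
        model = read_structure(path)
        assert len(model) == 3
        assert model.aa == ("M", "K", "G")
        assert model.coords[0] == pytest.approx([1.0, 2.0, 3.0])

    def test_bfactor_read_as_plddt(self, tmp_pdb):
        path = tmp_pdb([("ALA", 1, (0, 0, 0), 91.2), ("ALA", 2, (3, 0, 0), 55.5)])
        model = read_structure(path)
        assert model.plddt[0] == pytest.approx(91.2)

    def test_no_ca_atoms_is_error(self, tmp_path):
        path = tmp_path / "side.pdb"
        path.write_text(
            "ATOM      1  CB  ALA A   1       0.000   0.000   0.000  1.00 90.00           C\n"
            "END\n"
        )
        with pytest.raises(EmptyModelError):
            read_structure(path)

    def test_pdb_round_trip(self, tmp_path):
        model = make_model([90.0, 80.0, 42.5], aa="MKW")
        path = tmp_path / "rt.pdb"
        write_pdb(model, path)
        back = read_structure(path)
        assert back.aa == model.aa
        assert back.coords == pytest.approx(model.coords, abs=1e-3)
        assert back.plddt == pytest.approx(model.plddt, abs=0.01)


class TestDisorderSegments:
    def test_single_low_confidence_stretch(self):
        plddt = [85.0] * 20 + [40.0] * 30 + [88.0] * 20
        segs = disorder_segments(make_model(plddt))
        assert len(segs) == 1
        assert (segs[0].region.start, segs[0].region.end) == (21, 50)
        assert segs[0].mean_plddt == pytest.approx(40.0)

    def test_short_stretch_below_min_len(self):
        plddt = [85.0] * 20 + [40.0] * 10 + [88.0] * 20
        assert disorder_segments(make_model(plddt), min_len=20) == []

    def test_alternating_values_no_segment(self):
        plddt = [45.0, 55.0] * 30
        assert disorder_segments(make_model(plddt)) == []

    def test_segments_and_complement_cover_model_once(self):
        rng = np.random.default_rng(4)
        plddt = rng.uniform(0, 100, 300)
        model = make_model(plddt)
        segs = disorder_segments(model, min_len=5)
        covered = set()
        for s in segs:
            span = set(range(s.region.start, s.region.end + 1))
            assert not (covered & span)
            covered |= span
        assert covered <= set(range(1, 301))


class TestQualityBands:
    def test_all_high(self):
        assert quality_bands(make_model([95.0] * 10)) == (1.0, 0.0, 0.0, 0.0)

    def test_half_and_half(self):
        bands = quality_bands(make_model([80.0] * 5 + [60.0] * 5))
        assert bands == (0.0, 0.5, 0.5, 0.0)

    def test_uniform_plddt_band_fractions(self):
        rng = np.random.default_rng(13)
        bands = quality_bands(make_model(rng.uniform(0, 100, 10_000)))
        assert bands == pytest.approx((0.1, 0.2, 0.2, 0.5), abs=0.02)
        assert sum(bands) == pytest.approx(1.0)


class TestKabsch:
    def test_identity_superposition(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert sup.rotation == pytest.approx(np.eye(3), abs=1e-9)

    def test_recovers_planted_rigid_transforms(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            pts = rng.normal(size=(12, 3)) * 10
            rot = random_rotation(rng)
            trans = rng.uniform(-30, 30, 3)
            moved = pts @ rot.T + trans
            sup = kabsch_superpose(pts, moved)
            assert sup.rmsd < 1e-6
            assert sup.rotation == pytest.approx(rot, abs=1e-6)
            assert sup.apply(pts) == pytest.approx(moved, abs=1e-6)

    def test_mirrored_input_gives_proper_rotation(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pts = rng.normal(size=(15, 3)) * 5
            mirrored = pts * np.array([-1.0, 1.0, 1.0])
            sup = kabsch_superpose(mirrored, pts)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)
            assert sup.rmsd > 0

    def test_rmsd_symmetric_and_rigid_invariant(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(20, 3)) * 8
        b = a + rng.normal(0, 1.0, size=a.shape)
        r1 = kabsch_superpose(a, b).rmsd
        r2 = kabsch_superpose(b, a).rmsd
        assert r1 == pytest.approx(r2, abs=1e-9)
        rot = random_rotation(rng)
        assert kabsch_superpose(a @ rot.T + 3.0, b).rmsd == pytest.approx(r1, abs=1e-9)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestSuperposeByAlignment:
    def test_identity_pairing_zero_rmsd(self):
        model = make_model([90.0] * 10)
        pairs = [(int(r), int(r)) for r in model.resi]
        sup = superpose_by_alignment(model, model, pairs)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_noise_model_rmsd_expectation(self):
        # isotropic sigma per coordinate gives rmsd ~ sigma * sqrt(3)
        sigma = 0.5
        rmsds = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(60, 3)) * 12
            noisy = pts + rng.normal(0, sigma, pts.shape)
            rmsds.append(kabsch_superpose(pts, noisy).rmsd)
        assert np.mean(rmsds) == pytest.approx(sigma * np.sqrt(3), rel=0.2)

    def test_too_few_pairs(self):
        model = make_model([90.0] * 5)
        with pytest.raises(ValueError):
            superpose_by_alignment(model, model, [(1, 1), (2, 2)])


class TestCatalyticTriad:
    def triad_coords(self):
        return np.array([
            [0.0, 0.0, 0.0],
            [7.5, 0.0, 0.0],
            [5.7127, 8.2077, 0.0],
        ])

    def test_exact_geometry_found(self):
        coords = np.vstack([self.triad_coords(), [[50.0, 50.0, 50.0]]])
        model = make_model([90.0] * 4, coords=coords, aa="DHSA")
        hits = find_catalytic_triad(model)
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.asp_index, hit.his_index, hit.ser_index) == (1, 2, 3)
        assert hit.d_asp_his == pytest.approx(7.5, abs=0.01)
        assert hit.d_his_ser == pytest.approx(8.4, abs=0.01)
        assert hit.d_asp_ser == pytest.approx(10.0, abs=0.01)

    def test_no_histidine_empty(self):
        coords = self.triad_coords()
        model = make_model([90.0] * 3, coords=coords, aa="DAS")
        assert find_catalytic_triad(model) == []

    def test_distant_residues_empty(self):
        coords = np.array([[0, 0, 0], [20.0, 0, 0], [0, 20.0, 0]])
        model = make_model([90.0] * 3, coords=coords, aa="DHS")
        assert find_catalytic_triad(model) == []

    def test_sequence_order_enforced(self):
        # geometry fits but Ser precedes His in sequence: no hit
        coords = self.triad_coords()[[0, 2, 1]]
        model = make_model([90.0] * 3, coords=coords, aa="DSH")
        assert find_catalytic_triad(model) == []


class TestDomainSpan:
    def test_two_points(self):
        assert domain_span(np.array([[0, 0, 0], [40.0, 0, 0]])) == pytest.approx(4.0)

    def test_collinear_points(self):
        pts = np.array([[0, 0, 0], [10.0, 10.0, 10.0], [20.0, 20.0, 20.0]]) * (
            60 / np.linalg.norm([20.0, 20.0, 20.0])
        )
        assert domain_span(pts) == pytest.approx(6.0)

    def test_matches_pca_oracle(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(0, 5.0, size=(500, 3))
        centered = pts - pts.mean(axis=0)
        cov = np.cov(centered.T)
        w, v = np.linalg.eigh(cov)
        proj = centered @ v[:, -1]
        assert domain_span(pts) == pytest.approx(
            (proj.max() - proj.min()) / 10.0, abs=1e-9
        )


class TestStructureClustering:
    def make_fold(self, seed, n=40):
        rng = np.random.default_rng(seed)
        return rng.normal(size=(n, 3)) * 6

    def copy_with_noise(self, pts, seed, sigma=0.3):
        rng = np.random.default_rng(seed)
        rot = random_rotation(rng)
        return pts @ rot.T + rng.uniform(-20, 20, 3) + rng.normal(0, sigma, pts.shape)

    def as_model(self, label, pts):
        return (label, make_model([90.0] * len(pts), coords=pts, aa="A" * len(pts)))

    def test_noised_copies_one_group(self):
        fold = self.make_fold(0)
        domains = [self.as_model(f"d{i}", self.copy_with_noise(fold, i)) for i in range(5)]
        groups = cluster_domain_structures(domains, cut=3.5)
        assert groups == [["d0", "d1", "d2", "d3", "d4"]]

    def test_two_folds_two_groups(self):
        fold_a, fold_b = self.make_fold(1), self.make_fold(2)
        domains = [self.as_model(f"a{i}", self.copy_with_noise(fold_a, i)) for i in range(3)]
        domains += [self.as_model(f"b{i}", self.copy_with_noise(fold_b, 10 + i)) for i in range(3)]
        groups = cluster_domain_structures(domains, cut=3.5)
        assert sorted(map(tuple, groups)) == [("a0", "a1", "a2"), ("b0", "b1", "b2")]

    def test_singleton(self):
        groups = cluster_domain_structures([self.as_model("only", self.make_fold(3))])
        assert groups == [["only"]]

    def test_group_count_monotone_in_cut(self):
        fold_a, fold_b = self.make_fold(4), self.make_fold(5)
        domains = [self.as_model(f"a{i}", self.copy_with_noise(fold_a, i)) for i in range(3)]
        domains += [self.as_model(f"b{i}", self.copy_with_noise(fold_b, 20 + i)) for i in range(3)]
        counts = [len(cluster_domain_structures(domains, cut=c)) for c in (0.01, 3.5, 1e6)]
        assert counts[0] >= counts[1] >= counts[2]
        assert counts[0] == len(domains)
        assert counts[2] == 1


def test_disorder_fraction_region():
    plddt = [90.0] * 50 + [30.0] * 50
    model = make_model(plddt)
    assert disorder_fraction(model, Region(51, 100)) == 1.0
    assert disorder_fraction(model, Region(1, 50)) == 0.0
    assert disorder_fraction(model) == 0.5
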