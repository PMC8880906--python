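import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from trefoil_themes import structure_motif as sm
from trefoil_themes import synthetic_data as sd
from trefoil_themes.formats_io import Residue, Structure, Water

from oracles import grid_rmsd


def _rigid(coords, seed=0, translate=5.0):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(scale=translate, size=3)
    return coords @ R.T + t


class TestKabsch:
    def test_identical_sets_rmsd_zero(self, rng):
        P = rng.normal(size=(8, 3))
        R, t, rmsd = kabsch_result = sm.kabsch(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(R, np.eye(3), atol=1e-9)

    def test_rigid_transform_recovered(self, rng):
        P = rng.normal(size=(10, 3))
        Q = _rigid(P, seed=4)
        _, _, rmsd = sm.kabsch(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_mirror_of_chiral_set_has_positive_rmsd(self, rng):
        P = rng.normal(size=(4, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # reflection
        R, _, rmsd = sm.kabsch(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 1e-3
        # the proper-rotation optimum matches an independent rotation search
        assert rmsd == pytest.approx(grid_rmsd(P, Q), abs=1e-4)

    def test_three_point_sets_match_rotation_grid_oracle(self, rng):
        for _ in range(25):
            P = rng.normal(size=(3, 3))
            Q = rng.normal(size=(3, 3))
            _, _, rmsd = sm.kabsch(P, Q)
            assert rmsd == pytest.approx(grid_rmsd(P, Q), abs=1e-4)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError):
            sm.kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestTmScore:
    def test_d0_formula(self):
        assert sm.tm_d0(29) == pytest.approx(1.1886, abs=1e-3)
        assert sm.tm_d0(10) == 0.5  # floored

    def test_self_mapping_scores_one(self, btl_motif):
        mapping = [(i, i) for i in range(btl_motif.length)]
        tm = sm.tm_score(mapping, btl_motif.ca, btl_motif.ca, btl_motif.length)
        assert tm == pytest.approx(1.0, abs=1e-9)

    def test_all_pairs_at_d0_give_half(self):
        # the TM sum with every pair at exactly d0 is 1/2 by construction;
        # the full search may only improve on that fixed superposition
        n = 30
        d0 = sm.tm_d0(n)
        assert sm._tm_from_distances(np.full(n, d0), d0, n) == pytest.approx(0.5, abs=1e-12)
        P = np.zeros((n, 3))
        P[:, 0] = np.arange(n) * 100.0
        Q = P.copy()
        Q[:, 1] += d0 * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        tm = sm.tm_score([(i, i) for i in range(n)], P, Q, n)
        assert tm >= 0.5 - 1e-9

    def test_invariant_to_rigid_transforms(self, btl_motif, rng):
        mapping = [(i, i) for i in range(btl_motif.length)]
        noisy = btl_motif.ca + rng.normal(scale=1.0, size=btl_motif.ca.shape)
        tm0 = sm.tm_score(mapping, btl_motif.ca, noisy, btl_motif.length)
        tm1 = sm.tm_score(mapping, _rigid(btl_motif.ca, 1), _rigid(noisy, 2), btl_motif.length)
        assert tm1 == pytest.approx(tm0, abs=1e-6)


class TestMotifSearch:
    def test_exact_embedded_copy_scores_one_any_flank(self, btl_motif, rng):
        for seed in range(20):
            coil = sd.generate_decoy_structure(
                int(rng.integers(40, 80)), "random_coil", seed=seed
            )
            cut = btl_motif.segment_lengths[0]
            flank = coil.ca + 200.0  # far away, no interference
            n1 = int(rng.integers(3, 12))
            n2 = int(rng.integers(3, 12))
            target = np.vstack(
                [flank[:n1], btl_motif.ca[:cut], flank[n1 : n1 + 4],
                 btl_motif.ca[cut:], flank[n1 + 4 : n1 + 4 + n2]]
            )
            hit = sm.motif_search(btl_motif, target, "embedded")
            assert hit.tm_score == pytest.approx(1.0, abs=1e-6)

    def test_noise_half_angstrom_displacement_keeps_high_tm(self, btl_motif):
        # per-coordinate sigma 0.29 A gives ~0.5 A expected displacement;
        # TM ~ 1/(1+(0.5/d0)^2) stays >= 0.8 for this motif length
        tms = []
        for seed in range(20):
            s = sd.generate_btl_structure(0.29, dry=False, seed=seed)
            tms.append(sm.motif_search(btl_motif, s.ca, "noisy").tm_score)
        assert np.median(tms) >= 0.8

    def test_helix_decoys_score_low(self, btl_motif):
        low = 0
        for seed in range(20):
            helix = sd.generate_decoy_structure(36, "helix", seed=seed)
            if sm.motif_search(btl_motif, helix.ca, "helix").tm_score < 0.4:
                low += 1
        assert low >= 19

    def test_noise_monotonicity(self, btl_motif):
        medians = []
        for sigma in (0.0, 0.3, 0.8, 1.5):
            tms = [
                sm.motif_search(
                    btl_motif, sd.generate_btl_structure(sigma, seed=s).ca, "t"
                ).tm_score
                for s in range(8)
            ]
            medians.append(np.median(tms))
        assert all(a >= b - 1e-9 for a, b in zip(medians, medians[1:]))

    def test_too_short_target_gives_empty_hit(self, btl_motif):
        hit = sm.motif_search(btl_motif, np.zeros((5, 3)), "short")
        assert hit.tm_score == 0.0 and hit.mapping == []


class TestThemeRmsd:
    def test_identical_segments_zero(self, rng):
        P = rng.normal(size=(10, 3))
        aln = [(i, i) for i in range(1, 11)]
        assert sm.theme_rmsd(aln, P, P) == pytest.approx(0.0, abs=1e-9)

    def test_rigidly_moved_copy_zero(self, rng):
        P = rng.normal(size=(10, 3))
        aln = [(i, i) for i in range(1, 11)]
        assert sm.theme_rmsd(aln, P, _rigid(P, 3)) == pytest.approx(0.0, abs=1e-7)

    def test_three_point_value_matches_grid_oracle(self, rng):
        P = rng.normal(size=(3, 3))
        Q = rng.normal(size=(3, 3))
        aln = [(1, 1), (2, 2), (3, 3)]
        assert sm.theme_rmsd(aln, P, Q) == pytest.approx(grid_rmsd(P, Q), abs=1e-4)

    def test_missing_ca_pairs_dropped_then_undefined(self, rng):
        P = {1: np.zeros(3), 2: np.ones(3)}
        Q = {1: np.zeros(3), 2: np.ones(3)}
        aln = [(1, 1), (2, 2), (3, 3)]
        assert np.isnan(sm.theme_rmsd(aln, P, Q))


class TestWaterMotif:
    def test_generator_motif_detected_exactly_once(self, btl):
        reports = sm.find_water_motif(
            btl.structure, [r.number for r in btl.structure.residues], ss=btl.ss
        )
        assert len(reports) == 1
        report = reports[0]
        assert report.n_short_hbonds == 3
        assert sorted(report.partner_context) == ["loop", "strand", "strand"]

    def test_no_waters_no_reports(self, btl_dry):
        assert (
            sm.find_water_motif(
                btl_dry.structure,
                [r.number for r in btl_dry.structure.residues],
                ss=btl_dry.ss,
            )
            == []
        )

    def test_displaced_water_dropped(self, btl):
        # push the water 1.5 A radially outward: every partner distance grows
        w = btl.structure.waters[0].coord
        centroid = btl.ca.mean(axis=0)
        outward = (w - centroid) / np.linalg.norm(w - centroid)
        moved = Structure(
            "A",
            btl.structure.residues,
            [Water("w", w + 1.5 * outward)],
        )
        assert (
            sm.find_water_motif(
                moved, [r.number for r in btl.structure.residues], ss=btl.ss
            )
            == []
        )


class TestClampAndDry:
    def test_generator_clamp_true(self, btl):
        assert sm.hydrophobic_clamp(btl.structure, btl.clamp_residues)

    def test_glycine_breaks_clamp(self, btl):
        residues = [
            Residue(number=r.number, name=r.name, atoms=dict(r.atoms))
            for r in btl.structure.residues
        ]
        r1 = btl.clamp_residues[0]
        residues[r1 - 1].name = "GLY"
        residues[r1 - 1].atoms.pop("CB", None)
        assert not sm.hydrophobic_clamp(Structure("A", residues), btl.clamp_residues)

    def test_distant_residues_no_clamp(self, btl):
        # first and last strand residues are far across the sheet
        assert not sm.hydrophobic_clamp(btl.structure, (1, 36))

    def test_dry_variant_flagged(self, btl_dry, btl_motif):
        hit = sm.motif_search(btl_motif, btl_dry.ca, "dry")
        assert hit.tm_score > 0.5
        assert sm.detect_dry_motif(btl_dry.structure, hit, btl_motif.donor_positions, ss=btl_dry.ss)

    def test_wet_variant_not_dry(self, btl, btl_motif):
        hit = sm.motif_search(btl_motif, btl.ca, "wet")
        assert not sm.detect_dry_motif(btl.structure, hit, btl_motif.donor_positions, ss=btl.ss)

    def test_waterless_without_proline_is_incomplete_not_dry(self, btl, btl_motif):
        no_water = Structure("A", btl.structure.residues, [])
        hit = sm.motif_search(btl_motif, btl.ca, "incomplete")
        assert not sm.detect_dry_motif(no_water, hit, btl_motif.donor_positions, ss=btl.ss)
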