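import numpy as np
import pytest
from scipy import stats

from trefoil_themes import secstruct_fragments as sf
from trefoil_themes import structure_motif as sm
from trefoil_themes import synthetic_data as sd


class TestGenerateFamily:
    def test_rate_zero_gives_identical_members(self):
        msa = sd.generate_family("ACDEFGHIKL", 5, 0.0, seed=1)
        assert all(seq == "ACDEFGHIKL" for _, seq in msa.rows)

    def test_same_seed_is_deterministic(self):
        a = sd.generate_family("ACDEFGHIKL" * 5, 10, 0.3, seed=42)
        b = sd.generate_family("ACDEFGHIKL" * 5, 10, 0.3, seed=42)
        assert a.rows == b.rows

    def test_mean_identity_matches_binomial_expectation(self):
        # rate 0.3 on length 100: identity to master ~ Binomial(100, 0.7)/100
        master = "".join(
            np.random.default_rng(3).choice(list(sd.AMINO_ACIDS), size=100)
        )
        msa = sd.generate_family(master, 50, 0.3, seed=7)
        idents = [
            sum(a == b for a, b in zip(master, seq)) for _, seq in msa.rows[1:]
        ]
        assert abs(np.mean(idents) - 70.0) < 3.0

    def test_empty_master_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_family("", 5, 0.1, seed=0)


class TestPlantTheme:
    def test_zero_divergence_plants_exact_theme(self):
        host = "A" * 50
        out = sd.plant_theme("CDEFGHIKLMNPQRS", host, position=10, divergence_rate=0.0, seed=0)
        assert out[9:24] == "CDEFGHIKLMNPQRS"
        assert len(out) == 50

    def test_theme_equals_host_is_identity(self):
        host = "ACDEFGHIKLMNPQRS"
        assert sd.plant_theme(host, host, 1, 0.0, seed=0) == host

    def test_divergence_matches_binomial(self):
        theme = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"  # length 30
        host = "G" * 60
        matches = []
        for seed in range(40):
            out = sd.plant_theme(theme, host, 16, 0.2, seed=seed)
            matches.append(sum(a == b for a, b in zip(out[15:45], theme)))
        lo, hi = stats.binom.interval(0.9999, 30 * 40, 0.8)
        assert lo <= sum(matches) <= hi

    def test_theme_longer_than_host_rejected(self):
        with pytest.raises(ValueError):
            sd.plant_theme("ACDEFGHIKLMNPQRS", "ACD", 1, 0.0, seed=0)


class TestThemeScenario:
    def test_default_scenario_structure(self):
        s = sd.generate_theme_scenario(seed=0)
        assert len(s.truth) >= 1
        assert len(s.decoy_families) >= 2
        assert all(fam == "recipient" for _, fam in s.truth)

    def test_truth_windows_overlap_planted_segment(self):
        s = sd.generate_theme_scenario(seed=3)
        segments = sf.strand_segments(s.donor_ss, min_len=2)
        windows = dict(sf.make_windows(segments, k=4))
        t_lo = s.theme_position_donor
        t_hi = t_lo + len(s.theme) - 1
        for span, _ in s.truth:
            lo, hi = windows[span]
            overlap = min(hi, t_hi) - max(lo, t_lo) + 1
            assert overlap >= len(s.theme) / 2

    def test_decoys_never_in_truth(self):
        s = sd.generate_theme_scenario(seed=1)
        truth_targets = {fam for _, fam in s.truth}
        assert not any(fam.startswith("decoy") for fam in truth_targets)

    def test_sidecar_is_valid_json(self):
        import json

        s = sd.generate_theme_scenario(seed=2)
        payload = json.loads(s.truth_sidecar())
        assert payload["donor_family"] == "donor"
        assert payload["truth_pairs"]


class TestBtlStructure:
    def test_ca_trace_is_continuous(self, btl):
        d = np.linalg.norm(np.diff(btl.ca, axis=0), axis=1)
        assert d.min() > 3.7 and d.max() < 3.9

    def test_planted_water_has_three_short_backbone_partners(self, btl):
        w = btl.structure.waters[0].coord
        close = [
            (r.number, nm)
            for r in btl.structure.residues
            for nm in ("N", "O")
            if nm in r.atoms and np.linalg.norm(r.atoms[nm] - w) <= 3.0
        ]
        assert sorted(close) == sorted((i, a) for i, a in btl.water_partners)

    def test_partner_contexts_are_strand_strand_loop(self, btl):
        ctx = [btl.ss[i - 1] for i, _ in btl.water_partners]
        assert sorted(ctx) == ["C", "E", "E"]

    def test_dry_variant_has_no_water_and_proline_donor(self, btl_dry):
        assert btl_dry.structure.waters == []
        assert all(
            btl_dry.sequence[i - 1] == "P" for i in btl_dry.donor_positions
        )
        assert btl_dry.is_dry

    def test_self_alignment_tm_is_one(self, btl, btl_motif):
        hit = sm.motif_search(btl_motif, btl.ca, "self")
        assert hit.tm_score == pytest.approx(1.0, abs=1e-6)

    def test_same_seed_identical(self):
        a = sd.generate_btl_structure(0.3, seed=9)
        b = sd.generate_btl_structure(0.3, seed=9)
        assert np.array_equal(a.ca, b.ca)


class TestDecoys:
    def test_helix_decoy_assigned_mostly_h(self, helix_decoy):
        ss = sf.assign_ss(helix_decoy.structure)
        assert ss.count("H") / len(ss) >= 0.8

    def test_random_coil_has_no_water_motif(self, coil_decoy):
        reports = sm.find_water_motif(
            coil_decoy.structure,
            [r.number for r in coil_decoy.structure.residues],
            ss=coil_decoy.ss,
        )
        assert reports == []

    def test_decoy_determinism(self):
        a = sd.generate_decoy_structure(25, "random_coil", seed=5)
        b = sd.generate_decoy_structure(25, "random_coil", seed=5)
        assert np.array_equal(a.ca, b.ca)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_decoy_structure(25, "sheet", seed=0)
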