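import numpy as np
import pytest

from trefoil_themes import profile_hmm as ph
from trefoil_themes import secstruct_fragments as sf
from trefoil_themes.formats_io import MSA

from oracles import enumerate_local_paths, random_profile_hmm


class TestBuildHmm:
    def test_single_sequence_emission_formula(self):
        alpha = 0.5
        msa = MSA("m", [("m", "ACD")])
        hmm = ph.build_hmm(msa, pseudocount_alpha=alpha, background="uniform")
        assert hmm.M == 3
        bg_a = 0.05
        expected = (1 + alpha * bg_a) / (1 + alpha)
        assert hmm.match_emissions[0, ph.AA_ORDER.index("A")] == pytest.approx(expected)

    def test_low_occupancy_column_becomes_insert(self):
        rows = [("m", "AC"), ("a", "A-"), ("b", "A-"), ("c", "A-"), ("d", "A-")]
        hmm = ph.build_hmm(MSA("m", rows), occupancy_min=0.5)
        assert hmm.M == 1  # second column is 20% occupied -> insert

    def test_duplicate_rows_collapse_to_single_row_profile(self):
        single = ph.build_hmm(MSA("m", [("m", "ACDEF")]))
        dup = ph.build_hmm(
            MSA("m", [("m", "ACDEF")] + [(f"r{i}", "ACDEF") for i in range(99)])
        )
        assert np.allclose(single.match_emissions, dup.match_emissions, atol=1e-12)
        assert np.allclose(single.t_mm, dup.t_mm, atol=1e-12)

    def test_zero_match_columns_rejected(self):
        rows = [("m", "A"), ("a", "-"), ("b", "-"), ("c", "-")]
        with pytest.raises(ValueError):
            ph.build_hmm(MSA("m", rows), occupancy_min=0.5)

    def test_emissions_are_distributions(self):
        msa = MSA("m", [("m", "ACD-F"), ("x", "AC-EF"), ("y", "GCDEF")])
        hmm = ph.build_hmm(msa)
        assert np.allclose(hmm.match_emissions.sum(axis=1), 1.0)
        assert (hmm.match_emissions > 0).all()


class TestForwardScore:
    def test_one_state_match_is_log2_twenty(self):
        msa = MSA("m", [("m", "A")])
        hmm = ph.build_hmm(msa, pseudocount_alpha=1e-13, background="uniform")
        assert ph.forward_score(hmm, "A") == pytest.approx(np.log2(20.0), abs=1e-6)

    def test_matches_exhaustive_path_enumeration(self, rng):
        for _ in range(200):
            M = int(rng.integers(1, 4))
            L = int(rng.integers(1, 5))
            hmm = random_profile_hmm(rng, M)
            seq = "".join(rng.choice(list(ph.AA_ORDER), size=L))
            assert ph.forward_score(hmm, seq) == pytest.approx(
                enumerate_local_paths(hmm, seq, "sum"), abs=1e-9
            )

    def test_background_sequences_score_nonpositive_on_average(self, rng):
        msa = MSA("m", [("m", "ACDEFGHIKLMNPQRSTVWY")])
        hmm = ph.build_hmm(msa, background="uniform")
        scores = [
            ph.forward_score(hmm, "".join(rng.choice(list(ph.AA_ORDER), size=30)))
            for _ in range(300)
        ]
        assert np.mean(scores) <= 0.0

    def test_unknown_residue_scored_as_background(self):
        msa = MSA("m", [("m", "ACD")])
        hmm = ph.build_hmm(msa)
        assert np.isfinite(ph.forward_score(hmm, "AXD"))


class TestViterbi:
    def test_identity_alignment_on_master(self):
        msa = MSA("m", [("m", "ACDEFGHIK")])
        hmm = ph.build_hmm(msa, background="uniform")
        pairs, _ = ph.viterbi_align(hmm, "ACDEFGHIK")
        assert pairs == [(i, i) for i in range(1, 10)]

    def test_viterbi_never_exceeds_forward(self, rng):
        msa = MSA("m", [("m", "ACDEFGHIKL"), ("x", "ACDEFGWIKL")])
        hmm = ph.build_hmm(msa)
        for _ in range(100):
            seq = "".join(rng.choice(list(ph.AA_ORDER), size=int(rng.integers(3, 20))))
            _, v = ph.viterbi_align(hmm, seq)
            assert v <= ph.forward_score(hmm, seq) + 1e-9

    def test_matches_exhaustive_best_path(self, rng):
        for _ in range(200):
            M = int(rng.integers(1, 4))
            L = int(rng.integers(1, 5))
            hmm = random_profile_hmm(rng, M)
            seq = "".join(rng.choice(list(ph.AA_ORDER), size=L))
            score_o, pairs_o = enumerate_local_paths(hmm, seq, "max")
            pairs, score = ph.viterbi_align(hmm, seq)
            assert score == pytest.approx(score_o, abs=1e-9)
            assert pairs == pairs_o


class TestCalibration:
    def _calibrated(self, seed=0):
        msa = MSA("m", [("m", "ACDEFGHIKLMNPQR")])
        hmm = ph.build_hmm(msa)
        ph.calibrate_evalue(hmm, n_random=120, random_len=60, seed=seed)
        return hmm

    def test_evalue_at_mu_is_63_percent_of_db(self):
        hmm = self._calibrated()
        n = 500
        e = ph.evalue(hmm, hmm.calibration.fit.mu, db_size=n)
        assert e == pytest.approx(n * (1 - np.exp(-1)), rel=1e-6)

    def test_evalue_monotone_decreasing(self):
        hmm = self._calibrated()
        grid = np.linspace(-20, 60, 50)
        evs = [ph.evalue(hmm, s, 100) for s in grid]
        assert all(a >= b for a, b in zip(evs, evs[1:]))

    def test_evalue_scales_linearly_with_db_size(self):
        hmm = self._calibrated()
        assert ph.evalue(hmm, 10.0, 2000) == pytest.approx(2 * ph.evalue(hmm, 10.0, 1000))

    def test_uncalibrated_search_is_an_error(self):
        msa = MSA("m", [("m", "ACDEFGHIKLMNPQR")])
        hmm = ph.build_hmm(msa)
        with pytest.raises(RuntimeError):
            ph.search(hmm, [("t", "ACDEFG", "11.1.1")])

    def test_too_few_random_sequences_rejected(self):
        msa = MSA("m", [("m", "ACDEFGHIKLMNPQR")])
        hmm = ph.build_hmm(msa)
        with pytest.raises(ValueError):
            ph.calibrate_evalue(hmm, n_random=10)


class TestSearch:
    def _scenario_hits(self, scenario, evalue_max=1e-3, exclude=6):
        donor = scenario.families[0][0]
        segments = sf.strand_segments(scenario.donor_ss, min_len=2)
        windows = sf.make_windows(segments, k=4)
        db = scenario.database()
        out = {}
        for span, rng_ in windows:
            restricted = sf.restrict_msa(donor, rng_)
            hmm = ph.build_hmm(restricted, master_id=donor.master_id, strand_span=span)
            ph.calibrate_evalue(hmm, n_random=100, seed=11)
            out[span] = ph.search(hmm, db, evalue_max=evalue_max, exclude_xgroup=exclude)
        return out

    def test_exact_planted_theme_recovered(self, scenario_exact):
        hits_by_window = self._scenario_hits(scenario_exact)
        truth_spans = {span for span, _ in scenario_exact.truth}
        for span in truth_spans:
            rec = [h for h in hits_by_window[span] if h.target_domain.startswith("recipient")]
            assert rec and rec[0].evalue < 1e-3

    def test_exclude_xgroup_empties_matching_database(self, scenario_exact):
        donor = scenario_exact.families[0][0]
        segments = sf.strand_segments(scenario_exact.donor_ss, min_len=2)
        span, rng_ = sf.make_windows(segments, k=4)[0]
        restricted = sf.restrict_msa(donor, rng_)
        hmm = ph.build_hmm(restricted, master_id=donor.master_id, strand_span=span)
        ph.calibrate_evalue(hmm, n_random=100, seed=1)
        only_trefoil = [("t1", donor.master.replace("-", ""), "6.1.1")]
        assert ph.search(hmm, only_trefoil, exclude_xgroup=6) == []

    def test_evalue_max_zero_empties_results(self, scenario_exact):
        hits_by_window = self._scenario_hits(scenario_exact, evalue_max=0.0)
        assert all(not h for h in hits_by_window.values())

    def test_hits_sorted_by_evalue(self, scenario_exact):
        for hits in self._scenario_hits(scenario_exact).values():
            evs = [h.evalue for h in hits]
            assert evs == sorted(evs)
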