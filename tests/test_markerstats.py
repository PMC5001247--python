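"""Normalization, presence calling and the chi-square/FDR marker screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from isopept.markerstats import (MarkerRecord, bh_adjust, call_presence,
                                 classify_splicing, contingency_chisq,
                                 peptide_chisq, quantile_normalize,
                                 screen_markers, screen_study, storey_pi0,
                                 storey_qvalues)


class TestQuantileNormalize:
    def test_identical_columns_are_a_fixed_point(self):
        m = pd.DataFrame({"a": [1.0, 5.0, 3.0], "b": [1.0, 5.0, 3.0]})
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m)

    def test_rank_mean_by_hand(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        assert out["a"].tolist() == [2.5, 3.5, 4.5]
        assert out["b"].tolist() == [2.5, 3.5, 4.5]

    def test_rank_equivariance_under_row_permutation(self, rng):
        m = pd.DataFrame(rng.lognormal(size=(30, 4)),
                         columns=list("abcd"))
        out = quantile_normalize(m)
        perm = rng.permutation(30)
        m2 = m.copy()
        m2["b"] = m["b"].to_numpy()[perm]
        out2 = quantile_normalize(m2)
        assert np.allclose(out2["b"].to_numpy(), out["b"].to_numpy()[perm])

    def test_value_multisets_identical_after_normalization(self, rng):
        m = pd.DataFrame(rng.lognormal(size=(50, 3)))
        out = quantile_normalize(m)
        for col in out.columns[1:]:
            assert np.allclose(np.sort(out[col]), np.sort(out[0]))

    def test_missing_stays_missing_and_all_missing_rejected(self):
        m = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        assert np.isnan(out.loc[1, "a"])
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [np.nan], "b": [1.0]}))


class TestPresence:
    def test_threshold_direction_and_boundary(self):
        m = pd.DataFrame({"s1": [1.0, 5.0, 10.0]})
        out = call_presence(m, threshold=5.0)
        # at-threshold counts as present; below does not
        assert out["s1"].tolist() == [False, True, True]

    def test_all_below_threshold_all_absent(self):
        m = pd.DataFrame({"s1": [1.0, 2.0], "s2": [0.5, 1.5]})
        assert not call_presence(m, threshold=10.0).any().any()

    def test_missing_is_absent(self):
        m = pd.DataFrame({"s1": [np.nan, 50.0]})
        assert call_presence(m, threshold=0.0)["s1"].tolist() == [False, True]

    def test_auto_threshold_is_5th_percentile(self, rng):
        m = pd.DataFrame(rng.normal(10, 1, size=(100, 4)))
        out = call_presence(m, threshold="auto")
        frac = out.to_numpy().mean()
        assert 0.94 <= frac <= 0.96


class TestPeptideChisq:
    def test_identical_proportions_give_null(self):
        assert peptide_chisq(20, 40, 20, 40) == (0.0, 1.0)

    def test_closed_form_example(self):
        chi2, p = peptide_chisq(35, 40, 5, 40)
        assert chi2 == pytest.approx(45.0)
        assert p == pytest.approx(1.97e-11, rel=0.01)

    def test_degenerate_margin(self):
        assert peptide_chisq(0, 40, 0, 40) == (0.0, 1.0)
        assert peptide_chisq(40, 40, 40, 40) == (0.0, 1.0)

    def test_matches_scipy_contingency_without_correction(self, rng):
        for _ in range(50):
            n_h, n_c = int(rng.integers(2, 60)), int(rng.integers(2, 60))
            h, c = int(rng.integers(0, n_h + 1)), int(rng.integers(0, n_c + 1))
            chi2, p = peptide_chisq(h, n_h, c, n_c)
            table = np.array([[h, n_h - h], [c, n_c - c]])
            if (table.sum(axis=0) == 0).any():
                assert (chi2, p) == (0.0, 1.0)
                continue
            exp_chi2, exp_p, _, _ = sps.chi2_contingency(table, correction=False)
            assert chi2 == pytest.approx(exp_chi2)
            assert p == pytest.approx(exp_p)

    def test_zero_size_group_rejected(self):
        with pytest.raises(ValueError):
            peptide_chisq(0, 0, 1, 10)


class TestBH:
    def test_step_up_by_hand(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]).tolist() == [0.2]

    def test_outputs_dominate_inputs_and_order_invariance(self, rng):
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        perm = rng.permutation(40)
        assert np.allclose(bh_adjust(p[perm]), adj[perm])

    def test_empty(self):
        assert bh_adjust([]).size == 0


class TestStorey:
    def test_uniform_null_pi0_near_one_and_no_discoveries(self, rng):
        p = rng.uniform(size=2000)
        q, pi0 = storey_qvalues(p)
        assert 0.9 <= pi0 <= 1.0
        assert (q < 0.05).sum() == 0

    def test_all_tiny_pvalues(self):
        p = np.full(100, 1e-8)
        q, pi0 = storey_qvalues(p)
        assert (q <= 1e-8 + 1e-15).all()
        assert np.allclose(q, pi0 * 1e-8)

    def test_q_dominated_by_bh_when_pi0_below_one(self, rng):
        p = np.concatenate([rng.uniform(size=500) * 1e-4,
                            rng.uniform(size=1500)])
        q, pi0 = storey_qvalues(p)
        if pi0 <= 1.0:
            assert (q <= bh_adjust(p) + 1e-12).all()

    def test_order_invariance(self, rng):
        p = rng.uniform(size=300)
        q, _ = storey_qvalues(p)
        perm = rng.permutation(300)
        q2, _ = storey_qvalues(p[perm])
        assert np.allclose(q2, q[perm])

    def test_small_m_uses_fixed_lambda(self):
        p = np.array([0.8, 0.1, 0.2, 0.3])
        assert storey_pi0(p) == pytest.approx((p > 0.5).sum() / (4 * 0.5))
        # the estimate is clamped into (0, 1]
        assert storey_pi0(np.array([0.8, 0.9, 0.7, 0.6])) == 1.0

    def test_fewer_than_two_pvalues_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5])


class TestScreen:
    def make_records(self, qs):
        recs = []
        for i, q in enumerate(qs):
            r = MarkerRecord(peptide=f"p{i}", health_present=1,
                             cancer_present=30, n_health=40, n_cancer=40,
                             chi2=1.0, p=q)
            recs.append(r)
        return recs

    def test_fpr_is_alpha_times_count(self, rng):
        # 90 significant records: expected false positives 0.05 * 90
        p = np.concatenate([np.full(90, 1e-10), rng.uniform(0.2, 1, 910)])
        res = screen_markers(self.make_records(p), alpha=0.05)
        assert len(res.selected) == 90
        assert res.fpr == pytest.approx(4.5)

    def test_none_selected_and_alpha_zero(self, rng):
        res = screen_markers(self.make_records(rng.uniform(0.5, 1, 200)))
        assert res.selected == [] and res.fpr == 0.0
        res0 = screen_markers(self.make_records(np.full(200, 1e-9)), alpha=0.0)
        assert res0.selected == []

    def test_screen_study_end_to_end_recovers_planted(self):
        from isopept.synthdata import SimulationConfig, simulate_study
        cfg = SimulationConfig(seed=11, n_planted=10, n_null_peptides=300)
        intensities, groups, truth = simulate_study(cfg)
        res, presence = screen_study(intensities, groups)
        planted = set(truth.loc[truth["planted"], "peptide"])
        selected = {r.peptide for r in res.selected}
        assert len(selected & planted) >= 9
        assert len(selected - planted) <= 2
        assert presence.shape == intensities.shape

    def test_null_type_one_rate_matches_exact_size(self):
        # oracle: exact size of the discrete test at presence prob 0.5,
        # 40 v 40, by full binomial enumeration of the 2x2 tables
        from scipy.stats import binom
        probs = binom.pmf(np.arange(41), 40, 0.5)
        size = sum(probs[h] * probs[c]
                   for h in range(41) for c in range(41)
                   if peptide_chisq(h, 40, c, 40)[1] < 0.05)
        assert abs(size - 0.05) <= 0.01
        # seeded null simulation: empirical fraction within binomial
        # tolerance of the exact size, and q<0.05 declares ~nothing
        from isopept.synthdata import SimulationConfig, simulate_study
        cfg = SimulationConfig(seed=0, n_planted=0, n_null_peptides=2000)
        intensities, groups, _ = simulate_study(cfg)
        res, _ = screen_study(intensities, groups)
        frac = np.mean([r.p < 0.05 for r in res.records])
        assert abs(frac - size) <= 3 * np.sqrt(size * (1 - size) / 2000)
        assert len(res.selected) <= 2

    def test_direction(self):
        r = MarkerRecord("p", 5, 35, 40, 40, 1.0, 0.01)
        assert r.direction == "cancer"
        r2 = MarkerRecord("p", 35, 5, 40, 40, 1.0, 0.01)
        assert r2.direction == "health"


class TestClassifySplicing:
    @pytest.mark.parametrize("jtype, cls", [
        ("EXON", "single_exon"),
        ("E_E_SKIP", "exon_splicing"),
        ("E_E_NORMAL", "normal_exon"),
        ("E_I", "intron_retention_right"),
        ("I_E", "intron_retention_left"),
    ])
    def test_mapping(self, jtype, cls):
        assert classify_splicing(jtype) == cls

    def test_enum_accepted_and_unknown_rejected(self):
        from isopept.ijpdb import JunctionType
        assert classify_splicing(JunctionType.I_E) == "intron_retention_left"
        with pytest.raises(ValueError):
            classify_splicing("BOGUS")


class TestContingency:
    def test_marker_class_table_with_yates(self):
        chi2, df, p = contingency_chisq([[7, 60], [22, 1]], yates=True)
        assert round(chi2) == 53
        assert chi2 == pytest.approx(53.08, abs=0.01)
        assert df == 1
        assert p == pytest.approx(3.2e-13, rel=0.05)

    def test_transcript_multiplicity_table_without_yates(self):
        chi2, df, p = contingency_chisq([[30370, 19136], [3, 35]], yates=False)
        assert p == pytest.approx(1.35e-11, rel=0.05)

    def test_balanced_table_is_null(self):
        chi2, df, p = contingency_chisq([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == 1.0

    def test_uncorrected_equals_closed_form(self, rng):
        for _ in range(30):
            a, b, c, d = [int(x) for x in rng.integers(1, 200, size=4)]
            chi2, _, _ = contingency_chisq([[a, b], [c, d]])
            n = a + b + c + d
            closed = n * (a * d - b * c) ** 2 / \
                ((a + b) * (c + d) * (a + c) * (b + d))
            assert chi2 == pytest.approx(closed)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            contingency_chisq([[0, 0], [5, 5]])
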