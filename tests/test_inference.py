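"""Nested-model F-tests, BH adjustment, and differential abundance."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import turnoverkit as tk
from turnoverkit.errors import ContractError, DomainError


def two_group_series(k_pf, k_ef, six_day_grid, sigma=0.0, rng=None,
                     ess=(0.10,), e0=0.02, parent="prot"):
    out_pf, out_ef = [], []
    for i, e_ss in enumerate(ess):
        for group, k in (("PF", k_pf), ("EF", k_ef)):
            mu = tk.predict_labeling(
                tk.OneCompartmentParams(e0=e0, ess=e_ss, k=k), six_day_grid
            )
            if sigma > 0:
                mu = np.clip(mu + sigma * rng.standard_normal(mu.size), 0, 1)
            s = tk.PeptideTimeCourse(f"pep{i}", parent, group, six_day_grid, mu)
            (out_pf if group == "PF" else out_ef).append(s)
    return out_pf, out_ef


class TestCompareTurnover:
    def test_f_statistic_definition_and_upper_tail(self, six_day_grid, rng):
        pf, ef = two_group_series(0.15, 0.30, six_day_grid, sigma=0.004, rng=rng)
        c = tk.compare_turnover(pf, ef)
        # F must equal its nested-RSS definition and p its F upper tail
        assert c.F == pytest.approx(
            (c.rss_reduced - c.rss_full) / (c.rss_full / c.df_den), rel=1e-9
        )
        assert c.p == pytest.approx(float(scipy.stats.f.sf(c.F, 1, c.df_den)), rel=1e-9)
        assert c.rss_reduced >= c.rss_full
        assert c.log2_fold_change == pytest.approx(math.log2(c.k_ef / c.k_pf))

    def test_constructed_f_oracle(self):
        # constructed nested-RSS example: RSS_reduced=1.2, RSS_full=1.0,
        # df=(1, 50) -> F=10; upper-tail p checked against the independent
        # identity F(1, n) = t(n)^2, i.e. p = 2 * P(t_50 > sqrt(10))
        F = ((1.2 - 1.0) / 1) / (1.0 / 50)
        assert F == pytest.approx(10.0)
        p_f = float(scipy.stats.f.sf(F, 1, 50))
        p_t = 2 * float(scipy.stats.t.sf(math.sqrt(F), 50))
        assert p_f == pytest.approx(p_t, rel=1e-10)
        assert p_f == pytest.approx(0.00266, abs=5e-5)

    def test_identical_groups_give_null_result(self, six_day_grid, rng):
        pf, _ = two_group_series(0.2, 0.2, six_day_grid, sigma=0.005, rng=rng)
        ef = [tk.PeptideTimeCourse(s.peptide_id, s.parent_id, "EF", s.times, s.values)
              for s in pf]
        c = tk.compare_turnover(pf, ef)
        assert c.F == pytest.approx(0.0, abs=1e-6)
        assert abs(c.log2_fold_change) < 1e-4
        assert c.p > 0.99

    def test_group_permutation_inverts_fold_change(self, six_day_grid, rng):
        pf, ef = two_group_series(0.12, 0.20, six_day_grid, sigma=0.005, rng=rng)
        c1 = tk.compare_turnover(pf, ef)
        swapped_pf = [tk.PeptideTimeCourse(s.peptide_id, s.parent_id, "PF", s.times, s.values)
                      for s in ef]
        swapped_ef = [tk.PeptideTimeCourse(s.peptide_id, s.parent_id, "EF", s.times, s.values)
                      for s in pf]
        c2 = tk.compare_turnover(swapped_pf, swapped_ef)
        # coordinate descent alternates PF-then-EF, so the swapped problem
        # follows a mirrored optimization path; agreement is to the descent
        # convergence tolerance rather than machine precision
        assert c2.F == pytest.approx(c1.F, rel=5e-3, abs=1e-6)
        assert c2.log2_fold_change == pytest.approx(-c1.log2_fold_change, rel=5e-3)

    def test_mixed_parents_rejected(self, six_day_grid, rng):
        pf, ef = two_group_series(0.15, 0.2, six_day_grid, sigma=0.003, rng=rng)
        ef[0].parent_id = "other"
        with pytest.raises(ContractError):
            tk.compare_turnover(pf, ef)

    def test_flat_group_skipped_with_reason(self, six_day_grid):
        pf = [tk.PeptideTimeCourse("pep0", "prot", "PF", six_day_grid, np.full(6, 0.02))]
        mu = tk.predict_labeling(
            tk.OneCompartmentParams(e0=0.02, ess=0.1, k=0.2), six_day_grid
        )
        ef = [tk.PeptideTimeCourse("pep0", "prot", "EF", six_day_grid, mu)]
        c = tk.compare_turnover(pf, ef)
        assert not c.tested
        assert "PF" in c.skipped_reason


class TestBHAdjust:
    def test_hand_applied_step_up(self):
        assert tk.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_identity_and_edge_cases(self):
        assert tk.bh_adjust([0.037]) == pytest.approx([0.037])
        assert tk.bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])
        assert tk.bh_adjust([]) == []

    def test_order_preserved_and_monotone(self):
        p = [0.04, 0.001, 0.9, 0.02]
        adj = tk.bh_adjust(p)
        # adjusted values never below raw, and ranking by p preserved
        assert all(a >= r for a, r in zip(adj, p))
        order = np.argsort(p)
        assert all(np.diff(np.asarray(adj)[order]) >= -1e-12)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.2], [float("nan")]])
    def test_domain_violations(self, bad):
        with pytest.raises(DomainError):
            tk.bh_adjust(bad)


class TestDifferentialAbundance:
    def test_identical_groups(self):
        table = pd.DataFrame([[1, 2, 3, 1, 2, 3]], index=["f1"],
                             columns=list("abcdef"))
        res = tk.differential_abundance(table, ["PF"] * 3 + ["EF"] * 3)
        assert res[0].t_stat == pytest.approx(0.0)
        assert res[0].p == pytest.approx(1.0)

    def test_welch_matches_hand_computation(self):
        pf, ef = np.array([1.0, 2, 3, 4]), np.array([3.0, 4, 5, 6])
        table = pd.DataFrame([np.concatenate([pf, ef])], index=["f1"],
                             columns=[f"s{i}" for i in range(8)])
        res = tk.differential_abundance(table, ["PF"] * 4 + ["EF"] * 4)
        # hand computation of the Welch statistic and Satterthwaite df
        se2 = pf.var(ddof=1) / 4 + ef.var(ddof=1) / 4
        t_hand = (ef.mean() - pf.mean()) / math.sqrt(se2)
        df_hand = se2**2 / (
            (pf.var(ddof=1) / 4) ** 2 / 3 + (ef.var(ddof=1) / 4) ** 2 / 3
        )
        p_hand = 2 * scipy.stats.t.sf(abs(t_hand), df_hand)
        assert res[0].t_stat == pytest.approx(t_hand)
        assert res[0].p == pytest.approx(p_hand)
        assert res[0].log2_fc == pytest.approx(2.0)

    def test_undersized_group_reported_untested(self):
        table = pd.DataFrame([[1.0, 2.0, 3.0, 5.0]], index=["f1"],
                             columns=["a", "b", "c", "d"])
        res = tk.differential_abundance(table, ["PF", "PF", "PF", "EF"])
        assert not res[0].tested
        assert math.isnan(res[0].p)

    def test_bh_applied_across_tested_features(self, rng):
        table, groups, _ = tk.generate_intensity_table(
            50, [0.0] * 50, sigma=0.3, n_per_group=5, seed=9
        )
        res = tk.differential_abundance(table, groups)
        assert all(r.p_adj >= r.p - 1e-12 for r in res if r.tested)
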