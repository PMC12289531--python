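"""Two-group inference on turnover rates and log2 abundance tables.

Turnover comparisons between the ethanol-fed (EF) and pair-fed (PF) groups
use a nested-model F-test on the one-compartment fits: the full model gives
each group its own rate constant while sharing each peptide's (E0, Ess)
across groups (body-water enrichment was matched between groups, so the
plateau and baseline are properties of the peptide, not the diet); the
reduced model forces a single common k. With Gaussian residuals,

    F = [(RSS_reduced - RSS_full) / 1] / [RSS_full / (n - p_full)]

is referred to the F(1, n - p_full) upper tail. Multiplicity is controlled
per analysis family (native proteins, acetyl-sites, differential abundance)
with the Benjamini-Hochberg step-up procedure, and differential abundance on
log2 intensities uses a per-feature two-sample t-test (Welch by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError
from .kinetics import (
    FitOptions,
    PeptideTimeCourse,
    fit_joint,
    golden_section,
    _moments,
    solve_linear_subproblem,
)

__all__ = [
    "NestedModelComparison",
    "DifferentialResult",
    "compare_turnover",
    "bh_adjust",
    "differential_abundance",
]


@dataclass
class NestedModelComparison:
    """Full (two-rate) vs reduced (common-rate) comparison for one parent.

    ``skipped_reason`` is non-empty when either group's fit did not converge;
    statistical fields are then NaN and the record must be excluded from the
    FDR family.
    """

    parent_id: str
    k_pf: float = math.nan
    k_ef: float = math.nan
    log2_fold_change: float = math.nan
    rss_full: float = math.nan
    rss_reduced: float = math.nan
    df_num: int = 1
    df_den: int = 0
    F: float = math.nan
    p: float = math.nan
    p_adj: float = math.nan
    skipped_reason: str = ""

    @property
    def tested(self) -> bool:
        return not self.skipped_reason


@dataclass
class DifferentialResult:
    """Per-feature two-sample test on log2 intensities (EF minus PF)."""

    feature_id: str
    log2_fc: float = math.nan
    t_stat: float = math.nan
    p: float = math.nan
    p_adj: float = math.nan
    n_pf: int = 0
    n_ef: int = 0
    reason: str = ""

    @property
    def tested(self) -> bool:
        return not self.reason


def _match_peptides(series_pf, series_ef):
    """Group both arms' series by peptide id, preserving input order."""
    by_pep: dict[str, dict[str, PeptideTimeCourse]] = {}
    for s in series_pf:
        by_pep.setdefault(s.peptide_id, {})["PF"] = s
    for s in series_ef:
        by_pep.setdefault(s.peptide_id, {})["EF"] = s
    return by_pep


def compare_turnover(
    series_pf: Sequence[PeptideTimeCourse],
    series_ef: Sequence[PeptideTimeCourse],
    options: FitOptions | None = None,
) -> NestedModelComparison:
    """Nested-model F-test for a between-group change in turnover rate.

    Both arms must carry the same ``parent_id``. Peptides are matched by id;
    each matched peptide contributes one shared (E0, Ess) pair, estimated
    from both groups jointly. Fold change is reported as log2(k_EF / k_PF).
    Non-converged single-group fits yield a skipped record with a reason
    code instead of a p-value.
    """
    opts = options or FitOptions()
    series_pf = list(series_pf)
    series_ef = list(series_ef)
    parents = {s.parent_id for s in series_pf} | {s.parent_id for s in series_ef}
    if len(parents) != 1:
        from .errors import ContractError

        raise ContractError(f"compare_turnover requires a single parent id, got {sorted(parents)}")
    parent = parents.pop()

    fit_pf = fit_joint(series_pf, opts)
    fit_ef = fit_joint(series_ef, opts)
    if not fit_pf.converged or not fit_ef.converged:
        bad = []
        if not fit_pf.converged:
            bad.append(f"PF: {fit_pf.message}")
        if not fit_ef.converged:
            bad.append(f"EF: {fit_ef.message}")
        return NestedModelComparison(parent_id=parent, skipped_reason="; ".join(bad))

    by_pep = _match_peptides(series_pf, series_ef)
    pep_ids = list(by_pep)
    # per peptide: times, values, and a group indicator (0 = PF, 1 = EF)
    data = []
    for pid in pep_ids:
        arms = by_pep[pid]
        t = np.concatenate([arms[g].times for g in ("PF", "EF") if g in arms])
        e = np.concatenate([arms[g].values for g in ("PF", "EF") if g in arms])
        g = np.concatenate(
            [np.full(arms[g].n_obs, 0.0 if g == "PF" else 1.0) for g in ("PF", "EF") if g in arms]
        )
        data.append((t, e, g))

    n_obs = int(sum(t.size for t, _, _ in data))
    per_pep = 1 if opts.pin_e0 else 2
    p_full = per_pep * len(pep_ids) + 2
    df_den = n_obs - p_full
    if df_den < 1:
        return NestedModelComparison(
            parent_id=parent, skipped_reason=f"df_den={df_den} < 1 for the full model"
        )

    lo, hi = opts.k_bounds

    def rss_two_rates(k_pf_arr: np.ndarray, k_ef_arr: np.ndarray) -> np.ndarray:
        k_pf_arr = np.clip(np.asarray(k_pf_arr, float), lo, hi)
        k_ef_arr = np.clip(np.asarray(k_ef_arr, float), lo, hi)
        total = np.zeros(np.broadcast(k_pf_arr, k_ef_arr).shape)
        for t, e, g in data:
            k_slot = np.where(g > 0.5, k_ef_arr[..., None], k_pf_arr[..., None])
            x = -np.expm1(-k_slot * t)
            n, sx, sxx, se, sxe, see = _moments(x, e)
            _, _, rss = solve_linear_subproblem(n, sx, sxx, se, sxe, see, opts.pin_e0)
            total = total + rss
        return total

    # reduced model: common k (identical to the full model on its diagonal)
    grid = np.geomspace(lo, hi, opts.n_grid)
    rss_grid = rss_two_rates(grid, grid)
    i = int(np.argmin(rss_grid))
    k_ref, rss_ref = golden_section(
        lambda k: rss_two_rates(k, k),
        np.array(grid[max(i - 1, 0)]),
        np.array(grid[min(i + 1, grid.size - 1)]),
        opts.rel_tol,
    )
    if float(rss_grid[i]) < float(rss_ref):
        k_red, rss_reduced = float(grid[i]), float(rss_grid[i])
    else:
        k_red, rss_reduced = float(k_ref), float(rss_ref)

    # full model: coordinate descent from the reduced optimum in
    # mean-ratio coordinates k_PF = s/r, k_EF = s*r. The shared per-peptide
    # (E0, Ess) couple the two rates, so the RSS valley runs diagonally in
    # (k_PF, k_EF); the (s, r) axes align with it and alternation converges
    # in a few sweeps. RSS can only improve on RSS_reduced (nesting).
    s_hat, r_hat, rss_full = k_red, 1.0, rss_reduced
    r_lo, r_hi = math.sqrt(lo / hi), math.sqrt(hi / lo)
    for _ in range(4):
        prev = rss_full
        x_r, f_r = golden_section(
            lambda r: rss_two_rates(s_hat / r, s_hat * r),
            np.array(r_lo), np.array(r_hi), opts.rel_tol,
        )
        if float(f_r) < rss_full:
            r_hat, rss_full = float(x_r), float(f_r)
        x_s, f_s = golden_section(
            lambda s: rss_two_rates(s / r_hat, s * r_hat),
            np.array(lo), np.array(hi), opts.rel_tol,
        )
        if float(f_s) < rss_full:
            s_hat, rss_full = float(x_s), float(f_s)
        if prev - rss_full <= 1e-13 * max(prev, 1e-30):
            break
    k_pf_hat = float(np.clip(s_hat / r_hat, lo, hi))
    k_ef_hat = float(np.clip(s_hat * r_hat, lo, hi))

    num = max(rss_reduced - rss_full, 0.0)
    scale = rss_full / df_den
    F = num / scale if scale > 0 else (0.0 if num == 0.0 else math.inf)
    p = float(scipy.stats.f.sf(F, 1, df_den))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return NestedModelComparison(
        parent_id=parent,
        k_pf=k_pf_hat,
        k_ef=k_ef_hat,
        log2_fold_change=math.log2(k_ef_hat / k_pf_hat),
        rss_full=rss_full,
        rss_reduced=rss_reduced,
        df_num=1,
        df_den=df_den,
        F=F,
        p=p,
    )


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def differential_abundance(
    log2_table: pd.DataFrame,
    groups: Sequence[str],
    equal_var: bool = False,
) -> list[DifferentialResult]:
    """Per-feature two-sample t-tests on a log2 intensity table.

    ``log2_table`` is features x samples; ``groups`` labels each column as
    "PF" or "EF". Missing values (NaN) are dropped per feature; features
    with fewer than two remaining samples in either group are reported
    untested. ``log2_fc`` is mean(EF) - mean(PF). Welch's unequal-variance
    form is the default; set ``equal_var=True`` for the pooled-variance test.
    BH adjustment runs across all tested features.
    """
    groups = np.asarray([str(g) for g in groups])
    if groups.size != log2_table.shape[1]:
        raise DomainError("one group label per sample column required")
    unknown = set(groups) - {"PF", "EF"}
    if unknown:
        raise DomainError(f"unknown group labels: {sorted(unknown)}")

    results: list[DifferentialResult] = []
    for feature_id, row in log2_table.iterrows():
        vals = row.to_numpy(dtype=float)
        pf = vals[(groups == "PF") & np.isfinite(vals)]
        ef = vals[(groups == "EF") & np.isfinite(vals)]
        res = DifferentialResult(feature_id=str(feature_id), n_pf=pf.size, n_ef=ef.size)
        if pf.size < 2 or ef.size < 2:
            res.reason = "fewer than 2 samples in a group"
            results.append(res)
            continue
        res.log2_fc = float(ef.mean() - pf.mean())
        if pf.var(ddof=1) == 0.0 and ef.var(ddof=1) == 0.0:
            if ef.mean() == pf.mean():
                res.t_stat, res.p = 0.0, 1.0
            else:
                res.reason = "exact separation (zero variance, unequal means)"
            results.append(res)
            continue
        t_stat, p = scipy.stats.ttest_ind(ef, pf, equal_var=equal_var)
        res.t_stat = float(t_stat)
        res.p = min(max(float(p), np.finfo(float).tiny), 1.0)
        results.append(res)

    tested = [r for r in results if r.tested]
    if tested:
        adj = bh_adjust([r.p for r in tested])
        for r, a in zip(tested, adj):
            r.p_adj = float(a)
    return results


def adjust_comparisons(comparisons: Sequence[NestedModelComparison]) -> None:
    """Apply BH adjustment in place across one family of turnover tests."""
    tested = [c for c in comparisons if c.tested]
    if tested:
        adj = bh_adjust([c.p for c in tested])
        for c, a in zip(tested, adj):
            c.p_adj = float(a)
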