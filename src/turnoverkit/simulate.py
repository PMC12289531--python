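"""Synthetic data with known ground truth for every pipeline input.

Emulates the heavy-water labeling study design: two diet groups (pair-fed
PF, ethanol-fed EF) of terminally sampled animals on a multi-day time grid;
peptide labeling E(t) following the one-compartment model with
peptide-specific plateaus and Gaussian measurement noise; planted
turnover-rate fold changes organized by subcellular compartment
(mitochondrial rates fall under EF, cytosolic rates rise); log2 intensity
tables with planted mean shifts; and deuteroacetylated histone MS1/MS2
fixtures with known site stoichiometries. Every generator returns its
ground truth alongside the data so recovery tests are self-contained.

All randomness flows from a single integer seed per design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DomainError
from .kinetics import OneCompartmentParams, predict_labeling
from .stoichiometry import (
    H3_PEPTIDE,
    H4_PEPTIDE,
    H3_SITES,
    H4_SITES,
    H4_ION_COVERAGE,
    _PEPTIDE_SITES,
)

__all__ = [
    "BodyWaterParams",
    "SiteSpec",
    "ProteinSpec",
    "SyntheticDesign",
    "generate_body_water",
    "generate_timecourses",
    "generate_intensity_table",
    "generate_histone_fixture",
    "default_two_group_design",
]

TIMECOURSE_COLUMNS = [
    "dataset_id", "group", "animal_id", "time_days",
    "parent_id", "parent_kind", "peptide_id", "E",
]


@dataclass(frozen=True)
class BodyWaterParams:
    """Single-exponential body-water enrichment curve.

    A priming bolus sets the initial enrichment ``p0``; maintenance via
    heavy water in drinking water drives the approach to ``plateau``
    (default 0.035, i.e. the 3.5% steady state) at ``rise_rate`` per day.
    """

    p0: float = 0.02
    plateau: float = 0.035
    rise_rate: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.plateau < 1.0):
            raise DomainError("plateau must lie in (0, 1)")
        if not (0.0 <= self.p0 <= self.plateau):
            raise DomainError("bolus enrichment must lie in [0, plateau]")
        if not self.rise_rate > 0:
            raise DomainError("rise rate must be positive")


def generate_body_water(params: BodyWaterParams, times) -> np.ndarray:
    """p(t) = p_ss - (p_ss - p0) exp(-r t); monotone nondecreasing."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise DomainError("times must be nonnegative")
    return params.plateau - (params.plateau - params.p0) * np.exp(-params.rise_rate * t)


@dataclass(frozen=True)
class SiteSpec:
    """One acetyl-lysine site with its own turnover kinetics."""

    site: str  # e.g. "K307"
    k_pf: float
    fold_change_ef: float = 1.0

    def __post_init__(self) -> None:
        if not self.k_pf > 0 or not self.fold_change_ef > 0:
            raise DomainError("rates and fold changes must be positive")


@dataclass(frozen=True)
class ProteinSpec:
    """One parent protein: peptides share k within a group; plateaus differ."""

    protein_id: str
    compartment: str = "other"  # mitochondrial | cytosolic | nuclear | other
    n_peptides: int = 3
    k_pf: float = 0.15
    fold_change_ef: float = 1.0
    ess: tuple[float, ...] | None = None  # per-peptide plateaus; drawn if None
    acetyl_sites: tuple[SiteSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.n_peptides < 1:
            raise DomainError("n_peptides must be >= 1")
        if not self.k_pf > 0 or not self.fold_change_ef > 0:
            raise DomainError("rates and fold changes must be positive")
        if self.ess is not None and len(self.ess) != self.n_peptides:
            raise ContractError("ess must list one plateau per peptide")


@dataclass(frozen=True)
class SyntheticDesign:
    """Two-group terminal-sampling labeling design with planted effects."""

    proteins: tuple[ProteinSpec, ...]
    n_per_group: int = 9
    time_grid_days: tuple[float, ...] = (0.0, 1.0, 3.0, 7.0, 14.0, 21.0)
    ess_range: tuple[float, float] = (0.05, 0.15)
    e0_true: float = 0.02
    sigma_e: float = 0.005
    body_water: BodyWaterParams = field(default_factory=BodyWaterParams)
    dataset_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ContractError("design needs at least one protein")
        if len(set(self.time_grid_days)) < 3:
            raise DomainError("time grid needs >= 3 distinct values")
        if not self.sigma_e >= 0:
            raise DomainError("sigma_e must be nonnegative")


def _animal_times(design: SyntheticDesign) -> np.ndarray:
    grid = np.asarray(design.time_grid_days, dtype=float)
    return grid[np.arange(design.n_per_group) % grid.size]


def generate_timecourses(
    design: SyntheticDesign,
) -> tuple[pd.DataFrame, dict]:
    """Per-animal/peptide labeling table plus ground truth.

    Each animal contributes one terminal time point (round-robin over the
    grid). E values are one-compartment predictions plus truncated Gaussian
    noise; ``sigma_e = 0`` reproduces the model exactly. The same seed gives
    a byte-identical table.
    """
    rng = np.random.default_rng(design.seed)
    times = _animal_times(design)
    rows: list[dict] = []
    truth: dict = {"seed": design.seed, "parents": {}}

    def emit_parent(parent_id, kind, compartment, k_pf, fold_change, peptide_specs):
        k = {"PF": k_pf, "EF": k_pf * fold_change}
        truth["parents"][parent_id] = {
            "kind": kind,
            "compartment": compartment,
            "k_pf": k["PF"],
            "k_ef": k["EF"],
            "fold_change": fold_change,
            "is_changed": not math.isclose(fold_change, 1.0),
            "ess": {},
        }
        for pep_id, ess in peptide_specs:
            truth["parents"][parent_id]["ess"][pep_id] = ess
            for group in ("PF", "EF"):
                params = OneCompartmentParams(e0=design.e0_true, ess=ess, k=k[group])
                mu = predict_labeling(params, times)
                noise = rng.standard_normal(times.size) * design.sigma_e
                e_obs = np.clip(mu + noise, 0.0, 1.0)
                for i, (t, e) in enumerate(zip(times, e_obs)):
                    rows.append(
                        {
                            "dataset_id": design.dataset_id,
                            "group": group,
                            "animal_id": f"{group}_a{i + 1}",
                            "time_days": float(t),
                            "parent_id": parent_id,
                            "parent_kind": kind,
                            "peptide_id": pep_id,
                            "E": float(e),
                        }
                    )

    for prot in design.proteins:
        if prot.ess is not None:
            plateaus = list(prot.ess)
        else:
            plateaus = list(rng.uniform(*design.ess_range, size=prot.n_peptides))
        pep_specs = [
            (f"{prot.protein_id}_pep{j + 1}", float(plateaus[j]))
            for j in range(prot.n_peptides)
        ]
        emit_parent(
            prot.protein_id, "protein", prot.compartment,
            prot.k_pf, prot.fold_change_ef, pep_specs,
        )
        for site in prot.acetyl_sites:
            site_parent = f"{prot.protein_id}-{site.site}"
            ess_site = float(rng.uniform(*design.ess_range))
            emit_parent(
                site_parent, "acetyl_site", prot.compartment,
                site.k_pf, site.fold_change_ef,
                [(f"{site_parent}_pep1", ess_site)],
            )

    return pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS), truth


def default_two_group_design(
    n_proteins: int = 60,
    n_mito_down: int | None = None,
    n_cyto_up: int | None = None,
    fold: float = 1.5,
    n_peptides: int = 3,
    sigma_e: float = 0.005,
    seed: int = 0,
    k_base: float = 0.15,
) -> SyntheticDesign:
    """Compartment-effect template: under EF, mitochondrial turnover falls
    by ``fold`` and cytosolic turnover rises by ``fold``; the remaining
    parents are unchanged nulls. Planted counts default to one sixth of the
    proteins per direction (10 + 10 on the 60-protein default)."""
    if n_mito_down is None:
        n_mito_down = max(1, n_proteins // 6)
    if n_cyto_up is None:
        n_cyto_up = max(1, n_proteins // 6)
    if n_mito_down + n_cyto_up > n_proteins:
        raise ContractError("more planted effects than proteins")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_proteins):
        if i < n_mito_down:
            compartment, fc = "mitochondrial", 1.0 / fold
        elif i < n_mito_down + n_cyto_up:
            compartment, fc = "cytosolic", fold
        else:
            compartment, fc = "other", 1.0
        # modest between-protein spread of baseline rates
        k_pf = float(k_base * rng.uniform(0.6, 1.6))
        specs.append(
            ProteinSpec(
                protein_id=f"P{i + 1:03d}",
                compartment=compartment,
                n_peptides=n_peptides,
                k_pf=k_pf,
                fold_change_ef=fc,
            )
        )
    return SyntheticDesign(proteins=tuple(specs), sigma_e=sigma_e, seed=seed)


def generate_intensity_table(
    n_features: int,
    planted_log2_fc: Sequence[float],
    sigma: float,
    n_per_group: int = 9,
    seed: int = 0,
    base_log2: float = 20.0,
) -> tuple[pd.DataFrame, list[str], dict]:
    """Gaussian log2 intensity table with planted EF-vs-PF mean shifts.

    Returns (table, group labels, ground truth). Feature i has mean
    ``base_log2`` in PF and ``base_log2 + planted_log2_fc[i]`` in EF with
    independent N(0, sigma^2) noise.
    """
    if n_per_group < 2:
        raise DomainError("need >= 2 samples per group")
    if not sigma > 0:
        raise DomainError("sigma must be positive")
    fc = np.asarray(list(planted_log2_fc), dtype=float)
    if fc.size != n_features:
        raise ContractError("one planted log2 fold change per feature required")
    rng = np.random.default_rng(seed)
    pf = base_log2 + rng.standard_normal((n_features, n_per_group)) * sigma
    ef = (
        base_log2
        + fc[:, None]
        + rng.standard_normal((n_features, n_per_group)) * sigma
    )
    cols = [f"PF_s{i + 1}" for i in range(n_per_group)] + [
        f"EF_s{i + 1}" for i in range(n_per_group)
    ]
    table = pd.DataFrame(
        np.hstack([pf, ef]),
        index=[f"F{i + 1:04d}" for i in range(n_features)],
        columns=cols,
    )
    groups = ["PF"] * n_per_group + ["EF"] * n_per_group
    truth = {
        "planted_log2_fc": {f: float(v) for f, v in zip(table.index, fc)},
        "sigma": sigma,
        "seed": seed,
    }
    return table, groups, truth


# ---------------------------------------------------------------------------
# histone stoichiometry fixtures
# ---------------------------------------------------------------------------

def _canonical_mixture(peptide: str, truth: Mapping[str, float]) -> dict[frozenset, float]:
    """Unmodified + mono-acetyl mixture realizing the requested truth."""
    sites = _PEPTIDE_SITES[peptide]
    s = {site: float(truth.get(site, 0.0)) for site in sites}
    if any(v < 0 or v > 1 for v in s.values()):
        raise DomainError("stoichiometries must lie in [0, 1]")
    total = sum(s.values())
    if total > 1.0 + 1e-12:
        raise DomainError(
            f"infeasible truth: site stoichiometries sum to {total} > 1 "
            "(exceeds the total acetylated fraction available to mono forms)"
        )
    mixture = {frozenset(): 1.0 - total}
    for site, v in s.items():
        if v > 0:
            mixture[frozenset({site})] = v
    return mixture


def _truth_from_mixture(peptide: str, mixture: Mapping[frozenset, float]) -> dict[str, float]:
    sites = _PEPTIDE_SITES[peptide]
    return {
        site: sum(w for members, w in mixture.items() if site in members)
        for site in sites
    }


def generate_histone_fixture(
    peptide: str,
    true_stoichiometries: Mapping[str, float] | None = None,
    form_mixture: Mapping[frozenset, float] | None = None,
    noise_sigma: float = 0.0,
    sample: str = "s1",
    ms1_total: float = 1e6,
    ms2_scale: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """MS1/MS2 fragment table for a deuteroacetylated histone peptide.

    Either pass per-site ``true_stoichiometries`` (a canonical
    unmodified+mono mixture is constructed; infeasible truths with site sums
    above 1 raise) or an explicit ``form_mixture`` mapping frozensets of
    light sites to molar weights (may include multi-acetyl forms). Fragment
    intensities follow the telescoping light/heavy model; ``noise_sigma``
    applies multiplicative log-normal noise to every intensity. Returns the
    fragment table in the stoichiometry TSV schema plus the ground truth
    implied by the mixture.
    """
    if peptide not in _PEPTIDE_SITES:
        raise DomainError(f"unknown histone peptide {peptide!r}")
    sites = _PEPTIDE_SITES[peptide]
    if form_mixture is None:
        if true_stoichiometries is None:
            raise ContractError("need true_stoichiometries or form_mixture")
        form_mixture = _canonical_mixture(peptide, true_stoichiometries)
    else:
        form_mixture = {frozenset(k): float(v) for k, v in form_mixture.items()}
        bad = {s for members in form_mixture for s in members} - set(sites)
        if bad:
            raise DomainError(f"unknown sites for {peptide}: {sorted(bad)}")
    wsum = sum(form_mixture.values())
    if not math.isclose(wsum, 1.0, abs_tol=1e-9):
        raise DomainError(f"mixture weights sum to {wsum}, expected 1")

    rng = np.random.default_rng(seed)

    def jitter(x: float) -> float:
        if noise_sigma <= 0:
            return x
        return float(x * np.exp(noise_sigma * rng.standard_normal()))

    # group isomers into MS1-visible acetyl-count classes
    by_count: dict[int, dict[frozenset, float]] = {}
    for members, w in form_mixture.items():
        if w < 0:
            raise DomainError("mixture weights must be nonnegative")
        if w == 0:
            continue
        by_count.setdefault(len(members), {})[members] = w
    if 0 not in by_count:  # all-heavy reference form must exist for analysis
        by_count[0] = {frozenset(): 0.0}

    rows: list[dict] = []
    for count in sorted(by_count):
        isomers = by_count[count]
        class_w = sum(isomers.values())
        label = f"{count}ac"
        ms1 = jitter(ms1_total * class_w) if class_w > 0 else 0.0
        if count == 0 and class_w == 0.0:
            ms1 = 0.0
        ms2_total = max(ms1, 1.0) * ms2_scale if class_w > 0 else 0.0

        def add_ion(ion: str, light_fraction: float) -> None:
            rows.append(
                {
                    "peptide": peptide, "form_label": label, "sample": sample,
                    "ms1_intensity": ms1, "ion": ion, "channel": "light",
                    "intensity": jitter(ms2_total * light_fraction),
                }
            )
            rows.append(
                {
                    "peptide": peptide, "form_label": label, "sample": sample,
                    "ms1_intensity": ms1, "ion": ion, "channel": "heavy",
                    "intensity": jitter(ms2_total * (1.0 - light_fraction)),
                }
            )

        if peptide == H3_PEPTIDE:
            # b2 contains K18 only
            if class_w > 0:
                frac_k18 = sum(w for m, w in isomers.items() if "K18" in m) / class_w
            else:
                frac_k18 = 0.0
            add_ion("b2", frac_k18)
        else:
            for ion, covered in H4_ION_COVERAGE.items():
                if class_w > 0:
                    # fraction of the class's fragment signal in the light
                    # channel: molecules whose light site(s) fall in the ion
                    frac = sum(
                        w for m, w in isomers.items() if m & set(covered)
                    ) / class_w
                else:
                    frac = 0.0
                add_ion(ion, frac)

    table = pd.DataFrame(rows)
    truth = {
        "peptide": peptide,
        "site_stoichiometry": _truth_from_mixture(peptide, form_mixture),
        "form_mixture": {
            "+".join(sorted(m)) if m else "none": w for m, w in form_mixture.items()
        },
        "noise_sigma": noise_sigma,
        "seed": seed,
    }
    return table, truth
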