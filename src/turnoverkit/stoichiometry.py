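"""Site-specific histone acetylation stoichiometry from deuteroacetylated MS data.

Chemical derivatization with acetic anhydride-d6 converts every unmodified
lysine to a heavy acetyl (+45.0294 Da), so endogenous acetylation
(+42.0106 Da, "light") can be counted against a complete-acetylation
reference: after derivatization all forms of a peptide co-elute and the
light/heavy channels of its fragment ions report which lysine carried the
endogenous group.

Positional isomers (same acetyl count, different lysines) are isobaric at
MS1 and are resolved from MS2 fragments:

* H3 18-26 (KQLATKAAR, sites K18/K23): the b2 ion contains only K18, so the
  light share of b2 is the K18ac share of the monoacetylated precursor.
* H4 4-17 (GKGGKGLGKGGAKR, sites K5/K8/K12/K16): y5 covers K16, y7 covers
  {K12, K16}, y12 covers {K8, K12, K16}; light fractions per ion telescope
  into the four mono-acetyl site shares.

Per-site stoichiometry then weights each form's site occupancy by its MS1
abundance and divides by the summed MS1 of all quantified forms (the
all-heavy, endogenously unmodified form included). The four H4
diacetylated species K5K12/K5K16/K8K12/K8K16 are not separable without an
MS1-MS2-MS3 scheme and are reported as one combined class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DomainError, IncompleteDenominatorError

__all__ = [
    "LIGHT_ACETYL_DA",
    "HEAVY_ACETYL_DA",
    "H3_PEPTIDE",
    "H4_PEPTIDE",
    "H3_SITES",
    "H4_SITES",
    "H4_ION_COVERAGE",
    "PositionalIsomerQuant",
    "CombinedDiacetylQuant",
    "h3_mono_isomer_shares",
    "h4_mono_isomer_shares",
    "site_stoichiometry",
    "combine_unresolvable_diacetyl",
    "quantify_histone_table",
]

#: endogenous acetyl mass shift, Da
LIGHT_ACETYL_DA = 42.0106
#: chemical d3-acetyl mass shift, Da (42.0106 + 3 x (2H - 1H))
HEAVY_ACETYL_DA = 45.0294
#: default fragment channel-matching tolerance, Da
CHANNEL_TOL_DA = 0.02

H3_PEPTIDE = "KQLATKAAR"  # H3 residues 18-26
H4_PEPTIDE = "GKGGKGLGKGGAKR"  # H4 residues 4-17
H3_SITES = ("K18", "K23")
H4_SITES = ("K5", "K8", "K12", "K16")

#: lysines contained in each quantifier y ion of the H4 4-17 peptide
H4_ION_COVERAGE: dict[str, tuple[str, ...]] = {
    "y5": ("K16",),
    "y7": ("K12", "K16"),
    "y12": ("K8", "K12", "K16"),
}

#: H4 diacetyl positional isomers that are indistinguishable without MS3
UNRESOLVABLE_H4_DIACETYL = frozenset(
    [frozenset({"K5", "K12"}), frozenset({"K5", "K16"}),
     frozenset({"K8", "K12"}), frozenset({"K8", "K16"})]
)

_PEPTIDE_SITES = {H3_PEPTIDE: H3_SITES, H4_PEPTIDE: H4_SITES}


@dataclass
class PositionalIsomerQuant:
    """Quantified acetyl form (one acetyl-count class) of a histone peptide.

    ``site_shares`` is the positional-isomer distribution within the class
    (summing to 1); ``site_occupancy`` maps each site to the fraction of the
    form's molecules carrying a *light* (endogenous) acetyl there — for a
    mono class this equals the shares, for a fully determined multi-acetyl
    form it is 1 at every member site.
    """

    peptide: str
    form_label: str
    acetyl_count: int
    ms1_abundance: float
    site_shares: dict[str, float] = field(default_factory=dict)
    site_occupancy: dict[str, float] = field(default_factory=dict)
    clamped: bool = False
    resolvable: bool = True

    def __post_init__(self) -> None:
        if self.ms1_abundance < 0:
            raise DomainError("MS1 abundance must be nonnegative")
        if self.site_shares:
            total = sum(self.site_shares.values())
            if abs(total - 1.0) > 1e-9:
                raise DomainError(f"isomer shares sum to {total}, expected 1")


@dataclass
class CombinedDiacetylQuant:
    """Summed abundance of positional isomers reported as one class."""

    peptide: str
    members: tuple[str, ...]
    ms1_abundance: float
    acetyl_count: int = 2

    @property
    def label(self) -> str:
        return "+".join(self.members) if self.members else "(empty)"


def h3_mono_isomer_shares(b2_light: float, b2_heavy: float) -> dict[str, float]:
    """K18ac vs K23ac shares of monoacetylated H3 18-26 from the b2 pair.

    The b2 ion contains K18 only, so light b2 signal comes from K18ac
    precursors and heavy b2 from K23ac precursors (whose K18 carries the
    chemical d3-acetyl). Returns None-like empty dict is never produced;
    both channels zero raises, as the form is unquantifiable.
    """
    if b2_light < 0 or b2_heavy < 0:
        raise DomainError("fragment intensities must be nonnegative")
    total = b2_light + b2_heavy
    if not total > 0:
        raise DomainError("unquantifiable: both b2 channels are zero")
    share_k18 = b2_light / total
    return {"K18": share_k18, "K23": 1.0 - share_k18}


def h4_mono_isomer_shares(
    light_fractions: Mapping[str, float],
) -> tuple[dict[str, float], bool]:
    """Site shares of monoacetylated H4 4-17 by telescoping the y-ion ladder.

    ``light_fractions`` maps y5/y7/y12 to light/(light+heavy) fractions.
    Attribution: K16 = f(y5); K12 = f(y7) - f(y5); K8 = f(y12) - f(y7);
    K5 = 1 - f(y12). Noise can invert the ladder; negative shares are
    clamped to zero and the vector renormalized, with the clamping event
    reported in the second return value.
    """
    missing = set(H4_ION_COVERAGE) - set(light_fractions)
    if missing:
        raise DomainError(f"missing light fractions for ions: {sorted(missing)}")
    f5, f7, f12 = (float(light_fractions[i]) for i in ("y5", "y7", "y12"))
    for name, val in (("y5", f5), ("y7", f7), ("y12", f12)):
        if not (0.0 <= val <= 1.0):
            raise DomainError(f"light fraction of {name} outside [0, 1]: {val}")
    raw = {"K5": 1.0 - f12, "K8": f12 - f7, "K12": f7 - f5, "K16": f5}
    clamped = any(v < 0 for v in raw.values())
    shares = {s: max(v, 0.0) for s, v in raw.items()}
    total = sum(shares.values())
    if total <= 0:  # cannot happen for in-range fractions, but stay safe
        raise DomainError("degenerate light fractions: all shares zero")
    return {s: v / total for s, v in shares.items()}, clamped


def site_stoichiometry(
    forms: Sequence[PositionalIsomerQuant],
) -> dict[str, float]:
    """Per-site endogenous acetylation stoichiometry across all forms.

    stoich(site) = sum_f MS1(f) * occupancy_f(site) / sum_f MS1(f), where
    the denominator runs over every quantified form of the peptide and must
    include the all-heavy (endogenously unmodified) form — without it the
    completeness of the denominator cannot be guaranteed. Forms flagged
    non-resolvable contribute to the denominator only; a site absent from
    every form has stoichiometry exactly 0.
    """
    forms = list(forms)
    if not forms:
        raise ContractError("no forms supplied")
    peptides = {f.peptide for f in forms}
    if len(peptides) != 1:
        raise ContractError(f"forms from multiple peptides: {sorted(peptides)}")
    peptide = peptides.pop()
    if not any(f.acetyl_count == 0 for f in forms):
        raise IncompleteDenominatorError(
            "all-heavy (unmodified-endogenous) form missing; denominator incomplete"
        )
    total = sum(f.ms1_abundance for f in forms)
    if not total > 0:
        raise DomainError("no form has positive MS1 abundance")
    sites = _PEPTIDE_SITES.get(peptide)
    if sites is None:
        sites = tuple(sorted({s for f in forms for s in f.site_occupancy}))
    stoich = {s: 0.0 for s in sites}
    for f in forms:
        if not f.resolvable:
            continue
        for s, occ in f.site_occupancy.items():
            stoich[s] = stoich.get(s, 0.0) + f.ms1_abundance * occ
    return {s: v / total for s, v in stoich.items()}


def combine_unresolvable_diacetyl(
    forms: Iterable[PositionalIsomerQuant],
) -> CombinedDiacetylQuant:
    """Sum the H4 diacetyl species that MS2 alone cannot separate.

    All inputs must carry acetyl count 2 on the same peptide; the combined
    record keeps the member labels and the summed MS1 abundance. An empty
    input yields an empty record with zero abundance.
    """
    forms = list(forms)
    if not forms:
        return CombinedDiacetylQuant(peptide=H4_PEPTIDE, members=(), ms1_abundance=0.0)
    counts = {f.acetyl_count for f in forms}
    if counts != {2}:
        raise ContractError(f"cannot combine mixed acetyl counts: {sorted(counts)}")
    peptides = {f.peptide for f in forms}
    if len(peptides) != 1:
        raise ContractError("cannot combine forms from different peptides")
    return CombinedDiacetylQuant(
        peptide=peptides.pop(),
        members=tuple(f.form_label for f in forms),
        ms1_abundance=float(sum(f.ms1_abundance for f in forms)),
    )


# ---------------------------------------------------------------------------
# table-level quantification (TSV schema of pipeline_cli)
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("peptide", "form_label", "sample", "ms1_intensity", "ion", "channel", "intensity")


def _light_fraction(sub: pd.DataFrame, ion: str) -> float:
    rows = sub[sub["ion"] == ion]
    light = float(rows.loc[rows["channel"] == "light", "intensity"].sum())
    heavy = float(rows.loc[rows["channel"] == "heavy", "intensity"].sum())
    total = light + heavy
    if not total > 0:
        raise DomainError(f"no signal in either channel of ion {ion}")
    return light / total


def _form_from_rows(peptide: str, label: str, sub: pd.DataFrame) -> PositionalIsomerQuant:
    """Derive a form's site occupancy from its fragment rows.

    ``form_label`` encodes only the acetyl-count class visible at MS1
    ("0ac", "1ac", ...); site attribution comes from the fragments.
    """
    count = int(label.rstrip("ac").split("_")[-1]) if label[:-2].isdigit() else None
    if count is None:
        raise DomainError(f"form label {label!r} not of the form '<count>ac'")
    ms1 = float(sub["ms1_intensity"].iloc[0])
    sites = _PEPTIDE_SITES[peptide]
    if count == 0:
        return PositionalIsomerQuant(peptide, label, 0, ms1)
    if count == len(sites):  # fully acetylated endogenously: all sites light
        return PositionalIsomerQuant(
            peptide, label, count, ms1,
            site_shares={"+".join(sites): 1.0},
            site_occupancy={s: 1.0 for s in sites},
        )
    if count == 1:
        if peptide == H3_PEPTIDE:
            b2 = sub[sub["ion"] == "b2"]
            shares = h3_mono_isomer_shares(
                float(b2.loc[b2["channel"] == "light", "intensity"].sum()),
                float(b2.loc[b2["channel"] == "heavy", "intensity"].sum()),
            )
            clamped = False
        else:
            fractions = {ion: _light_fraction(sub, ion) for ion in H4_ION_COVERAGE}
            shares, clamped = h4_mono_isomer_shares(fractions)
        return PositionalIsomerQuant(
            peptide, label, 1, ms1,
            site_shares=dict(shares), site_occupancy=dict(shares), clamped=clamped,
        )
    # H4 2ac/3ac: positional attribution would need MS3; denominator only
    return PositionalIsomerQuant(
        peptide, label, count, ms1, resolvable=False,
    )


def quantify_histone_table(table: pd.DataFrame) -> pd.DataFrame:
    """Site stoichiometries for every (sample, peptide) in a fragment table.

    Input columns: peptide, form_label, sample, ms1_intensity, ion, channel
    (light/heavy), intensity — one row per fragment channel observation.
    Returns a tidy frame with columns sample, peptide, site, stoichiometry,
    n_forms, clamp_flag.
    """
    missing = set(_REQUIRED_COLS) - set(table.columns)
    if missing:
        raise DomainError(f"histone table missing columns: {sorted(missing)}")
    records = []
    for (sample, peptide), sub in table.groupby(["sample", "peptide"], sort=True):
        if peptide not in _PEPTIDE_SITES:
            raise DomainError(f"unknown histone peptide {peptide!r}")
        forms = [
            _form_from_rows(peptide, str(label), rows)
            for label, rows in sub.groupby("form_label", sort=True)
        ]
        stoich = site_stoichiometry(forms)
        clamp = any(f.clamped for f in forms)
        for site in _PEPTIDE_SITES[peptide]:
            records.append(
                {
                    "sample": sample,
                    "peptide": peptide,
                    "site": site,
                    "stoichiometry": stoich[site],
                    "n_forms": len(forms),
                    "clamp_flag": clamp,
                }
            )
    return pd.DataFrame.from_records(records)
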