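"""Mass-isotopomer distributions and deuterium-labeling quantities.

In a heavy-water labeling experiment the isotope envelope of a peptide (or
metabolite) ion is summarised by its mass-isotopomer distribution (MID):
the relative abundances of the peaks M0, M1, ..., Mn, where Mj sits j mass
units above the monoisotopic peak. Incorporation of deuterium shifts signal
out of M0 into the heavy isotopomers, so the total labeling at time t is

    E(t) = 1 - E0(t),   E0(t) = M0(t) / sum_j Mj(t).

This module owns the MID container, the normalization/labeling arithmetic,
and the excess-abundance estimator used for discrete tracers such as
ethanol-d6 (M+3 acetate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InvalidDistributionError

__all__ = [
    "MassIsotopomerDistribution",
    "LabelingValue",
    "normalize_mid",
    "labeling_from_mid",
    "tracer_molar_fraction",
]

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class MassIsotopomerDistribution:
    """Isotopomer intensities [M0, M1, ..., Mn] for one ion at one time.

    ``intensities[j]`` is the abundance of the isotopomer j mass units above
    monoisotopic. When ``normalized`` is True the values sum to one.
    """

    intensities: np.ndarray
    ion_id: str = ""
    time_days: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise InvalidDistributionError("intensities must be a nonempty 1-D sequence")
        if np.any(arr < 0):
            raise InvalidDistributionError("negative isotopomer intensity")
        if not np.any(arr > 0):
            raise InvalidDistributionError("all isotopomer intensities are zero")
        if self.time_days < 0:
            raise DomainError("time_days must be nonnegative")
        if self.normalized and abs(arr.sum() - 1.0) > _NORM_TOL:
            raise InvalidDistributionError("normalized=True but intensities do not sum to 1")
        object.__setattr__(self, "intensities", arr)

    @property
    def n_isotopomers(self) -> int:
        return int(self.intensities.size)


@dataclass(frozen=True)
class LabelingValue:
    """Total deuterium labeling E = 1 - (monoisotopic share) at one time."""

    time_days: float
    E: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.time_days < 0:
            raise DomainError("time_days must be nonnegative")
        if not (0.0 <= self.E <= 1.0):
            raise DomainError(f"E={self.E} outside [0, 1]")


def normalize_mid(
    intensities, *, ion_id: str = "", time_days: float = 0.0
) -> MassIsotopomerDistribution:
    """Normalize raw isotopomer intensities to a distribution summing to 1.

    Normalization happens over the isotopomer window supplied by the caller;
    the envelope is neither extended nor truncated (upstream extraction
    defines n).
    """
    if isinstance(intensities, MassIsotopomerDistribution):
        if intensities.normalized:
            return intensities
        arr = intensities.intensities
        ion_id = ion_id or intensities.ion_id
        time_days = time_days or intensities.time_days
    else:
        arr = np.asarray(intensities, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidDistributionError("intensities must be a nonempty 1-D sequence")
    if np.any(arr < 0):
        raise InvalidDistributionError("negative isotopomer intensity")
    total = arr.sum()
    if not total > 0:
        raise InvalidDistributionError("all isotopomer intensities are zero")
    return MassIsotopomerDistribution(
        intensities=arr / total, ion_id=ion_id, time_days=time_days, normalized=True
    )


def labeling_from_mid(mid) -> LabelingValue:
    """Total labeling E = 1 - M0 / sum_j Mj from a (raw or normalized) MID."""
    norm = normalize_mid(mid)
    e0 = float(norm.intensities[0])
    e = 1.0 - e0
    # guard rounding just outside [0, 1]
    e = min(max(e, 0.0), 1.0)
    return LabelingValue(time_days=norm.time_days, E=e)


def tracer_molar_fraction(
    mid_t: MassIsotopomerDistribution,
    mid_ref: MassIsotopomerDistribution,
    shift: int,
) -> float:
    """Excess abundance of the M+shift isotopomer over an unlabeled reference.

    Used for discrete tracers (e.g. M+3 acetate from ethanol-d6): the labeled
    species appears ``shift`` mass units above monoisotopic, so its molar
    fraction is estimated as the normalized abundance at M+shift minus the
    natural-abundance contribution observed in the reference spectrum,
    clamped at zero. Identical spectra give exactly 0.
    """
    if shift < 1:
        raise DomainError("shift must be a positive integer")
    mt = normalize_mid(mid_t)
    mr = normalize_mid(mid_ref)
    if shift >= mt.n_isotopomers:
        raise DomainError(
            f"shift {shift} exceeds isotopomer range of the labeled spectrum "
            f"(n={mt.n_isotopomers - 1})"
        )
    ref_at_shift = float(mr.intensities[shift]) if shift < mr.n_isotopomers else 0.0
    excess = float(mt.intensities[shift]) - ref_at_shift
    return max(0.0, excess)
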