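"""One-compartment turnover kinetics from heavy-water labeling time courses.

The labeling of a peptide follows a single-exponential rise to plateau,

    E(t) = E(0) + (E(ss) - E(0)) * (1 - exp(-k t)),

with baseline enrichment E(0), steady-state (plateau) enrichment E(ss) and
turnover rate constant k (per day). The half-life is t1/2 = ln(2)/k.

Fitting strategy (deterministic, no random starts): for fixed k the model is
linear in (E0, Ess),

    E(t) = a + b * x(t),   x = 1 - exp(-k t),  a = E0,  b = Ess - E0,

subject to the box/simplex constraints a >= 0, b >= 0, a + b <= 1 (i.e.
0 <= E0 <= Ess <= 1). The conditionally optimal (a, b) is a small convex QP
solved in closed form; k is profiled on a log-spaced grid and refined by
golden-section search. Joint ("collective") fits share one k across all
peptides of a protein (or all peptides covering one acetyl-site) with
peptide-specific (E0, Ess), which keeps the rate estimate driven by every
peptide while respecting sequence-specific plateau chemistry.

The closed-form helpers are vectorized over arbitrary leading axes so the
Monte-Carlo power machinery can reuse them on thousands of replicates at
once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ContractError, DomainError, InsufficientDataError

__all__ = [
    "K_BOUNDS",
    "OneCompartmentParams",
    "PeptideTimeCourse",
    "KineticFit",
    "HalfLife",
    "FitOptions",
    "predict_labeling",
    "half_life",
    "fit_time_course",
    "fit_joint",
]

#: default search bounds for the rate constant, per day
K_BOUNDS = (1e-4, 10.0)

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0  # 0.618...


@dataclass(frozen=True)
class OneCompartmentParams:
    """Parameters of the rise-to-plateau labeling model (all dimensionless
    except ``k`` in 1/day). Invariant: 0 <= e0 <= ess <= 1, k > 0."""

    e0: float
    ess: float
    k: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.e0 <= self.ess <= 1.0):
            raise DomainError(f"require 0 <= E0 <= Ess <= 1, got E0={self.e0}, Ess={self.ess}")
        if not self.k > 0:
            raise DomainError(f"rate constant must be positive, got k={self.k}")


@dataclass(frozen=True)
class HalfLife:
    """Half-life t1/2 = ln(2)/k, in days."""

    t_half_days: float

    def __post_init__(self) -> None:
        if not self.t_half_days > 0:
            raise DomainError("half-life must be positive")


def predict_labeling(params: OneCompartmentParams, t) -> np.ndarray | float:
    """E(t) = E0 + (Ess - E0)(1 - exp(-k t)); scalar in, scalar out."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("time must be nonnegative")
    out = params.e0 + (params.ess - params.e0) * (-np.expm1(-params.k * t_arr))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def half_life(k: float) -> HalfLife:
    """Half-life from the rate constant: t1/2 = ln(2)/k."""
    if not k > 0:
        raise DomainError(f"rate constant must be positive, got k={k}")
    return HalfLife(t_half_days=math.log(2.0) / k)


@dataclass
class PeptideTimeCourse:
    """Labeling observations E(t) for one peptide in one animal group.

    ``parent_id`` names the protein (accession) or acetyl-site (e.g.
    "Cps1-K307") whose turnover the peptide reports on.
    """

    peptide_id: str
    parent_id: str
    group: str
    times: np.ndarray
    values: np.ndarray
    animal_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size == 0 or self.times.shape != self.values.shape:
            raise ContractError("times and values must be equal-length, nonempty")
        if np.any(self.times < 0):
            raise DomainError("negative time in time course")
        if np.any((self.values < 0) | (self.values > 1)):
            raise DomainError("labeling values must lie in [0, 1]")
        if not self.animal_ids:
            self.animal_ids = [f"a{i}" for i in range(self.times.size)]

    @classmethod
    def from_observations(cls, peptide_id, parent_id, group, observations):
        """Build from an iterable of (animal_id, time_days, E) tuples."""
        obs = list(observations)
        if not obs:
            raise ContractError("at least one observation required")
        animals = [str(o[0]) for o in obs]
        t = [float(o[1]) for o in obs]
        e = [float(o[2]) for o in obs]
        return cls(peptide_id, parent_id, group, np.array(t), np.array(e), animals)

    @property
    def n_obs(self) -> int:
        return int(self.times.size)


@dataclass
class KineticFit:
    """Result of a single-series or joint one-compartment fit."""

    parent_id: str
    group: str
    k_hat: float
    per_peptide_params: dict[str, tuple[float, float]]  # peptide_id -> (E0, Ess)
    rss: float
    n_obs: int
    n_params: int
    se_k: float
    converged: bool
    message: str = ""

    @property
    def df(self) -> int:
        return self.n_obs - self.n_params

    @property
    def t_half_days(self) -> float:
        return half_life(self.k_hat).t_half_days


@dataclass(frozen=True)
class FitOptions:
    """Options for the profiled-k fitter.

    pin_e0
        Fix E(0) = 0 instead of fitting the baseline.
    k_bounds
        Search interval for k (1/day); boundary solutions are flagged
        non-converged.
    n_grid
        Log-spaced profile grid size before golden-section refinement.
    rel_tol
        Relative tolerance on k for the golden-section stage.
    """

    pin_e0: bool = False
    k_bounds: tuple[float, float] = K_BOUNDS
    n_grid: int = 200
    rel_tol: float = 1e-8


# ---------------------------------------------------------------------------
# constrained linear subproblem (vectorized over arbitrary leading axes)
# ---------------------------------------------------------------------------

def _moments(x: np.ndarray, e: np.ndarray):
    """Sufficient statistics of the linear subproblem; sums over last axis."""
    n = x.shape[-1]
    sx = x.sum(axis=-1)
    sxx = (x * x).sum(axis=-1)
    se = e.sum(axis=-1)
    sxe = (x * e).sum(axis=-1)
    see = (e * e).sum(axis=-1)
    return n, sx, sxx, se, sxe, see


def _rss_of(a, b, n, sx, sxx, se, sxe, see):
    return see - 2.0 * a * se - 2.0 * b * sxe + a * a * n + 2.0 * a * b * sx + b * b * sxx


def solve_linear_subproblem(n, sx, sxx, se, sxe, see, pin_e0: bool = False):
    """Minimize ||E - a - b x||^2 s.t. a >= 0, b >= 0, a + b <= 1.

    Inputs are (broadcastable arrays of) sufficient statistics. Returns
    (a, b, rss). The feasible set is a triangle, so the optimum is either the
    interior stationary point or the 1-D optimum on one of the three edges
    (clipped to the segment); all candidates are evaluated and the best kept.
    With ``pin_e0`` the intercept is fixed at zero (E0 = 0).
    """
    sx, sxx, se, sxe, see = np.broadcast_arrays(
        np.asarray(sx, float), np.asarray(sxx, float), np.asarray(se, float),
        np.asarray(sxe, float), np.asarray(see, float),
    )
    tiny = 1e-300

    # edge a = 0 (E0 pinned): b in [0, 1]
    b_a0 = np.clip(sxe / np.maximum(sxx, tiny), 0.0, 1.0)
    a_a0 = np.zeros_like(b_a0)
    rss_a0 = _rss_of(a_a0, b_a0, n, sx, sxx, se, sxe, see)
    if pin_e0:
        return a_a0, b_a0, np.maximum(rss_a0, 0.0)

    # edge b = 0 (flat): a in [0, 1]
    a_b0 = np.clip(se / n, 0.0, 1.0)
    b_b0 = np.zeros_like(a_b0)
    rss_b0 = _rss_of(a_b0, b_b0, n, sx, sxx, se, sxe, see)

    # edge a + b = 1 (Ess = 1): residual E - x - a(1 - x)
    den = n - 2.0 * sx + sxx
    num = se - sxe - sx + sxx
    a_e1 = np.clip(num / np.maximum(den, tiny), 0.0, 1.0)
    b_e1 = 1.0 - a_e1
    rss_e1 = _rss_of(a_e1, b_e1, n, sx, sxx, se, sxe, see)

    # interior stationary point
    det = n * sxx - sx * sx
    ok = det > 1e-12 * max(float(n), 1.0)
    safe_det = np.where(ok, det, 1.0)
    a_un = (se * sxx - sxe * sx) / safe_det
    b_un = (n * sxe - sx * se) / safe_det
    feas = ok & (a_un >= 0.0) & (b_un >= 0.0) & (a_un + b_un <= 1.0)
    rss_un = np.where(feas, _rss_of(a_un, b_un, n, sx, sxx, se, sxe, see), np.inf)

    stacked = np.stack([rss_un, rss_a0, rss_b0, rss_e1])
    a_all = np.stack([np.where(feas, a_un, 0.0), a_a0, a_b0, a_e1])
    b_all = np.stack([np.where(feas, b_un, 0.0), b_a0, b_b0, b_e1])
    idx = np.argmin(stacked, axis=0)
    take = np.take_along_axis
    a = take(a_all, idx[None, ...], axis=0)[0]
    b = take(b_all, idx[None, ...], axis=0)[0]
    rss = take(stacked, idx[None, ...], axis=0)[0]
    return a, b, np.maximum(rss, 0.0)


def golden_section(
    f: Callable[[np.ndarray], np.ndarray],
    lo: np.ndarray,
    hi: np.ndarray,
    rel_tol: float = 1e-8,
    max_iter: int = 120,
):
    """Vectorized golden-section minimization on per-element brackets.

    ``f`` maps an array of abscissae to an array of objective values.
    Returns the best point/value seen (including bracket interiors), which
    makes the caller's "never worse than the starting point" guarantees easy.
    """
    lo = np.asarray(lo, float).copy()
    hi = np.asarray(hi, float).copy()
    x1 = hi - _GOLDEN * (hi - lo)
    x2 = lo + _GOLDEN * (hi - lo)
    f1 = f(x1)
    f2 = f(x2)
    best_x = np.where(f1 <= f2, x1, x2)
    best_f = np.minimum(f1, f2)
    for _ in range(max_iter):
        width = hi - lo
        scale = np.maximum(np.abs(lo), 1e-12)
        if np.all(width <= rel_tol * scale):
            break
        left = f1 <= f2
        hi = np.where(left, x2, hi)
        lo = np.where(left, lo, x1)
        x1_new = hi - _GOLDEN * (hi - lo)
        x2_new = lo + _GOLDEN * (hi - lo)
        # one fresh evaluation per step; the surviving interior point is reused
        x_probe = np.where(left, x1_new, x2_new)
        f_probe = f(x_probe)
        f1, f2 = np.where(left, f_probe, f2), np.where(left, f1, f_probe)
        x1, x2 = x1_new, x2_new
        improved = f_probe < best_f
        best_x = np.where(improved, x_probe, best_x)
        best_f = np.where(improved, f_probe, best_f)
    return best_x, best_f


# ---------------------------------------------------------------------------
# profile-k fitting
# ---------------------------------------------------------------------------

def _profile_rss_factory(series_list: Sequence[PeptideTimeCourse], pin_e0: bool):
    """Return f(k_array) -> total RSS (same shape as k_array), profiling out
    the per-peptide (E0, Ess)."""
    data = [(s.times, s.values) for s in series_list]

    def rss_at(k: np.ndarray) -> np.ndarray:
        k_arr = np.asarray(k, float)
        total = np.zeros(k_arr.shape)
        for t, e in data:
            x = -np.expm1(-k_arr[..., None] * t)  # (..., n_i)
            n, sx, sxx, se, sxe, see = _moments(x, e)
            _, _, rss = solve_linear_subproblem(n, sx, sxx, se, sxe, see, pin_e0)
            total = total + rss
        return total

    return rss_at


def _peptide_params_at(series_list, k: float, pin_e0: bool):
    params: dict[str, tuple[float, float]] = {}
    rss_total = 0.0
    for s in series_list:
        x = -np.expm1(-k * s.times)
        n, sx, sxx, se, sxe, see = _moments(x, s.values)
        a, b, rss = solve_linear_subproblem(n, sx, sxx, se, sxe, see, pin_e0)
        params[s.peptide_id] = (float(a), float(a) + float(b))
        rss_total += float(rss)
    return params, rss_total


def fit_joint(
    series_list: Sequence[PeptideTimeCourse], options: FitOptions | None = None
) -> KineticFit:
    """Fit a shared rate constant k to all peptides of one parent and group.

    Each peptide keeps its own (E0, Ess); k is profiled on a log-spaced grid
    over ``options.k_bounds`` and refined by golden-section search. The fit
    is deterministic. Rate estimates at the search boundary, and series with
    no labeling signal (all plateaus equal to baselines), are flagged
    ``converged=False`` and should be excluded from downstream inference.
    """
    opts = options or FitOptions()
    series_list = list(series_list)
    if not series_list:
        raise InsufficientDataError("no series supplied")
    parent = series_list[0].parent_id
    group = series_list[0].group
    for s in series_list:
        if s.parent_id != parent:
            raise ContractError(f"mixed parent ids in joint fit: {parent!r} vs {s.parent_id!r}")
        if s.group != group:
            raise ContractError(f"mixed groups in joint fit: {group!r} vs {s.group!r}")

    all_times = np.concatenate([s.times for s in series_list])
    if np.unique(all_times).size < 3:
        raise InsufficientDataError(
            "need >= 3 distinct time points spanning baseline and labeled samples"
        )

    n_obs = int(sum(s.n_obs for s in series_list))
    n_pep = len(series_list)
    n_params = (1 if opts.pin_e0 else 2) * n_pep + 1
    if n_obs - n_params < 1:
        raise InsufficientDataError(
            f"{n_obs} observations cannot support {n_params} parameters (df < 1)"
        )

    rss_fun = _profile_rss_factory(series_list, opts.pin_e0)
    lo, hi = opts.k_bounds
    grid = np.geomspace(lo, hi, opts.n_grid)
    rss_grid = rss_fun(grid)
    i = int(np.argmin(rss_grid))
    b_lo = grid[max(i - 1, 0)]
    b_hi = grid[min(i + 1, grid.size - 1)]
    k_ref, rss_ref = golden_section(rss_fun, np.array(b_lo), np.array(b_hi), opts.rel_tol)
    if float(rss_grid[i]) < float(rss_ref):
        k_hat, rss_hat = float(grid[i]), float(rss_grid[i])
    else:
        k_hat, rss_hat = float(k_ref), float(rss_ref)

    params, rss_hat = _peptide_params_at(series_list, k_hat, opts.pin_e0)

    converged = True
    message = ""
    edge = 1e-6
    if k_hat <= lo * (1 + 10 * edge) or k_hat >= hi * (1 - 10 * edge):
        converged = False
        message = "rate estimate at search boundary (non-identifiable)"
    amp = max(ess - e0 for e0, ess in params.values())
    if amp < 1e-9:
        converged = False
        message = "no labeling signal (flat series)"

    se_k = _wald_se(rss_fun, k_hat, rss_hat, n_obs - n_params)

    return KineticFit(
        parent_id=parent,
        group=group,
        k_hat=k_hat,
        per_peptide_params=params,
        rss=rss_hat,
        n_obs=n_obs,
        n_params=n_params,
        se_k=se_k,
        converged=converged,
        message=message,
    )


def _wald_se(rss_fun, k_hat: float, rss_hat: float, df: int) -> float:
    """Standard error of k from the curvature of the profiled RSS.

    Var(k) ~ 2 sigma^2 / (d^2 RSS / dk^2) with sigma^2 = RSS/df, curvature by
    central finite differences at relative step 1e-4.
    """
    if df <= 0:
        return float("inf")
    h = 1e-4 * k_hat
    r_plus = float(rss_fun(np.array(k_hat + h)))
    r_minus = float(rss_fun(np.array(max(k_hat - h, 1e-12))))
    curv = (r_plus - 2.0 * rss_hat + r_minus) / (h * h)
    if not np.isfinite(curv) or curv <= 0:
        return float("inf")
    sigma2 = max(rss_hat, 0.0) / df
    return math.sqrt(2.0 * sigma2 / curv)


def fit_time_course(
    series: PeptideTimeCourse, options: FitOptions | None = None
) -> KineticFit:
    """Fit the one-compartment model to a single peptide's time course."""
    return fit_joint([series], options)
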