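"""Stage orchestration: fits, group comparisons, stoichiometry, power.

``run_pipeline`` chains the analysis stages on validated input tables and
writes TSV results plus a machine-readable JSON manifest (inputs, outputs,
parameters, seed, per-stage record counts, content hashes). Turnover
comparisons are FDR-adjusted within separate families — native proteins and
acetyl-sites — mirroring the separate analyses they summarize.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .errors import TurnoverKitError
from .inference import adjust_comparisons, compare_turnover
from .io import read_timecourse, time_courses_from_table
from .kinetics import FitOptions, fit_joint, half_life
from .power import PowerScenario, power_curve
from .stoichiometry import quantify_histone_table

logger = logging.getLogger("turnoverkit")

__all__ = ["RunConfig", "FitConfig", "PowerConfig", "run_pipeline"]


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pin_e0: bool = False
    k_bounds: tuple[float, float] = (1e-4, 10.0)
    n_grid: int = 200

    def to_options(self) -> FitOptions:
        return FitOptions(pin_e0=self.pin_e0, k_bounds=self.k_bounds, n_grid=self.n_grid)


class PowerConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_per_group: int = 9
    time_grid_days: tuple[float, ...] = (0.0, 1.0, 3.0, 7.0, 14.0, 21.0)
    peptides_per_parent: int = 1
    k_base: float = 0.15
    ess_range: tuple[float, float] = (0.05, 0.15)
    sigma_e: float = 0.005
    alpha: float = 0.05
    n_sim: int = 2000
    fold_changes: tuple[float, ...] = (1.0, 1.2, 1.3, 1.5, 2.0)


class RunConfig(BaseModel):
    """JSON-schema-validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    timecourse: str | None = None
    histone: str | None = None
    out_dir: str = "results"
    seed: int = 0
    alpha: float = 0.05
    stages: tuple[Literal["fit", "compare", "stoich", "power"], ...] = ("fit", "compare")
    fit: FitConfig = Field(default_factory=FitConfig)
    power: PowerConfig | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def fit_all(df: pd.DataFrame, options: FitOptions) -> pd.DataFrame:
    """Joint fit per (parent, group); one row per fit with half-life."""
    rows = []
    for (parent, group), series in time_courses_from_table(df).items():
        try:
            fit = fit_joint(series, options)
        except TurnoverKitError as exc:
            rows.append(
                {"parent_id": parent, "group": group, "k_hat": math.nan,
                 "t_half_days": math.nan, "se_k": math.nan, "rss": math.nan,
                 "n_obs": sum(s.n_obs for s in series), "n_peptides": len(series),
                 "converged": False, "message": str(exc)}
            )
            continue
        rows.append(
            {
                "parent_id": parent,
                "group": group,
                "k_hat": fit.k_hat,
                "t_half_days": half_life(fit.k_hat).t_half_days if fit.converged else math.nan,
                "se_k": fit.se_k,
                "rss": fit.rss,
                "n_obs": fit.n_obs,
                "n_peptides": len(series),
                "converged": fit.converged,
                "message": fit.message,
            }
        )
    return pd.DataFrame(rows).sort_values(["parent_id", "group"]).reset_index(drop=True)


def compare_all(df: pd.DataFrame, options: FitOptions) -> pd.DataFrame:
    """Two-group comparison per parent, BH-adjusted within parent-kind family."""
    grouped = time_courses_from_table(df)
    parents: dict[str, dict[str, list]] = {}
    kinds = dict(zip(df["parent_id"].astype(str), df["parent_kind"].astype(str)))
    for (parent, group), series in grouped.items():
        parents.setdefault(parent, {})[group] = series

    by_family: dict[str, list] = {}
    for parent, arms in sorted(parents.items()):
        kind = kinds.get(parent, "protein")
        if "PF" not in arms or "EF" not in arms:
            continue
        comp = compare_turnover(arms["PF"], arms["EF"], options)
        by_family.setdefault(kind, []).append(comp)

    rows = []
    for kind, comparisons in by_family.items():
        adjust_comparisons(comparisons)
        for c in comparisons:
            rows.append(
                {
                    "parent_id": c.parent_id,
                    "parent_kind": kind,
                    "k_PF": c.k_pf,
                    "k_EF": c.k_ef,
                    "log2_fc": c.log2_fold_change,
                    "F": c.F,
                    "df_num": c.df_num,
                    "df_den": c.df_den,
                    "p": c.p,
                    "p_adj": c.p_adj,
                    "converged_flags": "ok" if c.tested else c.skipped_reason,
                }
            )
    return pd.DataFrame(rows).sort_values(["parent_kind", "parent_id"]).reset_index(drop=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Outputs land in ``config.out_dir``; every table written is re-readable
    by the package's own readers. Stage failures raise after the manifest
    (with the failure recorded) is written.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    options = config.fit.to_options()
    manifest: dict = {
        "package": "turnoverkit",
        "version": __version__,
        "seed": config.seed,
        "config": config.model_dump(),
        "inputs": {},
        "outputs": {},
        "counts": {},
        "failure": None,
    }

    def record_output(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"][name] = _sha256(path)
        manifest["counts"][name] = int(len(df))
        logger.info("wrote %s (%d records)", path, len(df))

    try:
        df = None
        if config.timecourse:
            df = read_timecourse(config.timecourse)
            manifest["inputs"]["timecourse"] = _sha256(Path(config.timecourse))
            manifest["counts"]["timecourse_rows"] = int(len(df))
            if df.empty:
                raise TurnoverKitError("empty time-course table")

        if "fit" in config.stages:
            if df is None:
                raise TurnoverKitError("fit stage requires a timecourse input")
            record_output("fits.tsv", fit_all(df, options))
        if "compare" in config.stages:
            if df is None:
                raise TurnoverKitError("compare stage requires a timecourse input")
            record_output("comparisons.tsv", compare_all(df, options))
        if "stoich" in config.stages:
            if not config.histone:
                raise TurnoverKitError("stoich stage requires a histone input")
            table = pd.read_csv(config.histone, sep="\t")
            manifest["inputs"]["histone"] = _sha256(Path(config.histone))
            record_output("stoichiometry.tsv", quantify_histone_table(table))
        if "power" in config.stages:
            pc = config.power or PowerConfig()
            scenario = PowerScenario(
                n_per_group=pc.n_per_group,
                time_grid_days=pc.time_grid_days,
                peptides_per_parent=pc.peptides_per_parent,
                k_base=pc.k_base,
                ess_range=pc.ess_range,
                sigma_e=pc.sigma_e,
                alpha=pc.alpha,
                n_sim=pc.n_sim,
                seed=config.seed,
            )
            rows = [
                {
                    "fold_change": fc,
                    "power": res.power,
                    "mc_stderr": res.mc_stderr,
                    "n_sim_effective": res.n_sim_effective,
                }
                for fc, res in power_curve(scenario, pc.fold_changes)
            ]
            record_output("power.tsv", pd.DataFrame(rows))
    except Exception as exc:
        manifest["failure"] = f"{type(exc).__name__}: {exc}"
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
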