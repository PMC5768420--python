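"""Experiment orchestration: end-to-end runners and calibration.

Each runner consumes the JSON configuration (the shipped
``reference_calibration.json`` by default), executes model ensembles and/or
kinetics fits, and returns a tidy per-condition table plus provenance (root
seed and config hash).  All randomness derives from one root seed via
counter-based splitting, so results are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from importlib.resources import files

import numpy as np
import pandas as pd

from . import endo_kinetics as ek
from . import morphometrics as mm
from . import switch_model as sw
from . import synthetic_data as syn

logger = logging.getLogger("neurite_switch")

__all__ = [
    "load_config",
    "reference_config",
    "config_hash",
    "ExperimentResult",
    "steady_flux",
    "run_morphology_experiment",
    "run_uptake_experiment",
    "run_perturbation_panel",
    "CalibrationTarget",
    "calibrate_to_targets",
]


def reference_config() -> dict:
    """The shipped reference configuration (single calibrated parameter set)."""
    path = files("neurite_switch").joinpath("data/reference_calibration.json")
    return json.loads(path.read_text())


def load_config(path=None) -> dict:
    cfg = reference_config() if path is None else json.load(open(path))
    for key in ("model_parameters", "conditions"):
        if key not in cfg:
            raise ValueError(f"config missing required block '{key}'")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ExperimentResult:
    """Per-condition summary table plus provenance."""

    table: pd.DataFrame
    seed: int
    config_sha: str

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _params_and_conditions(cfg):
    params = sw.SwitchParameters.from_dict(cfg["model_parameters"])
    conds = [sw.SubstrateCondition(E_kPa=c["E_kPa"], label=c["label"])
             for c in cfg["conditions"]]
    return params, conds


def _sub_seed(root_seed: int, *key: int) -> int:
    """Derive a stable child seed (< 2**31) from the root and an index key."""
    return int(np.random.SeedSequence(root_seed, spawn_key=key).generate_state(1)[0] % (2**31))


def steady_flux(params: sw.SwitchParameters, condition: sw.SubstrateCondition,
                t_end: float = 300.0) -> float:
    """Endocytic flux J_E at the steady state reached from the standard
    low-adhesion initial condition (deterministic, sigma_dyn forced to 0)."""
    det = params.replace(sigma_dyn=0.0) if params.sigma_dyn else params
    traj = sw.simulate(det, condition, (0.0, t_end), t_eval=[0.0, t_end])
    return traj.endpoint.J_E


def _classify_population(records, cfg, seed):
    """Model ensemble -> synthetic profiles -> LO pipeline -> calls."""
    morph = cfg.get("morphometrics", {})
    imaged = syn.population_from_ensemble(
        records, noise_sd=0.1, seed=seed,
        n_angles=int(morph.get("n_angles", 360)))
    thr = float(morph.get("threshold_over_background", 2.0))
    min_samples = int(morph.get("min_arc_samples", 2))
    calls = []
    for cell in imaged:
        lo = mm.profile_to_lo(cell.profile, threshold=thr, min_samples=min_samples)
        calls.append(mm.classify(lo))
    return imaged, calls


def _condition_row(params, cond, pert, cfg, seed):
    ens_cfg = cfg.get("ensemble", {})
    n_cells = int(ens_cfg.get("n_cells", 150))
    t_end = float(ens_cfg.get("t_end_hr", 16.0))
    t_pheno = float(ens_cfg.get("t_pheno_hr", 5.0))
    records = sw.ensemble(params, cond, pert=pert, n_cells=n_cells,
                          t_end=t_end, seed=seed, t_pheno=t_pheno)
    imaged, calls = _classify_population(records, cfg, _sub_seed(seed, 91))
    n = len(records)
    n_sl = sum(c == "SL" for c in calls)
    n_bl = sum(c == "BL" for c in calls)
    n_none = n - n_sl - n_bl
    neur = [r.neurite_bearing for r in records]
    bl_no_neur = sum(c == "BL" and not nb for c, nb in zip(calls, neur))
    pert_params = sw.apply_perturbation(params, pert)
    flux = steady_flux(pert_params, cond)
    qd = cfg.get("qd", {})
    scale_q = float(qd.get("scale_q_dots_per_flux_hr", 0.0))
    window = float(qd.get("window_hr", 5.0))
    dots = ek.qd_count_simulation(flux, scale_q, window, n_cells,
                                  seed=_sub_seed(seed, 17),
                                  condition_label=cond.label)
    return {
        "label": cond.label, "E_kPa": cond.E_kPa, "perturbation": pert.kind,
        "strength": pert.strength, "n_cells": n,
        "pct_SL_5hr": 100.0 * n_sl / n, "pct_BL_5hr": 100.0 * n_bl / n,
        "pct_none_5hr": 100.0 * n_none / n,
        "pct_neurite_16hr": 100.0 * sum(neur) / n,
        "pct_BL_neuriteless_16hr": 100.0 * bl_no_neur / n,
        "mean_dots_per_cell": dots.mean,
        "steady_J_E": flux,
    }


def run_morphology_experiment(cfg: dict | None = None,
                              seed: int = 0) -> ExperimentResult:
    """Phenotype fractions per substrate: ensemble -> profiles -> LO calls.

    One row per condition with SL/BL percentages at the 5 hr readout,
    neurite fractions at 16 hr, and the QD-BDNF dot-count summary.
    """
    cfg = cfg if cfg is not None else reference_config()
    params, conds = _params_and_conditions(cfg)
    none = sw.Perturbation("none")
    rows = [_condition_row(params, cond, none, cfg, _sub_seed(seed, i))
            for i, cond in enumerate(conds)]
    return ExperimentResult(table=pd.DataFrame(rows), seed=seed,
                            config_sha=config_hash(cfg))


def run_uptake_experiment(cfg: dict | None = None, seed: int = 0,
                          noise_sd: float = 0.0) -> ExperimentResult:
    """Generate soft/stiff FM4-64 traces from the configured kinetics and fit.

    Reports the fitted plateau, half-time and the soft/stiff endpoint ratio
    at 40 min; noiseless runs are seed-independent.
    """
    cfg = cfg if cfg is not None else reference_config()
    uptake = cfg.get("uptake")
    if not uptake or not {"soft", "stiff"} <= uptake.keys():
        raise ValueError("config must define uptake.soft and uptake.stiff")
    fits = {}
    rows = []
    for i, (name, u) in enumerate(sorted(uptake.items())):
        trace = syn.gen_uptake_trace(
            F_max=float(u["F_max"]), t_half=float(u["t_half_min"]),
            noise_sd=noise_sd, seed=_sub_seed(seed, i),
            condition_label=u.get("condition_label", name))
        fit = ek.fit_uptake(trace)
        fits[name] = fit
        rows.append({"condition": name, "condition_label": fit.condition_label,
                     "F_max": fit.F_max, "t_half_min": fit.t_half,
                     "k_per_min": fit.k, "rss": fit.rss})
    cmp = ek.compare_uptake(fits["soft"], fits["stiff"])
    df = pd.DataFrame(rows)
    df["t_half_ratio_stiff_over_soft"] = cmp["t_half_ratio"]
    df["endpoint_ratio_soft_over_stiff_40min"] = cmp["endpoint_ratio_at_40min"]
    return ExperimentResult(table=df, seed=seed, config_sha=config_hash(cfg))


def run_perturbation_panel(cfg: dict | None = None, seed: int = 0,
                           kinds: list[str] | None = None) -> ExperimentResult:
    """Perturbations on the soft condition (ΔLD1 additionally on rigid).

    Each perturbation runs a full ensemble -> profiles -> LO pipeline on the
    0.1 kPa condition; the adhesion-binding deletion (pxn_delta_LD1), whose
    predicted effect is on rigid substrates, is also run at 20 kPa.
    """
    cfg = cfg if cfg is not None else reference_config()
    params, conds = _params_and_conditions(cfg)
    if kinds is None:
        kinds = list(cfg.get("perturbations", sw.PERTURBATION_KINDS))
    soft = min(conds, key=lambda c: c.E_kPa)
    rigid = [c for c in conds if c.E_kPa >= 20]
    rows = []
    for i, kind in enumerate(kinds):
        pert = sw.Perturbation(kind)   # validates the kind
        rows.append(_condition_row(params, soft, pert, cfg, _sub_seed(seed, 100 + i)))
        if kind == "pxn_delta_LD1" and rigid:
            rows.append(_condition_row(params, rigid[0], pert, cfg,
                                       _sub_seed(seed, 200 + i)))
    return ExperimentResult(table=pd.DataFrame(rows), seed=seed,
                            config_sha=config_hash(cfg))


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationTarget:
    """One quantity to match: an ExperimentResult-style statistic."""

    name: str
    statistic: str          # callable key, see _STATISTICS
    target_value: float
    tolerance: float
    weight: float = 1.0

    def __post_init__(self):
        if not (self.tolerance > 0):
            raise ValueError("tolerance must be > 0")
        if self.statistic not in _STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}; "
                             f"known: {sorted(_STATISTICS)}")


def _stat_pct_sl_soft(params, cfg, seed):
    rec = sw.ensemble(params, sw.SubstrateCondition(0.1), n_cells=150, seed=seed)
    return sw.phenotype_fractions(rec)["pct_SL"]


def _stat_pct_bl_stiff(params, cfg, seed):
    rec = sw.ensemble(params, sw.SubstrateCondition(20.0), n_cells=150, seed=seed)
    return sw.phenotype_fractions(rec)["pct_BL"]


def _stat_endo_fraction_soft(params, cfg, seed):
    return 100.0 * steady_flux(params, sw.SubstrateCondition(0.1)) / (params.kappa * params.P_T)


def _stat_flux_ratio(params, cfg, seed):
    js = steady_flux(params, sw.SubstrateCondition(0.1))
    jt = steady_flux(params, sw.SubstrateCondition(20.0))
    return js / jt if jt > 0 else float("inf")


_STATISTICS = {
    "pct_SL_soft_5hr": _stat_pct_sl_soft,
    "pct_BL_stiff_5hr": _stat_pct_bl_stiff,
    "endocytic_paxillin_pct_soft": _stat_endo_fraction_soft,
    "flux_ratio_soft_over_stiff": _stat_flux_ratio,
}

#: Parameters the calibration search may move, with their log-grid spans.
_SEARCHABLE = ("alpha_A", "alpha_E", "K_i", "K_fb", "cv_cell", "theta_seg", "K_E")


def _residual(params, targets, cfg, seed):
    total = 0.0
    for t in targets:
        value = _STATISTICS[t.statistic](params, cfg, seed)
        total += t.weight * ((value - t.target_value) / t.target_value) ** 2
    return total


def calibrate_to_targets(start_params: sw.SwitchParameters,
                         targets: list[CalibrationTarget],
                         budget: int = 200, seed: int = 0,
                         search: tuple = _SEARCHABLE[:2],
                         cfg: dict | None = None,
                         grid: tuple = (0.8, 0.9, 1.0, 1.1, 1.25)) -> tuple[sw.SwitchParameters, dict]:
    """Coordinate-wise log-grid search minimizing weighted squared relative miss.

    Cycles through ``search`` parameters, trying multiplicative steps from
    ``grid`` and keeping improvements, until the evaluation ``budget`` is
    spent or all targets sit inside their tolerances.  Deterministic for a
    given seed and budget.  Returns the best parameters plus a report with
    per-target residuals and a ``converged`` flag.
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    for name in search:
        if name not in _SEARCHABLE:
            raise ValueError(f"parameter {name!r} is not searchable")
    cfg = cfg if cfg is not None else reference_config()

    def within_tol(params):
        return all(abs(_STATISTICS[t.statistic](params, cfg, seed) - t.target_value)
                   <= t.tolerance for t in targets)

    best = start_params
    evals = 0
    if within_tol(best):
        return best, {"converged": True, "evaluations": 0,
                      "residual": _residual(best, targets, cfg, seed)}
    best_res = _residual(best, targets, cfg, seed)
    evals += 1
    improved = True
    while improved and evals < budget:
        improved = False
        for name in search:
            for mult in grid:
                if mult == 1.0 or evals >= budget:
                    continue
                cand = best.replace(**{name: getattr(best, name) * mult})
                try:
                    res = _residual(cand, targets, cfg, seed)
                except Exception:
                    continue
                finally:
                    evals += 1
                if res < best_res:
                    best, best_res, improved = cand, res, True
    converged = within_tol(best)
    report = {"converged": converged, "evaluations": evals, "residual": best_res}
    if not converged:
        logger.warning("calibration budget exhausted without meeting tolerances "
                       "(residual %.4g after %d evaluations)", best_res, evals)
    return best, report
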