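"""Substrate-stiffness-controlled bistable switch for neurite initiation.

Two slow variables — the endocytic machinery level ``M_E`` and the adhesion
machinery level ``M_A`` — compete for a shared, conserved scaffolding protein
(paxillin, total ``P_T``).  Paxillin binding to either machinery is fast
relative to machinery turnover, so at every instant the free/endocytic-bound/
adhesion-bound split is the unique root of a competitive-binding equilibrium
("sequestering").  Endocytic flux ``J_E = kappa * P_E`` drives a Hill-type
genetic positive feedback on ``M_E`` (endocytosis up-regulates expression of
its own machinery) and inhibits adhesion assembly, while adhesion assembly is
driven by substrate stiffness (Young's modulus ``E``) and inhibits endocytosis
indirectly by sequestering paxillin.  The mutual inhibition plus positive
feedback yields bistability over an intermediate stiffness window: soft
substrates (brain-like, 0.1–1 kPa) resolve to an endocytic-dominant,
neuritogenic state, rigid substrates (>= 20 kPa, glass) to an
adhesion-dominant, spreading state.

Readouts: Rac1 activity ``R = R0 + g_rac * J_E`` (endocytosis-coupled;
thresholded to call the segmented-lamellipodium phenotype) and a RhoA proxy
monotone in ``a_E * M_A``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

logger = logging.getLogger("neurite_switch")

__all__ = [
    "SubstrateCondition",
    "SwitchParameters",
    "PaxillinPartition",
    "SwitchState",
    "Trajectory",
    "FixedPoint",
    "BifurcationDiagram",
    "Perturbation",
    "PERTURBATION_KINDS",
    "CellRecord",
    "stiffness_to_adhesion_drive",
    "partition_paxillin",
    "rhs",
    "simulate",
    "find_fixed_points",
    "scan_bifurcation",
    "apply_perturbation",
    "ensemble",
    "cell_rng",
]

#: Stiffness (kPa) used to encode a glass/coverslip substrate: far above any
#: hydrogel modulus, so the adhesion drive is saturated.
GLASS_E_KPA = 1000.0

#: Multiplier standing in for an "infinite" dissociation constant (a binding
#: site that has effectively lost its ligand).  Kept finite for numerics.
INF_K_FACTOR = 1e9


# --------------------------------------------------------------------------
# Parameter and state containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstrateCondition:
    """A culture substrate: Young's modulus in kPa plus a display label."""

    E_kPa: float
    label: str = ""

    def __post_init__(self):
        if not (self.E_kPa > 0):
            raise ValueError(f"E_kPa must be > 0, got {self.E_kPa}")
        if not self.label:
            object.__setattr__(self, "label", f"{self.E_kPa:g} kPa")

    @classmethod
    def glass(cls) -> "SubstrateCondition":
        return cls(E_kPa=GLASS_E_KPA, label="glass")


@dataclass(frozen=True)
class SwitchParameters:
    """All constants of the sequestering switch model.

    Units: abundances in arbitrary units (a.u.), rates in 1/hr, stiffness in
    kPa, time in hours.  Defaults are the shipped reference calibration (see
    ``reference_parameters``).
    """

    # paxillin pool and competitive binding
    P_T: float = 10.0          # total paxillin (a.u.)
    S_E_per_ME: float = 0.5    # endocytic binding sites per unit M_E
    S_A_per_MA: float = 1.0    # adhesion binding sites per unit M_A
    K_E: float = 1.4           # paxillin / endocytic-scaffold K_d (a.u.)
    K_A: float = 1.0           # paxillin / adhesion-scaffold K_d (a.u.)
    kappa: float = 2.0         # endocytic flux per unit endocytic-bound paxillin (1/hr)
    # endocytic machinery: basal production + genetic positive feedback
    alpha_E: float = 2.8       # basal production (a.u./hr)
    beta_E: float = 2.0        # feedback production gain (a.u./hr)
    K_fb: float = 4.0          # feedback half-point on J_E (a.u./hr)
    n_fb: float = 6.0          # feedback Hill coefficient
    delta_E: float = 0.5       # degradation (1/hr)
    # adhesion machinery: stiffness-driven assembly, flux-inhibited
    alpha_A: float = 20.4      # max assembly rate (a.u./hr)
    K_i: float = 5.2           # endocytic-flux inhibition half-point (a.u./hr)
    p_i: float = 4.0           # inhibition Hill coefficient
    delta_A: float = 1.0       # turnover (1/hr)
    # stiffness -> adhesion drive mapping
    E_half: float = 5.0        # half-point (kPa)
    h_E: float = 2.0           # Hill coefficient
    # readouts
    g_rac: float = 1.0         # Rac1 gain on J_E (a.u. per a.u./hr)
    R0: float = 0.1            # baseline Rac1 (a.u.)
    theta_seg: float = 4.0     # Rac1 threshold for lamellipodium segmentation (a.u.)
    # neurite conversion probabilities at the 16 hr readout
    p_neur_SL: float = 0.98
    p_neur_BL: float = 0.15
    # cell-to-cell variability / intrinsic noise
    cv_cell: float = 0.20      # lognormal CV on (P_T, alpha_E, alpha_A)
    sigma_dyn: float = 0.0     # Langevin noise scale (a.u./sqrt(hr))

    def __post_init__(self):
        positive = [f.name for f in fields(self)
                    if f.name not in ("sigma_dyn", "cv_cell", "p_neur_SL",
                                      "p_neur_BL", "R0", "theta_seg", "g_rac")]
        for name in positive:
            if not (getattr(self, name) > 0):
                raise ValueError(f"parameter {name} must be > 0, got {getattr(self, name)}")
        for name in ("sigma_dyn", "cv_cell", "R0", "g_rac", "theta_seg"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be >= 0")
        if not (0.0 <= self.p_neur_BL <= self.p_neur_SL <= 1.0):
            raise ValueError("need 0 <= p_neur_BL <= p_neur_SL <= 1")
        if self.n_fb < 1 or self.p_i < 1:
            raise ValueError("Hill coefficients n_fb and p_i must be >= 1")

    def replace(self, **kw) -> "SwitchParameters":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SwitchParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SwitchParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def reference_parameters() -> SwitchParameters:
    """The shipped reference calibration (also in ``data/reference_calibration.json``)."""
    from importlib.resources import files

    path = files("neurite_switch").joinpath("data/reference_calibration.json")
    return SwitchParameters.from_dict(json.loads(path.read_text())["model_parameters"])


@dataclass(frozen=True)
class PaxillinPartition:
    """Fast-equilibrium split of total paxillin into three pools (a.u.)."""

    P_free: float
    P_E: float
    P_A: float

    @property
    def total(self) -> float:
        return self.P_free + self.P_E + self.P_A


@dataclass(frozen=True)
class SwitchState:
    """Slow machinery levels plus every derived fast/readout quantity."""

    M_E: float
    M_A: float
    partition: PaxillinPartition
    J_E: float   # endocytic flux, kappa * P_E (a.u./hr)
    R: float     # Rac1 readout, R0 + g_rac * J_E (a.u.)
    Rho: float   # RhoA readout, monotone in a_E * M_A (a.u.)

    @classmethod
    def from_machinery(cls, M_E: float, M_A: float,
                       condition: SubstrateCondition,
                       params: SwitchParameters) -> "SwitchState":
        part = partition_paxillin(params.P_T, M_E, M_A, params)
        J_E = params.kappa * part.P_E
        a_E = stiffness_to_adhesion_drive(condition.E_kPa, params)
        return cls(M_E=M_E, M_A=M_A, partition=part, J_E=J_E,
                   R=params.R0 + params.g_rac * J_E, Rho=a_E * M_A)


@dataclass(frozen=True)
class Trajectory:
    times: np.ndarray                  # hr, strictly increasing
    states: tuple                      # SwitchState per sample
    condition: SubstrateCondition
    seed: int | None = None

    def state_at(self, t: float) -> SwitchState:
        """State at the sample closest to time ``t`` (samples include t)."""
        i = int(np.argmin(np.abs(self.times - t)))
        return self.states[i]

    @property
    def endpoint(self) -> SwitchState:
        return self.states[-1]


@dataclass(frozen=True)
class FixedPoint:
    state: SwitchState
    eigenvalues: tuple
    stable: bool
    residual: float


@dataclass(frozen=True)
class BifurcationDiagram:
    E_grid: np.ndarray
    up_branch: tuple        # SwitchState per grid point, upward continuation
    down_branch: tuple      # SwitchState per grid point, downward continuation
    bistable_interval: tuple | None   # (E_low, E_high) in kPa, or None

    @property
    def hysteresis_width(self) -> float:
        if self.bistable_interval is None:
            return 0.0
        return self.bistable_interval[1] - self.bistable_interval[0]


PERTURBATION_KINDS = (
    "paxillin_kd", "cip4_kd", "dynamin_inhibition", "rac1_inhibition",
    "pxn_delta_LIM34", "pxn_delta_LD1", "pxn_LD13", "none",
)

#: Default strength per perturbation kind (fraction of the full effect).
DEFAULT_STRENGTH = {
    "paxillin_kd": 0.8,        # siRNA leaves ~20% residual paxillin
    "cip4_kd": 0.8,
    "dynamin_inhibition": 1.0,
    "rac1_inhibition": 1.0,
    "pxn_delta_LIM34": 1.0,
    "pxn_delta_LD1": 1.0,
    "pxn_LD13": 1.0,
    "none": 0.0,
}


@dataclass(frozen=True)
class Perturbation:
    """A molecular/pharmacological manipulation mapped onto parameter changes."""

    kind: str = "none"
    strength: float | None = None     # in [0, 1]; None -> kind default

    def __post_init__(self):
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(
                f"unknown perturbation kind {self.kind!r}; "
                f"valid kinds: {', '.join(PERTURBATION_KINDS)}")
        if self.strength is None:
            object.__setattr__(self, "strength", DEFAULT_STRENGTH[self.kind])
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError("strength must lie in [0, 1]")


@dataclass(frozen=True)
class CellRecord:
    """One simulated cell of a stochastic ensemble."""

    cell_id: int
    condition_label: str
    multipliers: dict            # lognormal draws applied to P_T, alpha_E, alpha_A
    state_5hr: SwitchState
    state_end: SwitchState
    phenotype: str               # "SL" | "BL"  (model truth at the 5 hr readout)
    neurite_bearing: bool        # Bernoulli readout at the 16 hr equivalent
    seed_key: tuple


# --------------------------------------------------------------------------
# Fast-equilibrium paxillin partition
# --------------------------------------------------------------------------

def stiffness_to_adhesion_drive(E_kPa: float, params: SwitchParameters) -> float:
    """Map Young's modulus to the dimensionless adhesion drive a_E in (0, 1).

    Hill function ``E^h / (E_half^h + E^h)``: strictly increasing, 0.5 at
    ``E_half``, saturating on rigid substrates (glass is encoded as 1000 kPa).
    """
    if not (E_kPa > 0):
        raise ValueError(f"E_kPa must be > 0, got {E_kPa}")
    x = (E_kPa / params.E_half) ** params.h_E
    return x / (1.0 + x)


def _partition_residual(P_f: float, P_T: float, S_E: float, S_A: float,
                        K_E: float, K_A: float) -> float:
    # strictly increasing in P_f, so the root on [0, P_T] is unique
    return P_f + S_E * P_f / (K_E + P_f) + S_A * P_f / (K_A + P_f) - P_T


def partition_paxillin(P_T: float, M_E: float, M_A: float,
                       params: SwitchParameters) -> PaxillinPartition:
    """Solve the rapid-equilibrium competitive-binding split of paxillin.

    ``P_E = S_E P_f/(K_E+P_f)``, ``P_A = S_A P_f/(K_A+P_f)`` with site
    capacities ``S_E = S_E_per_ME * M_E``, ``S_A = S_A_per_MA * M_A`` and
    conservation ``P_f + P_E + P_A = P_T``.  The conservation residual is
    strictly increasing in ``P_f``, so the root is unique; it is bracketed on
    ``[0, P_T]`` and found with Brent's method.
    """
    if P_T < 0 or M_E < 0 or M_A < 0:
        raise ValueError(f"negative input to partition: P_T={P_T}, M_E={M_E}, M_A={M_A}")
    if P_T == 0.0:
        return PaxillinPartition(0.0, 0.0, 0.0)
    S_E = params.S_E_per_ME * M_E
    S_A = params.S_A_per_MA * M_A
    if S_E == 0.0 and S_A == 0.0:
        return PaxillinPartition(P_T, 0.0, 0.0)
    try:
        P_f = brentq(_partition_residual, 0.0, P_T,
                     args=(P_T, S_E, S_A, params.K_E, params.K_A),
                     xtol=1e-15, rtol=8.9e-16, maxiter=200)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            f"partition solver failed for P_T={P_T}, S_E={S_E}, S_A={S_A}, "
            f"K_E={params.K_E}, K_A={params.K_A}: {exc}") from exc
    P_E = S_E * P_f / (params.K_E + P_f)
    P_A = S_A * P_f / (params.K_A + P_f)
    # tidy the tiny residual into the free pool so conservation is exact
    P_f = max(P_T - P_E - P_A, 0.0)
    return PaxillinPartition(P_f, P_E, P_A)


# --------------------------------------------------------------------------
# Slow dynamics
# --------------------------------------------------------------------------

def rhs(state: Sequence[float], condition: SubstrateCondition,
        params: SwitchParameters) -> tuple[float, float]:
    """Time derivatives (dM_E/dt, dM_A/dt) at machinery levels ``state``.

    dM_E/dt = alpha_E + beta_E * Hill(J_E; K_fb, n_fb) - delta_E * M_E
    dM_A/dt = alpha_A * a_E / (1 + (J_E/K_i)^p_i) - delta_A * M_A

    with J_E = kappa * P_E from the fast-equilibrium partition.
    """
    M_E, M_A = state
    if M_E < 0 or M_A < 0:
        raise ValueError(f"machinery levels must be >= 0, got {state}")
    part = partition_paxillin(params.P_T, M_E, M_A, params)
    J = params.kappa * part.P_E
    if J > 0:
        hill = J ** params.n_fb / (params.K_fb ** params.n_fb + J ** params.n_fb)
        inhib = 1.0 / (1.0 + (J / params.K_i) ** params.p_i)
    else:
        hill, inhib = 0.0, 1.0
    a_E = stiffness_to_adhesion_drive(condition.E_kPa, params)
    dME = params.alpha_E + params.beta_E * hill - params.delta_E * M_E
    dMA = params.alpha_A * a_E * inhib - params.delta_A * M_A
    if not (math.isfinite(dME) and math.isfinite(dMA)):
        raise FloatingPointError(
            f"non-finite derivative at state={state}, J_E={J}: ({dME}, {dMA})")
    return dME, dMA


def default_initial(params: SwitchParameters) -> tuple[float, float]:
    """The common low-adhesion initial condition: basal endocytic machinery,
    near-zero adhesions (cells have just contacted the gel)."""
    return (params.alpha_E / params.delta_E,
            0.01 * params.alpha_A / params.delta_A)


def simulate(params: SwitchParameters, condition: SubstrateCondition,
             t_span: tuple[float, float], initial: Sequence[float] | None = None,
             seed: int | None = None, t_eval: Sequence[float] | None = None,
             rng: np.random.Generator | None = None) -> Trajectory:
    """Integrate the switch ODE (optionally with Langevin noise).

    With ``sigma_dyn == 0`` this is a deterministic stiff-capable integration
    (LSODA, rtol 1e-8 / atol 1e-10) and the result is independent of ``seed``.
    With ``sigma_dyn > 0`` an Euler–Maruyama scheme (dt = 0.01 hr) adds
    additive noise to both machinery equations; negative excursions are
    clipped at zero.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ValueError("t_span must have positive extent")
    x0 = np.asarray(default_initial(params) if initial is None else initial, float)
    if np.any(x0 < 0):
        raise ValueError("initial machinery levels must be >= 0")
    if t_eval is None:
        t_eval = np.linspace(t0, t1, 161)
    t_eval = np.asarray(t_eval, float)

    if params.sigma_dyn > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        times, xs = _euler_maruyama(params, condition, (t0, t1), x0, t_eval, rng)
    else:
        def f(t, y):
            y = np.maximum(y, 0.0)
            return rhs(y, condition, params)

        sol = solve_ivp(f, (t0, t1), x0, method="LSODA", t_eval=t_eval,
                        rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        times, xs = sol.t, sol.y.T
        if np.any(xs < 0):
            n_clip = int(np.sum(np.any(xs < 0, axis=1)))
            logger.debug("clipped negative excursions at %d samples", n_clip)
            xs = np.maximum(xs, 0.0)

    states = tuple(SwitchState.from_machinery(x[0], x[1], condition, params)
                   for x in xs)
    return Trajectory(times=times, states=states, condition=condition, seed=seed)


def _euler_maruyama(params, condition, t_span, x0, t_eval, rng, dt=0.01):
    t0, t1 = t_span
    n = int(math.ceil((t1 - t0) / dt))
    x = x0.copy()
    sqdt = math.sqrt(dt)
    out, ti = [], 0
    t_grid = t0 + dt * np.arange(n + 1)
    for k in range(n + 1):
        t = t_grid[k]
        while ti < len(t_eval) and t_eval[ti] <= t + dt / 2:
            out.append(x.copy())
            ti += 1
        if k == n:
            break
        d = np.asarray(rhs(x, condition, params))
        x = x + d * dt + params.sigma_dyn * sqdt * rng.standard_normal(2)
        x = np.maximum(x, 0.0)
    while ti < len(t_eval):           # trailing samples at/after t1
        out.append(x.copy())
        ti += 1
    return t_eval, np.asarray(out)


# --------------------------------------------------------------------------
# Fixed points, stability, bifurcation
# --------------------------------------------------------------------------

def _jacobian(x, condition, params, h_scale=1e-6):
    J = np.empty((2, 2))
    for j in range(2):
        h = h_scale * (1.0 + abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] = max(xm[j] - h, 0.0)
        fp = np.asarray(rhs(xp, condition, params))
        fm = np.asarray(rhs(xm, condition, params))
        J[:, j] = (fp - fm) / (xp[j] - xm[j])
    return J


def find_fixed_points(params: SwitchParameters, condition: SubstrateCondition,
                      grid_n: int = 12, tol: float = 1e-9,
                      dedupe_tol: float = 1e-5) -> list[FixedPoint]:
    """Locate all steady states of the switch by multi-start Newton refinement.

    Starts are a coarse grid over ``(M_E, M_A)`` spanning the production/
    degradation ranges; converged roots are deduplicated at ``dedupe_tol``
    and classified by the eigenvalues of a central-difference Jacobian.
    """
    ME_max = (params.alpha_E + params.beta_E) / params.delta_E
    a_E = stiffness_to_adhesion_drive(condition.E_kPa, params)
    MA_max = max(params.alpha_A * a_E / params.delta_A, 1e-6)
    ME_grid = np.linspace(0.5 * params.alpha_E / params.delta_E, 1.05 * ME_max, grid_n)
    MA_grid = np.linspace(0.0, 1.05 * MA_max, grid_n)

    roots: list[np.ndarray] = []
    for me in ME_grid:
        for ma in MA_grid:
            x = np.array([me, ma], float)
            for _ in range(60):      # damped Newton
                f = np.asarray(rhs(np.maximum(x, 0.0), condition, params))
                if np.linalg.norm(f) < tol:
                    break
                Jm = _jacobian(np.maximum(x, 0.0), condition, params)
                try:
                    step = np.linalg.solve(Jm, -f)
                except np.linalg.LinAlgError:
                    break
                # keep iterates in the admissible quadrant
                lam = 1.0
                while lam > 1e-4 and np.any(x + lam * step < -1e-12):
                    lam *= 0.5
                x = np.maximum(x + lam * step, 0.0)
            else:
                continue
            f = np.asarray(rhs(x, condition, params))
            if np.linalg.norm(f) >= tol:
                continue
            if not any(np.linalg.norm(x - r) < dedupe_tol * (1 + np.linalg.norm(r))
                       for r in roots):
                roots.append(x)

    if not roots:
        raise RuntimeError(
            f"no fixed point found at E={condition.E_kPa} kPa — the system always "
            "has at least one steady state; check parameters")

    out = []
    for x in sorted(roots, key=lambda r: r[0]):
        Jm = _jacobian(x, condition, params)
        eig = np.linalg.eigvals(Jm)
        res = float(np.linalg.norm(rhs(x, condition, params)))
        out.append(FixedPoint(
            state=SwitchState.from_machinery(x[0], x[1], condition, params),
            eigenvalues=tuple(eig),
            stable=bool(np.all(eig.real < 0)),
            residual=res))
    return out


def _settle(params, condition, x0, t_end=400.0):
    """Integrate to steady state from x0 and return the machinery vector."""
    traj = simulate(params, condition, (0.0, t_end), initial=x0,
                    t_eval=[0.0, t_end])
    end = traj.endpoint
    return np.array([end.M_E, end.M_A])


def scan_bifurcation(params: SwitchParameters, E_grid: Sequence[float],
                     separation_tol: float = 0.05) -> BifurcationDiagram:
    """Upward/downward quasi-static continuation over a stiffness grid.

    The upward sweep seeds each stiffness with the settled state of the
    previous (lower) one, starting from the low-adhesion initial condition;
    the downward sweep is symmetric starting from the settled state at the
    stiffest point.  The bistable interval is where the two branches'
    endocytic paxillin fractions differ by more than ``separation_tol``.
    """
    E_grid = np.asarray(sorted(E_grid), float)
    if len(E_grid) < 10:
        raise ValueError("E_grid needs >= 10 points")

    up_states, x = [], np.asarray(default_initial(params), float)
    for E in E_grid:
        cond = SubstrateCondition(E)
        x = _settle(params, cond, x)
        up_states.append(SwitchState.from_machinery(x[0], x[1], cond, params))

    down_states, x = [], None
    for E in E_grid[::-1]:
        cond = SubstrateCondition(E)
        if x is None:
            # seed the top of the sweep from an adhesion-heavy start
            a_E = stiffness_to_adhesion_drive(E, params)
            x = np.array([params.alpha_E / params.delta_E,
                          params.alpha_A * a_E / params.delta_A])
        x = _settle(params, cond, x)
        down_states.append(SwitchState.from_machinery(x[0], x[1], cond, params))
    down_states = down_states[::-1]

    frac_up = np.array([s.partition.P_E / params.P_T for s in up_states])
    frac_dn = np.array([s.partition.P_E / params.P_T for s in down_states])
    split = np.abs(frac_up - frac_dn) > separation_tol
    if np.any(split):
        idx = np.nonzero(split)[0]
        if np.any(np.diff(idx) > 1):
            logger.warning("non-contiguous bistable region on the grid; "
                           "continuation may have jumped a fold")
        interval = (float(E_grid[idx[0]]), float(E_grid[idx[-1]]))
    else:
        interval = None
    return BifurcationDiagram(E_grid=E_grid, up_branch=tuple(up_states),
                              down_branch=tuple(down_states),
                              bistable_interval=interval)


# --------------------------------------------------------------------------
# Perturbations
# --------------------------------------------------------------------------

def apply_perturbation(params: SwitchParameters,
                       pert: Perturbation) -> SwitchParameters:
    """Return a modified parameter copy implementing a molecular perturbation.

    strength interpolates linearly between no effect (0) and the full effect
    (1).  Knockdowns scale abundances/capacities down; dynamin and Rac1
    inhibition zero the flux/readout gains; binding-domain deletions send the
    corresponding dissociation constant toward "infinity" (1e9 x reference).
    """
    s = pert.strength
    if pert.kind == "none" or s == 0.0:
        return params
    if pert.kind == "paxillin_kd":
        return params.replace(P_T=params.P_T * (1.0 - s))
    if pert.kind == "cip4_kd":
        return params.replace(S_E_per_ME=params.S_E_per_ME * (1.0 - s))
    if pert.kind == "dynamin_inhibition":
        # kappa must stay > 0 for parameter validity; 1e-12 x is flux-free
        return params.replace(kappa=params.kappa * max(1.0 - s, 1e-12))
    if pert.kind == "rac1_inhibition":
        return params.replace(g_rac=params.g_rac * (1.0 - s))
    # "infinite" K interpolated geometrically so strength 1 gives 1e9 x K
    grow = INF_K_FACTOR ** s
    if pert.kind == "pxn_delta_LIM34":
        return params.replace(K_E=params.K_E * grow)
    if pert.kind == "pxn_delta_LD1":
        return params.replace(K_A=params.K_A * grow)
    if pert.kind == "pxn_LD13":
        return params.replace(K_E=params.K_E * grow, K_A=params.K_A * grow)
    raise AssertionError(f"unhandled kind {pert.kind}")  # pragma: no cover


# --------------------------------------------------------------------------
# Stochastic single-cell ensembles
# --------------------------------------------------------------------------

def cell_rng(root_seed: int, cell_index: int) -> np.random.Generator:
    """Counter-based per-cell generator: cell ``i`` always gets the same
    stream for a given root seed, independent of ensemble size."""
    ss = np.random.SeedSequence(root_seed, spawn_key=(cell_index,))
    return np.random.default_rng(ss)


def _lognormal_multiplier(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def ensemble(params: SwitchParameters, condition: SubstrateCondition,
             pert: Perturbation = Perturbation("none"), n_cells: int = 150,
             t_end: float = 16.0, seed: int = 0,
             t_pheno: float = 5.0) -> list[CellRecord]:
    """Simulate a population of cells with lognormal cell-to-cell variability.

    Each cell draws independent lognormal multipliers (CV = ``cv_cell``) on
    total paxillin and on the basal endocytic / adhesion production rates,
    starts from the common low-adhesion initial condition, and is integrated
    to ``t_end`` hours.  Phenotype at the 5 hr readout: SL if the Rac1
    readout exceeds ``theta_seg``, else BL.  Neurite bearing at the 16 hr
    readout is a Bernoulli draw with the phenotype-specific probability.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    base = apply_perturbation(params, pert)
    records, failures = [], []
    for i in range(n_cells):
        rng = cell_rng(seed, i)
        mult = {k: _lognormal_multiplier(rng, base.cv_cell)
                for k in ("P_T", "alpha_E", "alpha_A")}
        p_i = base.replace(P_T=base.P_T * mult["P_T"],
                           alpha_E=base.alpha_E * mult["alpha_E"],
                           alpha_A=base.alpha_A * mult["alpha_A"])
        try:
            traj = simulate(p_i, condition, (0.0, t_end),
                            t_eval=sorted({0.0, t_pheno, t_end}), rng=rng)
        except Exception as exc:
            failures.append((i, str(exc)))
            logger.warning("cell %d failed to integrate and was excluded: %s", i, exc)
            continue
        st5 = traj.state_at(t_pheno)
        phenotype = "SL" if st5.R > base.theta_seg else "BL"
        p_neur = base.p_neur_SL if phenotype == "SL" else base.p_neur_BL
        neurite = bool(rng.random() < p_neur)
        records.append(CellRecord(
            cell_id=i, condition_label=condition.label, multipliers=mult,
            state_5hr=st5, state_end=traj.endpoint, phenotype=phenotype,
            neurite_bearing=neurite, seed_key=(seed, i)))
    if failures:
        logger.warning("%d/%d cells excluded after integration failure",
                       len(failures), n_cells)
    return records


def phenotype_fractions(records: Sequence[CellRecord]) -> dict:
    """Summary fractions (percent) for an ensemble."""
    n = len(records)
    if n == 0:
        raise ValueError("empty ensemble")
    n_sl = sum(r.phenotype == "SL" for r in records)
    n_bl = sum(r.phenotype == "BL" for r in records)
    n_neur = sum(r.neurite_bearing for r in records)
    n_bl_no = sum((r.phenotype == "BL") and not r.neurite_bearing for r in records)
    return {
        "n": n,
        "pct_SL": 100.0 * n_sl / n,
        "pct_BL": 100.0 * n_bl / n,
        "pct_neurite": 100.0 * n_neur / n,
        "pct_BL_neuriteless": 100.0 * n_bl_no / n,
        "mean_J_E_5hr": float(np.mean([r.state_5hr.J_E for r in records])),
    }
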