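"""Weighted nonlinear least-squares calibration of the kinetic model.

The fitting problem is

    min_theta  1/2 * sum_t e(t)^T W e(t)    s.t.  dC/dt = v r X,
                                                  theta_min <= theta <= theta_max

with e_i(t) the predicted-minus-measured concentration of measured
species i at sample time t, and W a diagonal per-species scaling matrix
that equalizes the order of magnitude of the discrepancies
(w_i = 1 / max_t |C_i^meas|^2).  The bounded trust-region-reflective
least-squares solver from scipy fulfils this contract.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .kinetics import SPECIES_INDEX, KineticParameterSet
from .simulate import SimulationError, Trajectory, simulate_batch, states_at

logger = logging.getLogger("abekin")

#: Objective value returned when the simulation fails at a trial point;
#: large enough to repel any line search yet finite so optimizers survive.
PENALTY_OBJECTIVE = 1e12


@dataclass
class ExperimentalDataset:
    """Measured (or synthetic) batch time courses.

    ``values`` has one row per sample time and one column per measured
    species; NaN marks a missing cell.  Times must be sorted and
    non-negative, species names canonical, and each measured species
    needs at least two observed values.
    """

    times: np.ndarray
    species: Tuple[str, ...]
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.shape != (self.times.size, len(self.species)):
            raise ValueError(
                f"dataset {self.label!r}: values must be (n_times, n_species), got "
                f"{self.values.shape} for {self.times.size} times / {len(self.species)} species"
            )
        if self.times.size == 0:
            raise ValueError(f"dataset {self.label!r} is empty")
        if np.any(self.times < 0) or np.any(np.diff(self.times) < 0):
            raise ValueError(f"dataset {self.label!r}: times must be sorted and non-negative")
        unknown = [s for s in self.species if s not in SPECIES_INDEX]
        if unknown:
            raise ValueError(f"dataset {self.label!r}: unknown species {unknown}")
        observed = np.sum(~np.isnan(self.values), axis=0)
        thin = [s for s, n in zip(self.species, observed) if n < 2]
        if thin:
            raise ValueError(
                f"dataset {self.label!r}: species {thin} have fewer than 2 observations"
            )

    @property
    def t_max(self) -> float:
        return float(self.times[-1])


def build_scaling_matrix(dataset: ExperimentalDataset) -> np.ndarray:
    """Per-species diagonal weights w_i = 1 / max_t |C_i^meas(t)|^2.

    A species measured as identically zero gets weight 0 (it cannot be
    scaled) and a warning is emitted.
    """
    maxima = np.nanmax(np.abs(dataset.values), axis=0)
    weights = np.zeros(len(dataset.species))
    for j, (name, m) in enumerate(zip(dataset.species, maxima)):
        if m > 0:
            weights[j] = 1.0 / (m * m)
        else:
            warnings.warn(
                f"species {name!r} has all-zero measurements; weight set to 0",
                stacklevel=2,
            )
    return weights


def _predict(
    params: KineticParameterSet,
    dataset: ExperimentalDataset,
    initial: np.ndarray,
    rtol: float,
    atol: float,
) -> np.ndarray:
    """Predicted concentrations at the dataset's sample times/species."""
    traj = simulate_batch(
        initial, params, t_end=max(dataset.t_max, 1e-6), rtol=rtol, atol=atol
    )
    states = states_at(traj, dataset.times)
    cols = [SPECIES_INDEX[s] for s in dataset.species]
    return states[:, cols]


def _weighted_residuals(
    params: KineticParameterSet,
    dataset: ExperimentalDataset,
    weights: np.ndarray,
    initial: np.ndarray,
    rtol: float,
    atol: float,
) -> np.ndarray:
    pred = _predict(params, dataset, initial, rtol, atol)
    e = pred - dataset.values
    e[np.isnan(e)] = 0.0  # missing cells contribute nothing
    return (e * np.sqrt(weights)[None, :]).ravel()


def objective(
    params: KineticParameterSet,
    dataset: ExperimentalDataset,
    weights: Optional[np.ndarray] = None,
    *,
    initial: Optional[np.ndarray] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Evaluate the scaled least-squares objective 1/2 sum_t e^T W e.

    Solver failures return :data:`PENALTY_OBJECTIVE` (with a logged
    diagnostic) instead of raising, so optimizers stay alive.
    """
    if weights is None:
        weights = build_scaling_matrix(dataset)
    if initial is None:
        initial = _initial_from_dataset(dataset)
    try:
        r = _weighted_residuals(params, dataset, np.asarray(weights, float), initial, rtol, atol)
    except SimulationError as exc:
        logger.warning("objective: simulation failed (%s); returning penalty", exc)
        return PENALTY_OBJECTIVE
    return 0.5 * float(r @ r)


def _initial_from_dataset(dataset: ExperimentalDataset) -> np.ndarray:
    """Default initial state: the dataset's first sample where measured,
    packaged pool defaults elsewhere."""
    from .data import packaged_fixture  # deferred to avoid import cycle

    initial = packaged_fixture("shinto_initial").copy()
    if dataset.times[0] == 0.0:
        first = dataset.values[0]
        for name, v in zip(dataset.species, first):
            if not np.isnan(v):
                initial[SPECIES_INDEX[name]] = v
    return initial


def pearson_by_species(
    trajectory: Trajectory, dataset: ExperimentalDataset
) -> Dict[str, float]:
    """Pearson r between predictions (interpolated at sample times) and
    measurements, per species; NaN where a species' measurements are
    constant (the coefficient is undefined there)."""
    states = states_at(trajectory, dataset.times)
    out: Dict[str, float] = {}
    for j, name in enumerate(dataset.species):
        meas = dataset.values[:, j]
        mask = ~np.isnan(meas)
        pred = states[mask, SPECIES_INDEX[name]]
        m = meas[mask]
        if m.size < 2 or np.ptp(m) == 0.0 or np.ptp(pred) == 0.0:
            out[name] = float("nan")
            continue
        out[name] = float(np.corrcoef(pred, m)[0, 1])
    return out


@dataclass
class FitResult:
    """Outcome of a bounded least-squares fit."""

    params: KineticParameterSet
    objective: float
    pearson: Dict[str, float]
    residuals: np.ndarray
    free_names: Tuple[str, ...]
    values: np.ndarray
    bounds: Tuple[np.ndarray, np.ndarray]
    at_bounds: Dict[str, str]
    diagnostics: Dict[str, object] = field(default_factory=dict)

    def summary(self) -> str:
        """Readable per-reaction table of the fitted constants, mirroring
        the published parameter-table layout."""
        lines = [f"fit label: {self.params.label}", f"objective: {self.objective:.6g}",
                 "reaction      v (1/h)      kA (mM)      kB (mM)      kC (mM)"]
        for i in range(1, 20):
            p = self.params.reactions[i]
            cells = [
                f"{x:12.5g}" if x is not None else " " * 12
                for x in (p.v, p.kA, p.kB, p.kC)
            ]
            lines.append(f"r{i:<11d} " + " ".join(cells))
        if self.at_bounds:
            lines.append("parameters at bounds: " + ", ".join(
                f"{k}({v})" for k, v in sorted(self.at_bounds.items())))
        lines.append("Pearson r: " + ", ".join(
            f"{k}={v:.3f}" for k, v in self.pearson.items()))
        return "\n".join(lines)


#: Default bound width around the starting values (theta/100, theta*100).
DEFAULT_BOUND_FACTOR = 100.0


def fit_parameters(
    dataset: ExperimentalDataset,
    initial_params: KineticParameterSet,
    *,
    free: Optional[Sequence[str]] = None,
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    initial_state: Optional[np.ndarray] = None,
    n_starts: int = 1,
    seed: int = 0,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    max_nfev: Optional[int] = None,
) -> FitResult:
    """Fit the requested parameter subset to a dataset.

    ``free`` names the constants to optimize (default: every constant
    that enters a rate law).  ``bounds`` maps names to (lo, hi); unnamed
    free parameters get [theta0/100, theta0*100] around their starting
    value.  ``n_starts > 1`` adds log-uniform multi-starts inside the
    bounds, seeded for reproducibility.  Raises ``RuntimeError`` if the
    model cannot be simulated at the starting point.
    """
    weights = build_scaling_matrix(dataset)
    if initial_state is None:
        initial_state = _initial_from_dataset(dataset)
    free_names: Tuple[str, ...] = tuple(free) if free else initial_params.free_parameter_names()
    theta0 = np.array([initial_params.value(n) for n in free_names])

    lo = np.empty_like(theta0)
    hi = np.empty_like(theta0)
    for k, name in enumerate(free_names):
        if bounds and name in bounds:
            lo[k], hi[k] = bounds[name]
        else:
            lo[k] = theta0[k] / DEFAULT_BOUND_FACTOR
            hi[k] = theta0[k] * DEFAULT_BOUND_FACTOR
        if not (0 < lo[k] <= hi[k]):
            raise ValueError(f"invalid bounds for {name}: ({lo[k]}, {hi[k]})")
    theta0 = np.clip(theta0, lo, hi)

    def with_theta(theta: np.ndarray) -> KineticParameterSet:
        p = initial_params
        for name, value in zip(free_names, theta):
            p = p.with_value(name, value)
        return p

    # the starting point must be simulable; fail fast otherwise
    try:
        _weighted_residuals(with_theta(theta0), dataset, weights, initial_state, rtol, atol)
    except SimulationError as exc:
        raise RuntimeError(
            f"model cannot be simulated at the initial parameter point: {exc}"
        ) from exc

    def resid(theta: np.ndarray) -> np.ndarray:
        try:
            return _weighted_residuals(
                with_theta(theta), dataset, weights, initial_state, rtol, atol
            )
        except SimulationError as exc:
            logger.warning("fit: simulation failed at trial point (%s); penalized", exc)
            return np.full(dataset.values.size, np.sqrt(2 * PENALTY_OBJECTIVE / dataset.values.size))

    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    best = None
    nfev_total = 0
    if np.all(lo == hi):
        # degenerate point bounds: nothing to optimize
        r0 = resid(theta0)
        best = (0.5 * float(r0 @ r0), theta0, r0, {"message": "bounds collapsed to a point", "nfev": 1})
        nfev_total = 1
    else:
        for start in starts:
            sol = least_squares(
                resid, start, bounds=(lo, hi), method="trf",
                x_scale=np.maximum(start, 1e-12), max_nfev=max_nfev,
                # finite-difference steps must dominate the ODE-solver
                # noise floor in the residuals or the Jacobian stalls
                diff_step=1e-3,
            )
            nfev_total += sol.nfev
            obj = 0.5 * float(sol.fun @ sol.fun)
            if best is None or obj < best[0]:
                best = (obj, sol.x, sol.fun, {"message": sol.message, "nfev": sol.nfev,
                                              "status": sol.status})

    obj, theta, res, diag = best
    fitted = with_theta(theta)
    at_bounds = {}
    for name, value, l, h in zip(free_names, theta, lo, hi):
        if l < h:
            if np.isclose(value, l, rtol=1e-8):
                at_bounds[name] = "lower"
            elif np.isclose(value, h, rtol=1e-8):
                at_bounds[name] = "upper"

    traj = simulate_batch(initial_state, fitted, t_end=max(dataset.t_max, 1e-6),
                          rtol=rtol, atol=atol)
    pred = states_at(traj, dataset.times)[:, [SPECIES_INDEX[s] for s in dataset.species]]
    residual_matrix = pred - dataset.values

    return FitResult(
        params=fitted,
        objective=obj,
        pearson=pearson_by_species(traj, dataset),
        residuals=residual_matrix,
        free_names=free_names,
        values=theta,
        bounds=(lo, hi),
        at_bounds=at_bounds,
        diagnostics={**diag, "n_starts": len(starts), "seed": seed,
                     "nfev_total": nfev_total, "weights": weights},
    )
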