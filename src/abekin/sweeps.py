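"""Process-condition sweeps: solvent endpoints and selectivity surfaces.

Batch endpoints (60 h) are computed over grids of initial glucose, NADH
and acetate concentrations, and summarized as butanol, acetone and the
butanol/acetone selectivity Bn/An.  NADH levels are applied as initial
concentrations by default (the cofactor is a dynamic state); a clamped
mode holds NADH at its initial value instead, for the alternative
reading in which the pool is externally buffered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .kinetics import SPECIES_INDEX, KineticParameterSet, validate_state
from .simulate import DEFAULT_T_END, SimulationError, simulate_batch

#: Acetone below this (mM) makes the selectivity ratio undefined.
SELECTIVITY_EPS = 1e-6

#: Default sweep axes: glucose 0-250 mM step 5, NADH 0-80 mM step 2.5.
DEFAULT_GLUCOSE_LEVELS = tuple(np.arange(0.0, 250.0 + 1e-9, 5.0))
DEFAULT_NADH_LEVELS = tuple(np.arange(0.0, 80.0 + 1e-9, 2.5))

_iAn = SPECIES_INDEX["An"]
_iBuOH = SPECIES_INDEX["BuOH"]


class UndefinedSelectivityError(ValueError):
    pass


def selectivity(endpoint_state: np.ndarray, eps: float = SELECTIVITY_EPS) -> float:
    """Butanol/acetone ratio Bn/An at an endpoint state.

    Raises :class:`UndefinedSelectivityError` when acetone <= eps.
    """
    an = float(endpoint_state[_iAn])
    if an <= eps:
        raise UndefinedSelectivityError(
            f"acetone endpoint {an:.3g} mM is at or below eps={eps}; selectivity undefined"
        )
    return float(endpoint_state[_iBuOH]) / an


@dataclass
class SweepGrid:
    """Endpoint summaries over a (glucose x nadh x acetate) grid.

    ``butanol``/``acetone``/``selectivity`` are arrays of shape
    (n_glucose, n_nadh, n_acetate); selectivity is NaN where undefined
    (acetone <= eps) and all three are NaN for failed cells, which are
    listed in ``failures``.
    """

    glucose_levels: np.ndarray
    nadh_levels: np.ndarray
    acetate_levels: np.ndarray
    butanol: np.ndarray
    acetone: np.ndarray
    selectivity: np.ndarray
    t_end: float
    base_initial: np.ndarray
    params: KineticParameterSet
    clamp_nadh: bool = False
    failures: List[Tuple[int, int, int, str]] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for a, g in enumerate(self.glucose_levels):
            for b, n in enumerate(self.nadh_levels):
                for c, ac in enumerate(self.acetate_levels):
                    rows.append((g, n, ac, self.butanol[a, b, c],
                                 self.acetone[a, b, c], self.selectivity[a, b, c]))
        return pd.DataFrame(
            rows,
            columns=["glucose_mM", "nadh_mM", "acetate_mM",
                     "butanol_mM", "acetone_mM", "selectivity"],
        )


def run_sweep(
    params: KineticParameterSet,
    base_initial: np.ndarray,
    glucose_levels: Sequence[float] = DEFAULT_GLUCOSE_LEVELS,
    nadh_levels: Sequence[float] = DEFAULT_NADH_LEVELS,
    acetate_levels: Optional[Sequence[float]] = None,
    t_end: float = DEFAULT_T_END,
    *,
    clamp_nadh: bool = False,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> SweepGrid:
    """Simulate every grid cell to ``t_end`` and record solvent endpoints.

    Each cell copies ``base_initial`` and overrides the initial glucose,
    NADH and (when an acetate axis is given) acetate.  Individual cell
    failures are flagged and the sweep continues.  Cell results are
    independent, so the outcome does not depend on traversal order.
    """
    base_initial = validate_state(base_initial)
    g_levels = np.asarray(sorted(glucose_levels), dtype=float)
    n_levels = np.asarray(sorted(nadh_levels), dtype=float)
    a_levels = (np.asarray(sorted(acetate_levels), dtype=float)
                if acetate_levels is not None
                else np.array([base_initial[SPECIES_INDEX["Ac"]]]))
    if (g_levels < 0).any() or (n_levels < 0).any() or (a_levels < 0).any():
        raise ValueError("sweep levels must be non-negative")

    shape = (g_levels.size, n_levels.size, a_levels.size)
    butanol = np.full(shape, np.nan)
    acetone = np.full(shape, np.nan)
    sel = np.full(shape, np.nan)
    failures: List[Tuple[int, int, int, str]] = []

    hold = ("NADH",) if clamp_nadh else ()
    for a, g in enumerate(g_levels):
        for b, n in enumerate(n_levels):
            for c, ac in enumerate(a_levels):
                init = base_initial.copy()
                init[SPECIES_INDEX["G"]] = g
                init[SPECIES_INDEX["NADH"]] = n
                init[SPECIES_INDEX["Ac"]] = ac
                try:
                    traj = simulate_batch(
                        init, params, t_end=t_end, rtol=rtol, atol=atol,
                        n_points=2, dense_output=False, hold_constant=hold,
                    )
                except SimulationError as exc:
                    failures.append((a, b, c, str(exc)))
                    continue
                end = traj.final_state()
                butanol[a, b, c] = end[_iBuOH]
                acetone[a, b, c] = end[_iAn]
                if end[_iAn] > SELECTIVITY_EPS:
                    sel[a, b, c] = end[_iBuOH] / end[_iAn]

    return SweepGrid(
        glucose_levels=g_levels, nadh_levels=n_levels, acetate_levels=a_levels,
        butanol=butanol, acetone=acetone, selectivity=sel,
        t_end=t_end, base_initial=base_initial, params=params,
        clamp_nadh=clamp_nadh, failures=failures,
    )


_QUANTITIES = ("butanol", "acetone", "selectivity")


def locate_extremum(
    grid: SweepGrid,
    quantity: str,
    kind: str = "max",
    *,
    glucose: Optional[Tuple[float, float]] = None,
    nadh: Optional[Tuple[float, float]] = None,
    acetate: Optional[Tuple[float, float]] = None,
) -> Tuple[Tuple[float, float, float], float]:
    """Extremum of a grid quantity over the admissible (optionally
    range-restricted) cells.

    Returns ((glucose, nadh, acetate), value).  Ties are broken toward
    the lowest axis values in axis order.  Raises ``ValueError`` if every
    admissible cell is undefined.
    """
    if quantity not in _QUANTITIES:
        raise KeyError(f"unknown quantity {quantity!r}; choose from {_QUANTITIES}")
    if kind not in ("max", "min"):
        raise ValueError(f"kind must be 'max' or 'min', got {kind!r}")
    values = getattr(grid, quantity)

    def axis_mask(levels: np.ndarray, window) -> np.ndarray:
        if window is None:
            return np.ones(levels.size, dtype=bool)
        lo, hi = window
        return (levels >= lo) & (levels <= hi)

    mask = (
        axis_mask(grid.glucose_levels, glucose)[:, None, None]
        & axis_mask(grid.nadh_levels, nadh)[None, :, None]
        & axis_mask(grid.acetate_levels, acetate)[None, None, :]
    )
    admissible = mask & ~np.isnan(values)
    if not admissible.any():
        raise ValueError(f"no admissible cell with defined {quantity} in the requested slice")

    masked = np.where(admissible, values, -np.inf if kind == "max" else np.inf)
    flat = np.argmax(masked) if kind == "max" else np.argmin(masked)
    # np.argmax/min return the first (lowest flat index) among ties, which
    # with C-ordering is exactly the lowest-axis-values-in-axis-order rule.
    a, b, c = np.unravel_index(flat, values.shape)
    return (
        (float(grid.glucose_levels[a]), float(grid.nadh_levels[b]), float(grid.acetate_levels[c])),
        float(values[a, b, c]),
    )
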