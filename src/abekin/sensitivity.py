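"""Local dynamic parametric sensitivity.

The sensitivity of species i to parameter theta_j at time tau is the
finite relative response

    S_{i,j}(tau) = [C_i(theta*, tau) - C_i(theta, tau)] / C_i(theta, tau)

where theta* perturbs the single parameter j by a signed fraction
(theta_j* = theta_j * (1 + f)).  S is only defined where the base
concentration is nonzero.  Reported percentages are 100*S.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .kinetics import SPECIES_INDEX, KineticParameterSet
from .simulate import DEFAULT_ATOL, DEFAULT_RTOL, Trajectory, simulate_batch, states_at

#: Default evaluation times (h): acidogenic phase, solventogenic phase,
#: end of fermentation.
DEFAULT_TAUS = (5.0, 15.0, 60.0)
#: Default signed perturbations: +/-20 %.
DEFAULT_FRACTIONS = (0.20, -0.20)


class UndefinedSensitivityError(ValueError):
    """Raised when the base concentration at tau is zero."""


@dataclass(frozen=True)
class SensitivityResult:
    """One (species, parameter, tau, fraction) sensitivity evaluation."""

    species: str
    parameter: str
    tau: float
    fraction: float
    sensitivity: float          # dimensionless relative change
    base_value: float           # C_i(theta, tau), mM
    perturbed_value: float      # C_i(theta*, tau), mM

    @property
    def percent(self) -> float:
        return 100.0 * self.sensitivity


def _base_trajectory(
    params: KineticParameterSet,
    initial: np.ndarray,
    t_end: float,
    rtol: float,
    atol: float,
) -> Trajectory:
    return simulate_batch(initial, params, t_end=t_end, rtol=rtol, atol=atol)


def local_sensitivity(
    params: KineticParameterSet,
    initial: np.ndarray,
    species: str,
    parameter: str,
    fraction: float,
    tau: float,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    _base: Optional[Trajectory] = None,
) -> SensitivityResult:
    """Perturb one parameter by a signed fraction, re-simulate, and
    return the relative concentration change at tau.

    Raises :class:`UndefinedSensitivityError` if the base concentration
    at tau is zero (the measure's side condition).
    """
    if species not in SPECIES_INDEX:
        raise KeyError(f"unknown species {species!r}")
    base = _base or _base_trajectory(params, initial, tau, rtol, atol)
    c_base = float(states_at(base, [tau])[0, SPECIES_INDEX[species]])
    if c_base == 0.0:
        raise UndefinedSensitivityError(
            f"base concentration of {species} at tau={tau} h is zero; "
            "the relative sensitivity is undefined"
        )
    if fraction == 0.0:
        return SensitivityResult(species, parameter, tau, 0.0, 0.0, c_base, c_base)
    perturbed = params.with_value(parameter, params.value(parameter) * (1.0 + fraction))
    traj = simulate_batch(initial, perturbed, t_end=tau, rtol=rtol, atol=atol)
    c_pert = float(states_at(traj, [tau])[0, SPECIES_INDEX[species]])
    return SensitivityResult(
        species, parameter, tau, fraction, (c_pert - c_base) / c_base, c_base, c_pert
    )


def sensitivity_ranking(
    params: KineticParameterSet,
    initial: np.ndarray,
    species: Sequence[str],
    *,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    taus: Sequence[float] = DEFAULT_TAUS,
    top_n: int = 10,
    parameters: Optional[Sequence[str]] = None,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> Dict[Tuple[float, str], List[Tuple[str, float, List[SensitivityResult]]]]:
    """Rank parameters by sensitivity magnitude per (tau, species).

    Each parameter's score is max over the signed fractions of |S|; ties
    are broken alphabetically by parameter name so the ordering is
    deterministic and independent of the input parameter order.  Returns
    ``{(tau, species): [(parameter, score, results), ...]}`` with at most
    ``top_n`` entries per key (the full ranking if top_n exceeds the
    parameter count).
    """
    names = tuple(sorted(parameters if parameters is not None
                         else params.free_parameter_names()))
    taus = tuple(float(t) for t in taus)
    t_end = max(taus)
    base = _base_trajectory(params, initial, t_end, rtol, atol)

    # one perturbed simulation per (parameter, fraction) serves all taus
    per_param: Dict[str, List[List[SensitivityResult]]] = {}
    c_base = {
        (tau, sp): float(states_at(base, [tau])[0, SPECIES_INDEX[sp]])
        for tau in taus for sp in species
    }
    results: Dict[Tuple[float, str], Dict[str, List[SensitivityResult]]] = {
        (tau, sp): {} for tau in taus for sp in species
    }
    for name in names:
        for f in fractions:
            perturbed = params.with_value(name, params.value(name) * (1.0 + f))
            traj = simulate_batch(initial, perturbed, t_end=t_end, rtol=rtol, atol=atol)
            for tau in taus:
                row = states_at(traj, [tau])[0]
                for sp in species:
                    cb = c_base[(tau, sp)]
                    if cb == 0.0:
                        continue
                    cp = float(row[SPECIES_INDEX[sp]])
                    res = SensitivityResult(sp, name, tau, f, (cp - cb) / cb, cb, cp)
                    results[(tau, sp)].setdefault(name, []).append(res)

    ranking: Dict[Tuple[float, str], List[Tuple[str, float, List[SensitivityResult]]]] = {}
    for key, by_param in results.items():
        scored = [
            (name, max(abs(r.sensitivity) for r in rs), rs)
            for name, rs in by_param.items()
        ]
        scored.sort(key=lambda item: (-item[1], item[0]))
        ranking[key] = scored[:top_n] if 0 < top_n < len(scored) else scored
    return ranking


def sensitivity_sweep(
    params: KineticParameterSet,
    initial: np.ndarray,
    species: Sequence[str],
    parameter_names: Sequence[str],
    *,
    fractions: Sequence[float] = tuple(np.round(np.arange(0.05, 0.501, 0.05), 3)),
    signed: bool = True,
    taus: Sequence[float] = DEFAULT_TAUS,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Full factorial sensitivity grid, long format.

    Columns: species, parameter, tau_h, fraction, S_percent.  With
    ``signed`` both +f and -f are evaluated for every listed fraction.
    The grid covers |parameters| x |fractions| x |taus| x |species|
    cells per sign.
    """
    fracs: List[float] = []
    for f in fractions:
        fracs.append(float(f))
        if signed and f != 0.0:
            fracs.append(-float(f))
    taus = tuple(float(t) for t in taus)
    t_end = max(taus)
    base = _base_trajectory(params, initial, t_end, rtol, atol)
    rows = []
    for name in parameter_names:
        for f in fracs:
            if f == 0.0:
                for tau in taus:
                    for sp in species:
                        rows.append((sp, name, tau, 0.0, 0.0))
                continue
            perturbed = params.with_value(name, params.value(name) * (1.0 + f))
            traj = simulate_batch(initial, perturbed, t_end=t_end, rtol=rtol, atol=atol)
            for tau in taus:
                brow = states_at(base, [tau])[0]
                prow = states_at(traj, [tau])[0]
                for sp in species:
                    cb = float(brow[SPECIES_INDEX[sp]])
                    s = (float(prow[SPECIES_INDEX[sp]]) - cb) / cb if cb != 0.0 else np.nan
                    rows.append((sp, name, tau, f, 100.0 * s))
    return pd.DataFrame(rows, columns=["species", "parameter", "tau_h", "fraction", "S_percent"])
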