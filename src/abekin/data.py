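"""Packaged parameter/initial-condition fixtures, synthetic datasets and file I/O.

The model was calibrated against two published batch experiments:

* fit A — *C. saccharoperbutylacetonicum* N1-4 grown on ~70.6 mM glucose
  with 40 mM exogenous acetate (Shinto-type conditions);
* fit B — *C. acetobutylicum* grown on 50 g/L (277.78 mM) glucose
  (Al-Shorgani-type conditions).

The raw calibration time courses come from those external studies and
are not redistributed here; :func:`generate_synthetic_dataset` produces
statistically similar pseudo-experimental tables for estimation work.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .estimate import ExperimentalDataset
from .kinetics import (
    SPECIES,
    SPECIES_INDEX,
    KineticParameterSet,
    ReactionParams,
    state_vector,
)
from .simulate import DEFAULT_T_END, Trajectory, simulate_batch, states_at

# --------------------------------------------------------------------------
# Parameter-table fixtures (fit A and fit B)
# --------------------------------------------------------------------------

# (v 1/h, kA mM, kB mM, kC mM); None = cell empty in the published table.
_FIT_A_TABLE: Dict[int, tuple] = {
    1: (9.89, 11.54, 89.50, 2.56),
    2: (41.10, 4.0e-4, None, None),
    3: (148.27, 4.91e-2, None, None),
    4: (14.23, 154.19, None, None),
    5: (6.22e-2, 494.70, None, None),
    6: (166.00, 0.31, None, None),
    7: (5.40e-3, 111.61, None, None),
    8: (144.91, 0.85, 12.77, None),
    9: (2.18, 85.45, None, None),
    10: (100.23, 3.63e-1, None, None),
    11: (7.63e-1, 46.31, 26.27, None),
    12: (6.35, 0.11, 144.58, None),
    13: (None, 5.06e-2, None, None),
    14: (44.43, 7.42e-1, 2.40, None),
    15: (3.55, 4.30, 53.62, None),
    16: (44.76, 2.43e-1, None, 2.56),
    17: (91.59, 2.85, 2.36, None),
    18: (4.84, 12.66, None, 2.56),
    19: (26.27, 6.0e-1, 28.45, 105.51),
}

# fit B as printed; the published table has empty v cells for r16 and
# r18, so this set is stored non-strict and cannot be simulated without
# supplying those two maximum rates.
_FIT_B_TABLE: Dict[int, tuple] = {
    1: (7.30, 42.40, 62.98, 5.11),
    2: (44.84, 3.20e-5, None, None),
    3: (144.84, 16.93, None, None),
    4: (24.61, 172.78, None, None),
    5: (2.06e-3, 502.49, None, None),
    6: (178.808, 2.53, None, None),
    7: (1.14e-4, 92.65, None, None),
    8: (106.84, 1.51e-2, 19.88, None),
    9: (5.96, 65.19, None, None),
    10: (83.61, 0.49, None, None),
    11: (15.95, 37.62, 46.45, None),
    12: (16.16, 1.05, 155.71, None),
    13: (None, 5.77e-4, None, None),
    14: (9.00, 4.51, 1.29, None),
    15: (91.37, 26.79, 46.78, None),
    16: (None, 1.09, None, None),
    17: (15.60, 23.78, 14.96, None),
    18: (None, 17.35, None, None),
    19: (14.61, 1.82, 32.49, 81.06),
}


def _table_to_set(label: str, table: Dict[int, tuple], strict: bool) -> KineticParameterSet:
    return KineticParameterSet(
        label,
        {i: ReactionParams(*cells) for i, cells in table.items()},
        strict=strict,
    )


#: Default initial concentration (mM) for the lumped intracellular pools
#: the calibration experiments did not measure.
DEFAULT_POOL_INITIAL = 1e-3
#: Default initial NADH (mM): the upper bound of the physiological range
#: (0.039-8.49 mM); see docs/methods.md for the rationale.
DEFAULT_NADH_INITIAL = 8.49


def _default_initial(**measured: float) -> np.ndarray:
    pools = {
        name: DEFAULT_POOL_INITIAL
        for name in ("F6P", "G3P", "Pyr", "Lac", "ACoA", "EtOH", "AACoA", "AcAc", "BCoA")
    }
    pools["NADH"] = DEFAULT_NADH_INITIAL
    pools.update(measured)
    return state_vector(**pools)


def packaged_fixture(name: str) -> Union[KineticParameterSet, np.ndarray]:
    """Return a packaged fixture by name.

    * ``"fit_A"`` / ``"fit_B"`` — the two published parameter sets;
    * ``"shinto_initial"`` — initial condition of the acetate-supplemented
      N1-4 batch (G 70.6, X 0.20, Ac 40.12, Buty 2.12, An 2.58,
      BuOH 4.46 mM); unmeasured pools default to 1e-3 mM and NADH to
      8.49 mM;
    * ``"alshorgani_initial"`` — initial condition of the 50 g/L
      (277.78 mM) glucose batch; only glucose was reported, the same
      inoculum (X 0.20 mM) and pool defaults are used with no exogenous
      acids or solvents.
    """
    if name == "fit_A":
        return _table_to_set("fit A", _FIT_A_TABLE, strict=True)
    if name == "fit_B":
        return _table_to_set("fit B", _FIT_B_TABLE, strict=False)
    if name == "shinto_initial":
        return _default_initial(G=70.6, X=0.20, Ac=40.12, Buty=2.12, An=2.58, BuOH=4.46)
    if name == "alshorgani_initial":
        return _default_initial(G=277.78, X=0.20)
    raise KeyError(
        f"unknown fixture {name!r}; available: fit_A, fit_B, shinto_initial, alshorgani_initial"
    )


# --------------------------------------------------------------------------
# Synthetic pseudo-experimental datasets
# --------------------------------------------------------------------------

#: Species measured in the calibration figures (six panels).
DEFAULT_MEASURED_SPECIES = ("G", "X", "Ac", "Buty", "An", "BuOH")
#: Default sampling schedule mimicking the published figures: 13 points
#: over the 60 h batch.
DEFAULT_SAMPLE_TIMES = tuple(np.linspace(0.0, DEFAULT_T_END, 13))


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for the synthetic generator.

    ``cv`` is the multiplicative coefficient of variation (fraction) and
    ``floor`` an additive noise floor (mM); both perturbations are
    Gaussian and the result is clamped at 0.  The ``seed`` makes
    generation reproducible.
    """

    cv: float = 0.05
    floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.floor < 0:
            raise ValueError("cv and floor must be non-negative")


def apply_noise(values: np.ndarray, noise: NoiseModel) -> np.ndarray:
    """Apply value*(1 + cv*z) + floor*z' noise (z, z' std-normal, seeded)."""
    rng = np.random.default_rng(noise.seed)
    z = rng.standard_normal(values.shape)
    zp = rng.standard_normal(values.shape)
    noisy = values * (1.0 + noise.cv * z) + noise.floor * zp
    return np.clip(noisy, 0.0, None)


def generate_synthetic_dataset(
    params: KineticParameterSet,
    initial: np.ndarray,
    sample_times: Sequence[float] = DEFAULT_SAMPLE_TIMES,
    measured_species: Sequence[str] = DEFAULT_MEASURED_SPECIES,
    noise: Optional[NoiseModel] = None,
    *,
    label: Optional[str] = None,
) -> ExperimentalDataset:
    """Simulate a batch and sample it into a pseudo-experimental table.

    The trajectory is sampled at ``sample_times`` for ``measured_species``
    and perturbed by ``noise`` (noise-free if None).
    """
    sample_times = np.asarray(sorted(sample_times), dtype=float)
    if sample_times.size and sample_times[0] < 0:
        raise ValueError("sample times must be non-negative")
    traj = simulate_batch(initial, params, t_end=float(sample_times[-1]))
    states = states_at(traj, sample_times)
    cols = [SPECIES_INDEX[s] for s in measured_species]
    values = states[:, cols]
    if noise is not None:
        values = apply_noise(values, noise)
        provenance = f"synthetic({params.label}, cv={noise.cv}, floor={noise.floor}, seed={noise.seed})"
    else:
        provenance = f"synthetic({params.label}, noise-free)"
    return ExperimentalDataset(
        times=sample_times,
        species=tuple(measured_species),
        values=values,
        label=label or provenance,
    )


# --------------------------------------------------------------------------
# File I/O
# --------------------------------------------------------------------------

def write_params(params: KineticParameterSet, path) -> None:
    """Serialize a parameter set as a flat YAML config (one record per
    reaction: id, v, kA, kB, kC; absent constants are null)."""
    records = []
    for i in range(1, 20):
        p = params.reactions[i]
        records.append({"id": i, "v": p.v, "kA": p.kA, "kB": p.kB, "kC": p.kC})
    doc = {"label": params.label, "strict": params.strict, "reactions": records}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_params(path) -> KineticParameterSet:
    """Read a parameter set written by :func:`write_params`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        records = doc["reactions"]
        label = doc.get("label", "unlabelled")
        strict = bool(doc.get("strict", True))
        reactions = {
            int(rec["id"]): ReactionParams(
                v=rec.get("v"), kA=rec.get("kA"), kB=rec.get("kB"), kC=rec.get("kC")
            )
            for rec in records
        }
    except (TypeError, KeyError) as exc:
        raise ValueError(f"{path}: malformed parameter config ({exc})") from exc
    return KineticParameterSet(label, reactions, strict=strict)


def write_timecourse(obj: Union[Trajectory, ExperimentalDataset], path) -> None:
    """Write a trajectory or dataset as CSV: ``time_h`` column followed by
    species columns (canonical names); missing cells stay blank."""
    if isinstance(obj, Trajectory):
        frame = pd.DataFrame(obj.states, columns=list(SPECIES))
        frame.insert(0, "time_h", obj.times)
    else:
        frame = pd.DataFrame(obj.values, columns=list(obj.species))
        frame.insert(0, "time_h", obj.times)
    frame.to_csv(path, index=False)


def read_timecourse(path) -> ExperimentalDataset:
    """Read a time-course CSV into an :class:`ExperimentalDataset`.

    Schema: first column ``time_h``, remaining columns canonical species
    names; blank cells are missing values.  Violations raise
    ``ValueError`` naming the offending column or line.  Decimal parsing
    is locale-independent ('.' only).
    """
    try:
        frame = pd.read_csv(path, sep=",", decimal=".")
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse CSV ({exc})") from exc
    if frame.columns.size == 0 or frame.columns[0] != "time_h":
        raise ValueError(f"{path}: first column must be 'time_h', got {list(frame.columns[:1])}")
    species = [c for c in frame.columns[1:]]
    unknown = [c for c in species if c not in SPECIES_INDEX]
    if unknown:
        raise ValueError(f"{path}: unknown species column(s) {unknown}; valid names: {SPECIES}")
    for col in frame.columns:
        bad = frame[col].apply(
            lambda v: not (isinstance(v, (int, float, np.integer, np.floating)) or pd.isna(v))
        )
        if bad.any():
            line = int(np.argmax(bad.values)) + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}")
    times = frame["time_h"].to_numpy(dtype=float)
    values = frame[species].to_numpy(dtype=float)
    return ExperimentalDataset(
        times=times, species=tuple(species), values=values, label=str(path)
    )


def write_sweep(grid, path) -> None:
    """Write a sweep grid as long-format CSV (see sweeps.to_dataframe)."""
    grid.to_dataframe().to_csv(path, index=False)
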