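"""Core kinetics of the NADH-modulated ABE fermentation model.

The model describes batch acetone-butanol-ethanol (ABE) fermentation by
solventogenic *Clostridium* as a network of 19 lumped enzymatic reactions
over 16 balanced species (extracellular substrates/products plus lumped
intracellular pools and the NADH cofactor).  Every balance has the form

    dC/dt = v . r(C) . X

where ``v`` is the 16x19 stoichiometric matrix, ``r`` the vector of
specific reaction rates (per unit biomass, 1/h) and ``X`` the biomass
concentration.  NADH enters as an explicit co-substrate of the three
NAD+-regenerating reductive steps (acetaldehyde dehydrogenase r11,
beta-hydroxybutyryl-CoA dehydrogenase r14, butyraldehyde dehydrogenase
r19), which is what lets the model switch from acidogenesis to
solventogenesis without artificial on-off terms.

All concentrations are mM; biomass is carried in mM as well (no
dry-weight conversion is attempted).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np

logger = logging.getLogger("abekin")

# --------------------------------------------------------------------------
# Species catalogue
# --------------------------------------------------------------------------

#: Canonical species order.  This ordering is shared by state vectors,
#: the rows of the stoichiometric matrix and trajectory columns; it must
#: never be permuted.
SPECIES: Tuple[str, ...] = (
    "G",      # glucose
    "F6P",    # fructose-6-phosphate
    "G3P",    # glyceraldehyde-3-phosphate
    "Pyr",    # pyruvate
    "Lac",    # lactate
    "ACoA",   # acetyl-CoA
    "X",      # biomass
    "Ac",     # acetate
    "EtOH",   # ethanol
    "AACoA",  # acetoacetyl-CoA
    "AcAc",   # acetoacetate (acetone precursor pool)
    "BCoA",   # butyryl-CoA
    "Buty",   # butyrate
    "An",     # acetone
    "BuOH",   # butanol
    "NADH",   # reduced nicotinamide cofactor
)

SPECIES_INDEX: Dict[str, int] = {name: i for i, name in enumerate(SPECIES)}

N_SPECIES = len(SPECIES)
N_REACTIONS = 19

# indices used in hot loops
_iG = SPECIES_INDEX["G"]
_iF6P = SPECIES_INDEX["F6P"]
_iG3P = SPECIES_INDEX["G3P"]
_iPyr = SPECIES_INDEX["Pyr"]
_iLac = SPECIES_INDEX["Lac"]
_iACoA = SPECIES_INDEX["ACoA"]
_iX = SPECIES_INDEX["X"]
_iAc = SPECIES_INDEX["Ac"]
_iAACoA = SPECIES_INDEX["AACoA"]
_iAcAc = SPECIES_INDEX["AcAc"]
_iBCoA = SPECIES_INDEX["BCoA"]
_iButy = SPECIES_INDEX["Buty"]
_iBuOH = SPECIES_INDEX["BuOH"]
_iNADH = SPECIES_INDEX["NADH"]


def state_vector(**concentrations: float) -> np.ndarray:
    """Build a 16-species state vector (mM) from keyword arguments.

    Unspecified species default to 0.  Unknown species names raise
    ``KeyError``.
    """
    state = np.zeros(N_SPECIES)
    for name, value in concentrations.items():
        if name not in SPECIES_INDEX:
            raise KeyError(f"unknown species {name!r}; valid names: {SPECIES}")
        state[SPECIES_INDEX[name]] = float(value)
    return state


def validate_state(state: np.ndarray) -> np.ndarray:
    """Check a state vector (length, finiteness, non-negativity)."""
    state = np.asarray(state, dtype=float)
    if state.shape != (N_SPECIES,):
        raise ValueError(f"state vector must have length {N_SPECIES}, got shape {state.shape}")
    if not np.all(np.isfinite(state)):
        raise ValueError("state vector contains non-finite entries")
    if np.any(state < 0):
        raise ValueError("state vector contains negative concentrations")
    return state


# --------------------------------------------------------------------------
# Kinetic parameter sets
# --------------------------------------------------------------------------

#: Constants each reaction carries: (has_v, has_kA, has_kB, has_kC).
#: r13 (first-order cell death) carries only kA, which is itself the
#: constant specific death rate.
PARAMETER_LAYOUT: Dict[int, Tuple[bool, bool, bool, bool]] = {
    1: (True, True, True, True),
    2: (True, True, False, False),
    3: (True, True, False, False),
    4: (True, True, False, False),
    5: (True, True, False, False),
    6: (True, True, False, False),
    7: (True, True, False, False),
    8: (True, True, True, False),
    9: (True, True, False, False),
    10: (True, True, False, False),
    11: (True, True, True, False),
    12: (True, True, True, False),
    13: (False, True, False, False),
    14: (True, True, True, False),
    15: (True, True, True, False),
    16: (True, True, False, True),   # kC stored but unused by the rate law
    17: (True, True, True, False),
    18: (True, True, False, True),   # kC stored but unused by the rate law
    19: (True, True, True, True),
}

#: Reactions whose tabulated kC does not appear in the printed rate law.
UNUSED_KC_REACTIONS = (16, 18)


@dataclass(frozen=True)
class ReactionParams:
    """Constants of one reaction: max specific rate v (1/h) and up to
    three binding/inhibition constants kA, kB, kC (mM)."""

    v: Optional[float] = None
    kA: Optional[float] = None
    kB: Optional[float] = None
    kC: Optional[float] = None

    def get(self, name: str) -> Optional[float]:
        return getattr(self, name)


@dataclass(frozen=True)
class KineticParameterSet:
    """Full parameterization of the 19-reaction network.

    ``reactions`` maps reaction number (1..19) to its constants; the
    presence pattern must match :data:`PARAMETER_LAYOUT` for the set to
    be simulable (``strict=False`` relaxes this to allow incompletely
    printed sets to be stored).
    """

    label: str
    reactions: Mapping[int, ReactionParams]
    strict: bool = True

    def __post_init__(self) -> None:
        missing = set(range(1, N_REACTIONS + 1)) - set(self.reactions)
        if missing:
            raise ValueError(f"parameter set {self.label!r} lacks reactions {sorted(missing)}")
        for i, p in self.reactions.items():
            layout = PARAMETER_LAYOUT[i]
            for flag, name in zip(layout, ("v", "kA", "kB", "kC")):
                value = p.get(name)
                if value is not None and not (math.isfinite(value) and value > 0):
                    raise ValueError(
                        f"reaction r{i}: constant {name} must be strictly positive, got {value}"
                    )
                if self.strict and flag and value is None:
                    raise ValueError(
                        f"parameter set {self.label!r} is missing {name} for reaction r{i}"
                    )
                if value is not None and not flag:
                    raise ValueError(
                        f"reaction r{i} does not carry constant {name} (got {value})"
                    )
        for i in UNUSED_KC_REACTIONS:
            if self.reactions[i].kC is not None:
                logger.info(
                    "parameter set %r: r%d carries kC=%.4g which the printed rate law "
                    "does not use; stored but ignored in rate evaluation",
                    self.label, i, self.reactions[i].kC,
                )

    # -- parameter addressing -------------------------------------------------
    @staticmethod
    def _split(name: str) -> Tuple[int, str]:
        """Parse a flat parameter name such as 'V1' or 'k19C'."""
        if name.startswith("V"):
            return int(name[1:]), "v"
        if name.startswith("k") and name[-1] in "ABC":
            return int(name[1:-1]), "k" + name[-1]
        raise KeyError(f"unrecognized parameter name {name!r}")

    def value(self, name: str) -> float:
        i, attr = self._split(name)
        v = self.reactions[i].get(attr)
        if v is None:
            raise KeyError(f"parameter {name!r} is absent from set {self.label!r}")
        return v

    def with_value(self, name: str, value: float) -> "KineticParameterSet":
        """Return a copy with one named parameter replaced."""
        i, attr = self._split(name)
        if self.reactions[i].get(attr) is None:
            raise KeyError(f"parameter {name!r} is absent from set {self.label!r}")
        reactions = dict(self.reactions)
        reactions[i] = replace(reactions[i], **{attr: float(value)})
        return KineticParameterSet(self.label, reactions, strict=self.strict)

    def parameter_names(self) -> Tuple[str, ...]:
        """Flat names of all present constants, in reaction order."""
        names = []
        for i in range(1, N_REACTIONS + 1):
            p = self.reactions[i]
            if p.v is not None:
                names.append(f"V{i}")
            for suffix in "ABC":
                if p.get("k" + suffix) is not None:
                    names.append(f"k{i}{suffix}")
        return tuple(names)

    def free_parameter_names(self) -> Tuple[str, ...]:
        """Names of constants that actually enter the rate laws (the
        tabulated-but-unused kC of r16/r18 are excluded)."""
        return tuple(
            n for n in self.parameter_names()
            if not (n.endswith("C") and int(n[1:-1]) in UNUSED_KC_REACTIONS)
        )

    def _arrays(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Constants as dense arrays (NaN for absent); cached."""
        cached = getattr(self, "_array_cache", None)
        if cached is None:
            out = []
            for attr in ("v", "kA", "kB", "kC"):
                arr = np.full(N_REACTIONS, np.nan)
                for i, p in self.reactions.items():
                    val = p.get(attr)
                    if val is not None:
                        arr[i - 1] = val
                out.append(arr)
            cached = tuple(out)
            object.__setattr__(self, "_array_cache", cached)
        return cached

    def _lists(self) -> Tuple[list, list, list, list]:
        """Constants as plain lists for the rate-evaluation hot path."""
        cached = getattr(self, "_list_cache", None)
        if cached is None:
            cached = tuple(arr.tolist() for arr in self._arrays())
            object.__setattr__(self, "_list_cache", cached)
        return cached


# --------------------------------------------------------------------------
# Rate-law families
# --------------------------------------------------------------------------

def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (math.isfinite(value) and value > 0):
            raise ValueError(f"{name} must be finite and > 0, got {value}")


def _check_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (math.isfinite(value) and value >= 0):
            raise ValueError(f"{name} must be finite and >= 0, got {value}")


def mm_rate(V: float, Km: float, S: float) -> float:
    """Michaelis-Menten rate V*S/(Km+S) (1/h).

    Monotone non-decreasing in S and bounded above by V.
    """
    _check_positive(V=V, Km=Km)
    _check_nonneg(S=S)
    return V * S / (Km + S)


def ping_pong_rate(V: float, K1: float, K2: float, S1: float, S2: float) -> float:
    """Two-substrate ping-pong rate V*S1*S2/(K1*S1 + K2*S2 + S1*S2).

    ``K1`` multiplies ``S1`` and ``K2`` multiplies ``S2`` in the
    denominator; callers are responsible for the pairing, which in this
    model is transcribed verbatim from the per-reaction equations (the
    NADH reactions pair each tabulated constant with the *other*
    species).  The 0/0 limit at S1=S2=0 is taken as 0.
    """
    _check_positive(V=V, K1=K1, K2=K2)
    _check_nonneg(S1=S1, S2=S2)
    den = K1 * S1 + K2 * S2 + S1 * S2
    if den == 0.0:
        return 0.0
    return V * S1 * S2 / den


def ping_pong_inhibited_rate(
    V: float, K1: float, K2: float, Ki: float, S1: float, S2: float, I: float
) -> float:
    """Ping-pong rate with a competitive inhibitor scaling the S1*S2
    denominator term by (1 + I/Ki).  Reduces to :func:`ping_pong_rate`
    at I=0 and is strictly decreasing in I for S1, S2 > 0."""
    _check_positive(Ki=Ki)
    _check_nonneg(I=I)
    _check_positive(V=V, K1=K1, K2=K2)
    _check_nonneg(S1=S1, S2=S2)
    den = K1 * S1 + K2 * S2 + S1 * S2 * (1.0 + I / Ki)
    if den == 0.0:
        return 0.0
    return V * S1 * S2 / den


def dual_mm_rate(V: float, KA: float, KB: float, S1: float, S2: float) -> float:
    """Product of two independent Michaelis-Menten factors,
    V * S1/(KA+S1) * S2/(KB+S2); used for the CoA-transferase acid
    re-assimilation steps where both substrates saturate independently."""
    _check_positive(V=V, KA=KA, KB=KB)
    _check_nonneg(S1=S1, S2=S2)
    return V * (S1 / (KA + S1)) * (S2 / (KB + S2))


def glucose_uptake_rate(
    V: float, kA: float, kB: float, kC: float, G: float, BuOH: float
) -> float:
    """Specific glucose consumption rate r1 (1/h).

    Single documented home of the r1 denominator grouping:

        r1 = V * G / ( kA*(1 + G/kC) + G*(1 + BuOH/kB) )

    kA (mM) is the Michaelis constant, kC (mM) the substrate-inhibition
    constant (the kA*(1+G/kC) term grows linearly in G, capping uptake
    well below V at high glucose), and kB (mM) the butanol-inhibition
    constant.  Assigning the small tabulated constant (2.56 mM) to the
    glucose-inhibition term and the large one (89.50 mM) to butanol is
    the only reading consistent with the model's own high-glucose
    behaviour (butanol accumulating far past 100 mM) and with the scale
    of the other butanol-inhibition constants in the same table
    (k12B=144.58, k19C=105.51 mM).  Correcting the grouping only
    requires editing this function.
    """
    _check_positive(V=V, kA=kA, kB=kB, kC=kC)
    _check_nonneg(G=G, BuOH=BuOH)
    return V * G / (kA * (1.0 + G / kC) + G * (1.0 + BuOH / kB))


def butyrate_uptake_rate(V: float, kA: float, kB: float, Buty: float) -> float:
    """Butyrate re-assimilation rate r17 (1/h),

        r17 = V * Buty / ( kA*(1 + kB/Buty) + Buty )

    evaluated in the equivalent polynomial form
    V*Buty^2 / (kA*Buty + kA*kB + Buty^2), which is smooth at Buty=0
    (the rate and its derivative vanish there); the kB/Buty term
    suppresses uptake at low butyrate."""
    _check_positive(V=V, kA=kA, kB=kB)
    _check_nonneg(Buty=Buty)
    return V * Buty * Buty / (kA * Buty + kA * kB + Buty * Buty)


# --------------------------------------------------------------------------
# The 19 reaction rates
# --------------------------------------------------------------------------

def compute_rate_vector(state: np.ndarray, params: KineticParameterSet) -> np.ndarray:
    """Evaluate all 19 specific reaction rates (1/h) at a state.

    Negative state entries (tolerated transients of stiff integration)
    are clamped to 0 before evaluation, so rates are always evaluated on
    an admissible state.  Raises ``KeyError`` naming the reaction if a
    required constant is absent.
    """
    v, kA, kB, kC = params._arrays()
    if not getattr(params, "_complete_checked", False):
        for i in range(1, N_REACTIONS + 1):
            layout = PARAMETER_LAYOUT[i]
            for needed, arr, name in zip(layout, (v, kA, kB, kC), ("v", "kA", "kB", "kC")):
                if needed and np.isnan(arr[i - 1]):
                    raise KeyError(
                        f"parameter set {params.label!r} cannot evaluate reaction r{i}: "
                        f"required constant {name} missing"
                    )
        object.__setattr__(params, "_complete_checked", True)
    # plain-float arithmetic: this function dominates the integration
    # cost, and Python floats are several times faster than numpy scalars
    c = [x if x > 0.0 else 0.0 for x in np.asarray(state, dtype=float).tolist()]
    G = c[_iG]; F6P = c[_iF6P]; G3P = c[_iG3P]; Pyr = c[_iPyr]
    Lac = c[_iLac]; ACoA = c[_iACoA]; Ac = c[_iAc]; AACoA = c[_iAACoA]
    AcAc = c[_iAcAc]; BCoA = c[_iBCoA]; Buty = c[_iButy]
    BuOH = c[_iBuOH]; NADH = c[_iNADH]
    v, kA, kB, kC = params._lists()

    # r1: glucose uptake (PTS), substrate + butanol inhibition; the
    # grouping is documented in glucose_uptake_rate, which this mirrors
    r1 = v[0] * G / (kA[0] * (1.0 + G / kC[0]) + G * (1.0 + BuOH / kB[0]))
    # r2: phosphofructokinase leg, F6P -> G3P
    r2 = v[1] * F6P / (kA[1] + F6P)
    # r3: GAPDH leg, G3P -> Pyr (+ NADH)
    r3 = v[2] * G3P / (kA[2] + G3P)
    # r4: lactate dehydrogenase (reverse), Lac -> Pyr
    r4 = v[3] * Lac / (kA[3] + Lac)
    # r5: lactate dehydrogenase (forward), Pyr -> Lac
    r5 = v[4] * Pyr / (kA[4] + Pyr)
    # r6: pyruvate-ferredoxin oxidoreductase, Pyr -> ACoA
    r6 = v[5] * Pyr / (kA[5] + Pyr)
    # r7: acetate re-uptake, Ac -> ACoA
    r7 = v[6] * Ac / (kA[6] + Ac)
    # r8: CoA-transferase (acetate leg): Ac + AACoA -> ACoA + AcAc
    r8 = v[7] * (Ac / (kA[7] + Ac)) * (AACoA / (kB[7] + AACoA))
    # r9: PTA/AK, ACoA -> Ac
    r9 = v[8] * ACoA / (kA[8] + ACoA)
    # r10: thiolase, ACoA -> AACoA
    r10 = v[9] * ACoA / (kA[9] + ACoA)
    # r11: AYDH/EDH, ACoA + NADH -> EtOH; constants pair with the
    # opposite species as printed (kA with NADH, kB with ACoA)
    den = ACoA * NADH + kA[10] * NADH + kB[10] * ACoA
    r11 = v[10] * ACoA * NADH / den if den > 0.0 else 0.0
    # r12: growth on ACoA with butanol inhibition
    r12 = v[11] * ACoA / ((kA[11] + ACoA) * (1.0 + BuOH / kB[11]))
    # r13: constant specific death rate
    r13 = kA[12]
    # r14: BHBD/ECH/BCD, AACoA + NADH -> BCoA (kA with NADH, kB with AACoA)
    den = AACoA * NADH + kA[13] * NADH + kB[13] * AACoA
    r14 = v[13] * AACoA * NADH / den if den > 0.0 else 0.0
    # r15: CoA-transferase (butyrate leg): Buty + AACoA -> BCoA + AcAc
    r15 = v[14] * (Buty / (kA[14] + Buty)) * (AACoA / (kB[14] + AACoA))
    # r16: acetoacetate decarboxylase, AcAc -> An
    r16 = v[15] * AcAc / (kA[15] + AcAc)
    # r17: butyrate uptake (PTB/BK reverse), smooth polynomial form
    r17 = v[16] * Buty * Buty / (kA[16] * Buty + kA[16] * kB[16] + Buty * Buty)
    # r18: PTB/BK, BCoA -> Buty
    r18 = v[17] * BCoA / (kA[17] + BCoA)
    # r19: BYDH/BDH, BCoA + NADH -> BuOH, competitive butanol inhibition;
    # here each constant pairs with its own species as printed
    den = kA[18] * BCoA + kB[18] * NADH + BCoA * NADH * (1.0 + BuOH / kC[18])
    r19 = v[18] * BCoA * NADH / den if den > 0.0 else 0.0
    return np.array([r1, r2, r3, r4, r5, r6, r7, r8, r9, r10, r11, r12, r13,
                     r14, r15, r16, r17, r18, r19])


# --------------------------------------------------------------------------
# Stoichiometric matrix
# --------------------------------------------------------------------------

#: Substrates and products of each reaction (the Fig.-1 network edge
#: list).  Coefficients are +-1 throughout, matching the printed balance
#: matrix; lumped reactions absorb the true molecularities into their
#: fitted constants.  NADH coefficients follow the model's cofactor
#: bookkeeping: glycolysis credits 2 NADH per glucose at the GAPDH leg
#: (the network carries one G3P per glucose), the ferredoxin cycle
#: credits 1 more at PFOR (part of that pool is drained to NADPH), and
#: each lumped reductive step (r11, r14, r19) debits 2.
REACTION_STOICHIOMETRY: Dict[int, Dict[str, int]] = {
    1: {"G": -1, "F6P": 1},                                    # glucose PTS uptake
    2: {"F6P": -1, "G3P": 1},                                  # PFK/aldolase
    3: {"G3P": -1, "Pyr": 1, "NADH": 2},                       # GAPDH..pyruvate kinase
    4: {"Lac": -1, "Pyr": 1},                                  # LDH reverse
    5: {"Pyr": -1, "Lac": 1},                                  # LDH forward
    6: {"Pyr": -1, "ACoA": 1, "NADH": 1},                      # PFOR + Fd/NADH cycle
    7: {"Ac": -1, "ACoA": 1},                                  # acetate re-uptake
    8: {"Ac": -1, "AACoA": -1, "ACoA": 1, "AcAc": 1},          # CoAT (acetate leg)
    9: {"ACoA": -1, "Ac": 1},                                  # PTA/AK
    10: {"ACoA": -1, "AACoA": 1},                              # thiolase
    11: {"ACoA": -1, "EtOH": 1, "NADH": -2},                   # AYDH/EDH
    12: {"ACoA": -1, "X": 1},                                  # growth
    13: {"X": -1},                                             # cell death
    14: {"AACoA": -1, "BCoA": 1, "NADH": -2},                  # BHBD/ECH/BCD
    15: {"Buty": -1, "AACoA": -1, "BCoA": 1, "AcAc": 1},       # CoAT (butyrate leg)
    16: {"AcAc": -1, "An": 1},                                 # acetoacetate decarboxylase
    17: {"Buty": -1, "BCoA": 1},                               # butyrate uptake
    18: {"BCoA": -1, "Buty": 1},                               # PTB/BK
    19: {"BCoA": -1, "BuOH": 1, "NADH": -2},                   # BYDH/BDH
}


def build_stoichiometric_matrix() -> np.ndarray:
    """Return the fixed 16x19 stoichiometric matrix (int).

    Rows follow :data:`SPECIES`, columns reaction numbers 1..19.  The
    entries are assembled from :data:`REACTION_STOICHIOMETRY`, the
    network edge list cross-validated against the printed balance
    matrix (which is used verbatim wherever its rows are internally
    consistent) and, for the cofactor row, against the model's stated
    NADH bookkeeping.
    """
    mat = np.zeros((N_SPECIES, N_REACTIONS), dtype=int)
    for j, stoich in REACTION_STOICHIOMETRY.items():
        for name, coeff in stoich.items():
            mat[SPECIES_INDEX[name], j - 1] = coeff
    return mat


_STOICH_FLOAT = build_stoichiometric_matrix().astype(float)


def rhs(t: float, state: np.ndarray, params: KineticParameterSet) -> np.ndarray:
    """Right-hand side of the balance equations, dC/dt = v . r(C) . X.

    The system is autonomous; ``t`` is accepted for ODE-solver
    compatibility only.  Every balance is scaled by the biomass entry of
    the state, so a culture with X = 0 is exactly quiescent.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N_SPECIES,):
        raise ValueError(f"state vector must have length {N_SPECIES}")
    X = state[_iX]
    if X <= 0.0:
        return np.zeros(N_SPECIES)
    return _STOICH_FLOAT @ compute_rate_vector(state, params) * X
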