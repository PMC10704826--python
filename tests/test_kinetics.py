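"""Rate-law families, the 19-reaction rate vector, stoichiometry and RHS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from abekin import (
    SPECIES,
    SPECIES_INDEX,
    build_stoichiometric_matrix,
    compute_rate_vector,
    dual_mm_rate,
    mm_rate,
    packaged_fixture,
    ping_pong_inhibited_rate,
    ping_pong_rate,
    rhs,
    state_vector,
)
from abekin.kinetics import PARAMETER_LAYOUT, glucose_uptake_rate

finite_pos = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)
finite_nonneg = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)


# --------------------------------------------------------------------------
# rate-law families
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "V, Km, S, expected",
    [
        (10.0, 5.0, 5.0, 5.0),                       # half saturation
        (10.0, 5.0, 0.0, 0.0),                       # zero substrate
        (41.10, 4.0e-4, 0.01, 41.10 * 0.01 / (4.0e-4 + 0.01)),  # r2 fit-A constants
    ],
)
def test_mm_rate_values(V, Km, S, expected):
    assert mm_rate(V, Km, S) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("bad", [dict(V=-1, Km=1, S=1), dict(V=1, Km=0, S=1),
                                 dict(V=1, Km=1, S=-0.5), dict(V=float("nan"), Km=1, S=1)])
def test_mm_rate_rejects_invalid_arguments(bad):
    with pytest.raises(ValueError):
        mm_rate(**bad)


@settings(derandomize=True, max_examples=200)
@given(V=finite_pos, Km=finite_pos, S1=finite_nonneg, S2=finite_nonneg)
def test_mm_rate_monotone_and_bounded(V, Km, S1, S2):
    lo, hi = sorted((S1, S2))
    assert 0.0 <= mm_rate(V, Km, lo) <= mm_rate(V, Km, hi) <= V


def test_ping_pong_values():
    assert ping_pong_rate(1.0, 1.0, 1.0, 1.0, 1.0) == pytest.approx(1.0 / 3.0)
    # co-substrate depletion halts the reaction
    assert ping_pong_rate(5.0, 2.0, 3.0, 7.0, 0.0) == 0.0
    assert ping_pong_rate(5.0, 2.0, 3.0, 0.0, 0.0) == 0.0  # 0/0 limit convention
    # saturation at the limit of large concentrations
    assert ping_pong_rate(5.0, 2.0, 3.0, 1e9, 1e9) == pytest.approx(5.0, rel=1e-5)


def test_ping_pong_inhibited_values():
    assert ping_pong_inhibited_rate(1, 1, 1, 1, 1, 1, 1) == pytest.approx(0.25)
    # fit-A r19 constants, direct substitution oracle
    V, kA, kB, kC = 26.27, 0.6, 28.45, 105.51
    BCoA, NADH, BuOH = 0.5, 3.0, 20.0
    expected = V * BCoA * NADH / (kA * BCoA + kB * NADH + BCoA * NADH * (1 + BuOH / kC))
    got = ping_pong_inhibited_rate(V, kA, kB, kC, BCoA, NADH, BuOH)
    assert got == pytest.approx(expected, rel=1e-12)


@settings(derandomize=True, max_examples=300)
@given(V=finite_pos, K1=finite_pos, K2=finite_pos, Ki=finite_pos,
       S1=finite_nonneg, S2=finite_nonneg)
def test_inhibitor_free_reduction(V, K1, K2, Ki, S1, S2):
    """Zero inhibitor reduces the inhibited ping-pong law to the plain one
    to machine precision."""
    assert ping_pong_inhibited_rate(V, K1, K2, Ki, S1, S2, 0.0) == ping_pong_rate(
        V, K1, K2, S1, S2
    )


def test_inhibitor_free_reduction_bulk(rng):
    """The same reduction on 1000 random inputs (seeded)."""
    for _ in range(1000):
        V, K1, K2, Ki = rng.uniform(1e-3, 1e3, 4)
        S1, S2 = rng.uniform(0, 1e3, 2)
        assert ping_pong_inhibited_rate(V, K1, K2, Ki, S1, S2, 0.0) == ping_pong_rate(
            V, K1, K2, S1, S2
        )


@settings(derandomize=True, max_examples=200)
@given(V=finite_pos, K1=finite_pos, K2=finite_pos, Ki=finite_pos,
       S1=finite_pos, S2=finite_pos, I1=finite_nonneg, I2=finite_nonneg)
def test_inhibition_strictly_decreasing(V, K1, K2, Ki, S1, S2, I1, I2):
    lo, hi = sorted((I1, I2))
    r_lo = ping_pong_inhibited_rate(V, K1, K2, Ki, S1, S2, lo)
    r_hi = ping_pong_inhibited_rate(V, K1, K2, Ki, S1, S2, hi)
    assert r_hi <= r_lo
    den_lo = K1 * S1 + K2 * S2 + S1 * S2 * (1.0 + lo / Ki)
    den_hi = K1 * S1 + K2 * S2 + S1 * S2 * (1.0 + hi / Ki)
    if den_hi > den_lo:  # inhibitor change representable at double precision
        assert r_hi < r_lo


def test_dual_mm_values():
    assert dual_mm_rate(8.0, 2.0, 3.0, 2.0, 3.0) == pytest.approx(2.0)  # V/4
    assert dual_mm_rate(8.0, 2.0, 3.0, 5.0, 0.0) == 0.0
    # fit-A r8 constants at half saturation of both substrates
    assert dual_mm_rate(144.91, 0.85, 12.77, 0.85, 12.77) == pytest.approx(144.91 / 4)


# --------------------------------------------------------------------------
# full rate vector
# --------------------------------------------------------------------------

def test_all_zero_state_only_death_rate(fit_a):
    r = compute_rate_vector(np.zeros(16), fit_a)
    assert r[12] == pytest.approx(5.06e-2)  # r13 = k13A
    others = np.delete(r, 12)
    assert np.all(others == 0.0)


def test_nadh_only_state_zeroes_ping_pong_rates(fit_a):
    state = state_vector(NADH=5.0)
    r = compute_rate_vector(state, fit_a)
    assert r[10] == 0.0 and r[13] == 0.0 and r[18] == 0.0  # r11, r14, r19


def test_rate_vector_matches_direct_substitution(fit_a, shinto_initial):
    """Independent arithmetic oracle: every printed rate law evaluated by
    direct substitution of the fit-A constants at the reference initial
    condition."""
    c = {name: shinto_initial[SPECIES_INDEX[name]] for name in SPECIES}
    G, Ac, Buty, An, BuOH = c["G"], c["Ac"], c["Buty"], c["An"], c["BuOH"]
    pool = 1e-3
    NADH = 8.49
    expected = [
        9.89 * G / (11.54 * (1 + G / 2.56) + G * (1 + BuOH / 89.50)),
        41.10 * pool / (4.0e-4 + pool),
        148.27 * pool / (4.91e-2 + pool),
        14.23 * pool / (154.19 + pool),
        6.22e-2 * pool / (494.70 + pool),
        166.00 * pool / (0.31 + pool),
        5.40e-3 * Ac / (111.61 + Ac),
        144.91 * (Ac / (0.85 + Ac)) * (pool / (12.77 + pool)),
        2.18 * pool / (85.45 + pool),
        100.23 * pool / (0.363 + pool),
        0.763 * pool * NADH / (pool * NADH + 46.31 * NADH + 26.27 * pool),
        6.35 * pool / ((0.11 + pool) * (1 + BuOH / 144.58)),
        5.06e-2,
        44.43 * pool * NADH / (pool * NADH + 0.742 * NADH + 2.40 * pool),
        3.55 * (Buty / (4.30 + Buty)) * (pool / (53.62 + pool)),
        44.76 * pool / (0.243 + pool),
        91.59 * Buty / (2.85 * (1 + 2.36 / Buty) + Buty),
        4.84 * pool / (12.66 + pool),
        26.27 * pool * NADH / (0.6 * pool + 28.45 * NADH + pool * NADH * (1 + BuOH / 105.51)),
    ]
    got = compute_rate_vector(shinto_initial, fit_a)
    assert got == pytest.approx(expected, rel=1e-12)


def test_rate_vector_saturation_bounds_random_states(fit_a, rng):
    """On 1000 random non-negative states every rate is finite,
    non-negative and bounded by its maximum specific rate."""
    vmax = np.array([
        fit_a.reactions[i].v if PARAMETER_LAYOUT[i][0] else fit_a.reactions[i].kA
        for i in range(1, 20)
    ])
    for _ in range(1000):
        state = rng.lognormal(mean=0.0, sigma=3.0, size=16)
        state[rng.random(16) < 0.3] = 0.0
        r = compute_rate_vector(state, fit_a)
        assert np.all(np.isfinite(r)) and np.all(r >= 0.0)
        assert np.all(r <= vmax * (1 + 1e-12))


def test_zero_substrate_zero_rate(fit_a, rng):
    """Zeroing the numerator substrate of each rate law zeroes that rate."""
    # reaction -> species whose absence stops it (numerator substrates)
    stoppers = {1: "G", 2: "F6P", 3: "G3P", 4: "Lac", 5: "Pyr", 6: "Pyr", 7: "Ac",
                8: "Ac", 9: "ACoA", 10: "ACoA", 11: "ACoA", 12: "ACoA", 14: "AACoA",
                15: "Buty", 16: "AcAc", 17: "Buty", 18: "BCoA", 19: "BCoA"}
    state = rng.lognormal(size=16)
    for i, name in stoppers.items():
        s = state.copy()
        s[SPECIES_INDEX[name]] = 0.0
        assert compute_rate_vector(s, fit_a)[i - 1] == 0.0


def test_rate_vector_consistent_with_rate_law_functions(fit_a, shinto_initial):
    """The vectorized evaluation agrees with the standalone rate-law
    functions (guards the inlined hot path against drift)."""
    r = compute_rate_vector(shinto_initial, fit_a)
    G = shinto_initial[SPECIES_INDEX["G"]]
    BuOH = shinto_initial[SPECIES_INDEX["BuOH"]]
    Ac = shinto_initial[SPECIES_INDEX["Ac"]]
    AACoA = shinto_initial[SPECIES_INDEX["AACoA"]]
    NADH = shinto_initial[SPECIES_INDEX["NADH"]]
    BCoA = shinto_initial[SPECIES_INDEX["BCoA"]]
    p1, p8, p11, p19 = (fit_a.reactions[i] for i in (1, 8, 11, 19))
    assert r[0] == pytest.approx(
        glucose_uptake_rate(p1.v, p1.kA, p1.kB, p1.kC, G, BuOH), rel=1e-14)
    assert r[7] == pytest.approx(
        dual_mm_rate(p8.v, p8.kA, p8.kB, Ac, AACoA), rel=1e-14)
    # printed NADH reactions pair each constant with the other species
    assert r[10] == pytest.approx(
        ping_pong_rate(p11.v, p11.kB, p11.kA, shinto_initial[SPECIES_INDEX["ACoA"]], NADH),
        rel=1e-14)
    assert r[18] == pytest.approx(
        ping_pong_inhibited_rate(p19.v, p19.kA, p19.kB, p19.kC, BCoA, NADH, BuOH),
        rel=1e-14)


def test_negative_entries_clamped_before_evaluation(fit_a, shinto_initial):
    wiggled = shinto_initial.copy()
    wiggled[SPECIES_INDEX["Lac"]] = -1e-9
    clean = shinto_initial.copy()
    clean[SPECIES_INDEX["Lac"]] = 0.0
    assert np.array_equal(compute_rate_vector(wiggled, fit_a),
                          compute_rate_vector(clean, fit_a))


def test_missing_parameter_names_reaction():
    incomplete = packaged_fixture("fit_B")  # printed table lacks V16/V18
    with pytest.raises(KeyError, match="r16"):
        compute_rate_vector(np.ones(16), incomplete)


# --------------------------------------------------------------------------
# stoichiometric matrix and RHS
# --------------------------------------------------------------------------

# Hand-encoded network adjacency (substrates, products) per reaction,
# transcribed from the pathway diagram independently of the builder.
ADJACENCY = {
    1: ({"G"}, {"F6P"}),
    2: ({"F6P"}, {"G3P"}),
    3: ({"G3P"}, {"Pyr", "NADH"}),
    4: ({"Lac"}, {"Pyr"}),
    5: ({"Pyr"}, {"Lac"}),
    6: ({"Pyr"}, {"ACoA", "NADH"}),
    7: ({"Ac"}, {"ACoA"}),
    8: ({"Ac", "AACoA"}, {"ACoA", "AcAc"}),
    9: ({"ACoA"}, {"Ac"}),
    10: ({"ACoA"}, {"AACoA"}),
    11: ({"ACoA", "NADH"}, {"EtOH"}),
    12: ({"ACoA"}, {"X"}),
    13: ({"X"}, set()),
    14: ({"AACoA", "NADH"}, {"BCoA"}),
    15: ({"Buty", "AACoA"}, {"BCoA", "AcAc"}),
    16: ({"AcAc"}, {"An"}),
    17: ({"Buty"}, {"BCoA"}),
    18: ({"BCoA"}, {"Buty"}),
    19: ({"BCoA", "NADH"}, {"BuOH"}),
}


def test_matrix_shape_and_entries():
    mat = build_stoichiometric_matrix()
    assert mat.shape == (16, 19)
    assert mat.dtype.kind == "i"
    assert set(np.unique(mat)) <= {-2, -1, 0, 1, 2}


def test_matrix_column_supports_match_network():
    mat = build_stoichiometric_matrix()
    for j, (subs, prods) in ADJACENCY.items():
        col = mat[:, j - 1]
        assert {SPECIES[i] for i in np.flatnonzero(col < 0)} == subs, f"r{j} substrates"
        assert {SPECIES[i] for i in np.flatnonzero(col > 0)} == prods, f"r{j} products"


def test_glucose_row_single_debit():
    row = build_stoichiometric_matrix()[SPECIES_INDEX["G"]]
    assert row[0] == -1
    assert np.count_nonzero(row) == 1


def test_death_column_debits_only_biomass():
    col = build_stoichiometric_matrix()[:, 12]
    assert col[SPECIES_INDEX["X"]] == -1
    assert np.count_nonzero(col) == 1


def test_nadh_row_credits_and_debits():
    row = build_stoichiometric_matrix()[SPECIES_INDEX["NADH"]]
    assert row[2] > 0 and row[5] > 0            # glycolysis + ferredoxin credits
    assert row[10] < 0 and row[13] < 0 and row[18] < 0  # r11, r14, r19 debits
    assert np.count_nonzero(row) == 5


def test_rhs_quiescence(fit_a, rng):
    """X = 0 implies exactly zero dynamics for arbitrary states."""
    for _ in range(20):
        state = rng.lognormal(size=16)
        state[SPECIES_INDEX["X"]] = 0.0
        assert np.all(rhs(0.0, state, fit_a) == 0.0)


def test_rhs_is_matrix_vector_product(fit_a, shinto_initial):
    """dC/dt equals v.r.X computed by an explicit loop oracle."""
    mat = build_stoichiometric_matrix()
    r = compute_rate_vector(shinto_initial, fit_a)
    X = shinto_initial[SPECIES_INDEX["X"]]
    expected = np.array([sum(mat[i, j] * r[j] for j in range(19)) for i in range(16)]) * X
    got = rhs(0.0, shinto_initial, fit_a)
    assert got == pytest.approx(expected, rel=1e-12)
    # glucose balance carries the single uptake debit
    assert got[SPECIES_INDEX["G"]] == pytest.approx(-r[0] * X)
    assert got[SPECIES_INDEX["G"]] <= 0.0


def test_rhs_autonomous(fit_a, shinto_initial):
    assert np.array_equal(rhs(0.0, shinto_initial, fit_a), rhs(42.0, shinto_initial, fit_a))
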