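"""Unit and property tests of the disproportionality statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from inversepv import (
    ContingencyTable,
    ScreenConfig,
    bh_adjust,
    build_tables,
    chi2_p,
    exact_p,
    ror,
    screen,
    woolf_ci,
)
from inversepv.ingest import CaseReport


# ---------------------------------------------------------------- oracles


def fisher_oracle(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Fixing both margins, sums P(k) over every achievable table whose point
    probability is at most that of the observed one (tie tolerance 1e-7).
    """
    n, row1, col1 = t.n, t.a + t.b, t.a + t.c
    kmin, kmax = max(0, row1 + col1 - n), min(row1, col1)
    ks = np.arange(kmin, kmax + 1)
    probs = hypergeom.pmf(ks, n, col1, row1)
    p_obs = hypergeom.pmf(t.a, n, col1, row1)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


def bh_oracle(p: list[float]) -> list[float]:
    """Literal step-up definition: q_(i) = min_{j>=i} min(1, p_(j) * m / j)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, p[i] * m / rank))
        adj[i] = running
    return adj


tables_st = st.tuples(
    st.integers(0, 60), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
).filter(lambda c: sum(c) > 0)


# ------------------------------------------------------------------- ROR


@pytest.mark.parametrize(
    "cells, expected",
    [
        ((10, 90, 100, 900), 1.0),
        ((40, 160, 1000, 2000), 0.5),
        ((5, 995, 50, 8950), 44750 / 49750),
    ],
)
def test_ror_hand_values(cells, expected):
    assert ror(ContingencyTable(*cells)) == pytest.approx(expected, rel=1e-12)


def test_ror_all_zero_table_is_undefined():
    with pytest.raises(ValueError):
        ror(ContingencyTable(0, 0, 0, 0))


def test_zero_cell_gets_haldane_anscombe_correction():
    # b = 0: all four cells get +0.5 for the ratio and CI, raw counts for p
    t = ContingencyTable(5, 0, 10, 85)
    assert ror(t) == pytest.approx((5.5 * 85.5) / (0.5 * 10.5))
    low, high = woolf_ci(t)
    assert low < ror(t) < high


@given(tables_st.filter(lambda c: all(v > 0 for v in c)))
@settings(max_examples=200, derandomize=True)
def test_ror_reciprocity(cells):
    a, b, c, d = cells
    swapped = ContingencyTable(b, a, d, c)
    assert ror(swapped) == pytest.approx(1 / ror(ContingencyTable(a, b, c, d)))


def test_ror_monotone_in_a():
    values = [ror(ContingencyTable(a, 50, 30, 400)) for a in range(1, 30)]
    assert all(x < y for x, y in zip(values, values[1:]))


# -------------------------------------------------------------- Woolf CI


def test_woolf_hand_value():
    low, high = woolf_ci(ContingencyTable(10, 90, 100, 900), 0.95)
    assert (round(low, 4), round(high, 4)) == (0.5040, 1.9842)


@given(tables_st.filter(lambda c: all(v > 0 for v in c)))
@settings(max_examples=200, derandomize=True)
def test_woolf_geometric_mean_identity(cells):
    t = ContingencyTable(*cells)
    low, high = woolf_ci(t)
    assert low < high
    assert math.sqrt(low * high) == pytest.approx(ror(t), rel=1e-12)


def test_woolf_rejects_bad_level():
    with pytest.raises(ValueError):
        woolf_ci(ContingencyTable(1, 1, 1, 1), 1.0)


# ---------------------------------------------------------- exact p-value


@pytest.mark.parametrize(
    "cells, expected",
    [
        ((2, 3, 3, 2), 1.0),
        ((5, 0, 0, 5), 2 / 252),
        ((7, 0, 12, 0), 1.0),  # empty column margin: single possible table
        ((0, 0, 3, 4), 1.0),  # empty row margin
    ],
)
def test_exact_p_known_values(cells, expected):
    assert exact_p(ContingencyTable(*cells)) == pytest.approx(expected, rel=1e-7)


@given(tables_st)
@settings(max_examples=300, derandomize=True)
def test_exact_p_equals_enumeration(cells):
    t = ContingencyTable(*cells)
    assert exact_p(t) == pytest.approx(fisher_oracle(t), rel=1e-7)


def test_chi2_option_sane():
    t = ContingencyTable(40, 160, 1000, 2000)
    p = chi2_p(t)
    assert 0 < p < 1
    assert chi2_p(ContingencyTable(0, 0, 5, 5)) == 1.0


# ---------------------------------------------------------------- BH-FDR


def test_bh_hand_value_and_single():
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert bh_adjust([0.4]) == pytest.approx([0.4])
    assert bh_adjust([]) == []


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_bh_matches_bruteforce_on_random_vectors():
    rng = np.random.default_rng(42)
    for _ in range(300):
        p = rng.random(rng.integers(1, 51)).tolist()
        assert bh_adjust(p) == pytest.approx(bh_oracle(p), rel=1e-12)


def test_bh_dominance_and_permutation_invariance():
    rng = np.random.default_rng(7)
    p = rng.random(20).tolist()
    adj = bh_adjust(p)
    assert all(q >= pr for q, pr in zip(adj, p))
    assert all(q <= 1 for q in adj)
    perm = rng.permutation(20)
    adj_perm = bh_adjust([p[i] for i in perm])
    assert adj_perm == pytest.approx([adj[i] for i in perm])


# ----------------------------------------------------------- table build


def _case(report_id, ingredients, pts):
    return CaseReport(
        report_id=report_id,
        case_id=report_id,
        ingredients={name: frozenset({"PS"}) for name in ingredients},
        event_pts=frozenset(pts),
    )


def test_build_tables_enumeration():
    reports = [
        _case("r1", ["drugX"], ["Ulcerative colitis"]),
        _case("r2", ["drugX"], []),
        _case("r3", [], ["Crohn's disease"]),
        _case("r4", [], []),
    ]
    tables = build_tables(reports, {"Ulcerative colitis", "Crohn's disease"})
    assert tables["drugX"] == ContingencyTable(1, 1, 1, 1)


def test_build_tables_double_pt_counts_once_and_matching_is_lenient():
    reports = [
        _case("r1", ["drugX"], ["ulcerative COLITIS ", "Crohn's disease"]),
        _case("r2", ["drugX"], ["PT_0001"]),
    ]
    tables = build_tables(reports, {"Ulcerative colitis", "Crohn's disease"})
    assert tables["drugX"] == ContingencyTable(1, 1, 0, 0)


def test_build_tables_margin_conservation(messy_dataset):
    from inversepv import ingest_directory

    cases, _ = ingest_directory(messy_dataset["dir"], messy_dataset["lexicon"])
    tables = build_tables(cases, {"Ulcerative colitis", "Crohn's disease"})
    assert all(t.n == len(cases) for t in tables.values())


def test_build_tables_rejects_empty_event_set():
    with pytest.raises(ValueError):
        build_tables([], set())


# ---------------------------------------------------------------- screen


def _screen_tables():
    return {
        "weak": ContingencyTable(3, 10, 500, 5000),  # below min_cases
        "inverse": ContingencyTable(40, 900, 900, 4000),
        "null": ContingencyTable(60, 500, 60, 500),
    }


def test_screen_excludes_below_min_cases():
    results = screen(_screen_tables(), ScreenConfig(min_cases=40))
    assert [r.ingredient for r in results] == ["inverse", "null"]


def test_screen_sorted_ascending_with_name_tiebreak():
    tables = {
        "beta": ContingencyTable(50, 100, 100, 200),
        "alpha": ContingencyTable(100, 200, 200, 400),
        "gamma": ContingencyTable(40, 50, 400, 500),
    }
    results = screen(tables, ScreenConfig(min_cases=1))
    assert [r.ingredient for r in results] == ["alpha", "beta", "gamma"]
    assert results[0].ror == results[1].ror == results[2].ror == 1.0


def test_screen_flag_invariants():
    results = screen(_screen_tables(), ScreenConfig(min_cases=40))
    for r in results:
        assert r.ci_low <= r.ror <= r.ci_high
        assert r.p_adj >= r.p_raw
        if r.inverse_flag:
            assert r.ror < 1 and r.p_adj < 0.05 and r.n_cases >= 40
    by_name = {r.ingredient: r for r in results}
    assert by_name["inverse"].inverse_flag
    assert not by_name["null"].inverse_flag


def test_screen_strict_ci_requires_bound_below_one():
    # marginally significant: p_adj < alpha but the CI straddles 1
    tables = {"drug": ContingencyTable(40, 620, 1000, 10000)}
    loose = screen(tables, ScreenConfig(min_cases=40))
    strict = screen(tables, ScreenConfig(min_cases=40, strict_ci=True))
    if loose[0].ci_high >= 1:
        assert not strict[0].inverse_flag


def test_screen_adjust_then_filter_uses_wider_family():
    tables = _screen_tables()
    default = screen(tables, ScreenConfig(min_cases=40))
    wide = screen(tables, ScreenConfig(min_cases=40, adjust_then_filter=True))
    assert [r.ingredient for r in default] == [r.ingredient for r in wide]
    # the wide family includes "weak", so adjusted p can only be >=
    for d, w in zip(default, wide):
        assert w.p_adj >= d.p_raw


def test_screen_empty_family_warns(caplog):
    import logging

    with caplog.at_level(logging.WARNING):
        assert screen({"x": ContingencyTable(1, 1, 1, 1)}, ScreenConfig()) == []
    assert "min_cases" in caplog.text


def test_screen_config_validation():
    with pytest.raises(ValueError):
        ScreenConfig(alpha=0)
    with pytest.raises(ValueError):
        ScreenConfig(min_cases=0)
    with pytest.raises(ValueError):
        ScreenConfig(event_pts=frozenset())
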