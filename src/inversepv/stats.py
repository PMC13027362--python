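"""Disproportionality statistics for report-level case/non-case screening.

The screen follows the classical pharmacovigilance case/non-case design: for
each drug, reports are cross-classified by exposure to the drug (any role)
and occurrence of the target event, giving the 2x2 table

    =============  ======  =========
    .              event   no event
    =============  ======  =========
    drug           a       b
    no drug        c       d
    =============  ======  =========

The reporting odds ratio ROR = (a*d)/(b*c) estimates how disproportionately
the drug co-occurs with the event relative to the rest of the database;
ROR < 1 with a small adjusted p-value is an *inverse signal*, the
hypothesis-generating hint of a protective association that this package
screens for.  Confidence intervals use the Woolf construction
exp(ln ROR ± z * sqrt(1/a + 1/b + 1/c + 1/d)), whose bounds are
geometrically symmetric about the point estimate; raw p-values come from
the two-sided Fisher exact test (a Pearson chi-square is available as an
option); multiplicity is handled with Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .ingest import CaseReport

logger = logging.getLogger(__name__)

#: Default target event: the two MedDRA preferred terms that make up
#: inflammatory bowel disease at PT level.
DEFAULT_EVENT_PTS = frozenset({"Ulcerative colitis", "Crohn's disease"})


@dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2x2 counts for one drug against the target event set."""

    a: int  # drug & event
    b: int  # drug, no event
    c: int  # no drug, event
    d: int  # neither

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class SignalResult:
    """Per-drug screening statistics; one row of the screen's output table."""

    ingredient: str
    table: ContingencyTable | None
    ror: float
    ci_low: float
    ci_high: float
    p_raw: float | None
    p_adj: float | None
    n_cases: int | None
    inverse_flag: bool
    positive_flag: bool
    corrected: bool = False  # Haldane-Anscombe applied to ror/CI
    therapeutic_class: str | None = None

    def selected(self, direction: str) -> bool:
        if direction == "inverse":
            return self.inverse_flag
        if direction == "positive":
            return self.positive_flag
        if direction == "both":
            return self.inverse_flag or self.positive_flag
        raise ValueError(f"unknown direction {direction!r}")


class ScreenConfig(BaseModel):
    """Thresholds and options of the inverse-signal screen.

    ``min_cases`` is the minimum number of drug+event reports (cell ``a``)
    for a drug to enter the tested family; the conservative default of 40
    trades sensitivity for estimate stability, since inverse signals are
    especially vulnerable to small-number noise.  ``strict_ci`` additionally
    requires the CI to exclude 1 on the flagged side.
    """

    event_pts: frozenset[str] = DEFAULT_EVENT_PTS
    min_cases: int = 40
    alpha: float = 0.05
    ci_level: float = 0.95
    direction: Literal["inverse", "positive", "both"] = "inverse"
    strict_ci: bool = False
    p_method: Literal["fisher", "chi2"] = "fisher"
    adjust_then_filter: bool = False

    @field_validator("event_pts")
    @classmethod
    def _nonempty_events(cls, v: frozenset[str]) -> frozenset[str]:
        if not v:
            raise ValueError("event_pts must be non-empty")
        return v

    @field_validator("min_cases")
    @classmethod
    def _min_cases(cls, v: int) -> int:
        if v < 1:
            raise ValueError("min_cases must be >= 1")
        return v

    @field_validator("alpha", "ci_level")
    @classmethod
    def _open_unit(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("must lie strictly between 0 and 1")
        return v


def _match_pt(pt: str) -> str:
    return pt.strip().casefold()


def build_tables(
    reports: Sequence[CaseReport], event_pts: Iterable[str]
) -> dict[str, ContingencyTable]:
    """Cross-classify every ingredient against the target event set.

    A report is a *case* if it lists at least one preferred term in
    ``event_pts`` (matched case-insensitively after trimming), regardless of
    how many it lists; drug exposure counts any role.  Every returned table
    sums to ``len(reports)``.
    """
    targets = {_match_pt(pt) for pt in event_pts}
    if not targets:
        raise ValueError("event_pts must be non-empty")
    total = len(reports)
    n_event = 0
    exposed: dict[str, int] = {}
    exposed_event: dict[str, int] = {}
    for rep in reports:
        is_case = any(_match_pt(pt) in targets for pt in rep.event_pts)
        n_event += is_case
        for ingredient in rep.ingredients:
            exposed[ingredient] = exposed.get(ingredient, 0) + 1
            if is_case:
                exposed_event[ingredient] = exposed_event.get(ingredient, 0) + 1
    tables = {}
    for ingredient in sorted(exposed):
        a = exposed_event.get(ingredient, 0)
        b = exposed[ingredient] - a
        c = n_event - a
        d = total - a - b - c
        tables[ingredient] = ContingencyTable(a, b, c, d)
    return tables


def _cells(table: ContingencyTable) -> tuple[float, float, float, float, bool]:
    """Cells for ratio estimation, Haldane-Anscombe corrected when needed.

    Any zero cell gets 0.5 added to all four cells so that the odds ratio
    and its log-scale variance exist; the raw counts are untouched for the
    exact test.
    """
    cells = (table.a, table.b, table.c, table.d)
    if all(v == 0 for v in cells):
        raise ValueError("ROR undefined for the all-zero table")
    if any(v == 0 for v in cells):
        return tuple(v + 0.5 for v in cells) + (True,)  # type: ignore[return-value]
    return (*map(float, cells), False)


def ror(table: ContingencyTable) -> float:
    """Reporting odds ratio (a*d)/(b*c), Haldane-Anscombe corrected on zeros."""
    a, b, c, d, _ = _cells(table)
    return (a * d) / (b * c)


def woolf_ci(
    table: ContingencyTable, ci_level: float = 0.95
) -> tuple[float, float]:
    """Woolf (log-normal) confidence interval for the ROR.

    Uses the full-precision two-sided normal quantile; the bounds satisfy
    sqrt(low * high) == ror(table) by construction.
    """
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must lie strictly between 0 and 1")
    a, b, c, d, _ = _cells(table)
    z = sps.norm.ppf(0.5 + ci_level / 2)
    log_ror = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_ror - z * se), math.exp(log_ror + z * se)


def exact_p(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value on the raw (uncorrected) counts.

    Sums hypergeometric probabilities, over all tables with the observed
    margins, of outcomes whose point probability does not exceed that of
    the observed table.  Degenerate margins admit a single table and give 1.
    """
    return float(sps.fisher_exact(table.as_array(), alternative="two-sided").pvalue)


def chi2_p(table: ContingencyTable) -> float:
    """Pearson chi-square p-value without continuity correction."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    return float(sps.chi2_contingency(arr, correction=False).pvalue)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def screen(
    tables: Mapping[str, ContingencyTable], cfg: ScreenConfig | None = None
) -> list[SignalResult]:
    """Run the disproportionality screen over a family of drug tables.

    By default the family is restricted to drugs with at least
    ``min_cases`` drug+event reports *before* the BH adjustment
    (filter-then-adjust); ``adjust_then_filter`` instead adjusts across all
    drugs and filters afterwards.  The full tested family is returned —
    flagged and unflagged — sorted by ascending ROR with ties broken by
    ingredient name.
    """
    cfg = cfg or ScreenConfig()
    p_fn = exact_p if cfg.p_method == "fisher" else chi2_p

    if cfg.adjust_then_filter:
        family = sorted(tables)
    else:
        family = sorted(k for k, t in tables.items() if t.a >= cfg.min_cases)
    if not family:
        logger.warning("no drug reaches min_cases=%d; empty screen", cfg.min_cases)
        return []

    p_raw = [p_fn(tables[k]) for k in family]
    p_adj = bh_adjust(p_raw)

    results = []
    for name, praw, padj in zip(family, p_raw, p_adj):
        table = tables[name]
        if table.a < cfg.min_cases:
            continue
        a, b, c, d, corrected = _cells(table)
        est = (a * d) / (b * c)
        low, high = woolf_ci(table, cfg.ci_level)
        significant = padj < cfg.alpha and table.a >= cfg.min_cases
        inverse = est < 1 and significant and (not cfg.strict_ci or high < 1)
        positive = est > 1 and significant and (not cfg.strict_ci or low > 1)
        results.append(
            SignalResult(
                ingredient=name,
                table=table,
                ror=est,
                ci_low=low,
                ci_high=high,
                p_raw=praw,
                p_adj=padj,
                n_cases=table.a,
                inverse_flag=inverse,
                positive_flag=positive,
                corrected=corrected,
            )
        )
    results.sort(key=lambda r: (r.ror, r.ingredient))
    return results


def write_results(results: Sequence[SignalResult], path: str | Path) -> None:
    """Write the full screened family as TSV, one row per drug, ascending ROR."""
    lines = [
        "ingredient\ta\tb\tc\td\tror\tci_low\tci_high\tp_raw\tp_adj"
        "\tinverse_flag\tcorrected_flag"
    ]
    for r in results:
        t = r.table
        cells = (t.a, t.b, t.c, t.d) if t is not None else ("", "", "", "")
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    r.ingredient,
                    *cells,
                    f"{r.ror:.6g}",
                    f"{r.ci_low:.6g}",
                    f"{r.ci_high:.6g}",
                    "" if r.p_raw is None else f"{r.p_raw:.6g}",
                    "" if r.p_adj is None else f"{r.p_adj:.6g}",
                    r.inverse_flag,
                    r.corrected,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
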