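"""Operating characteristics of the screen, measured by simulation.

Inverse disproportionality signals are fragile: they inherit all the
reporting biases of a spontaneous-report database, and on top of that the
screen itself could over-flag (poor FDR control) or mis-cover (bad Woolf
intervals).  The studies here quantify what the procedure does under a
*known* generative model — false-flag rate under the global null, CI
coverage, and bias/power against planted odds ratios — using the
count-level shortcut of :func:`inversepv.simulate.direct_count_simulation`
for speed.  A report-level smoke comparison in the test suite guards
against drift between the two simulation paths.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .simulate import SimConfig, direct_count_simulation
from .stats import ScreenConfig, exact_p, ror, screen, woolf_ci


@dataclass(frozen=True)
class CalibrationReport:
    """Summary of one simulation scenario."""

    scenario: str
    m_pairs: int
    n_reports: int
    replicates: int
    seed: int
    flagged_fraction: float | None = None
    coverage: float | None = None
    mean_log_ror: float | None = None
    sd_log_ror: float | None = None
    planted_or: float | None = None
    mean_ror: float | None = None
    log_ror_bias: float | None = None
    small_cells: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2) + "\n", encoding="utf-8"
        )


def write_report_tsv(
    reports: Sequence[CalibrationReport], path: str | Path
) -> None:
    """Human-readable TSV summary, one scenario per row."""
    fields = list(asdict(reports[0])) if reports else []
    lines = ["\t".join(fields)]
    for rep in reports:
        d = asdict(rep)
        lines.append(
            "\t".join("" if d[f] is None else f"{d[f]}" for f in fields)
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _spawn_seeds(seed: int, n: int) -> list[int]:
    # stable per-replicate substreams; keep values in int32 range
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def null_fdr_study(
    m_pairs: int,
    n_reports: int,
    screen_cfg: ScreenConfig,
    replicates: int,
    seed: int,
    exposure_prob: float = 0.05,
    baseline_event_prob: float = 0.05,
) -> CalibrationReport:
    """False-flag rate of the screen when every planted odds ratio is 1.

    With Benjamini–Hochberg adjustment and independent pairs, the expected
    fraction of tested drugs flagged (either direction) must not exceed
    alpha.  Reported ``flagged_fraction`` is the mean over replicates of
    flagged / family size.
    """
    if m_pairs < 100:
        raise ValueError("m_pairs >= 100 required for a stable estimate")
    cfg = SimConfig(
        n_cases=n_reports,
        n_drugs=1,
        exposure_prob=exposure_prob,
        baseline_event_prob=baseline_event_prob,
        planted_or=1.0,
        seed=seed,
    )
    both = screen_cfg.model_copy(update={"direction": "both"})
    fractions = []
    for rep_seed in _spawn_seeds(seed, replicates):
        tables = direct_count_simulation(m_pairs, n_reports, cfg, seed=rep_seed)
        named = {f"PAIR_{k:05d}": t for k, t in enumerate(tables)}
        results = screen(named, both)
        if results:
            flagged = sum(r.selected("both") for r in results)
            fractions.append(flagged / len(results))
    return CalibrationReport(
        scenario="null_fdr",
        m_pairs=m_pairs,
        n_reports=n_reports,
        replicates=replicates,
        seed=seed,
        planted_or=1.0,
        flagged_fraction=float(np.mean(fractions)) if fractions else 0.0,
    )


def coverage_study(
    planted_or: float,
    n_reports: int,
    replicates: int,
    seed: int,
    exposure_prob: float = 0.3,
    baseline_event_prob: float = 0.3,
    ci_level: float = 0.95,
) -> CalibrationReport:
    """Fraction of replicates whose Woolf CI contains the planted OR.

    Approaches ``ci_level`` when all expected cells are large; with
    near-zero expected cells coverage degrades, which is reported via
    ``small_cells`` rather than asserted away.
    """
    if planted_or <= 0:
        raise ValueError("planted_or must be positive")
    cfg = SimConfig(
        n_cases=n_reports,
        n_drugs=1,
        exposure_prob=exposure_prob,
        baseline_event_prob=baseline_event_prob,
        planted_or=planted_or,
        seed=seed,
    )
    tables = direct_count_simulation(replicates, n_reports, cfg, seed=seed)
    hits, logs = [], []
    for t in tables:
        low, high = woolf_ci(t, ci_level)
        hits.append(low <= planted_or <= high)
        logs.append(math.log(ror(t)))
    odds0 = baseline_event_prob / (1 - baseline_event_prob)
    p1 = odds0 * planted_or / (1 + odds0 * planted_or)
    expected_cells = (
        n_reports * exposure_prob * p1,
        n_reports * exposure_prob * (1 - p1),
        n_reports * (1 - exposure_prob) * baseline_event_prob,
        n_reports * (1 - exposure_prob) * (1 - baseline_event_prob),
    )
    return CalibrationReport(
        scenario="coverage",
        m_pairs=replicates,
        n_reports=n_reports,
        replicates=replicates,
        seed=seed,
        planted_or=planted_or,
        coverage=float(np.mean(hits)),
        mean_log_ror=float(np.mean(logs)),
        sd_log_ror=float(np.std(logs, ddof=1)) if len(logs) > 1 else None,
        small_cells=bool(min(expected_cells) < 5),
    )


def recovery_study(
    planted_grid: Sequence[float],
    n_reports: int,
    replicates: int,
    seed: int,
    screen_cfg: ScreenConfig | None = None,
    exposure_prob: float = 0.05,
    baseline_event_prob: float = 0.1,
) -> list[CalibrationReport]:
    """Bias and inverse-flag power across a grid of planted odds ratios.

    Each grid point simulates ``replicates`` single-drug datasets; the flag
    decision per replicate uses the exact p (the family has size one, so
    the BH adjustment is the identity).
    """
    if not planted_grid:
        raise ValueError("planted_grid must be non-empty")
    screen_cfg = screen_cfg or ScreenConfig()
    reports = []
    for g, orr in enumerate(planted_grid):
        cfg = SimConfig(
            n_cases=n_reports,
            n_drugs=1,
            exposure_prob=exposure_prob,
            baseline_event_prob=baseline_event_prob,
            planted_or=float(orr),
            seed=seed,
        )
        tables = direct_count_simulation(
            replicates, n_reports, cfg, seed=_spawn_seeds(seed, len(planted_grid))[g]
        )
        logs, flags = [], []
        for t in tables:
            est = ror(t)
            logs.append(math.log(est))
            flags.append(
                est < 1
                and t.a >= screen_cfg.min_cases
                and exact_p(t) < screen_cfg.alpha
            )
        reports.append(
            CalibrationReport(
                scenario="recovery",
                m_pairs=replicates,
                n_reports=n_reports,
                replicates=replicates,
                seed=seed,
                planted_or=float(orr),
                flagged_fraction=float(np.mean(flags)),
                mean_log_ror=float(np.mean(logs)),
                sd_log_ror=float(np.std(logs, ddof=1)) if len(logs) > 1 else None,
                mean_ror=float(np.exp(np.mean(logs))),
                log_ror_bias=float(np.mean(logs) - math.log(orr)),
            )
        )
    return reports
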