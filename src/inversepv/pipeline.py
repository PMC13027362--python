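"""Post-statistical candidate selection: feasibility funnel, class restriction,
ranking and export.

The statistical screen is deliberately mechanism-blind; turning flagged
inverse signals into repurposing candidates requires clinical judgments
(non-systemic formulations, diagnostics, withdrawn products,
pharmacokinetically implausible compounds, drugs known ineffective or
disease-aggravating) and a therapeutic-class restriction.  Those judgments
are not algorithmically reproducible, so they enter here as declarative,
versioned configuration — exclusion lists and a class map — with every
removal logged to a funnel audit whose stage counts must reconcile exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

from pydantic import BaseModel

from .stats import SignalResult

UNCLASSIFIED = "UNCLASSIFIED"

#: Feasibility categories in matching order; the first match is the
#: recorded exclusion reason when lists overlap.
FEASIBILITY_CATEGORIES = (
    "non_systemic",
    "diagnostic",
    "withdrawn",
    "pk_implausible",
    "known_ineffective_or_aggravating",
)


class FeasibilityConfig(BaseModel):
    """Named exclusion lists applied after the statistical screen."""

    non_systemic: frozenset[str] = frozenset()
    diagnostic: frozenset[str] = frozenset()
    withdrawn: frozenset[str] = frozenset()
    pk_implausible: frozenset[str] = frozenset()
    known_ineffective_or_aggravating: frozenset[str] = frozenset()

    def reason_for(self, ingredient: str) -> str | None:
        key = ingredient.casefold()
        for category in FEASIBILITY_CATEGORIES:
            members = {m.casefold() for m in getattr(self, category)}
            if key in members:
                return category
        return None

    @classmethod
    def from_json(cls, path: str | Path) -> "FeasibilityConfig":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


class ClassMap(BaseModel):
    """Ingredient -> therapeutic class, plus the classes counted as
    immune-mediated/immunomodulatory for the restriction stage."""

    classes: dict[str, str] = {}
    designated: frozenset[str] = frozenset()

    def class_of(self, ingredient: str) -> str:
        key = ingredient.casefold()
        for name, label in self.classes.items():
            if name.casefold() == key:
                return label
        return UNCLASSIFIED

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassMap":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass(frozen=True)
class FunnelStage:
    stage: str
    entering: int
    surviving: int
    exclusions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.entering - self.surviving != len(self.exclusions):
            raise ValueError(
                f"stage {self.stage!r}: removals do not match exclusion reasons"
            )


@dataclass
class FunnelAudit:
    """Ordered stage records of the candidate-selection flow."""

    stages: list[FunnelStage] = field(default_factory=list)

    def push(self, stage: FunnelStage) -> None:
        if self.stages and self.stages[-1].surviving != stage.entering:
            raise ValueError(
                f"stage {stage.stage!r} enters with {stage.entering}, previous "
                f"stage survived {self.stages[-1].surviving}"
            )
        self.stages.append(stage)

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "stage": s.stage,
                "entering": s.entering,
                "surviving": s.surviving,
                "exclusions": s.exclusions,
            }
            for s in self.stages
        ]
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def apply_feasibility(
    results: Sequence[SignalResult], cfg: FeasibilityConfig
) -> tuple[list[SignalResult], FunnelStage]:
    """Drop ingredients on the exclusion lists, recording one reason each.

    Exclusions are clinical-coherence judgments, never based on signal
    strength; an empty config is the identity.  Ascending-ROR order is
    preserved.
    """
    kept, excluded = [], {}
    for r in results:
        reason = cfg.reason_for(r.ingredient)
        if reason is None:
            kept.append(r)
        else:
            excluded[r.ingredient] = reason
    stage = FunnelStage("feasibility", len(results), len(kept), excluded)
    return kept, stage


def restrict_to_classes(
    results: Sequence[SignalResult], class_map: ClassMap
) -> tuple[list[SignalResult], FunnelStage]:
    """Keep candidates whose therapeutic class is designated.

    Every result (kept or not) is annotated with its class label; unmapped
    ingredients are UNCLASSIFIED and never designated.
    """
    annotated = [
        replace(r, therapeutic_class=class_map.class_of(r.ingredient))
        for r in results
    ]
    kept = [r for r in annotated if r.therapeutic_class in class_map.designated]
    excluded = {
        r.ingredient: f"class:{r.therapeutic_class}"
        for r in annotated
        if r.therapeutic_class not in class_map.designated
    }
    stage = FunnelStage("class_restriction", len(results), len(kept), excluded)
    return kept, stage


def rank_and_export(
    results: Sequence[SignalResult], directory: str | Path
) -> tuple[Path, Path]:
    """Write candidates.tsv and forest.tsv, ascending ROR, 3-decimal rounding.

    The forest table adds the log-scale midpoint sqrt(ci_low * ci_high) of
    each interval (equal to the point estimate for a Woolf interval), ready
    for forest-plot rendering.  Ties on ROR order lexicographically.
    """
    ordered = sorted(results, key=lambda r: (r.ror, r.ingredient))
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    cand_path = directory / "candidates.tsv"
    forest_path = directory / "forest.tsv"
    cand = ["drug\tror\tci_low\tci_high"]
    forest = ["drug\tror\tci_low\tci_high\tlog_mid"]
    for r in ordered:
        base = f"{r.ingredient}\t{r.ror:.3f}\t{r.ci_low:.3f}\t{r.ci_high:.3f}"
        cand.append(base)
        forest.append(base + f"\t{math.sqrt(r.ci_low * r.ci_high):.3f}")
    cand_path.write_text("\n".join(cand) + "\n", encoding="utf-8")
    forest_path.write_text("\n".join(forest) + "\n", encoding="utf-8")
    return cand_path, forest_path


def plot_forest(results: Sequence[SignalResult], path: str | Path) -> None:
    """Optional matplotlib hook: render the candidates as a forest plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = sorted(results, key=lambda r: (r.ror, r.ingredient), reverse=True)
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(ordered) + 1.5))
    ys = range(len(ordered))
    ax.hlines(ys, [r.ci_low for r in ordered], [r.ci_high for r in ordered])
    ax.plot([r.ror for r in ordered], ys, "s", color="black", markersize=4)
    ax.axvline(1.0, linestyle="--", color="grey")
    ax.set_yticks(list(ys), [r.ingredient for r in ordered])
    ax.set_xscale("log")
    ax.set_xlabel("Reporting odds ratio (log scale)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _data_path(name: str):
    return resources.files("inversepv").joinpath("data", name)


def load_reference_candidates() -> list[SignalResult]:
    """Packaged reference candidate table (drug, ROR, 95% CI bounds).

    Only the published summary statistics are available — not the underlying
    2x2 counts — so table, p-values and case counts are None; all rows are
    flagged inverse signals by construction.
    """
    results = []
    text = _data_path("reference_candidates.tsv").read_text(encoding="utf-8")
    header, *lines = text.splitlines()
    if header.split("\t") != ["drug", "ror", "ci_low", "ci_high"]:
        raise ValueError("unexpected reference candidate header")
    for line in lines:
        drug, r, lo, hi = line.split("\t")
        results.append(
            SignalResult(
                ingredient=drug,
                table=None,
                ror=float(r),
                ci_low=float(lo),
                ci_high=float(hi),
                p_raw=None,
                p_adj=None,
                n_cases=None,
                inverse_flag=True,
                positive_flag=False,
            )
        )
    return results


def load_reference_class_map() -> ClassMap:
    """Packaged therapeutic-class annotation of the reference candidates."""
    return ClassMap(
        **json.loads(_data_path("reference_class_map.json").read_text("utf-8"))
    )


def load_reference_feasibility() -> FeasibilityConfig:
    """Packaged feasibility config (empty: the reference table is already
    post-feasibility)."""
    return FeasibilityConfig(
        **json.loads(_data_path("reference_feasibility.json").read_text("utf-8"))
    )
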