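"""Synthetic spontaneous-reporting-system generator with known ground truth.

Real FAERS extracts are multi-gigabyte downloads with no planted truth, so
every downstream stage here is exercised on simulated individual case
safety reports instead.  The generative model: each case is exposed to each
drug independently with probability ``exposure_prob``; the odds of the
target event are the baseline odds multiplied by ``planted_or_j`` for every
exposed drug j (effects combine multiplicatively on the odds scale, so the
marginal report-level odds ratio estimates the planted value); exposures
are emitted under messy verbatim spellings (brand names, salts, dosage
suffixes) drawn from per-drug variant lists; co-exposed constituents of a
combination product are collapsed into the combo's verbatim name; and a
configurable fraction of cases additionally emit a superseded version-1 row
that case version control must discard.

Everything is driven by one :class:`numpy.random.Generator` seeded from the
config, so an identical config yields byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .ingest import DrugMention, RawReport, normalize_key
from .stats import ContingencyTable

_ROLES = ("PS", "SS", "C", "I")
_NOISE_VOCAB = 500  # "PT_0001" ... "PT_0500"; disjoint from any target PT

#: Target-event preferred terms written into REAC rows of event cases.
DEFAULT_TARGET_PTS = ("Ulcerative colitis", "Crohn's disease")


class SimConfig(BaseModel):
    """Generative parameters of the synthetic reporting system.

    ``exposure_prob`` and ``planted_or`` accept a scalar (shared by all
    drugs) or one value per drug; ``planted_or`` multiplies the baseline
    odds of the target event for exposed cases (1.0 = null, < 1 plants an
    inverse signal).  ``duplicate_fraction`` is the probability that a case
    also emits a superseded version-1 row.
    """

    n_cases: int = Field(gt=0)
    n_drugs: int = Field(gt=0)
    exposure_prob: float | tuple[float, ...] = 0.05
    baseline_event_prob: float = 0.05
    planted_or: float | tuple[float, ...] = 1.0
    duplicate_fraction: float = Field(default=0.0, ge=0.0, lt=1.0)
    name_variants: tuple[tuple[str, ...], ...] | None = None
    combo_products: tuple[tuple[str, tuple[int, ...]], ...] = ()
    n_noise_events: int = Field(default=2, ge=0)
    target_pts: tuple[str, ...] = DEFAULT_TARGET_PTS
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        for p in self.exposure_probs():
            if not 0 < p < 1:
                raise ValueError("exposure_prob values must lie in (0, 1)")
        if not 0 < self.baseline_event_prob < 1:
            raise ValueError("baseline_event_prob must lie in (0, 1)")
        for v in self.planted_ors():
            if not v > 0:
                raise ValueError("planted_or values must be positive")
        if self.name_variants is not None:
            if len(self.name_variants) != self.n_drugs:
                raise ValueError("name_variants must list one tuple per drug")
            if any(len(v) == 0 for v in self.name_variants):
                raise ValueError("every drug needs at least one name variant")
        for verbatim, idxs in self.combo_products:
            if not idxs:
                raise ValueError(f"combo {verbatim!r} has no constituents")
            if any(not 0 <= j < self.n_drugs for j in idxs):
                raise ValueError(f"combo {verbatim!r} references unknown drug index")
        if not self.target_pts:
            raise ValueError("target_pts must be non-empty")
        return self

    def _per_drug(self, value: float | tuple[float, ...]) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if arr.size == 1:
            return np.full(self.n_drugs, arr[0])
        if arr.size != self.n_drugs:
            raise ValueError("per-drug parameter length must equal n_drugs")
        return arr

    def exposure_probs(self) -> np.ndarray:
        return self._per_drug(self.exposure_prob)

    def planted_ors(self) -> np.ndarray:
        return self._per_drug(self.planted_or)

    def drug_name(self, j: int) -> str:
        return f"DRUG_{j:04d}"

    def variants_for(self, j: int) -> tuple[str, ...]:
        if self.name_variants is not None:
            return self.name_variants[j]
        name = self.drug_name(j)
        return (name, f"{name} 20MG TABLET", f"Brandex-{j:04d}")

    def default_lexicon_entries(self) -> dict[str, list[str]]:
        """Lexicon entries resolving every verbatim this config can emit."""
        entries: dict[str, list[str]] = {}
        for j in range(self.n_drugs):
            for verbatim in self.variants_for(j):
                key = normalize_key(verbatim)
                target = [self.drug_name(j)]
                if entries.setdefault(key, target) != target:
                    raise ValueError(f"variant key collision on {key!r}")
        for verbatim, idxs in self.combo_products:
            key = normalize_key(verbatim)
            target = [self.drug_name(j) for j in idxs]
            if entries.setdefault(key, target) != target:
                raise ValueError(f"combo key collision on {key!r}")
        return entries

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.model_dump(), indent=2, default=list) + "\n",
            encoding="utf-8",
        )


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters and realized deduplicated report-level counts."""

    drug_names: tuple[str, ...]
    planted_or: np.ndarray
    exposure_counts: np.ndarray
    tables: tuple[ContingencyTable, ...]
    n_cases: int

    def __post_init__(self) -> None:
        for t in self.tables:
            if t.n != self.n_cases:
                raise ValueError("realized counts must sum to the report total")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["drug\tplanted_or\texposed\ta\tb\tc\td"]
        for name, orr, exp, t in zip(
            self.drug_names, self.planted_or, self.exposure_counts, self.tables
        ):
            lines.append(f"{name}\t{orr:g}\t{exp}\t{t.a}\t{t.b}\t{t.c}\t{t.d}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _draw(cfg: SimConfig) -> dict[str, np.ndarray]:
    """All random draws for one dataset, in one fixed order."""
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_cases, cfg.n_drugs
    exposed = rng.random((n, m)) < cfg.exposure_probs()
    base_odds = cfg.baseline_event_prob / (1 - cfg.baseline_event_prob)
    log_odds = np.log(base_odds) + exposed @ np.log(cfg.planted_ors())
    p_event = 1 / (1 + np.exp(-log_odds))
    event = rng.random(n) < p_event
    return {
        "exposed": exposed,
        "event": event,
        "variant_u": rng.random((n, m)),
        "role_idx": rng.integers(0, len(_ROLES), size=(n, m)),
        "noise_idx": rng.integers(1, _NOISE_VOCAB + 1, size=(n, cfg.n_noise_events)),
        "target_idx": rng.integers(0, len(cfg.target_pts), size=n),
        "dup": rng.random(n) < cfg.duplicate_fraction,
    }


def _ground_truth(cfg: SimConfig, draws: dict[str, np.ndarray]) -> GroundTruth:
    exposed, event = draws["exposed"], draws["event"]
    exp_counts = exposed.sum(axis=0)
    a = (exposed & event[:, None]).sum(axis=0)
    b = exp_counts - a
    c = int(event.sum()) - a
    d = cfg.n_cases - a - b - c
    tables = tuple(
        ContingencyTable(int(a[j]), int(b[j]), int(c[j]), int(d[j]))
        for j in range(cfg.n_drugs)
    )
    return GroundTruth(
        drug_names=tuple(cfg.drug_name(j) for j in range(cfg.n_drugs)),
        planted_or=cfg.planted_ors().copy(),
        exposure_counts=exp_counts.astype(int),
        tables=tables,
        n_cases=cfg.n_cases,
    )


def simulate_ground_truth(cfg: SimConfig) -> GroundTruth:
    """Realized counts only, skipping report assembly (cheap at large n)."""
    return _ground_truth(cfg, _draw(cfg))


def generate_cases(cfg: SimConfig) -> tuple[list[RawReport], GroundTruth]:
    """Materialize raw report rows (duplicates included) plus ground truth."""
    draws = _draw(cfg)
    truth = _ground_truth(cfg, draws)
    variants = [cfg.variants_for(j) for j in range(cfg.n_drugs)]

    rows: list[RawReport] = []
    for i in range(cfg.n_cases):
        exposed_set = set(np.flatnonzero(draws["exposed"][i]).tolist())
        mentions: list[DrugMention] = []
        consumed: set[int] = set()
        seq = 0
        for verbatim, idxs in cfg.combo_products:
            members = set(idxs)
            if members <= exposed_set and not (members & consumed):
                seq += 1
                role = _ROLES[draws["role_idx"][i, min(idxs)]]
                mentions.append(DrugMention(seq, role, verbatim))
                consumed |= members
        for j in sorted(exposed_set - consumed):
            seq += 1
            vlist = variants[j]
            verbatim = vlist[int(draws["variant_u"][i, j] * len(vlist))]
            mentions.append(DrugMention(seq, _ROLES[draws["role_idx"][i, j]], verbatim))

        pts = {f"PT_{k:04d}" for k in draws["noise_idx"][i]}
        if draws["event"][i]:
            pts.add(cfg.target_pts[draws["target_idx"][i]])

        case_id = f"C{i + 1:07d}"
        definitive_version = 2 if draws["dup"][i] else 1
        if draws["dup"][i]:
            rows.append(
                RawReport(
                    report_id=f"R{i + 1:07d}A",
                    case_id=case_id,
                    case_version=1,
                    drug_mentions=tuple(mentions),
                    event_pts=frozenset(pts),
                )
            )
        rows.append(
            RawReport(
                report_id=f"R{i + 1:07d}",
                case_id=case_id,
                case_version=definitive_version,
                drug_mentions=tuple(mentions),
                event_pts=frozenset(pts),
            )
        )
    return rows, truth


def write_faers_tables(rows: Sequence[RawReport], directory: str | Path) -> None:
    """Write demo.txt / drug.txt / reac.txt in the ``$``-delimited dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    demo = ["report_id$case_id$case_version"]
    drug = ["report_id$drug_seq$role_code$verbatim_name"]
    reac = ["report_id$pt"]
    for row in rows:
        demo.append(f"{row.report_id}${row.case_id}${row.case_version}")
        for m in sorted(row.drug_mentions, key=lambda m: m.drug_seq):
            drug.append(f"{row.report_id}${m.drug_seq}${m.role_code}${m.verbatim_name}")
        for pt in sorted(row.event_pts):
            reac.append(f"{row.report_id}${pt}")
    for name, lines in (("demo.txt", demo), ("drug.txt", drug), ("reac.txt", reac)):
        (directory / name).write_text("\n".join(lines) + "\n", encoding="utf-8")


def direct_count_simulation(
    m_pairs: int, n_reports: int, cfg: SimConfig, seed: int | None = None
) -> list[ContingencyTable]:
    """Count-level shortcut: draw 2x2 tables directly from the model.

    For each of ``m_pairs`` independent drug-event pairs the exposed margin
    is Binomial(n_reports, exposure_prob) and the event counts are binomial
    within each margin, with the exposed-arm probability derived from the
    baseline odds times the planted odds ratio.  Marginally equivalent to
    materializing reports; used by the calibration studies for speed.
    """
    if m_pairs < 1:
        raise ValueError("m_pairs must be >= 1")
    if n_reports < 1:
        raise ValueError("n_reports must be >= 1")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    def spread(value: float | tuple[float, ...]) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if arr.size == 1:
            return np.full(m_pairs, arr[0])
        if arr.size != m_pairs:
            raise ValueError("per-pair parameter length must equal m_pairs")
        return arr

    e = spread(cfg.exposure_prob)
    orr = spread(cfg.planted_or)
    p0 = cfg.baseline_event_prob
    odds1 = (p0 / (1 - p0)) * orr
    p1 = odds1 / (1 + odds1)

    n1 = rng.binomial(n_reports, e)
    a = rng.binomial(n1, p1)
    c = rng.binomial(n_reports - n1, p0)
    return [
        ContingencyTable(int(a[k]), int(n1[k] - a[k]), int(c[k]), int(n_reports - n1[k] - c[k]))
        for k in range(m_pairs)
    ]
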