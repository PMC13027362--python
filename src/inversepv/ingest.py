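"""Reading and cleaning of FAERS-dialect spontaneous-report tables.

FAERS quarterly extracts arrive as three ``$``-delimited tables keyed by
report id: a DEMO-like table (one row per report version), a DRUG-like table
(one row per drug mention) and a REAC-like table (one row per MedDRA
preferred term).  This module parses that dialect, applies FDA-style case
version control (per case id, only the highest version is current),
normalizes verbatim drug names to active substances through a
:class:`DrugLexicon`, decomposes combination products, and keeps an exact
audit of every row it touches.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

#: Lexicon marker for a verbatim name that curation could not map to an
#: active substance.  Mentions hitting it are dropped (and audited).
UNRESOLVABLE = "UNRESOLVABLE"

_DEMO_COLUMNS = ["report_id", "case_id", "case_version"]
_DRUG_COLUMNS = ["report_id", "drug_seq", "role_code", "verbatim_name"]
_REAC_COLUMNS = ["report_id", "pt"]

_DOSAGE_TOKEN = re.compile(r"^\d+(\.\d+)?(MG|MCG|G|ML|IU|UI|%)?$")
_FORM_TOKENS = frozenset(
    {
        "TABLET",
        "TABLETS",
        "CAPSULE",
        "CAPSULES",
        "INJECTION",
        "SOLUTION",
        "ORAL",
        "CREAM",
        # bare units, for doses written as "20 MG"
        "MG",
        "MCG",
        "ML",
        "IU",
        "%",
    }
)
_PUNCT = re.compile(r"[^\w+\- ]")


class ParseError(ValueError):
    """Raised when a dialect file is missing, malformed, or inconsistent."""


@dataclass(frozen=True)
class DrugMention:
    """One row of the DRUG-like table: a verbatim drug string with its role."""

    drug_seq: int
    role_code: str
    verbatim_name: str

    def __post_init__(self) -> None:
        if self.role_code not in ROLE_CODES:
            raise ValueError(f"unknown role code {self.role_code!r}")


@dataclass(frozen=True)
class RawReport:
    """A report version exactly as read from the tables, before any cleaning."""

    report_id: str
    case_id: str
    case_version: int
    drug_mentions: tuple[DrugMention, ...]
    event_pts: frozenset[str]

    def __post_init__(self) -> None:
        seqs = [m.drug_seq for m in self.drug_mentions]
        if len(seqs) != len(set(seqs)):
            raise ValueError(
                f"report {self.report_id}: duplicate drug_seq within report"
            )
        if self.case_version < 0:
            raise ValueError(f"report {self.report_id}: negative case_version")


@dataclass(frozen=True)
class CaseReport:
    """One deduplicated, name-normalized case.

    ``ingredients`` maps each active-substance name to the union of role
    codes under which it was mentioned; names are lexicon outputs only,
    never raw verbatim strings.
    """

    report_id: str
    case_id: str
    ingredients: Mapping[str, frozenset[str]]
    event_pts: frozenset[str]


@dataclass
class IngestAudit:
    """Exact row accounting across the ingest stages.

    Conservation invariants (checked by :meth:`validate`):
    ``input_reports == reports_kept + duplicate_versions_removed`` and
    ``reports_kept == case_reports + reports_dropped_empty``.
    """

    input_reports: int = 0
    duplicate_versions_removed: int = 0
    reports_kept: int = 0
    orphan_drug_rows: int = 0
    orphan_reac_rows: int = 0
    mentions_total: int = 0
    mentions_normalized: int = 0
    combinations_decomposed: int = 0
    mentions_dropped_unresolvable: int = 0
    mentions_dropped_missing_key: int = 0
    reports_dropped_empty: int = 0
    case_reports: int = 0

    def validate(self) -> None:
        if self.input_reports and (
            self.input_reports
            != self.reports_kept + self.duplicate_versions_removed
        ):
            raise AssertionError("dedup stage does not conserve report count")
        if self.reports_kept and (
            self.reports_kept != self.case_reports + self.reports_dropped_empty
        ):
            raise AssertionError("normalize stage does not conserve report count")
        dropped = (
            self.mentions_dropped_unresolvable + self.mentions_dropped_missing_key
        )
        if self.mentions_total != self.mentions_normalized + dropped:
            raise AssertionError("mention accounting does not reconcile")

    def merged(self, other: "IngestAudit") -> "IngestAudit":
        out = IngestAudit()
        for name in vars(out):
            setattr(out, name, getattr(self, name) + getattr(other, name))
        return out


def normalize_key(verbatim: str) -> str:
    """Collapse a verbatim drug string to its lexicon lookup key.

    Uppercases, strips punctuation (keeping ``+``, ``-`` and word
    characters), collapses internal whitespace, then repeatedly removes
    trailing dosage tokens (digits plus unit) and dose-form words such as
    TABLET/CAPSULE/INJECTION.  ``"Lipitor  20mg Tablet"`` -> ``"LIPITOR"``.
    """
    s = _PUNCT.sub(" ", verbatim.upper())
    tokens = s.split()
    while tokens and (
        _DOSAGE_TOKEN.match(tokens[-1]) or tokens[-1] in _FORM_TOKENS
    ):
        tokens.pop()
    return " ".join(tokens)


class DrugLexicon:
    """Curated map from normalized verbatim keys to active substances.

    Each entry maps a key (already passed through :func:`normalize_key`) to
    either a non-empty list of ingredient names — more than one for a
    combination product — or the :data:`UNRESOLVABLE` marker.
    """

    def __init__(self, entries: Mapping[str, Sequence[str] | str]):
        if not entries:
            raise ValueError("lexicon must contain at least one entry")
        self._entries: dict[str, tuple[str, ...] | str] = {}
        for key, value in entries.items():
            if value == UNRESOLVABLE:
                self._entries[key] = UNRESOLVABLE
                continue
            if isinstance(value, str) or not value:
                raise ValueError(f"lexicon entry {key!r}: ingredient list required")
            self._entries[key] = tuple(value)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: str) -> bool:
        return key in self._entries

    def lookup(self, verbatim: str) -> tuple[str, ...] | str | None:
        """Resolve a raw verbatim name; ``None`` means the key is absent."""
        return self._entries.get(normalize_key(verbatim))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DrugLexicon":
        entries: dict[str, Sequence[str] | str] = {}
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
            key, value = parts
            if key in entries:
                raise ParseError(f"{path}:{lineno}: duplicate key {key!r}")
            entries[key] = (
                UNRESOLVABLE if value == UNRESOLVABLE else value.split("|")
            )
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        lines = []
        for key in sorted(self._entries):
            value = self._entries[key]
            rendered = value if value == UNRESOLVABLE else "|".join(value)
            lines.append(f"{key}\t{rendered}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_table(
    path: Path, columns: list[str]
) -> pd.DataFrame:
    if not path.exists():
        raise ParseError(f"missing dialect file: {path}")
    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise ParseError(
            f"{path}: malformed header {list(df.columns)!r}, expected {columns!r}"
        )
    return df


def read_faers_tables(directory: str | Path) -> list[RawReport]:
    """Parse demo.txt / drug.txt / reac.txt into one RawReport per DEMO row.

    DRUG and REAC rows are joined to DEMO by report id; orphan rows (no
    matching DEMO row) are counted, logged, and discarded.
    """
    directory = Path(directory)
    demo = _read_table(directory / "demo.txt", _DEMO_COLUMNS)
    drug = _read_table(directory / "drug.txt", _DRUG_COLUMNS)
    reac = _read_table(directory / "reac.txt", _REAC_COLUMNS)

    for col, table, name in (
        ("case_version", demo, "demo.txt"),
        ("drug_seq", drug, "drug.txt"),
    ):
        bad = ~table[col].str.fullmatch(r"-?\d+")
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ParseError(
                f"{directory / name}:{line}: non-integer {col} "
                f"{table.loc[bad.idxmax(), col]!r}"
            )

    known = set(demo["report_id"])
    if len(known) != len(demo):
        raise ParseError(f"{directory / 'demo.txt'}: duplicate report_id")
    orphan_drug = int((~drug["report_id"].isin(known)).sum())
    orphan_reac = int((~reac["report_id"].isin(known)).sum())
    if orphan_drug or orphan_reac:
        logger.warning(
            "discarding orphan rows with no DEMO match: %d drug, %d reac",
            orphan_drug,
            orphan_reac,
        )

    mentions_by_report: dict[str, list[DrugMention]] = {}
    for row in drug.itertuples(index=False):
        if row.report_id not in known:
            continue
        mentions_by_report.setdefault(row.report_id, []).append(
            DrugMention(int(row.drug_seq), row.role_code, row.verbatim_name)
        )
    pts_by_report: dict[str, set[str]] = {}
    for row in reac.itertuples(index=False):
        if row.report_id not in known:
            continue
        pts_by_report.setdefault(row.report_id, set()).add(row.pt)

    reports = []
    for row in demo.itertuples(index=False):
        reports.append(
            RawReport(
                report_id=row.report_id,
                case_id=row.case_id,
                case_version=int(row.case_version),
                drug_mentions=tuple(
                    sorted(
                        mentions_by_report.get(row.report_id, []),
                        key=lambda m: m.drug_seq,
                    )
                ),
                event_pts=frozenset(pts_by_report.get(row.report_id, set())),
            )
        )
    return reports


def deduplicate(
    reports: Iterable[RawReport],
) -> tuple[list[RawReport], IngestAudit]:
    """Keep, per case id, only the current version of the report.

    FDA case version control: the highest ``case_version`` supersedes all
    earlier ones.  A version tie (which compliant extracts should not
    contain) is broken deterministically by the lexicographically greatest
    report id.  Input order of surviving reports is preserved.
    """
    reports = list(reports)
    best: dict[str, RawReport] = {}
    for rep in reports:
        cur = best.get(rep.case_id)
        if (
            cur is None
            or rep.case_version > cur.case_version
            or (
                rep.case_version == cur.case_version
                and rep.report_id > cur.report_id
            )
        ):
            best[rep.case_id] = rep
    keep_ids = {rep.report_id for rep in best.values()}
    kept = [rep for rep in reports if rep.report_id in keep_ids]
    audit = IngestAudit(
        input_reports=len(reports),
        duplicate_versions_removed=len(reports) - len(kept),
        reports_kept=len(kept),
    )
    return kept, audit


def normalize(
    reports: Iterable[RawReport], lexicon: DrugLexicon
) -> tuple[list[CaseReport], IngestAudit]:
    """Map verbatim drug mentions to active substances via the lexicon.

    Combination entries contribute every constituent ingredient; mentions
    whose key is marked UNRESOLVABLE — or absent from the lexicon entirely
    (audited separately) — are dropped; a report whose mentions all fail to
    resolve is dropped as a whole, while a report with no drug mentions at
    all is kept as background.  Role codes are unioned per ingredient
    within a report.  Expects deduplicated input.
    """
    if len(lexicon) == 0:  # pragma: no cover - constructor already forbids
        raise ValueError("empty lexicon")
    reports = list(reports)
    audit = IngestAudit(reports_kept=len(reports))
    out: list[CaseReport] = []
    for rep in reports:
        ingredients: dict[str, set[str]] = {}
        for mention in rep.drug_mentions:
            audit.mentions_total += 1
            resolved = lexicon.lookup(mention.verbatim_name)
            if resolved is None:
                audit.mentions_dropped_missing_key += 1
                continue
            if resolved == UNRESOLVABLE:
                audit.mentions_dropped_unresolvable += 1
                continue
            audit.mentions_normalized += 1
            if len(resolved) > 1:
                audit.combinations_decomposed += 1
            for ingredient in resolved:
                ingredients.setdefault(ingredient, set()).add(mention.role_code)
        if not ingredients and rep.drug_mentions:
            # had drug mentions but none resolved: excluded as unresolvable
            audit.reports_dropped_empty += 1
            continue
        out.append(
            CaseReport(
                report_id=rep.report_id,
                case_id=rep.case_id,
                ingredients={k: frozenset(v) for k, v in ingredients.items()},
                event_pts=rep.event_pts,
            )
        )
    audit.case_reports = len(out)
    return out, audit


def ingest_directory(
    directory: str | Path, lexicon: DrugLexicon
) -> tuple[list[CaseReport], IngestAudit]:
    """read -> deduplicate -> normalize, with a merged audit."""
    raw = read_faers_tables(directory)
    deduped, dedup_audit = deduplicate(raw)
    cases, norm_audit = normalize(deduped, lexicon)
    audit = dedup_audit.merged(norm_audit)
    audit.reports_kept = dedup_audit.reports_kept  # merged() double counts it
    audit.validate()
    return cases, audit
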