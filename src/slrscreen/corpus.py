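"""Citation records, screening decisions, and training-label construction.

A systematic-review screening record carries two sequential decisions: an
abstract-level include/exclude (with a PICOS reason for every exclude) and,
for abstract includes only, a full-text decision. Training labels can be
derived from either stage; evaluation truth is always full-text inclusion.
"""

from __future__ import annotations

import csv
import enum
import io
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ExclusionReason",
    "LabelScheme",
    "Citation",
    "Label",
    "LabelledDataset",
    "SplitSpec",
    "ValidationError",
    "FormatError",
    "read_citations",
    "write_citations",
    "deduplicate",
    "derive_labels",
    "recode_reason",
    "stratified_split",
    "CSV_COLUMNS",
]


class ValidationError(ValueError):
    """A record or dataset violates the screening-data contract."""


class FormatError(ValueError):
    """An input file does not match the expected column/tag layout."""


class ExclusionReason(enum.Enum):
    """The seven PICOS-aligned reasons for exclusion.

    Declaration order is the resolution hierarchy: when several reasons
    qualify for one citation, the highest-priority (lowest ``priority``
    value) reason wins. Study design outranks everything; short follow-up
    ("time") ranks last.
    """

    STUDY_DESIGN = "study_design"
    POPULATION = "population"
    INTERVENTION = "intervention"
    COMPARATOR = "comparator"
    OUTCOMES = "outcomes"
    OTHER = "other"
    TIME = "time"

    @property
    def priority(self) -> int:
        """Rank in the hierarchy; 0 is highest (study design)."""
        return _REASON_PRIORITY[self]


_REASON_PRIORITY = {r: i for i, r in enumerate(ExclusionReason)}

HIERARCHY: tuple[ExclusionReason, ...] = tuple(ExclusionReason)


class LabelScheme(enum.Enum):
    """How training labels are built from the two screening stages."""

    ABSTRACT = "abstract"
    FULL_TEXT = "full_text"
    MODIFIED_FULL_TEXT = "modified_full_text"


_DECISIONS_ABS = {"include", "exclude"}
_DECISIONS_FT = {"include", "exclude", "not_screened"}


@dataclass
class Citation:
    """One screening record with both decision stages.

    ``fulltext_decision`` is ``"not_screened"`` for abstract excludes (the
    full text is only retrieved for abstract includes). The final truth
    label used by every evaluation is ``fulltext_decision == "include"``.
    """

    id: str
    title: str
    abstract: str
    abstract_decision: str
    abstract_reason: Optional[ExclusionReason] = None
    fulltext_decision: str = "not_screened"
    fulltext_reason: Optional[ExclusionReason] = None
    dataset_tag: str = ""

    def __post_init__(self) -> None:
        if self.abstract_decision not in _DECISIONS_ABS:
            raise ValidationError(
                f"citation {self.id!r}: bad abstract_decision {self.abstract_decision!r}"
            )
        if self.fulltext_decision not in _DECISIONS_FT:
            raise ValidationError(
                f"citation {self.id!r}: bad fulltext_decision {self.fulltext_decision!r}"
            )
        if self.abstract_decision == "exclude" and self.abstract_reason is None:
            raise ValidationError(
                f"citation {self.id!r}: excluded at abstract level without a reason"
            )
        if self.fulltext_decision in ("include", "exclude") and self.abstract_decision != "include":
            raise ValidationError(
                f"citation {self.id!r}: full text screened but abstract decision is "
                f"{self.abstract_decision!r}"
            )
        if self.fulltext_decision == "exclude" and self.fulltext_reason is None:
            raise ValidationError(
                f"citation {self.id!r}: excluded at full text without a reason"
            )

    @property
    def true_include(self) -> bool:
        """Evaluation truth: included in the final review set."""
        return self.fulltext_decision == "include"

    @property
    def true_reason(self) -> Optional[ExclusionReason]:
        """The reviewers' reason for a true exclude (full-text reason when
        the full text was screened, otherwise the abstract reason)."""
        if self.true_include:
            return None
        if self.fulltext_decision == "exclude":
            return self.fulltext_reason
        return self.abstract_reason


@dataclass(frozen=True)
class Label:
    """A training label: include, or exclude with exactly one reason."""

    decision: str  # "include" | "exclude"
    reason: Optional[ExclusionReason] = None

    def __post_init__(self) -> None:
        if self.decision not in _DECISIONS_ABS:
            raise ValidationError(f"bad label decision {self.decision!r}")
        if self.decision == "exclude" and self.reason is None:
            raise ValidationError("exclude label without a reason")
        if self.decision == "include" and self.reason is not None:
            raise ValidationError("include label must not carry a reason")


@dataclass
class LabelledDataset:
    """Citations paired one-to-one with training labels under a scheme."""

    citations: list[Citation]
    labels: list[Label]
    scheme: LabelScheme

    def __post_init__(self) -> None:
        if len(self.citations) != len(self.labels):
            raise ValidationError(
                f"{len(self.citations)} citations but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.citations)

    @property
    def n_includes(self) -> int:
        return sum(1 for lb in self.labels if lb.decision == "include")

    @property
    def n_excludes(self) -> int:
        return len(self.labels) - self.n_includes

    def reasons_present(self) -> list[ExclusionReason]:
        """Distinct exclusion reasons among the labels, in hierarchy order."""
        seen = {lb.reason for lb in self.labels if lb.reason is not None}
        return [r for r in HIERARCHY if r in seen]


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition parameters (default 75% training)."""

    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction <= 1.0):
            raise ValidationError(
                f"train_fraction must be in (0, 1], got {self.train_fraction}"
            )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = (
    "id",
    "title",
    "abstract",
    "abstract_decision",
    "abstract_reason",
    "fulltext_decision",
    "fulltext_reason",
    "dataset_tag",
)

_REASON_TOKENS = {r.value: r for r in ExclusionReason}


def _parse_reason(token: str, row_id: str, column: str) -> Optional[ExclusionReason]:
    if token == "":
        return None
    try:
        return _REASON_TOKENS[token]
    except KeyError:
        raise ValidationError(
            f"row {row_id!r}: unknown {column} token {token!r}"
        ) from None


def read_citations(path, format: str = "csv", sidecar=None) -> list[Citation]:
    """Read a citation collection from disk.

    ``format="csv"`` expects the canonical header (:data:`CSV_COLUMNS`);
    ``format="ris"`` reads TI/AB tags from a RIS file and takes decisions
    from a ``sidecar`` CSV keyed on id.
    """
    path = Path(path)
    if format == "csv":
        return _read_csv(path)
    if format == "ris":
        if sidecar is None:
            raise FormatError("RIS import needs a sidecar decisions CSV")
        return _read_ris(path, Path(sidecar))
    raise FormatError(f"unknown citation format {format!r}")


def _row_to_citation(row: dict[str, str]) -> Citation:
    rid = row["id"]
    if row["abstract_decision"] == "exclude" and row["abstract_reason"] == "":
        raise ValidationError(f"row {rid!r}: exclude without an abstract_reason")
    if row["fulltext_decision"] == "exclude" and row["fulltext_reason"] == "":
        raise ValidationError(f"row {rid!r}: full-text exclude without a fulltext_reason")
    try:
        return Citation(
            id=rid,
            title=row["title"],
            abstract=row["abstract"],
            abstract_decision=row["abstract_decision"],
            abstract_reason=_parse_reason(row["abstract_reason"], rid, "abstract_reason"),
            fulltext_decision=row["fulltext_decision"],
            fulltext_reason=_parse_reason(row["fulltext_reason"], rid, "fulltext_reason"),
            dataset_tag=row["dataset_tag"],
        )
    except ValidationError:
        raise
    except KeyError as exc:  # pragma: no cover - guarded by header check
        raise FormatError(f"missing column {exc.args[0]!r}") from None


def _read_csv(path: Path) -> list[Citation]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row") from None
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column {missing[0]!r}")
        idx = {c: header.index(c) for c in CSV_COLUMNS}
        citations = []
        for raw in reader:
            row = {c: raw[idx[c]] for c in CSV_COLUMNS}
            citations.append(_row_to_citation(row))
    return citations


_RIS_TAG = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")


def _read_ris(path: Path, sidecar: Path) -> list[Citation]:
    """Minimal RIS reader: TI -> title, AB -> abstract, ID/AN -> id.

    Decisions and reasons come from the sidecar CSV (canonical columns minus
    title/abstract), joined on id.
    """
    records: list[dict[str, str]] = []
    current: dict[str, str] = {}
    last_tag = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            m = _RIS_TAG.match(line)
            if m:
                tag, value = m.group(1), m.group(2)
                last_tag = tag
                if tag == "ER":
                    records.append(current)
                    current = {}
                    last_tag = None
                elif tag in current:
                    current[tag] += " " + value
                else:
                    current[tag] = value
            elif line.strip() and last_tag:  # continuation line
                current[last_tag] += " " + line.strip()
    if current:
        records.append(current)

    with open(sidecar, newline="", encoding="utf-8") as fh:
        side = {row["id"]: row for row in csv.DictReader(fh)}

    citations = []
    for rec in records:
        rid = rec.get("ID") or rec.get("AN")
        if rid is None:
            raise ValidationError("RIS record without an ID/AN tag")
        if rid not in side:
            raise ValidationError(f"RIS record {rid!r} missing from sidecar decisions")
        row = dict(side[rid])
        row.setdefault("dataset_tag", "")
        row["id"] = rid
        row["title"] = rec.get("TI", "")
        row["abstract"] = rec.get("AB", "")
        citations.append(_row_to_citation(row))
    return citations


def write_citations(citations: Iterable[Citation], path) -> None:
    """Write the canonical CSV (UTF-8, comma-delimited, all fields quoted).

    The output is byte-deterministic, so read -> write round-trips on a
    canonical file reproduce it exactly.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_ALL, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for c in citations:
            writer.writerow(
                [
                    c.id,
                    c.title,
                    c.abstract,
                    c.abstract_decision,
                    c.abstract_reason.value if c.abstract_reason else "",
                    c.fulltext_decision,
                    c.fulltext_reason.value if c.fulltext_reason else "",
                    c.dataset_tag,
                ]
            )


# ---------------------------------------------------------------------------
# Dataset construction
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")


def _dup_key(c: Citation) -> str:
    return _WS.sub(" ", (c.title + "\x1f" + c.abstract).lower()).strip()


def deduplicate(citations: Sequence[Citation]) -> list[Citation]:
    """Drop repeated publications, keyed on normalized title+abstract.

    The first occurrence (input order) is kept; order is preserved. The key
    is case- and whitespace-insensitive because duplicates from different
    databases typically differ only in formatting and id.
    """
    seen: set[str] = set()
    out = []
    for c in citations:
        k = _dup_key(c)
        if k not in seen:
            seen.add(k)
            out.append(c)
    return out


def derive_labels(citations: Sequence[Citation], scheme: LabelScheme) -> LabelledDataset:
    """Build training labels from the screening decisions.

    - ``ABSTRACT``: labels follow the abstract-stage decision; every
      citation is retained.
    - ``FULL_TEXT``: abstract excludes keep their abstract reason; abstract
      includes are relabelled by the full-text decision (full-text excludes
      take the full-text reason).
    - ``MODIFIED_FULL_TEXT``: abstract-stage labels, but citations included
      at abstract level and excluded at full text are removed entirely —
      their exclusion was decided outside the abstract, so their text is
      misleading as an "exclude" example.
    """
    if scheme is not LabelScheme.ABSTRACT:
        abs_includes = [c for c in citations if c.abstract_decision == "include"]
        if abs_includes and all(c.fulltext_decision == "not_screened" for c in abs_includes):
            raise ValidationError(
                f"scheme {scheme.value} needs full-text decisions but none are present"
            )

    kept: list[Citation] = []
    labels: list[Label] = []
    for c in citations:
        if c.abstract_decision == "exclude":
            kept.append(c)
            labels.append(Label("exclude", c.abstract_reason))
            continue
        # abstract include
        if scheme is LabelScheme.ABSTRACT:
            kept.append(c)
            labels.append(Label("include"))
        elif scheme is LabelScheme.FULL_TEXT:
            if c.fulltext_decision == "include":
                kept.append(c)
                labels.append(Label("include"))
            elif c.fulltext_decision == "exclude":
                kept.append(c)
                labels.append(Label("exclude", c.fulltext_reason))
            else:
                raise ValidationError(
                    f"citation {c.id!r}: abstract include never screened at full text"
                )
        else:  # MODIFIED_FULL_TEXT
            if c.fulltext_decision == "exclude":
                continue  # over-inclusion at abstract stage: drop
            kept.append(c)
            labels.append(Label("include"))
    return LabelledDataset(kept, labels, scheme)


def recode_reason(
    dataset: LabelledDataset, from_: ExclusionReason, to: ExclusionReason
) -> LabelledDataset:
    """Re-categorize one exclusion reason as another, in labels and records.

    Used e.g. to fold a reason with too few examples to learn from (such as
    short follow-up) into "other". Idempotent once applied.
    """
    if from_ is to:
        raise ValidationError("recode_reason requires from != to")

    def swap(r: Optional[ExclusionReason]) -> Optional[ExclusionReason]:
        return to if r is from_ else r

    citations = [
        replace(c, abstract_reason=swap(c.abstract_reason), fulltext_reason=swap(c.fulltext_reason))
        for c in dataset.citations
    ]
    labels = [
        Label(lb.decision, swap(lb.reason)) if lb.reason is from_ else lb
        for lb in dataset.labels
    ]
    return LabelledDataset(citations, labels, dataset.scheme)


def stratified_split(
    dataset: LabelledDataset, spec: SplitSpec
) -> tuple[LabelledDataset, LabelledDataset]:
    """Partition into train/test, stratified on the include/exclude label.

    Within each stratum the training count is round-half-up of
    ``train_fraction`` times the stratum size; membership is a seeded
    permutation, so the same seed always yields the same partition. An
    empty stratum with a fractional split only triggers a warning.
    """
    if len(dataset) == 0:
        raise ValidationError("cannot split an empty dataset")
    rng = np.random.default_rng(spec.seed)
    train_idx: set[int] = set()
    for decision in ("include", "exclude"):
        stratum = [i for i, lb in enumerate(dataset.labels) if lb.decision == decision]
        if not stratum:
            if 0.0 < spec.train_fraction < 1.0:
                warnings.warn(
                    f"stratum {decision!r} is empty; assigning it wholly to train",
                    stacklevel=2,
                )
            continue
        n_train = int(np.floor(spec.train_fraction * len(stratum) + 0.5))
        order = rng.permutation(len(stratum))
        train_idx.update(stratum[j] for j in order[:n_train])
    train_mask = [i in train_idx for i in range(len(dataset))]
    train = LabelledDataset(
        [c for c, m in zip(dataset.citations, train_mask) if m],
        [lb for lb, m in zip(dataset.labels, train_mask) if m],
        dataset.scheme,
    )
    test = LabelledDataset(
        [c for c, m in zip(dataset.citations, train_mask) if not m],
        [lb for lb, m in zip(dataset.labels, train_mask) if not m],
        dataset.scheme,
    )
    return train, test
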