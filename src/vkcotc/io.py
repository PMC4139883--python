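"""FASTA input/output, sequence validation and redundancy reduction.

Benchmark construction for subfamily classifiers typically proceeds in
three steps: discard sequences with ambiguous residues, drop fragments,
and reduce redundancy at a fixed identity cutoff (conventionally 60%).
This module covers the first and third steps; fragment detection needs
source-database annotation and is out of scope (an explicit id-exclusion
list serves instead).

Redundancy reduction follows the greedy longest-first single-pass
clustering strategy popularised by CD-HIT, but computes exact global
(Needleman-Wunsch) alignments instead of word-filter heuristics: at
benchmark scale (hundreds of sequences) exactness is affordable and
makes results bit-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The canonical 20-letter amino-acid alphabet, alphabetically ordered.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class FastaParseError(ValueError):
    """Raised when FASTA input is structurally malformed."""


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: id (header token before first whitespace),
    description (remainder of the header) and the residue string."""

    id: str
    description: str
    sequence: str


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of checking a record against the 20-letter alphabet.

    ``offending_characters`` lists (1-based position, character) for every
    residue outside the canonical alphabet; ``valid`` is true iff empty.
    """

    record_id: str
    valid: bool
    offending_characters: tuple[tuple[int, str], ...]


@dataclass
class LabeledDataset:
    """Ordered protein records, one class label per record.

    ``classes`` preserves first-appearance order of the distinct labels;
    all counting, selection and evaluation downstream use this order.
    """

    records: list[ProteinRecord]
    labels: list[str]
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise ValueError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )
        if not self.classes:
            seen: dict[str, None] = {}
            for lab in self.labels:
                seen.setdefault(lab)
            self.classes = list(seen)
        else:
            missing = set(self.labels) - set(self.classes)
            if missing:
                raise ValueError(f"labels not in class list: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        """Row subset preserving the full class list (folds keep class order)."""
        idx = list(indices)
        return LabeledDataset(
            records=[self.records[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            classes=list(self.classes),
        )


def _read_text(source: str | Path | TextIO) -> str:
    if hasattr(source, "read"):
        return source.read()  # type: ignore[union-attr]
    return Path(source).read_text()


def read_fasta(source: str | Path | TextIO) -> list[ProteinRecord]:
    """Parse FASTA text into :class:`ProteinRecord` objects.

    Multi-line sequence bodies are concatenated, whitespace stripped and
    residues upper-cased; input order is preserved. Sequence data before
    the first ``>`` header and headers with empty bodies are errors.
    """
    text = _read_text(source)
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FastaParseError(
                f"line {lineno}: sequence data precedes the first FASTA header"
            )
        break

    from io import StringIO

    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        seq = str(rec.seq).replace(" ", "").replace("\t", "").upper()
        if not seq:
            raise FastaParseError(f"record {rec.id!r} has an empty sequence body")
        parts = rec.description.split(maxsplit=1)
        description = parts[1] if len(parts) > 1 else ""
        records.append(ProteinRecord(id=rec.id, description=description, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], dest: str | Path | TextIO) -> None:
    """Write records as multi-line FASTA (id + description headers)."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    if hasattr(dest, "write"):
        SeqIO.write(seqrecords, dest, "fasta")
    else:
        with open(dest, "w") as fh:
            SeqIO.write(seqrecords, fh, "fasta")


def validate_record(record: ProteinRecord) -> ValidationReport:
    """Check every residue against the canonical 20-letter alphabet.

    Ambiguity codes (B, X, Z), selenocysteine (U) and any other symbol —
    including ``*`` and ``-`` — are reported with their 1-based position.
    """
    offending = tuple(
        (pos, ch)
        for pos, ch in enumerate(record.sequence, start=1)
        if ch not in _AA_SET
    )
    return ValidationReport(
        record_id=record.id, valid=not offending, offending_characters=offending
    )


def load_labeled_dataset(
    class_sources: Mapping[str, str | Path | TextIO],
    drop_invalid: bool = False,
) -> LabeledDataset:
    """Read one FASTA source per class and assemble a labeled dataset.

    Records are concatenated in class order then file order. With
    ``drop_invalid`` records failing :func:`validate_record` are dropped
    (the count is logged); otherwise any invalid record is an error.
    Duplicate ids across sources and classes left with zero valid
    records are errors.
    """
    if not class_sources:
        raise ValueError("at least one class source is required")
    records: list[ProteinRecord] = []
    labels: list[str] = []
    seen_ids: dict[str, str] = {}
    duplicates: list[str] = []
    for label, source in class_sources.items():
        class_records = read_fasta(source)
        n_dropped = 0
        kept: list[ProteinRecord] = []
        for rec in class_records:
            report = validate_record(rec)
            if not report.valid:
                if drop_invalid:
                    n_dropped += 1
                    continue
                bad = ", ".join(f"{c}@{p}" for p, c in report.offending_characters)
                raise ValueError(
                    f"record {rec.id!r} in class {label!r} has illegal residues: {bad}"
                )
            kept.append(rec)
        if n_dropped:
            logger.info("class %s: dropped %d invalid record(s)", label, n_dropped)
        if not kept:
            raise ValueError(f"class {label!r} has no valid records")
        for rec in kept:
            if rec.id in seen_ids:
                duplicates.append(rec.id)
            seen_ids[rec.id] = label
        records.extend(kept)
        labels.extend([label] * len(kept))
    if duplicates:
        raise ValueError(f"duplicate record ids across sources: {sorted(set(duplicates))}")
    return LabeledDataset(records=records, labels=labels, classes=list(class_sources))


def read_label_map(source: str | Path | TextIO) -> dict[str, str]:
    """Read a two-column tab-separated (record id, class label) file."""
    text = _read_text(source)
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"label map line {lineno}: expected 2 tab-separated columns")
        rec_id, label = parts[0].strip(), parts[1].strip()
        if rec_id in mapping:
            raise ValueError(f"label map line {lineno}: duplicate record id {rec_id!r}")
        mapping[rec_id] = label
    return mapping


def load_labeled_dataset_from_label_map(
    fasta_source: str | Path | TextIO,
    label_map: Mapping[str, str] | str | Path | TextIO,
    drop_invalid: bool = False,
) -> LabeledDataset:
    """Assemble a labeled dataset from a single FASTA plus an id→label map."""
    if not isinstance(label_map, Mapping):
        label_map = read_label_map(label_map)
    records = read_fasta(fasta_source)
    unknown = [r.id for r in records if r.id not in label_map]
    if unknown:
        raise ValueError(f"records without a label: {unknown}")
    out_records: list[ProteinRecord] = []
    out_labels: list[str] = []
    for rec in records:
        report = validate_record(rec)
        if not report.valid:
            if drop_invalid:
                continue
            raise ValueError(f"record {rec.id!r} has illegal residues")
        out_records.append(rec)
        out_labels.append(label_map[rec.id])
    if not out_records:
        raise ValueError("no valid records")
    return LabeledDataset(records=out_records, labels=out_labels)


def _make_aligner() -> Align.PairwiseAligner:
    # Match +1, mismatch 0, linear gap -1 (end gaps included): the simplest
    # scoring under which identical sequences align gap-free with full score.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity in [0, 1].

    Identity = identical aligned residue pairs divided by the length of
    the shorter sequence (the CD-HIT convention), under match +1 /
    mismatch 0 / linear gap -1 scoring.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    alignment = _ALIGNER.align(a, b)[0]
    identities = alignment.counts().identities
    return identities / min(len(a), len(b))


def greedy_redundancy_filter(
    records: list[ProteinRecord],
    threshold: float = 0.60,
) -> tuple[list[ProteinRecord], dict[str, list[str]]]:
    """Greedy longest-first redundancy reduction at an identity cutoff.

    Records are visited longest-first; each joins the cluster of the first
    previously kept representative with identity >= threshold, otherwise
    it founds a new cluster. Returns the representatives restored to their
    original relative order, plus a representative-id → member-ids map
    (representative listed first).
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    order = sorted(range(len(records)), key=lambda i: (-len(records[i].sequence), i))
    rep_indices: list[int] = []
    clusters: dict[str, list[str]] = {}
    for i in order:
        rec = records[i]
        for j in rep_indices:
            if pairwise_identity(rec.sequence, records[j].sequence) >= threshold:
                clusters[records[j].id].append(rec.id)
                break
        else:
            rep_indices.append(i)
            clusters[rec.id] = [rec.id]
    kept = [records[i] for i in sorted(rep_indices)]
    return kept, clusters


def write_curation_report(
    rows: Iterable[tuple[str, str, str]], dest: str | Path | TextIO
) -> None:
    """Write a (record id, action, detail) tab-separated curation report.

    Actions are ``kept``, ``dropped_invalid`` or ``dropped_redundant``.
    """
    lines = ["record_id\taction\tdetail\n"]
    lines += [f"{rid}\t{action}\t{detail}\n" for rid, action, detail in rows]
    if hasattr(dest, "write"):
        dest.writelines(lines)  # type: ignore[union-attr]
    else:
        Path(dest).write_text("".join(lines))
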