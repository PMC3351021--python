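"""FASTA and label-file input/output, residue validation, exact deduplication.

Sequences with residues outside the 20-letter standard alphabet are handled
according to an ambiguity policy: ``drop-sequence`` (default; the
physicochemical feature definitions are only valid over the standard
residues) or ``strip-residue``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple, Union

from .records import (
    AMBIGUOUS_RESIDUES,
    NON_ENZYME,
    STANDARD_RESIDUES,
    ECLabel,
    LabelError,
    ProteinRecord,
)

logger = logging.getLogger(__name__)

DROP_SEQUENCE = "drop-sequence"
STRIP_RESIDUE = "strip-residue"

LabelMap = Dict[str, Union[ECLabel, str]]


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line."""


def read_fasta(
    path: Union[str, Path],
    policy: str = DROP_SEQUENCE,
) -> List[ProteinRecord]:
    """Parse a FASTA file into validated :class:`ProteinRecord` objects.

    Records appear in file order, residues uppercased. Non-standard residues
    (B, Z, X, U, O, J, ``*``) are resolved per *policy*; every drop or strip
    is logged. Returns an empty list for an empty file.
    """
    if policy not in (DROP_SEQUENCE, STRIP_RESIDUE):
        raise ValueError(f"unknown ambiguity policy {policy!r}")

    records: List[ProteinRecord] = []
    header: Union[str, None] = None
    header_line = 0
    chunks: List[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FastaParseError(
                f"{path}: record starting at line {header_line} has no residues"
            )
        name, _, desc = header.partition(" ")
        rec = ProteinRecord(id=name, residues=seq, description=desc)
        bad = set(rec.residues) - STANDARD_RESIDUES
        if bad:
            unexpected = bad - AMBIGUOUS_RESIDUES
            if unexpected:
                raise FastaParseError(
                    f"{path}: record {rec.id!r} contains invalid characters "
                    f"{sorted(unexpected)}"
                )
            if policy == DROP_SEQUENCE:
                logger.info(
                    "dropping %s: ambiguous residues %s", rec.id, sorted(bad)
                )
                return
            stripped = "".join(c for c in rec.residues if c in STANDARD_RESIDUES)
            logger.info(
                "stripping %d ambiguous residues from %s",
                len(rec.residues) - len(stripped),
                rec.id,
            )
            if not stripped:
                logger.info("dropping %s: nothing left after stripping", rec.id)
                return
            rec.residues = stripped
        records.append(rec.validate())

    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: line {lineno}: sequence data before any '>' header"
                    )
                chunks.append(line)
        flush()
    return records


def write_fasta(records: Iterable[ProteinRecord], path: Union[str, Path], width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            handle.write(head + "\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")


def dedup_exact(
    records: Sequence[ProteinRecord],
) -> Tuple[List[ProteinRecord], int]:
    """Remove exact duplicate residue strings, keeping the first occurrence.

    Returns ``(kept, removed_count)`` with input order preserved among kept
    records. This is the 100%-identity redundancy-removal step; clustering at
    lower identity thresholds is out of scope.
    """
    seen = set()
    kept: List[ProteinRecord] = []
    removed = 0
    for rec in records:
        if rec.residues in seen:
            removed += 1
            continue
        seen.add(rec.residues)
        kept.append(rec)
    return kept, removed


def read_labels(path: Union[str, Path]) -> LabelMap:
    """Read a two-column ``id<TAB>label`` file.

    Labels are ``non_enzyme``, ``X.Y``, or a bare main class ``X``. Duplicate
    ids and out-of-range classes raise :class:`LabelError`.
    """
    labels: LabelMap = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LabelError(f"{path}: line {lineno}: expected 'id<TAB>label'")
            seq_id, text = parts[0].strip(), parts[1].strip()
            if seq_id in labels:
                raise LabelError(f"{path}: line {lineno}: duplicate id {seq_id!r}")
            if text == NON_ENZYME:
                labels[seq_id] = NON_ENZYME
            else:
                try:
                    labels[seq_id] = ECLabel.parse(text)
                except LabelError as exc:
                    raise LabelError(f"{path}: line {lineno}: {exc}") from exc
    return labels


def write_labels(labels: LabelMap, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for seq_id, label in labels.items():
            handle.write(f"{seq_id}\t{label}\n")


def attach_labels(records: Sequence[ProteinRecord], labels: LabelMap) -> List[ProteinRecord]:
    """Attach labels to records by id; unlabeled records keep ``label=None``."""
    for rec in records:
        if rec.id in labels:
            rec.label = labels[rec.id]
    return list(records)


def labels_from_headers(records: Sequence[ProteinRecord]) -> LabelMap:
    """Fallback dialect: labels encoded in FASTA headers as ``|EC=1.10`` or
    ``|EC=non_enzyme`` tokens in the description."""
    labels: LabelMap = {}
    for rec in records:
        for token in rec.description.split("|"):
            token = token.strip()
            if token.startswith("EC="):
                value = token[3:]
                labels[rec.id] = NON_ENZYME if value == NON_ENZYME else ECLabel.parse(value)
    return labels
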