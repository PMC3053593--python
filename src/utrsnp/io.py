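"""Readers and writers: FLIc FASTA + annotation tables, ESTs, panel consensus.

File conventions
----------------
* FLIc/EST sequences: plain multi-record FASTA (wrapped or unwrapped).
* Annotation table: TSV with header ``accession  cds_start  cds_end
  utr3_start  utr3_end``; coordinates 1-based inclusive, empty CDS fields
  allowed.  Converted to 0-based half-open internally.
* Panel consensus: FASTA whose record ids are ``<amplicon_id>|<individual_id>``;
  IUPAC ambiguity codes, '-' (homozygous deletion) and lowercase a/c/g/t
  (heterozygous base/gap) permitted.  Case is significant and preserved.
"""

from __future__ import annotations

import csv
from typing import Optional

from Bio import SeqIO

from .core import (
    FlicRecord,
    Interval,
    PanelGenotypes,
    ValidationError,
    normalize_sequence,
)

ANNOTATION_COLUMNS = ["accession", "cds_start", "cds_end", "utr3_start", "utr3_end"]


def _write_fasta(records: list[tuple[str, str]], path) -> None:
    """Deterministic FASTA writer, 60-column wrap, case preserved."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """All records of a FASTA file as (id, sequence), case preserved."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_ests(path) -> list[tuple[str, str]]:
    """EST reads as (id, normalized uppercase sequence)."""
    return [
        (name, normalize_sequence(seq, accession=name))
        for name, seq in read_fasta(path)
    ]


# ---------------------------------------------------------------------------
# FLIc records
# ---------------------------------------------------------------------------


def _parse_coord(value: str, column: str, accession: str) -> Optional[int]:
    value = value.strip()
    if value == "":
        return None
    try:
        return int(value)
    except ValueError:
        raise ValidationError(f"{accession}: non-integer {column}={value!r}") from None


def read_annotations(path) -> dict[str, dict]:
    """Annotation rows keyed by accession; coordinates still 1-based."""
    rows: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(ANNOTATION_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValidationError(
                f"annotation table missing columns {sorted(missing)}"
            )
        for row in reader:
            rows[row["accession"].strip()] = row
    return rows


def read_flics(fasta_path, annotation_path):
    """Load annotated FLIc records.

    Returns ``(records, errors)``: records passing validation, and one
    human-readable message per record that failed (missing annotation,
    interval out of bounds, ...).  Nothing is silently dropped.
    """
    annotations = read_annotations(annotation_path)
    records: list[FlicRecord] = []
    errors: list[str] = []
    for name, seq in read_fasta(fasta_path):
        row = annotations.get(name)
        if row is None:
            errors.append(f"{name}: no annotation row")
            continue
        try:
            cds_start = _parse_coord(row["cds_start"], "cds_start", name)
            cds_end = _parse_coord(row["cds_end"], "cds_end", name)
            utr3_start = _parse_coord(row["utr3_start"], "utr3_start", name)
            utr3_end = _parse_coord(row["utr3_end"], "utr3_end", name)
            if utr3_start is None or utr3_end is None:
                raise ValidationError(f"{name}: missing 3'UTR coordinates")
            cds = None
            if cds_start is not None and cds_end is not None:
                cds = Interval(cds_start - 1, cds_end)  # 1-based incl -> 0-based half-open
            record = FlicRecord(
                accession=name,
                sequence=seq,
                utr3=Interval(utr3_start - 1, utr3_end),
                cds=cds,
                complete_cds_flag=cds is not None,
            ).validate()
        except ValidationError as exc:
            errors.append(str(exc))
            continue
        records.append(record)
    return records, errors


def write_flics(records: list[FlicRecord], fasta_path, annotation_path) -> None:
    """Inverse of :func:`read_flics`; round-trips sequences and intervals."""
    _write_fasta([(r.accession, r.sequence) for r in records], fasta_path)
    with open(annotation_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for r in records:
            cds_start = "" if r.cds is None else r.cds.start + 1
            cds_end = "" if r.cds is None else r.cds.end
            writer.writerow(
                [r.accession, cds_start, cds_end, r.utr3.start + 1, r.utr3.end]
            )


# ---------------------------------------------------------------------------
# Panel consensus
# ---------------------------------------------------------------------------


def read_panel(path, references: Optional[dict[str, str]] = None) -> dict[str, PanelGenotypes]:
    """Panel FASTA -> one :class:`PanelGenotypes` per amplicon.

    Record ids are ``<amplicon_id>|<individual_id>``; individual ids
    prefixed ``ext:`` go into the extension panel.  ``references``
    optionally maps amplicon id to the reference amplicon sequence.
    """
    grouped: dict[str, PanelGenotypes] = {}
    for name, seq in read_fasta(path):
        if "|" not in name:
            raise ValidationError(
                f"panel record id {name!r} lacks '<amplicon>|<individual>' form"
            )
        amplicon_id, individual = name.split("|", 1)
        panel = grouped.get(amplicon_id)
        if panel is None:
            ref = references.get(amplicon_id) if references else None
            panel = PanelGenotypes(amplicon_id, [], [], reference=ref)
            grouped[amplicon_id] = panel
        if individual.startswith("ext:"):
            panel.extension_individuals.append(individual[4:])
            panel.extension_calls.append(seq)
        else:
            panel.individuals.append(individual)
            panel.calls.append(seq)
    for panel in grouped.values():
        panel.validate()
    return grouped


def write_panel(panels: dict[str, PanelGenotypes], path) -> None:
    records: list[tuple[str, str]] = []
    for amplicon_id in sorted(panels):
        panel = panels[amplicon_id]
        for ind, call in zip(panel.individuals, panel.calls):
            records.append((f"{amplicon_id}|{ind}", call))
        for ind, call in zip(panel.extension_individuals, panel.extension_calls):
            records.append((f"{amplicon_id}|ext:{ind}", call))
    _write_fasta(records, path)


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Public deterministic FASTA writer (targets, paralogs, ESTs)."""
    _write_fasta(records, path)
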