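"""Labeled enhancer/promoter sequence pairs and their on-disk formats.

A :class:`SequencePairRecord` is the unit of all I/O in this package: one
enhancer window (default 3000 bp), one promoter window (default 2000 bp), a
binary interaction label and a cell-line tag.  Datasets are stored either as
a TSV table (header ``id  enhancer  promoter  label  cell_line``) or as a
pair of FASTA files matched record-by-record on id.  Sequences are stored as
raw strings — never as expanded one-hot matrices — so a dataset file scales
at roughly one byte per base.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")

TSV_HEADER = ["id", "enhancer", "promoter", "label", "cell_line"]


class RecordValidationError(ValueError):
    """A record violated the length/alphabet contract; names the offender."""


@dataclass(frozen=True)
class SequencePairRecord:
    """One labeled enhancer/promoter pair.

    Attributes
    ----------
    id : str
        Unique record identifier.
    enhancer, promoter : str
        Upper-case sequences over ``{A, C, G, T, N}``.
    label : int
        1 for an interacting pair, 0 otherwise.
    cell_line : str
        Free-text cell-line tag (e.g. ``"GM12878"``); ``"synthetic"`` for
        generated data.
    """

    id: str
    enhancer: str
    promoter: str
    label: int
    cell_line: str = "synthetic"

    def validate(self, enh_len: int | None = None, prom_len: int | None = None) -> None:
        if self.label not in (0, 1):
            raise RecordValidationError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")
        for role, seq, want in (("enhancer", self.enhancer, enh_len), ("promoter", self.promoter, prom_len)):
            if want is not None and len(seq) != want:
                raise RecordValidationError(
                    f"record {self.id!r}: {role} length {len(seq)} != required {want}"
                )
            bad = set(seq) - ALPHABET
            if bad:
                raise RecordValidationError(
                    f"record {self.id!r}: {role} contains characters outside ACGTN: {sorted(bad)}"
                )

    def with_id(self, new_id: str) -> "SequencePairRecord":
        return replace(self, id=new_id)


def validate_records(
    records: list[SequencePairRecord],
    enh_len: int | None = None,
    prom_len: int | None = None,
) -> None:
    """Validate every record, raising on the first offender (named by id)."""
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise RecordValidationError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        rec.validate(enh_len, prom_len)


# ---------------------------------------------------------------------------
# TSV table
# ---------------------------------------------------------------------------

def write_tsv(records: list[SequencePairRecord], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(TSV_HEADER) + "\n")
        for rec in records:
            fh.write(f"{rec.id}\t{rec.enhancer}\t{rec.promoter}\t{rec.label}\t{rec.cell_line}\n")


def read_tsv(path: str | os.PathLike) -> list[SequencePairRecord]:
    records: list[SequencePairRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            return []
        cols = header.rstrip("\n").split("\t")
        if cols != TSV_HEADER:
            raise RecordValidationError(f"unexpected TSV header {cols!r}; expected {TSV_HEADER!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise RecordValidationError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            rid, enh, prom, label, cell = parts
            try:
                lab = int(label)
            except ValueError as exc:
                raise RecordValidationError(f"{path}:{lineno}: non-integer label {label!r}") from exc
            rec = SequencePairRecord(rid, enh.upper(), prom.upper(), lab, cell)
            try:
                rec.validate()
            except RecordValidationError as exc:
                raise RecordValidationError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Paired FASTA
# ---------------------------------------------------------------------------

def _fasta_records(records, which):
    for rec in records:
        seq = rec.enhancer if which == "enhancer" else rec.promoter
        yield SeqRecord(Seq(seq), id=rec.id, description=f"label={rec.label} cell_line={rec.cell_line}")


def write_fasta_pair(records: list[SequencePairRecord], enh_path, prom_path) -> None:
    """Write enhancers and promoters as two FASTA files matched by id.

    Labels and cell lines ride along in the description field so the pair of
    files round-trips without a side table.  Lines wrap at 80 columns.
    """
    for path, which in ((enh_path, "enhancer"), (prom_path, "promoter")):
        with open(path, "w", encoding="utf-8") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
            writer.write_file(_fasta_records(records, which))


def _parse_description(desc: str) -> tuple[int, str]:
    label, cell = 0, "synthetic"
    for token in desc.split():
        if token.startswith("label="):
            label = int(token[len("label="):])
        elif token.startswith("cell_line="):
            cell = token[len("cell_line="):]
    return label, cell


def read_fasta_pair(enh_path, prom_path) -> list[SequencePairRecord]:
    enh = {r.id: r for r in SeqIO.parse(str(enh_path), "fasta")}
    prom = {r.id: r for r in SeqIO.parse(str(prom_path), "fasta")}
    orphans = sorted(set(enh) ^ set(prom))
    if orphans:
        raise RecordValidationError(f"unpaired FASTA ids (present in only one file): {orphans}")
    records = []
    for rid, erec in enh.items():
        label, cell = _parse_description(erec.description)
        rec = SequencePairRecord(rid, str(erec.seq).upper(), str(prom[rid].seq).upper(), label, cell)
        rec.validate()
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Generic entry points (format by extension / path shape)
# ---------------------------------------------------------------------------

def write_dataset(records: list[SequencePairRecord], path: str | os.PathLike) -> None:
    """Write a dataset as TSV (single path) — see :func:`write_fasta_pair` for FASTA."""
    validate_records(records)
    write_tsv(records, path)


def read_dataset(path: str | os.PathLike) -> list[SequencePairRecord]:
    return read_tsv(path)
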