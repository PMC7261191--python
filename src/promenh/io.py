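"""Readers and writers for FASTA, BED6, narrowPeak and the pipeline TSV tables.

All TSV outputs carry a header line preceded by ``#``-prefixed metadata
(package version, seed, config hash) so that every result file records its
provenance.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .intervals import GenomicInterval, NarrowPeak

VALID_BASES = frozenset("ACGTN")

TAG_TABLE_COLUMNS = ["element_id", "library_id", "strand", "rel_position", "count"]
LIBRARY_MAP_COLUMNS = ["library_id", "group", "class"]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, on_invalid: str = "error") -> dict[str, str]:
    """Read a FASTA file into ``{name: uppercase sequence}``.

    ``on_invalid`` controls characters outside ``ACGTN``: ``"error"`` rejects
    the record, ``"mask"`` maps them to ``N``.
    """
    if on_invalid not in ("error", "mask"):
        raise ValueError("on_invalid must be 'error' or 'mask'")
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if not stripped:
        raise ParseError(f"{path}: empty FASTA file")
    if not stripped.startswith(">"):
        bad_line = text.splitlines()[0]
        raise ParseError(f"{path}: line 1: expected '>' header, got {bad_line!r}")
    genome: dict[str, str] = {}
    for record in SeqIO.parse(_io.StringIO(text), "fasta"):
        name = record.id
        if not name:
            raise ParseError(f"{path}: record with empty header")
        seq = str(record.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {name!r} has an empty sequence")
        invalid = set(seq) - VALID_BASES
        if invalid:
            if on_invalid == "error":
                raise ParseError(
                    f"{path}: record {name!r} contains invalid characters "
                    f"{sorted(invalid)}"
                )
            seq = "".join(c if c in VALID_BASES else "N" for c in seq)
        if name in genome:
            raise ParseError(f"{path}: duplicate record {name!r}")
        genome[name] = seq
    if not genome:
        raise ParseError(f"{path}: no FASTA records found")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED6 / narrowPeak


def read_bed(path: str | Path, kind: str = "bed6"):
    """Read a BED file as intervals (``kind="bed6"``) or peaks (``"narrowPeak"``).

    Input order is preserved; records violating the interval invariants raise
    a :class:`ParseError` naming the offending line.
    """
    if kind not in ("bed6", "narrowPeak"):
        raise ValueError(f"kind must be 'bed6' or 'narrowPeak', got {kind!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    min_cols = 3 if kind == "bed6" else 10
    if df.shape[1] < min_cols:
        raise ParseError(
            f"{path}: expected >= {min_cols} columns for {kind}, got {df.shape[1]}"
        )
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        chrom = str(row[0])
        try:
            start, end = int(row[1]), int(row[2])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: line {idx}: non-integer coordinates") from exc
        strand = str(row[5]) if df.shape[1] >= 6 and pd.notna(row[5]) else "."
        try:
            interval = GenomicInterval(chrom, start, end, strand)
        except ValueError as exc:
            raise ParseError(f"{path}: line {idx}: {exc}") from exc
        if kind == "bed6":
            out.append(interval)
        else:
            name = str(row[3]) if pd.notna(row[3]) else "."
            try:
                peak = NarrowPeak(
                    interval=interval,
                    name=name,
                    score=int(float(row[4])) if pd.notna(row[4]) else 0,
                    signal=float(row[6]),
                    pvalue_log=float(row[7]),
                    qvalue_log=float(row[8]),
                    summit_offset=int(row[9]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {idx}: {exc}") from exc
            out.append(peak)
    return out


def write_bed(records: Sequence, path: str | Path, names: Iterable[str] | None = None) -> None:
    """Write intervals or NarrowPeak records back to BED6 / narrowPeak text."""
    with open(path, "w") as fh:
        if names is None:
            names = (getattr(r, "name", "." ) if isinstance(r, NarrowPeak) else "."
                     for r in records)
        for rec, name in zip(records, names):
            if isinstance(rec, NarrowPeak):
                iv = rec.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.name}\t{rec.score}\t"
                    f"{iv.strand}\t{rec.signal:g}\t{rec.pvalue_log:g}\t"
                    f"{rec.qvalue_log:g}\t{rec.summit_offset}\n"
                )
            else:
                fh.write(
                    f"{rec.chrom}\t{rec.start}\t{rec.end}\t{name}\t0\t{rec.strand}\n"
                )


# ---------------------------------------------------------------------------
# TSV tables


def write_tsv(df: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_tag_table(path: str | Path) -> pd.DataFrame:
    """Per-library CAGE tag counts: element_id, library_id, strand, rel_position, count."""
    df = read_tsv(path)
    missing = set(TAG_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: tag table missing columns {sorted(missing)}")
    if (df["count"] < 0).any():
        raise ParseError(f"{path}: negative tag counts")
    return df


def read_library_map(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = set(LIBRARY_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: library map missing columns {sorted(missing)}")
    if df["library_id"].duplicated().any():
        raise ParseError(f"{path}: a library maps to more than one group")
    return df
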