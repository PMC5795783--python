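"""Readers and writers for BED, BED6/GFF3 TSS catalogs, BEDPE and TSV tables.

BED-family formats are 0-based half-open; GFF3 is 1-based inclusive and is
converted to internal coordinates at this boundary. All writers emit
tab-separated, newline-terminated UTF-8 text.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Tuple

import gffutils.iterators
import pandas as pd

from .intervals import ContactPair, GenomicInterval, Peak, TSSRecord


class ParseError(ValueError):
    """A malformed line in a genomic text format, with file/line context."""

    def __init__(self, path: str, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


def _data_lines(path) -> Iterable[Tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _parse_coords(path, lineno: int, chrom: str, start_s: str, end_s: str) -> Tuple[int, int]:
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer coordinates {start_s!r}/{end_s!r}") from None
    if start < 0:
        raise ParseError(path, lineno, f"negative start {start}")
    if end <= start:
        raise ParseError(path, lineno, f"start >= end ({start} >= {end})")
    if not chrom:
        raise ParseError(path, lineno, "empty chromosome name")
    return start, end


def read_bed(path, factor: str = "") -> List[Peak]:
    """Read a BED3+ file into a list of :class:`Peak`.

    Missing name fields are auto-assigned stable ids ``peak_<lineno>``.
    Duplicate peak ids raise :class:`ParseError`.
    """
    peaks: List[Peak] = []
    seen: set = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(path, lineno, f"expected >=3 tab-separated fields, got {len(fields)}")
        start, end = _parse_coords(path, lineno, fields[0], fields[1], fields[2])
        name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else f"peak_{lineno}"
        score: Optional[float] = None
        if len(fields) > 4 and fields[4] not in ("", "."):
            try:
                score = float(fields[4])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric score {fields[4]!r}") from None
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
        if name in seen:
            raise ParseError(path, lineno, f"duplicate peak id {name!r}")
        seen.add(name)
        peaks.append(Peak(GenomicInterval(fields[0], start, end, strand), name, factor, score))
    return peaks


def write_bed(peaks: Iterable[Peak], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in peaks:
            iv = p.interval
            score = "0" if p.score is None else format(p.score, "g")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.peak_id}\t{score}\t{iv.strand}\n")


def read_tss(path, format: str = "bed6", id_attribute: str = "ID") -> List[TSSRecord]:
    """Read a TSS catalog from BED6 or GFF3.

    For BED6 the TSS is the start of the span on ``+`` features and
    ``end - 1`` on ``-`` features (internal 0-based coordinates). GFF3
    features are converted from 1-based inclusive first. Duplicate
    (gene, position) pairs are collapsed; a gene may legitimately keep
    several distinct TSS records (alternative promoters).
    """
    if format == "bed6":
        records = list(_read_tss_bed6(path))
    elif format == "gff3":
        records = list(_read_tss_gff3(path, id_attribute))
    else:
        raise ValueError(f"unknown TSS format {format!r} (use 'bed6' or 'gff3')")
    out: List[TSSRecord] = []
    seen: set = set()
    for rec in records:
        key = (rec.gene_id, rec.chrom, rec.tss_position)
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def _read_tss_bed6(path) -> Iterable[TSSRecord]:
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(path, lineno, f"BED6 needs 6 fields, got {len(fields)}")
        start, end = _parse_coords(path, lineno, fields[0], fields[1], fields[2])
        name, strand = fields[3], fields[5]
        if strand not in ("+", "-"):
            raise ParseError(path, lineno, f"TSS strand must be + or -, got {strand!r}")
        if not name or name == ".":
            raise ParseError(path, lineno, "TSS record lacks a gene name")
        tss = start if strand == "+" else end - 1
        yield TSSRecord(name, fields[0], tss, strand)


def _read_tss_gff3(path, id_attribute: str) -> Iterable[TSSRecord]:
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype not in ("gene", "transcript", "mRNA"):
            continue
        if feat.strand not in ("+", "-"):
            raise ParseError(path, 0, f"feature at {feat.seqid}:{feat.start} has unknown strand")
        ids = feat.attributes.get(id_attribute) or feat.attributes.get("gene_id")
        if not ids:
            raise ParseError(
                path, 0,
                f"feature at {feat.seqid}:{feat.start}-{feat.end} lacks attribute {id_attribute!r}",
            )
        # GFF3 1-based inclusive -> 0-based half-open
        start0, end0 = feat.start - 1, feat.end
        tss = start0 if feat.strand == "+" else end0 - 1
        yield TSSRecord(ids[0], feat.seqid, tss, feat.strand)


def write_tss_bed6(tsss: Iterable[TSSRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in tsss:
            fh.write(f"{t.chrom}\t{t.tss_position}\t{t.tss_position + 1}\t{t.gene_id}\t0\t{t.strand}\n")


def read_bedpe(path) -> List[ContactPair]:
    """Read a BEDPE contact list; anchors validated as genomic intervals."""
    contacts: List[ContactPair] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(path, lineno, f"BEDPE needs >=6 fields, got {len(fields)}")
        s1, e1 = _parse_coords(path, lineno, fields[0], fields[1], fields[2])
        s2, e2 = _parse_coords(path, lineno, fields[3], fields[4], fields[5])
        name = fields[6] if len(fields) > 6 and fields[6] not in ("", ".") else f"contact_{lineno}"
        score: Optional[float] = None
        if len(fields) > 7 and fields[7] not in ("", "."):
            try:
                score = float(fields[7])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric score {fields[7]!r}") from None
        contacts.append(
            ContactPair(GenomicInterval(fields[0], s1, e1), GenomicInterval(fields[3], s2, e2), name, score)
        )
    return contacts


def write_bedpe(contacts: Iterable[ContactPair], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in contacts:
            a, b = c.anchor1, c.anchor2
            score = "." if c.score is None else format(c.score, "g")
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t{c.contact_id}\t{score}\n"
            )


def read_expression(path) -> pd.DataFrame:
    """Read a gene x condition expression table (TSV, first column gene)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene rows in {path}: {dups[:5]}")
    if (df.values < 0).any():
        raise ValueError(f"negative expression values in {path}")
    return df


def read_ortholog_table(path) -> Tuple[str, str, List[Tuple[str, str]]]:
    """Read a 2-column ortholog TSV; the header names the two species."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"ortholog table {path} must have exactly 2 columns")
    species_a, species_b = df.columns[0], df.columns[1]
    pairs = [(a, b) for a, b in df.itertuples(index=False)]
    return species_a, species_b, pairs


def read_ct_table(path) -> pd.DataFrame:
    """Read a qPCR table with columns sample, gene, ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "gene", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table {path} lacks columns {sorted(missing)}")
    return df


def read_gene_list(path) -> List[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
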