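"""Readers and writers for the on-disk formats the pipeline touches.

Internal convention: coordinates are 0-based half-open on the forward
strand, with an explicit ``strand`` flag for minus-strand features.  Every
on-disk format keeps its native convention (FASTA free-form, tabular hits
and GFF-lite 1-based inclusive), and the converters here are the only place
the two conventions meet.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
import logging
import sys
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclasses.dataclass
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.residues)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into records, normalizing wrapping and case.

    Raises :class:`FormatError` on an empty file or duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), desc))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Newick trees (dendropy.Tree is the in-memory carrier throughout)


def read_newick(source: str | Path, *, is_string: bool = False) -> dendropy.Tree:
    """Parse a Newick tree; raises :class:`FormatError` on malformed input."""
    try:
        if is_string:
            tree = dendropy.Tree.get(data=source, schema="newick",
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(path=str(source), schema="newick",
                                     preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"malformed Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate leaf labels in tree")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    text = tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# 12-column tabular homology hits


@dataclasses.dataclass
class HitRow:
    """One homology hit, subject coordinates normalized to the forward strand.

    ``sstart``/``send`` are 0-based half-open with ``sstart < send``; the
    original orientation survives in ``strand``.
    """

    query_id: str
    subject_id: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int  # 0-based half-open on the query protein
    qend: int
    sstart: int  # 0-based half-open, forward strand
    send: int
    strand: str  # '+' or '-'
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError("e-value must be non-negative")
        if not (0 <= self.sstart < self.send):
            raise FormatError("subject interval must be normalized (start < end)")


def read_hits_table(path: str | Path, e_cutoff: float | None = None) -> list[HitRow]:
    """Parse 12-column tab-separated homology output.

    Subject coordinates arrive 1-based inclusive; rows where sstart > send
    are minus-strand and are flipped to forward coordinates.  Rows with
    e-value above ``e_cutoff`` (when given) are dropped.
    """
    rows: list[HitRow] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(f"{path}:{ln}: expected 12 columns, got {len(parts)}")
            (qid, sid, pident, length, mism, gapo, qs, qe, ss, se, ev, bits) = parts
            ss_i, se_i = int(ss), int(se)
            strand = "+" if ss_i <= se_i else "-"
            lo, hi = (ss_i, se_i) if strand == "+" else (se_i, ss_i)
            row = HitRow(
                query_id=qid,
                subject_id=sid,
                pident=float(pident),
                length=int(length),
                mismatch=int(mism),
                gapopen=int(gapo),
                qstart=int(qs) - 1,
                qend=int(qe),
                sstart=lo - 1,
                send=hi,
                strand=strand,
                evalue=float(ev),
                bitscore=float(bits),
            )
            if e_cutoff is None or row.evalue <= e_cutoff:
                rows.append(row)
    return rows


def write_hits_table(rows: Sequence[HitRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in rows:
            ss, se = (r.sstart + 1, r.send) if r.strand == "+" else (r.send, r.sstart + 1)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id, r.subject_id, f"{r.pident:.2f}", r.length,
                        r.mismatch, r.gapopen, r.qstart + 1, r.qend,
                        ss, se, f"{r.evalue:.3g}", f"{r.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF-lite annotation (seqid, source, type, start, end, score, strand, attrs)


@dataclasses.dataclass
class GffFeature:
    seqid: str
    source: str
    type: str
    start: int  # 0-based half-open internally
    end: int
    score: float | None
    strand: str
    attributes: dict[str, str]


def read_gff_lite(path: str | Path) -> list[GffFeature]:
    feats: list[GffFeature] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise FormatError(f"{path}:{ln}: expected 8 columns, got {len(parts)}")
            seqid, source, ftype, start, end, score, strand, attrs = parts
            attributes = {}
            for kv in attrs.split(";"):
                kv = kv.strip()
                if kv:
                    k, _, v = kv.partition("=")
                    attributes[k] = v
            feats.append(
                GffFeature(
                    seqid, source, ftype, int(start) - 1, int(end),
                    None if score == "." else float(score), strand, attributes,
                )
            )
    return feats


def write_gff_lite(feats: Sequence[GffFeature], path: str | Path,
                   header: dict[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        for f in feats:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items())
            score = "." if f.score is None else f"{f.score:g}"
            fh.write(
                f"{f.seqid}\t{f.source}\t{f.type}\t{f.start + 1}\t{f.end}\t"
                f"{score}\t{f.strand}\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Delimited tables


def read_matrix(path: str | Path, index_col: int = 0, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=index_col)
    if df.shape[1] == 0:
        raise FormatError(f"no data columns in {path}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Config and logging


def read_config(path: str | Path) -> dict[str, object]:
    """Load a flat key-value config (YAML mapping; nested keys rejected)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise FormatError("config must be a flat key-value mapping")
    for k, v in data.items():
        if isinstance(v, (dict, list)):
            raise FormatError(f"config key {k!r} is nested; flat keys only")
    return data


def get_logger(name: str = "chemorep", run_id: str | None = None,
               seed: int | None = None) -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    if run_id is not None or seed is not None:
        logger.info("run-id=%s seed=%s", run_id, seed)
    return logger
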