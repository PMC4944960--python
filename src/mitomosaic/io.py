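"""Shared file formats: FASTA, GFF3, the pipeline's TSV dialects, and JSON.

All sequence coordinates are 0-based half-open in memory.  GFF3 on disk is
1-based inclusive, converted at this boundary (internal ``[s, e)`` maps to
``(s + 1, e)`` in a GFF3 row).  Features on circular molecules may wrap the
origin; a wrapping feature is written as two GFF3 parts sharing an ``ID``.
FASTA sequences are normalised to uppercase on read; ``N`` is preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A malformed record, reported with file and line context."""


# --------------------------------------------------------------------------
# FASTA

_DNA_OK = set("ACGTN")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-FASTA into an ordered ``{id: sequence}`` mapping.

    Sequences are uppercased; characters outside ``{A,C,G,T,N}`` raise
    :class:`FormatError`.  Duplicate ids raise as well.
    """
    path = Path(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _DNA_OK
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains non-DNA characters {sorted(bad)}"
            )
        if rec.id in out:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(path: str | Path, seqs: Mapping[str, str],
                descriptions: Mapping[str, str] | None = None,
                width: int = 60) -> None:
    """Write sequences as wrapped FASTA (60 columns by default)."""
    records = []
    for name, seq in seqs.items():
        desc = (descriptions or {}).get(name, "")
        records.append(SeqRecord(Seq(seq), id=name, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# --------------------------------------------------------------------------
# GFF3

@dataclass
class Feature:
    """A located feature with 0-based half-open coordinates.

    ``end`` may exceed the molecule length to denote wrapping the circular
    origin (the on-disk representation is two joined parts).
    """
    seqid: str
    type: str
    start: int
    end: int
    strand: str = "+"
    id: str | None = None
    attributes: dict[str, str] = field(default_factory=dict)
    source: str = "mitomosaic"

    @property
    def length(self) -> int:
        return self.end - self.start


def _attr_string(feat: Feature) -> str:
    parts = []
    if feat.id is not None:
        parts.append(f"ID={feat.id}")
    for k, v in feat.attributes.items():
        parts.append(f"{k}={v}")
    return ";".join(parts) if parts else "."


def write_gff3(path: str | Path, features: Iterable[Feature],
               molecule_lengths: Mapping[str, int] | None = None) -> None:
    """Write GFF3 v3; features wrapping a circular origin are split in two parts.

    ``molecule_lengths`` is required to split wrapping features (those with
    ``end > length``).
    """
    lines = ["##gff-version 3"]
    for feat in features:
        length = (molecule_lengths or {}).get(feat.seqid)
        if length is not None and feat.end > length:
            if feat.start >= length:
                raise FormatError(f"feature {feat.id}: start beyond molecule end")
            # two parts sharing the ID join the wrap
            spans = [(feat.start, length), (0, feat.end - length)]
        else:
            spans = [(feat.start, feat.end)]
        for s, e in spans:
            lines.append("\t".join([
                feat.seqid, feat.source, feat.type,
                str(s + 1), str(e), ".", feat.strand, ".",
                _attr_string(feat),
            ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path,
              molecule_lengths: Mapping[str, int] | None = None) -> list[Feature]:
    """Read GFF3, re-joining wrap parts (same ID, one part ending at the
    molecule length and the other starting at 1) into single wrapping features."""
    path = Path(path)
    feats: list[Feature] = []
    by_id: dict[str, Feature] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        if not raw or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) != 9:
            raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
        seqid, source, ftype, start, end, _score, strand, _phase, attrs = cols
        try:
            s, e = int(start) - 1, int(end)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
        if s < 0 or e < s:
            raise FormatError(f"{path}:{lineno}: invalid interval {start}..{end}")
        attributes: dict[str, str] = {}
        fid = None
        if attrs != ".":
            for item in attrs.split(";"):
                if not item:
                    continue
                if "=" not in item:
                    raise FormatError(f"{path}:{lineno}: malformed attribute {item!r}")
                k, v = item.split("=", 1)
                if k == "ID":
                    fid = v
                else:
                    attributes[k] = v
        feat = Feature(seqid, ftype, s, e, strand, fid, attributes, source)
        if fid is not None and fid in by_id:
            prev = by_id[fid]
            length = (molecule_lengths or {}).get(seqid)
            if length is not None and prev.end == length and feat.start == 0:
                prev.end = length + feat.end  # re-join the wrap
                continue
        feats.append(feat)
        if fid is not None:
            by_id[fid] = feat
    return feats


# --------------------------------------------------------------------------
# TSV dialects

LINKS_COLUMNS = ["contig_a", "end_a", "contig_b", "end_b", "support"]
DEPTH_SUMMARY_COLUMNS = ["contig", "mean_depth"]
DEPTHS_COLUMNS = ["contig", "position", "depth"]
PRIMERS_COLUMNS = ["name", "fwd", "rev", "max_product"]


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    unknown = [c for c in df.columns if c not in columns]
    if unknown:
        raise FormatError(f"{path}: unknown column(s) {unknown}")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df[list(columns)]


def read_links_tsv(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, LINKS_COLUMNS)
    df["support"] = df["support"].astype(int)
    for col in ("end_a", "end_b"):
        bad = ~df[col].isin(["H", "T"])
        if bad.any():
            row = df.index[bad][0]
            raise FormatError(f"{path}: row {row}: {col} must be H or T")
    return df


def write_links_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df[LINKS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_depth_summary_tsv(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, DEPTH_SUMMARY_COLUMNS)
    df["mean_depth"] = df["mean_depth"].astype(float)
    return df


def write_depth_summary_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df[DEPTH_SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_depths_tsv(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, DEPTHS_COLUMNS)
    df["position"] = df["position"].astype(int)
    df["depth"] = df["depth"].astype(float)
    return df


def read_primers_tsv(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, PRIMERS_COLUMNS)
    df["max_product"] = df["max_product"].astype(int)
    return df


def write_primers_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df[PRIMERS_COLUMNS].to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# JSON

def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
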