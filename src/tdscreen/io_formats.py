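"""Readers and writers for annotation, read intervals, tables and catalogs.

All genomic coordinates are handled internally in the BED convention:
0-based, half-open ``[start, end)``.  GTF input (1-based, closed) is
shifted on ingest.  The transcription start site (TSS) of a minus-strand
transcript is ``end - 1``, the last base of the half-open span.
"""

from __future__ import annotations

import json
import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("tdscreen")

__all__ = [
    "TranscriptModel",
    "ReadInterval",
    "TFCatalog",
    "KnownFactorSet",
    "read_annotation",
    "write_annotation_bed12",
    "read_gene_map",
    "write_gene_map",
    "read_table",
    "read_value_column",
    "read_bed_reads",
    "write_bed_reads",
    "read_tf_list",
    "write_tf_list",
    "read_known_factors",
    "write_known_factors",
    "write_screen_result",
    "read_screen_result",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """One transcript of a gene: the unit of gene-body counting.

    Coordinates are 0-based half-open.  ``tss`` is ``start`` on the plus
    strand and ``end - 1`` on the minus strand.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if self.start < 0:
            raise ValueError(f"transcript {self.transcript_id}: negative start")
        if not self.start < self.end:
            raise ValueError(
                f"transcript {self.transcript_id}: start ({self.start}) must be "
                f"< end ({self.end})"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReadInterval:
    """A single aligned read as a genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid read interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class TFCatalog:
    """The set of transcription-factor gene ids for one genome."""

    tf_ids: frozenset
    genome_label: str = ""

    def __post_init__(self) -> None:
        if not self.tf_ids:
            raise ValueError("TF catalog must not be empty")
        object.__setattr__(self, "tf_ids", frozenset(self.tf_ids))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.tf_ids

    def __len__(self) -> int:
        return len(self.tf_ids)


@dataclass(frozen=True)
class KnownFactorSet:
    """Known transdifferentiation factors for one ordered cell-type pair."""

    source_cell: str
    target_cell: str
    factor_ids: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "factor_ids", frozenset(self.factor_ids))

    def validate_against(self, catalog: TFCatalog) -> frozenset:
        """Return the factors present in *catalog*; warn about misses."""
        missing = self.factor_ids - catalog.tf_ids
        if missing:
            logger.warning(
                "%d known factor(s) for %s->%s absent from the TF catalog: %s",
                len(missing), self.source_cell, self.target_cell,
                ", ".join(sorted(missing)),
            )
        return self.factor_ids & catalog.tf_ids


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(text: str) -> dict:
    return dict(_GTF_ATTR.findall(text))


def read_annotation(
    path: str,
    fmt: str | None = None,
    gene_map: Mapping[str, str] | str | None = None,
) -> list[TranscriptModel]:
    """Read a transcript annotation from a BED12 or GTF file.

    Parameters
    ----------
    path:
        Annotation file.  The dialect is inferred from the extension
        (``.bed``/``.bed12`` vs ``.gtf``/``.gff``) unless *fmt* is given
        as ``"bed12"`` or ``"gtf"``.
    gene_map:
        Transcript-to-gene mapping, required for BED12 input (BED has no
        gene field).  Either a mapping or the path of a two-column TSV
        ``transcript_id<TAB>gene_id``.

    Returns
    -------
    list of :class:`TranscriptModel` with 0-based half-open coordinates;
    GTF coordinates (1-based closed) are shifted on ingest.
    """
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        if ext in (".bed", ".bed12"):
            fmt = "bed12"
        elif ext in (".gtf", ".gff"):
            fmt = "gtf"
        else:
            raise ValueError(f"cannot infer annotation dialect from {path!r}")
    if fmt == "bed12":
        return _read_bed12(path, gene_map)
    if fmt == "gtf":
        return _read_gtf(path)
    raise ValueError(f"unknown annotation dialect {fmt!r}")


def _read_bed12(path: str, gene_map) -> list[TranscriptModel]:
    if gene_map is None:
        raise ValueError("BED12 annotation requires a transcript->gene map")
    if isinstance(gene_map, str):
        gene_map = read_gene_map(gene_map)
    out: list[TranscriptModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: BED12 record needs >= 6 fields, "
                    f"got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if name not in gene_map:
                raise ValueError(
                    f"{path}:{lineno}: transcript {name!r} missing from gene map"
                )
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate transcript id {name!r}")
            seen.add(name)
            try:
                out.append(TranscriptModel(
                    gene_id=gene_map[name], transcript_id=name, chrom=chrom,
                    strand=strand, start=start_i, end=end_i,
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not out:
        logger.warning("annotation file %s contained no records", path)
    return out


def _read_gtf(path: str) -> list[TranscriptModel]:
    # Prefer explicit `transcript` features; fall back to the exon hull.
    transcripts: dict[str, dict] = {}
    have_transcript_features = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"{path}:{lineno}: GTF record needs 9 fields, got {len(fields)}"
                )
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("transcript", "exon"):
                continue
            attr = _parse_gtf_attributes(attrs)
            if "gene_id" not in attr:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            if "transcript_id" not in attr:
                raise ValueError(f"{path}:{lineno}: missing transcript_id attribute")
            try:
                # GTF is 1-based closed: shift start to 0-based half-open.
                start_i, end_i = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            tid = attr["transcript_id"]
            rec = transcripts.get(tid)
            if feature == "transcript":
                if have_transcript_features and rec is not None and rec["explicit"]:
                    raise ValueError(
                        f"{path}:{lineno}: duplicate transcript id {tid!r}"
                    )
                have_transcript_features = True
                transcripts[tid] = {
                    "gene_id": attr["gene_id"], "chrom": chrom, "strand": strand,
                    "start": start_i, "end": end_i, "explicit": True,
                }
            else:  # exon: extend the hull only if no explicit record exists
                if rec is None:
                    transcripts[tid] = {
                        "gene_id": attr["gene_id"], "chrom": chrom,
                        "strand": strand, "start": start_i, "end": end_i,
                        "explicit": False,
                    }
                elif not rec["explicit"]:
                    rec["start"] = min(rec["start"], start_i)
                    rec["end"] = max(rec["end"], end_i)
    if not transcripts:
        logger.warning("annotation file %s contained no records", path)
    return [
        TranscriptModel(
            gene_id=rec["gene_id"], transcript_id=tid, chrom=rec["chrom"],
            strand=rec["strand"], start=rec["start"], end=rec["end"],
        )
        for tid, rec in transcripts.items()
    ]


def write_annotation_bed12(
    transcripts: Iterable[TranscriptModel], path: str
) -> None:
    """Write transcripts as single-block BED12 records."""
    with open(path, "w") as fh:
        for t in transcripts:
            block = str(t.length)
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.transcript_id}\t0\t"
                f"{t.strand}\t{t.start}\t{t.end}\t0\t1\t{block},\t0,\n"
            )


def gene_map_of(transcripts: Iterable[TranscriptModel]) -> pd.Series:
    """Transcript-to-gene mapping implied by an annotation."""
    items = {t.transcript_id: t.gene_id for t in transcripts}
    return pd.Series(items, name="gene_id").rename_axis("transcript_id")


def read_gene_map(path: str) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: gene map needs two columns")
    tx_col, gene_col = df.columns[:2]
    dup = df[tx_col][df[tx_col].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate transcript id {dup.iloc[0]!r}")
    return dict(zip(df[tx_col], df[gene_col]))


def write_gene_map(gene_map: Mapping[str, str] | pd.Series, path: str) -> None:
    ser = pd.Series(dict(gene_map)).sort_index()
    ser.rename_axis("transcript_id").rename("gene_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_table(
    path: str,
    key_column: str,
    numeric_columns: Sequence[str],
) -> pd.DataFrame:
    """Read a keyed TSV into a DataFrame indexed by *key_column*.

    Columns are matched by name, so their order in the file is free.
    NA cells are preserved as missing values.  Duplicate keys and
    non-numeric entries in a numeric column are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={key_column: str})
    missing = [c for c in (key_column, *numeric_columns) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    dup = df[key_column][df[key_column].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate key {dup.iloc[0]!r}")
    out = df.set_index(key_column)[list(numeric_columns)]
    for col in numeric_columns:
        try:
            out[col] = pd.to_numeric(out[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric value in column {col!r}") from exc
    return out


def read_value_column(path: str, key_column: str, value_column: str) -> pd.Series:
    """Read one keyed numeric column (e.g. ``gene_id -> tpm``) as a Series."""
    return read_table(path, key_column, [value_column])[value_column]


# ---------------------------------------------------------------------------
# Read-interval (BED) I/O
# ---------------------------------------------------------------------------

def read_bed_reads(path: str) -> pd.DataFrame:
    """Read aligned reads from a 3+-column BED file.

    Returns a DataFrame with columns ``chrom``, ``start``, ``end``
    (0-based half-open); extra BED columns are ignored.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": int, "end": int},
    )
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"{path}: line {bad[0] + 1}: start >= end")
    return df


def write_bed_reads(reads: pd.DataFrame, path: str) -> None:
    reads[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Catalogs and known-factor lists
# ---------------------------------------------------------------------------

def read_tf_list(path: str, genome_label: str = "") -> TFCatalog:
    """Read a plain-text TF catalog, one gene id per line."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    if len(ids) != len(set(ids)):
        raise ValueError(f"{path}: duplicate ids in TF catalog")
    return TFCatalog(tf_ids=frozenset(ids), genome_label=genome_label)


def write_tf_list(catalog: TFCatalog, path: str) -> None:
    with open(path, "w") as fh:
        for gid in sorted(catalog.tf_ids):
            fh.write(gid + "\n")


def read_known_factors(path: str) -> list[KnownFactorSet]:
    """Read a TSV of known factors: columns source_cell, target_cell, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source_cell", "target_cell", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out = []
    for (src, tgt), grp in df.groupby(["source_cell", "target_cell"], sort=True):
        out.append(KnownFactorSet(src, tgt, frozenset(grp["gene_id"])))
    return out


def write_known_factors(sets: Iterable[KnownFactorSet], path: str) -> None:
    rows = [
        {"source_cell": s.source_cell, "target_cell": s.target_cell, "gene_id": g}
        for s in sets for g in sorted(s.factor_ids)
    ]
    pd.DataFrame(rows, columns=["source_cell", "target_cell", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Screen results
# ---------------------------------------------------------------------------

SCREEN_RESULT_COLUMNS = (
    "dz_expr", "dz_mod", "dominance_count", "rank", "selected", "known"
)


def write_screen_result(result, path: str) -> None:
    """Write a :class:`~tdscreen.screen.ScreenResult` as a TSV.

    One row per TF; numeric columns are written with 6 decimals so a
    write/read round trip is lossless at that precision.
    """
    rows = result.rows
    if rows.empty:
        raise ValueError("refusing to write an empty screen result")
    out = rows[list(SCREEN_RESULT_COLUMNS)].copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6f")


def read_screen_result(path: str) -> pd.DataFrame:
    df = read_table(path, "gene_id", ["dz_expr", "dz_mod", "dominance_count", "rank"])
    flags = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    df["selected"] = flags["selected"].astype(bool)
    df["known"] = flags["known"].astype(bool)
    df["dominance_count"] = df["dominance_count"].astype(int)
    df["rank"] = df["rank"].astype(int)
    return df


def write_manifest(params: Mapping, path: str) -> None:
    """Write a run manifest (all parameter values) as JSON."""
    with open(path, "w") as fh:
        json.dump({k: params[k] for k in sorted(params)}, fh, indent=2, default=str)
        fh.write("\n")
    logger.info("run manifest written to %s", path)
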