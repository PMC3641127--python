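"""ChIP-seq gene-body scoring: counting, normalization, input correction.

The modification level of a transcript in one cell type is obtained by
counting ChIP-seq reads over the gene body (the full annotated span,
introns included), normalizing by gene length, taking the natural log
and Z-scoring across all transcripts, then subtracting the Z-score of
an un-enriched input library processed identically.  Differential
modification dZ = Z_target - Z_source is finally collapsed from
transcripts to genes by keeping, per gene, the isoform with the largest
absolute differential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .expression import DifferentialProfile, FeatureProfile, zscore
from .io_formats import ReadInterval, TranscriptModel

logger = logging.getLogger("tdscreen")

__all__ = [
    "GeneBodyCounts",
    "count_reads_over_gene_bodies",
    "normalize_gene_body_counts",
    "normalize_and_zscore",
    "input_correct",
    "collapse_isoforms",
]


@dataclass(frozen=True)
class GeneBodyCounts:
    """Per-transcript read counts over gene bodies for one library."""

    sample_label: str
    counts: pd.Series      # transcript_id -> reads (non-negative int)
    lengths: pd.Series     # transcript_id -> bp
    skipped_reads: int = 0

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            missing = self.counts.index.difference(self.lengths.index)
            if len(missing):
                raise ValueError(
                    f"transcript {missing[0]!r} counted but has no length"
                )
            object.__setattr__(
                self, "lengths", self.lengths.loc[self.counts.index]
            )
        if (self.counts < 0).any():
            raise ValueError("negative read count")


def _reads_frame(reads) -> pd.DataFrame:
    if isinstance(reads, pd.DataFrame):
        return reads
    rows = [(r.chrom, r.start, r.end) for r in reads]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def count_reads_over_gene_bodies(
    reads: pd.DataFrame | Iterable[ReadInterval],
    transcripts: Iterable[TranscriptModel],
    sample_label: str = "",
) -> GeneBodyCounts:
    """Count reads overlapping each transcript's gene body by >= 1 bp.

    A read contributes +1 to every transcript whose half-open span it
    overlaps, so a read may count toward several (overlapping)
    transcripts.  Reads on chromosomes absent from the annotation are
    skipped and tallied in ``skipped_reads``.

    The count for a transcript ``[s, e)`` on a chromosome with ``N``
    reads is computed from sorted read endpoints as
    ``N - #{reads starting >= e} - #{reads ending <= s}``; the two
    excluded sets are disjoint for non-empty intervals, which makes this
    equivalent to the quadratic all-pairs overlap check.
    """
    transcripts = list(transcripts)
    df = _reads_frame(reads)
    counts = pd.Series(
        np.zeros(len(transcripts), dtype=np.int64),
        index=pd.Index([t.transcript_id for t in transcripts], name="transcript_id"),
        name="count",
    )
    lengths = pd.Series(
        [t.length for t in transcripts], index=counts.index, name="length"
    )
    chroms = {t.chrom for t in transcripts}
    skipped = 0
    for chrom, grp in df.groupby("chrom", sort=False):
        if chrom not in chroms:
            skipped += len(grp)
            continue
        starts = np.sort(grp["start"].to_numpy())
        ends = np.sort(grp["end"].to_numpy())
        n = len(grp)
        idx = [i for i, t in enumerate(transcripts) if t.chrom == chrom]
        t_start = np.array([transcripts[i].start for i in idx])
        t_end = np.array([transcripts[i].end for i in idx])
        starting_after = n - np.searchsorted(starts, t_end, side="left")
        ending_before = np.searchsorted(ends, t_start, side="right")
        counts.iloc[idx] = n - starting_after - ending_before
    if skipped:
        logger.warning(
            "%s: %d read(s) on chromosomes absent from the annotation were "
            "not counted", sample_label or "gene-body counting", skipped,
        )
    return GeneBodyCounts(
        sample_label=sample_label, counts=counts, lengths=lengths,
        skipped_reads=skipped,
    )


def normalize_gene_body_counts(counts: GeneBodyCounts) -> pd.Series:
    """Length-normalized counts in reads per kb, with one pseudo-read.

    ``(count + 1) / (length / 1000)`` — the pseudo-read keeps the
    subsequent log defined for transcripts without coverage and is
    negligible for well-covered gene bodies.
    """
    if (counts.lengths <= 0).any():
        bad = counts.lengths.index[counts.lengths <= 0][0]
        raise ValueError(f"transcript {bad!r} has non-positive length")
    return (counts.counts + 1.0) / (counts.lengths / 1000.0)


def normalize_and_zscore(
    counts: GeneBodyCounts, feature: str, cell_type: str
) -> FeatureProfile:
    """Per-transcript Z-scores of log length-normalized gene-body counts."""
    if len(counts.counts) < 2:
        raise ValueError("need at least 2 transcripts to Z-score")
    normalized = normalize_gene_body_counts(counts)
    return FeatureProfile(
        feature=feature,
        cell_type=cell_type,
        values=zscore(np.log(normalized)),
    )


def input_correct(
    chip: FeatureProfile, input_lib: FeatureProfile
) -> FeatureProfile:
    """Subtract the input-library Z-score from the ChIP Z-score.

    Both profiles must come from the same cell type.  Transcripts absent
    from the input profile are dropped (count logged).
    """
    if chip.cell_type != input_lib.cell_type:
        raise ValueError(
            f"cell-type mismatch: {chip.cell_type!r} vs {input_lib.cell_type!r}"
        )
    common = chip.values.index.intersection(input_lib.values.index)
    dropped = len(chip.values) - len(common)
    if dropped:
        logger.info(
            "input correction (%s, %s): dropped %d transcript(s) absent from "
            "the input library", chip.feature, chip.cell_type, dropped,
        )
    if len(common) == 0:
        raise ValueError("no transcripts shared between ChIP and input profiles")
    return FeatureProfile(
        feature=chip.feature,
        cell_type=chip.cell_type,
        values=chip.values.loc[common] - input_lib.values.loc[common],
        input_corrected=True,
    )


def collapse_isoforms(
    diff: DifferentialProfile, gene_map
) -> DifferentialProfile:
    """Collapse a per-transcript differential profile to genes.

    Per gene the isoform with the largest absolute differential is
    retained (strong repression signals are negative, so the magnitude
    decides); exact ties go to the lexicographically smallest
    transcript id.
    """
    gene_map = pd.Series(dict(gene_map)) if not isinstance(gene_map, pd.Series) else gene_map
    values = diff.values.dropna()
    genes = values.index.map(gene_map)
    if genes.isna().any():
        missing = values.index[genes.isna()][0]
        raise ValueError(f"transcript {missing!r} missing from gene map")
    df = pd.DataFrame({
        "gene_id": genes.to_numpy(),
        "dz": values.to_numpy(),
        "transcript_id": values.index.to_numpy(),
    })
    df["absdz"] = df["dz"].abs()
    df = df.sort_values(
        ["gene_id", "absdz", "transcript_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    best = df.groupby("gene_id", sort=True).first()
    return DifferentialProfile(
        feature=diff.feature,
        source_cell=diff.source_cell,
        target_cell=diff.target_cell,
        values=best["dz"].rename("dz").rename_axis("gene_id"),
    )
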