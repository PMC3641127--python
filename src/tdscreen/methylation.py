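"""Promoter methylation scoring from precomputed absolute methylation scores.

Promoters are defined as 1 kb upstream to 0.5 kb downstream of the
transcription start site.  Raw per-promoter absolute methylation scores
(AMS, as produced by a meDIP analysis) are consumed from tables — not
computed here — and rescaled per sample to [0, 1] (0 = no methylation,
1 = completely methylated).  Differential methylation is the target
minus source rescaled score, collapsed to genes by the largest-absolute
isoform, exactly as for histone modification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .chip import collapse_isoforms
from .expression import DifferentialProfile
from .io_formats import TranscriptModel

logger = logging.getLogger("tdscreen")

__all__ = [
    "PROMOTER_UPSTREAM",
    "PROMOTER_DOWNSTREAM",
    "PromoterInterval",
    "MethylationProfile",
    "promoter_interval",
    "rescale_ams",
    "differential_methylation",
]

#: Promoter extent around the TSS, in bp.
PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 500


@dataclass(frozen=True)
class PromoterInterval:
    """Promoter window of one transcript (0-based half-open)."""

    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("promoter start must be non-negative")
        if self.end - self.start > PROMOTER_UPSTREAM + PROMOTER_DOWNSTREAM:
            raise ValueError("promoter wider than its defining window")


@dataclass(frozen=True)
class MethylationProfile:
    """Rescaled [0, 1] promoter methylation per transcript, one cell type."""

    cell_type: str
    values: pd.Series

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", self.values.astype(float))
        v = self.values.dropna()
        if ((v < 0) | (v > 1)).any():
            raise ValueError("rescaled methylation scores must lie in [0, 1]")


def promoter_interval(t: TranscriptModel) -> PromoterInterval:
    """Promoter window (1 kb upstream, 0.5 kb downstream of the TSS).

    On the minus strand the window is mirrored around the TSS (which is
    the base at ``end - 1``); the start is clamped at 0.
    """
    if t.strand == "+":
        start, end = t.tss - PROMOTER_UPSTREAM, t.tss + PROMOTER_DOWNSTREAM
    else:
        start = t.tss - PROMOTER_DOWNSTREAM + 1
        end = t.tss + PROMOTER_UPSTREAM + 1
    return PromoterInterval(
        transcript_id=t.transcript_id, chrom=t.chrom,
        start=max(0, start), end=end, strand=t.strand,
    )


def promoter_bed_frame(transcripts) -> pd.DataFrame:
    """Promoter windows of an annotation as a BED-like DataFrame."""
    rows = [
        (p.chrom, p.start, p.end, p.transcript_id, 0, p.strand)
        for p in map(promoter_interval, transcripts)
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def rescale_ams(raw: pd.Series, cell_type: str) -> MethylationProfile:
    """Min-max rescale raw AMS values to [0, 1] within one sample."""
    raw = raw.astype(float)
    defined = raw.dropna()
    if len(defined) < 2:
        raise ValueError("need at least 2 promoters to rescale")
    lo, hi = defined.min(), defined.max()
    if hi == lo:
        raise ValueError("constant AMS values cannot be rescaled")
    return MethylationProfile(
        cell_type=cell_type, values=((raw - lo) / (hi - lo)).rename("ams")
    )


def differential_methylation(
    target: MethylationProfile, source: MethylationProfile, gene_map
) -> DifferentialProfile:
    """Per-gene dMeth = target - source rescaled score, in [-1, 1].

    Computed per transcript on the shared transcript set, then collapsed
    to genes by the isoform with the largest absolute differential
    (ties to the smallest transcript id).
    """
    t = target.values.dropna()
    s = source.values.dropna()
    common = t.index.intersection(s.index)
    if len(common) == 0:
        raise ValueError("no transcripts shared between the two profiles")
    per_transcript = DifferentialProfile(
        feature="methylation",
        source_cell=source.cell_type,
        target_cell=target.cell_type,
        values=(t.loc[common] - s.loc[common]).rename("dmeth"),
    )
    collapsed = collapse_isoforms(per_transcript, gene_map)
    return DifferentialProfile(
        feature="methylation",
        source_cell=collapsed.source_cell,
        target_cell=collapsed.target_cell,
        values=collapsed.values.rename("dmeth"),
    )
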