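"""Expression scoring: log(1+TPM), genome-wide Z-scores and differential dZ.

The screen's expression statistic for a gene g and an ordered cell-type
pair (source, target) is

    dZ_expr(g) = Z_target(g) - Z_source(g),

where Z is the per-cell-type Z-score of log(1+TPM) computed across all
annotated genes (not only TFs).  Positive dZ means higher expression in
the target cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("tdscreen")

__all__ = [
    "FEATURES",
    "FeatureProfile",
    "DifferentialProfile",
    "log1p_expression",
    "zscore",
    "differential",
    "sum_to_gene_level",
    "expression_profile",
]

#: Feature labels understood by the pipeline.
FEATURES = ("expression", "H3K27me3", "H3K9me3", "methylation")


@dataclass(frozen=True)
class FeatureProfile:
    """Per-entity Z-scores for one feature in one cell type.

    ``values`` maps entity ids (genes or transcripts) to dimensionless
    Z-scores.  Before input correction a profile has mean 0 and sample
    standard deviation 1 over its defined values.
    """

    feature: str
    cell_type: str
    values: pd.Series
    input_corrected: bool = False

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}")
        object.__setattr__(self, "values", self.values.astype(float))

    def is_normalized(self, tol: float = 1e-9) -> bool:
        v = self.values.dropna()
        return bool(
            abs(v.mean()) <= tol and abs(v.std(ddof=1) - 1.0) <= tol
        )


@dataclass(frozen=True)
class DifferentialProfile:
    """Per-entity dZ = Z(target) - Z(source) for one feature and pair."""

    feature: str
    source_cell: str
    target_cell: str
    values: pd.Series

    def swapped(self) -> "DifferentialProfile":
        """The same comparison with source and target exchanged."""
        return DifferentialProfile(
            feature=self.feature,
            source_cell=self.target_cell,
            target_cell=self.source_cell,
            values=-self.values,
        )


def log1p_expression(tpm: pd.Series) -> pd.Series:
    """Natural log of (1 + TPM).

    TPM values must be non-negative; 0 maps to 0 and the transform is
    monotone.
    """
    tpm = tpm.astype(float)
    if (tpm.dropna() < 0).any():
        bad = tpm.index[tpm < 0][0]
        raise ValueError(f"negative TPM for {bad!r}")
    return pd.Series(np.log1p(tpm.to_numpy()), index=tpm.index, name="log1p_tpm")


def zscore(values: pd.Series) -> pd.Series:
    """Z-scores: standard deviations away from the (sample) mean.

    The sample (n-1) standard deviation is used.  Requires at least two
    defined values and a non-zero spread; the result has mean 0 and
    sample standard deviation 1, and is invariant under positive affine
    transforms of the input.
    """
    values = values.astype(float)
    defined = values.dropna()
    if len(defined) < 2:
        raise ValueError("zscore needs at least 2 defined values")
    sd = defined.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("zscore undefined for constant input (zero variance)")
    return (values - defined.mean()) / sd


def expression_profile(tpm: pd.Series, cell_type: str) -> FeatureProfile:
    """Z-scored log(1+TPM) profile across all genes of one cell type."""
    return FeatureProfile(
        feature="expression",
        cell_type=cell_type,
        values=zscore(log1p_expression(tpm)),
    )


def differential(
    profile_target: FeatureProfile, profile_source: FeatureProfile
) -> DifferentialProfile:
    """dZ = Z_target - Z_source per entity present in both profiles.

    Entities missing from either profile are dropped (the count is
    logged).  The two profiles must carry the same feature label.
    """
    if profile_target.feature != profile_source.feature:
        raise ValueError(
            f"feature mismatch: {profile_target.feature!r} vs "
            f"{profile_source.feature!r}"
        )
    t = profile_target.values.dropna()
    s = profile_source.values.dropna()
    common = t.index.intersection(s.index)
    if len(common) == 0:
        raise ValueError("no entities shared between the two profiles")
    dropped = (len(t) - len(common)) + (len(s) - len(common))
    if dropped:
        logger.info(
            "differential %s %s->%s: dropped %d entit(ies) absent from one side",
            profile_target.feature, profile_source.cell_type,
            profile_target.cell_type, dropped,
        )
    return DifferentialProfile(
        feature=profile_target.feature,
        source_cell=profile_source.cell_type,
        target_cell=profile_target.cell_type,
        values=(t.loc[common] - s.loc[common]).rename("dz"),
    )


def sum_to_gene_level(transcript_tpm: pd.Series, gene_map) -> pd.Series:
    """Gene TPM as the sum of its transcripts' TPM."""
    gene_map = pd.Series(dict(gene_map)) if not isinstance(gene_map, pd.Series) else gene_map
    genes = transcript_tpm.index.map(gene_map)
    if genes.isna().any():
        missing = transcript_tpm.index[genes.isna()][0]
        raise ValueError(f"transcript {missing!r} missing from gene map")
    return transcript_tpm.groupby(genes).sum().rename("tpm")
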