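"""Synthetic paired two-cell-type datasets with planted transdifferentiation factors.

The generator emulates the statistical structure the screen assumes:
per-gene log-expression and per-transcript log-modification baselines
shared between two cell types, independent within-cell-type noise, and
a set of *planted* TFs that are shifted up in expression in the target
cell and up in Polycomb-type modification in the source cell.  ChIP and
input libraries are materialized as read intervals on one synthetic
chromosome so that every pipeline stage — interval counting, length
normalization, Z-scoring, input correction, isoform collapse — is
exercised on realistic inputs without any external data.

Default effect sizes are calibrated (by Monte-Carlo runs of the full
pipeline) so the planted group's realized means approximate dZ_expr
~ 1.8 and dZ_mod ~ -3.1 while background TFs sit near 0 on both axes.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import io_formats
from .chip import collapse_isoforms, count_reads_over_gene_bodies, input_correct, normalize_and_zscore
from .expression import DifferentialProfile, differential, expression_profile
from .io_formats import KnownFactorSet, TFCatalog, TranscriptModel
from .screen import ScreenResult, run_screen

logger = logging.getLogger("tdscreen")

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate",
    "emit",
    "load_dataset",
    "score_dataset",
    "screen_dataset",
]

CHROM = "chrS"          # single synthetic chromosome
READ_LENGTH = 36        # bp, typical short-read ChIP
GENE_SPACING = 1000     # bp between gene loci
MEDIAN_LENGTH = 10_000  # bp, median transcript length (log-normal)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic two-cell-type experiment.

    Expression and modification carry separate baseline spreads and
    within-cell-type noise scales: on the log scale, expression varies
    far more between genes than Polycomb-type modification density
    does, and the two assays have unrelated noise floors.  Planted
    effects enter on the log scale so a configured delta translates to
    an approximately constant dZ shift after genome-wide Z-scoring.

    delta_expr is added to the planted genes' log-expression in the
    TARGET cell; delta_mod to their log-modification rate in the SOURCE
    cell (hence planted dZ_mod is negative).
    """

    n_genes: int = 5000
    n_tfs: int = 1400
    n_planted: int = 40
    delta_expr: float = 3.62      # log-units, target cell, planted genes
    delta_mod: float = 4.05       # log-units, source cell, planted genes
    mu_expr: float = 3.0          # mean baseline log(1+TPM)-scale expression
    sigma_between: float = 2.0    # between-gene spread of log expression
    sigma_within: float = 0.5     # within-cell-type expression noise
    sigma_between_mod: float = 0.8  # between-gene spread of log modification
    sigma_within_mod: float = 0.4   # within-cell-type modification noise
    sigma_bias: float = 1.2       # accessibility/copy-number bias, shared by
                                  # the ChIP and input libraries of a cell type
    mean_depth: float = 50.0      # expected ChIP reads per 10 kb transcript
    input_depth: float = 50.0     # expected input reads per 10 kb transcript
    isoforms_per_gene: int = 2
    seed: int = 0
    source_cell: str = "source"
    target_cell: str = "target"

    def validate(self) -> None:
        if not 1 <= self.n_planted <= self.n_tfs <= self.n_genes:
            raise ValueError(
                "need 1 <= n_planted <= n_tfs <= n_genes, got "
                f"{self.n_planted}/{self.n_tfs}/{self.n_genes}"
            )
        for name in ("sigma_between", "sigma_within", "sigma_between_mod",
                     "sigma_within_mod", "sigma_bias"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.mean_depth <= 0 or self.input_depth <= 0:
            raise ValueError("read depths must be > 0")
        if self.isoforms_per_gene < 1:
            raise ValueError("isoforms_per_gene must be >= 1")


@dataclass(frozen=True)
class SimulatedDataset:
    """In-memory synthetic dataset plus its ground truth."""

    config: SimulationConfig
    annotation: list            # TranscriptModel collection
    gene_map: pd.Series         # transcript_id -> gene_id
    expression: dict            # cell_type -> Series gene_id -> TPM
    chip_reads: dict            # cell_type -> DataFrame(chrom, start, end)
    input_reads: dict           # cell_type -> DataFrame(chrom, start, end)
    chip_counts: dict           # cell_type -> Series transcript_id -> drawn count
    input_counts: dict
    tf_catalog: TFCatalog
    known: KnownFactorSet       # the planted truth

    @property
    def planted_ids(self) -> frozenset:
        return self.known.factor_ids


def _make_reads(rng, starts, ends, counts) -> pd.DataFrame:
    """Place `counts[i]` uniform read start positions in transcript i."""
    total = int(counts.sum())
    span_start = np.repeat(starts, counts)
    span_len = np.repeat(np.maximum(ends - starts - READ_LENGTH, 1), counts)
    offsets = rng.integers(0, span_len, size=total)
    read_start = span_start + offsets
    return pd.DataFrame({
        "chrom": CHROM,
        "start": read_start,
        "end": read_start + READ_LENGTH,
    })


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Draw one paired two-cell-type dataset; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    c = config

    gene_ids = np.array([f"G{i:05d}" for i in range(c.n_genes)])
    tf_idx = np.sort(rng.choice(c.n_genes, size=c.n_tfs, replace=False))
    planted_idx = np.sort(rng.choice(tf_idx, size=c.n_planted, replace=False))
    planted_mask = np.zeros(c.n_genes, dtype=bool)
    planted_mask[planted_idx] = True

    # --- annotation: isoforms share the gene's start, tiled on one chromosome
    k = c.isoforms_per_gene
    base_len = np.exp(rng.normal(np.log(MEDIAN_LENGTH), 0.5, size=c.n_genes))
    iso_frac = rng.uniform(0.6, 1.0, size=(c.n_genes, k))
    iso_frac[:, 0] = 1.0
    iso_len = np.maximum((base_len[:, None] * iso_frac).astype(np.int64), 200)
    gene_start = np.concatenate(
        [[0], np.cumsum(iso_len.max(axis=1) + GENE_SPACING)[:-1]]
    )
    strands = rng.choice(["+", "-"], size=c.n_genes)
    tx_start = np.repeat(gene_start, k)
    tx_end = tx_start + iso_len.reshape(-1)
    tx_gene = np.repeat(gene_ids, k)
    tx_strand = np.repeat(strands, k)
    tx_ids = np.array([
        f"{g}.{j + 1}" for g in gene_ids for j in range(k)
    ])
    annotation = [
        TranscriptModel(
            gene_id=tx_gene[i], transcript_id=tx_ids[i], chrom=CHROM,
            strand=tx_strand[i], start=int(tx_start[i]), end=int(tx_end[i]),
        )
        for i in range(len(tx_ids))
    ]
    gene_map = pd.Series(tx_gene, index=pd.Index(tx_ids, name="transcript_id"),
                         name="gene_id")

    # --- expression (gene level): shared baseline + per-cell noise
    a_g = rng.normal(c.mu_expr, c.sigma_between, size=c.n_genes)
    expression = {}
    for cell in (c.source_cell, c.target_cell):
        log_val = a_g + rng.normal(0.0, c.sigma_within, size=c.n_genes)
        if cell == c.target_cell:
            log_val = log_val + c.delta_expr * planted_mask
        tpm = np.expm1(np.clip(log_val, 0.0, None))
        tpm = tpm / tpm.sum() * 1e6
        expression[cell] = pd.Series(tpm, index=pd.Index(gene_ids, name="gene_id"),
                                     name="tpm")

    # --- modification (transcript level): Poisson reads over gene bodies
    mu_mod = -(c.sigma_between_mod ** 2 + c.sigma_within_mod ** 2) / 2.0
    b_g = rng.normal(mu_mod, c.sigma_between_mod, size=c.n_genes)
    b_t = np.repeat(b_g, k)
    tx_planted = np.repeat(planted_mask, k)
    # isoform-specific effect jitter (+-10%) exercises the collapse rule
    iso_jitter = rng.uniform(0.9, 1.1, size=len(tx_ids))
    tx_len = (tx_end - tx_start).astype(float)
    chip_reads, input_reads, chip_counts, input_counts = {}, {}, {}, {}
    tx_index = pd.Index(tx_ids, name="transcript_id")
    bias_mu = -(c.sigma_bias ** 2) / 2.0
    for cell in (c.source_cell, c.target_cell):
        # per-transcript, per-cell-type accessibility/copy-number bias seen
        # by both the ChIP and the input library -- what input correction
        # is meant to remove
        u_t = rng.normal(bias_mu, c.sigma_bias, size=len(tx_ids))
        log_rate = b_t + rng.normal(0.0, c.sigma_within_mod, size=len(tx_ids))
        if cell == c.source_cell:
            log_rate = log_rate + c.delta_mod * iso_jitter * tx_planted
        lam_chip = c.mean_depth * (tx_len / MEDIAN_LENGTH) * np.exp(log_rate + u_t)
        n_chip = rng.poisson(lam_chip)
        lam_input = c.input_depth * (tx_len / MEDIAN_LENGTH) * np.exp(u_t)
        n_input = rng.poisson(lam_input)
        chip_counts[cell] = pd.Series(n_chip, index=tx_index, name="count")
        input_counts[cell] = pd.Series(n_input, index=tx_index, name="count")
        chip_reads[cell] = _make_reads(rng, tx_start, tx_end, n_chip)
        input_reads[cell] = _make_reads(rng, tx_start, tx_end, n_input)

    catalog = TFCatalog(tf_ids=frozenset(gene_ids[tf_idx]), genome_label="synthetic")
    known = KnownFactorSet(
        source_cell=c.source_cell, target_cell=c.target_cell,
        factor_ids=frozenset(gene_ids[planted_idx]),
    )
    return SimulatedDataset(
        config=c, annotation=annotation, gene_map=gene_map,
        expression=expression, chip_reads=chip_reads, input_reads=input_reads,
        chip_counts=chip_counts, input_counts=input_counts,
        tf_catalog=catalog, known=known,
    )


# ---------------------------------------------------------------------------
# Scoring and screening a dataset end to end
# ---------------------------------------------------------------------------

def score_dataset(
    dataset: SimulatedDataset, feature: str = "H3K27me3"
) -> tuple[DifferentialProfile, DifferentialProfile]:
    """Run the expression and ChIP scoring stages on a dataset.

    Returns the gene-level differential expression and (input-corrected,
    isoform-collapsed) differential modification profiles, oriented
    target - source.
    """
    c = dataset.config
    expr_profiles = {
        cell: expression_profile(tpm, cell)
        for cell, tpm in dataset.expression.items()
    }
    dz_expr = differential(
        expr_profiles[c.target_cell], expr_profiles[c.source_cell]
    )
    corrected = {}
    for cell in (c.source_cell, c.target_cell):
        chip = normalize_and_zscore(
            count_reads_over_gene_bodies(
                dataset.chip_reads[cell], dataset.annotation,
                sample_label=f"chip_{cell}",
            ),
            feature=feature, cell_type=cell,
        )
        inp = normalize_and_zscore(
            count_reads_over_gene_bodies(
                dataset.input_reads[cell], dataset.annotation,
                sample_label=f"input_{cell}",
            ),
            feature=feature, cell_type=cell,
        )
        corrected[cell] = input_correct(chip, inp)
    dz_mod_tx = differential(corrected[c.target_cell], corrected[c.source_cell])
    dz_mod = collapse_isoforms(dz_mod_tx, dataset.gene_map)
    return dz_expr, dz_mod


def screen_dataset(dataset: SimulatedDataset) -> ScreenResult:
    """Score a dataset and run the two-criteria screen on its TF catalog."""
    dz_expr, dz_mod = score_dataset(dataset)
    return run_screen(dz_expr, dz_mod, dataset.tf_catalog, dataset.known)


# ---------------------------------------------------------------------------
# Emission to disk and re-ingestion
# ---------------------------------------------------------------------------

def emit(dataset: SimulatedDataset, directory: str) -> dict:
    """Write a dataset in the formats the readers consume.

    Produces a BED12 annotation plus gene map, per-cell expression TSVs,
    ChIP and input BED read files, the TF catalog, the planted
    known-factor list and a JSON manifest of all parameters.  Returns
    the path of every file written.
    """
    if not dataset.annotation:
        raise ValueError("refusing to emit an empty dataset")
    os.makedirs(directory, exist_ok=True)
    c = dataset.config
    paths = {}

    paths["annotation"] = p = os.path.join(directory, "annotation.bed12")
    io_formats.write_annotation_bed12(dataset.annotation, p)
    paths["gene_map"] = p = os.path.join(directory, "gene_map.tsv")
    io_formats.write_gene_map(dataset.gene_map, p)
    for cell, tpm in dataset.expression.items():
        paths[f"expression_{cell}"] = p = os.path.join(
            directory, f"expression_{cell}.tsv"
        )
        tpm.round(6).rename("tpm").to_csv(p, sep="\t")
    for cell in dataset.chip_reads:
        paths[f"chip_{cell}"] = p = os.path.join(directory, f"chip_{cell}.bed")
        io_formats.write_bed_reads(dataset.chip_reads[cell], p)
        paths[f"input_{cell}"] = p = os.path.join(directory, f"input_{cell}.bed")
        io_formats.write_bed_reads(dataset.input_reads[cell], p)
    paths["tf_list"] = p = os.path.join(directory, "tf_list.txt")
    io_formats.write_tf_list(dataset.tf_catalog, p)
    paths["known_factors"] = p = os.path.join(directory, "known_factors.tsv")
    io_formats.write_known_factors([dataset.known], p)
    paths["manifest"] = p = os.path.join(directory, "manifest.json")
    io_formats.write_manifest(asdict(c), p)
    logger.info("simulated dataset written to %s (%d files)", directory, len(paths))
    return paths


def load_dataset(directory: str) -> SimulatedDataset:
    """Re-ingest a dataset previously written by :func:`emit`."""
    with open(os.path.join(directory, "manifest.json")) as fh:
        config = SimulationConfig(**json.load(fh))
    annotation = io_formats.read_annotation(
        os.path.join(directory, "annotation.bed12"),
        gene_map=os.path.join(directory, "gene_map.tsv"),
    )
    gene_map = io_formats.gene_map_of(annotation)
    expression = {
        cell: io_formats.read_value_column(
            os.path.join(directory, f"expression_{cell}.tsv"), "gene_id", "tpm"
        )
        for cell in (config.source_cell, config.target_cell)
    }
    chip_reads = {
        cell: io_formats.read_bed_reads(os.path.join(directory, f"chip_{cell}.bed"))
        for cell in (config.source_cell, config.target_cell)
    }
    input_reads = {
        cell: io_formats.read_bed_reads(os.path.join(directory, f"input_{cell}.bed"))
        for cell in (config.source_cell, config.target_cell)
    }
    catalog = io_formats.read_tf_list(
        os.path.join(directory, "tf_list.txt"), genome_label="synthetic"
    )
    known = io_formats.read_known_factors(
        os.path.join(directory, "known_factors.tsv")
    )[0]
    return SimulatedDataset(
        config=config, annotation=annotation, gene_map=gene_map,
        expression=expression, chip_reads=chip_reads, input_reads=input_reads,
        chip_counts={}, input_counts={},
        tf_catalog=catalog, known=known,
    )
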