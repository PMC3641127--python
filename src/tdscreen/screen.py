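"""The two-criteria screen: dominance ranking, recovery and enrichment.

A candidate transdifferentiation factor should be more highly expressed
in the target cell (large dZ_expr) and more Polycomb-repressed in the
source cell (negative dZ_mod).  TFs are ranked by their dominance
count — the number of other TFs strictly better on *both* criteria —
so count 0 marks the two-dimensional Pareto front.  Recovery curves
measure how early a ranking finds a set of known factors; the signature
box selects candidates comparable to the known anchors; fold enrichment
summarizes the selection against the whole TF catalog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import DifferentialProfile
from .io_formats import KnownFactorSet, TFCatalog

logger = logging.getLogger("tdscreen")

__all__ = [
    "ScreenResult",
    "RecoveryCurve",
    "dominance_count",
    "min_tie_ranks",
    "rank_single_feature",
    "recovery_curve",
    "smooth_ties",
    "recovered_at_top",
    "select_signature_box",
    "fold_enrichment",
    "ks_one_sided",
    "group_mean_dz",
    "run_screen",
    "plot_screen",
]


# ---------------------------------------------------------------------------
# Dominance ranking
# ---------------------------------------------------------------------------

def dominance_count(
    dz_expr: pd.Series, dz_mod: pd.Series, chunk: int = 2048
) -> pd.Series:
    """Number of other TFs strictly better on both screen criteria.

    For TF *i*, counts j != i with ``dz_expr[j] > dz_expr[i]`` and
    ``dz_mod[j] < dz_mod[i]`` (strict on both sides, so identical
    points never dominate each other).  TFs missing either value are
    excluded (count logged).
    """
    df = pd.concat({"e": dz_expr, "m": dz_mod}, axis=1)
    dropped = int(df.isna().any(axis=1).sum())
    if dropped:
        logger.info("dominance_count: excluded %d TF(s) with missing values", dropped)
    df = df.dropna()
    if df.empty:
        raise ValueError("no TFs with both differential values")
    e = df["e"].to_numpy()
    m = df["m"].to_numpy()
    n = len(df)
    counts = np.zeros(n, dtype=np.int64)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        better = (e[None, :] > e[lo:hi, None]) & (m[None, :] < m[lo:hi, None])
        counts[lo:hi] = better.sum(axis=1)
    return pd.Series(counts, index=df.index, name="dominance_count")


def min_tie_ranks(keys: pd.Series, ascending: bool = True) -> pd.Series:
    """Competition ranks (1 = best); tied entries share the smallest rank."""
    r = keys.rank(method="min", ascending=ascending)
    return r.astype(int).rename("rank")


def rank_single_feature(values: pd.Series, direction: str) -> pd.Series:
    """Rank TFs by one differential feature.

    ``direction="descending"`` puts the largest value first (used for
    dZ_expr: most target-enriched on top); ``"ascending"`` puts the
    smallest first (dZ_mod: most source-repressed on top).  Returns
    min-tie ranks; within a tie the gene ids order deterministically
    when the ranking is listed.
    """
    if direction not in ("descending", "ascending"):
        raise ValueError(f"unknown direction {direction!r}")
    return min_tie_ranks(values, ascending=(direction == "ascending"))


def ranked_list(values: pd.Series, direction: str) -> list:
    """Gene ids ordered best-first, ties broken by gene id."""
    asc = direction == "ascending"
    df = pd.DataFrame({"v": values})
    df = df.sort_index().sort_values("v", ascending=asc, kind="mergesort")
    return list(df.index)


# ---------------------------------------------------------------------------
# Recovery curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryCurve:
    """Fraction of known factors recovered along a ranked TF list.

    ``points`` has columns ``position`` (1-based rank depth, i.e. the
    number of TFs at or better than the score threshold defining the
    point) and ``fraction`` (recovered fraction of the known set).
    """

    points: pd.DataFrame
    n_known: int
    n_universe: int
    smoothed: bool = False

    def __post_init__(self) -> None:
        p = self.points["position"].to_numpy()
        f = self.points["fraction"].to_numpy()
        if len(p) and not (np.diff(p) > 0).all():
            raise ValueError("positions must be strictly increasing")
        if len(f) and (np.diff(f) < 0).any():
            raise ValueError("recovered fraction must be non-decreasing")

    @property
    def position_fractions(self) -> np.ndarray:
        """Positions as fractions of the ranked universe (plot x-axis)."""
        return self.points["position"].to_numpy() / self.n_universe


def recovery_curve(ranking, known: KnownFactorSet | set) -> RecoveryCurve:
    """Recovery of known factors as a function of list position.

    Parameters
    ----------
    ranking:
        Either an ordered sequence of gene ids (best first, positions
        1..n) or a Series of sort keys over the TF universe where
        *smaller is better* (e.g. a dominance count).  With keyed input,
        one curve point is produced per distinct key value c, at
        position ``#{TFs with key <= c}``.
    known:
        The known factors.  Factors absent from the ranked universe are
        excluded from the denominator (with a warning).
    """
    known_ids = known.factor_ids if isinstance(known, KnownFactorSet) else set(known)
    if not known_ids:
        raise ValueError("empty known-factor set")
    if isinstance(ranking, pd.Series):
        keys = ranking.dropna()
    else:
        ids = list(ranking)
        keys = pd.Series(np.arange(1, len(ids) + 1), index=ids)
    universe = set(keys.index)
    present = known_ids & universe
    if len(present) < len(known_ids):
        logger.warning(
            "recovery_curve: %d known factor(s) absent from the ranked "
            "universe were excluded", len(known_ids) - len(present),
        )
    if not present:
        raise ValueError("no known factors present in the ranked universe")
    order = np.sort(keys.to_numpy())
    known_keys = np.sort(keys.loc[sorted(present)].to_numpy())
    thresholds = np.unique(order)
    positions = np.searchsorted(order, thresholds, side="right")
    recovered = np.searchsorted(known_keys, thresholds, side="right")
    points = pd.DataFrame({
        "position": positions,
        "fraction": recovered / len(present),
    })
    return RecoveryCurve(
        points=points, n_known=len(present), n_universe=len(keys), smoothed=False
    )


def smooth_ties(curve: RecoveryCurve) -> RecoveryCurve:
    """Keep only the best (smallest) position attaining each fraction.

    Positions in a ranked list that recover the same fraction of known
    factors are redundant; retaining the most highly ranking one turns
    the raw step curve into a sparse, still non-decreasing one.  The
    operation is idempotent and preserves the set of attained fractions.
    """
    pts = curve.points
    if pts.empty:
        raise ValueError("cannot smooth an empty curve")
    keep = ~pts["fraction"].duplicated(keep="first")
    return RecoveryCurve(
        points=pts.loc[keep].reset_index(drop=True),
        n_known=curve.n_known,
        n_universe=curve.n_universe,
        smoothed=True,
    )


def recovered_at_top(
    ranks: pd.Series, known_ids, top_fraction: float
) -> float:
    """Fraction of known factors ranked within the top *top_fraction*.

    ``ranks`` are min-tie ranks over the TF universe (1 = best); the
    cutoff is ``round(top_fraction * n_universe)`` positions.
    """
    known = [g for g in known_ids if g in ranks.index]
    if not known:
        raise ValueError("no known factors present in the ranked universe")
    cutoff = int(round(top_fraction * len(ranks)))
    return float((ranks.loc[known] <= cutoff).mean())


# ---------------------------------------------------------------------------
# Signature box and enrichment
# ---------------------------------------------------------------------------

def select_signature_box(
    dz_expr: pd.Series,
    dz_mod: pd.Series,
    anchors,
    feature: str = "both",
) -> tuple[pd.Index, tuple[float, float]]:
    """Select TFs with differentials comparable to the anchor factors.

    Thresholds are set by the anchors: ``dz_expr_min`` is their minimum
    differential expression and ``dz_mod_max`` their maximum
    differential modification.  Selection is inclusive (``>=`` / ``<=``),
    so anchors are always selected.  ``feature`` may restrict the box to
    a single criterion (``"expression"`` or ``"modification"``).
    """
    anchor_ids = anchors.factor_ids if isinstance(anchors, KnownFactorSet) else set(anchors)
    anchor_ids = [a for a in anchor_ids if a in dz_expr.index and a in dz_mod.index]
    if not anchor_ids:
        raise ValueError("empty anchor set")
    dz_expr_min = float(dz_expr.loc[anchor_ids].min())
    dz_mod_max = float(dz_mod.loc[anchor_ids].max())
    df = pd.concat({"e": dz_expr, "m": dz_mod}, axis=1).dropna()
    if feature == "both":
        mask = (df["e"] >= dz_expr_min) & (df["m"] <= dz_mod_max)
    elif feature == "expression":
        mask = df["e"] >= dz_expr_min
    elif feature == "modification":
        mask = df["m"] <= dz_mod_max
    else:
        raise ValueError(f"unknown feature selector {feature!r}")
    return df.index[mask], (dz_expr_min, dz_mod_max)


def fold_enrichment(n_known: int, n_other_selected: int, n_total: int) -> float:
    """Enrichment of a selection for known factors relative to all TFs.

    ``(n_total - n_known) / (n_known + n_other_selected)``: the ratio of
    the candidate pool outside the known set to the size of the
    selection.  Reported values are conventionally rounded to the
    nearest integer.
    """
    if n_known < 1:
        raise ValueError("n_known must be >= 1")
    if n_other_selected < 0:
        raise ValueError("n_other_selected must be >= 0")
    if not n_total > n_known + n_other_selected:
        raise ValueError("n_total must exceed the selection size")
    return (n_total - n_known) / (n_known + n_other_selected)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def ks_one_sided(group_a, group_b, alternative: str) -> tuple[float, float]:
    """One-sided two-sample Kolmogorov-Smirnov test.

    ``alternative="greater"`` tests that *group_a* is stochastically
    larger than *group_b* (used for dZ_expr of known factors vs other
    TFs); ``"less"`` tests the reverse (used for dZ_mod).  Returns the
    signed-supremum D statistic and its p-value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    # scipy's alternatives are phrased in terms of the empirical CDF of
    # the first sample: its 'less' means F_a < F_b somewhere, i.e. a is
    # stochastically larger.  Map accordingly.
    scipy_alt = "less" if alternative == "greater" else "greater"
    res = stats.ks_2samp(a, b, alternative=scipy_alt)
    return float(res.statistic), float(res.pvalue)


def group_mean_dz(diffs: DifferentialProfile | pd.Series, group) -> float:
    """Arithmetic mean dZ over the group's genes present in the profile."""
    values = diffs.values if isinstance(diffs, DifferentialProfile) else diffs
    group = [g for g in group if g in values.index]
    if not group:
        raise ValueError("group does not intersect the profile")
    return float(values.loc[group].mean())


# ---------------------------------------------------------------------------
# The assembled screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenResult:
    """Per-TF screen outcome for one ordered cell-type pair.

    ``rows`` is indexed by gene id with columns dz_expr, dz_mod,
    dominance_count, rank (min-tie on the dominance count), selected
    (inside the signature box anchored on the known factors) and known.
    """

    pair: tuple[str, str]
    rows: pd.DataFrame
    thresholds: tuple[float, float]

    @property
    def n_total(self) -> int:
        return len(self.rows)

    @property
    def n_known(self) -> int:
        return int(self.rows["known"].sum())

    @property
    def n_other_selected(self) -> int:
        return int((self.rows["selected"] & ~self.rows["known"]).sum())

    def enrichment(self) -> float:
        return fold_enrichment(self.n_known, self.n_other_selected, self.n_total)

    def summary(self) -> dict:
        """Group means, one-sided KS tests and fold enrichment."""
        known = self.rows.index[self.rows["known"]]
        other = self.rows.index[~self.rows["known"]]
        d_e, p_e = ks_one_sided(
            self.rows.loc[known, "dz_expr"], self.rows.loc[other, "dz_expr"],
            alternative="greater",
        )
        d_m, p_m = ks_one_sided(
            self.rows.loc[known, "dz_mod"], self.rows.loc[other, "dz_mod"],
            alternative="less",
        )
        return {
            "pair": f"{self.pair[0]}->{self.pair[1]}",
            "n_total": self.n_total,
            "n_known": self.n_known,
            "n_other_selected": self.n_other_selected,
            "mean_dz_expr_known": group_mean_dz(self.rows["dz_expr"], known),
            "mean_dz_expr_other": group_mean_dz(self.rows["dz_expr"], other),
            "mean_dz_mod_known": group_mean_dz(self.rows["dz_mod"], known),
            "mean_dz_mod_other": group_mean_dz(self.rows["dz_mod"], other),
            "ks_D_expr": d_e, "ks_p_expr": p_e,
            "ks_D_mod": d_m, "ks_p_mod": p_m,
            "fold_enrichment": self.enrichment(),
            "dz_expr_min": self.thresholds[0],
            "dz_mod_max": self.thresholds[1],
        }


def run_screen(
    dz_expr: DifferentialProfile | pd.Series,
    dz_mod: DifferentialProfile | pd.Series,
    catalog: TFCatalog,
    known: KnownFactorSet,
) -> ScreenResult:
    """Assemble the per-TF screen for one ordered cell-type pair.

    Genome-wide differential profiles are subset to the TF catalog;
    TFs missing either value are dropped (logged by
    :func:`dominance_count`).  Known factors absent from the surviving
    TF rows are ignored with a warning.
    """
    if isinstance(dz_expr, DifferentialProfile):
        pair = (dz_expr.source_cell, dz_expr.target_cell)
        dz_expr = dz_expr.values
    else:
        pair = (known.source_cell, known.target_cell)
    if isinstance(dz_mod, DifferentialProfile):
        dz_mod = dz_mod.values
    tf_ids = pd.Index(sorted(catalog.tf_ids))
    df = pd.DataFrame({
        "dz_expr": dz_expr.reindex(tf_ids),
        "dz_mod": dz_mod.reindex(tf_ids),
    }).dropna()
    if df.empty:
        raise ValueError("no TFs with both differential values")
    df["dominance_count"] = dominance_count(df["dz_expr"], df["dz_mod"])
    df["rank"] = min_tie_ranks(df["dominance_count"])
    known_present = [g for g in sorted(known.factor_ids) if g in df.index]
    if len(known_present) < len(known.factor_ids):
        logger.warning(
            "screen %s->%s: %d known factor(s) not among the scored TFs",
            pair[0], pair[1], len(known.factor_ids) - len(known_present),
        )
    df["known"] = df.index.isin(known_present)
    selected, thresholds = select_signature_box(
        df["dz_expr"], df["dz_mod"], known_present
    )
    df["selected"] = df.index.isin(selected)
    return ScreenResult(pair=pair, rows=df, thresholds=thresholds)


def plot_screen(result: ScreenResult, path: str) -> None:
    """Scatter of dZ_expr vs dZ_mod with the signature box drawn."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    rows = result.rows
    other = rows[~rows["known"]]
    known = rows[rows["known"]]
    ax.scatter(other["dz_expr"], other["dz_mod"], s=6, c="0.6", label="other TFs")
    ax.scatter(
        known["dz_expr"], known["dz_mod"], s=20, c="tab:blue",
        label="known factors",
    )
    e_min, m_max = result.thresholds
    ax.axvline(e_min, c="k", lw=0.5, ls="--")
    ax.axhline(m_max, c="k", lw=0.5, ls="--")
    ax.set_xlabel(r"differential expression (dZ)")
    ax.set_ylabel(r"differential modification (dZ)")
    ax.set_title(f"{result.pair[0]} → {result.pair[1]}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
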