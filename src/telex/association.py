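"""Gene-TE association by linear modeling and correlation-sign filtering.

Each differentially expressed TE locus is paired with its positionally
associated gene (host gene for overlapping loci, nearest gene for
intergenic ones).  Gene expression is then regressed on TE expression
across all samples of the contrast; pairs whose slope is significant
(p <= 0.05, inclusive) are kept, their Pearson correlation computed, and
each pair labeled POSITIVE or NEGATIVE by the correlation sign.  Negative
pairs are the candidate set for TE-mediated gene repression.

Expression is transformed to log2(CPM + 1) before modeling by default;
``raw_counts=True`` reproduces the naive fit on untransformed counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .report import round_half_up

logger = logging.getLogger(__name__)

ALPHA_PAIR_DEFAULT = 0.05

PAIR_COLUMNS = ["gene_id", "te_id", "location", "slope", "lm_p", "correlation", "sign"]


def build_pairs(
    de_tes: pd.DataFrame,
    classifications: pd.DataFrame,
) -> pd.DataFrame:
    """Pair every retained DE TE with its associated gene.

    ``de_tes`` must carry ``feature_id`` (TE locus ids) and ``call``;
    NS rows are ignored.  ``classifications`` is the TSV frame from the
    classification stage (te_id, label, gene_id, distance_bp).  A DE TE
    missing from the classifications is an error; one without an
    associated gene (e.g. alone on its chromosome) is dropped with a
    warning.
    """
    cls = classifications.set_index("te_id")
    pairs = []
    for _, row in de_tes.iterrows():
        if row["call"] == "NS":
            continue
        te_id = row["feature_id"]
        if te_id not in cls.index:
            raise KeyError(f"DE TE {te_id} absent from classifications")
        c = cls.loc[te_id]
        if c["label"] == "DISCARDED":
            continue
        gene = c["gene_id"]
        if not gene or (isinstance(gene, float) and np.isnan(gene)):
            logger.warning("DE TE %s has no associated gene; dropped", te_id)
            continue
        pairs.append((gene, te_id, c["label"]))
    return pd.DataFrame(pairs, columns=["gene_id", "te_id", "location"])


def transform_expression(counts: pd.DataFrame, raw_counts: bool = False) -> pd.DataFrame:
    """log2(CPM + 1) per sample; library sizes are column sums of the full
    matrix passed in."""
    if raw_counts:
        return counts.astype(float)
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples {bad}")
    cpm = counts.to_numpy(dtype=float) / lib * 1e6
    return pd.DataFrame(np.log2(cpm + 1.0), index=counts.index, columns=counts.columns)


def fit_linear_model(
    gene_expr: np.ndarray | Sequence[float], te_expr: np.ndarray | Sequence[float]
) -> tuple[float, float]:
    """OLS of gene on TE with intercept; returns (slope, two-sided t-test
    p-value on the slope)."""
    x = np.asarray(te_expr, dtype=float)
    y = np.asarray(gene_expr, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired samples")
    if np.ptp(x) == 0:
        raise ValueError("TE expression is constant; slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue)


def pearson_correlation(
    x: np.ndarray | Sequence[float], y: np.ndarray | Sequence[float]
) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(x, y)[0, 1])


def _sign_label(corr: float) -> str:
    if corr > 0:
        return "POSITIVE"
    if corr < 0:
        return "NEGATIVE"
    return "ZERO"


def score_pairs(
    pairs: pd.DataFrame,
    expression: pd.DataFrame,
) -> pd.DataFrame:
    """Fit the linear model and correlation for every candidate pair.

    ``expression`` is the (already transformed) features x samples table
    containing both gene and TE rows.  Pairs with a constant gene or TE
    vector are dropped with a warning (slope/correlation undefined).
    """
    rows = []
    for _, p in pairs.iterrows():
        gene, te = p["gene_id"], p["te_id"]
        if gene not in expression.index or te not in expression.index:
            logger.warning("pair (%s, %s): expression missing; dropped", gene, te)
            continue
        gx = expression.loc[gene].to_numpy(dtype=float)
        tx = expression.loc[te].to_numpy(dtype=float)
        try:
            slope, lm_p = fit_linear_model(gx, tx)
            corr = pearson_correlation(gx, tx)
        except ValueError as exc:
            logger.warning("pair (%s, %s): %s; dropped", gene, te, exc)
            continue
        rows.append((gene, te, p["location"], slope, lm_p, corr, _sign_label(corr)))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def select_pairs(
    pairs: pd.DataFrame, alpha_pair: float = ALPHA_PAIR_DEFAULT
) -> pd.DataFrame:
    """Keep pairs with lm_p <= alpha_pair (boundary inclusive)."""
    if pairs.empty:
        return pairs.copy()
    return pairs[pairs["lm_p"] <= alpha_pair].reset_index(drop=True)


@dataclass
class PairSummary:
    n_pairs: int
    n_positive: int
    n_negative: int
    n_zero: int
    pct_positive: float
    pct_negative: float
    by_location: dict[str, tuple[int, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "n_zero": self.n_zero,
            "pct_positive": self.pct_positive,
            "pct_negative": self.pct_negative,
            "by_location": {
                loc: {"n_positive": pn, "n_negative": nn}
                for loc, (pn, nn) in self.by_location.items()
            },
        }


def summarize_pairs(pairs: pd.DataFrame) -> PairSummary:
    """Sign counts and percentages (half-up, one decimal) overall and per
    location class."""
    n = len(pairs)
    if n == 0:
        return PairSummary(0, 0, 0, 0, 0.0, 0.0, {})
    n_pos = int((pairs["sign"] == "POSITIVE").sum())
    n_neg = int((pairs["sign"] == "NEGATIVE").sum())
    n_zero = n - n_pos - n_neg
    by_loc = {}
    for loc, sub in pairs.groupby("location", sort=True):
        by_loc[str(loc)] = (
            int((sub["sign"] == "POSITIVE").sum()),
            int((sub["sign"] == "NEGATIVE").sum()),
        )
    return PairSummary(
        n_pairs=n,
        n_positive=n_pos,
        n_negative=n_neg,
        n_zero=n_zero,
        pct_positive=round_half_up(100.0 * n_pos / n),
        pct_negative=round_half_up(100.0 * n_neg / n),
        by_location=by_loc,
    )


@dataclass
class NegativeGeneTable:
    """Unique genes from negatively correlated pairs, grouped by the TE
    location class that links them.  A gene reached through both an
    intronic and an intergenic TE appears in both groups but counts once
    in the total."""

    genes_by_location: dict[str, list[str]]
    n_by_location: dict[str, int]
    total_genes: int

    def to_dict(self) -> dict:
        return {
            "genes_by_location": self.genes_by_location,
            "n_by_location": self.n_by_location,
            "total_genes": self.total_genes,
        }


def negative_pair_gene_table(pairs: pd.DataFrame) -> NegativeGeneTable:
    neg = pairs[pairs["sign"] == "NEGATIVE"] if not pairs.empty else pairs
    if neg.empty:
        return NegativeGeneTable({}, {}, 0)
    by_loc: dict[str, list[str]] = {}
    for loc, sub in neg.groupby("location", sort=True):
        by_loc[str(loc)] = sorted(sub["gene_id"].unique())
    return NegativeGeneTable(
        genes_by_location=by_loc,
        n_by_location={loc: len(g) for loc, g in by_loc.items()},
        total_genes=int(neg["gene_id"].nunique()),
    )
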