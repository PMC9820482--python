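"""Negative-binomial differential expression between two conditions.

A desk-scale analogue of the DESeq2 workflow: median-of-ratios size
factors, per-feature method-of-moments NB dispersion (variance
mu + alpha*mu^2), an NB GLM with log link and a condition indicator fitted
per feature, a Wald test on the condition coefficient, Benjamini-Hochberg
adjustment, and an UP/DOWN/NS call at |log2FC| >= 1.5 and adjusted
p <= 0.05 (both thresholds inclusive).

Deliberate simplifications relative to DESeq2: no dispersion shrinkage, no
independent filtering, no outlier refitting.  These are documented in the
methods note; the thresholds and the normalization are the analysis'
defining components and are implemented exactly.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LFC_THRESHOLD_DEFAULT = 1.5
ALPHA_DEFAULT = 0.05
DISPERSION_FLOOR = 1e-8


def size_factors(
    counts: pd.DataFrame, fallback: Optional[str] = "poscounts"
) -> pd.Series:
    """Median-of-ratios size factors (one per sample/column).

    Each sample's factor is the median across features of the ratio of its
    count to the feature's geometric mean, computed over features with
    strictly positive counts in every sample.  If no such feature exists,
    the ``poscounts`` fallback takes geometric means over positive entries
    only; with ``fallback=None`` that situation raises instead.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.ndim != 2 or mat.shape[1] == 0:
        raise ValueError("counts must be a features x samples table")
    if (mat < 0).any():
        raise ValueError("counts must be nonnegative")
    if mat.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")

    all_pos = (mat > 0).all(axis=1)
    with np.errstate(divide="ignore"):
        logmat = np.log(mat)
    if all_pos.any():
        loggeo = logmat[all_pos].mean(axis=1)
        ratios = logmat[all_pos] - loggeo[:, None]
        sf = np.exp(np.median(ratios, axis=0))
    elif fallback == "poscounts":
        pos = mat > 0
        usable = pos.any(axis=1)
        if not usable.any():
            raise ValueError("all-zero count matrix: size factors undefined")
        loggeo = np.where(
            usable,
            np.where(pos, logmat, 0.0).sum(axis=1) / np.maximum(pos.sum(axis=1), 1),
            np.nan,
        )
        sf = np.empty(mat.shape[1])
        for j in range(mat.shape[1]):
            r = logmat[:, j] - loggeo
            r = r[usable & pos[:, j]]
            if r.size == 0:
                raise ValueError(f"sample {counts.columns[j]}: no usable feature")
            sf[j] = np.exp(np.median(r))
    else:
        raise ValueError(
            "no feature has positive counts in all samples and the "
            "poscounts fallback is disabled"
        )
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    condition_labels: Optional[pd.Series | Mapping[str, str]] = None,
    floor: float = DISPERSION_FLOOR,
    pooled: bool = False,
) -> pd.Series:
    """Per-feature method-of-moments NB dispersion on normalized counts.

    With condition labels, the residual variance is pooled within
    conditions so that a true expression difference between groups does
    not inflate the dispersion.  Features whose variance does not exceed
    their mean (Poisson-like or constant) get the floor.  Each condition
    needs >= 2 samples; with fewer replicates, pass ``pooled=True`` to
    fall back to a blind (condition-ignorant) estimate.
    """
    q = counts.to_numpy(dtype=float) / factors.reindex(counts.columns).to_numpy()

    if condition_labels is not None and not pooled:
        labels = pd.Series(condition_labels).reindex(counts.columns)
        groups = [np.flatnonzero(labels.to_numpy() == g) for g in labels.unique()]
        sizes = np.array([len(g) for g in groups])
        if (sizes < 2).any():
            raise ValueError(
                "each condition needs >= 2 samples for moment estimation; "
                "use pooled=True for a blind estimate"
            )
        nt = sizes.sum()
        resid_ss = np.zeros(q.shape[0])
        mean_acc = np.zeros(q.shape[0])
        msq_acc = np.zeros(q.shape[0])
        for idx in groups:
            sub = q[:, idx]
            m = sub.mean(axis=1)
            resid_ss += ((sub - m[:, None]) ** 2).sum(axis=1)
            mean_acc += len(idx) * m
            msq_acc += len(idx) * m**2
        var = resid_ss / (nt - len(groups))
        mean = mean_acc / nt
        msq = msq_acc / nt
    else:
        mean = q.mean(axis=1)
        var = q.var(axis=1, ddof=1)
        msq = mean**2

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mean) / msq
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    alpha = np.maximum(alpha, floor)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def nb_wald_test(
    counts: pd.DataFrame,
    factors: pd.Series,
    dispersions: pd.Series,
    condition_labels: pd.Series | Mapping[str, str],
    control: str = "control",
) -> pd.DataFrame:
    """Per-feature NB GLM Wald test of treated vs control.

    The model is ``count ~ 1 + condition`` with a log link and
    log(size factor) offset; log2FC is the condition coefficient divided
    by ln 2, oriented so that positive means higher in the treated group.
    The Wald statistic coef/se is referred to a t distribution with
    n_samples - 2 degrees of freedom rather than the normal: with ~10
    replicates per group the estimated dispersion makes the normal
    reference anticonservative.  All-zero features get log2FC 0 and p 1.
    Non-converging fits get p 1 and are flagged in the ``flagged`` column.
    """
    labels = pd.Series(condition_labels).reindex(counts.columns)
    conds = labels.unique()
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {list(conds)}")
    if control not in conds:
        raise ValueError(f"control label {control!r} not among {list(conds)}")
    for c in conds:
        if (labels == c).sum() < 2:
            raise ValueError(f"condition {c!r} has < 2 samples")

    treated_ind = (labels.to_numpy() != control).astype(float)
    design = np.column_stack([np.ones_like(treated_ind), treated_ind])
    offset = np.log(factors.reindex(counts.columns).to_numpy(dtype=float))
    sf = factors.reindex(counts.columns).to_numpy(dtype=float)
    mat = counts.to_numpy(dtype=float)
    disp = dispersions.reindex(counts.index).to_numpy(dtype=float)

    ln2 = np.log(2.0)
    wald_df = max(mat.shape[1] - 2, 1)
    rows = []
    for i, fid in enumerate(counts.index):
        y = mat[i]
        base_mean = float((y / sf).mean())
        if y.sum() == 0:
            rows.append((fid, base_mean, 0.0, 1.0, False))
            continue
        fam = sm.families.NegativeBinomial(alpha=max(disp[i], DISPERSION_FLOOR))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, design, family=fam, offset=offset).fit(maxiter=100)
            coef = float(res.params[1])
            se = float(res.bse[1])
            if not res.converged or not np.isfinite(coef) or not np.isfinite(se) or se == 0:
                raise RuntimeError("IRLS did not converge")
            p = float(2.0 * stats.t.sf(abs(coef) / se, df=wald_df))
            rows.append((fid, base_mean, coef / ln2, p, False))
        except Exception as exc:  # pragma: no cover - rare numeric failures
            logger.warning("feature %s: NB fit failed (%s); p set to 1", fid, exc)
            rows.append((fid, base_mean, 0.0, 1.0, True))
    return pd.DataFrame(
        rows, columns=["feature_id", "base_mean", "log2fc", "p_value", "flagged"]
    ).set_index("feature_id", drop=False)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    records: pd.DataFrame,
    lfc_threshold: float = LFC_THRESHOLD_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Attach UP/DOWN/NS calls; |log2FC| >= threshold and p_adj <= alpha,
    both boundaries inclusive."""
    out = records.copy()
    sig = out["p_adj"] <= alpha
    out["call"] = "NS"
    out.loc[sig & (out["log2fc"] >= lfc_threshold), "call"] = "UP"
    out.loc[sig & (out["log2fc"] <= -lfc_threshold), "call"] = "DOWN"
    return out


def run_de(
    counts: pd.DataFrame,
    condition_labels: pd.Series | Mapping[str, str],
    control: str = "control",
    lfc_threshold: float = LFC_THRESHOLD_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    pooled_dispersion: bool = False,
) -> pd.DataFrame:
    """Full DE stage: size factors, dispersions, Wald tests, BH, calls."""
    sf = size_factors(counts)
    disp = estimate_dispersion(
        counts, sf, condition_labels=condition_labels, pooled=pooled_dispersion
    )
    res = nb_wald_test(counts, sf, disp, condition_labels, control=control)
    res["p_adj"] = bh_adjust(res["p_value"].to_numpy())
    return call_de(res, lfc_threshold=lfc_threshold, alpha=alpha)
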