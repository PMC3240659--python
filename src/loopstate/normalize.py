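"""Intensity-dependent normalization of log ratios within print-tip groups.

Spots printed by the same pin (one block) share location- and pin-specific
bias, so the M-vs-A trend is estimated and subtracted per (slide, block)
group: M' = M − ĉ(A), with ĉ a robust lowess fit of M on A.  Groups too
small for curve fitting fall back to median centring.  A is never changed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

RATIO_COLUMNS = ["gene_id", "slide_id", "block", "replicate", "A", "M"]


def compute_ma(spots: pd.DataFrame) -> pd.DataFrame:
    """Background-corrected M/A values for each spot.

    M = log2(Cy5 corrected) − log2(Cy3 corrected), A = their mean, with
    Cy5 = f635 − b635 and Cy3 = f532 − b532.  Spots with a non-positive
    corrected intensity in either channel cannot be log-transformed and are
    dropped with a logged count.
    """
    cy5 = spots["f635_mean"].to_numpy(float) - spots["b635_mean"].to_numpy(float)
    cy3 = spots["f532_mean"].to_numpy(float) - spots["b532_mean"].to_numpy(float)
    ok = (cy5 > 0) & (cy3 > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("compute_ma: dropped %d spots with non-positive corrected intensity",
                    n_dropped)
    l5 = np.log2(cy5[ok])
    l3 = np.log2(cy3[ok])
    out = pd.DataFrame(
        {
            "gene_id": spots.loc[ok, "gene_id"].to_numpy(),
            "slide_id": spots.loc[ok, "slide_id"].to_numpy(),
            "block": spots.loc[ok, "block"].to_numpy(),
            "replicate": spots.loc[ok, "replicate"].to_numpy(),
            "A": (l5 + l3) / 2.0,
            "M": l5 - l3,
        }
    )
    return out


def _normalize_group(a: np.ndarray, m: np.ndarray, span: float, iterations: int,
                     min_group: int) -> np.ndarray:
    if len(m) < min_group:
        return m - np.median(m)
    if np.ptp(a) == 0:  # no intensity spread: trend degenerates to a constant
        return m - np.mean(m)
    trend = lowess(m, a, frac=span, it=iterations, return_sorted=False)
    return m - trend


def normalize_within_print_tip(
    ratios: pd.DataFrame,
    span: float = 0.4,
    iterations: int = 3,
    min_group: int = 20,
) -> pd.DataFrame:
    """Add an ``M_normalized`` column: M minus the per-(slide, block) trend.

    ``span`` is the lowess smoothing fraction, ``iterations`` the number of
    robustness reweighting passes.  Groups with fewer than ``min_group``
    spots are centred on their median instead of curve-fitted.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    out = ratios.copy()
    out["M_normalized"] = np.nan
    for (slide, block), idx in out.groupby(["slide_id", "block"]).groups.items():
        sub = out.loc[idx]
        if len(sub) == 0:  # pragma: no cover - groupby never yields empty groups
            logger.warning("empty group slide=%s block=%s skipped", slide, block)
            continue
        out.loc[idx, "M_normalized"] = _normalize_group(
            sub["A"].to_numpy(float), sub["M"].to_numpy(float),
            span, iterations, min_group,
        )
    return out


class PrintTipLowessNormalizer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer for within-print-tip lowess normalization."""

    def __init__(self, span: float = 0.4, iterations: int = 3, min_group: int = 20):
        self.span = span
        self.iterations = iterations
        self.min_group = min_group

    def fit(self, X: pd.DataFrame, y=None) -> "PrintTipLowessNormalizer":
        missing = {"slide_id", "block", "A", "M"} - set(X.columns)
        if missing:
            raise ValueError(f"ratio table missing columns: {sorted(missing)}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return normalize_within_print_tip(
            X, span=self.span, iterations=self.iterations, min_group=self.min_group
        )
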