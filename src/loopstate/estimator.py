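"""Per-gene log-linear estimation of UV-vs-control contrasts from a loop design.

For one gene, the normalized log ratio of each non-mock slide k obeys

    m_k = gamma + lambda(head_k) - lambda(tail_k) + eps_k,

with one dye-bias term ``gamma`` shared across the arrays, a relative log2
level ``lambda`` per sample, and iid residual error.  Replicate spots on a
slide are averaged first, so the response is slide-level.  The levels are
identifiable only up to a constant; lambda(C1) = 0 is pinned, which is
immaterial because only the contrasts x_i = lambda(UVi) - lambda(Ci) are
reported.

Each contrast is estimable iff its defining lambda combination lies in the
row space of the gene's design matrix — combinatorially, iff Ci and UVi are
connected through the gene's available slides *and* the dye-bias term is not
confounded along the way.  A gene with any non-estimable contrast is
*singular* and excluded from downstream pattern fitting.  Ordinary least
squares (minimum-norm via SVD) supplies estimates, standard errors, and the
residual SD.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .design import ALL_SAMPLES, LoopDesign, ROLE_MOCK, default_loop_design

PROFILE_COLUMNS = (
    ["gene_id"]
    + [f"x{i}" for i in range(1, 7)]
    + [f"se{i}" for i in range(1, 7)]
    + [f"est{i}" for i in range(1, 7)]
    + ["gamma_hat", "sigma_hat", "n_slides", "singular"]
)

_RANK_TOL = 1e-9


def _parameter_index(samples: tuple[str, ...] = ALL_SAMPLES) -> dict[str, int]:
    """Column index of each free parameter: gamma first, lambdas except C1."""
    index = {"gamma": 0}
    col = 1
    for s in samples:
        if s == "C1":
            continue
        index[s] = col
        col += 1
    return index


def build_gene_system(
    gene_ratios: pd.DataFrame,
    design: LoopDesign,
    m_col: str = "m",
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Design matrix and response for one gene's available non-mock slides.

    ``gene_ratios`` holds one row per slide with columns ``slide_id`` and
    ``m_col``.  Returns (X, y, parameter index); X has a leading gamma
    column and one signed-incidence column per free lambda.
    """
    pidx = _parameter_index(tuple(design.samples))
    non_mock = {s.slide_id: s for s in design if s.role != ROLE_MOCK}
    rows, y = [], []
    for rec in gene_ratios.itertuples():
        slide = non_mock.get(int(rec.slide_id))
        if slide is None:  # mock or unknown slide: not part of the estimation
            continue
        row = np.zeros(len(pidx))
        row[0] = 1.0  # gamma
        if slide.cy5 != "C1":
            row[pidx[slide.cy5]] += 1.0
        if slide.cy3 != "C1":
            row[pidx[slide.cy3]] -= 1.0
        rows.append(row)
        y.append(float(getattr(rec, m_col)))
    if not rows:
        return np.zeros((0, len(pidx))), np.zeros(0), pidx
    return np.asarray(rows), np.asarray(y), pidx


def _contrast_vector(i: int, pidx: dict[str, int]) -> np.ndarray | None:
    """x_i = lambda(UVi) - lambda(Ci), with the pinned lambda(C1) = 0.

    None when the design carries no parameter for a needed sample (the
    contrast is then trivially non-estimable).
    """
    if f"UV{i}" not in pidx or (i != 1 and f"C{i}" not in pidx):
        return None
    c = np.zeros(len(pidx))
    c[pidx[f"UV{i}"]] = 1.0
    if i != 1:
        c[pidx[f"C{i}"]] -= 1.0
    return c


def estimate_profile(
    X: np.ndarray, y: np.ndarray, pidx: dict[str, int]
) -> dict:
    """OLS solution of one gene's system with estimability flags.

    Returns a dict with x1..x6, se1..se6, est1..est6, gamma_hat, sigma_hat,
    n_slides, singular.  Non-estimable quantities are NaN, never imputed;
    sigma and standard errors are NaN when the residual degrees of freedom
    are zero.
    """
    out: dict[str, float | bool | int] = {"n_slides": int(X.shape[0])}
    if X.shape[0] == 0:
        for i in range(1, 7):
            out[f"x{i}"] = np.nan
            out[f"se{i}"] = np.nan
            out[f"est{i}"] = False
        out.update(gamma_hat=np.nan, sigma_hat=np.nan, singular=True)
        return out

    u, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    tol = max(tol, _RANK_TOL)
    keep = s > tol
    rank = int(keep.sum())
    vr = vt[keep]            # orthonormal basis of the row space
    s_r = s[keep]
    # minimum-norm least squares
    beta = vr.T @ ((u[:, keep].T @ y) / s_r)
    resid = y - X @ beta
    dof = X.shape[0] - rank
    rss = float(resid @ resid)
    sigma_hat = np.sqrt(rss / dof) if dof > 0 else np.nan
    out["sigma_hat"] = sigma_hat

    def estimable(c: np.ndarray) -> bool:
        proj = vr.T @ (vr @ c)
        return bool(np.linalg.norm(c - proj) <= 1e-8 * max(1.0, np.linalg.norm(c)))

    singular = False
    for i in range(1, 7):
        c = _contrast_vector(i, pidx)
        if c is not None and estimable(c):
            out[f"x{i}"] = float(c @ beta)
            var_unit = float(np.sum(((vr @ c) / s_r) ** 2))
            out[f"se{i}"] = float(sigma_hat * np.sqrt(var_unit)) if dof > 0 else np.nan
            out[f"est{i}"] = True
        else:
            out[f"x{i}"] = np.nan
            out[f"se{i}"] = np.nan
            out[f"est{i}"] = False
            singular = True
    c_gamma = np.zeros(len(pidx))
    c_gamma[0] = 1.0
    out["gamma_hat"] = float(beta[0]) if estimable(c_gamma) else np.nan
    out["singular"] = singular
    return out


def aggregate_replicates(
    ratios: pd.DataFrame, m_col: str = "M_normalized"
) -> pd.DataFrame:
    """Average replicate spots to one response per gene x slide."""
    grouped = (
        ratios.groupby(["gene_id", "slide_id"], sort=True)[m_col]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "m", "size": "n_spots"})
    )
    return grouped


def estimate_profiles(
    ratios: pd.DataFrame,
    design: LoopDesign | None = None,
    m_col: str | None = None,
) -> pd.DataFrame:
    """Fit the loop model for every gene in a normalized ratio table.

    ``m_col`` defaults to ``M_normalized`` when present, else ``M``; a
    pre-aggregated table with an ``m`` column is used as-is.
    """
    design = design or default_loop_design()
    if m_col is None:
        m_col = "M_normalized" if "M_normalized" in ratios.columns else "M"
    if "m" in ratios.columns and "replicate" not in ratios.columns:
        slide_level = ratios
    else:
        slide_level = aggregate_replicates(ratios, m_col=m_col)
    rows = []
    for gene_id, sub in slide_level.groupby("gene_id", sort=True):
        X, y, pidx = build_gene_system(sub, design, m_col="m")
        rec = estimate_profile(X, y, pidx)
        rec["gene_id"] = gene_id
        rows.append(rec)
    profiles = pd.DataFrame(rows)
    return profiles[PROFILE_COLUMNS]


def count_nonsingular(profiles: pd.DataFrame) -> int:
    """Number of genes whose six contrasts are all estimable."""
    return int((~profiles["singular"].astype(bool)).sum())


def write_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_profiles(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")


class LoopContrastEstimator(BaseEstimator):
    """sklearn-style estimator for per-gene loop-design contrast profiles.

    Parameters
    ----------
    design:
        The hybridization design; defaults to the seventeen-slide loop.
    m_col:
        Response column in the ratio table (default: ``M_normalized`` when
        present, else ``M``).

    Attributes (after ``fit``)
    --------------------------
    profiles_:
        One row per gene: contrasts x1..x6, standard errors, estimability
        flags, dye-bias and residual-SD estimates, and the singular flag.
    n_nonsingular_:
        Number of genes with all six contrasts estimable.
    """

    def __init__(self, design: LoopDesign | None = None, m_col: str | None = None):
        self.design = design
        self.m_col = m_col

    def fit(self, X: pd.DataFrame, y=None) -> "LoopContrastEstimator":
        self.profiles_ = estimate_profiles(X, design=self.design, m_col=self.m_col)
        self.n_nonsingular_ = count_nonsingular(self.profiles_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit(X)
        return self.profiles_
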