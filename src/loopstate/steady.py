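"""Template-correlation detection of perturbation-then-relaxation responses.

A gene that responds immediately to each repeated perturbation and relaxes
before the next one has an expression profile resembling the alternating
ideal pattern v = (r, s, r, s, r, s): level r at the three post-dose time
points (T1, T3, T5) and level s at the three pre-dose points (T2, T4, T6).
The statistic is the Pearson correlation R between a gene's six-point
contrast profile x and v.  Because v takes only two values, R reduces in
closed form to

    R = sign(r - s) * (mean(x at T1,T3,T5) - mean(x at T2,T4,T6)) / (2 * SD_pop(x)),

with the population (n-denominator) SD.  |R| measures similarity to the
steady-state template regardless of the particular (r, s).

Under a null of exchangeable profile entries (or iid Gaussian entries), R
for a length-n profile has density proportional to (1 - r^2)^((n-4)/2) on
[-1, 1]; for n = 6 this is f(r) = 0.75 (1 - r^2).  Both a Monte-Carlo null
(Gaussian or per-profile permutation) and the analytic family are provided.

Classification: genes first pass a variability filter (sample SD of the six
contrasts strictly above ``sd_min``, default 0.21); then R strictly above
``r_threshold`` (default 0.75) labels the gene "up" (response then
relaxation), R strictly below the negative threshold labels it "down", and
anything else "none".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

X_COLUMNS = [f"x{i}" for i in range(1, 7)]
_ODD = np.arange(0, 6, 2)   # T1, T3, T5 (response points)
_EVEN = np.arange(1, 6, 2)  # T2, T4, T6 (relaxed points)


def ideal_pattern(r: float = 1.0, s: float = 0.0, n: int = 6) -> np.ndarray:
    """The alternating template (r, s, r, s, ...) of length n."""
    if r == s:
        raise ValueError("pattern levels r and s must differ")
    v = np.empty(n)
    v[0::2] = r
    v[1::2] = s
    return v


def profile_sd(x, ddof: int = 1) -> float:
    """Variability of a profile across its time points (sample SD by default).

    Returns NaN when any entry is missing; such genes are excluded from
    scoring rather than rescored on a shorter pattern.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or not np.all(np.isfinite(x)):
        return float("nan")
    return float(np.std(x, ddof=ddof))


def steady_state_r(x, r: float = 1.0, s: float = 0.0) -> float:
    """Closed-form correlation of a complete 6-point profile with (r,s,r,s,r,s).

    Undefined (NaN) for zero-variance or incomplete profiles.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (6,):
        raise ValueError("steady_state_r expects a complete 6-point profile")
    if not np.all(np.isfinite(x)):
        return float("nan")
    sd = np.std(x)  # population SD: keeps the ratio exactly the Pearson R
    if sd == 0:
        return float("nan")
    raw = (x[_ODD].mean() - x[_EVEN].mean()) / (2.0 * sd)
    return float(np.sign(r - s) * raw)


def steady_state_r_brute(x, r: float = 1.0, s: float = 0.0) -> float:
    """Direct Pearson correlation against the template (reference route)."""
    x = np.asarray(x, dtype=float)
    v = ideal_pattern(r, s, len(x))
    if np.std(x) == 0:
        return float("nan")
    return float(np.corrcoef(x, v)[0, 1])


def _r_many(xs: np.ndarray) -> np.ndarray:
    """Vectorized closed-form R for an (n_profiles, 6) array."""
    sd = xs.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xs[:, _ODD].mean(axis=1) - xs[:, _EVEN].mean(axis=1)) / (2.0 * sd)
    return np.where(sd > 0, r, np.nan)


def analytic_null_density(r, n: int = 6):
    """Null density of R for a length-n profile: (1-r^2)^((n-4)/2) / B(1/2, (n-2)/2).

    The n = 6 member is f(r) = 0.75 (1 - r^2).  Domain error outside [-1, 1].
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("R is only defined on [-1, 1]")
    if n < 3:
        raise ValueError("profile length must be at least 3")
    norm = special.beta(0.5, (n - 2) / 2.0)
    with np.errstate(divide="ignore"):
        dens = (1.0 - r**2) ** ((n - 4) / 2.0) / norm
    return dens if dens.ndim else float(dens)


def analytic_null_cdf(r, n: int = 6):
    """CDF of the analytic null via the regularized incomplete beta function."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("R is only defined on [-1, 1]")
    half_tail = special.betainc(0.5, (n - 2) / 2.0, r**2)
    cdf = 0.5 * (1.0 + np.sign(r) * half_tail)
    return cdf if cdf.ndim else float(cdf)


def analytic_tail_probability(threshold: float, n: int = 6) -> float:
    """P(|R| > threshold) under the analytic null."""
    return float(1.0 - (analytic_null_cdf(threshold, n) - analytic_null_cdf(-threshold, n)))


@dataclass
class NullModel:
    """Monte-Carlo null distribution of the template correlation."""

    draws: np.ndarray
    seed: int | None
    mode: str

    @property
    def n_draws(self) -> int:
        return int(self.draws.size)

    def density_at(self, r: float, halfwidth: float = 0.025) -> float:
        """Empirical density via a symmetric counting window around r."""
        lo, hi = max(r - halfwidth, -1.0), min(r + halfwidth, 1.0)
        frac = np.mean((self.draws >= lo) & (self.draws <= hi))
        return float(frac / (hi - lo))

    def tail_probability(self, threshold: float) -> float:
        return float(np.mean(np.abs(self.draws) > threshold))

    def ks_distance(self, n: int = 6) -> float:
        """Kolmogorov-Smirnov distance to the analytic null CDF."""
        x = np.sort(self.draws)
        cdf = analytic_null_cdf(x, n=n)
        k = np.arange(1, x.size + 1)
        d_plus = np.max(k / x.size - cdf)
        d_minus = np.max(cdf - (k - 1) / x.size)
        return float(max(d_plus, d_minus))

    def summary(self) -> dict:
        return {
            "n_draws": self.n_draws,
            "seed": self.seed,
            "mode": self.mode,
            "density_at_zero": self.density_at(0.0),
            "ks_distance_vs_analytic": self.ks_distance(),
            "tail_prob_gt_0.75": self.tail_probability(0.75),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def simulate_null(
    n_draws: int = 1_000_000,
    seed: int | None = None,
    mode: str = "normal",
    profile=None,
    n_points: int = 6,
    batch: int = 500_000,
) -> NullModel:
    """Monte-Carlo null draws of R.

    ``mode="normal"`` scores profiles of iid standard-normal entries;
    ``mode="permutation"`` permutes the entries of a supplied profile
    uniformly at random.  Both are exchangeable nulls and share the
    analytic limiting density.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    rng = np.random.default_rng(seed)
    if mode == "normal":
        chunks = []
        remaining = n_draws
        while remaining > 0:
            m = min(batch, remaining)
            xs = rng.standard_normal((m, n_points))
            if n_points == 6:
                chunks.append(_r_many(xs))
            else:
                v = ideal_pattern(1.0, 0.0, n_points)
                vc = v - v.mean()
                xc = xs - xs.mean(axis=1, keepdims=True)
                denom = np.linalg.norm(xc, axis=1) * np.linalg.norm(vc)
                chunks.append((xc @ vc) / denom)
            remaining -= m
        draws = np.concatenate(chunks)
    elif mode == "permutation":
        if profile is None:
            raise ValueError("permutation mode needs a profile to permute")
        x = np.asarray(profile, dtype=float)
        if np.std(x) == 0:
            raise ValueError("cannot permute a zero-variance profile")
        order = np.argsort(rng.random((n_draws, x.size)), axis=1)
        draws = _r_many(x[order]) if x.size == 6 else None
        if draws is None:
            raise ValueError("permutation mode supports 6-point profiles")
    else:
        raise ValueError("mode must be 'normal' or 'permutation'")
    draws = draws[np.isfinite(draws)]
    return NullModel(draws=draws, seed=seed, mode=mode)


CALL_COLUMNS = ["gene_id", "sd", "R", "passed_sd_filter", "label", "reason"]


def classify_profiles(
    profiles: pd.DataFrame,
    sd_min: float = 0.21,
    r_threshold: float = 0.75,
    sd_ddof: int = 1,
    pattern_r: float = 1.0,
    pattern_s: float = 0.0,
) -> pd.DataFrame:
    """Steady-state calls for a table of contrast profiles.

    Singular or incomplete profiles are skipped (label "none", reason
    recorded).  All thresholds are strict: SD must exceed ``sd_min`` and
    R must exceed ``r_threshold`` in magnitude.
    """
    rows = []
    for rec in profiles.itertuples():
        x = np.array([getattr(rec, c) for c in X_COLUMNS], dtype=float)
        singular = bool(getattr(rec, "singular", False))
        entry = {"gene_id": rec.gene_id, "sd": np.nan, "R": np.nan,
                 "passed_sd_filter": False, "label": "none", "reason": ""}
        if singular or not np.all(np.isfinite(x)):
            entry["reason"] = "singular" if singular else "incomplete"
            rows.append(entry)
            continue
        sd = profile_sd(x, ddof=sd_ddof)
        entry["sd"] = sd
        if not sd > sd_min:
            entry["reason"] = "sd_filter"
            rows.append(entry)
            continue
        entry["passed_sd_filter"] = True
        r = steady_state_r(x, r=pattern_r, s=pattern_s)
        entry["R"] = r
        if np.isnan(r):
            entry["reason"] = "zero_variance"
        elif r > r_threshold:
            entry["label"] = "up"
        elif r < -r_threshold:
            entry["label"] = "down"
        rows.append(entry)
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


class DirectionalConsistency(NamedTuple):
    n_directional: int
    n_total: int
    fraction: float  # NaN for an empty set
    n_zero: int


def directional_consistency(values, direction: str = "up") -> DirectionalConsistency:
    """Count profile entries moving in one direction across a gene set.

    ``values`` is a 2D array / DataFrame of profile entries on any time
    grid; missing entries are excluded from the total, exact zeros count as
    neither direction and are tallied separately.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    arr = np.asarray(
        values if not isinstance(values, pd.DataFrame) else values.to_numpy(),
        dtype=float,
    )
    finite = np.isfinite(arr)
    n_total = int(finite.sum())
    if n_total == 0:
        return DirectionalConsistency(0, 0, float("nan"), 0)
    signs = np.sign(arr[finite])
    n_dir = int(np.sum(signs > 0)) if direction == "up" else int(np.sum(signs < 0))
    n_zero = int(np.sum(signs == 0))
    return DirectionalConsistency(n_dir, n_total, n_dir / n_total, n_zero)


def crossplatform_correlation(x_a, x_b) -> float:
    """Pearson correlation between paired measurements from two platforms.

    Utility for validating array-derived fold changes against an external
    assay.  Requires at least 3 pairs; degenerate variance gives NaN.
    """
    a = np.asarray(x_a, dtype=float)
    b = np.asarray(x_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1D vectors")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


class SteadyStateClassifier(BaseEstimator):
    """sklearn-style classifier of steady-state (response-relaxation) genes.

    ``fit`` calibrates the Monte-Carlo null (stored as ``null_model_``)
    against the analytic density; ``predict`` returns the per-gene label
    array and stores the full call table as ``calls_``.
    """

    def __init__(
        self,
        sd_min: float = 0.21,
        r_threshold: float = 0.75,
        sd_ddof: int = 1,
        null_draws: int = 100_000,
        null_mode: str = "normal",
        random_state: int | None = None,
    ):
        self.sd_min = sd_min
        self.r_threshold = r_threshold
        self.sd_ddof = sd_ddof
        self.null_draws = null_draws
        self.null_mode = null_mode
        self.random_state = random_state

    def fit(self, X=None, y=None) -> "SteadyStateClassifier":
        if self.null_draws:
            self.null_model_ = simulate_null(
                n_draws=self.null_draws, seed=self.random_state, mode="normal"
            )
        else:
            self.null_model_ = None
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        self.calls_ = classify_profiles(
            X, sd_min=self.sd_min, r_threshold=self.r_threshold, sd_ddof=self.sd_ddof
        )
        return self.calls_["label"].to_numpy()


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA", keep_default_na=True)
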