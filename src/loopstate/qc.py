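"""Spot quality control for two-color arrays.

A spot is valid when all three criteria hold, with strict inequalities:

1. SNR, defined as (foreground − background) / SD(background), greater than
   ``snr_min`` (default 5) in *both* channels;
2. spot diameter greater than ``diameter_min`` µm (default 75);
3. pixel coefficient of variation less than ``cv_max`` (default 1.0, i.e.
   100%) in both channels.

Spots with zero background SD have an undefined SNR; by default they are
flagged invalid with a dedicated flag, but the clean synthetic case
(foreground above background, zero background noise) can be treated as
infinite SNR via ``zero_bsd_policy="infinite"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

FLAG_COLUMNS = ["snr_pass", "diameter_pass", "cv_pass", "bsd_zero", "valid"]


@dataclass
class FilterReport:
    """Survival statistics of one filtering pass.

    ``fraction_valid`` is None (reported missing, not zero) for empty input.
    Per-criterion failure counts are tallied independently; a spot may fail
    several criteria at once.
    """

    n_total: int
    n_valid: int
    n_fail_snr: int
    n_fail_diameter: int
    n_fail_cv: int
    n_bsd_zero: int

    @property
    def fraction_valid(self) -> float | None:
        if self.n_total == 0:
            return None
        return self.n_valid / self.n_total

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fraction_valid"] = self.fraction_valid
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def validate_spots(
    spots: pd.DataFrame,
    snr_min: float = 5.0,
    diameter_min: float = 75.0,
    cv_max: float = 1.0,
    zero_bsd_policy: str = "invalid",
) -> pd.DataFrame:
    """Per-spot pass/fail flags for the three validity criteria.

    Returns a DataFrame aligned with ``spots`` holding boolean columns
    ``snr_pass``, ``diameter_pass``, ``cv_pass``, ``bsd_zero`` and the
    conjunction ``valid``.
    """
    if zero_bsd_policy not in ("invalid", "infinite"):
        raise ValueError("zero_bsd_policy must be 'invalid' or 'infinite'")

    sig5 = spots["f635_mean"].to_numpy(float) - spots["b635_mean"].to_numpy(float)
    sig3 = spots["f532_mean"].to_numpy(float) - spots["b532_mean"].to_numpy(float)
    sd5 = spots["b635_sd"].to_numpy(float)
    sd3 = spots["b532_sd"].to_numpy(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        snr5 = np.where(sd5 > 0, sig5 / np.where(sd5 > 0, sd5, 1.0), np.nan)
        snr3 = np.where(sd3 > 0, sig3 / np.where(sd3 > 0, sd3, 1.0), np.nan)

    bsd_zero = (sd5 == 0) | (sd3 == 0)
    snr_pass = (snr5 > snr_min) & (snr3 > snr_min)
    if zero_bsd_policy == "infinite":
        ok5 = np.where(sd5 == 0, sig5 > 0, snr5 > snr_min)
        ok3 = np.where(sd3 == 0, sig3 > 0, snr3 > snr_min)
        snr_pass = ok5 & ok3
    else:
        snr_pass = np.where(bsd_zero, False, snr_pass)

    diameter_pass = spots["diameter_um"].to_numpy(float) > diameter_min
    cv_pass = (spots["cv635"].to_numpy(float) < cv_max) & (
        spots["cv532"].to_numpy(float) < cv_max
    )
    flags = pd.DataFrame(
        {
            "snr_pass": snr_pass,
            "diameter_pass": diameter_pass,
            "cv_pass": cv_pass,
            "bsd_zero": bsd_zero,
        },
        index=spots.index,
    )
    flags["valid"] = flags["snr_pass"] & flags["diameter_pass"] & flags["cv_pass"]
    return flags


def filter_table(
    spots: pd.DataFrame,
    snr_min: float = 5.0,
    diameter_min: float = 75.0,
    cv_max: float = 1.0,
    zero_bsd_policy: str = "invalid",
) -> tuple[pd.DataFrame, FilterReport]:
    """Split a spot table into its valid subset plus a survival report."""
    flags = validate_spots(spots, snr_min, diameter_min, cv_max, zero_bsd_policy)
    report = FilterReport(
        n_total=int(len(spots)),
        n_valid=int(flags["valid"].sum()),
        n_fail_snr=int((~flags["snr_pass"]).sum()),
        n_fail_diameter=int((~flags["diameter_pass"]).sum()),
        n_fail_cv=int((~flags["cv_pass"]).sum()),
        n_bsd_zero=int(flags["bsd_zero"].sum()),
    )
    return spots.loc[flags["valid"]].copy(), report


class SpotQualityFilter(BaseEstimator, TransformerMixin):
    """sklearn-style transformer applying the three spot-validity criteria.

    ``transform`` returns the valid subset of a spot table; the survival
    report of the latest transform is available as ``report_``.
    """

    def __init__(
        self,
        snr_min: float = 5.0,
        diameter_min: float = 75.0,
        cv_max: float = 1.0,
        zero_bsd_policy: str = "invalid",
    ):
        self.snr_min = snr_min
        self.diameter_min = diameter_min
        self.cv_max = cv_max
        self.zero_bsd_policy = zero_bsd_policy

    def fit(self, X: pd.DataFrame, y=None) -> "SpotQualityFilter":
        missing = {"f635_mean", "b635_mean", "b635_sd", "cv635",
                   "f532_mean", "b532_mean", "b532_sd", "cv532",
                   "diameter_um"} - set(X.columns)
        if missing:
            raise ValueError(f"spot table missing columns: {sorted(missing)}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        valid, report = filter_table(
            X, self.snr_min, self.diameter_min, self.cv_max, self.zero_bsd_policy
        )
        self.report_ = report
        return valid
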