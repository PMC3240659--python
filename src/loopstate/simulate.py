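"""Synthetic spot-level two-color loop-design data with known ground truth.

The measurement model mirrors the log-linear view of a dual-color slide: the
background-corrected log2 ratio of a spot for gene g on slide k is

    M_gk = gamma_g + (lambda_g(cy5 sample) - lambda_g(cy3 sample)) + eps,
    eps ~ Normal(0, sigma_g),

where ``gamma`` is a gene-level dye bias, ``lambda`` the relative log2
expression level of each of the twelve samples, and ``sigma`` the residual
noise scale.  Channel intensities are reconstructed around a per-gene
baseline A so that foreground minus background recovers the intended M and A
exactly; backgrounds are lognormal around a fixed floor.  A configurable
fraction of spots is made defective by violating exactly one of the three
QC criteria (low SNR, small diameter, or high pixel CV), so QC truth labels
are available for testing.

Gene archetypes encode the perturbation-series ground truth as UV-vs-control
contrasts x_i = lambda(UVi) - lambda(Ci):

* ``steady_up``     x = (+a, 0, +a, 0, +a, 0)   response then relaxation
* ``steady_down``   x = (-a, 0, -a, 0, -a, 0)
* ``cumulative_up``   x = a * (1..6)/6          monotone accumulation
* ``cumulative_down`` x = -a * (1..6)/6
* ``flat``          x = 0                       unresponsive

Randomness is reproducible end to end: one top-level seed, with per-gene
substreams spawned from (seed, gene index) so adding genes never perturbs
existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import LoopDesign, default_loop_design

ARCHETYPES = ("steady_up", "steady_down", "cumulative_up", "cumulative_down", "flat")

#: columns of the GPR-like spot table, in writing order
SPOT_COLUMNS = [
    "gene_id", "slide_id", "block", "row", "col", "replicate",
    "f635_mean", "b635_mean", "b635_sd", "cv635",
    "f532_mean", "b532_mean", "b532_sd", "cv532",
    "diameter_um",
]

DEFECT_MODES = ("snr", "diameter", "cv")


class ConfigError(ValueError):
    """Raised when a generator or pipeline configuration is inconsistent."""


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic loop-design generator.

    Defaults emulate a six-time-point repeated-perturbation series measured
    in quadruplicate on seventeen slides.  ``effect_size`` is the log2
    response amplitude ``a`` of the planted archetypes; noise and dye-bias
    scales are drawn per gene from the given ranges.
    """

    n_steady_up: int = 100
    n_steady_down: int = 100
    n_cumulative_up: int = 50
    n_cumulative_down: int = 50
    n_flat: int = 300
    effect_size: float = 0.5
    noise_sd_range: tuple[float, float] = (0.05, 0.15)
    dye_bias_range: tuple[float, float] = (-0.3, 0.3)
    replicate_spots: int = 4
    defective_spot_rate: float = 0.2
    print_tip_blocks: int = 4
    baseline_range: tuple[float, float] = (8.0, 12.0)
    background_level: float = 100.0
    background_sd_frac: float = 0.1
    block_trend_slope: float = 0.0
    block_trend_center: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_steady_up, self.n_steady_down, self.n_cumulative_up,
                  self.n_cumulative_down, self.n_flat)
        if any(c < 0 for c in counts) or sum(counts) == 0:
            raise ConfigError("archetype counts must be non-negative with a positive total")
        if not 0.0 <= self.defective_spot_rate <= 1.0:
            raise ConfigError("defective_spot_rate must be a probability in [0, 1]")
        if self.replicate_spots < 1 or self.print_tip_blocks < 1:
            raise ConfigError("replicate_spots and print_tip_blocks must be positive")
        for name in ("noise_sd_range", "dye_bias_range", "baseline_range"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
                raise ConfigError(f"{name} must be a finite (low, high) pair")
        if self.noise_sd_range[0] < 0:
            raise ConfigError("noise SD must be non-negative")

    @property
    def n_genes(self) -> int:
        return (self.n_steady_up + self.n_steady_down + self.n_cumulative_up
                + self.n_cumulative_down + self.n_flat)


def _archetype_contrasts(archetype: str, a: float) -> np.ndarray:
    t = np.arange(1, 7, dtype=float)
    if archetype == "steady_up":
        return np.where(t % 2 == 1, a, 0.0)
    if archetype == "steady_down":
        return np.where(t % 2 == 1, -a, 0.0)
    if archetype == "cumulative_up":
        return a * t / 6.0
    if archetype == "cumulative_down":
        return -a * t / 6.0
    if archetype == "flat":
        return np.zeros(6)
    raise ConfigError(f"unknown archetype {archetype!r}")


def _gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, gene_index)))


def make_truth(config: GeneratorConfig) -> pd.DataFrame:
    """Draw per-gene ground truth: archetype, lambda levels, gamma, sigma.

    Control samples sit at relative level 0; lambda(UVi) carries the
    archetype's contrast x_i, so x_i = lambda(UVi) - lambda(Ci) exactly.
    """
    rows = []
    plan = (
        ["steady_up"] * config.n_steady_up
        + ["steady_down"] * config.n_steady_down
        + ["cumulative_up"] * config.n_cumulative_up
        + ["cumulative_down"] * config.n_cumulative_down
        + ["flat"] * config.n_flat
    )
    for idx, archetype in enumerate(plan):
        rng = _gene_rng(config.seed, idx)
        gamma = rng.uniform(*config.dye_bias_range)
        sigma = rng.uniform(*config.noise_sd_range)
        baseline = rng.uniform(*config.baseline_range)
        x = _archetype_contrasts(archetype, config.effect_size)
        row = {
            "gene_id": f"G{idx:05d}",
            "archetype": archetype,
            "block": (idx % config.print_tip_blocks) + 1,
            "baseline": baseline,
            "gamma": gamma,
            "sigma": sigma,
        }
        for i in range(6):
            row[f"x{i + 1}"] = x[i]
            row[f"lam_C{i + 1}"] = 0.0
            row[f"lam_UV{i + 1}"] = x[i]
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_slides(
    truth: pd.DataFrame,
    design: LoopDesign | None = None,
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Emit the spot-level table for every gene x slide x replicate spot.

    Returns a DataFrame with the GPR-like ``SPOT_COLUMNS`` plus two hidden
    ground-truth columns, ``is_defective`` and ``defect_mode`` (dropped by
    :func:`write_spot_table`).
    """
    config = config or GeneratorConfig()
    design = design or default_loop_design()

    lam_cols = {s: f"lam_{s}" for s in design.samples}
    for sample, col in lam_cols.items():
        if col not in truth.columns:
            raise ConfigError(
                f"design references sample {sample!r} with no lambda entry in the truth table"
            )

    slides = list(design)
    n_slides = len(slides)
    reps = config.replicate_spots
    frames = []
    for idx, gene in enumerate(truth.itertuples()):
        rng = _gene_rng(config.seed, idx)
        # burn the truth draws so spot noise is decoupled from make_truth order
        rng.uniform(size=3)
        lam = {s: getattr(gene, f"lam_{s}") for s in design.samples}
        a0 = float(gene.baseline)
        trend = config.block_trend_slope * (a0 - config.block_trend_center)

        n_spots = n_slides * reps
        eps = rng.normal(0.0, gene.sigma, size=n_spots)
        delta = np.repeat([lam[s.cy5] - lam[s.cy3] for s in slides], reps)
        m = gene.gamma + delta + eps + trend

        cy5 = np.power(2.0, a0 + m / 2.0)
        cy3 = np.power(2.0, a0 - m / 2.0)
        b5 = config.background_level * rng.lognormal(0.0, 0.2, size=n_spots)
        b3 = config.background_level * rng.lognormal(0.0, 0.2, size=n_spots)
        b5_sd = config.background_sd_frac * b5
        b3_sd = config.background_sd_frac * b3
        f5 = cy5 + b5
        f3 = cy3 + b3
        cv5 = rng.uniform(0.1, 0.4, size=n_spots)
        cv3 = rng.uniform(0.1, 0.4, size=n_spots)
        diameter = rng.uniform(90.0, 110.0, size=n_spots)

        defective = rng.random(n_spots) < config.defective_spot_rate
        mode_idx = rng.integers(0, len(DEFECT_MODES), size=n_spots)
        bad_channel = rng.integers(0, 2, size=n_spots)
        modes = np.where(defective, np.array(DEFECT_MODES)[mode_idx], "")
        for j in np.flatnonzero(defective):
            mode = modes[j]
            if mode == "snr":  # push one channel's signal into the background noise
                if bad_channel[j] == 0:
                    f5[j] = b5[j] + 3.0 * b5_sd[j]
                else:
                    f3[j] = b3[j] + 3.0 * b3_sd[j]
            elif mode == "diameter":
                diameter[j] = 50.0
            else:  # cv
                if bad_channel[j] == 0:
                    cv5[j] = 1.5
                else:
                    cv3[j] = 1.5
        within = idx // config.print_tip_blocks  # position of the gene inside its block
        frames.append(pd.DataFrame({
            "gene_id": gene.gene_id,
            "slide_id": np.repeat([s.slide_id for s in slides], reps),
            "block": int(gene.block),
            "row": within + 1,
            "col": np.tile(np.arange(1, reps + 1), n_slides),
            "replicate": np.tile(np.arange(1, reps + 1), n_slides),
            "f635_mean": f5, "b635_mean": b5, "b635_sd": b5_sd, "cv635": cv5,
            "f532_mean": f3, "b532_mean": b3, "b532_sd": b3_sd, "cv532": cv3,
            "diameter_um": diameter,
            "is_defective": defective,
            "defect_mode": modes,
        }))
    spots = pd.concat(frames, ignore_index=True)
    return spots[SPOT_COLUMNS + ["is_defective", "defect_mode"]]


def generate_dataset(
    config: GeneratorConfig | None = None,
    design: LoopDesign | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, LoopDesign]:
    """Convenience: (spot table, truth table, design) for one configuration."""
    config = config or GeneratorConfig()
    design = design or default_loop_design()
    truth = make_truth(config)
    spots = simulate_slides(truth, design, config)
    return spots, truth, design


def write_spot_table(spots: pd.DataFrame, path: str | Path) -> None:
    spots[SPOT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_spot_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
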