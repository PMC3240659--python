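"""End-to-end orchestration: generate → QC → normalize → estimate → classify.

A single structured YAML config drives the run; every stage writes its
output in a plain-text format (TSV/CSV/JSON, missing values as "NA") and the
run manifest records the config hash, seeds, and the record-count funnel
(spots in/out, genes, non-singular genes, SD-filter survivors, class I/II
counts).  Identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .design import LoopDesign, default_loop_design
from .estimator import count_nonsingular, estimate_profiles, write_profiles
from .normalize import compute_ma, normalize_within_print_tip
from .qc import filter_table
from .simulate import GeneratorConfig, generate_dataset, read_spot_table, write_spot_table, write_truth_table
from .steady import classify_profiles, write_calls

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """All knobs of the pipeline in one serializable object."""

    output_dir: str = "loopstate_run"
    spot_table: str | None = None
    design_sheet: str | None = None
    generator: GeneratorConfig | None = field(default_factory=GeneratorConfig)
    snr_min: float = 5.0
    diameter_min: float = 75.0
    cv_max: float = 1.0
    zero_bsd_policy: str = "invalid"
    lowess_span: float = 0.4
    lowess_iterations: int = 3
    min_group: int = 20
    sd_min: float = 0.21
    r_threshold: float = 0.75
    sd_ddof: int = 1

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = d.get("generator")
        if gen is not None and not isinstance(gen, GeneratorConfig):
            for key in ("noise_sd_range", "dye_bias_range", "baseline_range"):
                if key in gen and gen[key] is not None:
                    gen[key] = tuple(gen[key])
            d["generator"] = GeneratorConfig(**gen)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record counts and provenance of one pipeline run."""

    config_hash: str
    seed: int | None
    version: str
    n_spots_in: int = 0
    n_spots_valid: int = 0
    n_genes: int = 0
    n_nonsingular: int = 0
    n_sd_pass: int = 0
    n_class_up: int = 0
    n_class_down: int = 0

    def funnel_consistent(self) -> bool:
        return (
            self.n_spots_valid <= self.n_spots_in
            and self.n_nonsingular <= self.n_genes
            and self.n_sd_pass <= self.n_nonsingular
            and self.n_class_up + self.n_class_down <= self.n_sd_pass
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def export_class_matrix(calls: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """Signed-profile matrix of the classified genes, grouped by class.

    Up-regulated (class I) genes first, then down-regulated (class II),
    each block in gene-id order; missing entries stay explicit (NA on
    write).  Values are the profile contrasts, passed through unchanged.
    """
    merged = calls.merge(profiles, on="gene_id", how="left")
    x_cols = [f"x{i}" for i in range(1, 7)]
    blocks = []
    for label in ("up", "down"):
        sub = merged.loc[merged["label"] == label, ["gene_id", "label"] + x_cols]
        blocks.append(sub.sort_values("gene_id"))
    out = pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame(
        columns=["gene_id", "label"] + x_cols
    )
    return out


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full chain and write all stage outputs under output_dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.generator.seed if config.generator is not None else None
    manifest = RunManifest(
        config_hash=config.config_hash(), seed=seed, version=__version__
    )

    # --- stage: input -----------------------------------------------------
    try:
        if config.generator is not None:
            spots, truth, design = generate_dataset(config.generator)
            write_spot_table(spots, out / "spots.tsv")
            write_truth_table(truth, out / "truth.tsv")
            design.to_csv(out / "design.csv")
        else:
            if not config.spot_table or not config.design_sheet:
                raise PipelineError(
                    "stage input: need spot_table and design_sheet when no generator is configured"
                )
            spots = read_spot_table(config.spot_table)
            design = LoopDesign.from_csv(config.design_sheet)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError(f"stage input: {exc}") from exc
    manifest.n_spots_in = len(spots)
    logger.info("input: %d spots, %d slides", len(spots), len(design))

    # --- stage: spot filter ----------------------------------------------
    try:
        valid, report = filter_table(
            spots, config.snr_min, config.diameter_min, config.cv_max,
            config.zero_bsd_policy,
        )
        write_spot_table(valid, out / "valid_spots.tsv")
        report.to_json(out / "filter_report.json")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage filter: {exc}") from exc
    manifest.n_spots_valid = report.n_valid
    logger.info("filter: %d/%d spots valid", report.n_valid, report.n_total)

    # --- stage: normalization --------------------------------------------
    try:
        ratios = compute_ma(valid)
        ratios = normalize_within_print_tip(
            ratios, span=config.lowess_span,
            iterations=config.lowess_iterations, min_group=config.min_group,
        )
        ratios.to_csv(out / "ratios.tsv", sep="\t", index=False, na_rep="NA")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage normalize: {exc}") from exc
    logger.info("normalize: %d ratio records", len(ratios))

    # --- stage: loop estimation ------------------------------------------
    try:
        profiles = estimate_profiles(ratios, design=design)
        write_profiles(profiles, out / "profiles.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage estimate: {exc}") from exc
    manifest.n_genes = len(profiles)
    manifest.n_nonsingular = count_nonsingular(profiles)
    logger.info("estimate: %d genes, %d non-singular",
                manifest.n_genes, manifest.n_nonsingular)

    # --- stage: classification -------------------------------------------
    try:
        calls = classify_profiles(
            profiles, sd_min=config.sd_min, r_threshold=config.r_threshold,
            sd_ddof=config.sd_ddof,
        )
        write_calls(calls, out / "calls.tsv")
        matrix = export_class_matrix(calls, profiles)
        matrix.to_csv(out / "class_matrix.tsv", sep="\t", index=False, na_rep="NA")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage classify: {exc}") from exc
    manifest.n_sd_pass = int(calls["passed_sd_filter"].sum())
    manifest.n_class_up = int((calls["label"] == "up").sum())
    manifest.n_class_down = int((calls["label"] == "down").sum())
    logger.info("classify: %d pass SD filter, %d up, %d down",
                manifest.n_sd_pass, manifest.n_class_up, manifest.n_class_down)

    manifest.to_json(out / "manifest.json")
    return manifest
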