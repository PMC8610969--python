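"""Configured, reproducible end-to-end runs: simulate → maps → summarize → compare.

A run is fully described by a :class:`RunConfig` (serialisable to YAML),
so identical config + seed reproduces identical outputs.  A run writes:

* per-lesion parameter maps (optional, NIfTI),
* ``summaries.csv`` — one row per (lesion, parameter, variant) with mean
  and histogram metrics in report units,
* ``roc_mean.csv`` / ``roc_metrics.csv`` — diagnostic tables in the
  published layout (Dir, AUC, CI1, CI2, Cut-off, Sen, Spec, Acc),
* ``compare_extent.csv`` / ``compare_tissue.csv`` / ``compare_metric.csv``
  — the three paired-AUC comparison families,
* ``run_log.json`` — seed, config hash, exclusion counts, stage timings.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from .bvalues import BValueScheme
from .maps import PARAMETERS, SimplifiedIVIM
from .phantom import CohortSpec, generate_cohort
from .roc import compare_modes, roc_table
from .roi import METRICS, summarize_all


class DataError(RuntimeError):
    """Unreadable or inconsistent input data (CLI exit code 2)."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    ``input_dir`` of None selects synthetic mode (the cohort described by
    ``cohort``); otherwise lesions are read from ``<input_dir>/<id>_dwi.*``
    and ``<id>_roi.*`` file pairs.
    """

    out_dir: str = "ivimroi_run"
    seed: int = 0
    input_dir: str | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    metrics: tuple[str, ...] = METRICS
    alpha: float = 0.05
    write_maps: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise ValueError(f"unknown metrics {sorted(unknown)}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.cohort = replace(self.cohort, seed=self.seed)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["cohort"]["scheme"] = [float(b) for b in self.cohort.scheme.values]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        cohort = d.pop("cohort", {})
        if "scheme" in cohort:
            cohort["scheme"] = BValueScheme(*cohort["scheme"])
        if "grid_shape" in cohort:
            cohort["grid_shape"] = tuple(cohort["grid_shape"])
        d["cohort"] = CohortSpec(**cohort)
        if "metrics" in d:
            d["metrics"] = tuple(d["metrics"])
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        d["cohort"]["scheme"] = [float(b) for b in self.cohort.scheme.values]
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _load_real_cohort(input_dir: Path):
    from .io import load_roiset, load_study

    prefixes = sorted(p.name[: -len("_roi.json")] for p in input_dir.glob("*_roi.json"))
    if not prefixes:
        raise DataError(f"no '<id>_roi.json' lesion sidecars found in {input_dir}")
    lesions = []
    for stem in prefixes:
        try:
            study = load_study(input_dir / f"{stem}_dwi")
            roiset = load_roiset(input_dir / f"{stem}_roi")
        except (OSError, ValueError) as exc:
            raise DataError(f"lesion {stem}: {exc}") from exc
        lesions.append((study, roiset, {"lesion": roiset.lesion_id}))
    return lesions


@dataclass
class PipelineResult:
    """Result bundle of one run (tables in memory, files on disk)."""

    summaries: pd.DataFrame
    roc_mean: pd.DataFrame
    roc_metrics: pd.DataFrame
    comparisons: dict[str, pd.DataFrame]
    truth: pd.DataFrame | None
    log: dict
    out_dir: Path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages of a configured run and write the result bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "config_hash": config.config_hash(), "stages": {}}
    t0 = time.perf_counter()

    truth = None
    if config.input_dir is None:
        lesions, truth = generate_cohort(config.cohort)
        truth.to_csv(out_dir / "ground_truth.csv", index=False)
    else:
        lesions = _load_real_cohort(Path(config.input_dir))
    if not lesions:
        raise DataError("empty cohort")
    log["n_lesions"] = len(lesions)
    log["stages"]["cohort"] = round(time.perf_counter() - t0, 3)

    t1 = time.perf_counter()
    frames = []
    exclusions: dict[str, int] = {p: 0 for p in PARAMETERS}
    for study, roiset, _ in lesions:
        maps = SimplifiedIVIM(study).fit()
        if config.write_maps:
            from .io import save_maps

            save_maps(maps, out_dir / "maps", roiset.lesion_id)
        summ = summarize_all(roiset, maps)
        frames.append(summ)
        whole = summ[(summ["extent"] == "3DA") & (summ["tissue"] == "inclCDA")]
        for p in PARAMETERS:
            row = whole[whole["parameter"] == p].iloc[0]
            exclusions[p] += int(row["n_voxels"] - row["n_defined"])
    summaries = pd.concat(frames, ignore_index=True)
    summaries.to_csv(out_dir / "summaries.csv", index=False)
    log["voxels_excluded_per_parameter"] = exclusions
    log["stages"]["maps_and_summaries"] = round(time.perf_counter() - t1, 3)

    t2 = time.perf_counter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        roc_mean = roc_table(summaries, metrics=("mean",), level=0.95)
        roc_metrics = roc_table(summaries, metrics=config.metrics, level=0.95)
        comparisons = compare_modes(summaries, alpha=config.alpha)
    roc_mean.to_csv(out_dir / "roc_mean.csv", index=False)
    roc_metrics.to_csv(out_dir / "roc_metrics.csv", index=False)
    for name, df in comparisons.items():
        df.to_csv(out_dir / f"compare_{name}.csv", index=False)
    log["stages"]["roc_and_comparisons"] = round(time.perf_counter() - t2, 3)
    log["total_seconds"] = round(time.perf_counter() - t0, 3)

    config.to_yaml(out_dir / "config.yaml")
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return PipelineResult(
        summaries=summaries,
        roc_mean=roc_mean,
        roc_metrics=roc_metrics,
        comparisons=comparisons,
        truth=truth,
        log=log,
        out_dir=out_dir,
    )


def render_table3(roc: pd.DataFrame) -> pd.DataFrame:
    """Format a ROC table in the published layout and precision.

    Values arrive in report units (already scaled ×10⁶ / ×10³ by the
    summary stage): group MV/SD rounded to integers, AUC/CI/Sen/Spec/Acc
    to three decimals, cut-offs to one decimal.
    """
    out = pd.DataFrame(
        {
            "ROI": roc["extent"] + "-" + roc["tissue"],
            "Par": roc["parameter"],
            "Metric": roc.get("metric", "mean"),
            "MV_mal": roc["mv_malignant"].round(0).astype(int),
            "SD_mal": roc["sd_malignant"].round(0).astype(int),
            "N_mal": roc["n_malignant"],
            "MV_ben": roc["mv_benign"].round(0).astype(int),
            "SD_ben": roc["sd_benign"].round(0).astype(int),
            "N_ben": roc["n_benign"],
            "Dir": roc["dir"],
            "AUC": roc["auc"].map(lambda x: f"{x:.3f}"),
            "CI1": roc["ci1"].map(lambda x: f"{x:.3f}"),
            "CI2": roc["ci2"].map(lambda x: f"{x:.3f}"),
            "Cut-off": roc["cutoff"].map(lambda x: f"{x:.1f}"),
            "Sen": roc["sen"].map(lambda x: f"{x:.3f}"),
            "Spec": roc["spec"].map(lambda x: f"{x:.3f}"),
            "Acc": roc["acc"].map(lambda x: f"{x:.3f}"),
        }
    )
    return out
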