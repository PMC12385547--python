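"""End-to-end orchestration: simulate -> preprocess -> fit -> extract -> reliability.

A :class:`RunConfig` bundles every stage's parameters; :func:`run_full`
executes the five stages on a simulated cohort, writes CSV/JSON outputs and
returns a :class:`RunManifest` with config hash, per-stage timings,
warnings and checksummed output files.  Re-running with the same config
reproduces byte-identical CSV/JSON data outputs.

:func:`validate_tables` recomputes every derivable cell of a printed
summary table (pooled means, confidence intervals, limits of agreement,
average ICCs) from the printed inputs and reports agreement at three
decimals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _sstats

from . import io as cio
from .phantom import CohortSpec, GMButterfly, MotionModel, PhantomSpec, simulate_cohort
from .preprocess import average_repetitions, correct_stack, crop_to_canal
from .reliability import ReliabilityModel, round_half_away, spearman_brown
from .roi import (
    ROIPlacement,
    adjust_exit_angles,
    extract,
    fit_ellipse,
    place_rois,
    sample_profile,
    segment_cord,
)
from .stack import DWIStack
from .tensor import DiffusionScheme, compute_maps, interpolate_maps

__all__ = ["RunConfig", "RunManifest", "run_full", "process_stack", "validate_tables"]


@dataclass(frozen=True)
class PreprocessConfig:
    crop_half_width: int = 16
    band_width: int = 3
    max_shift: int = 5


@dataclass(frozen=True)
class TensorConfig:
    eigenvalue_floor: float = 0.0
    mask_threshold_fraction: float = 0.10
    target_spacing: float = 0.2
    rd_printed_variant: bool = False


@dataclass(frozen=True)
class ROIConfig:
    profile_fraction: float = 0.72
    placement: ROIPlacement = field(default_factory=ROIPlacement)


@dataclass(frozen=True)
class StatsConfig:
    icc_model: str = "absolute"
    cv_aggregation: str = "mean"
    correction: str = "bonferroni"


@dataclass(frozen=True)
class RunConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    tensor: TensorConfig = field(default_factory=TensorConfig)
    roi: ROIConfig = field(default_factory=ROIConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    write_images: bool = False
    outdir: str = "cordti_run"

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            return obj

        return conv(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(dc_type, data):
            if data is None:
                return dc_type()
            kwargs = {}
            for f in dataclasses.fields(dc_type):
                if f.name not in data:
                    continue
                v = data[f.name]
                sub = {
                    "gm_butterfly": GMButterfly,
                    "motion": MotionModel,
                    "scheme": DiffusionScheme,
                    "placement": ROIPlacement,
                }.get(f.name)
                if sub is not None and isinstance(v, dict):
                    v = build(sub, v)
                elif isinstance(v, list):
                    v = tuple(tuple(e) if isinstance(e, list) else e for e in v)
                kwargs[f.name] = v
            return dc_type(**kwargs)

        seed = int(raw.get("seed", 0))
        phantom_raw = dict(raw.get("phantom") or {})
        cohort_raw = dict(raw.get("cohort") or {})
        phantom_raw.setdefault("seed", seed)
        cohort_raw.setdefault("seed", seed)
        return cls(
            phantom=build(PhantomSpec, phantom_raw),
            cohort=build(CohortSpec, cohort_raw),
            preprocess=build(PreprocessConfig, raw.get("preprocess")),
            tensor=build(TensorConfig, raw.get("tensor")),
            roi=build(ROIConfig, raw.get("roi")),
            stats=build(StatsConfig, raw.get("stats")),
            seed=seed,
            write_images=bool(raw.get("write_images", False)),
            outdir=str(raw.get("outdir", "cordti_run")),
        )


@dataclass
class StageRecord:
    name: str
    seconds: float
    warnings: list[str]
    outputs: list[str]


@dataclass
class RunManifest:
    config_hash: str
    stages: list[StageRecord]
    outputs: dict[str, str]  # path -> sha256

    def to_json(self, path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "stages": [dataclasses.asdict(s) for s in self.stages],
            "outputs": self.outputs,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def process_stack(
    stack: DWIStack,
    scheme: DiffusionScheme,
    pre: PreprocessConfig = PreprocessConfig(),
    ten: TensorConfig = TensorConfig(),
    roi_cfg: ROIConfig = ROIConfig(),
):
    """Preprocess one stack, fit maps and extract tract metrics.

    Returns (tract_metrics, shift_estimates, maps_interp, ellipse).
    """
    cropped = crop_to_canal(stack, "auto", pre.crop_half_width)
    corrected, shifts = correct_stack(cropped, pre.band_width, pre.max_shift)
    averaged = average_repetitions(corrected)
    maps, _field = compute_maps(
        averaged,
        scheme,
        eigenvalue_floor=ten.eigenvalue_floor,
        mask_threshold_fraction=ten.mask_threshold_fraction,
        rd_printed_variant=ten.rd_printed_variant,
    )
    maps_i = interpolate_maps(maps, ten.target_spacing)
    b0 = averaged.mean_b0()
    mask = segment_cord(b0, averaged.spacing)
    # fit geometry at native resolution, sample/extract on the fine grid
    ellipse = fit_ellipse(mask, averaged.spacing)
    prof = sample_profile(maps_i.fa, maps_i.spacing, ellipse, roi_cfg.profile_fraction)
    ellipse = adjust_exit_angles(ellipse, prof)
    rois = place_rois(ellipse, roi_cfg.placement)
    tm = extract(maps_i, rois)
    return tm, shifts, maps_i, ellipse


def run_full(config: RunConfig) -> RunManifest:
    """Execute all five stages and write outputs under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[StageRecord] = []
    outputs: dict[str, str] = {}

    def record(name, t0, warns, paths):
        stages.append(
            StageRecord(
                name=name,
                seconds=round(time.perf_counter() - t0, 3),
                warnings=[str(w.message) for w in warns],
                outputs=[str(p) for p in paths],
            )
        )
        for p in paths:
            outputs[str(p)] = _sha256(Path(p))

    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    cfg_path = outdir / "config.json"

    # 1. simulate ------------------------------------------------------------
    t0 = time.perf_counter()
    with warnings.catch_warnings(record=True) as warns:
        warnings.simplefilter("always")
        cohort = simulate_cohort(config.cohort, config.phantom)
        truth_path = outdir / "truth_table.csv"
        cohort.truth_table().to_csv(truth_path, index=False)
        paths = [cfg_path, truth_path]
        if config.write_images:
            for e in cohort.entries:
                stem = f"sub-{e.participant:02d}_{e.scanner}_ses-{e.session}"
                written = cio.save_stack(
                    e.stack, config.phantom.scheme, outdir / "dwi", stem
                )
                paths.extend(written.values())
    record("simulate", t0, warns, paths)

    # 2-4. preprocess / fit / extract ---------------------------------------
    t0 = time.perf_counter()
    shift_rows, tidy_rows = [], []
    with warnings.catch_warnings(record=True) as warns:
        warnings.simplefilter("always")
        for e in cohort.entries:
            tm, shifts, _maps, _ell = process_stack(
                e.stack,
                config.phantom.scheme,
                config.preprocess,
                config.tensor,
                config.roi,
            )
            for s in shifts:
                shift_rows.append(
                    {
                        "participant": e.participant,
                        "scanner": e.scanner,
                        "session": e.session,
                        "volume": s.volume,
                        "shift_px": s.shift,
                        "score": round(s.score, 6),
                    }
                )
            for region, row in tm.region_means.iterrows():
                for metric in ("fa", "md", "ad", "rd"):
                    tidy_rows.append(
                        {
                            "participant": e.participant,
                            "scanner": e.scanner,
                            "session": e.session,
                            "region": region,
                            "metric": metric,
                            "value": row[metric],
                        }
                    )
        shifts_path = outdir / "shifts.csv"
        pd.DataFrame(shift_rows).to_csv(shifts_path, index=False)
        tidy_path = outdir / "tract_metrics.csv"
        tidy = pd.DataFrame(tidy_rows)
        tidy.to_csv(tidy_path, index=False)
    record("preprocess_fit_extract", t0, warns, [shifts_path, tidy_path])

    # 5. reliability ---------------------------------------------------------
    t0 = time.perf_counter()
    with warnings.catch_warnings(record=True) as warns:
        warnings.simplefilter("always")
        paths = []
        if config.cohort.sessions_per_scanner < 2:
            warnings.warn(
                "fewer than 2 sessions per scanner: reliability stage skipped"
            )
        else:
            results = ReliabilityModel.from_dataframe(tidy).fit(
                icc_model=config.stats.icc_model,
                cv_aggregation=config.stats.cv_aggregation,
                correction=config.stats.correction,
            )
            report_path = outdir / "reliability_report.csv"
            results.to_csv(report_path)
            json_path = outdir / "reliability_full.json"
            results.to_json(json_path)
            paths = [report_path, json_path]
    record("reliability", t0, warns, paths)

    manifest = RunManifest(
        config_hash=config.config_hash(), stages=stages, outputs=outputs
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# printed-table validation
# ---------------------------------------------------------------------------

_REQUIRED_REF_COLS = {
    "scanner", "metric", "region", "n",
    "test_mean", "test_sd", "retest_mean", "retest_sd",
    "diff_mean", "diff_sd",
}


def validate_tables(reference: pd.DataFrame, tol: float = 0.0015) -> pd.DataFrame:
    """Recompute derivable printed cells and compare at three decimals.

    For each reference row the pooled mean, the 95% CIs of the test/retest/
    pooled means and of the mean difference, the 1.96-SD limits of
    agreement, and the average ICC (Spearman-Brown of the printed single
    ICC and its CI) are recomputed from the printed inputs.  Each cell
    yields one output row with the printed value, the recomputed value,
    ``match_3dec`` (equality after half-away rounding to 3 decimals) and
    ``within_tol`` (absolute difference <= ``tol``, which absorbs the
    rounding already present in the printed inputs).  Inconsistent printed
    rows therefore surface as mismatches, not exceptions.
    """
    if len(reference) == 0:
        return pd.DataFrame(
            columns=["scanner", "metric", "region", "cell", "printed",
                     "recomputed", "abs_diff", "match_3dec", "within_tol"]
        )
    missing = _REQUIRED_REF_COLS - set(reference.columns)
    if missing:
        raise ValueError(f"malformed reference table, missing columns: {sorted(missing)}")

    out_rows = []

    def compare(row, cell, recomputed):
        printed = row.get(cell, np.nan)
        if pd.isna(printed) or pd.isna(recomputed):
            return
        diff = abs(float(printed) - float(recomputed))
        out_rows.append(
            {
                "scanner": row["scanner"],
                "metric": row["metric"],
                "region": row["region"],
                "cell": cell,
                "printed": float(printed),
                "recomputed": float(recomputed),
                "abs_diff": diff,
                "match_3dec": round_half_away(recomputed, 3) == float(printed),
                "within_tol": diff <= tol,
            }
        )

    for _, row in reference.iterrows():
        n = int(row["n"])
        tq = _sstats.t.ppf(0.975, n - 1)

        compare(row, "pooled_mean", (row["test_mean"] + row["retest_mean"]) / 2.0)
        for stem in ("test", "retest", "pooled", "diff"):
            m, sd = row.get(f"{stem}_mean"), row.get(f"{stem}_sd")
            if pd.isna(m) or pd.isna(sd):
                continue
            half = tq * sd / np.sqrt(n)
            compare(row, f"{stem}_ci_lo", m - half)
            compare(row, f"{stem}_ci_hi", m + half)
        compare(row, "loa_lo", row["diff_mean"] - 1.96 * row["diff_sd"])
        compare(row, "loa_hi", row["diff_mean"] + 1.96 * row["diff_sd"])
        if "icc_single" in row and not pd.isna(row.get("icc_single")):
            compare(row, "icc_average", spearman_brown(row["icc_single"]))
            for end in ("lo", "hi"):
                v = row.get(f"icc_single_{end}")
                if not pd.isna(v):
                    compare(row, f"icc_average_{end}", spearman_brown(v))
    return pd.DataFrame(out_rows)
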