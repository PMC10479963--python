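"""End-to-end orchestration: preprocessing, fitting, detection, reporting.

Mirrors the analysis blocks of the bonobo study on a tidy long-format
cohort: body weight (kg and kg**(1/k)), forearm length (cm and cm**k) and
log-transformed urinary markers are smoothed per sex with grouped random
intercepts per individual, velocities and spurt landmarks are extracted,
peaks are aligned across variables and scales, the weight-length scaling
exponent is checked, and male-female difference curves get cluster-
bootstrap bands.  Everything is deterministic given the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allometry as allom
from .cohort import HORMONE_VARIABLES, VARIABLES, default_reference, simulate_cohort
from .smoothing import BasisSpec, SmoothFit, difference_curve, fit_grouped, fix_lambda_policy, lambda_for_edf
from .spurt import detect_spurt, hormone_landmarks, transform_dimension, velocity_curve

__all__ = ["PipelineConfig", "FilterReport", "preprocess", "run_full", "ReportBundle"]

log = logging.getLogger("growthscale")

_SCHEMA = ["id", "sex", "zoo", "age_years", "variable", "value", "pregnant", "date_index"]

# analysis dimensions per variable: (dimension tag, transform exponent applied
# to the raw value before fitting); hormones are fitted on the log scale only
_DIMENSIONS = {
    "weight_kg": [("weight", None), ("weight_downscaled", "down")],
    "forearm_cm": [("length_linear", None), ("length_corrected", "up")],
}


@dataclass
class PipelineConfig:
    input: str | None = None  # tidy cohort CSV; None simulates the default cohort
    out_dir: str = "results/run"
    variables: list[str] = field(default_factory=lambda: list(VARIABLES))
    k: float = 2.5
    sexes: tuple[str, ...] = ("F", "M")
    age_range: tuple[float, float] = (0.5, 25.0)  # developmental analysis window
    decline_window: tuple[float, float] = (15.0, 55.0)  # senescent-decline window
    grid_step: float = 0.1
    n_boot: int = 200
    seed: int = 1
    n_per_sex: int = 80  # only used when input is None
    # per-variable smoothing policy consulted through fix_lambda_policy; an
    # entry may be a number, "auto", or ("edf", target)
    lambda_policy: dict = field(default_factory=dict)
    daily_average: bool = True
    exclude_pregnant: bool = True
    log_vars: list[str] = field(default_factory=lambda: list(HORMONE_VARIABLES))
    min_rel_rise: float = 0.10
    basis: BasisSpec | None = None  # None: the landmark-battery default basis

    def __post_init__(self):
        if not 2.0 <= self.k <= 3.0:
            raise ValueError("k must lie in [2, 3]")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(doc) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "basis" in doc:
            doc["basis"] = BasisSpec(**doc["basis"])
        for key in ("sexes", "age_range", "decline_window"):
            if key in doc:
                doc[key] = tuple(doc[key])
        if "lambda_policy" in doc:
            doc["lambda_policy"] = {
                var: tuple(v) if isinstance(v, list) else v
                for var, v in doc["lambda_policy"].items()
            }
        return cls(**doc)


@dataclass
class FilterReport:
    records_in: int
    daily_averaged: int  # weight records merged away
    pregnant_dropped: int
    log_transformed: int
    records_out: int


def _validate_schema(df: pd.DataFrame) -> None:
    missing = [c for c in _SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"cohort is missing columns {missing}")
    problems = []
    bad_value = df.index[~(df["value"] > 0) | ~np.isfinite(df["value"])]
    if len(bad_value):
        problems.append(f"non-positive/non-finite value at rows {list(bad_value[:10])}")
    bad_age = df.index[(df["age_years"] < 0) | (df["age_years"] > 55)]
    if len(bad_age):
        problems.append(f"age outside [0, 55] at rows {list(bad_age[:10])}")
    if problems:
        raise ValueError("; ".join(problems))


def preprocess(cohort: pd.DataFrame, config: PipelineConfig | None = None) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the standard cleaning rules; idempotent.

    1. weight records sharing id and calendar day are collapsed to their
       daily mean; 2. pregnant-flagged records are dropped for every
       variable except forearm length; 3. urinary markers are replaced by
       their natural log and renamed ``log_<variable>`` (so a second pass
       is a no-op).
    """
    config = config or PipelineConfig()
    _validate_schema(cohort)
    df = cohort.copy()
    n_in = len(df)

    merged = 0
    if config.daily_average:
        is_w = df["variable"] == "weight_kg"
        w = df[is_w]
        grouped = (
            w.groupby(["id", "date_index"], as_index=False)
            .agg(
                sex=("sex", "first"), zoo=("zoo", "first"),
                age_years=("age_years", "mean"), variable=("variable", "first"),
                value=("value", "mean"), pregnant=("pregnant", "any"),
            )
        )
        merged = len(w) - len(grouped)
        df = pd.concat([grouped[_SCHEMA], df[~is_w]], ignore_index=True)

    dropped = 0
    if config.exclude_pregnant:
        drop = df["pregnant"] & (df["variable"] != "forearm_cm")
        dropped = int(drop.sum())
        df = df[~drop]

    to_log = df["variable"].isin(config.log_vars)
    n_log = int(to_log.sum())
    if n_log:
        if (df.loc[to_log, "value"] <= 0).any():
            raise ValueError("non-positive values cannot be log-transformed")
        df.loc[to_log, "value"] = np.log(df.loc[to_log, "value"])
        df.loc[to_log, "variable"] = "log_" + df.loc[to_log, "variable"]

    df = df.sort_values(["sex", "id", "variable", "age_years"], kind="stable").reset_index(drop=True)
    return df, FilterReport(
        records_in=n_in, daily_averaged=merged, pregnant_dropped=dropped,
        log_transformed=n_log, records_out=len(df),
    )


@dataclass
class ReportBundle:
    landmarks: pd.DataFrame  # sex x variable x dimension spurt summaries
    summary: pd.DataFrame  # the Fig-4-style landmark battery for this cohort
    hormones: pd.DataFrame  # hormone landmark table
    alignment: pd.DataFrame
    allometry_fit: allom.AllometryFit
    isometry: allom.IsometryDecision
    differences: dict  # variable -> DifferenceCurve
    fits: dict  # (sex, variable, dimension) -> SmoothFit
    filter_report: FilterReport
    config: PipelineConfig

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        (out / "fits").mkdir(parents=True, exist_ok=True)
        self.landmarks.to_csv(out / "landmarks.csv", index=False)
        self.summary.to_csv(out / "summary_landmarks.csv", index=False)
        self.hormones.to_csv(out / "hormone_landmarks.csv", index=False)
        self.alignment.to_csv(out / "alignment.csv", index=False)
        with open(out / "allometry.json", "w") as fh:
            json.dump(
                {"fit": dataclasses.asdict(self.allometry_fit),
                 "isometry": dataclasses.asdict(self.isometry)},
                fh, indent=1,
            )
        for (sex, var, dim), fit in self.fits.items():
            fit.to_json(out / "fits" / f"{sex}_{var}_{dim}.json")
        for var, dc in self.differences.items():
            pd.DataFrame(
                {"age": dc.ages, "difference": dc.difference, "lo": dc.lo, "hi": dc.hi}
            ).to_csv(out / f"difference_{var}.csv", index=False)
        with open(out / "filter_report.json", "w") as fh:
            json.dump(dataclasses.asdict(self.filter_report), fh, indent=1)


def _fit_variable(sub: pd.DataFrame, variable: str, config: PipelineConfig) -> SmoothFit:
    from .landmarks import EDF_POLICY, PIPELINE_BASIS

    basis = config.basis or PIPELINE_BASIS
    ages = sub["age_years"].to_numpy()
    values = sub["value"].to_numpy()
    policy = fix_lambda_policy(variable, config.lambda_policy)
    if policy == "auto":
        # the battery's edf defaults stand behind "auto" at the pipeline level;
        # an explicit config entry (number, "auto" is the module default) wins
        policy_edf = EDF_POLICY.get(variable.removeprefix("log_"), "auto")
        if variable.removeprefix("log_") not in config.lambda_policy and not isinstance(policy_edf, str):
            policy = ("edf", policy_edf)
    if isinstance(policy, tuple) and policy[0] == "edf":
        lam = lambda_for_edf(ages, values, float(policy[1]), spec=basis)
    else:
        lam = policy
    return fit_grouped(ages, values, sub["id"].to_numpy(), spec=basis, lam=lam)


def _load_cohort(config: PipelineConfig) -> pd.DataFrame:
    if config.input is None:
        log.info("no input path; simulating default cohort (n=%d/sex, seed=%d)",
                 config.n_per_sex, config.seed)
        return simulate_cohort(default_reference(config.k), n_per_sex=config.n_per_sex,
                               seed=config.seed)
    return pd.read_csv(config.input)


def run_full(config: PipelineConfig | None = None) -> ReportBundle:
    """Run the whole analysis; returns the report bundle (also written to disk)."""
    config = config or PipelineConfig()
    t_start = time.perf_counter()
    cohort = _load_cohort(config)
    clean, report = preprocess(cohort, config)
    log.info("preprocess: %s", report)

    fits: dict = {}
    frames: dict = {}  # (sex, variable, dim) -> analysis frame on the fitted scale
    landmark_rows = []
    hormone_rows = []
    summaries = []
    stage = "fit"
    try:
        for variable in config.variables:
            fit_var = f"log_{variable}" if variable in config.log_vars else variable
            growth = variable in _DIMENSIONS  # weight/forearm: log-response fits
            dims = _DIMENSIONS.get(variable, [("log", None)])
            for sex in config.sexes:
                sub = clean[(clean["variable"] == fit_var) & (clean["sex"] == sex)]
                sub = sub[(sub["age_years"] >= config.age_range[0])
                          & (sub["age_years"] <= config.age_range[1])]
                if sub.empty:
                    raise ValueError(f"no records for {variable!r} ({sex})")
                for dim, direction in dims:
                    t0 = time.perf_counter()
                    sub_d = sub.copy()
                    if direction == "up":
                        sub_d["value"] = transform_dimension(
                            sub_d["value"], "length_linear", "length_corrected", config.k)
                    elif direction == "down":
                        sub_d["value"] = transform_dimension(
                            sub_d["value"], "weight", "weight_downscaled", config.k)
                    if growth:
                        sub_d["value"] = np.log(sub_d["value"])
                    fit = _fit_variable(sub_d, variable, config)
                    fits[(sex, variable, dim)] = fit
                    frames[(sex, variable, dim)] = sub_d
                    lo = max(fit.age_range[0], config.age_range[0])
                    hi = min(fit.age_range[1], config.age_range[1])
                    vc = velocity_curve(fit, grid_step=config.grid_step,
                                        dimension=dim, variable=variable, sex=sex,
                                        age_range=(lo, hi))
                    if growth:  # back-transform: d/dt exp(f) = exp(f) * f'
                        vc.velocity = np.exp(fit.predict(vc.ages)) * vc.velocity
                    summary = detect_spurt(vc, min_rel_rise=config.min_rel_rise)
                    summaries.append(summary)
                    landmark_rows.append(
                        {"sex": sex, "variable": variable, "dimension": dim,
                         "take_off": _r1(summary.take_off_age),
                         "peak_age": _r1(summary.peak_age),
                         "peak_velocity": summary.peak_velocity,
                         "cessation": _r1(summary.cessation_age),
                         "detected": summary.detected, "edf": round(fit.edf, 2),
                         "lambda": fit.lam}
                    )
                    if dim == "log":
                        hl = hormone_landmarks(fit, grid_step=config.grid_step)
                        hormone_rows.append(
                            {"sex": sex, "variable": variable,
                             "rise_fastest": _r1(hl.rise_fastest_age),
                             "plateau": _r1(hl.plateau_age),
                             "decline_onset": None}  # filled below for testosterone
                        )
                    log.info("fit %s %s %s: edf=%.1f (%.2fs)", sex, variable, dim,
                             fit.edf, time.perf_counter() - t0)

        stage = "decline"
        # senescent decline onset is a changepoint on the adult plateau, not a
        # spline-derivative feature; estimated per sex on the decline window
        from .landmarks import segmented_decline_onset

        if "testosterone" in config.variables:
            for sex in config.sexes:
                adult = clean[(clean["variable"] == "log_testosterone")
                              & (clean["sex"] == sex)
                              & (clean["age_years"] >= config.decline_window[0])
                              & (clean["age_years"] <= config.decline_window[1])]
                onset = segmented_decline_onset(adult["age_years"], adult["value"])
                for row in hormone_rows:
                    if row["sex"] == sex and row["variable"] == "testosterone":
                        row["decline_onset"] = _r1(onset)

        stage = "summary"
        from .landmarks import cohort_landmarks

        summary_table = cohort_landmarks(
            clean, k=config.k, window=config.age_range,
            decline_min_age=config.decline_window[0],
            min_rel_rise=config.min_rel_rise,
        ).to_frame()

        stage = "alignment"
        from .spurt import peak_alignment

        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            alignment = peak_alignment(summaries) if len(summaries) >= 2 else pd.DataFrame()

        stage = "allometry"
        pairs = allom.match_pairs(cohort[~(cohort["pregnant"] & (cohort["variable"] == "weight_kg"))])
        afit = allom.fit_loglog(pairs["weight"], pairs["length"])
        iso = allom.check_isometry(afit, config.k)

        stage = "difference"
        differences = {}
        boot_counter = 0
        for variable in config.variables:
            dim = _DIMENSIONS.get(variable, [("log", None)])[0][0]
            fm, ff = fits.get(("M", variable, dim)), fits.get(("F", variable, dim))
            if fm is None or ff is None:
                continue
            grid = np.arange(config.age_range[0], config.age_range[1] + 1e-9, config.grid_step)
            boot_counter += 1
            differences[variable] = difference_curve(
                fm, ff, grid, frames[("M", variable, dim)], frames[("F", variable, dim)],
                n_boot=config.n_boot, seed=config.seed * 100_003 + boot_counter,
            )
    except Exception:
        log.error("pipeline aborted in stage %r", stage)
        raise

    bundle = ReportBundle(
        landmarks=pd.DataFrame(landmark_rows),
        summary=summary_table,
        hormones=pd.DataFrame(hormone_rows),
        alignment=alignment,
        allometry_fit=afit,
        isometry=iso,
        differences=differences,
        fits=fits,
        filter_report=report,
        config=config,
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    log.info("pipeline done in %.1fs", time.perf_counter() - t_start)
    return bundle


def _r1(x):
    return None if x is None else round(x, 1)


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(asctime)s] %(levelname)s %(message)s", "%H:%M:%S"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
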