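"""Readers, writers, run configuration, and the pipeline driver.

The canonical interchange format is the long trial table — one row per
trial per epoch with columns ``session_id, trial_index, block, speed,
boundary, direction, target_location, outcome, choice, saccade_onset_ms,
in_response_field, epoch, spike_count`` — as CSV (default) or Parquet.
Scenario and run configuration load from YAML and are validated against
a strict schema (unknown keys rejected) before any computation.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .behavior import behavioral_rates, fit_behavior
from .decoding import cross_validated_accuracy, equalize_trials
from .synth import (TRIAL_COLUMNS, PsychoParams, ScenarioSpec,
                    build_scenario, scenario_frame)
from .task import TaskConfig
from .unit_metrics import population_category_index, screen_unit

__all__ = [
    "SchemaError", "ScenarioConfig", "RunConfig", "read_trials",
    "write_trials", "load_run_config", "run_pipeline",
]

_OUTCOMES = {"correct", "incorrect", "fixation_break"}
_CHOICES = {"slow", "fast", "none"}


class SchemaError(ValueError):
    """A data file or configuration violates the expected schema."""


# ---------------------------------------------------------------------------
# configuration models

class ScenarioConfig(BaseModel):
    """YAML-friendly mirror of :class:`speedcat.synth.ScenarioSpec`."""

    model_config = ConfigDict(extra="forbid")

    n_neurons: int = 30
    tuning_family: str = "speed_tuned"
    baseline_rate_hz: float = 3.0
    tuning_amplitude_hz: float = 10.0
    boundary_amplitude_hz: float = 8.0
    near_boundary_factor: float = 2.0
    tuning_width: float = 3.0
    direction_amplitude_hz: float = 0.0
    direction_suppression_near: float = 1.0
    speed_fraction: float = 0.3
    include_direction: bool = False
    incorrect_spikes: str = "veridical"
    n_blocks: int = 8
    fixation_break_rate: float = 0.13
    psycho: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {"slow": {"s50": 6.9}, "fast": {"s50": 11.3}})

    def to_spec(self, seed: int) -> ScenarioSpec:
        task = TaskConfig(fixation_break_rate=self.fixation_break_rate)
        psycho = {b: PsychoParams(**p) for b, p in self.psycho.items()}
        fields = self.model_dump(exclude={"psycho", "fixation_break_rate"})
        return ScenarioSpec(task=task, psycho=psycho, seed=seed, **fields)


class RunConfig(BaseModel):
    """Validated end-to-end pipeline configuration."""

    model_config = ConfigDict(extra="forbid")

    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    dataset: str | None = None          # read trials instead of simulating
    stages: list[str] = Field(
        default_factory=lambda: ["simulate", "behavior", "unit_metrics",
                                 "decode"])
    epoch: str = "post_saccade"
    classes: int = 16
    trial_filter: str = "correct_only"
    n_eq: int            # explicit: core analysis choices carry no defaults
    n_draws: int
    seed: int
    cv_scheme: str = "train_one"
    alpha: float = 0.05
    n_boot: int = 2000
    output_dir: str = "speedcat_out"

    @field_validator("classes")
    @classmethod
    def _check_classes(cls, v):
        if v not in (16, 32):
            raise ValueError("classes must be 16 or 32")
        return v

    @field_validator("stages")
    @classmethod
    def _check_stages(cls, v):
        known = {"simulate", "behavior", "unit_metrics", "decode"}
        bad = set(v) - known
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}")
        return v

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# trial tables

def write_trials(trials: pd.DataFrame | list[pd.DataFrame], path) -> Path:
    """Write a long-format trial table (CSV or Parquet by extension)."""
    if isinstance(trials, list):
        trials = scenario_frame(trials)
    path = Path(path)
    if path.suffix == ".parquet":
        trials.to_parquet(path, index=False)
    else:
        trials.to_csv(path, index=False)
    return path


def _validate_trials(df: pd.DataFrame, config: TaskConfig) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    if df.empty:
        raise SchemaError("empty trial table")

    def first_bad(mask: pd.Series, column: str, problem: str):
        if mask.any():
            row = int(df.index[mask][0])
            raise SchemaError(
                f"row {row}, column {column!r}: {problem} "
                f"(value {df.loc[row, column]!r})")

    first_bad(~df["speed"].isin(config.speeds), "speed",
              f"speed not in grid {list(config.speeds)}")
    first_bad(~df["boundary"].isin(config.boundaries), "boundary",
              f"label not in {list(config.boundaries)}")
    first_bad(~df["direction"].isin(config.directions), "direction",
              f"label not in {list(config.directions)}")
    first_bad(~df["outcome"].isin(_OUTCOMES), "outcome",
              f"label not in {sorted(_OUTCOMES)}")
    first_bad(~df["choice"].isin(_CHOICES), "choice",
              f"label not in {sorted(_CHOICES)}")
    first_bad(~df["epoch"].isin(config.epoch_windows), "epoch",
              f"epoch not in {list(config.epoch_windows)}")
    counts = pd.to_numeric(df["spike_count"], errors="coerce")
    first_bad(counts.isna() | (counts < 0) | (counts % 1 != 0),
              "spike_count", "must be a nonnegative integer")


def read_trials(path, config: TaskConfig | None = None
                ) -> list[pd.DataFrame]:
    """Read and validate a long trial table; returns one frame per session."""
    config = config or TaskConfig()
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    _validate_trials(df, config)
    return [g.reset_index(drop=True)
            for _, g in df.groupby("session_id", sort=True)]


# ---------------------------------------------------------------------------
# pipeline

def _dump_json(obj, path: Path) -> None:
    class _Encoder(json.JSONEncoder):
        def default(self, o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return super().default(o)

    path.write_text(json.dumps(obj, indent=2, cls=_Encoder))


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> behavior -> unit_metrics -> decode.

    Stages not listed in ``config.stages`` are skipped; later stages
    consume the simulated (or loaded) trial tables. All outputs embed
    the config hash and master seed. Returns the report bundle.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "speedcat_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.model_dump(),
    }
    bundle: dict = {"meta": meta}
    task = TaskConfig(
        fixation_break_rate=config.scenario.fixation_break_rate)

    if config.dataset is not None:
        sessions = read_trials(config.dataset, task)
    elif "simulate" in config.stages:
        spec = config.scenario.to_spec(seed=config.seed)
        sessions, _truth = build_scenario(spec)
        write_trials(sessions, outdir / "trials.csv")
    else:
        raise SchemaError("no dataset given and 'simulate' stage disabled")
    trials = scenario_frame(sessions)
    meta["n_sessions"] = len(sessions)
    meta["n_trials"] = int(trials[["session_id", "trial_index"]]
                           .drop_duplicates().shape[0])

    if "behavior" in config.stages:
        fits = fit_behavior(trials, task)
        rates = behavioral_rates(trials)
        bundle["behavior"] = {
            "fits": {b: f.to_dict() for b, f in fits.items()},
            "rates": rates.to_dict(orient="records"),
        }
        rates.to_csv(outdir / "behavior_rates.csv", index=False)
        _dump_json(bundle["behavior"], outdir / "behavior.json")

    if "unit_metrics" in config.stages:
        ss = np.random.SeedSequence(config.seed).spawn(len(sessions))
        units = []
        for session, child in zip(sessions, ss):
            rep = screen_unit(session, task, n_boot=config.n_boot,
                              alpha=config.alpha,
                              seed=np.random.default_rng(child))
            units.append({
                "neuron_id": session["session_id"].iloc[0],
                "responsive": {e: r for e, r in rep["responsive"].items()},
                "boundary_sensitive": {
                    e: {"flag": r["flag"],
                        "per_speed": r["per_speed"].to_dict(orient="records")}
                    for e, r in rep["boundary_sensitive"].items()},
            })
        pop_ci = population_category_index(sessions, config.epoch, task)
        bundle["unit_metrics"] = {"units": units,
                                  "population_ci":
                                  pop_ci.to_dict(orient="records")}
        pop_ci.to_csv(outdir / "population_ci.csv", index=False)
        _dump_json(bundle["unit_metrics"], outdir / "unit_metrics.json")

    if "decode" in config.stages:
        ens = equalize_trials(
            sessions, config.epoch, task, n_eq=config.n_eq,
            include_direction=config.classes == 32,
            trial_filter=config.trial_filter, seed=config.seed)
        report = cross_validated_accuracy(
            ens, n_draws=config.n_draws, scheme=config.cv_scheme,
            seed=config.seed + 1)
        bundle["decode"] = report.to_dict()
        bundle["decode"]["reconstructed_fraction"] = \
            ens.reconstructed_fraction()
        bundle["decode"]["excluded_neurons"] = ens.excluded
        report.per_class.to_csv(outdir / "decode_per_class.csv", index=False)
        _dump_json(bundle["decode"], outdir / "decode.json")

    _dump_json(meta, outdir / "run_log.json")
    return bundle
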