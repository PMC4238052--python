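"""Synthetic task, behavior, and spike-count generation.

Emulates the statistical structure of a sequentially recorded speed
categorization experiment: block-randomized schedules over 64 trial types,
choices drawn from boundary-specific psychometric curves, fixation breaks
reshuffled within their block, and per-epoch Poisson spike counts from
condition-dependent tuning tables. One synthetic "session" is generated
per neuron, so downstream population analyses must assemble a
pseudo-population exactly as they would for real sequential recordings.

Only per-epoch counts are generated — no spike times — and trials are
independent (no adaptation or reward-history effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import POST_DECISION_EPOCHS, ConfigurationError, TaskConfig

__all__ = [
    "PsychoParams", "GroundTruthTuning", "ScenarioSpec", "ScheduleError",
    "generate_schedule", "simulate_choices", "simulate_spike_counts",
    "make_tuning", "build_scenario", "scenario_frame", "flat_scenario",
]

#: Columns of the long-format trial table (one row per trial per epoch).
TRIAL_COLUMNS = [
    "session_id", "trial_index", "block", "speed", "boundary", "direction",
    "target_location", "outcome", "choice", "saccade_onset_ms",
    "in_response_field", "epoch", "spike_count",
]

TUNING_FAMILIES = ("flat", "speed_tuned", "boundary_gated", "category_step",
                   "redundant")


class ScheduleError(RuntimeError):
    """Raised when schedule generation cannot terminate."""


@dataclass(frozen=True)
class PsychoParams:
    """Naka-Rushton psychometric curve P(choice = fast | speed).

    P(s) = lower + (upper - lower) * s^e / (s^e + s50^e). With symmetric
    asymptotes (lower + upper = 1) the point of subjective equality is
    exactly ``s50``.
    """

    lower: float = 0.02
    upper: float = 0.98
    s50: float = 9.0
    exponent: float = 4.0

    def __post_init__(self) -> None:
        if not (0 <= self.lower < self.upper <= 1):
            raise ValueError("need 0 <= lower < upper <= 1")
        if self.s50 <= 0 or self.exponent <= 0:
            raise ValueError("s50 and exponent must be positive")

    def p_fast(self, speed) -> np.ndarray:
        from .behavior import naka_rushton
        return naka_rushton(speed, self.lower, self.upper, self.s50,
                            self.exponent)


#: Study-condition psychometric defaults: the measured mean points of
#: subjective equality sit inward of the true cues (5 and 13 deg/s).
DEFAULT_PSYCHO: dict[str, PsychoParams] = {
    "slow": PsychoParams(s50=6.9),
    "fast": PsychoParams(s50=11.3),
}


@dataclass(frozen=True)
class GroundTruthTuning:
    """Generative mean spike count per joint condition class for one epoch.

    ``class_means`` maps a class key — (speed, boundary) for 16 classes or
    (speed, boundary, direction) for 32 — to the expected count in the
    epoch window. This is the generative analogue of the decoder's tuning
    table f_i(s).
    """

    neuron_id: str
    epoch: str
    class_means: dict[tuple, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.class_means.values()):
            raise ValueError("class means must be nonnegative")

    @property
    def include_direction(self) -> bool:
        return len(next(iter(self.class_means))) == 3

    def mean_for(self, speed: float, boundary: str, direction: str) -> float:
        key = ((speed, boundary, direction) if self.include_direction
               else (speed, boundary))
        try:
            return self.class_means[key]
        except KeyError:
            raise KeyError(
                f"neuron {self.neuron_id}, epoch {self.epoch}: no tuning "
                f"entry for class {key}") from None


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of a synthetic experiment.

    Rates are in spikes/s and are converted to expected counts with each
    epoch's window length. ``tuning_family`` selects the generative model
    for the two post-decision epochs (cue/decision epochs stay at the
    baseline rate, matching a population that is responsive only after
    the decision):

    - ``flat``: every joint class has the same rate (baseline + amplitude).
    - ``speed_tuned``: Gaussian speed tuning with a per-neuron preferred
      speed, identical across boundaries.
    - ``boundary_gated``: speed tuning plus a boundary-contingent rate
      change confined to one speed per neuron (near-boundary speeds 6 and
      12 are preferentially gated by ``near_boundary_factor``).
    - ``category_step``: rate steps by ``boundary_amplitude_hz`` when the
      stimulus falls on the fast side of the currently cued boundary.
    - ``redundant``: every neuron carries the boundary signal, only a
      ``speed_fraction`` subset is speed tuned.
    """

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
    incorrect_spikes: str = "veridical"  # or "chosen_category"
    n_blocks: int = 8
    psycho: dict[str, PsychoParams] = field(
        default_factory=lambda: dict(DEFAULT_PSYCHO))
    task: TaskConfig = field(default_factory=TaskConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ConfigurationError("n_neurons must be >= 1")
        if self.tuning_family not in TUNING_FAMILIES:
            raise ConfigurationError(
                f"unknown tuning_family {self.tuning_family!r}; "
                f"choose from {TUNING_FAMILIES}")
        for name in ("baseline_rate_hz", "tuning_amplitude_hz",
                     "boundary_amplitude_hz"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.incorrect_spikes not in ("veridical", "chosen_category"):
            raise ConfigurationError(
                "incorrect_spikes must be 'veridical' or 'chosen_category'")


# ---------------------------------------------------------------------------
# schedule

def generate_schedule(config: TaskConfig, n_blocks: int, seed,
                      max_reinsertions: int | None = None) -> pd.DataFrame:
    """Block-randomized trial schedule with fixation-break reshuffling.

    Each block presents every trial type once in random order. A trial
    aborted by a fixation break (Bernoulli at ``config.fixation_break_rate``)
    is emitted as an aborted trial and its type is re-inserted at a random
    later position within the same block (appended at the tail when the
    block queue is empty), so every type is eventually completed.

    Returns a per-trial frame with outcome either ``"fixation_break"`` or
    ``"pending"`` (to be filled by :func:`simulate_choices`).
    """
    if n_blocks < 1:
        raise ConfigurationError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    types = config.trial_types()
    if max_reinsertions is None:
        max_reinsertions = 100 * len(types) * n_blocks
    rows = []
    trial_index = 0
    n_reinserted = 0
    for block in range(n_blocks):
        order = [types[i] for i in rng.permutation(len(types))]
        pending = list(order)
        while pending:
            speed, boundary, direction, target = pending.pop(0)
            broke = rng.random() < config.fixation_break_rate
            rows.append((trial_index, block, speed, boundary, direction,
                         target, "fixation_break" if broke else "pending"))
            trial_index += 1
            if broke:
                n_reinserted += 1
                if n_reinserted > max_reinsertions:
                    raise ScheduleError(
                        "fixation-break reinsertion limit exceeded "
                        f"({max_reinsertions}); fixation_break_rate="
                        f"{config.fixation_break_rate} too close to 1")
                if pending:
                    # random strictly later slot: never an immediate repeat
                    pos = int(rng.integers(1, len(pending) + 1))
                else:
                    pos = 0  # tail of the block
                pending.insert(pos, (speed, boundary, direction, target))
    return pd.DataFrame(rows, columns=[
        "trial_index", "block", "speed", "boundary", "direction",
        "target_location", "outcome"])


# ---------------------------------------------------------------------------
# choices

def simulate_choices(trials: pd.DataFrame,
                     psycho: dict[str, PsychoParams],
                     config: TaskConfig, seed,
                     saccade_median_ms: float = 309.0,
                     saccade_sigma: float = 0.15) -> pd.DataFrame:
    """Draw choices from boundary-specific psychometric curves.

    Each completed trial's choice is Bernoulli on the cued boundary's
    P(fast | speed); the outcome is correct iff the choice matches the
    side of the true reference speed. Saccade onsets are lognormal with
    the configured median (metadata only — never used by the decoder).
    Fixation-break trials keep choice ``"none"``.
    """
    rng = np.random.default_rng(seed)
    out = trials.copy()
    missing = set(out["boundary"].unique()) - set(psycho)
    if missing:
        raise ValueError(f"no psychometric parameters for boundaries {missing}")
    completed = out["outcome"] != "fixation_break"
    p = np.zeros(len(out))
    for b, params in psycho.items():
        mask = (out["boundary"] == b).to_numpy()
        p[mask] = params.p_fast(out.loc[mask, "speed"].to_numpy())
    if np.any((p < 0) | (p > 1)):
        raise ValueError("psychometric probabilities outside [0, 1]")
    chose_fast = rng.random(len(out)) < p
    choice = np.where(chose_fast, "fast", "slow")
    refs = out["boundary"].map(config.boundary_cues).to_numpy()
    correct_is_fast = out["speed"].to_numpy() > refs
    correct = chose_fast == correct_is_fast
    out["choice"] = np.where(completed, choice, "none")
    out["outcome"] = np.where(
        completed, np.where(correct, "correct", "incorrect"), "fixation_break")
    onsets = rng.lognormal(np.log(saccade_median_ms), saccade_sigma, len(out))
    out["saccade_onset_ms"] = np.where(completed, onsets, np.nan)
    return out


# ---------------------------------------------------------------------------
# spikes

def _replacement_speed(speed: float, boundary: str, choice: str,
                       config: TaskConfig) -> float:
    """Nearest speed belonging to the (incorrectly) chosen category."""
    ref = config.boundary_cues[boundary]
    candidates = [s for s in config.speeds
                  if ("fast" if s > ref else "slow") == choice]
    return min(candidates, key=lambda s: abs(s - speed))


def simulate_spike_counts(trials: pd.DataFrame,
                          tunings: list[GroundTruthTuning],
                          config: TaskConfig, seed,
                          session_id: str = "s000",
                          incorrect_spikes: str = "veridical") -> pd.DataFrame:
    """Expand a per-trial frame into the long format with Poisson counts.

    One row per trial per epoch; counts are independent Poisson draws at
    the class mean of this neuron's tuning for that epoch. Fixation-break
    trials carry no post-decision epochs. With
    ``incorrect_spikes="chosen_category"``, post-decision counts on
    incorrect trials are drawn from the tuning of the nearest speed in the
    (wrong) chosen category, modeling a trace of the subjective rather
    than veridical stimulus.
    """
    rng = np.random.default_rng(seed)
    by_epoch = {t.epoch: t for t in tunings}
    missing = set(config.epoch_windows) - set(by_epoch)
    if missing:
        raise ValueError(f"no tuning for epochs {sorted(missing)}")
    frames = []
    completed = (trials["outcome"] != "fixation_break").to_numpy()
    for epoch in config.epoch_windows:
        tuning = by_epoch[epoch]
        sub = trials if epoch not in POST_DECISION_EPOCHS else trials[completed]
        means = np.empty(len(sub))
        rows = zip(sub["speed"], sub["boundary"], sub["direction"],
                   sub["outcome"], sub["choice"])
        for k, (speed, boundary, direction, outcome, choice) in enumerate(rows):
            if (incorrect_spikes == "chosen_category"
                    and epoch in POST_DECISION_EPOCHS
                    and outcome == "incorrect"):
                speed = _replacement_speed(speed, boundary, choice, config)
            means[k] = tuning.mean_for(speed, boundary, direction)
        frame = sub.copy()
        frame["epoch"] = epoch
        frame["spike_count"] = rng.poisson(means)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out["session_id"] = session_id
    out["in_response_field"] = True
    out = out.sort_values(["trial_index", "epoch"], kind="stable")
    return out[TRIAL_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# tuning construction

def make_tuning(spec: ScenarioSpec, neuron_id: str,
                rng: np.random.Generator) -> list[GroundTruthTuning]:
    """Draw one neuron's ground-truth tuning for every epoch.

    Post-decision epochs (post_saccade, reward) carry the family's
    condition-dependent rates; baseline/cue/decision stay at the baseline
    rate, emulating a post-decision-responsive population.
    """
    cfg = spec.task
    speeds = np.asarray(cfg.speeds)
    near = {6.0, 12.0}

    # per-neuron latent parameters, drawn once and shared across epochs
    pref_speed = float(rng.choice(speeds))
    pref_boundary = str(rng.choice(cfg.boundaries))
    if spec.tuning_family == "boundary_gated":
        w = np.where(np.isin(speeds, sorted(near)),
                     spec.near_boundary_factor, 1.0)
        gated_speed = float(rng.choice(speeds, p=w / w.sum()))
    else:
        gated_speed = np.nan
    is_speed_coder = (spec.tuning_family != "redundant"
                      or rng.random() < spec.speed_fraction)
    pref_direction = str(rng.choice(cfg.directions))

    def rate(speed: float, boundary: str, direction: str) -> float:
        r = spec.baseline_rate_hz
        fam = spec.tuning_family
        if fam == "flat":
            r += spec.tuning_amplitude_hz
        elif fam in ("speed_tuned", "boundary_gated", "redundant"):
            if is_speed_coder:
                r += spec.tuning_amplitude_hz * np.exp(
                    -0.5 * ((speed - pref_speed) / spec.tuning_width) ** 2)
            if fam == "boundary_gated" and speed == gated_speed \
                    and boundary == pref_boundary:
                r += spec.boundary_amplitude_hz
            if fam == "redundant" and boundary == pref_boundary:
                r += spec.boundary_amplitude_hz
        elif fam == "category_step":
            if speed > cfg.boundary_cues[boundary]:
                r += spec.boundary_amplitude_hz
        if spec.direction_amplitude_hz > 0 and direction == pref_direction:
            supp = (spec.direction_suppression_near
                    if speed in near else 1.0)
            r += spec.direction_amplitude_hz * supp
        return max(r, 0.0)

    tunings = []
    for epoch in cfg.epoch_windows:
        dur = cfg.epoch_duration_s(epoch)
        post = epoch in POST_DECISION_EPOCHS
        means: dict[tuple, float] = {}
        for b in cfg.boundaries:
            for d in cfg.directions:
                for s in speeds:
                    r = rate(s, b, d) if post else spec.baseline_rate_hz
                    key = (float(s), b, d) if spec.include_direction \
                        else (float(s), b)
                    means[key] = r * dur
        tunings.append(GroundTruthTuning(neuron_id, epoch, means))
    return tunings


def build_scenario(spec: ScenarioSpec
                   ) -> tuple[list[pd.DataFrame], list[GroundTruthTuning]]:
    """Generate a full synthetic experiment: one session per neuron.

    The master seed spawns independent substreams for tuning, schedule,
    choices, and spikes of each neuron, so a fixed seed reproduces the
    scenario exactly while individual stages remain independently
    regenerable.

    Returns the list of long-format session frames and the flat list of
    ground-truth tunings (n_neurons x n_epochs entries) for
    parameter-recovery tests.
    """
    master = np.random.SeedSequence(spec.seed)
    sessions, truths = [], []
    for i, child in enumerate(master.spawn(spec.n_neurons)):
        s_tune, s_sched, s_choice, s_spk = child.spawn(4)
        neuron_id = f"n{i:03d}"
        tunings = make_tuning(spec, neuron_id,
                              np.random.default_rng(s_tune))
        sched = generate_schedule(spec.task, spec.n_blocks, s_sched)
        trials = simulate_choices(sched, spec.psycho, spec.task, s_choice)
        session = simulate_spike_counts(
            trials, tunings, spec.task, s_spk, session_id=neuron_id,
            incorrect_spikes=spec.incorrect_spikes)
        sessions.append(session)
        truths.extend(tunings)
    return sessions, truths


def scenario_frame(sessions: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-neuron sessions into one long trial table."""
    return pd.concat(sessions, ignore_index=True)


def flat_scenario(n_neurons: int, mean_count: float, seed: int,
                  n_blocks: int = 8, task: TaskConfig | None = None,
                  **kwargs) -> ScenarioSpec:
    """Convenience spec: identical tuning across every joint class.

    ``mean_count`` is the expected post-saccade count, converted to the
    equivalent rate internally.
    """
    task = task or TaskConfig()
    rate = mean_count / task.epoch_duration_s("post_saccade")
    return ScenarioSpec(
        n_neurons=n_neurons, tuning_family="flat", baseline_rate_hz=rate,
        tuning_amplitude_hz=0.0, n_blocks=n_blocks, task=task, seed=seed,
        **kwargs)
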