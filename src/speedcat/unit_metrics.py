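"""Single-neuron screening and category metrics.

Screening mirrors the study's two-stage selection: (1) task
responsiveness — a bootstrap comparison of baseline firing rate against
each post-fixation epoch, in spikes/s because window lengths differ; and
(2) boundary sensitivity — per-speed bootstrap comparison of spike counts
between the two boundary contexts, Bonferroni-corrected over the 8
speeds.

Two per-neuron category metrics quantify context coding:

- category index, CI = |(R_slow - R_fast) / (R_slow + R_fast)| per speed,
  where R_slow/R_fast are the mean counts under the slow/fast boundary;
- ratio-difference index — the unsigned difference in mean counts between
  neighboring speeds 4/6 or 12/14, split by whether the pair straddles
  the currently cued boundary (inter-category) or not (intra-category).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .resampling import ResampleResult, bonferroni, bootstrap_diff
from .task import STRADDLE_PAIRS, TaskConfig

__all__ = [
    "RatioDiffResult", "epoch_counts", "responsiveness_test",
    "boundary_sensitivity", "category_index", "category_index_profile",
    "ratio_diff", "screen_unit", "population_category_index",
]


def epoch_counts(session: pd.DataFrame, epoch: str,
                 completed_only: bool = True,
                 rf_only: bool = True) -> pd.DataFrame:
    """Per-trial spike counts of one neuron for one epoch.

    Fixation-break trials and (optionally) trials outside the neuron's
    response field are excluded, matching the study's inclusion rules.
    """
    t = session[session["epoch"] == epoch]
    if completed_only:
        t = t[t["outcome"] != "fixation_break"]
    if rf_only and "in_response_field" in t.columns:
        t = t[t["in_response_field"]]
    cols = ["trial_index", "speed", "boundary", "direction", "outcome",
            "choice", "spike_count"]
    return t[[c for c in cols if c in t.columns]].reset_index(drop=True)


def responsiveness_test(baseline_counts, task_counts,
                        baseline_duration_s: float,
                        task_duration_s: float,
                        n_boot: int = 2000, alpha: float = 0.05,
                        seed=None) -> ResampleResult:
    """Bootstrap test for a baseline vs task-epoch rate difference.

    Counts are converted to rates (spikes/s) before comparison because
    the windows differ in length (400 ms baseline vs 600-800 ms epochs).
    Requires at least 10 trials on each side.
    """
    a = np.asarray(baseline_counts, dtype=float)
    b = np.asarray(task_counts, dtype=float)
    if a.size < 10 or b.size < 10:
        raise ValueError("need >= 10 trials per side for the "
                         "responsiveness test")
    return bootstrap_diff(a / baseline_duration_s, b / task_duration_s,
                          n_resamples=n_boot, alpha=alpha, seed=seed)


def boundary_sensitivity(counts: pd.DataFrame, config: TaskConfig,
                         n_boot: int = 2000, alpha: float = 0.05,
                         seed=None) -> pd.DataFrame:
    """Per-speed slow-vs-fast boundary comparison, Bonferroni over speeds.

    Returns one row per speed with the bootstrap p-value and the
    corrected significance flag (threshold alpha / n_speeds). A neuron is
    category-sensitive when any speed is significant. Speeds missing one
    boundary condition are reported with NaN p-values.
    """
    rng = np.random.default_rng(seed)
    m = len(config.speeds)
    rows = []
    for speed in config.speeds:
        sub = counts[counts["speed"] == speed]
        a = sub.loc[sub["boundary"] == "slow", "spike_count"].to_numpy()
        b = sub.loc[sub["boundary"] == "fast", "spike_count"].to_numpy()
        if a.size == 0 or b.size == 0:
            rows.append({"speed": speed, "p_value": np.nan,
                         "statistic": np.nan, "significant": False,
                         "missing": True})
            continue
        res = bootstrap_diff(a, b, n_resamples=n_boot, alpha=alpha, m=m,
                             seed=rng)
        rows.append({"speed": speed, "p_value": res.p_value,
                     "statistic": res.statistic,
                     "significant": res.significant, "missing": False})
    out = pd.DataFrame(rows)
    valid = ~out["missing"]
    out.loc[valid, "significant"] = bonferroni(
        out.loc[valid, "p_value"].to_numpy(), alpha=alpha, m=m)
    return out


def category_index(r_slow: float, r_fast: float) -> float:
    """|(R_slow - R_fast) / (R_slow + R_fast)|; NaN when both means are 0."""
    if r_slow < 0 or r_fast < 0:
        raise ValueError("mean counts must be nonnegative")
    total = r_slow + r_fast
    if total == 0:
        return float("nan")
    return abs((r_slow - r_fast) / total)


def category_index_profile(counts: pd.DataFrame,
                           config: TaskConfig) -> pd.DataFrame:
    """CI per speed from mean counts under each boundary."""
    rows = []
    for speed in config.speeds:
        sub = counts[counts["speed"] == speed]
        a = sub.loc[sub["boundary"] == "slow", "spike_count"]
        b = sub.loc[sub["boundary"] == "fast", "spike_count"]
        ci = (category_index(a.mean(), b.mean())
              if len(a) and len(b) else np.nan)
        rows.append({"speed": speed, "ci": ci,
                     "r_slow": a.mean() if len(a) else np.nan,
                     "r_fast": b.mean() if len(b) else np.nan})
    return pd.DataFrame(rows)


@dataclass
class RatioDiffResult:
    """Intra/inter-category mean-count differences for one speed pair."""

    pair: tuple[float, float]
    inter_diff: float
    intra_diff: float
    selected: bool

    def to_dict(self) -> dict:
        return {"pair": list(self.pair), "inter_diff": self.inter_diff,
                "intra_diff": self.intra_diff, "selected": self.selected}


def ratio_diff(counts: pd.DataFrame,
               pairs=tuple(STRADDLE_PAIRS)) -> list[RatioDiffResult]:
    """Ratio-difference index for the near-boundary speed pairs.

    For each pair the unsigned difference of mean counts between the two
    speeds is computed separately under each boundary; the difference
    under the boundary the pair straddles (4/6 straddles the slow cue at
    5 deg/s, 12/14 the fast cue at 13 deg/s) is the inter-category value,
    the other the intra-category value. The pair with the larger maximum
    difference is flagged ``selected`` (the neuron's preferred pair, used
    for population analysis). Pairs with missing cells are skipped.
    """
    results = []
    for pair in pairs:
        straddled = STRADDLE_PAIRS[pair]
        diffs = {}
        ok = True
        for boundary in ("slow", "fast"):
            means = []
            for speed in pair:
                sel = counts[(counts["speed"] == speed)
                             & (counts["boundary"] == boundary)]
                if sel.empty:
                    ok = False
                    break
                means.append(sel["spike_count"].mean())
            if not ok:
                break
            diffs[boundary] = abs(means[0] - means[1])
        if not ok:
            continue
        inter = diffs[straddled]
        intra = diffs["fast" if straddled == "slow" else "slow"]
        results.append(RatioDiffResult(pair=pair, inter_diff=float(inter),
                                       intra_diff=float(intra),
                                       selected=False))
    if results:
        best = max(range(len(results)),
                   key=lambda i: max(results[i].inter_diff,
                                     results[i].intra_diff))
        results[best].selected = True
    return results


def screen_unit(session: pd.DataFrame, config: TaskConfig,
                n_boot: int = 2000, alpha: float = 0.05,
                seed=None) -> dict:
    """Full screening report for one neuron.

    Responsiveness (baseline vs each post-fixation epoch, in Hz) and
    boundary sensitivity per post-decision epoch.
    """
    rng = np.random.default_rng(seed)
    base = epoch_counts(session, "baseline",
                        completed_only=False)["spike_count"].to_numpy()
    base_dur = config.epoch_duration_s("baseline")
    report: dict = {"responsive": {}, "boundary_sensitive": {}}
    for epoch in config.epoch_windows:
        if epoch == "baseline":
            continue
        ec = epoch_counts(session, epoch)
        if len(ec) < 10:
            report["responsive"][epoch] = {"p_value": np.nan, "flag": False}
            continue
        res = responsiveness_test(
            base, ec["spike_count"].to_numpy(), base_dur,
            config.epoch_duration_s(epoch), n_boot=n_boot, alpha=alpha,
            seed=rng)
        report["responsive"][epoch] = {"p_value": res.p_value,
                                       "flag": res.significant}
    for epoch in ("post_saccade", "reward"):
        ec = epoch_counts(session, epoch)
        tab = boundary_sensitivity(ec, config, n_boot=n_boot, alpha=alpha,
                                   seed=rng)
        report["boundary_sensitive"][epoch] = {
            "per_speed": tab,
            "flag": bool(tab["significant"].any()),
        }
    return report


def population_category_index(sessions: list[pd.DataFrame], epoch: str,
                              config: TaskConfig) -> pd.DataFrame:
    """Mean CI per speed across neurons (population CI profile)."""
    profiles = []
    for session in sessions:
        counts = epoch_counts(session, epoch)
        prof = category_index_profile(counts, config)
        prof["neuron"] = session["session_id"].iloc[0]
        profiles.append(prof)
    allp = pd.concat(profiles, ignore_index=True)
    return (allp.groupby("speed")["ci"].agg(["mean", "sem", "count"])
            .reset_index()
            .rename(columns={"mean": "mean_ci", "sem": "sem_ci",
                             "count": "n_neurons"}))
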