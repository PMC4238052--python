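"""Independent-Poisson maximum-likelihood population decoding.

The decoder reads out the joint stimulus class — (speed, boundary) over
16 classes, or (speed, boundary, direction) over 32 — from a
pseudo-population of spike counts. Under the model each neuron i fires a
Poisson count r_i with class-specific mean f_i(s_j), independently across
neurons, so the population log likelihood of class s_j is

    log L(s_j) = sum_i [ r_i * log f_i(s_j) - f_i(s_j) ]   ( - sum_i log r_i! )

where the factorial term is dropped as class-independent; the decoded
class is the argmax. Tuning means are estimated from training trials only
and floored at one spike per window to avoid log(0).

Because neurons were recorded sequentially, the pseudo-population is
assembled by condition label with per-draw random trial pairing, and
every (neuron, class) cell is equalized to a fixed trial count (surplus
subsampled, deficit filled with Poisson surrogate trials at the observed
class mean). Cross-validation follows the inverted leave-one-out scheme
(train on one randomly selected trial per class, test on the remaining
n - 1); a conventional leave-one-out is available behind
``scheme="loo"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .task import NEIGHBOR_PAIRS, TaskConfig
from .unit_metrics import epoch_counts

__all__ = [
    "PoissonPopulationDecoder", "TuningTable", "Ensemble", "DecodeReport",
    "estimate_tuning", "log_likelihood", "decode_trial", "equalize_trials",
    "cross_validated_accuracy", "accuracy_vs_population_size",
    "llr_pair_discrimination", "direction_decoding",
    "incorrect_trial_decoding", "normalized_accuracy",
]

DEFAULT_FLOOR = 1.0
DEFAULT_N_EQ = 10
DEFAULT_N_DRAWS = 1000


# ---------------------------------------------------------------------------
# core likelihood machinery

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _loglik_matrix(R: np.ndarray, F: np.ndarray) -> np.ndarray:
    """log L for test counts R (n_neurons, n_trials) under tuning F
    (n_neurons, n_classes), factorial term dropped. Returns
    (n_trials, n_classes).

    Zero tuning means (possible only with floor=0) are handled by the
    convention 0 * log 0 = 0, so a zero-mean class is disqualified
    (-inf) as soon as any neuron fires.
    """
    if np.any(F == 0):
        with np.errstate(divide="ignore", invalid="ignore"):
            logF = np.log(F)  # -inf where F == 0
            # elementwise: avoids nan from 0 * -inf in the matmul
            term = R[:, :, None] * logF[:, None, :]
        term[np.broadcast_to((R == 0)[:, :, None], term.shape)
             & np.broadcast_to((F == 0)[:, None, :], term.shape)] = 0.0
        return term.sum(axis=0) - F.sum(axis=0)
    return R.T @ np.log(F) - F.sum(axis=0)


def _argmax_random_ties(ll: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise argmax with exact ties broken uniformly at random."""
    m = ll.max(axis=1, keepdims=True)
    ties = ll == m
    k = ties.sum(axis=1)
    r = (rng.random(ll.shape[0]) * k).astype(np.int64)
    cs = np.cumsum(ties, axis=1)
    pick = (cs == (r + 1)[:, None]) & ties
    return pick.argmax(axis=1)


def log_likelihood(counts, tuning) -> np.ndarray:
    """Population log likelihood per class for one trial's counts.

    Parameters
    ----------
    counts : array-like of shape (n_neurons,)
        Observed nonnegative integer spike counts r_i.
    tuning : array-like of shape (n_neurons, n_classes)
        Tuning means f_i(s_j), all shared across the same class set.
    """
    r = np.asarray(counts, dtype=float)
    F = np.asarray(tuning, dtype=float)
    if r.ndim != 1 or F.ndim != 2 or F.shape[0] != r.size:
        raise ValueError(
            f"dimension mismatch: counts {r.shape}, tuning {F.shape}")
    return _loglik_matrix(r[:, None], F)[0]


def decode_trial(loglik, seed=None) -> int:
    """Argmax class of a log-likelihood vector, random on exact ties."""
    ll = np.asarray(loglik, dtype=float)
    if ll.size == 0:
        raise ValueError("empty log-likelihood vector")
    return int(_argmax_random_ties(ll[None, :], _as_rng(seed))[0])


# ---------------------------------------------------------------------------
# tuning estimation

@dataclass
class TuningTable:
    """Estimated per-class mean counts for one neuron (training side)."""

    neuron_id: str
    epoch: str
    class_means: np.ndarray          # (n_classes,)
    floor_applied: np.ndarray        # boolean (n_classes,)
    floor: float = DEFAULT_FLOOR


def estimate_tuning(train_counts: list[np.ndarray], neuron_id: str = "",
                    epoch: str = "", floor: float = DEFAULT_FLOOR
                    ) -> TuningTable:
    """Per-class training means, floored at ``floor`` spikes per window.

    ``train_counts`` holds one array of training-trial counts per class;
    every class needs at least one trial (equalize first).
    """
    means = np.empty(len(train_counts))
    for j, c in enumerate(train_counts):
        c = np.asarray(c, dtype=float)
        if c.size == 0:
            raise ValueError(
                f"class {j} has no training trials; run trial "
                "equalization before tuning estimation")
        means[j] = c.mean()
    floored = means < floor
    return TuningTable(neuron_id=neuron_id, epoch=epoch,
                       class_means=np.maximum(means, floor),
                       floor_applied=floored, floor=floor)


class PoissonPopulationDecoder(ClassifierMixin, BaseEstimator):
    """Sklearn-style independent-Poisson maximum-likelihood classifier.

    Parameters
    ----------
    floor : float
        Minimum per-class tuning mean (spikes per window); guards
        against log(0) for silent training conditions.
    random_state : int or Generator, optional
        Stream for random tie-breaking in :meth:`predict`.

    Attributes
    ----------
    classes_ : ndarray
        Sorted unique class labels seen in ``fit``.
    tuning_ : ndarray of shape (n_neurons, n_classes)
        Floored per-class mean counts.
    floor_applied_ : ndarray of bool, same shape
        Where the floor replaced a smaller training mean.
    """

    def __init__(self, floor: float = DEFAULT_FLOOR, random_state=None):
        self.floor = floor
        self.random_state = random_state

    def fit(self, X, y):
        """Estimate tuning from training counts.

        X is (n_trials, n_neurons) spike counts; y the class label per
        trial. Every class must appear at least once.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_trials, n_neurons) aligned with y")
        if np.any(X < 0):
            raise ValueError("spike counts must be nonnegative")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = self.classes_.size
        means = np.empty((X.shape[1], n_classes))
        for j in range(n_classes):
            means[:, j] = X[y_idx == j].mean(axis=0)
        self.floor_applied_ = means < self.floor
        self.tuning_ = np.maximum(means, self.floor)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """Log likelihood of each class for each trial (factorial dropped)."""
        check_is_fitted(self, "tuning_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError("wrong number of neurons")
        return _loglik_matrix(X.T, self.tuning_)

    def predict(self, X):
        ll = self.decision_function(X)
        idx = _argmax_random_ties(ll, _as_rng(self.random_state))
        return self.classes_[idx]


# ---------------------------------------------------------------------------
# pseudo-population assembly

@dataclass
class Ensemble:
    """Trial-equalized pseudo-population for one epoch.

    ``counts[i, j, t]`` is neuron i's spike count on (real or surrogate)
    trial t of class j; every cell holds exactly ``n_eq`` trials.
    Neurons are treated as statistically independent — trial pairing
    across neurons is arbitrary and is re-randomized per decoding draw.
    """

    counts: np.ndarray               # (n_neurons, n_classes, n_eq) int
    classes: list[tuple]             # (speed, boundary[, direction])
    neuron_ids: list[str]
    epoch: str
    n_eq: int
    trial_filter: str
    reconstructed: np.ndarray        # boolean, same shape as counts
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_classes(self) -> int:
        return self.counts.shape[1]

    @property
    def class_speeds(self) -> np.ndarray:
        return np.asarray([c[0] for c in self.classes])

    @property
    def class_boundaries(self) -> np.ndarray:
        return np.asarray([c[1] for c in self.classes])

    @property
    def class_directions(self) -> np.ndarray | None:
        if len(self.classes[0]) < 3:
            return None
        return np.asarray([c[2] for c in self.classes])

    def reconstructed_fraction(self, by_boundary: bool = True):
        """Fraction of surrogate trials, overall or per boundary."""
        if not by_boundary:
            return float(self.reconstructed.mean())
        out = {}
        for b in np.unique(self.class_boundaries):
            mask = self.class_boundaries == b
            out[str(b)] = float(self.reconstructed[:, mask, :].mean())
        return out

    def subset(self, neuron_idx) -> "Ensemble":
        idx = np.asarray(neuron_idx)
        return Ensemble(
            counts=self.counts[idx], classes=self.classes,
            neuron_ids=[self.neuron_ids[i] for i in idx], epoch=self.epoch,
            n_eq=self.n_eq, trial_filter=self.trial_filter,
            reconstructed=self.reconstructed[idx], excluded=self.excluded)


def _filter_outcomes(counts: pd.DataFrame, trial_filter: str,
                     incorrect_speeds: tuple) -> pd.DataFrame:
    if trial_filter == "all":
        base = counts
    elif trial_filter == "correct_only":
        base = counts[counts["outcome"] == "correct"]
    elif trial_filter == "incorrect_only":
        base = counts[counts["outcome"] == "incorrect"]
    else:
        raise ValueError(f"unknown trial filter {trial_filter!r}")
    if incorrect_speeds:
        swap = counts["speed"].isin(incorrect_speeds)
        base = pd.concat([
            base[~base["speed"].isin(incorrect_speeds)],
            counts[swap & (counts["outcome"] == "incorrect")],
        ])
    return base


def equalize_trials(sessions: list[pd.DataFrame], epoch: str,
                    config: TaskConfig | None = None,
                    n_eq: int = DEFAULT_N_EQ,
                    include_direction: bool = False,
                    trial_filter: str = "correct_only",
                    incorrect_speeds: tuple = (),
                    seed=None) -> Ensemble:
    """Assemble a trial-equalized pseudo-population from session tables.

    For every (neuron, class) cell: more than ``n_eq`` real trials are
    subsampled without replacement to ``n_eq``; fewer are topped up with
    surrogate trials drawn Poisson at the observed class mean. Neurons
    with any empty cell (no real trial after filtering) are excluded with
    a logged reason.

    ``incorrect_speeds`` restricts the listed speeds to incorrect trials
    (all other speeds keep the base filter) — the entry point for
    incorrect-trial decoding of the near-boundary stimuli.
    """
    config = config or TaskConfig()
    rng = _as_rng(seed)
    classes = config.joint_classes(include_direction)
    kept_counts, kept_recon, kept_ids, excluded = [], [], [], []
    for session in sessions:
        neuron_id = str(session["session_id"].iloc[0])
        ec = epoch_counts(session, epoch)
        ec = _filter_outcomes(ec, trial_filter, incorrect_speeds)
        cell = np.empty((len(classes), n_eq), dtype=np.int64)
        recon = np.zeros((len(classes), n_eq), dtype=bool)
        reason = None
        for j, cls in enumerate(classes):
            mask = (ec["speed"] == cls[0]) & (ec["boundary"] == cls[1])
            if include_direction:
                mask &= ec["direction"] == cls[2]
            vals = ec.loc[mask, "spike_count"].to_numpy()
            if vals.size == 0:
                reason = f"no trials for class {cls} after filtering"
                break
            if vals.size >= n_eq:
                cell[j] = rng.choice(vals, size=n_eq, replace=False)
            else:
                deficit = n_eq - vals.size
                cell[j, :vals.size] = vals
                cell[j, vals.size:] = rng.poisson(vals.mean(), size=deficit)
                recon[j, vals.size:] = True
        if reason is not None:
            excluded.append((neuron_id, reason))
            continue
        kept_counts.append(cell)
        kept_recon.append(recon)
        kept_ids.append(neuron_id)
    if not kept_counts:
        raise ValueError(
            "no neurons survived equalization: "
            + "; ".join(f"{n}: {r}" for n, r in excluded[:5]))
    return Ensemble(counts=np.stack(kept_counts),
                    classes=classes, neuron_ids=kept_ids, epoch=epoch,
                    n_eq=n_eq, trial_filter=trial_filter,
                    reconstructed=np.stack(kept_recon), excluded=excluded)


# ---------------------------------------------------------------------------
# cross-validated decoding

@dataclass
class DecodeReport:
    """Aggregated decoding accuracies over train/test draws."""

    classes: list[tuple]
    n_draws: int
    n_eq: int
    scheme: str
    trial_filter: str
    joint_accuracy: float
    speed_accuracy: float
    boundary_accuracy: float
    direction_accuracy: float | None
    per_class: pd.DataFrame
    draw_joint: np.ndarray
    draw_speed: np.ndarray
    draw_boundary: np.ndarray
    chance: dict[str, float]

    def sem(self, which: str = "speed") -> float:
        """Standard error of the across-draw mean accuracy."""
        draws = {"joint": self.draw_joint, "speed": self.draw_speed,
                 "boundary": self.draw_boundary}[which]
        return float(np.std(draws, ddof=1) / np.sqrt(draws.size))

    def to_dict(self) -> dict:
        return {
            "n_draws": self.n_draws, "n_eq": self.n_eq,
            "scheme": self.scheme, "trial_filter": self.trial_filter,
            "joint_accuracy": self.joint_accuracy,
            "speed_accuracy": self.speed_accuracy,
            "boundary_accuracy": self.boundary_accuracy,
            "direction_accuracy": self.direction_accuracy,
            "speed_accuracy_sem": self.sem("speed"),
            "boundary_accuracy_sem": self.sem("boundary"),
            "chance": self.chance,
            "per_class": self.per_class.to_dict(orient="records"),
        }


def _single_draw(counts: np.ndarray, rng: np.random.Generator,
                 floor: float, scheme: str):
    """One train/test draw. Returns (true class idx, predicted class idx)
    for every test trial."""
    perm = rng.permuted(counts, axis=2)
    n_neurons, n_classes, n_eq = perm.shape
    if scheme == "train_one":
        # train on one randomly selected trial per class, test on n-1
        F = np.maximum(perm[:, :, 0].astype(float), floor)
        test = perm[:, :, 1:]
        n_test = n_eq - 1
        R = test.reshape(n_neurons, n_classes * n_test)
        ll = _loglik_matrix(R.astype(float), F)
        pred = _argmax_random_ties(ll, rng)
        # reshape is class-major along axis 1, so true labels repeat per class
        true = np.repeat(np.arange(n_classes), n_test)
        return true, pred
    if scheme == "loo":
        trues, preds = [], []
        total = perm.astype(float).sum(axis=2)
        for t in range(n_eq):
            train_mean = (total - perm[:, :, t]) / (n_eq - 1)
            F = np.maximum(train_mean, floor)
            R = perm[:, :, t].astype(float)
            ll = _loglik_matrix(R, F)
            preds.append(_argmax_random_ties(ll, rng))
            trues.append(np.arange(n_classes))
        return np.concatenate(trues), np.concatenate(preds)
    raise ValueError(f"unknown cross-validation scheme {scheme!r}")


def cross_validated_accuracy(ensemble: Ensemble,
                             n_draws: int = DEFAULT_N_DRAWS,
                             scheme: str = "train_one",
                             floor: float = DEFAULT_FLOOR,
                             seed=None) -> DecodeReport:
    """Decoding accuracy over repeated random train/test draws.

    Per draw the trial pairing across neurons is re-randomized within
    each class; the decoder is trained on one randomly selected trial per
    (neuron, class) (``scheme="train_one"``) or on the n-1 complement
    (``scheme="loo"``) and evaluated on the held-out trials. Reports the
    joint accuracy and the speed/boundary (and direction, for 32-class
    ensembles) marginals: a marginal is correct when that component of
    the joint argmax matches the true class.
    """
    if ensemble.n_eq < 2:
        raise ValueError("n_eq must be >= 2 to hold out test trials")
    rng = _as_rng(seed)
    J = ensemble.n_classes
    speeds = ensemble.class_speeds
    bounds = ensemble.class_boundaries
    dirs = ensemble.class_directions

    joint_hits = np.zeros(J)
    speed_hits = np.zeros(J)
    bound_hits = np.zeros(J)
    dir_hits = np.zeros(J) if dirs is not None else None
    n_tested = np.zeros(J)
    draw_joint = np.empty(n_draws)
    draw_speed = np.empty(n_draws)
    draw_bound = np.empty(n_draws)

    for d in range(n_draws):
        true, pred = _single_draw(ensemble.counts, rng, floor, scheme)
        j_ok = pred == true
        s_ok = speeds[pred] == speeds[true]
        b_ok = bounds[pred] == bounds[true]
        np.add.at(joint_hits, true, j_ok)
        np.add.at(speed_hits, true, s_ok)
        np.add.at(bound_hits, true, b_ok)
        if dirs is not None:
            np.add.at(dir_hits, true, dirs[pred] == dirs[true])
        np.add.at(n_tested, true, 1)
        draw_joint[d] = j_ok.mean()
        draw_speed[d] = s_ok.mean()
        draw_bound[d] = b_ok.mean()

    per_class = pd.DataFrame({
        "speed": speeds, "boundary": bounds,
        "joint_accuracy": joint_hits / n_tested,
        "speed_accuracy": speed_hits / n_tested,
        "boundary_accuracy": bound_hits / n_tested,
    })
    if dirs is not None:
        per_class["direction"] = dirs
        per_class["direction_accuracy"] = dir_hits / n_tested
    chance = {"speed": 1.0 / np.unique(speeds).size,
              "boundary": 1.0 / np.unique(bounds).size}
    if dirs is not None:
        chance["direction"] = 1.0 / np.unique(dirs).size
    return DecodeReport(
        classes=ensemble.classes, n_draws=n_draws, n_eq=ensemble.n_eq,
        scheme=scheme, trial_filter=ensemble.trial_filter,
        joint_accuracy=float(draw_joint.mean()),
        speed_accuracy=float(draw_speed.mean()),
        boundary_accuracy=float(draw_bound.mean()),
        direction_accuracy=(float((dir_hits / n_tested).mean())
                            if dirs is not None else None),
        per_class=per_class, draw_joint=draw_joint, draw_speed=draw_speed,
        draw_boundary=draw_bound, chance=chance)


def normalized_accuracy(accuracy: float, chance: float) -> float:
    """Chance-normalized accuracy (acc - chance) / (1 - chance):
    0 at chance, 1 at perfect."""
    return (accuracy - chance) / (1.0 - chance)


def accuracy_vs_population_size(ensemble: Ensemble, sizes,
                                n_draws: int = 200,
                                scheme: str = "train_one",
                                floor: float = DEFAULT_FLOOR,
                                seed=None) -> pd.DataFrame:
    """Chance-normalized accuracy as a function of ensemble size.

    For each size N a random subset of N neurons (without replacement) is
    drawn per train/test draw; reported accuracies are means over draws,
    normalized by (acc - chance) / (1 - chance).
    """
    rng = _as_rng(seed)
    sizes = list(sizes)
    if any(n < 2 or n > ensemble.n_neurons for n in sizes):
        raise ValueError(
            f"sizes must lie in [2, {ensemble.n_neurons}]")
    speeds = ensemble.class_speeds
    bounds = ensemble.class_boundaries
    chance_s = 1.0 / np.unique(speeds).size
    chance_b = 1.0 / np.unique(bounds).size
    rows = []
    for n in sizes:
        acc_s = np.empty(n_draws)
        acc_b = np.empty(n_draws)
        for d in range(n_draws):
            idx = rng.choice(ensemble.n_neurons, size=n, replace=False)
            true, pred = _single_draw(ensemble.counts[idx], rng, floor,
                                      scheme)
            acc_s[d] = (speeds[pred] == speeds[true]).mean()
            acc_b[d] = (bounds[pred] == bounds[true]).mean()
        rows.append({
            "n_neurons": n,
            "speed_accuracy": acc_s.mean(),
            "boundary_accuracy": acc_b.mean(),
            "speed_accuracy_sem": acc_s.std(ddof=1) / np.sqrt(n_draws),
            "boundary_accuracy_sem": acc_b.std(ddof=1) / np.sqrt(n_draws),
            "speed_normalized": normalized_accuracy(acc_s.mean(), chance_s),
            "boundary_normalized": normalized_accuracy(acc_b.mean(),
                                                       chance_b),
        })
    return pd.DataFrame(rows)


def llr_pair_discrimination(ensemble: Ensemble,
                            pairs=NEIGHBOR_PAIRS,
                            config: TaskConfig | None = None,
                            n_draws: int = DEFAULT_N_DRAWS,
                            floor: float = DEFAULT_FLOOR,
                            seed=None) -> pd.DataFrame:
    """Pairwise neighboring-speed discrimination via the log-likelihood
    ratio, separately per boundary.

    For each pair (s1, s2) the decoder computes
    log LR = log L(s1) - log L(s2) on held-out trials under the same
    train-on-one scheme and selects s1 when LR > 0, s2 when LR < 0
    (LR = 0 broken at random). A pair is tagged "inter" under the
    boundary whose reference speed lies between the two members (the
    stimuli fall in different categories) and "intra" otherwise.
    """
    config = config or TaskConfig()
    rng = _as_rng(seed)
    class_index = {c: j for j, c in enumerate(ensemble.classes)}
    if ensemble.class_directions is not None:
        raise ValueError("pair discrimination expects a 16-class ensemble")
    rows = []
    for s1, s2 in pairs:
        for boundary in config.boundaries:
            key1, key2 = (s1, boundary), (s2, boundary)
            if key1 not in class_index or key2 not in class_index:
                continue
            sub = ensemble.counts[:, [class_index[key1],
                                      class_index[key2]], :]
            acc = np.empty(n_draws)
            for d in range(n_draws):
                perm = rng.permuted(sub, axis=2)
                F = np.maximum(perm[:, :, 0].astype(float), floor)
                test = perm[:, :, 1:]
                n_test = test.shape[2]
                R = test.reshape(ensemble.n_neurons, 2 * n_test).astype(float)
                ll = _loglik_matrix(R, F)
                lr = ll[:, 0] - ll[:, 1]
                pick_s1 = np.where(lr == 0, rng.random(lr.size) < 0.5,
                                   lr > 0)
                true_is_s1 = np.tile([[True], [False]],
                                     (1, n_test)).reshape(-1)
                acc[d] = (pick_s1 == true_is_s1).mean()
            ref = config.boundary_cues[boundary]
            tag = "inter" if min(s1, s2) < ref < max(s1, s2) else "intra"
            rows.append({"s1": s1, "s2": s2, "boundary": boundary,
                         "accuracy": acc.mean(),
                         "accuracy_sem": acc.std(ddof=1) / np.sqrt(n_draws),
                         "category": tag})
    return pd.DataFrame(rows)


def direction_decoding(ensemble: Ensemble,
                       n_draws: int = DEFAULT_N_DRAWS,
                       scheme: str = "train_one",
                       floor: float = DEFAULT_FLOOR,
                       seed=None) -> DecodeReport:
    """Joint decoding over the 32 direction-augmented classes.

    The reported statistic of interest is the per-stimulus accuracy of
    the direction margin (up vs down), available per class in
    ``per_class["direction_accuracy"]``.
    """
    if ensemble.class_directions is None:
        raise ValueError("direction decoding requires an ensemble built "
                         "with include_direction=True (32 classes)")
    counts = pd.Series(ensemble.class_directions).value_counts()
    if counts.nunique() != 1:
        raise ValueError("directions unbalanced across classes")
    return cross_validated_accuracy(ensemble, n_draws=n_draws,
                                    scheme=scheme, floor=floor, seed=seed)


def incorrect_trial_decoding(sessions: list[pd.DataFrame], epoch: str,
                             config: TaskConfig | None = None,
                             speeds: tuple = (6.0, 12.0),
                             n_eq: int = DEFAULT_N_EQ,
                             n_draws: int = DEFAULT_N_DRAWS,
                             scheme: str = "train_one",
                             floor: float = DEFAULT_FLOOR,
                             seed=None) -> dict:
    """Compare decoding of near-boundary speeds on incorrect vs correct
    trials.

    Two ensembles are decoded: one equalized from correct trials only,
    and one in which the listed speeds draw from incorrect trials while
    all other classes keep correct trials. Reported accuracies are the
    marginal speed accuracies restricted to the listed speeds.
    """
    config = config or TaskConfig()
    rng = _as_rng(seed)
    s1, s2 = np.random.SeedSequence(rng.integers(2**31)).spawn(2)
    correct = equalize_trials(sessions, epoch, config, n_eq=n_eq,
                              trial_filter="correct_only", seed=s1)
    try:
        incorrect = equalize_trials(sessions, epoch, config, n_eq=n_eq,
                                    trial_filter="correct_only",
                                    incorrect_speeds=tuple(speeds), seed=s2)
    except ValueError as err:
        raise ValueError(
            f"cannot build incorrect-trial ensemble for speeds {speeds}: "
            f"{err}. Generate more trials or choose speeds with a higher "
            "error rate (near-boundary speeds 6 and 12)") from err
    rep_c = cross_validated_accuracy(correct, n_draws=n_draws,
                                     scheme=scheme, floor=floor, seed=rng)
    rep_i = cross_validated_accuracy(incorrect, n_draws=n_draws,
                                     scheme=scheme, floor=floor, seed=rng)

    def _subset_acc(rep: DecodeReport) -> float:
        pc = rep.per_class
        return float(pc.loc[pc["speed"].isin(speeds),
                            "speed_accuracy"].mean())

    return {
        "correct_report": rep_c,
        "incorrect_report": rep_i,
        "speeds": tuple(speeds),
        "correct_speed_accuracy": _subset_acc(rep_c),
        "incorrect_speed_accuracy": _subset_acc(rep_i),
    }
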