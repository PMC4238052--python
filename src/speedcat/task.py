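"""Task design: stimulus grid, category boundaries, epochs, trial types.

The behavioral task is a two-boundary speed categorization: random-dot
stimuli drift at one of 8 speeds (2, 4, ..., 16 deg/s) and the subject
classifies each as "slow" or "fast" relative to a cued reference speed
(5 deg/s for the slow boundary, 13 deg/s for the fast one). Direction of
motion (up/down) and the spatial location of the two choice targets are
task-irrelevant and counterbalanced, giving 8 x 2 x 2 x 2 = 64 trial
types per block.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when a task configuration violates its invariants."""


#: Analysis epochs with (alignment, duration ms). Baseline is the 400 ms
#: fixation period; post_saccade and reward are aligned to saccade and
#: reward onset respectively.
DEFAULT_EPOCHS: dict[str, tuple[str, float]] = {
    "baseline": ("fixation", 400.0),
    "cue": ("cue_onset", 700.0),
    "decision": ("stimulus_onset", 800.0),
    "post_saccade": ("saccade_onset", 400.0),
    "reward": ("reward_onset", 600.0),
}

#: Epochs that exist only on completed (non-aborted) trials.
POST_DECISION_EPOCHS = ("post_saccade", "reward")

#: The seven pairs of neighboring speeds used for pairwise discrimination.
NEIGHBOR_PAIRS: tuple[tuple[float, float], ...] = (
    (2.0, 4.0), (4.0, 6.0), (6.0, 8.0), (8.0, 10.0),
    (10.0, 12.0), (12.0, 14.0), (14.0, 16.0),
)

#: Near-boundary pairs and the boundary each straddles.
STRADDLE_PAIRS: dict[tuple[float, float], str] = {
    (4.0, 6.0): "slow",   # straddles the slow cue at 5 deg/s
    (12.0, 14.0): "fast",  # straddles the fast cue at 13 deg/s
}


@dataclass(frozen=True)
class TaskConfig:
    """Immutable description of the categorization task design.

    Parameters
    ----------
    speeds
        Strictly increasing stimulus speeds in deg/s.
    boundary_cues
        Map boundary label -> reference speed in deg/s. Each reference
        must fall strictly inside the speed range so that both categories
        are non-empty under either cue.
    directions, target_locations
        Task-irrelevant counterbalanced factors.
    epoch_windows
        Map epoch -> (alignment event, duration ms).
    fixation_break_rate
        Probability that a trial is aborted during the decision period
        without a choice.
    """

    speeds: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0)
    boundary_cues: dict[str, float] = field(
        default_factory=lambda: {"slow": 5.0, "fast": 13.0})
    directions: tuple[str, ...] = ("up", "down")
    target_locations: tuple[str, ...] = ("in_rf", "opposite_rf")
    epoch_windows: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_EPOCHS))
    fixation_break_rate: float = 0.13

    def __post_init__(self) -> None:
        if len(self.speeds) == 0 or len(self.boundary_cues) == 0:
            raise ConfigurationError("speeds and boundary_cues must be non-empty")
        if any(b >= a for a, b in zip(self.speeds[1:], self.speeds)):
            raise ConfigurationError("speeds must be strictly increasing")
        lo, hi = self.speeds[0], self.speeds[-1]
        for label, ref in self.boundary_cues.items():
            if not lo < ref < hi:
                raise ConfigurationError(
                    f"boundary cue {label!r} at {ref} deg/s lies outside "
                    f"the open speed range ({lo}, {hi})")
        if not 0.0 <= self.fixation_break_rate <= 1.0:
            raise ConfigurationError("fixation_break_rate must be in [0, 1]")
        for epoch, (_, dur) in self.epoch_windows.items():
            if dur <= 0:
                raise ConfigurationError(f"epoch {epoch!r} duration must be > 0")

    @property
    def boundaries(self) -> tuple[str, ...]:
        return tuple(self.boundary_cues)

    @property
    def trials_per_block(self) -> int:
        """Number of distinct trial types (64 under the default design)."""
        return (len(self.speeds) * len(self.boundary_cues)
                * len(self.directions) * len(self.target_locations))

    def trial_types(self) -> list[tuple[float, str, str, str]]:
        """Enumerate (speed, boundary, direction, target_location) types."""
        return list(itertools.product(
            self.speeds, self.boundaries, self.directions,
            self.target_locations))

    def joint_classes(self, include_direction: bool = False) -> list[tuple]:
        """Decoding classes: (speed, boundary) or (speed, boundary, direction).

        Class order follows the convention speed-major within boundary:
        indices 1..8 are the 8 speeds under the slow boundary, 9..16 under
        the fast boundary; with direction the 16-block repeats for up then
        down within each boundary (32 classes total).
        """
        if include_direction:
            return [(s, b, d) for b in self.boundaries
                    for d in self.directions for s in self.speeds]
        return [(s, b) for b in self.boundaries for s in self.speeds]

    def correct_choice(self, speed: float, boundary: str) -> str:
        """The rewarded choice: 'fast' iff speed exceeds the cued reference."""
        return "fast" if speed > self.boundary_cues[boundary] else "slow"

    def epoch_duration_s(self, epoch: str) -> float:
        """Epoch window length in seconds (for count -> rate conversion)."""
        return self.epoch_windows[epoch][1] / 1000.0
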