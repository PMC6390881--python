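"""Adaptive titration procedures holding 2AFC accuracy near 75% correct.

Two procedures are provided:

* :class:`BrightnessStaircase` — two interleaved, weighted staircases on
  stimulus brightness (integer steps on a 128–256 scale).  Rule 1
  decreases brightness by 2 steps once two consecutive correct
  responses have accumulated; rule 2 decreases by 3 steps once three
  consecutive correct responses have accumulated.  Either rule
  increases brightness by 4 steps after an incorrect response.  The
  rules strictly alternate trial by trial and each keeps its own streak
  counter.  Crucially the counter is *not* reset to zero after a
  decrease fires: once a rule's streak has reached its quota, every
  further correct response in the streak triggers another decrease.
  An incorrect response breaks the streak.  This non-standard variant
  converges near 73–75% correct (a classical weighted 2-down/1-up with
  these step sizes would settle near 80%).

* :class:`SetSizeStaircase` — block-wise adjustment of the memory
  encoding set size from the mean accuracy of the previous two blocks:
  +1 item above 75% correct, −1 item below 70%, unchanged in between.
  The displayed set size is floored at 2 items while the underlying
  staircase value is unbounded below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "BrightnessStaircase",
    "SetSizeStaircase",
    "TitrationResult",
    "brightness_update",
    "setsize_update",
    "run_titration",
]

BRIGHTNESS_MIN = 128
BRIGHTNESS_MAX = 256

#: (streak quota, decrease step) for the two interleaved rules
_RULES = ((2, 2), (3, 3))
_UP_STEP = 4


@dataclass
class BrightnessStaircase:
    """State of the interleaved weighted brightness staircase."""

    level: int = 192
    active_rule: int = 1  # 1-based index of the rule acting on the next trial
    streaks: list[int] = field(default_factory=lambda: [0, 0])
    history: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not BRIGHTNESS_MIN <= self.level <= BRIGHTNESS_MAX:
            raise ValueError(f"brightness {self.level} outside [{BRIGHTNESS_MIN}, {BRIGHTNESS_MAX}]")
        if self.active_rule not in (1, 2):
            raise ValueError("active_rule must be 1 or 2")

    def update(self, accuracy: int) -> "BrightnessStaircase":
        """Apply the active rule to one trial outcome and alternate rules."""
        if accuracy not in (0, 1):
            raise ValueError("accuracy must be 0 or 1")
        r = self.active_rule - 1
        quota, down = _RULES[r]
        self.history.append((self.level, accuracy))
        if accuracy:
            self.streaks[r] += 1
            if self.streaks[r] >= quota:
                self.level -= down
        else:
            self.streaks[r] = 0
            self.level += _UP_STEP
        self.level = int(min(max(self.level, BRIGHTNESS_MIN), BRIGHTNESS_MAX))
        self.active_rule = 2 if self.active_rule == 1 else 1
        return self


@dataclass
class SetSizeStaircase:
    """Block-wise set-size staircase for the recognition-memory task.

    ``value`` is the underlying (unbounded below) staircase value;
    ``displayed`` is the set size actually shown, floored at 2 images.
    """

    value: float = 4.0
    floor: int = 2
    block_accuracies: list[float] = field(default_factory=list)

    @property
    def displayed(self) -> int:
        return max(self.floor, int(round(self.value)))

    def record_block(self, accuracy: float) -> "SetSizeStaircase":
        """Record a block mean accuracy and adjust the set size.

        The update uses the mean over the previous two blocks and is a
        no-op until two block means are available.
        """
        self.block_accuracies.append(float(accuracy))
        if len(self.block_accuracies) >= 2:
            m = float(np.mean(self.block_accuracies[-2:]))
            if m > 0.75:
                self.value += 1
            elif m < 0.70:
                self.value -= 1
        return self


def brightness_update(state: BrightnessStaircase, accuracy: int) -> BrightnessStaircase:
    """Functional wrapper around :meth:`BrightnessStaircase.update`."""
    return state.update(accuracy)


def setsize_update(state: SetSizeStaircase, block_accuracies: list[float]) -> SetSizeStaircase:
    """Apply the set-size rule given the last (up to two) block means.

    No-op unless two block means are supplied.
    """
    if len(block_accuracies) < 2:
        return state
    m = float(np.mean(block_accuracies[-2:]))
    if m > 0.75:
        state.value += 1
    elif m < 0.70:
        state.value -= 1
    return state


@dataclass(frozen=True)
class TitrationResult:
    """Outcome of a closed-loop titration run."""

    final_level: int
    percent_correct: float
    levels: np.ndarray
    correct: np.ndarray


def run_titration(
    params,
    n_trials: int,
    rng: np.random.Generator | None = None,
    start_level: int = BRIGHTNESS_MAX,
    accuracy_fn: Callable[[float], float] | None = None,
) -> TitrationResult:
    """Closed-loop titration of a simulated observer.

    Parameters
    ----------
    params
        :class:`~metacog.observers.ObserverParams` describing the
        observer (ignored when ``accuracy_fn`` is given).
    n_trials
        Number of titration trials (at least 60, the length of the
        initial titration block).
    accuracy_fn
        Optional override mapping brightness level to expected accuracy
        (used e.g. to probe untitratable flat observers).

    Returns
    -------
    TitrationResult
        Final brightness, realised proportion correct over all trials,
        and the per-trial level trajectory and outcomes.
    """
    from .observers import psychometric_accuracy  # local import, no cycle at runtime

    if n_trials < 60:
        raise ValueError("titration requires at least the 60-trial initial block")
    if rng is None:
        rng = np.random.default_rng(getattr(params, "seed", 0))
    stair = BrightnessStaircase(level=start_level)
    acc_of = accuracy_fn or (lambda lvl: psychometric_accuracy(params, lvl, "perception"))
    levels = np.empty(n_trials, dtype=int)
    correct = np.empty(n_trials, dtype=int)
    u = rng.random(n_trials)
    for i in range(n_trials):
        levels[i] = stair.level
        acc = int(u[i] < acc_of(stair.level))
        correct[i] = acc
        stair.update(acc)
    return TitrationResult(stair.level, float(correct.mean()), levels, correct)
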