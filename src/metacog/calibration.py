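"""Quadratic-scoring-rule calibration and the two feedback point schedules.

The experimental feedback schedule scores metacognitive calibration with
the quadratic scoring rule (QSR), a proper scoring rule equal to one
minus the Brier score: confidence ratings 1–4 are mapped linearly onto a
subjective probability correct, p = -1/3 + confidence/3, and each trial
scores 1 - (accuracy - p)^2.  The control schedule scores achieved task
difficulty, the inverse distance of the staircase brightness from its
minimum: difficulty = 128 - (brightness - 128).

Block scores (means over 27-trial feedback blocks) are converted to
reward points through a Gaussian CDF fitted to a feedback-free pilot
distribution of block scores, which equates the points distribution
across the two feedback types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import norm

__all__ = [
    "BlockScore",
    "PointsMap",
    "confidence_to_prob",
    "qsr_trial",
    "brightness_to_difficulty",
    "fit_points_map",
    "score_to_points",
    "block_scores",
]

BLOCK_LENGTH = 27


def confidence_to_prob(confidence):
    """Map a 1–4 confidence rating to subjective p(correct) = -1/3 + confidence/3."""
    conf = np.asarray(confidence)
    if not np.isin(conf, (1, 2, 3, 4)).all():
        raise ValueError("confidence ratings must be integers in 1..4")
    p = -1.0 / 3.0 + conf / 3.0
    return float(p) if np.isscalar(confidence) else p


def qsr_trial(accuracy, confidence):
    """Single-trial quadratic scoring rule: 1 - (accuracy - p(correct))^2.

    Maximal (1.0) for a confident correct response or an unconfident
    error; one minus the Brier score of the implied probability report.
    """
    acc = np.asarray(accuracy)
    if not np.isin(acc, (0, 1)).all():
        raise ValueError("accuracy must be 0 or 1")
    p = confidence_to_prob(confidence)
    s = 1.0 - (acc - p) ** 2
    return float(s) if np.isscalar(accuracy) else s


def brightness_to_difficulty(brightness):
    """Difficulty level 128 - (brightness - 128), mapping [128, 256] onto [128, 0]."""
    b = np.asarray(brightness, dtype=float)
    if ((b < 128) | (b > 256)).any():
        raise ValueError("brightness must lie in [128, 256]")
    d = 128.0 - (b - 128.0)
    return float(d) if np.isscalar(brightness) else d


@dataclass(frozen=True)
class BlockScore:
    """Feedback-block summary: mean QSR, mean difficulty and awarded points."""

    block: int
    mean_qsr: float
    mean_difficulty: float
    points: int | None = None


@dataclass(frozen=True)
class PointsMap:
    """Gaussian-CDF transform from a block score to reward points.

    ``mu``/``sigma`` are the maximum-likelihood Gaussian parameters of a
    pilot distribution of block scores; points = round(max_points * Phi((s - mu)/sigma)),
    which sends the pilot median to half the maximum.
    """

    mu: float
    sigma: float
    max_points: int = 100

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


def fit_points_map(pilot_block_scores, max_points: int = 100) -> PointsMap:
    """ML Gaussian fit to a pilot distribution of block-level scores."""
    s = np.asarray(pilot_block_scores, dtype=float)
    if s.size < 10:
        raise ValueError("need at least 10 pilot block scores")
    mu, sigma = norm.fit(s)
    if sigma <= 1e-12:
        raise ValueError("pilot scores have zero variance")
    return PointsMap(mu=float(mu), sigma=float(sigma), max_points=max_points)


def score_to_points(score, points_map: PointsMap):
    """Transform a block score into points through the fitted Gaussian CDF."""
    if not isinstance(points_map, PointsMap):
        raise TypeError("points_map must be a fitted PointsMap")
    s = np.asarray(score, dtype=float)
    pts = np.rint(points_map.max_points * ndtr((s - points_map.mu) / points_map.sigma))
    return int(pts) if np.isscalar(score) else pts.astype(int)


def block_scores(
    trials: pd.DataFrame,
    points_map: PointsMap | None = None,
    feedback: str = "qsr",
    block_length: int = BLOCK_LENGTH,
) -> list[BlockScore]:
    """Per-block feedback scores for one session of trials.

    ``trials`` needs columns accuracy, confidence and (for difficulty)
    stimulus_level; blocks are consecutive runs of ``block_length``
    trials in the given order.
    """
    if feedback not in ("qsr", "difficulty"):
        raise ValueError("feedback must be 'qsr' or 'difficulty'")
    out: list[BlockScore] = []
    n_blocks = len(trials) // block_length
    for b in range(n_blocks):
        chunk = trials.iloc[b * block_length : (b + 1) * block_length]
        mq = float(np.mean(qsr_trial(chunk.accuracy.to_numpy(), chunk.confidence.to_numpy())))
        md = float(np.mean(brightness_to_difficulty(chunk.stimulus_level.to_numpy()))) if (
            "stimulus_level" in chunk and feedback == "difficulty"
        ) else float("nan")
        score = mq if feedback == "qsr" else md
        pts = score_to_points(score, points_map) if points_map is not None else None
        out.append(BlockScore(block=b + 1, mean_qsr=mq, mean_difficulty=md, points=pts))
    return out
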