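"""Decision scoring: type I/II errors, EER, ROC, noise robustness.

Following the verification protocol: a type I error misclassifies a
selection gaze (TP-class) as non-gazing, a type II error misclassifies
a non-gazing episode (TN-class) as a selection. The decision rule is
strict (selected iff score > threshold). The EER sweep tries every
distinct score as a threshold, picks the one where the two error rates
are most similar (ties to the lower threshold), and averages them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateEvaluationError

__all__ = [
    "LabeledScore",
    "EERResult",
    "error_rates",
    "compute_eer",
    "roc_curve",
    "noise_experiment",
]


@dataclass(frozen=True)
class LabeledScore:
    """A fuzzy output score with its ground-truth class (1 = gazing/TP-class)."""

    score: float
    truth: int


def _split(scores: Sequence[LabeledScore]) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([s.score for s in scores if s.truth == 1])
    neg = np.array([s.score for s in scores if s.truth == 0])
    if pos.size == 0 or neg.size == 0:
        raise DegenerateEvaluationError("degenerate evaluation set: need both classes")
    return pos, neg


def error_rates(scores: Sequence[LabeledScore], threshold: float) -> tuple[float, float]:
    """(type I %, type II %) at a threshold under the strict decision rule."""
    pos, neg = _split(scores)
    type1 = 100.0 * float(np.mean(pos <= threshold))
    type2 = 100.0 * float(np.mean(neg > threshold))
    return type1, type2


@dataclass(frozen=True)
class EERResult:
    threshold: float
    type1_pct: float
    type2_pct: float
    eer_pct: float


def compute_eer(scores: Sequence[LabeledScore]) -> EERResult:
    """Sweep all distinct scores as thresholds; EER = mean error at the
    threshold where |type I - type II| is smallest (lower threshold on ties)."""
    _split(scores)  # validate both classes present
    thresholds = np.unique([s.score for s in scores])
    best = None
    for t in thresholds:  # ascending; strict < keeps the lowest tie
        t1, t2 = error_rates(scores, float(t))
        gap = abs(t1 - t2)
        if best is None or gap < best[0] - 1e-12:
            best = (gap, float(t), t1, t2)
    gap, t, t1, t2 = best
    return EERResult(threshold=t, type1_pct=round(t1, 2), type2_pct=round(t2, 2), eer_pct=round((t1 + t2) / 2.0, 2))


def roc_curve(scores: Sequence[LabeledScore]) -> list[tuple[float, float]]:
    """ROC points (100 - type II %, type I %), one per distinct threshold.

    Sorted by ascending threshold, with the everything-selected and
    nothing-selected extremes included, so the curve spans (0, 0) to
    (100, 100).
    """
    pos, neg = _split(scores)
    all_scores = np.unique([s.score for s in scores])
    thresholds = np.concatenate([[all_scores[0] - 1.0], all_scores])
    points = []
    for t in thresholds:
        t1, t2 = error_rates(scores, float(t))
        points.append((100.0 - t2, t1))
    return points


def noise_experiment(
    session,
    sigmas: Sequence[float],
    seed: int = 0,
    n_reps: int = 1,
    pipeline_kwargs: dict | None = None,
) -> dict[float, float]:
    """EER after Gaussian perturbation of detected pupil size and gaze.

    For each sigma, the session's pupil-size series is perturbed with
    zero-mean Gaussian noise of that standard deviation (area pixels)
    and the gaze trace with the same sigma per coordinate (monitor
    pixels); features and fuzzy scores are recomputed and the EER
    measured, averaged over ``n_reps`` seeded replicates.
    """
    from .pipeline import score_session  # local import to avoid a cycle

    kwargs = pipeline_kwargs or {}
    out: dict[float, float] = {}
    for si, sigma in enumerate(sigmas):
        eers = []
        for rep in range(n_reps):
            rng = np.random.default_rng(seed + 7919 * si + rep)
            noisy = _perturb_session(session, sigma, rng)
            scored = score_session(noisy, **kwargs)
            eers.append(compute_eer(scored).eer_pct)
        out[float(sigma)] = float(np.mean(eers))
    return out


def _perturb_session(session, sigma: float, rng: np.random.Generator):
    from copy import copy

    noisy = copy(session)
    if sigma > 0:
        noisy.pupil_sizes = np.maximum(
            1.0, session.pupil_sizes + rng.normal(0.0, sigma, session.pupil_sizes.shape)
        )
        noisy.gaze = session.gaze + rng.normal(0.0, sigma, session.gaze.shape)
    else:
        noisy.pupil_sizes = session.pupil_sizes.copy()
        noisy.gaze = session.gaze.copy()
    return noisy
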