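"""Mamdani-style fuzzy fusion of the three selection features.

Each normalized feature (after inverting Features 1 and 2 so that
"high" always means "selection-like") gets two linear membership
functions, Low and High:

    muL(x) = 1 on [0, aL], falls linearly to 0 on [aL, bL], 0 after
    muH(x) = 0 on [0, aH], rises linearly to 1 on [aH, bH], 1 after

The ramp endpoints are fitted from labeled feature distributions by a
maximum-entropy criterion: with class masses
p_L = sum_x m_L(x) muL(x) and p_H = sum_x m_H(x) muH(x), the entropy
-p_L log p_L - p_H log p_H is maximized over a grid of (a, b) pairs.

The eight L/H label combinations fire through a fixed rule table; each
rule's inference value (IV) is the MIN (or MAX) of its three member
degrees. IVs aggregate per output label (L/M/H triangular-ramp output
sets on [0, 1]) by maximum, and a defuzzifier (FOM / MOM / LOM / COG /
BOA) reduces the clipped union to one score. The score is compared
against a threshold (strict inequality) to decide target selection.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateFeatureRangeError,
    NonOverlappingRampsError,
)

__all__ = [
    "FeatureVector",
    "RampPair",
    "MembershipParams",
    "RULE_TABLE",
    "InferenceValue",
    "OutputMFs",
    "normalize_features",
    "eval_membership",
    "fit_membership_entropy",
    "infer_ivs",
    "defuzzify",
    "decide",
    "fuzzy_score",
]

#: Rule base: antecedent labels of (feature 1, feature 2, feature 3) -> output label.
RULE_TABLE: Mapping[tuple[str, str, str], str] = {
    ("L", "L", "L"): "L",
    ("L", "L", "H"): "L",
    ("L", "H", "L"): "M",
    ("L", "H", "H"): "H",
    ("H", "L", "L"): "L",
    ("H", "L", "H"): "M",
    ("H", "H", "L"): "H",
    ("H", "H", "H"): "H",
}

#: Canonical enumeration order of the eight antecedent combinations.
COMBINATIONS: tuple[tuple[str, str, str], ...] = tuple(itertools.product("LH", repeat=3))


@dataclass(frozen=True)
class FeatureVector:
    """Normalized (f1, f2, f3) in [0,1]^3; f1/f2 already inverted (high = selection-like)."""

    f1: float
    f2: float
    f3: float

    def __post_init__(self) -> None:
        for name in ("f1", "f2", "f3"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def __iter__(self):
        return iter((self.f1, self.f2, self.f3))


@dataclass(frozen=True)
class RampPair:
    """L and H ramp endpoints for one feature; slopes/intercepts follow by continuity."""

    a_low: float
    b_low: float
    a_high: float
    b_high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.a_low < self.b_low <= 1.0):
            raise ValueError("need 0 <= aL < bL <= 1")
        if not (0.0 <= self.a_high < self.b_high <= 1.0):
            raise ValueError("need 0 <= aH < bH <= 1")

    # Continuity fixes the linear pieces: pL*aL+qL = 1, pL*bL+qL = 0 (pL < 0)
    # and pH*aH+qH = 0, pH*bH+qH = 1 (pH > 0).
    @property
    def p_low(self) -> float:
        return -1.0 / (self.b_low - self.a_low)

    @property
    def q_low(self) -> float:
        return self.b_low / (self.b_low - self.a_low)

    @property
    def p_high(self) -> float:
        return 1.0 / (self.b_high - self.a_high)

    @property
    def q_high(self) -> float:
        return -self.a_high / (self.b_high - self.a_high)


@dataclass(frozen=True)
class MembershipParams:
    """One :class:`RampPair` per input feature."""

    feature1: RampPair
    feature2: RampPair
    feature3: RampPair

    def __iter__(self):
        return iter((self.feature1, self.feature2, self.feature3))


@dataclass(frozen=True)
class InferenceValue:
    """Firing strength of one antecedent combination with its output label."""

    combination: tuple[str, str, str]
    iv: float
    out_label: str


def normalize_features(
    raw_f1: float,
    raw_f2: float,
    raw_f3: float,
    ranges: Mapping[str, tuple[float, float]],
) -> FeatureVector:
    """Min-max scale the raw features to [0,1] (clipping outside the
    training range) and invert Features 1 and 2 so all three increase
    with selection evidence."""
    out = []
    for name, raw in zip(("f1", "f2", "f3"), (raw_f1, raw_f2, raw_f3)):
        lo, hi = ranges[name]
        if hi <= lo:
            raise DegenerateFeatureRangeError(f"degenerate feature range for {name}")
        out.append(float(np.clip((raw - lo) / (hi - lo), 0.0, 1.0)))
    return FeatureVector(1.0 - out[0], 1.0 - out[1], out[2])


def eval_membership(x: float, ramps: RampPair) -> tuple[float, float]:
    """(muL, muH) membership degrees of a normalized feature value."""
    if x <= ramps.a_low:
        mu_l = 1.0
    elif x >= ramps.b_low:
        mu_l = 0.0
    else:
        mu_l = ramps.p_low * x + ramps.q_low
    if x <= ramps.a_high:
        mu_h = 0.0
    elif x >= ramps.b_high:
        mu_h = 1.0
    else:
        mu_h = ramps.p_high * x + ramps.q_high
    return (float(np.clip(mu_l, 0.0, 1.0)), float(np.clip(mu_h, 0.0, 1.0)))


def _neg_p_log_p(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = -p[pos] * np.log(p[pos])
    return out


def fit_membership_entropy(
    m_high: np.ndarray,
    m_low: np.ndarray,
    grid_step: float = 0.01,
) -> RampPair:
    """Maximum-entropy fit of one feature's L/H ramps.

    ``m_high`` / ``m_low`` are class histograms of the (normalized)
    feature for gazing-for-selection and non-gazing data, sampled on a
    uniform grid over [0, 1]; they are renormalized to sum to 1. With
    class masses p_L = sum m_L(x) muL(x) and p_H = sum m_H(x) muH(x),
    the entropy -p_L log p_L - p_H log p_H is maximized over all (a, b)
    grid pairs for both ramps jointly, subject to the two functions
    overlapping (a_H < b_L), so every input value keeps a non-zero L or
    H degree -- the L and H value classes are not separated and the
    fitted functions must share support. The two entropy terms depend
    on disjoint parameters, so the constrained joint optimum is found
    by combining the per-``b_L`` and per-``a_H`` maxima; ties take the
    lexicographically smallest parameters. Deterministic given the grid.
    """
    m_high = np.asarray(m_high, dtype=float)
    m_low = np.asarray(m_low, dtype=float)
    if m_high.sum() <= 0 or m_low.sum() <= 0:
        raise ValueError("class histograms must be non-empty")
    if m_high.shape != m_low.shape:
        raise ValueError("class histograms must share a grid")
    m_high = m_high / m_high.sum()
    m_low = m_low / m_low.sum()
    xs = np.linspace(0.0, 1.0, m_high.size)

    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    pairs = [(a, b) for a in grid for b in grid if b > a + grid_step / 2]
    a_arr = np.array([p[0] for p in pairs])
    b_arr = np.array([p[1] for p in pairs])

    # mu over the histogram grid for every (a, b) pair, vectorized.
    mu_l = np.clip((b_arr[:, None] - xs[None, :]) / (b_arr - a_arr)[:, None], 0.0, 1.0)
    mu_h = np.clip((xs[None, :] - a_arr[:, None]) / (b_arr - a_arr)[:, None], 0.0, 1.0)
    p_l = mu_l @ m_low
    p_h = mu_h @ m_high
    if not np.any(p_l > 0) or not np.any(p_h > 0):
        raise NonOverlappingRampsError("non-overlapping ramps: zero class mass everywhere")
    ent_l = _neg_p_log_p(p_l)
    ent_h = _neg_p_log_p(p_h)

    # Best L term for each b_L and best H term for each a_H (first index
    # wins ties, i.e. the lexicographically smallest partner endpoint).
    n = grid.size
    best_l_for_b = np.full(n, -np.inf)
    best_l_idx = np.full(n, -1)
    best_h_for_a = np.full(n, -np.inf)
    best_h_idx = np.full(n, -1)
    b_pos = np.searchsorted(grid, b_arr)
    a_pos = np.searchsorted(grid, a_arr)
    for i in range(len(pairs)):
        if ent_l[i] > best_l_for_b[b_pos[i]]:
            best_l_for_b[b_pos[i]] = ent_l[i]
            best_l_idx[b_pos[i]] = i
        if ent_h[i] > best_h_for_a[a_pos[i]]:
            best_h_for_a[a_pos[i]] = ent_h[i]
            best_h_idx[a_pos[i]] = i
    # Joint maximum subject to a_H < b_L: for each b_L take the best H
    # term over a_H strictly below it (prefix maximum).
    prefix_best = np.full(n, -np.inf)
    prefix_idx = np.full(n, -1)
    running, run_idx = -np.inf, -1
    for j in range(n):
        prefix_best[j], prefix_idx[j] = running, run_idx
        if best_h_for_a[j] > running:
            running, run_idx = best_h_for_a[j], j
    total = best_l_for_b + prefix_best
    if not np.any(np.isfinite(total)):
        raise NonOverlappingRampsError("non-overlapping ramps: constraint infeasible on grid")
    jb = int(np.argmax(total))  # first (smallest b_L) tie wins
    il = int(best_l_idx[jb])
    ih = int(best_h_idx[int(prefix_idx[jb])])
    return RampPair(
        a_low=float(a_arr[il]),
        b_low=float(b_arr[il]),
        a_high=float(a_arr[ih]),
        b_high=float(b_arr[ih]),
    )


def infer_ivs(
    fv: FeatureVector,
    params: MembershipParams,
    rules: Mapping[tuple[str, str, str], str] = RULE_TABLE,
    mode: Literal["MIN", "MAX"] = "MIN",
) -> list[InferenceValue]:
    """Fire all eight antecedent combinations.

    Each combination's IV is the minimum (MIN rule) or maximum (MAX
    rule) of the three member degrees; its output label comes from the
    rule table.
    """
    if mode not in ("MIN", "MAX"):
        raise ValueError("mode must be 'MIN' or 'MAX'")
    degrees = [
        dict(zip("LH", eval_membership(x, ramps))) for x, ramps in zip(fv, params)
    ]
    combine = min if mode == "MIN" else max
    out = []
    for combo in COMBINATIONS:
        members = [degrees[i][label] for i, label in enumerate(combo)]
        out.append(InferenceValue(combo, float(combine(members)), rules[combo]))
    return out


@dataclass(frozen=True)
class OutputMFs:
    """Piecewise-linear output sets on [0, 1].

    L falls 1 -> 0 over [0, 0.5]; M is the triangle 0 -> 1 -> 0 with apex
    at 0.5; H rises 0 -> 1 over [0.5, 1].
    """

    def mu(self, label: str, x: float) -> float:
        if label == "L":
            return max(0.0, 1.0 - 2.0 * x)
        if label == "M":
            return max(0.0, 1.0 - 2.0 * abs(x - 0.5))
        if label == "H":
            return max(0.0, 2.0 * x - 1.0)
        raise ValueError(f"unknown output label {label!r}")


def aggregate_heights(ivs: Sequence[InferenceValue]) -> dict[str, float]:
    """Per-output-label aggregate: the maximum IV sharing that label."""
    heights = {"L": 0.0, "M": 0.0, "H": 0.0}
    for item in ivs:
        heights[item.out_label] = max(heights[item.out_label], item.iv)
    return heights


def _union_breakpoints(heights: dict[str, float]) -> np.ndarray:
    """Abscissae where the clipped-union height function can change slope.

    Every component piece of the clipped output sets is a line with
    slope in {-2, 0, +2}; the union is piecewise linear between kink
    points and pairwise line intersections, all collected here.
    """
    hl, hm, hh = heights["L"], heights["M"], heights["H"]
    lines = [  # (slope, intercept) of every active linear piece
        (-2.0, 1.0),  # L ramp
        (0.0, hl),  # L clip level
        (2.0, 0.0),  # M rising
        (-2.0, 2.0),  # M falling
        (0.0, hm),  # M clip level
        (2.0, -1.0),  # H ramp
        (0.0, hh),  # H clip level
        (0.0, 0.0),  # floor
    ]
    pts = {0.0, 0.25, 0.5, 0.75, 1.0}
    for (s1, c1), (s2, c2) in itertools.combinations(lines, 2):
        if s1 != s2:
            x = (c2 - c1) / (s1 - s2)
            if 0.0 <= x <= 1.0:
                pts.add(round(x, 15))
    return np.array(sorted(pts))


def union_height(x: np.ndarray | float, heights: dict[str, float]) -> np.ndarray | float:
    """Height of the aggregated (max of clipped output sets) fuzzy region at x."""
    x = np.asarray(x, dtype=float)
    l = np.minimum(heights["L"], np.maximum(0.0, 1.0 - 2.0 * x))
    m = np.minimum(heights["M"], np.maximum(0.0, 1.0 - 2.0 * np.abs(x - 0.5)))
    h = np.minimum(heights["H"], np.maximum(0.0, 2.0 * x - 1.0))
    return np.maximum(np.maximum(l, m), h)


def defuzzify(
    ivs: Sequence[InferenceValue],
    method: Literal["FOM", "MOM", "LOM", "COG", "BOA"] = "COG",
    mfs: OutputMFs | None = None,
) -> float:
    """Reduce the aggregated fuzzy output region to a single score in [0, 1].

    The union of the height-clipped output sets is piecewise linear, so
    all five defuzzifiers are computed exactly on its breakpoint
    decomposition: FOM/LOM are the first/last abscissae attaining the
    union's maximum, MOM their midpoint, COG the centroid of the union
    region (overlaps counted once), and BOA the abscissa that splits the
    union's area in half. If every IV is zero the score is 0 (with a
    warning).
    """
    heights = aggregate_heights(ivs)
    if max(heights.values()) <= 0.0:
        warnings.warn("all inference values are zero; returning score 0", stacklevel=2)
        return 0.0
    bp = _union_breakpoints(heights)
    u = np.asarray(union_height(bp, heights))

    if method in ("FOM", "LOM", "MOM"):
        umax = u.max()
        at_max = bp[np.isclose(u, umax, atol=1e-12)]
        w1, w3 = float(at_max.min()), float(at_max.max())
        if method == "FOM":
            return w1
        if method == "LOM":
            return w3
        return 0.5 * (w1 + w3)

    # Exact segment-wise integration of the piecewise-linear union.
    x1, x2 = bp[:-1], bp[1:]
    u1, u2 = u[:-1], u[1:]
    seg_area = (x2 - x1) * (u1 + u2) / 2.0
    area = float(seg_area.sum())
    if method == "COG":
        xm = (x1 + x2) / 2.0
        um = (u1 + u2) / 2.0  # union is linear on each segment
        seg_moment = (x2 - x1) / 6.0 * (x1 * u1 + 4.0 * xm * um + x2 * u2)
        return float(seg_moment.sum() / area)
    if method == "BOA":
        half = area / 2.0
        acc = 0.0
        for i in range(len(seg_area)):
            if acc + seg_area[i] >= half - 1e-15:
                need = half - acc
                dx = x2[i] - x1[i]
                if dx == 0:
                    return float(x1[i])
                slope = (u2[i] - u1[i]) / dx
                # Solve u1*t + slope*t^2/2 = need for t in [0, dx] via the
                # cancellation-free root t = 2*need / (u1 + sqrt(u1^2 + 2*slope*need)).
                denom = u1[i] + np.sqrt(max(0.0, u1[i] ** 2 + 2.0 * slope * need))
                t = 2.0 * need / denom if denom > 0 else 0.0
                return float(x1[i] + np.clip(t, 0.0, dx))
            acc += seg_area[i]
        return float(bp[-1])
    raise ValueError(f"unknown defuzzification method {method!r}")


def decide(score: float, threshold: float) -> bool:
    """Selection decision: True iff ``score`` strictly exceeds ``threshold``."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    return score > threshold


def fuzzy_score(
    fv: FeatureVector,
    params: MembershipParams,
    mode: Literal["MIN", "MAX"] = "MIN",
    method: Literal["FOM", "MOM", "LOM", "COG", "BOA"] = "COG",
) -> float:
    """Convenience: membership -> inference -> defuzzified score."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return defuzzify(infer_ivs(fv, params, mode=mode), method=method)
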