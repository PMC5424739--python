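"""Fuzzy fusion: membership functions, rule firing, defuzzification."""

import numpy as np
import pytest

from gazefuzz.errors import DegenerateFeatureRangeError
from gazefuzz.fuzzy import (
    COMBINATIONS,
    RULE_TABLE,
    FeatureVector,
    InferenceValue,
    MembershipParams,
    RampPair,
    decide,
    defuzzify,
    eval_membership,
    fit_membership_entropy,
    fuzzy_score,
    infer_ivs,
    normalize_features,
    union_height,
)

#: Printed reference: inference values for degrees (0.75/0.25, 0.00/1.00, 0.32/0.68).
TABLE3_MIN = [
    (0.00, "L"), (0.00, "L"), (0.32, "M"), (0.68, "H"),
    (0.00, "L"), (0.00, "M"), (0.25, "H"), (0.25, "H"),
]
TABLE3_MAX = [
    (0.75, "L"), (0.75, "L"), (1.00, "M"), (1.00, "H"),
    (0.32, "L"), (0.68, "M"), (1.00, "H"), (1.00, "H"),
]
WORKED_FV = FeatureVector(0.30, 0.50, 0.45)


def oracle_defuzz(heights, method, n=100_001):
    """Independent numeric-integration defuzzifier on a dense grid."""
    xs = np.linspace(0.0, 1.0, n)
    u = np.asarray(union_height(xs, heights))
    if method == "COG":
        return np.trapezoid(xs * u, xs) / np.trapezoid(u, xs)
    if method == "BOA":
        cum = np.concatenate([[0.0], np.cumsum((u[:-1] + u[1:]) / 2 * np.diff(xs))])
        return float(xs[np.searchsorted(cum, cum[-1] / 2)])
    raise ValueError(method)


class TestRuleTable:
    def test_rule_table_is_the_published_eight_rules(self):
        expected = {
            ("L", "L", "L"): "L", ("L", "L", "H"): "L",
            ("L", "H", "L"): "M", ("L", "H", "H"): "H",
            ("H", "L", "L"): "L", ("H", "L", "H"): "M",
            ("H", "H", "L"): "H", ("H", "H", "H"): "H",
        }
        assert dict(RULE_TABLE) == expected


class TestMembership:
    def test_worked_example_degrees(self, worked_example_params):
        p = worked_example_params
        assert eval_membership(0.30, p.feature1) == pytest.approx((0.75, 0.25))
        assert eval_membership(0.50, p.feature2) == pytest.approx((0.00, 1.00))
        assert eval_membership(0.45, p.feature3) == pytest.approx((0.32, 0.68))

    def test_plateaus(self):
        ramps = RampPair(0.3, 0.7, 0.3, 0.7)
        assert eval_membership(0.1, ramps) == (1.0, 0.0)
        assert eval_membership(0.9, ramps) == (0.0, 1.0)

    def test_ramp_midpoint_is_half(self):
        ramps = RampPair(0.2, 0.6, 0.2, 0.6)
        mu_l, mu_h = eval_membership(0.4, ramps)
        assert mu_l == pytest.approx(0.5) and mu_h == pytest.approx(0.5)

    def test_continuity_constants(self):
        r = RampPair(0.2, 0.6, 0.3, 0.9)
        assert r.p_low * r.a_low + r.q_low == pytest.approx(1.0)
        assert r.p_low * r.b_low + r.q_low == pytest.approx(0.0)
        assert r.p_high * r.a_high + r.q_high == pytest.approx(0.0)
        assert r.p_high * r.b_high + r.q_high == pytest.approx(1.0)
        assert r.p_low < 0 < r.p_high


class TestNormalization:
    RANGES = {"f1": (0.0, 2.0), "f2": (0.0, 50.0), "f3": (0.0, 0.2)}

    def test_training_minimum_inverts_to_one(self):
        fv = normalize_features(0.0, 25.0, 0.1, self.RANGES)
        assert fv.f1 == 1.0  # strongest accommodation evidence

    def test_training_maximum_of_f3_maps_to_one(self):
        assert normalize_features(1.0, 25.0, 0.2, self.RANGES).f3 == 1.0

    def test_out_of_range_raw_clips(self):
        fv = normalize_features(5.0, -3.0, 0.5, self.RANGES)
        assert fv.f1 == 0.0 and fv.f2 == 1.0 and fv.f3 == 1.0

    def test_degenerate_range_raises(self):
        with pytest.raises(DegenerateFeatureRangeError):
            normalize_features(1, 1, 1, {"f1": (2.0, 2.0), "f2": (0, 1), "f3": (0, 1)})


class TestInference:
    def test_published_min_and_max_columns(self, worked_example_params):
        for mode, expected in (("MIN", TABLE3_MIN), ("MAX", TABLE3_MAX)):
            ivs = infer_ivs(WORKED_FV, worked_example_params, mode=mode)
            got = [(round(iv.iv, 2), iv.out_label) for iv in ivs]
            assert got == expected

    def test_worked_combination_hlh(self, worked_example_params):
        idx = COMBINATIONS.index(("H", "L", "H"))
        iv_min = infer_ivs(WORKED_FV, worked_example_params, mode="MIN")[idx]
        iv_max = infer_ivs(WORKED_FV, worked_example_params, mode="MAX")[idx]
        assert (iv_min.iv, iv_min.out_label) == (0.00, "M")
        assert (round(iv_max.iv, 2), iv_max.out_label) == (0.68, "M")

    def test_min_never_exceeds_max_per_combination(self, rng, worked_example_params):
        for _ in range(50):
            fv = FeatureVector(*rng.uniform(0, 1, 3))
            lo = infer_ivs(fv, worked_example_params, mode="MIN")
            hi = infer_ivs(fv, worked_example_params, mode="MAX")
            assert all(a.iv <= b.iv for a, b in zip(lo, hi))

    def test_unanimous_degrees_collapse_min_and_max(self):
        params = MembershipParams(*(RampPair(0.4, 0.6, 0.4, 0.6),) * 3)
        fv = FeatureVector(1.0, 1.0, 1.0)  # degree exactly 1 in H everywhere
        idx = COMBINATIONS.index(("H", "H", "H"))
        assert infer_ivs(fv, params, mode="MIN")[idx].iv == infer_ivs(fv, params, mode="MAX")[idx].iv == 1.0


def make_ivs(h_l, h_m, h_h):
    return [
        InferenceValue(("L", "L", "L"), h_l, "L"),
        InferenceValue(("L", "H", "L"), h_m, "M"),
        InferenceValue(("H", "H", "H"), h_h, "H"),
    ]


class TestDefuzzification:
    def test_low_only_fom_is_zero(self):
        # L active below full height: plateau [0, w1] at height h, FOM = 0
        assert defuzzify(make_ivs(0.6, 0, 0), "FOM") == 0.0

    def test_mom_is_midpoint_of_fom_and_lom(self, rng):
        for _ in range(25):
            ivs = make_ivs(*rng.uniform(0, 1, 3))
            fom = defuzzify(ivs, "FOM")
            lom = defuzzify(ivs, "LOM")
            assert defuzzify(ivs, "MOM") == pytest.approx((fom + lom) / 2)

    def test_published_min_aggregate_cog_and_boa(self):
        """Aggregate heights L=0.00, M=0.32, H=0.68; oracle values pinned."""
        ivs = make_ivs(0.0, 0.32, 0.68)
        assert defuzzify(ivs, "COG") == pytest.approx(0.616282, abs=1e-4)
        assert defuzzify(ivs, "BOA") == pytest.approx(0.679450, abs=1e-4)

    def test_cog_boa_match_numeric_oracle_on_random_heights(self, rng):
        for _ in range(100):
            heights = dict(zip("LMH", rng.uniform(0, 1, 3)))
            if max(heights.values()) <= 0:
                continue
            ivs = make_ivs(heights["L"], heights["M"], heights["H"])
            for method in ("COG", "BOA"):
                assert defuzzify(ivs, method) == pytest.approx(
                    oracle_defuzz(heights, method), abs=1e-4
                )

    def test_maxima_ordering_and_support(self, rng):
        for _ in range(50):
            ivs = make_ivs(*rng.uniform(0, 1, 3))
            fom, mom, lom = (defuzzify(ivs, m) for m in ("FOM", "MOM", "LOM"))
            assert fom <= mom <= lom
            for m in ("COG", "BOA"):
                assert 0.0 <= defuzzify(ivs, m) <= 1.0

    def test_all_zero_ivs_score_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert defuzzify(make_ivs(0, 0, 0), "COG") == 0.0


class TestEntropyFit:
    @staticmethod
    def brute_force(m_high, m_low, step=0.05):
        """Exhaustive constrained grid evaluation of the entropy criterion."""
        m_high = m_high / m_high.sum()
        m_low = m_low / m_low.sum()
        xs = np.linspace(0, 1, m_high.size)
        grid = np.round(np.arange(0, 1 + step / 2, step), 10)
        best, best_val = None, -np.inf

        def term(p):
            return 0.0 if p <= 0 else -p * np.log(p)

        for al in grid:
            for bl in grid:
                if bl <= al:
                    continue
                mu_l = np.clip((bl - xs) / (bl - al), 0, 1)
                tl = term(float(mu_l @ m_low))
                for ah in grid:
                    if ah >= bl:
                        continue
                    for bh in grid:
                        if bh <= ah:
                            continue
                        mu_h = np.clip((xs - ah) / (bh - ah), 0, 1)
                        val = tl + term(float(mu_h @ m_high))
                        if val > best_val + 1e-12:
                            best, best_val = (al, bl, ah, bh), val
        return best, best_val

    @staticmethod
    def achieved(params, m_high, m_low):
        m_high = m_high / m_high.sum()
        m_low = m_low / m_low.sum()
        xs = np.linspace(0, 1, m_high.size)
        mu_l = np.clip((params.b_low - xs) / (params.b_low - params.a_low), 0, 1)
        mu_h = np.clip((xs - params.a_high) / (params.b_high - params.a_high), 0, 1)
        p_l, p_h = float(mu_l @ m_low), float(mu_h @ m_high)

        def term(p):
            return 0.0 if p <= 0 else -p * np.log(p)

        return term(p_l) + term(p_h)

    def test_matches_exhaustive_grid_oracle_on_point_masses(self):
        m_low = np.zeros(21)
        m_low[2] = 1.0  # mass at 0.1
        m_high = np.zeros(21)
        m_high[18] = 1.0  # mass at 0.9
        params = fit_membership_entropy(m_high, m_low, grid_step=0.05)
        _, oracle_val = self.brute_force(m_high, m_low, step=0.05)
        assert self.achieved(params, m_high, m_low) == pytest.approx(oracle_val, abs=1e-12)

    def test_symmetric_distributions_give_mirror_symmetric_optimum(self):
        m = np.ones(21)
        params = fit_membership_entropy(m, m, grid_step=0.05)
        mirrored = fit_membership_entropy(m[::-1], m[::-1], grid_step=0.05)
        assert self.achieved(params, m, m) == pytest.approx(
            self.achieved(mirrored, m, m), abs=1e-12
        )

    def test_grid_refinement_never_decreases_the_maximum(self, rng):
        m_high = rng.uniform(0, 1, 21)
        m_low = rng.uniform(0, 1, 21)
        coarse = fit_membership_entropy(m_high, m_low, grid_step=0.1)
        fine = fit_membership_entropy(m_high, m_low, grid_step=0.05)
        assert self.achieved(fine, m_high, m_low) >= self.achieved(coarse, m_high, m_low) - 1e-12


class TestDecision:
    @pytest.mark.parametrize(
        "score, threshold, expected",
        [(0.68, 0.30, True), (0.30, 0.30, False), (0.99, 1.0, False)],
    )
    def test_strict_threshold(self, score, threshold, expected):
        assert decide(score, threshold) is expected


class TestScoreShape:
    def test_score_is_monotone_in_the_dwell_feature(self, rng):
        """More gaze stillness (higher inverted f2) never lowers the COG score."""
        params = MembershipParams(*(RampPair(0.25, 0.75, 0.25, 0.75),) * 3)
        for _ in range(300):
            f = rng.uniform(0, 1, 3)
            d = rng.uniform(0, 1 - f[1])
            s1 = fuzzy_score(FeatureVector(*f), params)
            s2 = fuzzy_score(FeatureVector(f[0], f[1] + d, f[2]), params)
            assert s2 >= s1 - 1e-9

    def test_rule_base_is_not_monotone_in_feature_one(self):
        """Low pupil evidence + stillness + texture fires H (a published rule),
        so raising f1 through the crossover can transiently lower the score."""
        params = MembershipParams(*(RampPair(0.25, 0.75, 0.25, 0.75),) * 3)
        low = fuzzy_score(FeatureVector(0.25, 1.0, 1.0), params)  # LHH fully fires
        mid = fuzzy_score(FeatureVector(0.50, 1.0, 1.0), params)  # crossover
        assert mid < low
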