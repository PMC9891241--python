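"""Unit and property tests for the scoring mathematics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gqscore.core import (
    DropThreshold,
    band_assignment,
    classify_outlier,
    gqs_region,
    naive_flag,
    neg_log10_p,
    perp_distance,
    predict_logp,
    rescore_with_index,
    residual_and_ratio,
    score_region,
    threshold_loss,
)
from gqscore.exceptions import DegenerateRegionError
from gqscore.ld import LDProfile

from conftest import make_panel, make_records, make_scored

SQRT2 = math.sqrt(2.0)


class TestPrediction:
    @pytest.mark.parametrize(
        "r2,index_logp,expected",
        [(1.0, 9.5, 9.5), (0.5, 10.0, 5.0), (0.25, 8.0, 2.0)],
    )
    def test_line_through_origin(self, r2, index_logp, expected):
        assert predict_logp(r2, index_logp) == pytest.approx(expected)

    def test_index_p_of_one_is_degenerate(self):
        with pytest.raises(DegenerateRegionError):
            predict_logp(0.5, 0.0)

    @pytest.mark.parametrize(
        "p_obs,p_hat,expected",
        [(5.0, 5.0, (0.0, 0.0)), (0.0, 5.0, (-5.0, -1.0)), (6.0, 4.0, (2.0, 0.5))],
    )
    def test_residual_and_ratio(self, p_obs, p_hat, expected):
        assert residual_and_ratio(p_obs, p_hat) == pytest.approx(expected)

    def test_ratio_rejects_nonpositive_prediction(self):
        with pytest.raises(ValueError):
            residual_and_ratio(1.0, 0.0)


class TestThresholdGeometry:
    def test_default_endpoints(self, default_thr):
        # 100 % loss at the r² floor, 40 % at complete LD
        assert threshold_loss(0.4, default_thr) == pytest.approx(1.0)
        assert threshold_loss(1.0, default_thr) == pytest.approx(0.4)

    def test_default_reduces_to_14_minus_r2(self, default_thr):
        assert threshold_loss(0.7, default_thr) == pytest.approx(0.7)

    def test_below_floor_is_undefined(self, default_thr):
        with pytest.raises(ValueError):
            threshold_loss(0.3, default_thr)

    def test_worst_case_distance(self, default_thr):
        assert default_thr.worst_case_distance == pytest.approx(0.6 / SQRT2)

    @pytest.mark.parametrize(
        "r2,loss,expected",
        [(1.0, 1.0, 0.6 / SQRT2), (0.7, 0.7, 0.0), (0.7, 1.0, 0.3 / SQRT2)],
    )
    def test_perp_distance(self, r2, loss, expected, default_thr):
        assert perp_distance(r2, loss, default_thr) == pytest.approx(expected)

    @pytest.mark.parametrize("r2,loss", [(1.0, 1.0), (0.7, 1.0), (0.55, 0.9)])
    def test_perp_distance_matches_sampling_oracle(self, r2, loss, default_thr):
        # brute-force minimum Euclidean distance over densely sampled line points
        xs = np.linspace(-2.0, 3.0, 2_000_001)
        ys = 1.4 - xs
        d = np.sqrt((xs - r2) ** 2 + (ys - loss) ** 2).min()
        assert perp_distance(r2, loss, default_thr) == pytest.approx(d, abs=1e-6)

    def test_nondefault_slope_geometry(self):
        thr = DropThreshold(r2_floor=0.5, loss_at_floor=0.9, loss_at_one=0.3)
        m = thr.slope
        assert m == pytest.approx(-1.2)
        x0, y0 = 0.8, 0.95
        expected = abs(y0 - thr.loss_at(x0)) / math.sqrt(1 + m * m)
        assert thr.distance(x0, y0) == pytest.approx(expected)


class TestOutlierClassification:
    @pytest.mark.parametrize(
        "r2,loss,expected",
        [
            (0.9, 0.8, True),  # above the line (0.8 > 1.4 − 0.9)
            (0.9, 0.3, False),  # below the line
            (0.3, 1.0, False),  # below the r² floor: uninformative
            (0.9, 0.5, False),  # exactly on the line: strict inequality
            (0.4, 1.0, False),  # exactly at the floor: strict inequality
        ],
    )
    def test_against_default_line(self, r2, loss, expected, default_thr):
        assert classify_outlier(r2, loss, default_thr) is expected

    @pytest.mark.parametrize(
        "s,band",
        [(-0.5, "within68"), (-0.68, "within68"), (-0.8, "within95"),
         (-0.97, "within99"), (-1.0, "beyond99"), (1.2, "beyond99"), (0.0, "within68")],
    )
    def test_band_assignment_by_abs_ratio(self, s, band):
        assert band_assignment(s) == band

    @pytest.mark.parametrize(
        "s,flagged", [(-0.8, True), (-0.75, False), (0.9, False), (-1.0, True)]
    )
    def test_naive_75pct_flag(self, s, flagged):
        assert naive_flag(s) is flagged


class TestRegionScore:
    def test_worked_example_distance_ratio(self, default_thr):
        # a region whose strongest outlier sits 0.342 from the line:
        # pick (r², loss) = (1.0, 0.4 + 0.342·√2) so distance is exactly 0.342
        loss = 0.4 + 0.342 * SQRT2
        p_obs = (1.0 - loss) * 10.0
        sn = make_scored("bad", 1.0, p_obs, 10.0)
        assert sn.is_outlier and sn.perp_dist == pytest.approx(0.342)
        res = gqs_region([sn, make_scored("ok", 0.9, 9.0, 10.0)], default_thr)
        assert res.max_loss_dist == pytest.approx(0.342)
        assert res.gqs == pytest.approx(1.0 - 0.342 / (0.6 / SQRT2))
        assert res.strongest_outlier == "bad"

    def test_no_supporting_ld_gives_minus_one(self, default_thr):
        scored = [make_scored(f"v{i}", 0.05 + 0.03 * i, 1.0, 10.0) for i in range(10)]
        res = gqs_region(scored, default_thr)
        assert res.gqs == -1.0
        assert res.n_outliers == 0

    def test_clean_supported_region_scores_one(self, default_thr):
        scored = [make_scored("v1", 0.95, 9.4, 10.0)]
        res = gqs_region(scored, default_thr)
        assert res.gqs == 1.0 and res.n_outliers == 0

    def test_empty_region_warns_and_flags(self, default_thr):
        with pytest.warns(UserWarning):
            res = gqs_region([], default_thr)
        assert res.gqs == -1.0

    def test_gain_snps_never_outliers_but_advised(self, default_thr):
        gain = make_scored("gain", 0.8, 20.0, 10.0)  # s = +1.5
        res = gqs_region([gain], default_thr)
        assert res.gqs == 1.0
        assert res.secondary_signal_ids == ["gain"]

    def test_outlier_distance_tie_names_smallest_id(self, default_thr):
        a = make_scored("zzz", 1.0, 1.0, 10.0)
        b = make_scored("aaa", 1.0, 1.0, 10.0)
        res = gqs_region([a, b], default_thr)
        assert res.strongest_outlier == "aaa"


def _brute_force_gqs(pairs, index_logp, thr):
    """Independent recomputation of the region score by direct arithmetic."""
    dists = []
    supported = False
    for r2, p_obs in pairs:
        if r2 < 0.01:
            continue
        p_hat = r2 * index_logp
        s = (p_obs - p_hat) / p_hat
        loss = -s if s < 0 else 0.0
        if r2 > thr.r2_floor:
            supported = True
            bound = thr.loss_at_floor + (thr.loss_at_one - thr.loss_at_floor) * (
                r2 - thr.r2_floor
            ) / (1.0 - thr.r2_floor)
            if loss > bound:
                m = (thr.loss_at_one - thr.loss_at_floor) / (1.0 - thr.r2_floor)
                dists.append(abs(loss - bound) / math.sqrt(1.0 + m * m))
    if not supported:
        return -1.0
    if not dists:
        return 1.0
    worst = abs(1.0 - thr.loss_at(1.0)) / math.sqrt(1.0 + thr.slope**2)
    return 1.0 - max(dists) / worst


class TestProperties:
    @settings(max_examples=300, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.001, 1.0),
                st.floats(0.0, 40.0),
            ),
            min_size=0,
            max_size=30,
        ),
        st.floats(1.0, 40.0),
    )
    def test_score_bounded_and_matches_brute_force(self, pairs, index_logp):
        """GQS ∈ {−1} ∪ [0, 1] and equals an arithmetic-from-scratch oracle."""
        thr = DropThreshold()
        scored = [
            make_scored(f"v{i}", r2, p_obs, index_logp)
            for i, (r2, p_obs) in enumerate(pairs)
        ]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = gqs_region(scored, thr)
        assert res.gqs == -1.0 or 0.0 <= res.gqs <= 1.0
        assert res.gqs == pytest.approx(
            _brute_force_gqs(pairs, index_logp, thr), abs=1e-9
        )

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(0.45, 1.0),
        st.floats(0.0, 10.0),
        st.floats(0.1, 5.0),
    )
    def test_worsening_the_worst_outlier_never_raises_score(self, r2, p_obs, drop):
        thr = DropThreshold()
        base = [make_scored("x", r2, p_obs, 10.0)]
        worse = [make_scored("x", r2, max(0.0, p_obs - drop), 10.0)]
        g0 = gqs_region(base, thr).gqs
        g1 = gqs_region(worse, thr).gqs
        assert g1 <= g0 + 1e-12

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0.05, 1.0), st.floats(0.1, 20.0), st.floats(0.2, 5.0))
    def test_ratio_scale_equivariance(self, r2, p_obs, factor):
        """S depends only on p_obs/p_hat, so scaling all −log10 P cancels."""
        _, s1 = residual_and_ratio(p_obs, r2 * 10.0)
        _, s2 = residual_and_ratio(p_obs * factor, r2 * 10.0 * factor)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_index_lies_on_its_own_line(self):
        e, s = residual_and_ratio(12.5, predict_logp(1.0, 12.5))
        assert e == 0.0 and s == 0.0


class TestScoreRegionPipeline:
    def test_index_excluded_and_equilibrium_filtered(self, default_thr):
        records = make_records(
            [(1, 100, "idx", 1e-10), (1, 110, "hi", 1e-9), (1, 120, "eq", 0.5)]
        )
        profile = LDProfile("idx", {"idx": 1.0, "hi": 0.9, "eq": 0.004})
        res = score_region(records, profile, default_thr)
        ids = [sn.var_id for sn in res.scored]
        assert ids == ["hi"]  # index and equilibrium SNP both excluded
        assert res.index_id == "idx"

    def test_clamped_zero_p_keeps_index_finite(self, default_thr):
        assert neg_log10_p(0.0) > 300
        with pytest.raises(ValueError):
            neg_log10_p(1.5)

    def test_rescore_with_same_index_is_idempotent(self, default_thr):
        panel = make_panel(
            [[0, 1, 2, 1, 0, 2, 1, 0, 1, 2],
             [0, 1, 2, 1, 0, 2, 1, 0, 1, 2],
             [2, 1, 0, 1, 2, 0, 1, 2, 1, 0]]
        )
        records = make_records(
            [(1, 100, "v0", 1e-9), (1, 110, "v1", 1e-8), (1, 120, "v2", 1e-7)]
        )
        r1 = rescore_with_index(records, panel, "v0", default_thr, min_pairs=2)
        r2 = rescore_with_index(records, panel, "v0", default_thr, min_pairs=2)
        assert r1.gqs == r2.gqs and r1.index_id == r2.index_id == "v0"

    def test_rescore_with_p_one_index_is_degenerate(self, default_thr):
        panel = make_panel(
            [[0, 1, 2, 1, 0, 2, 1, 0, 1, 2], [2, 1, 0, 1, 2, 0, 1, 2, 1, 0]]
        )
        records = make_records([(1, 100, "v0", 1e-9), (1, 110, "v1", 1.0)])
        with pytest.raises(DegenerateRegionError):
            rescore_with_index(records, panel, "v1", default_thr, min_pairs=2)
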