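"""Median/normalize/SD-threshold hit calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from carrierscreen._exceptions import PairingError
from carrierscreen.hits import (
    ExclusionReport,
    call_hits,
    exclude_edges,
    normalize_scores,
    replicate_median,
)


def measurements(values: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    for strain, counts in values.items():
        for i, c in enumerate(counts):
            rows.append({"row": 0, "col": i, "strain_id": strain, "pixel_count": c})
    return pd.DataFrame(rows)


def scores_frame(scores: list[float]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain_id": [f"s{i}" for i in range(len(scores))],
            "median_drug": scores,
            "median_control": [100.0] * len(scores),
            "score": scores,
        }
    )


class TestReplicateMedian:
    def test_median_is_suppressor_robust(self):
        med = replicate_median(measurements({"a": [120, 122, 125, 400]}))
        assert med["median_px"].iloc[0] == 123.5

    def test_identical_replicates(self):
        med = replicate_median(measurements({"a": [50, 50, 50, 50]}))
        assert med["median_px"].iloc[0] == 50

    def test_three_replicates_logged(self, caplog):
        report = ExclusionReport()
        with caplog.at_level("WARNING"):
            med = replicate_median(measurements({"a": [10, 20, 30]}), report)
        assert med["median_px"].iloc[0] == 20
        assert report.short_replicates == [("a", 3)]

    def test_all_missing_dropped_and_reported(self):
        report = ExclusionReport()
        frame = measurements({"a": [1, 2, 3, 4]})
        frame.loc[frame["strain_id"] == "a", "pixel_count"] = np.nan
        med = replicate_median(frame, report)
        assert med.empty
        assert report.all_missing == ["a"]


class TestExcludeEdges:
    def test_border_spot_count_on_test_plate(self, test_layout):
        table = test_layout.frame.copy()
        table["pixel_count"] = 1.0
        kept = exclude_edges(test_layout, table)
        assert len(kept) == 768 - 108 == 660
        assert not kept["is_edge"].any()

    def test_interior_subset_unchanged(self, test_layout):
        interior = test_layout.frame[~test_layout.frame["is_edge"]].copy()
        interior["pixel_count"] = 2.0
        kept = exclude_edges(test_layout, interior)
        assert len(kept) == len(interior)

    def test_edge_boost_shifts_plate_sd(self, catalog, test_layout):
        """With a strong edge effect, including the border visibly inflates
        the plate SD — the reason the WT buffer is excluded."""
        from carrierscreen.colony import PlateImage, quantify_plate
        from carrierscreen.simulate import SimParams, make_truth, render_plate_image

        params = SimParams(rng_seed=4, edge_boost=2.0, pixel_noise_sd=0.0, suppressor_rate=0.0)
        truth = make_truth(catalog, inhibition=0.0)
        result = render_plate_image(test_layout, truth, params, treated=False)
        table = quantify_plate(PlateImage(result.image, result.corners), test_layout)
        sd_with = table["pixel_count"].std(ddof=1)
        sd_without = exclude_edges(test_layout, table)["pixel_count"].std(ddof=1)
        assert sd_with > 10 * max(sd_without, 1e-9)


class TestNormalizeScores:
    def med(self, values: dict[str, float]) -> pd.DataFrame:
        return pd.DataFrame(
            {"strain_id": list(values), "median_px": list(values.values()),
             "n_replicates": 4}
        )

    def test_ratio_times_100(self):
        scored = normalize_scores(self.med({"a": 60}), self.med({"a": 120}))
        assert scored["score"].iloc[0] == 50.0

    def test_identical_plates_score_100(self):
        meds = self.med({"a": 10, "b": 250, "c": 7})
        scored = normalize_scores(meds, meds)
        assert (scored["score"] == 100.0).all()

    def test_zero_control_excluded_and_reported(self):
        report = ExclusionReport()
        scored = normalize_scores(
            self.med({"a": 60, "b": 60}), self.med({"a": 120, "b": 0}), report
        )
        assert list(scored["strain_id"]) == ["a"]
        assert report.zero_control == ["b"]

    def test_disjoint_plates_rejected(self):
        with pytest.raises(PairingError):
            normalize_scores(self.med({"a": 1}), self.med({"b": 1}))


class TestCallHits:
    def test_single_outlier_z_matches_direct_computation(self):
        """59 strains at 100 plus one at 190: z ~ 7.6, called at 3 SD."""
        frame = scores_frame([100.0] * 59 + [190.0])
        calls = call_hits(frame)
        values = np.array([100.0] * 59 + [190.0])
        z_expected = (190 - values.mean()) / values.std(ddof=1)
        out = calls[calls["score"] == 190].iloc[0]
        assert out["z"] == pytest.approx(z_expected)
        assert z_expected == pytest.approx(7.62, abs=0.01)
        assert out["call"] == "resistant"

    def test_threshold_semantics_between_25_and_3(self):
        rng = np.random.default_rng(0)
        base = list(100 + rng.normal(0, 1, 200))
        frame = scores_frame(base)
        mean, sd = frame["score"].mean(), frame["score"].std(ddof=1)
        target = mean + 2.7 * sd
        frame.loc[0, "score"] = target
        # recompute: plant so z lands near 2.7 after the shift
        z = (target - frame["score"].mean()) / frame["score"].std(ddof=1)
        assert 2.5 < z < 3.0
        at3 = call_hits(frame, resistant_sd=3.0)
        at25 = call_hits(frame, resistant_sd=2.5)
        assert at3.loc[at3["strain_id"] == "s0", "call"].iloc[0] == "none"
        assert at25.loc[at25["strain_id"] == "s0", "call"].iloc[0] == "resistant"

    def test_degenerate_plate_yields_no_calls(self):
        report = ExclusionReport()
        calls = call_hits(scores_frame([100.0] * 10), report=report)
        assert (calls["call"] == "none").all()
        assert report.degenerate_plate

    def test_sensitive_below_minus_25_sd(self):
        frame = scores_frame([100.0] * 59 + [10.0])
        calls = call_hits(frame)
        assert calls.loc[calls["score"] == 10.0, "call"].iloc[0] == "sensitive"

    @given(
        st.floats(0.1, 50.0),
        st.floats(-500.0, 500.0),
    )
    def test_affine_invariance_of_calls(self, scale, shift):
        """Scaling all scores by k > 0 and shifting leaves every call unchanged."""
        rng = np.random.default_rng(1)
        base = list(100 + rng.normal(0, 8, 80)) + [200.0, 5.0]
        raw = call_hits(scores_frame(base))
        transformed = call_hits(scores_frame([scale * s + shift for s in base]))
        assert list(raw["call"]) == list(transformed["call"])

    def test_threshold_nesting(self):
        """Resistant set at 3 SD is contained in 2.5 SD, contained in 2 SD."""
        rng = np.random.default_rng(2)
        base = list(100 + rng.normal(0, 10, 150)) + [160.0, 145.0, 130.0]
        sets = {}
        for sd in (3.0, 2.5, 2.0):
            calls = call_hits(scores_frame(base), resistant_sd=sd)
            sets[sd] = set(calls.loc[calls["call"] == "resistant", "strain_id"])
        assert sets[3.0] <= sets[2.5] <= sets[2.0]
        report = ExclusionReport()
        call_hits(scores_frame(base), report=report)
        assert (
            report.calls_per_threshold[3.0]
            <= report.calls_per_threshold[2.5]
            <= report.calls_per_threshold[2.0]
        )
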