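"""Gating cascade: compensation, size/cell gates, thresholds, classification."""

import math

import numpy as np
import pandas as pd
import pytest

from dropgate import (
    AssayModel,
    CellClass,
    CompensationMatrix,
    GateConfig,
    amplification_threshold,
    cell_gate,
    classify_positive,
    compensate,
    downsample,
    estimate_compensation,
    percent_positive,
    quadrant_counts,
    run_gating,
    simulate_event_table,
    size_gate,
)


def table(durations=None, **channels):
    n = len(next(iter(channels.values()))) if channels else len(durations)
    df = pd.DataFrame({"droplet_id": np.arange(n)})
    df["duration_samples"] = durations if durations is not None else 100
    for ch, vals in channels.items():
        df[f"mean_{ch}"] = vals
    return df


class TestCompensation:
    def test_identity_matrix_leaves_events_unchanged(self):
        events = table(A=[1.0, 2.0], B=[3.0, 4.0])
        out = compensate(events, CompensationMatrix.identity(["A", "B"]))
        pd.testing.assert_frame_equal(out, events)

    def test_two_channel_spillover_solved_exactly(self):
        # observed (1.2, 1.0) under S = [[1, 0.2], [0, 1]] -> true (1.0, 1.0)
        events = table(A=[1.2], B=[1.0])
        m = CompensationMatrix([[1.0, 0.2], [0.0, 1.0]], ["A", "B"])
        out = compensate(events, m)
        assert out["mean_A"].iloc[0] == pytest.approx(1.0)
        assert out["mean_B"].iloc[0] == pytest.approx(1.0)

    def test_compensation_inverts_simulated_spillover(self):
        S = np.array([[1.0, 0.1], [0.25, 1.0]])
        cls = CellClass("pos", {"FAM": 0.9})
        clean = AssayModel(classes=[cls], proportions=[1.0], noise_sd=0.0, seed=6)
        mixed = AssayModel(
            classes=[cls], proportions=[1.0], noise_sd=0.0, crosstalk=S, seed=6
        )
        ev_clean, _ = simulate_event_table(clean, 400)
        ev_mixed, _ = simulate_event_table(mixed, 400)
        out = compensate(ev_mixed, CompensationMatrix(S, ["HEX", "FAM"]))
        np.testing.assert_allclose(
            out[["mean_HEX", "mean_FAM"]], ev_clean[["mean_HEX", "mean_FAM"]]
        )

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError):
            CompensationMatrix([[1.0, 1.0], [1.0, 1.0]], ["A", "B"])

    def test_estimate_recovers_generating_spillover(self, rng):
        spill = 0.2
        n = 1000
        a = rng.normal(1000.0, 10.0, n)
        b_only = table(B=a, A=a * spill + rng.normal(0, 1.0, n))
        a_only = table(A=a, B=rng.normal(0, 1.0, n) + a * 0.0)
        m = estimate_compensation({"A": a_only, "B": b_only}, ["A", "B"])
        assert m.matrix[0, 1] == pytest.approx(spill, rel=0.01)
        assert abs(m.matrix[1, 0]) < 0.01

    def test_zero_spillover_controls_give_identity(self, rng):
        a = table(A=rng.normal(1000, 5, 100), B=np.zeros(100))
        b = table(B=rng.normal(1000, 5, 100), A=np.zeros(100))
        m = estimate_compensation({"A": a, "B": b}, ["A", "B"])
        np.testing.assert_allclose(m.matrix, np.eye(2), atol=1e-3)

    def test_control_without_events_rejected(self):
        empty = table(A=np.array([]), B=np.array([]))
        with pytest.raises(ValueError):
            estimate_compensation({"A": empty, "B": empty}, ["A", "B"])


class TestSizeGate:
    @pytest.mark.parametrize(
        "n, trim, remaining", [(100, 0.08, 84), (25, 0.08, 21), (50, 0.0, 50)]
    )
    def test_floor_rule_per_tail(self, n, trim, remaining, rng):
        events = table(durations=rng.permutation(n) + 10, A=np.ones(n))
        assert len(size_gate(events, trim)) == remaining

    def test_tails_removed_are_the_extremes(self):
        events = table(durations=np.arange(10, 110), A=np.ones(100))
        out = size_gate(events, 0.08)
        assert out["duration_samples"].min() == 18
        assert out["duration_samples"].max() == 101

    def test_survivor_order_preserved(self, rng):
        events = table(durations=rng.permutation(60) + 1, A=np.ones(60))
        out = size_gate(events, 0.1)
        assert list(out["droplet_id"]) == sorted(out["droplet_id"])

    def test_trim_at_half_rejected(self):
        with pytest.raises(ValueError):
            size_gate(table(durations=[1, 2, 3], A=[0, 0, 0]), 0.5)


class TestCellGate:
    def test_identical_stain_levels_yield_no_cells(self):
        events = table(HEX=np.full(50, 100.0))
        cells, empties = cell_gate(events, GateConfig())
        assert len(cells) == 0 and len(empties) == 50

    def test_bright_minority_gated_as_cells(self):
        # median 100, cutoff 280: exactly the ten 1000-level events pass
        events = table(HEX=np.concatenate([np.full(90, 100.0), np.full(10, 1000.0)]))
        cells, empties = cell_gate(events, GateConfig())
        assert len(cells) == 10
        assert (cells["mean_HEX"] == 1000.0).all()

    def test_partition_is_exhaustive(self, rng):
        events = table(HEX=rng.lognormal(5, 1, 333))
        cells, empties = cell_gate(events, GateConfig())
        assert len(cells) + len(empties) == 333
        assert set(cells["droplet_id"]).isdisjoint(empties["droplet_id"])


class TestDownsample:
    def test_identity_when_n_exceeds_table(self):
        events = table(A=np.arange(5.0))
        pd.testing.assert_frame_equal(downsample(events, 10), events)

    def test_exact_sample_size_distinct_ids(self, rng):
        events = table(A=rng.random(50_000))
        out = downsample(events, 10_000, seed=1)
        assert len(out) == 10_000
        assert out["droplet_id"].is_unique

    def test_seed_reproducibility(self, rng):
        events = table(A=rng.random(1000))
        pd.testing.assert_frame_equal(
            downsample(events, 100, seed=7), downsample(events, 100, seed=7)
        )


class TestThresholdAndCalls:
    def test_amplification_threshold_is_fold_times_median(self):
        empties = table(FAM=np.full(11, 100.0))
        assert amplification_threshold(empties, "FAM", 2.8) == pytest.approx(280.0)
        assert amplification_threshold(empties, "FAM", 1.0) == pytest.approx(100.0)

    def test_even_sized_median_averages_central_values(self):
        empties = table(FAM=[90.0, 110.0])
        assert amplification_threshold(empties, "FAM", 2.8) == pytest.approx(280.0)

    def test_classification_against_threshold(self):
        cells = table(FAM=[300.0, 100.0, 290.0, 50.0])
        calls = classify_positive(cells, {"FAM": 280.0})
        assert list(calls["call_FAM"]) == [True, False, True, False]
        assert percent_positive(calls, "FAM") == pytest.approx(0.5)

    def test_threshold_above_max_gives_all_negative(self):
        cells = table(FAM=[1.0, 2.0, 3.0])
        calls = classify_positive(cells, {"FAM": 10.0})
        assert percent_positive(calls, "FAM") == 0.0

    def test_percent_positive_order_invariant(self, rng):
        cells = table(FAM=rng.random(200) * 400)
        calls = classify_positive(cells, {"FAM": 280.0})
        shuffled = calls.sample(frac=1.0, random_state=0)
        assert percent_positive(shuffled, "FAM") == percent_positive(calls, "FAM")

    def test_missing_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_positive(table(FAM=[1.0]), {"HEX": 1.0})


class TestQuadrants:
    def test_hand_counts(self):
        calls = table(X=np.zeros(5), Y=np.zeros(5))
        calls["call_X"] = [True] * 3 + [False] * 2
        calls["call_Y"] = [False] * 3 + [True] * 2
        q = quadrant_counts(calls, "X", "Y")
        assert q == {"--": 0, "+-": 3, "-+": 2, "++": 0}

    def test_empty_table_all_zero(self):
        calls = table(X=np.array([]), Y=np.array([]))
        calls["call_X"] = calls["call_Y"] = np.array([], dtype=bool)
        assert sum(quadrant_counts(calls, "X", "Y").values()) == 0

    def test_simulated_double_marker_quadrant_fraction(self):
        """An x+/y- class lands in the (+,-) quadrant at its expression rate."""
        cls = CellClass("epithelial", {"KRT19": 0.994, "VIM": 0.002})
        model = AssayModel(
            classes=[cls],
            proportions=[1.0],
            marker_channels=["KRT19", "VIM"],
            seed=14,
        )
        config = GateConfig(marker_channels=["KRT19", "VIM"], downsample_n=100_000)
        events, gt = simulate_event_table(model, 40_000)
        report = run_gating(events, config)
        q = report["quadrants"]
        total = sum(q.values())
        frac = q["+-"] / total
        # doublets OR their states, nudging the expected fraction slightly
        expected = 0.994 * (1 - 0.002)
        se = math.sqrt(expected * (1 - expected) / total)
        assert abs(frac - expected) < 4 * se + 0.005


class TestCascade:
    def test_cascade_conserves_events(self, mixture_model):
        events, _ = simulate_event_table(mixture_model, 20_000)
        config = GateConfig(downsample_n=500)
        report = run_gating(events, config)
        assert (
            report["n_removed_size_gate"]
            + report["n_empties"]
            + report["n_removed_downsample"]
            + report["n_analyzed"]
            == report["n_input"]
        )

    def test_end_to_end_positive_fraction_recovery(self):
        """Pipeline estimate converges to p*TPR + (1-p)*FPR."""
        p, tpr, fpr = 0.1, 0.971, 2e-4
        model = AssayModel(
            classes=[
                CellClass("pos", {"FAM": tpr}),
                CellClass("neg", {"FAM": fpr}),
            ],
            proportions=[p, 1 - p],
            loading_rate=0.03,  # keep doublets rare
            seed=31,
        )
        events, _ = simulate_event_table(model, 300_000)
        report = run_gating(events, GateConfig(downsample_n=100_000))
        expected = p * tpr + (1 - p) * fpr
        n = report["n_analyzed"]
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(report["percent_positive"]["FAM"] - expected) < 3 * se + 0.002

    def test_classification_concordant_with_ground_truth(self, mixture_model):
        events, gt = simulate_event_table(mixture_model, 30_000)
        report = run_gating(events, GateConfig(downsample_n=100_000))
        calls = report["calls"].merge(gt, on="droplet_id")
        occupied = calls[calls["cell_count"] > 0]
        agree = (occupied["call_FAM"] == occupied["true_FAM"]).mean()
        assert agree > 0.999
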