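"""Adaptation-signature pipeline on synthetic event tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thalcort import (
    SynthParams,
    adaptation_correlation,
    aggregate_preceding,
    apply_inclusion,
    build_pairs,
    run_pipeline,
    sensitivity_sweep,
    synth_recordings,
)


def make_table(rows):
    return pd.DataFrame(
        rows,
        columns=["animal_id", "recording_id", "onset_s", "amplitude",
                 "participation", "kind"],
    )


class TestApplyInclusion:
    def test_low_participation_dropped(self):
        t = make_table([("a", 0, 1.0, 1.0, 0.19, "L"),
                        ("a", 0, 2.0, 1.0, 0.5, "L")])
        kept, _ = apply_inclusion(t, min_h=0)
        assert len(kept) == 1 and kept.iloc[0]["onset_s"] == 2.0

    def test_eleven_qualifying_h_events_excluded(self):
        rows = []
        t = 0.0
        for k in range(11):
            rows.append(("a", 0, t, 1.0, 0.5, "L"))
            rows.append(("a", 0, t + 10.0, 5.0, 0.9, "H"))
            t += 400.0  # isolate the pairs so each H has one qualifier
        kept, elig = apply_inclusion(make_table(rows))
        assert not elig.iloc[0]["eligible"]
        assert kept.empty

    def test_hand_counted_eligibility(self):
        rows = []
        t = 0.0
        for k in range(15):
            rows.append(("a", 0, t, 1.0, 0.5, "L"))
            rows.append(("a", 0, t + 10.0, 5.0, 0.9, "H"))
            t += 400.0
        # one extra H with no preceding activity within 300 s
        rows.append(("a", 0, t + 350.0, 5.0, 0.9, "H"))
        kept, elig = apply_inclusion(make_table(rows))
        assert elig.iloc[0]["n_h_qualifying"] == 15
        assert elig.iloc[0]["eligible"]

    def test_empty_table(self):
        kept, elig = apply_inclusion(make_table([]))
        assert kept.empty and elig.empty


class TestAggregatePreceding:
    def test_no_preceding_events(self):
        t = make_table([("a", 0, 100.0, 5.0, 0.9, "H")])
        assert aggregate_preceding(t, 0) is None

    def test_kernel_at_zero_lag(self):
        t = make_table([("a", 0, 99.999, 2.0, 0.5, "L"),
                        ("a", 0, 100.0, 5.0, 0.9, "H")])
        agg = aggregate_preceding(t, 1)
        assert agg == pytest.approx(2.0, rel=1e-4)

    def test_two_event_closed_form(self):
        t = make_table([("a", 0, 0.0, 4.0, 0.5, "L"),
                        ("a", 0, 100.0, 2.0, 0.5, "L"),
                        ("a", 0, 200.0, 5.0, 0.9, "H")])
        agg = aggregate_preceding(t, 2, t_max=300.0, tau_decay=1000.0)
        expected = (2.0 * np.exp(-0.1) + 4.0 * np.exp(-0.2)) / 2
        assert agg == pytest.approx(expected)

    def test_window_cut(self):
        t = make_table([("a", 0, 0.0, 4.0, 0.5, "L"),
                        ("a", 0, 350.0, 5.0, 0.9, "H")])
        assert aggregate_preceding(t, 1, t_max=300.0) is None

    def test_other_animals_ignored(self):
        t = make_table([("b", 0, 99.0, 9.0, 0.5, "L"),
                        ("a", 0, 100.0, 5.0, 0.9, "H")])
        assert aggregate_preceding(t, 1) is None


class TestSplittingInvariance:
    def test_recording_split_leaves_pairs_unchanged(self):
        params = SynthParams(n_animals=2, recordings_per_animal=4)
        table = synth_recordings(params, 0.5, np.random.default_rng(3))
        split = table.copy()
        # re-label each recording into two pseudo-recordings at its midpoint
        split["recording_id"] = (
            split["recording_id"] * 2
            + (split.groupby(["animal_id", "recording_id"])["onset_s"]
               .transform(lambda s: s > s.mean()).astype(int))
        )
        a = build_pairs(table)
        b = build_pairs(split)
        pd.testing.assert_frame_equal(a, b)


class TestAdaptationCorrelation:
    def test_exact_line(self, rng):
        x = rng.uniform(0, 5, 50)
        pairs = pd.DataFrame(
            {"animal_id": "a", "h_amplitude": 2 * x + 1, "aggregate": x}
        )
        res = adaptation_correlation(pairs, n_boot=100, rng=0)
        assert res.r == pytest.approx(1.0)
        assert res.ci_low <= res.r <= res.ci_high

    def test_shuffled_pairs_null(self, rng):
        x = rng.uniform(0, 5, 500)
        y = 2 * x + rng.normal(0, 0.1, 500)
        rng.shuffle(y)
        pairs = pd.DataFrame(
            {"animal_id": "a", "h_amplitude": y, "aggregate": x}
        )
        res = adaptation_correlation(pairs, n_boot=50, rng=0)
        assert abs(res.r) < 0.1

    def test_too_few_pairs(self):
        pairs = pd.DataFrame(
            {"animal_id": "a", "h_amplitude": [1, 2], "aggregate": [1, 2]}
        )
        with pytest.raises(ValueError):
            adaptation_correlation(pairs)

    def test_subsample_scheme(self, rng):
        x = rng.uniform(0, 5, 100)
        pairs = pd.DataFrame(
            {"animal_id": "a",
             "h_amplitude": x + rng.normal(0, 1, 100),
             "aggregate": x}
        )
        res = adaptation_correlation(pairs, n_boot=200, rng=0,
                                     scheme="subsample")
        assert res.ci_low <= res.r <= res.ci_high


class TestSynthRecordings:
    def test_seed_determinism(self):
        p = SynthParams(n_animals=2)
        a = synth_recordings(p, 0.5, 7)
        b = synth_recordings(p, 0.5, 7)
        pd.testing.assert_frame_equal(a, b)

    def test_null_gain_gives_null_correlation(self):
        rs = []
        for seed in range(20):
            table = synth_recordings(SynthParams(), 0.0, seed)
            pairs = build_pairs(table)
            rs.append(stats.pearsonr(pairs["aggregate"],
                                     pairs["h_amplitude"]).statistic)
        assert abs(np.mean(rs)) < 0.05

    def test_r_monotone_in_gain(self):
        means = []
        for gain in (0.0, 0.5, 1.5):
            rs = []
            for seed in range(5):
                table = synth_recordings(SynthParams(), gain, seed)
                pairs = build_pairs(table)
                rs.append(stats.pearsonr(pairs["aggregate"],
                                         pairs["h_amplitude"]).statistic)
            means.append(np.mean(rs))
        assert means[0] < means[1] < means[2]

    def test_onsets_sorted_within_animal(self):
        table = synth_recordings(SynthParams(n_animals=3), 0.0, 1)
        for _, grp in table.groupby("animal_id"):
            assert grp["onset_s"].is_monotonic_increasing


class TestSensitivitySweep:
    def test_degenerate_grid_reproduces_pipeline(self):
        table = synth_recordings(SynthParams(), 0.5, 11)
        sweep = sensitivity_sweep(table, (300.0,), (1000.0,), (0.2,),
                                  n_boot=100, rng=0)
        res = run_pipeline(table, n_boot=100, rng=0)
        assert sweep.iloc[0]["r"] == pytest.approx(res.r)

    def test_flat_kernel_limit(self):
        """With tau_decay far beyond t_max the kernel is flat and r barely
        moves across tau values."""
        table = synth_recordings(SynthParams(), 0.8, 5)
        sweep = sensitivity_sweep(
            table, (300.0,), (1e4, 1e5, 1e6), (0.2,), n_boot=50, rng=0
        )
        assert sweep["r"].max() - sweep["r"].min() < 0.05

    def test_positive_gain_robust_across_grid(self):
        table = synth_recordings(SynthParams(), 1.0, 2)
        sweep = sensitivity_sweep(
            table, (150.0, 300.0, 450.0), (500.0, 1000.0, 1500.0),
            (0.1, 0.2, 0.3), n_boot=50, rng=0,
        )
        assert (sweep["r"] > 0).all()
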