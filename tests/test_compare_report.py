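"""Direction classification, concordance scoring and Welch statistics."""

import math

import numpy as np
import pandas as pd
import pytest

import massnet as mn
from massnet.compare_report import (
    OSCILLATORY_AMBIGUOUS,
    WelchResult,
    concordance,
    report_grid,
    rows_to_frame,
)
from massnet.spectral import SpectralSummary

BANDS = ["delta", "theta", "alpha1", "alpha2", "beta", "gamma"]


def make_summary(rows: list[dict]) -> SpectralSummary:
    """Build a batch summary from explicit per-iteration measure rows."""
    table = pd.DataFrame(rows)
    for band in BANDS:
        table[band] = table.get(band, 0.0)
    means = table.mean()
    stds = table.std(ddof=1) if len(rows) > 1 else table.iloc[0] * 0.0
    return SpectralSummary(
        rel_power={b: float(means[b]) for b in BANDS},
        total_power=float(means["total_power"]),
        peak_frequency=float(means["peak_frequency"]),
        mean_spike_density=float(means["mean_spike_density"])
        if "mean_spike_density" in table
        else None,
        n_iterations=len(rows),
        dispersion={c: float(stds[c]) for c in table.columns},
        per_iteration=table,
    )


def batch(theta, peak, alpha2, beta, total, density, n=4, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        rows.append(
            {
                "theta": theta + jitter * rng.standard_normal(),
                "alpha1": 0.5,
                "alpha2": alpha2 + jitter * rng.standard_normal(),
                "beta": beta + jitter * rng.standard_normal(),
                "peak_frequency": peak + 10 * jitter * rng.standard_normal(),
                "total_power": total + jitter * rng.standard_normal(),
                "mean_spike_density": density + jitter * rng.standard_normal(),
            }
        )
    return make_summary(rows)


CONTROL = batch(theta=0.20, peak=9.0, alpha2=0.10, beta=0.10, total=1.0, density=4.0,
                jitter=1e-3, seed=1)


class TestClassifyDirection:
    def test_identical_batches_unchanged(self):
        row = mn.classify_direction(CONTROL, CONTROL, "self")
        assert row.neuronal_activity == "unchanged"
        assert row.oscillatory_behavior == "unchanged"
        assert row.total_power == "unchanged"

    def test_slowing_with_hyperactivity(self):
        scen = batch(theta=0.30, peak=8.0, alpha2=0.08, beta=0.08, total=1.5,
                     density=5.0, jitter=1e-3, seed=2)
        row = mn.classify_direction(scen, CONTROL, "ad-like")
        assert row.neuronal_activity == "higher"
        assert row.oscillatory_behavior == "slower"
        assert row.total_power == "higher"

    def test_theta_drop_classifies_faster(self):
        # disinhibition-type response: theta down, peak up, activity up
        scen = batch(theta=0.10, peak=10.5, alpha2=0.30, beta=0.12, total=1.5,
                     density=8.0, jitter=1e-3, seed=3)
        row = mn.classify_direction(scen, CONTROL, "2B-like")
        assert row.oscillatory_behavior == "faster"
        assert row.neuronal_activity == "higher"

    def test_conflicting_theta_and_peak_is_mixed(self):
        scen = batch(theta=0.30, peak=10.0, alpha2=0.10, beta=0.10, total=1.0,
                     density=4.0, jitter=1e-3, seed=4)
        assert mn.classify_direction(scen, CONTROL, "x").oscillatory_behavior == "mixed"

    def test_flat_theta_resolves_by_fast_power_then_peak(self):
        faster = batch(theta=0.20, peak=9.0, alpha2=0.25, beta=0.15, total=1.0,
                       density=4.0, jitter=1e-3, seed=5)
        assert mn.classify_direction(faster, CONTROL, "x").oscillatory_behavior == "faster"
        slower = batch(theta=0.20, peak=8.0, alpha2=0.10, beta=0.10, total=1.0,
                       density=4.0, jitter=1e-3, seed=6)
        assert mn.classify_direction(slower, CONTROL, "x").oscillatory_behavior == "slower"

    def test_zero_tolerance_matches_raw_mean_signs(self):
        tol = mn.DirectionTolerances(theta=0.0, peak_frequency=0.0, fast_power=0.0,
                                     spike_density=0.0, total_power=0.0)
        scen = batch(theta=0.2001, peak=8.99, alpha2=0.10, beta=0.10, total=1.0001,
                     density=4.0001, jitter=0.0, n=2)
        ctrl = batch(theta=0.20, peak=9.0, alpha2=0.10, beta=0.10, total=1.0,
                     density=4.0, jitter=0.0, n=2)
        row = mn.classify_direction(scen, ctrl, "x", tolerances=tol)
        assert row.neuronal_activity == "higher"
        assert row.total_power == "higher"
        assert row.oscillatory_behavior == "slower"

    def test_iteration_order_invariance(self):
        scen = batch(theta=0.26, peak=8.4, alpha2=0.09, beta=0.09, total=1.3,
                     density=5.0, jitter=5e-3, seed=7)
        shuffled = make_summary(
            scen.per_iteration.sample(frac=1.0, random_state=9).to_dict("records")
        )
        a = mn.classify_direction(scen, CONTROL, "x")
        b = mn.classify_direction(shuffled, CONTROL, "x")
        assert (a.neuronal_activity, a.oscillatory_behavior, a.total_power) == (
            b.neuronal_activity, b.oscillatory_behavior, b.total_power)

    def test_common_rescaling_invariance(self):
        # scaling both batches' signals by c scales total power by c^2 and
        # leaves every label unchanged
        scen = batch(theta=0.30, peak=8.0, alpha2=0.08, beta=0.08, total=1.5,
                     density=5.0, jitter=1e-3, seed=8)
        def rescale(s, c):
            rows = s.per_iteration.copy()
            rows["total_power"] *= c ** 2
            return make_summary(rows.to_dict("records"))
        a = mn.classify_direction(scen, CONTROL, "x")
        b = mn.classify_direction(rescale(scen, 10.0), rescale(CONTROL, 10.0), "x")
        assert (a.neuronal_activity, a.oscillatory_behavior, a.total_power) == (
            b.neuronal_activity, b.oscillatory_behavior, b.total_power)

    def test_requires_two_iterations_for_se_tolerances(self):
        single = batch(theta=0.2, peak=9.0, alpha2=0.1, beta=0.1, total=1.0,
                       density=4.0, n=1)
        with pytest.raises(ValueError):
            mn.classify_direction(single, CONTROL, "x")


class TestReferenceTable:
    def test_reference_directions_verbatim(self):
        t = mn.TABLE_REFERENCE_DIRECTIONS
        assert len(t) == 12
        # neuronal activity row: all disease-like higher except 1B; contrasts mirrored
        for g in ("1A", "1C", "2A", "2B", "2C"):
            assert t[f"{g}_ad"]["neuronal_activity"] == "higher"
            assert t[f"{g}_contrast"]["neuronal_activity"] == "lower"
        assert t["1B_ad"]["neuronal_activity"] == "lower"
        assert t["1B_contrast"]["neuronal_activity"] == "higher"
        # total power row: disease-like higher, contrast lower, throughout
        for g in ("1A", "1B", "1C", "2A", "2B", "2C"):
            assert t[f"{g}_ad"]["total_power"] == "higher"
            assert t[f"{g}_contrast"]["total_power"] == "lower"
        # oscillatory row: slowing everywhere disease-like except 2B;
        # contrasts faster except 2B (slower); 1A contrast flagged ambiguous
        for g in ("1A", "1B", "1C", "2A", "2C"):
            assert t[f"{g}_ad"]["oscillatory_behavior"] == "slower"
        assert t["2B_ad"]["oscillatory_behavior"] == "faster"
        assert t["2B_contrast"]["oscillatory_behavior"] == "slower"
        for g in ("1A", "1B", "1C", "2A", "2C"):
            assert t[f"{g}_contrast"]["oscillatory_behavior"] == "faster"
        assert OSCILLATORY_AMBIGUOUS == {"1A_contrast"}


class TestSummarizeAndConcordance:
    def test_control_only_yields_empty_report(self):
        assert mn.summarize_all_scenarios({"control": CONTROL}) == []

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError):
            mn.summarize_all_scenarios({"1A_ad": CONTROL})

    def test_concordance_counts_and_ambiguity(self):
        slow = batch(theta=0.30, peak=8.0, alpha2=0.08, beta=0.08, total=1.5,
                     density=5.0, jitter=1e-3, seed=10)
        rows = mn.summarize_all_scenarios(
            {"control": CONTROL, "1A_ad": slow, "1A_contrast": slow}
        )
        scores = concordance(rows)
        # 1A_ad matches all three outcomes; 1A_contrast mismatches activity
        # and total power but its oscillatory label is accepted either way
        assert scores["neuronal_activity"] == {
            "matched": 1, "of": 2,
            "mismatches": ["1A_contrast: higher != lower"],
        }
        assert scores["total_power"]["matched"] == 1
        assert scores["oscillatory_behavior"]["matched"] == 2

    def test_report_grid_and_frame(self):
        slow = batch(theta=0.30, peak=8.0, alpha2=0.08, beta=0.08, total=1.5,
                     density=5.0, jitter=1e-3, seed=11)
        rows = mn.summarize_all_scenarios({"control": CONTROL, "1A_ad": slow})
        grid = report_grid(rows)
        assert "1A_ad" in grid and "Oscillatory behavior" in grid
        frame = rows_to_frame(rows)
        assert list(frame["scenario"]) == ["1A_ad"]
        assert frame.loc[0, "neuronal_activity"] == "higher"


class TestWelchTTest:
    def test_hand_formula_oracle(self):
        # Welch statistic and df computed by hand for (1,2,3) vs (4,5,6)
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        va = vb = 1.0  # sample variances
        se = math.sqrt(va / 3 + vb / 3)
        t_hand = (2.0 - 5.0) / se
        df_hand = (va / 3 + vb / 3) ** 2 / (
            (va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2
        )
        res = mn.welch_ttest(a, b)
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)
        assert res.df == pytest.approx(df_hand, rel=1e-12)
        assert 0 < res.pvalue < 0.05

    def test_identical_groups(self):
        res = mn.welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_swapping_groups_flips_sign(self):
        a, b = [1.0, 2.0, 2.5], [3.0, 4.5, 5.0]
        r1 = mn.welch_ttest(a, b)
        r2 = mn.welch_ttest(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_degenerate_zero_variance(self):
        assert mn.welch_ttest([2.0, 2.0], [2.0, 2.0]) == WelchResult(0.0, 2.0, 1.0)
        res = mn.welch_ttest([3.0, 3.0], [2.0, 2.0])
        assert res.statistic == np.inf and res.pvalue == 0.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            mn.welch_ttest([1.0], [2.0, 3.0])
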