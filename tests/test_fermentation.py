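"""Synthetic fermentation time courses and end-product ratio analysis."""

import numpy as np
import pytest

from acetoflux.fermentation import (
    DEFAULT_HORIZONS,
    GrowthParams,
    TimeCourse,
    TimeCourseFormatError,
    default_params,
    end_product_ratios,
    growth_summary,
    read_timecourse,
    simulate_fermentation,
    write_timecourse,
)


def test_same_seed_identical_distinct_seed_same_skeleton():
    a = simulate_fermentation(default_params("CO", seed=11))
    b = simulate_fermentation(default_params("CO", seed=11))
    c = simulate_fermentation(default_params("CO", seed=12))
    assert np.array_equal(a.od600, b.od600)
    for prod in a.products:
        assert np.array_equal(a.products[prod], b.products[prod])
    assert not np.array_equal(a.od600, c.od600)
    # the noiseless skeleton is seed-independent
    quiet = default_params("CO", seed=11)
    quiet.noise_sd = {p: 0.0 for p in quiet.noise_sd}
    quiet.od_noise_sd = 0.0
    quiet2 = default_params("CO", seed=12)
    quiet2.noise_sd = {p: 0.0 for p in quiet2.noise_sd}
    quiet2.od_noise_sd = 0.0
    s1, s2 = simulate_fermentation(quiet), simulate_fermentation(quiet2)
    assert np.array_equal(s1.od600, s2.od600)


def test_noiseless_endpoints_reach_caps():
    params = default_params("CO", seed=0)
    params.noise_sd = {p: 0.0 for p in params.noise_sd}
    params.od_noise_sd = 0.0
    tc = simulate_fermentation(params, DEFAULT_HORIZONS["CO"])
    for prod, cap in params.product_caps.items():
        assert tc.products[prod][-1] == pytest.approx(cap, rel=1e-3)
    assert tc.od600[-1] == pytest.approx(params.od_max, rel=2e-3)


def test_co_endpoints_near_stated_titers():
    params = default_params("CO", seed=5)
    tc = simulate_fermentation(params)
    for prod, cap in params.product_caps.items():
        sd = params.noise_sd[prod]
        assert abs(tc.products[prod][-1] - cap) < 3 * sd + 1e-6


def test_h2_condition_is_acetate_dominant():
    tc = simulate_fermentation(default_params("H2_CO2", seed=2))
    assert tc.products["acetate"][-1] > 10 * tc.products["ethanol"][-1]
    summary = growth_summary(tc)
    assert abs(summary["peak_od"] - 1.6) < 3 * 0.3


def test_printed_co_titers_round_to_1_1_4():
    """Ratios of the stated end titers (acetate 185, butanediol 188,
    ethanol 713 mM) are about 1 : 1.016 : 3.854 and round to 1:1:4."""
    tc = TimeCourse(
        condition="CO",
        times=np.array([0.0, 120.0]),
        od600=np.array([0.1, 8.4]),
        products={
            "acetate": np.array([0.0, 185.0]),
            "butanediol": np.array([0.0, 188.0]),
            "ethanol": np.array([0.0, 713.0]),
        },
    )
    ratios = end_product_ratios(tc, "acetate")
    assert ratios["acetate"]["ratio"] == pytest.approx(1.0)
    assert ratios["butanediol"]["ratio"] == pytest.approx(188 / 185, rel=1e-12)
    assert ratios["ethanol"]["ratio"] == pytest.approx(713 / 185, rel=1e-12)
    assert [ratios[p]["rounded"] for p in ("acetate", "butanediol", "ethanol")] == [1, 1, 4]


def test_ratios_scale_invariant_and_equal_products_unity():
    times = np.array([0.0, 12.0])
    tc = TimeCourse("CO", times, np.array([0.1, 1.0]),
                    {"a": np.array([0.0, 50.0]), "b": np.array([0.0, 50.0])})
    ratios = end_product_ratios(tc, "a")
    assert all(r["ratio"] == 1.0 for r in ratios.values())
    scaled = TimeCourse("CO", times, tc.od600,
                        {k: 7.5 * v for k, v in tc.products.items()})
    assert end_product_ratios(scaled, "a") == ratios


def test_zero_reference_raises():
    tc = TimeCourse("CO", np.array([0.0]), np.array([0.1]),
                    {"a": np.array([0.0]), "b": np.array([1.0])})
    with pytest.raises(ZeroDivisionError, match="reference"):
        end_product_ratios(tc, "a")


def test_ratio_recovery_across_seeds():
    """Simulating caps in ratio 1:1:4, the mean estimated ratios over 20
    seeds recover the generator's ground truth within 5%."""
    params0 = default_params("CO", seed=0)
    caps = {"acetate": 180.0, "butanediol": 180.0, "ethanol": 720.0}
    estimates = {p: [] for p in caps}
    for seed in range(20):
        params = default_params("CO", seed=seed)
        params.product_caps = dict(caps)
        params.noise_sd = dict(params0.noise_sd)
        tc = simulate_fermentation(params)
        ratios = end_product_ratios(tc, "acetate")
        for p in caps:
            estimates[p].append(ratios[p]["ratio"])
    assert np.mean(estimates["butanediol"]) == pytest.approx(1.0, rel=0.05)
    assert np.mean(estimates["ethanol"]) == pytest.approx(4.0, rel=0.05)


def test_growth_summary_tie_breaks():
    monotone = TimeCourse("CO", np.array([0.0, 12.0, 24.0]),
                          np.array([0.1, 0.5, 1.0]), {"a": np.zeros(3)})
    assert growth_summary(monotone)["time_of_peak"] == 24.0
    constant = TimeCourse("CO", np.array([0.0, 12.0, 24.0]),
                          np.full(3, 2.0), {"a": np.zeros(3)})
    assert growth_summary(constant)["time_of_peak"] == 0.0  # first attainment


def test_csv_round_trip(tmp_path):
    tc = simulate_fermentation(default_params("H2_CO2", seed=9))
    path = tmp_path / "tc.csv"
    write_timecourse(tc, path)
    again = read_timecourse(path)
    assert again.condition == tc.condition
    assert np.allclose(again.times, tc.times)
    assert np.allclose(again.od600, tc.od600)
    assert set(again.products) == set(tc.products)
    for prod in tc.products:
        assert np.allclose(again.products[prod], tc.products[prod])
    assert again.replicate_sd == tc.replicate_sd


def test_read_rejects_missing_column_and_unsorted_times(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("time_h,ethanol_mM\n0,1\n12,2\n")
    with pytest.raises(TimeCourseFormatError, match="od600"):
        read_timecourse(path)
    path.write_text("time_h,od600,ethanol_mM\n12,1,1\n0,2,2\n")
    with pytest.raises(TimeCourseFormatError, match="increasing"):
        read_timecourse(path)


def test_negative_parameters_rejected():
    params = default_params("CO")
    params.od_max = -1.0
    with pytest.raises(ValueError, match="od_max"):
        simulate_fermentation(params)
    params = default_params("CO")
    params.noise_sd["ethanol"] = -2.0
    with pytest.raises(ValueError, match="noise"):
        simulate_fermentation(params)
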