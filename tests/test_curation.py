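import numpy as np
import pandas as pd
import pytest

from lagfuse import CohortConfig, generate_patient
from lagfuse.curation import (
    check_stationarity,
    curate,
    densify_events,
    downsample_align,
    fill_missing_test,
    fill_missing_train,
    fit_transform,
    invert_to_mgdl,
    invert_transform,
    reframe,
    trim_common_span,
    window_count,
)
from lagfuse.exceptions import ContractViolation, CurationError
from lagfuse.synthetic import RawPatientData

from conftest import make_transformed_series


def _grid(start, n, step=5):
    return pd.date_range(start, periods=n, freq=f"{step}min")


def _raw(bg, activity, carbs=None, bolus=None, split="2021-01-06"):
    empty = pd.Series(dtype=float)
    return RawPatientData("P0", bg, activity, carbs if carbs is not None else empty,
                          bolus if bolus is not None else empty, pd.Timestamp(split))


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

def test_trim_staggered_spans():
    g = _grid("2021-01-01", 288 * 11)
    bg = pd.Series(100.0, index=g[: 288 * 10])            # days 1-10
    act = pd.Series(70.0, index=g[288: 288 * 11])         # days 2-11
    out = trim_common_span(_raw(bg, act))
    assert out.bg.index[0] == out.activity.index[0] == g[288]
    assert out.bg.index[-1] == out.activity.index[-1] == g[288 * 10 - 1]


def test_trim_identity_when_spans_equal():
    g = _grid("2021-01-01", 100)
    bg = pd.Series(np.arange(100.0), index=g)
    act = pd.Series(np.ones(100), index=g)
    out = trim_common_span(_raw(bg, act))
    pd.testing.assert_series_equal(out.bg, bg)
    pd.testing.assert_series_equal(out.activity, act)


def test_trim_three_staggered_starts_uses_intersection():
    g = _grid("2021-01-01", 50)
    bg = pd.Series(1.0, index=g[5:45])
    act = pd.Series(2.0, index=g[10:50])
    out = trim_common_span(_raw(bg, act))
    assert out.bg.index[0] == g[10] and out.bg.index[-1] == g[44]


def test_trim_empty_overlap_errors():
    g = _grid("2021-01-01", 20)
    bg = pd.Series(1.0, index=g[:5])
    act = pd.Series(2.0, index=g[10:])
    with pytest.raises(CurationError):
        trim_common_span(_raw(bg, act))


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def test_interpolation_fills_on_the_line():
    g = _grid("2021-01-01", 5)
    obs = pd.Series([100.0, 140.0], index=[g[0], g[4]])
    filled = fill_missing_train(obs, g)
    np.testing.assert_allclose(filled, [100, 110, 120, 130, 140])


def test_interpolation_is_identity_without_gaps():
    g = _grid("2021-01-01", 6)
    obs = pd.Series(np.arange(6.0) ** 2, index=g)
    np.testing.assert_array_equal(fill_missing_train(obs, g), obs.values)


def test_midpoint_interpolation():
    g = _grid("2021-01-01", 3)
    obs = pd.Series([100.0, 110.0], index=[g[0], g[2]])
    assert fill_missing_train(obs, g)[1] == 105.0


def test_causal_extrapolation_continues_slope():
    g = _grid("2021-01-01", 3)
    obs = pd.Series([100.0, 110.0], index=g[:2])
    assert fill_missing_test(obs, g)[2] == 120.0


def test_causal_extrapolation_stepwise_through_gap():
    g = _grid("2021-01-01", 4)
    obs = pd.Series([100.0, 110.0], index=g[:2])
    np.testing.assert_allclose(fill_missing_test(obs, g), [100, 110, 120, 130])


def test_causal_fill_identity_without_gaps():
    g = _grid("2021-01-01", 4)
    obs = pd.Series([1.0, 2.0, 4.0, 8.0], index=g)
    np.testing.assert_array_equal(fill_missing_test(obs, g), obs.values)


def test_causal_fill_never_uses_future():
    """Deleting all observations after a filled point leaves it unchanged."""
    rng = np.random.default_rng(0)
    g = _grid("2021-01-01", 60)
    mask = rng.random(60) < 0.7
    mask[:2] = True
    obs = pd.Series(rng.normal(120, 20, mask.sum()), index=g[mask])
    full = fill_missing_test(obs, g)
    for i in np.flatnonzero(~mask):
        truncated = obs[obs.index < g[i]]
        again = fill_missing_test(truncated, g[: i + 1])
        assert again[i] == full[i]


def test_lofc_fallback_with_single_prior_point(caplog):
    g = _grid("2021-01-01", 3)
    obs = pd.Series([100.0], index=[g[0]])
    out = fill_missing_test(obs, g)
    np.testing.assert_array_equal(out, [100, 100, 100])


# ---------------------------------------------------------------------------
# sparsity and alignment
# ---------------------------------------------------------------------------

def test_densify_no_events_all_zero():
    g = _grid("2021-01-01", 10)
    out = densify_events(pd.Series(dtype=float), g)
    assert (out == 0).all() and len(out) == 10


def test_densify_single_on_grid_event():
    g = _grid("2021-01-01 10:00", 5)
    ev = pd.Series([45.0], index=[pd.Timestamp("2021-01-01 10:05")])
    out = densify_events(ev, g)
    assert out[1] == 45.0 and np.count_nonzero(out) == 1


def test_densify_collisions_summed():
    g = _grid("2021-01-01 10:00", 5)
    ev = pd.Series([30.0, 15.0], index=pd.to_datetime(
        ["2021-01-01 10:01", "2021-01-01 10:02"]))
    out = densify_events(ev, g)
    assert out[0] == 45.0 and np.count_nonzero(out) == 1


def test_densify_tie_breaks_earlier():
    g = _grid("2021-01-01 10:00", 3)
    ev = pd.Series([10.0], index=[pd.Timestamp("2021-01-01 10:02:30")])
    out = densify_events(ev, g)
    assert out[0] == 10.0 and out[1] == 0.0


def test_downsample_identity_when_aligned():
    g = _grid("2021-01-01", 20)
    act = pd.Series(np.arange(20.0), index=g)
    np.testing.assert_array_equal(downsample_align(act, g), act.values)


def test_downsample_nearest_neighbour():
    g = pd.DatetimeIndex([pd.Timestamp("2021-01-01 10:00")])
    act = pd.Series([1.0, 2.0], index=pd.to_datetime(
        ["2021-01-01 09:58", "2021-01-01 10:01"]))
    assert downsample_align(act, g)[0] == 2.0


def test_downsample_tie_breaks_earlier():
    g = pd.DatetimeIndex([pd.Timestamp("2021-01-01 10:00")])
    act = pd.Series([1.0, 2.0], index=pd.to_datetime(
        ["2021-01-01 09:59", "2021-01-01 10:01"]))
    assert downsample_align(act, g)[0] == 1.0


def test_downsample_empty_errors():
    with pytest.raises(CurationError):
        downsample_align(pd.Series(dtype=float), _grid("2021-01-01", 3))


# ---------------------------------------------------------------------------
# transform / inversion
# ---------------------------------------------------------------------------

def _complete_series(n=200, split=150, seed=0):
    rng = np.random.default_rng(seed)
    g = _grid("2021-01-01", n)
    from lagfuse.curation import PatientSeries
    return PatientSeries("P1", g, {
        "bg": rng.normal(150, 40, n),
        "activity": rng.normal(70, 10, n),
        "carbs": np.where(rng.random(n) < 0.02, rng.uniform(20, 60, n), 0.0),
        "bolus": np.where(rng.random(n) < 0.02, rng.uniform(1, 5, n), 0.0),
    }, split)


def test_standardisation_uses_train_statistics_only():
    ps = _complete_series()
    ts, scaler = fit_transform(ps)
    s = ps.split_index
    for ch, vals in ps.channels.items():
        assert scaler.mean[ch] == pytest.approx(vals[:s].mean())
        assert scaler.sd[ch] == pytest.approx(vals[:s].std())
    # train segment of the scaled series has mean ~0, unit variance
    z_bg = (ps.channels["bg"] - scaler.mean["bg"]) / scaler.sd["bg"]
    assert abs(z_bg[:s].mean()) < 1e-12 and z_bg[:s].std() == pytest.approx(1.0)


def test_z_closed_form():
    # mean 150, sd 50: x=200 -> z=1
    assert (200.0 - 150.0) / 50.0 == 1.0  # anchor for the round trip below
    ps = _complete_series()
    _, scaler = fit_transform(ps)
    x = scaler.mean["bg"] + scaler.sd["bg"]
    z = (x - scaler.mean["bg"]) / scaler.sd["bg"]
    assert z == pytest.approx(1.0)


def test_differencing_values():
    z = np.array([0.0, 1.0, 0.5])
    np.testing.assert_allclose(np.diff(z), [1.0, -0.5])


def test_transform_round_trip_exact():
    ps = _complete_series(seed=3)
    ts, scaler = fit_transform(ps)
    inv = invert_transform(ts, scaler)
    for ch in ps.channels:
        assert np.max(np.abs(inv[ch] - ps.channels[ch])) < 1e-9


def test_zero_train_sd_names_channel():
    ps = _complete_series()
    ps.channels["carbs"][: ps.split_index] = 0.0
    with pytest.raises(CurationError, match="carbs"):
        fit_transform(ps)


def test_invert_zero_diffs_holds_anchor():
    ps = _complete_series()
    _, scaler = fit_transform(ps)
    anchor = 0.5
    out = invert_to_mgdl(np.zeros(6), scaler, anchor)
    expected = anchor * scaler.sd["bg"] + scaler.mean["bg"]
    np.testing.assert_allclose(out, expected)


def test_invert_hand_example():
    ps = _complete_series()
    _, scaler = fit_transform(ps)
    scaler.mean["bg"], scaler.sd["bg"] = 150.0, 50.0
    out = invert_to_mgdl(np.array([0.2, -0.2]), scaler, 0.0)
    np.testing.assert_allclose(out, [160.0, 150.0])


def test_invert_round_trip_on_true_targets(tiny_transformed):
    ps, ts, scaler = tiny_transformed
    tr, te = reframe(ts, 6, 6)
    anchors = scaler.anchor(te.t0_index)
    ref = invert_to_mgdl(te.y, scaler, anchors)
    for j in range(te.n_windows):
        t0 = te.t0_index[j]
        np.testing.assert_allclose(ref[j], ps.channels["bg"][t0 : t0 + 6], atol=1e-9)


def test_invert_requires_one_anchor_per_window():
    ps = _complete_series()
    _, scaler = fit_transform(ps)
    with pytest.raises(ContractViolation):
        invert_to_mgdl(np.zeros((3, 6)), scaler, np.zeros(2))


# ---------------------------------------------------------------------------
# stationarity (single instances; the multi-seed harness lives in acceptance)
# ---------------------------------------------------------------------------

def test_stationarity_verdicts():
    rng = np.random.default_rng(42)
    walk = np.cumsum(rng.normal(size=2000))
    assert check_stationarity(np.diff(walk)).verdict == "stationary"
    assert check_stationarity(walk).verdict == "non-stationary"
    assert check_stationarity(rng.normal(size=2000)).verdict == "stationary"


def test_stationarity_degenerate_inputs():
    with pytest.raises(CurationError):
        check_stationarity(np.ones(100))
    with pytest.raises(CurationError):
        check_stationarity(np.arange(10.0))


# ---------------------------------------------------------------------------
# reframing
# ---------------------------------------------------------------------------

def test_window_count_formula_single_segment():
    # n=10, L=3, H=2 -> 6 windows in total across roles
    chans = {c: np.arange(10.0) + i for i, c in enumerate(("bg", "activity", "carbs", "bolus"))}
    ts = make_transformed_series(chans, split_index=7)
    tr, te = reframe(ts, 3, 2)
    straddle = 10 - 3 - 2 + 1 - tr.n_windows - te.n_windows
    assert tr.n_windows + te.n_windows + straddle == window_count(10, 3, 2) == 6
    assert straddle == 1  # H-1 windows straddle the split


def test_windows_are_exact_slices():
    rng = np.random.default_rng(1)
    chans = {c: rng.normal(size=40) for c in ("bg", "activity", "carbs", "bolus")}
    ts = make_transformed_series(chans, split_index=30)
    L, H = 5, 3
    tr, te = reframe(ts, L, H)
    stack = np.stack([chans[c] for c in ("bg", "activity", "carbs", "bolus")], axis=-1)
    for ws in (tr, te):
        for j in range(ws.n_windows):
            k = ws.t0_index[j] - 1 - L  # transformed-scale window start
            np.testing.assert_array_equal(ws.X[j], stack[k : k + L])
            np.testing.assert_array_equal(ws.y[j], chans["bg"][k + L : k + L + H])


def test_no_train_target_in_test_span_and_full_test_coverage():
    chans = {c: np.arange(50.0) for c in ("bg", "activity", "carbs", "bolus")}
    ts = make_transformed_series(chans, split_index=40)
    L, H = 6, 6
    tr, te = reframe(ts, L, H)
    s_orig = ts.split_index + 1
    assert (tr.end_index <= s_orig - 1).all()
    assert (te.t0_index >= s_orig).all()
    assert te.t0_index[0] == s_orig  # first test target is the first test point
    assert te.t0_index[-1] == ts.n + 1 - H  # covers the reachable test span


def test_reframe_too_short_errors():
    chans = {c: np.arange(5.0) for c in ("bg", "activity", "carbs", "bolus")}
    ts = make_transformed_series(chans, split_index=4)
    with pytest.raises(CurationError):
        reframe(ts, 6, 6)


# ---------------------------------------------------------------------------
# pipeline-level properties
# ---------------------------------------------------------------------------

def test_curation_idempotent_on_complete_series(tiny_raw):
    ps = curate(tiny_raw)
    raw2 = RawPatientData(
        patient_id=ps.patient_id,
        bg=pd.Series(ps.channels["bg"], index=ps.grid),
        activity=pd.Series(ps.channels["activity"], index=ps.grid),
        carbs=pd.Series(ps.channels["carbs"][ps.channels["carbs"] > 0],
                        index=ps.grid[ps.channels["carbs"] > 0]),
        bolus=pd.Series(ps.channels["bolus"][ps.channels["bolus"] > 0],
                        index=ps.grid[ps.channels["bolus"] > 0]),
        split_time=ps.grid[ps.split_index],
    )
    ps2 = curate(raw2)
    assert ps2.split_index == ps.split_index
    for ch in ps.channels:
        np.testing.assert_allclose(ps2.channels[ch], ps.channels[ch], atol=1e-12)


def test_curated_series_is_complete_and_regular(tiny_raw):
    ps = curate(tiny_raw)
    ps.validate()
    assert set(ps.channels) == {"bg", "activity", "carbs", "bolus"}
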