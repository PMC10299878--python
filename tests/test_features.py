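import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swaylab import (
    COPTrial,
    ParameterError,
    average_features,
    mean_distance,
    mean_velocity,
    sway_area,
    trial_features,
)

from .conftest import make_circle_trial


def test_circle_mean_distance_equals_radius(circle_trial):
    md = mean_distance(circle_trial)
    assert md.overall == pytest.approx(1.0, abs=1e-9)


def test_circle_mean_velocity_matches_polyline_oracle(circle_trial):
    mv = mean_velocity(circle_trial)
    # oracle: explicit polyline length of the sampled circle
    steps = np.hypot(np.diff(circle_trial.ap), np.diff(circle_trial.ml))
    elapsed = (circle_trial.n_samples - 1) / circle_trial.fs
    assert mv.overall == pytest.approx(steps.sum() / elapsed, rel=1e-12)
    assert mv.overall == pytest.approx(2 * np.pi * 0.5 * 1.0, rel=1e-3)


def test_alternating_ap_channel():
    ap = np.tile([1.0, -1.0], 50)
    t = COPTrial(ap=ap, ml=np.zeros(100), fs=100.0)
    md = mean_distance(t)
    assert (md.ap, md.ml, md.overall) == (1.0, 0.0, 1.0)


def test_ramp_velocity():
    n = 3001
    t = COPTrial(ap=np.linspace(0, 30, n), ml=np.zeros(n), fs=100.0)
    mv = mean_velocity(t)
    assert mv.ap == pytest.approx(1.0, rel=1e-12)
    assert mv.ml == 0.0
    assert mv.overall == pytest.approx(1.0, rel=1e-12)


def test_constant_trial_zero_velocity_and_distance():
    t = COPTrial(ap=np.zeros(100), ml=np.zeros(100), fs=100.0)
    assert mean_velocity(t).overall == 0.0
    assert mean_distance(t).overall == 0.0


def test_mean_distance_requires_demeaned_input():
    t = COPTrial(ap=np.full(100, 3.0), ml=np.zeros(100), fs=100.0)
    with pytest.raises(ParameterError, match="demean"):
        mean_distance(t)


def test_sway_area_scaling_law(noise_trial):
    from swaylab import demean

    t = demean(noise_trial)
    base = sway_area(t)
    scaled = sway_area(t.replace(ap=3.0 * t.ap, ml=3.0 * t.ml))
    assert scaled == pytest.approx(9.0 * base, rel=1e-9)


def test_sway_area_degenerate_covariance_is_zero(caplog):
    t = COPTrial(ap=np.sin(np.linspace(0, 6.28, 100)), ml=np.zeros(100), fs=100.0)
    t = t.replace(ap=t.ap - t.ap.mean(), ml=t.ml)
    with caplog.at_level("WARNING"):
        assert sway_area(t) == 0.0
    assert "degenerate" in caplog.text


def test_brute_force_oracle_on_short_trials(rng):
    """Every time-domain measure equals a from-the-definition recomputation."""
    for _ in range(5):
        n = int(rng.integers(5, 50))
        ap = rng.normal(0, 2, n)
        ml = rng.normal(0, 1, n)
        ap -= ap.mean()
        ml -= ml.mean()
        t = COPTrial(ap=ap, ml=ml, fs=20.0)

        md = mean_distance(t)
        assert md.ap == pytest.approx(sum(abs(v) for v in ap) / n, abs=1e-9)
        assert md.overall == pytest.approx(
            sum((a**2 + m**2) ** 0.5 for a, m in zip(ap, ml)) / n, abs=1e-9
        )

        mv = mean_velocity(t)
        path = sum(
            ((ap[i + 1] - ap[i]) ** 2 + (ml[i + 1] - ml[i]) ** 2) ** 0.5
            for i in range(n - 1)
        )
        assert mv.overall == pytest.approx(path / ((n - 1) / 20.0), abs=1e-9)

        # covariance by explicit sums (sample, ddof=1)
        saa = sum(a * a for a in ap) / (n - 1)
        smm = sum(m * m for m in ml) / (n - 1)
        sam = sum(a * m for a, m in zip(ap, ml)) / (n - 1)
        det = saa * smm - sam * sam
        if det > 1e-10:
            expected = np.pi * 5.991464547107979 * det**0.5
            assert sway_area(t) == pytest.approx(expected, rel=1e-9)


def test_time_reversal_invariance(rng):
    ap = rng.normal(0, 2, 500)
    ml = rng.normal(0, 1, 500)
    t = COPTrial(ap=ap - ap.mean(), ml=ml - ml.mean(), fs=100.0)
    rev = t.replace(ap=t.ap[::-1].copy(), ml=t.ml[::-1].copy())
    assert mean_distance(rev).overall == pytest.approx(mean_distance(t).overall, rel=1e-12)
    assert mean_velocity(rev).overall == pytest.approx(mean_velocity(t).overall, rel=1e-12)
    assert sway_area(rev) == pytest.approx(sway_area(t), rel=1e-12)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(c=st.floats(min_value=0.05, max_value=20.0))
def test_amplitude_scaling_laws(c):
    # whole number of cycles, so the trajectory is centred by construction
    t = make_circle_trial(radius=1.0, duration=4.0)
    base_md = mean_distance(t)
    base_mv = mean_velocity(t)
    base_area = sway_area(t)
    s = t.replace(ap=c * t.ap, ml=c * t.ml)
    assert mean_distance(s).overall == pytest.approx(c * base_md.overall, rel=1e-9)
    assert mean_velocity(s).overall == pytest.approx(c * base_mv.overall, rel=1e-9)
    assert sway_area(s) == pytest.approx(c * c * base_area, rel=1e-9)


def test_directional_bounds_on_extracted_features(noise_trial):
    f = trial_features(noise_trial)
    assert f.mean_velocity.overall >= max(f.mean_velocity.ap, f.mean_velocity.ml)
    assert f.mean_velocity.overall <= f.mean_velocity.ap + f.mean_velocity.ml
    assert f.mean_distance.overall >= max(f.mean_distance.ap, f.mean_distance.ml)
    assert f.mean_distance.overall <= f.mean_distance.ap + f.mean_distance.ml
    assert f.sway_area >= 0


def test_average_features_contract(noise_trial, rng):
    others = [
        COPTrial(ap=rng.normal(0, 2, 3000), ml=rng.normal(0, 2, 3000), fs=100.0)
        for _ in range(2)
    ]
    feats = [trial_features(t) for t in (noise_trial, *others)]
    avg = average_features(feats)
    # identity on three identical sets (up to (a+a+a)/3 rounding)
    same = average_features([feats[0]] * 3)
    np.testing.assert_allclose(
        same.to_series().to_numpy(), feats[0].to_series().to_numpy(), rtol=1e-15
    )
    # element-wise mean and permutation invariance (up to fp addition order)
    assert avg.sway_area == pytest.approx(np.mean([f.sway_area for f in feats]))
    shuffled = average_features([feats[2], feats[0], feats[1]])
    np.testing.assert_allclose(
        shuffled.to_series().to_numpy(), avg.to_series().to_numpy(), rtol=1e-12
    )
    with pytest.raises(ParameterError):
        average_features(feats[:2])
    relaxed = average_features(feats[:1], require_three=False)
    assert relaxed.to_series().equals(feats[0].to_series())
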