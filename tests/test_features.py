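"""Feature extraction: normalisations, derivatives, rise-time estimators."""

import numpy as np
import pytest

from ratiodecode.dataset import SensorArrayDataset
from ratiodecode.features import FeatureMatrix, FeatureSpec, extract, pca_scores
from ratiodecode.simulate import ExperimentTimeline, SensorTimeSeries


def make_dataset(values_fn, n_samples=4, n_sensors=3, total=1000.0, injection=100.0):
    """Dataset whose differential traces are values_fn(i, j, t)."""
    tl = ExperimentTimeline(total_duration=total, injection_time=injection)
    t = tl.times()
    profiles = []
    for i in range(n_samples):
        cat = f"R{(i % 10) + 1}"
        for j in range(n_sensors):
            y = np.asarray(values_fn(i, j, t), dtype=float)
            profiles.append(
                SensorTimeSeries(
                    sample_id=f"s{i}",
                    category=cat,
                    sensor_id=f"S{j}",
                    times=t,
                    shifts={"differential": y},
                    timeline=tl,
                )
            )
    return SensorArrayDataset(profiles)


def first_order(f_inf, tau, injection=100.0):
    return lambda t: f_inf * -np.expm1(-np.clip(t - injection, 0, None) / tau)


class TestNormalisations:
    def test_autoscale_unit_rows(self):
        ds = make_dataset(lambda i, j, t: np.full(t.size, [3.0, 4.0, 0.0][j] + i))
        fm = extract(ds, FeatureSpec(name="AS"), 500.0)
        norms = np.linalg.norm(fm.values, axis=1)
        np.testing.assert_allclose(norms, 1.0)

    def test_autoscale_example_3_4_0(self):
        ds = make_dataset(lambda i, j, t: np.full(t.size, [3.0, 4.0, 0.0][j]), n_samples=1)
        fm = extract(ds, FeatureSpec(name="AS"), 500.0)
        np.testing.assert_allclose(fm.values[0], [0.6, 0.8, 0.0])

    def test_zscore_columns_standardised(self):
        rng = np.random.default_rng(0)
        base = rng.normal(100, 20, size=(8, 3))
        ds = make_dataset(lambda i, j, t: np.full(t.size, base[i, j]), n_samples=8)
        fm = extract(ds, FeatureSpec(name="Zscore"), 400.0)
        np.testing.assert_allclose(fm.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(fm.values.std(axis=0), 1.0)

    def test_zscore_constant_column_guard(self):
        ds = make_dataset(lambda i, j, t: np.full(t.size, 7.0), n_samples=5)
        fm = extract(ds, FeatureSpec(name="Zscore"), 400.0)
        np.testing.assert_array_equal(fm.values, 0.0)

    def test_autorange_unit_rms_columns(self):
        rng = np.random.default_rng(1)
        base = rng.normal(50, 10, size=(6, 3))
        ds = make_dataset(lambda i, j, t: np.full(t.size, base[i, j]), n_samples=6)
        fm = extract(ds, FeatureSpec(name="AR"), 400.0)
        rms = np.sqrt((fm.values**2).mean(axis=0))
        np.testing.assert_allclose(rms, 1.0)

    def test_xc_divides_by_volume_level(self):
        ds = make_dataset(lambda i, j, t: np.full(t.size, 10.0), n_samples=10)
        fm = extract(ds, FeatureSpec(name="XC"), 400.0)
        # categories cycle R1..R10: first five low (C=1), last five high (C=2)
        np.testing.assert_allclose(fm.values[:5], 10.0)
        np.testing.assert_allclose(fm.values[5:], 5.0)

    def test_ratiof_pairwise_ratios(self):
        ds = make_dataset(lambda i, j, t: np.full(t.size, [8.0, 4.0, 2.0][j]), n_samples=1)
        fm = extract(ds, FeatureSpec(name="RatioF"), 400.0)
        np.testing.assert_allclose(fm.values[0], [2.0, 4.0, 2.0])
        assert len(fm.feature_names) == 3


class TestTransients:
    def test_deriv_recovers_ramp_slope(self):
        ds = make_dataset(lambda i, j, t: (j + 1) * 0.5 * t)
        fm = extract(ds, FeatureSpec(name="Deriv"), 500.0)
        np.testing.assert_allclose(fm.values, [[0.5, 1.0, 1.5]] * 4, rtol=1e-9)

    @pytest.mark.parametrize("tau", [50.0, 150.0, 300.0])
    def test_tau1_recovers_tau_on_first_order_curves(self, tau):
        curve = first_order(400.0, tau)
        ds = make_dataset(lambda i, j, t: curve(t), n_samples=2, total=max(1000.0, 12 * tau))
        for frac in (0.05, 0.1, 0.5, 1.0, 2.0, 3.0):
            t_station = 100.0 + round(frac * tau)
            fm = extract(ds, FeatureSpec(name="Tau1"), t_station)
            np.testing.assert_allclose(fm.values, tau, rtol=0.01)

    @pytest.mark.parametrize("tau", [50.0, 150.0, 300.0])
    def test_tau2_matches_closed_form(self, tau):
        # for f = f_inf (1 - e^(-t/tau)):  f_inf / f'  =  tau * e^(t/tau)
        curve = first_order(400.0, tau)
        ds = make_dataset(lambda i, j, t: curve(t), n_samples=2, total=max(1000.0, 12 * tau))
        # stations where the symmetric slope window fits after injection
        fracs = (0.25, 0.5, 1.0) if tau < 100 else (0.1, 0.5, 1.0)
        for frac in fracs:
            t_station = 100.0 + round(frac * tau)
            dt = (t_station - 100.0) / tau
            fm = extract(ds, FeatureSpec(name="Tau2"), t_station)
            np.testing.assert_allclose(fm.values, tau * np.exp(dt), rtol=0.01)

    def test_off_grid_station_rejected(self, tiny_noiseless_dataset):
        with pytest.raises(ValueError, match="not on the acquisition grid"):
            extract(tiny_noiseless_dataset, FeatureSpec(name="Orig"), 100.5)

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            FeatureSpec(name="Wavelet")


class TestInvariances:
    def test_order_invariance_up_to_permutation(self, tiny_noiseless_dataset):
        ds = tiny_noiseless_dataset
        perm = list(reversed(ds.sample_ids))
        shuffled = ds.subset(perm)
        for name in ("Orig", "Zscore", "AS", "AR", "LnF", "Tau1"):
            a = extract(ds, FeatureSpec(name=name), 300.0)
            b = extract(shuffled, FeatureSpec(name=name), 300.0)
            lookup = {sid: row for sid, row in zip(b.sample_ids, b.values)}
            for sid, row in zip(a.sample_ids, a.values):
                np.testing.assert_allclose(row, lookup[sid], rtol=1e-10)


class TestPCA:
    def test_perfectly_correlated_sensors_one_component(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        X = np.column_stack([x, 2 * x, -x])
        res = pca_scores(X, n_components=1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(45, 3)) @ np.diag([3.0, 1.0, 0.3])
        res = pca_scores(X, n_components=3)
        evals = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        np.testing.assert_allclose(res.explained_variance, evals, rtol=1e-10)
        # scores reproduce the centred data in the component basis
        np.testing.assert_allclose(res.scores @ res.components, X - X.mean(0), atol=1e-10)

    def test_rank_truncation_warns(self):
        X = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.warns(UserWarning, match="rank"):
            res = pca_scores(X, n_components=2)
        assert res.scores.shape[1] == 1


class TestFeatureMatrix:
    def test_concat_requires_matching_samples(self):
        fm1 = FeatureMatrix(100.0, ["a"], [[1.0], [2.0]], ["R1", "R2"], ["s1", "s2"])
        fm2 = FeatureMatrix(100.0, ["b"], [[1.0], [2.0]], ["R1", "R2"], ["s1", "s3"])
        with pytest.raises(ValueError, match="different samples"):
            FeatureMatrix.concat([fm1, fm2])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            FeatureMatrix(0.0, ["a"], [[np.nan]], ["R1"], ["s1"])
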