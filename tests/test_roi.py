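"""ROI pipeline: residualisation, upsampling, epochs, per-timepoint GLM,
leave-one-out inference, PPI and the connectivity surface."""

import numpy as np
import pandas as pd
import pytest

from conformity.bold import hrf
from conformity.roi import (
    EPOCH_DT,
    EPOCH_POINTS,
    EpochMatrix,
    beta_timecourse,
    connectivity_grid,
    extract_epochs,
    loo_peak_test,
    ppi_timecourse,
    residualize,
    upsample,
    window_columns,
)


class TestResidualize:
    def test_signal_as_its_own_nuisance_vanishes(self, rng):
        y = rng.normal(0, 1, 200)
        r = residualize(y, y[:, None])
        assert np.allclose(r, 0.0, atol=1e-10)

    def test_orthogonal_nuisance_only_demeans(self, rng):
        n = 400
        y = np.sin(np.arange(n) * 0.1) + 5.0
        nuis = rng.normal(0, 1, (n, 3))
        nuis -= nuis.mean(0)
        # project the nuisance out of y first so they are exactly orthogonal
        y_orth = y - nuis @ np.linalg.lstsq(nuis, y, rcond=None)[0]
        r = residualize(y_orth, nuis)
        assert np.allclose(r, y_orth - y_orth.mean(), atol=1e-9)

    def test_known_motion_mixture_removed(self, rng):
        n = 500
        motion = np.cumsum(rng.normal(0, 0.1, (n, 6)), axis=0)
        clean = rng.normal(0, 1, n)
        contaminated = clean + motion @ rng.normal(0, 0.5, 6)
        r = residualize(contaminated, motion)
        for j in range(6):
            assert abs(np.corrcoef(r, motion[:, j])[0, 1]) < 1e-6

    def test_rank_deficient_nuisance_warns(self, rng):
        y = rng.normal(0, 1, 100)
        col = rng.normal(0, 1, 100)
        with pytest.warns(UserWarning, match="rank deficient"):
            residualize(y, np.column_stack([col, col]))


class TestUpsample:
    def test_constant_series_stays_constant(self):
        t, v = upsample(np.full(40, 3.3), tr=3.74)
        assert np.allclose(v, 3.3)
        assert t[1] - t[0] == pytest.approx(EPOCH_DT)

    def test_sample_count_ratio(self):
        t, v = upsample(np.zeros(100), tr=3.74)
        assert len(v) / 100 == pytest.approx(3.74 / 0.2, rel=0.02)

    def test_smooth_sinusoid_interpolated_accurately(self):
        tr, n = 3.74, 200
        coarse = np.arange(n) * tr
        period = 60.0  # far below the TR Nyquist limit
        y = np.sin(2 * np.pi * coarse / period)
        t, v = upsample(y, tr)
        err = np.abs(v - np.sin(2 * np.pi * t / period))
        assert err.max() < 0.01  # < 1% of unit amplitude


class TestExtractEpochs:
    def test_window_geometry(self):
        times = np.arange(0, 200, EPOCH_DT)
        values = times.copy()
        ep = extract_epochs(times, values, [100.0])
        assert ep.data.shape == (1, EPOCH_POINTS)
        assert ep.data[0, 0] == pytest.approx(99.0)  # onset - 1 s
        assert ep.data[0, -1] == pytest.approx(113.8)
        assert ep.rel_times[0] == pytest.approx(-1.0)
        assert ep.rel_times[-1] == pytest.approx(13.8)

    def test_impulse_lands_at_expected_column(self):
        times = np.arange(0, 120, EPOCH_DT)
        values = np.zeros_like(times)
        onset = 50.0
        values[int(round((onset + 5.0) / EPOCH_DT))] = 1.0
        ep = extract_epochs(times, values, [onset])
        assert np.argmax(ep.data[0]) == 30  # (5 + 1) / 0.2

    def test_all_valid_onsets_kept(self):
        times = np.arange(0, 800, EPOCH_DT)
        values = np.random.default_rng(0).normal(size=times.size)
        onsets = np.linspace(20, 700, 30)
        ep = extract_epochs(times, values, onsets)
        assert ep.data.shape == (30, EPOCH_POINTS)

    def test_edge_epochs_dropped_with_warning(self):
        times = np.arange(0, 100, EPOCH_DT)
        values = np.zeros_like(times)
        with pytest.warns(UserWarning, match="outside the run"):
            ep = extract_epochs(times, values, [0.5, 50.0, 95.0])
        assert ep.kept.tolist() == [False, True, False]
        assert ep.data.shape == (1, EPOCH_POINTS)


def _epochs_from(data):
    n, T = data.shape
    return EpochMatrix(
        data=data, rel_times=-1.0 + EPOCH_DT * np.arange(T),
        kept=np.ones(n, bool),
    )


class TestBetaTimecourse:
    def test_constructed_encoding_recovered_with_hrf_shape(self, rng):
        """Epochs built as w * conf * hrf yield a confidence beta time course
        proportional to the HRF with the injected sign."""
        n = 40
        conf = rng.uniform(0, 1, n)
        shape = hrf(np.maximum(_epochs_from(np.zeros((1, 75))).rel_times, 0.0))
        w = -0.7
        zconf = (conf - conf.mean()) / conf.std()
        data = 1.0 * shape[None, :] + w * zconf[:, None] * shape[None, :]
        bt = beta_timecourse(_epochs_from(data), pd.DataFrame({"conf": conf}))
        curve = bt.curve("conf")
        peak = curve[np.argmax(np.abs(curve))]
        assert peak < 0
        assert np.corrcoef(curve, w * shape)[0, 1] > 0.999

    def test_permuted_modulator_has_no_effect(self, rng):
        n = 60
        conf = rng.uniform(0, 1, n)
        shape = hrf(np.maximum(-1.0 + EPOCH_DT * np.arange(75), 0.0))
        data = (1 + conf[:, None]) * shape[None, :]
        perm = rng.permutation(conf)
        bt = beta_timecourse(_epochs_from(data), pd.DataFrame({"x": perm}))
        assert np.abs(bt.curve("x")).max() < 0.15 * np.abs(bt.curve("intercept")).max()

    def test_two_injected_weights_recovered_in_ratio(self, rng):
        n = 200
        a, b = rng.normal(0, 1, n), rng.normal(0, 1, n)
        shape = hrf(np.maximum(-1.0 + EPOCH_DT * np.arange(75), 0.0))
        data = (2.0 * a + 1.0 * b)[:, None] * shape[None, :]
        bt = beta_timecourse(
            _epochs_from(data), pd.DataFrame({"a": a, "b": b}), standardize=False
        )
        k = np.argmax(np.abs(bt.curve("a")))
        assert bt.curve("a")[k] / bt.curve("b")[k] == pytest.approx(2.0, rel=1e-6)

    def test_constant_modulator_flagged_undefined(self, rng):
        data = rng.normal(0, 1, (20, 75))
        with pytest.warns(UserWarning, match="constant modulator"):
            bt = beta_timecourse(_epochs_from(data), pd.DataFrame({"c": np.ones(20)}))
        assert np.isnan(bt.curve("c")).all()


class TestLooPeak:
    def test_identical_curves_collect_the_shared_peak(self):
        shape = hrf(np.maximum(-1.0 + EPOCH_DT * np.arange(75), 0.0))
        B = np.tile(0.8 * shape, (20, 1))
        res = loo_peak_test(B)
        assert np.allclose(res.values, 0.8)
        assert res.test.p < 0.01
        assert np.allclose(res.peak_times, 5.0, atol=0.3)

    def test_sign_flip_flips_values_keeps_p(self, rng):
        B = rng.normal(0.3, 1.0, (15, 75))
        a, b = loo_peak_test(B), loo_peak_test(-B)
        assert np.allclose(a.values, -b.values)
        assert a.test.p == pytest.approx(b.test.p)

    def test_needs_three_participants(self, rng):
        with pytest.raises(ValueError):
            loo_peak_test(rng.normal(size=(2, 75)))


class TestPpi:
    def test_scale_invariance_of_standardised_seed(self, rng):
        n = 50
        seed = _epochs_from(rng.normal(0, 1, (n, 75)))
        target = _epochs_from(rng.normal(0, 1, (n, 75)))
        mods = pd.DataFrame(
            {"conf_norm": rng.uniform(0, 1, n), "prev_influence": rng.uniform(0, 1, n)}
        )
        r1 = ppi_timecourse(target, seed, mods)
        seed10 = _epochs_from(seed.data * 10.0)
        r2 = ppi_timecourse(target, seed10, mods)
        assert np.allclose(r1.coefs, r2.coefs, atol=1e-9)

    def test_gain_modulated_target_yields_triple_interaction(self, rng):
        """Direct construction: target = (1 + g * zc * zf) * seed."""
        n = 60
        c = rng.uniform(0, 1, n)
        f = rng.uniform(0, 1, n)
        zc = (c - c.mean()) / c.std()
        zf = (f - f.mean()) / f.std()
        seed_data = rng.normal(0, 1, (n, 75))
        gain = 1.0 + 0.6 * zc * zf
        target = _epochs_from(gain[:, None] * seed_data)
        res = ppi_timecourse(
            target, _epochs_from(seed_data),
            pd.DataFrame({"conf_norm": c, "prev_influence": f}),
        )
        tri = res.curve("seed:conf_norm:prev_influence")
        assert np.median(tri) > 0.3

    def test_null_coupling_interactions_near_zero(self, rng):
        n = 80
        seed_data = rng.normal(0, 1, (n, 75))
        target = _epochs_from(2.0 * seed_data + 0.05 * rng.normal(0, 1, (n, 75)))
        res = ppi_timecourse(
            target, _epochs_from(seed_data),
            pd.DataFrame({"conf_norm": rng.uniform(0, 1, n),
                          "prev_influence": rng.uniform(0, 1, n)}),
        )
        for term in ("seed:conf_norm", "seed:prev_influence",
                     "seed:conf_norm:prev_influence"):
            assert np.abs(res.curve(term)).max() < 0.05


class TestConnectivityGrid:
    def test_window_covers_six_columns(self):
        rel = -1.0 + EPOCH_DT * np.arange(75)
        assert window_columns(rel, 2.0, 3.0).sum() == 6

    def test_zero_interactions_flat_surface(self):
        g = connectivity_grid({"seed": 0.4})
        assert np.allclose(g.grid, 0.4)
        assert g.grid.shape == (17, 17)  # [-2, 2] step 0.25

    def test_pure_product_interaction_is_a_symmetric_saddle(self):
        g = connectivity_grid({"seed": 0.0, "seed:conf_norm:prev_influence": 0.5})
        # bilinear form: invariant under joint sign flip of both axes
        assert np.allclose(g.grid, g.grid[::-1, ::-1])
        assert g.grid.max() == pytest.approx(0.5 * 4)
        assert g.grid.min() == pytest.approx(-0.5 * 4)
        # anti-symmetric under flipping a single axis
        assert np.allclose(g.grid, -g.grid[::-1, :])
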