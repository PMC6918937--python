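"""Histogram MI estimator and the channel-pair adjacency assembly."""

import collections
import math

import numpy as np
import pytest

from fatiguenet import (
    EpochSet,
    MIEstimatorConfig,
    WeightedAdjacency,
    adjacency_from_epochs,
    mean_mi,
    mutual_information,
)
from fatiguenet.connectivity import read_adjacency_csv, write_adjacency_csv


def _count_table_mi(x, y, n_bins, correct):
    """Independent oracle: MI from explicit joint/marginal count dictionaries."""
    def bins(v):
        lo, hi = min(v), max(v)
        out = []
        for s in v:
            b = int((s - lo) / (hi - lo) * n_bins)
            out.append(min(b, n_bins - 1))
        return out

    bx, by = bins(x), bins(y)
    n = len(x)
    joint = collections.Counter(zip(bx, by))
    mx = collections.Counter(bx)
    my = collections.Counter(by)
    mi = 0.0
    for (i, j), c in joint.items():
        pxy = c / n
        mi += pxy * math.log(pxy / ((mx[i] / n) * (my[j] / n)))
    if correct:
        mi -= (len(joint) - len(mx) - len(my) + 1) / (2 * n)
    return max(mi, 0.0)


class TestMutualInformation:
    def test_symmetric_exactly(self, rng):
        x = rng.standard_normal(1280)
        y = rng.standard_normal(1280)
        assert mutual_information(x, y) == mutual_information(y, x)

    def test_identity_channel_equals_binned_entropy(self):
        # x uniform over bins: plug-in MI(x, x) = H(binned x) = ln(n_bins)
        n_bins = 16
        x = np.tile(np.arange(n_bins, dtype=float), 80)  # 1280 samples
        cfg = MIEstimatorConfig(n_bins=n_bins, bias_correction=False)
        assert mutual_information(x, x, cfg) == pytest.approx(np.log(n_bins), abs=1e-12)

    def test_matches_count_table_oracle(self, rng):
        # small integer-valued inputs: bin index = value, so the estimator
        # must agree with the explicit count-table computation to 1e-12
        for correct in (False, True):
            for trial in range(5):
                k = int(rng.integers(3, 7))
                x = rng.integers(0, k, size=200).astype(float)
                y = rng.integers(0, k, size=200).astype(float)
                cfg = MIEstimatorConfig(n_bins=k, bias_correction=correct)
                ours = mutual_information(x, y, cfg)
                oracle = _count_table_mi(x.tolist(), y.tolist(), k, correct)
                assert ours == pytest.approx(oracle, abs=1e-12)

    def test_independent_noise_floor(self):
        # bias-corrected MI of independent uniform noise stays tiny
        vals = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            vals.append(
                mutual_information(
                    r.uniform(size=1280), r.uniform(size=1280),
                    MIEstimatorConfig(n_bins=16),
                )
            )
        assert np.percentile(vals, 95) < 0.05

    def test_gaussian_closed_form(self):
        # MI of a bivariate Gaussian is -0.5 ln(1 - rho^2)
        rho = 0.9
        expected = -0.5 * np.log(1 - rho**2)
        estimates = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = r.standard_normal(12800)
            y = rho * x + np.sqrt(1 - rho**2) * r.standard_normal(12800)
            estimates.append(mutual_information(x, y, MIEstimatorConfig(n_bins=16)))
        assert np.mean(estimates) == pytest.approx(expected, rel=0.15)

    def test_constant_input_is_zero_with_warning(self):
        x = np.ones(1280)
        y = np.arange(1280, dtype=float)
        with pytest.warns(UserWarning):
            assert mutual_information(x, y) == 0.0

    def test_input_validation(self, rng):
        with pytest.raises(ValueError):
            mutual_information(np.arange(100.0), np.arange(101.0))
        with pytest.raises(ValueError):
            # 16 bins need at least 64 samples
            mutual_information(
                np.arange(40.0), np.arange(40.0), MIEstimatorConfig(n_bins=16)
            )
        bad = np.arange(1280.0)
        bad[5] = np.nan
        with pytest.raises(ValueError):
            mutual_information(bad, np.arange(1280.0))

    def test_default_bin_rule(self):
        assert MIEstimatorConfig().bins_for(1280) == 16

    def test_added_noise_cannot_raise_mi(self):
        # data-processing sanity, checked in the mean over seeds
        clean, noisy = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.standard_normal(1280)
            y = x + 0.5 * r.standard_normal(1280)
            y2 = y + 2.0 * r.standard_normal(1280)
            clean.append(mutual_information(x, y))
            noisy.append(mutual_information(x, y2))
        assert np.mean(noisy) < np.mean(clean)


class TestAdjacency:
    def _epochs_from(self, arr2d, n_epochs=1):
        data = np.repeat(arr2d[None, :, :], n_epochs, axis=0)
        labels = tuple(f"ch{i:02d}" for i in range(arr2d.shape[1]))
        return EpochSet(data, fs=256.0, channels=labels, meta={"band": "alpha1"})

    def test_identical_channels_saturate(self, rng):
        x = rng.standard_normal(1280)
        es = self._epochs_from(np.tile(x[:, None], (1, 19)))
        adj = adjacency_from_epochs(es)
        off = adj.values[~np.eye(19, dtype=bool)]
        assert np.allclose(off, off[0])
        assert off[0] > 2.0  # near ln(16), far above any noise floor

    def test_independent_channels_near_zero(self, rng):
        es = self._epochs_from(rng.standard_normal((1280, 19)), n_epochs=3)
        adj = adjacency_from_epochs(es)
        assert mean_mi(adj) < 0.05

    def test_matches_pairwise_scalar_estimator(self, rng):
        sig = rng.standard_normal((640, 5))
        es = self._epochs_from(sig)
        adj = adjacency_from_epochs(es)
        cfg = MIEstimatorConfig()
        for i in range(5):
            for j in range(i + 1, 5):
                expected = mutual_information(sig[:, i], sig[:, j], cfg)
                assert adj.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_epoch_averaging(self, rng):
        a = rng.standard_normal((640, 3))
        b = rng.standard_normal((640, 3))
        es = EpochSet(
            np.stack([a, b]), fs=256.0, channels=("x", "y", "z")
        )
        adj = adjacency_from_epochs(es)
        cfg = MIEstimatorConfig()
        expected = 0.5 * (
            mutual_information(a[:, 0], a[:, 1], cfg)
            + mutual_information(b[:, 0], b[:, 1], cfg)
        )
        assert adj.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_invariants_of_produced_matrix(self, rng):
        es = self._epochs_from(rng.standard_normal((640, 8)))
        adj = adjacency_from_epochs(es)
        assert np.array_equal(adj.values, adj.values.T)
        assert (adj.values >= 0).all()
        assert np.all(np.diag(adj.values) == 0)

    def test_validation_rejects_bad_matrices(self):
        with pytest.raises(ValueError):
            WeightedAdjacency(np.array([[0.0, 1.0], [2.0, 0.0]]), ("a", "b"))
        with pytest.raises(ValueError):
            WeightedAdjacency(np.array([[0.0, -1.0], [-1.0, 0.0]]), ("a", "b"))


class TestMeanMI:
    def test_trivial_values(self):
        labels = tuple("abcd")
        zeros = WeightedAdjacency(np.zeros((4, 4)), labels)
        assert mean_mi(zeros) == 0.0
        vals = np.full((4, 4), 0.2)
        np.fill_diagonal(vals, 0.0)
        assert mean_mi(WeightedAdjacency(vals, labels)) == pytest.approx(0.2)

    def test_matches_brute_force_loop(self, rng):
        n = 19
        vals = rng.uniform(size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        adj = WeightedAdjacency(vals, tuple(f"c{i}" for i in range(n)))
        acc = [vals[i, j] for i in range(n) for j in range(i + 1, n)]
        assert len(acc) == 171
        assert mean_mi(adj) == pytest.approx(np.mean(acc), abs=1e-14)


def test_adjacency_csv_roundtrip(tmp_path, rng):
    vals = rng.uniform(size=(5, 5))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    adj = WeightedAdjacency(vals, ("Fp1", "Fp2", "F3", "F4", "Cz"), rhythm="alpha1")
    path = tmp_path / "adj.csv"
    write_adjacency_csv(adj, path)
    back = read_adjacency_csv(path, rhythm="alpha1")
    assert back.channels == adj.channels
    assert np.allclose(back.values, adj.values, atol=1e-12)
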