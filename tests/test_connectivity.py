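"""Envelope extraction, LOFC/HOFC construction, Fisher z."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_connectivity
from eegnetkit.connectivity import (
    ConnectivityMatrix,
    EnvelopeMatrix,
    amplitude_envelope,
    compute_hofc,
    compute_lofc,
    fisher_z,
    mean_connectivity,
)
from eegnetkit.montage import MONTAGE_16
from eegnetkit.preprocess import BandSignals


def _env(data, band="alpha", rate=128.0, n=None):
    n = n or data.shape[0]
    return EnvelopeMatrix(
        data=np.abs(data), band=band, rate=rate, channel_labels=MONTAGE_16[:n]
    )


class TestEnvelope:
    def test_constant_tone_envelope_equals_amplitude(self):
        t = np.arange(int(8 * 128)) / 128
        x = 2.0 * np.sin(2 * np.pi * 10 * t)
        bs = BandSignals(band="alpha", data=np.tile(x, (16, 1)), rate=128.0,
                         channel_labels=MONTAGE_16)
        env = amplitude_envelope(bs).data[0]
        interior = env[64:-64]
        assert np.abs(interior - 2.0).max() < 0.1  # < 5% of amplitude 2

    def test_am_tone_envelope_tracks_modulation(self):
        t = np.arange(int(16 * 128)) / 128
        modulation = 1 + 0.5 * np.cos(2 * np.pi * 1 * t)
        x = modulation * np.cos(2 * np.pi * 10 * t)
        bs = BandSignals(band="alpha", data=np.tile(x, (16, 1)), rate=128.0,
                         channel_labels=MONTAGE_16)
        env = amplitude_envelope(bs).data[0]
        interior = slice(128, -128)
        rmse = np.sqrt(np.mean((env[interior] - modulation[interior]) ** 2))
        assert rmse / np.sqrt(np.mean(modulation[interior] ** 2)) < 0.05

    def test_zero_signal_zero_envelope(self):
        bs = BandSignals(band="alpha", data=np.zeros((16, 1280)), rate=128.0,
                         channel_labels=MONTAGE_16)
        assert np.allclose(amplitude_envelope(bs).data, 0.0)

    def test_too_short_segment_names_minimum(self):
        bs = BandSignals(band="delta", data=np.ones((16, 100)), rate=128.0,
                         channel_labels=MONTAGE_16)
        with pytest.raises(ValueError, match="256"):
            amplitude_envelope(bs)


class TestLOFC:
    def test_identical_channels_give_unit_weight(self, rng):
        base = rng.uniform(0.5, 2.0, size=200)
        data = np.vstack([base, base, rng.uniform(0.5, 2.0, (2, 200))])
        w = compute_lofc(_env(data, n=4)).weights
        assert w[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_channels_give_unit_weight(self, rng):
        base = rng.uniform(0.5, 2.0, size=200)
        data = np.vstack([base, 3.0 - base, rng.uniform(0.5, 2.0, (2, 200))])
        w = compute_lofc(_env(data, n=4)).weights
        assert w[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_two_pass_covariance_oracle(self):
        # fixed 4-channel toy block
        data = np.array([
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [2.0, 1.0, 4.0, 3.0, 6.0],
            [5.0, 3.0, 1.0, 2.0, 2.5],
            [0.5, 1.5, 2.5, 2.0, 3.5],
        ])
        w = compute_lofc(_env(data, n=4)).weights
        n = 4
        for i in range(n):
            for j in range(i + 1, n):
                a, b = data[i], data[j]
                da, db = a - a.mean(), b - b.mean()
                r = (da * db).sum() / np.sqrt((da**2).sum() * (db**2).sum())
                assert w[i, j] == pytest.approx(abs(r), abs=1e-12)

    def test_zero_variance_channel_named_in_error(self):
        data = np.ones((4, 100))
        data[1:] += np.random.default_rng(0).standard_normal((3, 100))
        with pytest.raises(ValueError, match="FP1"):
            compute_lofc(_env(data, n=4))

    def test_affine_invariance(self, rng):
        data = rng.uniform(0.1, 2.0, size=(6, 300))
        w1 = compute_lofc(_env(data, n=6)).weights
        gains = rng.uniform(0.5, 3.0, size=(6, 1))
        offsets = rng.uniform(0.0, 5.0, size=(6, 1))
        w2 = compute_lofc(_env(gains * data + offsets, n=6)).weights
        assert np.allclose(w1, w2, atol=1e-10)


class TestFisherZ:
    def test_closed_form_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(1.5 / 0.5), abs=1e-12)
        z1 = fisher_z(1.0)
        assert z1 == pytest.approx(np.arctanh(1 - 1e-7), abs=1e-9)
        assert 7.5 < z1 < 8.5

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(np.nan)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
    def test_odd_and_monotone(self, a, b):
        assert fisher_z(-a) == pytest.approx(-fisher_z(a), abs=1e-12)
        if a < b:
            assert fisher_z(a) < fisher_z(b)


class TestHOFC:
    def test_identical_profiles_give_unit_hofc(self, rng):
        n = 6
        w = rng.uniform(0.1, 0.9, size=(n, n))
        w = (w + w.T) / 2
        w[0, 2:] = w[1, 2:]
        w[2:, 0] = w[2:, 1]
        w[0, 1] = w[1, 0] = 0.5
        np.fill_diagonal(w, 0.0)
        cm = ConnectivityMatrix(weights=w, order="low", band="delta",
                                channel_labels=MONTAGE_16[:n])
        h = compute_hofc(cm)
        assert h.weights[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_orthogonalized_profiles_give_zero(self):
        # 5 nodes: construct columns 0 and 1 so that over the 3 shared rows
        # the Fisher-z profiles are exactly uncorrelated.
        n = 5
        w = np.zeros((n, n))
        prof0 = np.array([0.2, 0.5, 0.8])
        prof1 = np.array([0.3, 0.7, 0.3])
        z0 = np.arctanh(prof0)
        z1 = np.arctanh(prof1)
        # Gram-Schmidt in z-space: remove the centered projection of z1 on z0
        z0c = z0 - z0.mean()
        z1c = z1 - z1.mean()
        z1_orth = z1c - (z1c @ z0c) / (z0c @ z0c) * z0c + z1.mean()
        prof1 = np.tanh(z1_orth)
        rows = [2, 3, 4]
        for k, r in enumerate(rows):
            w[r, 0] = w[0, r] = prof0[k]
            w[r, 1] = w[1, r] = prof1[k]
        w[0, 1] = w[1, 0] = 0.4
        w[2, 3] = w[3, 2] = w[3, 4] = w[4, 3] = w[2, 4] = w[4, 2] = 0.25
        cm = ConnectivityMatrix(weights=w, order="low", band="delta",
                                channel_labels=MONTAGE_16[:n])
        h = compute_hofc(cm)
        assert h.weights[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_matches_explicit_deletion_oracle(self, rng):
        cm = random_connectivity(rng, n=6)
        h = compute_hofc(cm).weights
        z = np.arctanh(np.clip(cm.weights, -(1 - 1e-7), 1 - 1e-7))
        n = 6
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                keep = [k for k in range(n) if k not in (i, j)]
                a, b = z[keep, i], z[keep, j]
                da, db = a - a.mean(), b - b.mean()
                r = (da * db).sum() / np.sqrt((da**2).sum() * (db**2).sum())
                assert h[i, j] == pytest.approx(abs(r), abs=1e-12)

    def test_permutation_equivariance(self, rng):
        cm = random_connectivity(rng, n=8)
        h = compute_hofc(cm).weights
        perm = rng.permutation(8)
        wp = cm.weights[np.ix_(perm, perm)]
        cmp_ = ConnectivityMatrix(weights=wp, order="low", band="delta",
                                  channel_labels=tuple(MONTAGE_16[p] for p in perm))
        hp = compute_hofc(cmp_).weights
        assert np.allclose(hp, h[np.ix_(perm, perm)], atol=1e-10)

    def test_too_few_nodes_rejected(self, rng):
        cm = random_connectivity(rng, n=3)
        with pytest.raises(ValueError, match="4 nodes"):
            compute_hofc(cm)

    def test_requires_low_order_input(self, rng):
        cm = random_connectivity(rng, n=6, order="high")
        with pytest.raises(ValueError, match="low-order"):
            compute_hofc(cm)


class TestMeanConnectivity:
    def test_uniform_half(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 0.0)
        cm = ConnectivityMatrix(weights=w, order="low", band="delta",
                                channel_labels=MONTAGE_16[:4])
        assert mean_connectivity(cm) == pytest.approx(0.5)

    def test_empty_graph_zero(self):
        cm = ConnectivityMatrix(weights=np.zeros((4, 4)), order="low", band="delta",
                                channel_labels=MONTAGE_16[:4])
        assert mean_connectivity(cm) == 0.0

    def test_three_node_mean(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.2
        w[0, 2] = w[2, 0] = 0.4
        w[1, 2] = w[2, 1] = 0.6
        cm = ConnectivityMatrix(weights=w, order="low", band="delta",
                                channel_labels=MONTAGE_16[:3])
        assert mean_connectivity(cm) == pytest.approx(0.4, abs=1e-12)


class TestMatrixIO:
    def test_csv_and_json_roundtrip(self, rng, tmp_path):
        from eegnetkit.connectivity import (
            load_matrix_csv,
            load_matrix_json,
            save_matrix_csv,
            save_matrix_json,
        )

        cm = random_connectivity(rng, n=6, band="theta")
        save_matrix_csv(cm, tmp_path / "m.csv")
        back = load_matrix_csv(tmp_path / "m.csv", order="low", band="theta")
        assert np.allclose(back.weights, cm.weights, atol=1e-10)
        assert back.channel_labels == cm.channel_labels

        save_matrix_json(cm, tmp_path / "m.json")
        back = load_matrix_json(tmp_path / "m.json")
        assert np.allclose(back.weights, cm.weights)
        assert back.band == "theta" and back.order == "low"
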