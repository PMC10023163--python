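import numpy as np
import pandas as pd
import pytest

from synaptoscope import synthgen
from synaptoscope.synthgen import (
    CAV1_PRESET,
    CAV2_PRESET,
    DANTROLENE_NEMADIPINE_PRESET,
    NEMADIPINE_PRESET,
    QuantalSimConfig,
    SynapseSimConfig,
    lognormal_params,
    sample_ztp,
    simulate_minis,
    simulate_synapse,
    simulate_tracks,
    simulate_vesicle_profiles,
    ztp_rate,
)


class TestBlinkModel:
    def test_ztp_rate_solves_observed_mean(self):
        lam = ztp_rate(2.7)
        # independent check of the defining identity, and the frozen root
        assert lam / (1 - np.exp(-lam)) == pytest.approx(2.7, abs=1e-9)
        assert lam == pytest.approx(2.4721, abs=1e-3)

    def test_ztp_rate_rejects_mean_at_most_one(self):
        with pytest.raises(ValueError):
            ztp_rate(1.0)

    def test_sample_ztp_never_zero_and_mean_matches(self, rng):
        lam = ztp_rate(2.7)
        draws = sample_ztp(rng, lam, 10_000)
        assert draws.min() >= 1
        assert draws.mean() == pytest.approx(2.7, abs=0.05)


class TestPhotonModel:
    def test_lognormal_params_match_mode_and_mean(self):
        mu, sigma = lognormal_params(575, 765)
        assert np.exp(mu - sigma**2) == pytest.approx(575)
        assert np.exp(mu + sigma**2 / 2) == pytest.approx(765)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            lognormal_params(800, 765)


class TestSimulateSynapse:
    def test_zero_channels_empty(self):
        cfg = SynapseSimConfig(
            name="empty", probe="CaV1", channels_per_synapse=0,
            placement=("dispersed", 1000.0, 100.0),
        )
        locs, ledger = simulate_synapse(cfg, seed=0)
        assert len(locs) == 0
        assert ledger["n_channels"] == 0

    def test_unsatisfiable_blink_mean_is_config_error(self):
        with pytest.raises(ValueError):
            SynapseSimConfig(
                name="bad", probe="CaV1", channels_per_synapse=10,
                placement=("dispersed", 1000.0, 100.0), blink_mean=0.9,
            )

    def test_same_seed_identical_output(self):
        a, la = simulate_synapse(CAV1_PRESET, seed=42)
        b, lb = simulate_synapse(CAV1_PRESET, seed=42)
        pd.testing.assert_frame_equal(a.data, b.data)
        np.testing.assert_array_equal(la["blink_channel"], lb["blink_channel"])

    def test_ledger_self_consistent(self):
        locs, ledger = simulate_synapse(CAV1_PRESET, seed=1)
        # grouping the ledger's own blink assignments reproduces the
        # number of visible channels exactly
        visible = len(np.unique(ledger["blink_channel"]))
        assert visible == ledger["n_channels"] - ledger["n_dark"]
        assert ledger["blinks_per_channel"].sum() == len(locs)

    def test_blink_mean_across_many_channels(self):
        rng = np.random.default_rng(2)
        total_blinks = 0
        total_channels = 0
        for _ in range(130):
            locs, ledger = simulate_synapse(CAV1_PRESET, rng)
            total_blinks += len(locs)
            total_channels += ledger["n_channels"]
        assert total_blinks / total_channels == pytest.approx(2.7, abs=0.05)

    def test_hardcore_separation_enforced(self):
        from scipy.spatial.distance import pdist

        _, ledger = simulate_synapse(CAV1_PRESET, seed=3)
        assert pdist(ledger["channel_positions"]).min() >= CAV1_PRESET.placement[2]

    def test_dense_cluster_within_diameter(self):
        _, ledger = simulate_synapse(CAV2_PRESET, seed=4)
        r = np.linalg.norm(ledger["channel_positions"], axis=1)
        assert r.max() <= CAV2_PRESET.placement[1] / 2 + 1e-9

    def test_dark_fraction_reduces_visible_channels(self):
        cfg = SynapseSimConfig(
            name="dark", probe="CaV1", channels_per_synapse=500,
            placement=("dispersed", 4000.0, 100.0), dark_fraction=0.3,
        )
        _, ledger = simulate_synapse(cfg, seed=5)
        assert ledger["n_dark"] == pytest.approx(150, abs=40)

    def test_precision_all_within_filter_range(self):
        locs, _ = simulate_synapse(CAV1_PRESET, seed=6)
        prec = locs.data["precision_nm"]
        assert (prec > 0).all()
        # typical blinks localize to ~15-30 nm
        assert 10 < prec.median() < 35


class TestSimulateMinis:
    def test_degenerate_single_class(self):
        cfg = QuantalSimConfig(name="d", mode=7.0, weights=(1.0, 0.0, 0.0), sigma1=0.0)
        amps, classes = simulate_minis(cfg, 100, seed=0)
        np.testing.assert_allclose(amps, 7.0)
        assert (classes == 1).all()

    def test_class_frequencies_match_weights(self):
        amps, classes = simulate_minis(NEMADIPINE_PRESET, 100_000, seed=1)
        freqs = np.bincount(classes, minlength=4)[1:] / 100_000
        np.testing.assert_allclose(freqs, (0.67, 0.18, 0.15), atol=0.005)

    def test_mixture_mean_closed_form(self):
        cfg = DANTROLENE_NEMADIPINE_PRESET
        amps, _ = simulate_minis(cfg, 100_000, seed=2)
        expected = sum(w * k * cfg.mode for k, w in zip((1, 2, 3), cfg.weights))
        assert expected == pytest.approx(8.1)
        assert amps.mean() == pytest.approx(expected, abs=0.05)

    def test_all_positive(self):
        amps, _ = simulate_minis(NEMADIPINE_PRESET, 50_000, seed=3)
        assert (amps > 0).all()

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            QuantalSimConfig(name="bad", mode=7.0, weights=(0.5, 0.2, 0.2))


class TestSimulateVesicles:
    def test_no_depletion_same_law(self):
        ns, st = simulate_vesicle_profiles(300, depletion=0.0, seed=4)
        mean_ns = ns["distance_nm"].notna().groupby(ns["synapse_id"]).sum().mean()
        mean_st = st["distance_nm"].notna().groupby(st["synapse_id"]).sum().mean()
        total = synthgen.DEFAULT_DOCKED_PROFILE.sum()
        assert mean_ns == pytest.approx(total, rel=0.1)
        assert mean_st == pytest.approx(total, rel=0.1)

    def test_full_depletion_first_bin_empties_it(self):
        depletion = np.zeros(18)
        depletion[0] = 1.0
        _, st = simulate_vesicle_profiles(100, depletion=depletion, seed=5)
        d = st["distance_nm"].dropna()
        assert (d >= 33.0).all()


class TestSimulateTracks:
    def test_deterministic_under_seed(self):
        a, ba = simulate_tracks(2, seed=6)
        b, bb = simulate_tracks(2, seed=6)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.x_um, tb.x_um)
        assert ba == bb

    def test_ledger_covers_every_frame(self):
        tracks, ledgers = simulate_tracks(3, seed=7)
        for tr, bouts in zip(tracks, ledgers):
            covered = sum(e - s + 1 for _, s, e in bouts)
            assert covered == len(tr.t_s)
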