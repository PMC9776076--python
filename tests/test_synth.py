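"""Synthetic EEG generator: determinism, coupling recovery, spectra."""

import numpy as np
import pytest
from scipy.signal import periodogram

from eegfc import (BAND_BY_NAME, CouplingSpec, SyntheticConfig,
                   default_montage, epoch_mi_matrix, generate_experiment,
                   generate_stage, ground_truth_coupling, null_config,
                   subject_seed, vr_effect_config)

BAND = BAND_BY_NAME["low_gamma"]


def pair_config(gain=1.0, seed=0, duration=20.0, band=BAND):
    montage = default_montage()
    coupling = CouplingSpec("pair", band, ("O1", "O2"),
                            {s: gain for s in range(1, 6)})
    return SyntheticConfig(montage=montage, couplings=(coupling,),
                           seed=seed, stage_duration=duration)


class TestGenerateStage:
    def test_deterministic(self):
        cfg = pair_config(seed=7)
        a = generate_stage(cfg, 3)
        b = generate_stage(cfg, 3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_stages_have_independent_noise(self):
        cfg = pair_config(seed=7)
        a, b = generate_stage(cfg, 1), generate_stage(cfg, 2)
        assert not np.allclose(a.data, b.data)

    def test_zero_gain_channels_independent(self):
        cfg = pair_config(gain=0.0, seed=3, duration=30.0)
        rec = generate_stage(cfg, 1)
        iu = np.triu_indices(5, k=1)
        # off-diagonal MI is pure plug-in bias, which decays ~ n^(-1/3):
        # small at this length and shrinking as the record grows
        short = epoch_mi_matrix(rec.data[:5, :1500]).values[iu]
        full = epoch_mi_matrix(rec.data[:5, :]).values[iu]
        assert full.max() < 0.15
        assert full.mean() < short.mean()

    def test_coupled_pair_has_largest_mi(self, montage29):
        cfg = pair_config(gain=1.5, seed=11)
        rec = generate_stage(cfg, 1)
        from eegfc import band_limited_epochs, stage_mi_matrix
        es = band_limited_epochs(rec, BAND, n_epochs=20)
        m = stage_mi_matrix(es)
        i, j = montage29.index("O1"), montage29.index("O2")
        off = m.values[np.triu_indices(29, k=1)]
        assert m.values[i, j] == off.max()

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError):
            generate_stage(pair_config(), 6)

    def test_band_above_nyquist_rejected(self):
        from eegfc import BandDefinition
        band = BandDefinition("too-high", 100.0, 300.0)
        with pytest.raises(ValueError):
            pair_config(band=band)


class TestGenerateExperiment:
    def test_five_stages_with_configured_duration(self):
        cfg = pair_config(duration=5.0)
        recs = generate_experiment(cfg)
        assert [r.stage for r in recs] == [1, 2, 3, 4, 5]
        assert all(r.duration == pytest.approx(5.0) for r in recs)
        assert all(r.n_channels == 29 for r in recs)


class TestGroundTruth:
    def test_zero_gains_zero_matrix(self):
        gt = ground_truth_coupling(pair_config(gain=0.0), 1, BAND)
        assert np.all(gt.values == 0)

    def test_single_pair_entry(self, montage29):
        gt = ground_truth_coupling(pair_config(gain=2.0), 1, BAND)
        i, j = montage29.index("O1"), montage29.index("O2")
        assert gt.values[i, j] == pytest.approx(4.0)
        assert np.count_nonzero(gt.values) == 2

    def test_posterior_block_support(self, montage29):
        # the within-posterior block couples exactly the nine
        # parieto-occipital channels
        block = {"Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8", "TP10"}
        montage = default_montage()
        coupling = CouplingSpec("posterior", BAND, tuple(sorted(block)),
                                {1: 0.5})
        cfg = SyntheticConfig(montage=montage, couplings=(coupling,),
                              stage_duration=1.0)
        gt = ground_truth_coupling(cfg, 1, BAND)
        nz = {(montage.labels[i], montage.labels[j])
              for i, j in zip(*np.nonzero(gt.values))}
        assert all(a in block and b in block for a, b in nz)
        assert len(nz) == 9 * 8

    def test_vr_preset_gains_ordered(self):
        cfg = vr_effect_config()
        for band_name in ("beta", "low_gamma", "high_gamma"):
            g = {s: ground_truth_coupling(cfg, s, band_name).values.sum()
                 for s in (1, 3, 4)}
            assert g[1] < g[4] < g[3]
        null = null_config()
        sums = {s: ground_truth_coupling(null, s, "beta").values.sum()
                for s in range(1, 6)}
        assert len({round(v, 9) for v in sums.values()}) == 1


class TestSpectralContent:
    def test_band_limited_source_power_in_band(self):
        # a (32, 50) Hz source leaks < 5% of its power outside the band
        cfg = pair_config(gain=5.0, seed=2, duration=40.0)
        rec = generate_stage(cfg, 1)
        i = cfg.montage.index("O1")
        f, pxx = periodogram(rec.data[i], fs=cfg.sampling_rate)
        in_band = (f >= BAND.low) & (f <= BAND.high)
        # subtract the pink-noise floor estimated from a zero-gain twin
        rec0 = generate_stage(pair_config(gain=0.0, seed=2, duration=40.0), 1)
        _, pxx0 = periodogram(rec0.data[i], fs=cfg.sampling_rate)
        src = pxx - pxx0
        assert src[~in_band].sum() < 0.05 * src.sum()

    def test_pink_noise_spectrum_slope(self):
        cfg = pair_config(gain=0.0, seed=4, duration=60.0)
        rec = generate_stage(cfg, 1)
        f, pxx = periodogram(rec.data[0], fs=500.0)
        sel = (f > 1) & (f < 100)
        slope = np.polyfit(np.log(f[sel]), np.log(pxx[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.25)


class TestMonotonicity:
    def test_mi_nondecreasing_in_gain(self):
        # estimated MI between coupled channels rises with the gain,
        # in expectation over seeds
        mean_mi = []
        for gain in (0.0, 0.5, 1.0, 2.0):
            vals = []
            for seed in range(20):
                cfg = pair_config(gain=gain, seed=seed, duration=4.0)
                rec = generate_stage(cfg, 1)
                i, j = cfg.montage.index("O1"), cfg.montage.index("O2")
                from eegfc import mutual_information
                vals.append(mutual_information(rec.data[i], rec.data[j]))
            mean_mi.append(np.mean(vals))
        assert all(a <= b + 1e-12 for a, b in zip(mean_mi, mean_mi[1:]))


def test_subject_seed_stable_and_bounded():
    seeds = [subject_seed(0, i) for i in range(50)]
    assert len(set(seeds)) == 50
    assert all(0 <= s < 2 ** 31 for s in seeds)
    assert seeds == [subject_seed(0, i) for i in range(50)]
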