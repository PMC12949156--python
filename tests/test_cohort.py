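"""Synthetic cohort generator: structure, determinism, and the planted links."""

import numpy as np
import pandas as pd
import pytest

from synaptometry.cohort import (
    CohortConfig,
    EFR_STIMULI,
    _efr_amplitudes,
    build_measures_table,
    efr_stimulus_spec,
    generate_cohort,
    simulate_efr_trials,
)
from synaptometry.efr import amplitude_spectrum, bootstrap_spectrum, estimate_noise_floor
from synaptometry.stats import pearson_with_ci


class TestCohortStructure:
    def test_default_group_sizes_total_57(self, default_cohort_config):
        ears, truth = generate_cohort(default_cohort_config)
        assert len(ears) == 17 + 13 + 14 + 13 == 57
        assert len(truth) == 57 * 2
        counts = truth.groupby("group")["ear_id"].nunique()
        assert counts.to_dict() == {
            "young": 17, "acute_noise": 13, "aged": 14, "aged_noise": 13
        }

    def test_sex_split(self, default_cohort_config):
        ears, _ = generate_cohort(default_cohort_config)
        sexes = pd.Series([e.sex for e in ears]).value_counts()
        assert sexes["F"] == 32 and sexes["M"] == 25

    def test_determinism_same_seed(self, default_cohort_config):
        _, t1 = generate_cohort(default_cohort_config)
        _, t2 = generate_cohort(default_cohort_config)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_differs(self):
        _, t1 = generate_cohort(CohortConfig(seed=1))
        _, t2 = generate_cohort(CohortConfig(seed=2))
        assert not np.allclose(t1["synapses_per_ihc"], t2["synapses_per_ihc"])

    def test_acute_loss_is_focal_and_half_at_32k(self, default_cohort_config):
        _, truth = generate_cohort(default_cohort_config)
        mean = truth.groupby(["group", "frequency_hz"])["synapses_per_ihc"].mean()
        ratio32 = mean["acute_noise", 32000.0] / mean["young", 32000.0]
        assert ratio32 == pytest.approx(0.5, rel=0.10)
        ratio16 = mean["acute_noise", 16000.0] / mean["young", 16000.0]
        assert ratio16 > 0.85  # near baseline at 16 kHz

    def test_aging_loss_is_broad(self, default_cohort_config):
        _, truth = generate_cohort(default_cohort_config)
        mean = truth.groupby(["group", "frequency_hz"])["synapses_per_ihc"].mean()
        for group in ("aged", "aged_noise"):
            for f in (16000.0, 32000.0):
                assert mean[group, f] < 0.85 * mean["young", f]
        # severity ordering: aged_noise < aged < young
        assert mean["aged_noise", 16000.0] < mean["aged", 16000.0] < mean["young", 16000.0]

    def test_synapses_nonnegative_and_ohc_group_ordered(self, default_cohort_config):
        ears, truth = generate_cohort(default_cohort_config)
        assert (truth["synapses_per_ihc"] >= 0).all()
        ohc = truth.groupby("group")["ohc_loss_db"].mean()
        assert ohc["young"] < ohc["acute_noise"] < ohc["aged"] < ohc["aged_noise"]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(group_sizes={"young": -1})
        with pytest.raises(ValueError):
            CohortConfig(group_loss={("young", 16000.0): 1.4})
        with pytest.raises(ValueError):
            # RAM must remain less OHC-sensitive than SAM by default premise
            CohortConfig(ohc_sensitivity={
                "abr": 0.1, "sam_110": 0.2, "sam_1000": 0.2,
                "ram_110": 0.5, "ram_1000": 0.5,
            })


class TestPlantedLinks:
    def test_amplitude_linear_in_synapses(self, default_cohort_config):
        cfg = default_cohort_config
        ears, _ = generate_cohort(cfg)
        ear = ears[0]
        ear.ohc_loss = {f: 0.0 for f in cfg.frequencies}
        ear.nuisance_db = {k: 0.0 for k in ear.nuisance_db}
        a1 = _efr_amplitudes(ear, 16000.0, "ram_1000", cfg)
        ear2_syn = {f: 2 * s for f, s in ear.synapses.items()}
        ear.synapses = ear2_syn
        a2 = _efr_amplitudes(ear, 16000.0, "ram_1000", cfg)
        assert np.allclose(a2, 2 * a1)

    def test_expected_amplitude_monotone_in_synapses(self, default_cohort_config):
        cfg = default_cohort_config
        ears, _ = generate_cohort(cfg)
        ear = ears[0]
        ear.ohc_loss = {f: 10.0 for f in cfg.frequencies}
        ear.nuisance_db = {k: 0.0 for k in ear.nuisance_db}
        amps = []
        for syn in (4.0, 8.0, 12.0, 16.0):
            ear.synapses = {f: syn for f in cfg.frequencies}
            amps.append(_efr_amplitudes(ear, 16000.0, "sam_110", cfg)[0])
        assert np.all(np.diff(amps) > 0)

    def test_collinearity_dpoae_vs_evoked(self, default_cohort_config):
        cfg = default_cohort_config
        ears, _ = generate_cohort(cfg)
        table = build_measures_table(ears, cfg, efr_mode="fast")
        sub = table[["dpoae_threshold", "abr_80"]].dropna()
        res = pearson_with_ci(sub["dpoae_threshold"], sub["abr_80"], 95.0)
        assert res.r < 0 and res.significant

    def test_measure_synapse_correlations_positive(self, default_cohort_config):
        cfg = default_cohort_config
        ears, _ = generate_cohort(cfg)
        table = build_measures_table(ears, cfg, efr_mode="fast")
        broad = table[table.group != "acute_noise"]
        for col in ("abr_80", "ram_1000_f0", "sam_1000_f0"):
            sub = broad[[col, "synapses"]].dropna()
            res = pearson_with_ci(sub[col], sub["synapses"], 95.0)
            assert res.r > 0 and res.significant, col


class TestEFRTrials:
    def test_deterministic_given_seed(self, small_cohort_config):
        cfg = small_cohort_config
        ears, _ = generate_cohort(cfg)
        spec = efr_stimulus_spec("sam_110", 16000.0, cfg)
        t1 = simulate_efr_trials(ears[0], spec, cfg)
        t2 = simulate_efr_trials(ears[0], spec, cfg)
        assert np.array_equal(t1.trials, t2.trials)

    def test_polarity_alternates_with_equal_counts(self, small_cohort_config):
        cfg = small_cohort_config
        ears, _ = generate_cohort(cfg)
        ts = simulate_efr_trials(ears[0], efr_stimulus_spec("ram_110", 32000.0, cfg), cfg)
        assert ts.n_trials == 2 * cfg.efr_trials
        assert np.sum(ts.polarity > 0) == np.sum(ts.polarity < 0)
        assert np.all(ts.polarity[::2] == 1) and np.all(ts.polarity[1::2] == -1)

    def test_noiseless_artifact_free_trials_identical(self, small_cohort_config):
        cfg = small_cohort_config
        cfg.noise_sd = {**cfg.noise_sd, "efr_trial_uv": 0.0}
        cfg.artifact_amp_uv = 0.0
        ears, _ = generate_cohort(cfg)
        ts = simulate_efr_trials(ears[0], efr_stimulus_spec("ram_1000", 16000.0, cfg), cfg)
        assert np.allclose(ts.trials, ts.trials[0][None, :], atol=1e-7)
        b = bootstrap_spectrum(ts, rng=0)
        assert np.std(b.mags[:, 0]) < 1e-7

    def test_artifact_cancels_in_balanced_average(self, small_cohort_config):
        cfg = small_cohort_config
        cfg.artifact_amp_uv = 50.0
        ears, _ = generate_cohort(cfg)
        ts = simulate_efr_trials(ears[0], efr_stimulus_spec("sam_1000", 16000.0, cfg), cfg)
        spec = amplitude_spectrum(ts.trials.mean(axis=0, dtype=np.float64))
        carrier_bin = round(ts.carrier_hz / ts.bin_hz)
        floor = estimate_noise_floor(spec, carrier_bin)
        assert spec[carrier_bin] < 3 * floor
        # sanity: the artifact is huge in a single-polarity average
        pos_mean = ts.trials[ts.polarity > 0].mean(axis=0, dtype=np.float64)
        assert amplitude_spectrum(pos_mean)[carrier_bin] > 10 * floor

    def test_unknown_frequency_errors(self, small_cohort_config):
        cfg = small_cohort_config
        ears, _ = generate_cohort(cfg)
        with pytest.raises(ValueError):
            simulate_efr_trials(ears[0], efr_stimulus_spec("sam_110", 8000.0, cfg), cfg)


class TestMeasuresTable:
    def test_missingness_matches_generator_log(self, default_cohort_config):
        cfg = default_cohort_config
        ears, _ = generate_cohort(cfg)
        table = build_measures_table(ears, cfg, efr_mode="fast")
        flagged = {e.ear_id for e in ears if e.missing_1k_32k}
        miss = table[table["ram_1000_f0"].isna() & (table.frequency_hz == 32000.0)]
        assert set(miss["ear_id"]) == flagged
        assert table[table.frequency_hz == 16000.0]["ram_1000_f0"].notna().all()
        # 110-Hz measures unaffected
        assert table["sam_110_f0"].notna().all()

    def test_fast_and_trial_modes_agree_in_distribution(self):
        # same ear, same links: the two generation paths must give the same
        # f0 measure up to estimation noise (a few SD of the bin noise)
        cfg = CohortConfig(seed=5, group_sizes={"young": 2},
                           missing_1k_32k_frac=0.0,
                           efr_sample_rate_hz=16384.0, frequencies=(4000.0,),
                           baseline_synapses={4000.0: 15.0})
        ears, _ = generate_cohort(cfg)
        fast = build_measures_table(ears, cfg, efr_mode="fast")
        slow = build_measures_table(ears, cfg, efr_mode="trials")
        for col in ("ram_1000_f0", "sam_110_f0"):
            assert np.allclose(fast[col], slow[col], atol=1.5), col

    def test_table_shape_and_keys(self, small_cohort_config):
        cfg = small_cohort_config
        ears, _ = generate_cohort(cfg)
        table = build_measures_table(ears, cfg, efr_mode="fast")
        assert len(table) == len(ears) * 2
        assert not table.duplicated(["ear_id", "frequency_hz"]).any()
        for stim in EFR_STIMULI:
            assert f"{stim}_f0" in table.columns
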