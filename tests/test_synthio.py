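"""Generator contracts: stage structure, determinism, forward-model shape."""

import dataclasses

import numpy as np
import pytest

from graperipe import preprocess, synthio
from graperipe.synthio import ConfigurationError, SynthConfig


class TestChemistry:
    def test_default_stage_counts(self, default_dataset):
        chem, labels, _ = default_dataset
        assert len(chem) == 200
        assert np.bincount(labels).tolist() == [32, 34, 55, 49, 30]
        assert list(chem.columns) == [
            "sample_id",
            "stage",
            "ssc_brix",
            "ta_g_l",
            "tp_mg_g",
            "tn_mg_g",
            "ssc_ta_ratio",
        ]

    def test_zero_sd_reproduces_stage_means(self, noiseless_chemistry_config):
        chem, _ = synthio.generate_chemistry(noiseless_chemistry_config)
        v = chem[chem["stage"] == "V"]
        assert v["ssc_ta_ratio"].iloc[0] == pytest.approx(18.71 / 3.42)
        assert v["ssc_ta_ratio"].iloc[0] == pytest.approx(5.47, abs=0.005)
        i = chem[chem["stage"] == "I"]
        assert i["ssc_brix"].iloc[0] == pytest.approx(11.93)
        assert i["ta_g_l"].iloc[0] == pytest.approx(12.91)

    def test_sample_means_converge_to_stage_means(self, default_dataset):
        chem, labels, _ = default_dataset
        for idx, model in enumerate(synthio.default_chemistry_models()):
            sub = chem[np.asarray(labels) == idx]
            for col, mean, sd in [
                ("ssc_brix", model.mean_ssc, model.sd_ssc),
                ("ta_g_l", model.mean_ta, model.sd_ta),
                ("tp_mg_g", model.mean_tp, model.sd_tp),
                ("tn_mg_g", model.mean_tn, model.sd_tn),
            ]:
                # truncation at 0 biases the mean upward by < 0.04 units
                # at these mean/SD ratios, well inside the 3 SD/sqrt(n) band
                assert abs(sub[col].mean() - mean) < 3 * sd / np.sqrt(len(sub))

    def test_ratio_is_ssc_over_ta(self, default_dataset):
        chem, _, _ = default_dataset
        np.testing.assert_allclose(
            chem["ssc_ta_ratio"], chem["ssc_brix"] / chem["ta_g_l"]
        )

    def test_values_positive(self, default_dataset):
        chem, _, _ = default_dataset
        assert (chem[["ssc_brix", "ta_g_l", "tp_mg_g", "tn_mg_g"]] > 0).all().all()

    def test_determinism(self, default_config):
        a, la = synthio.generate_chemistry(default_config)
        b, lb = synthio.generate_chemistry(default_config)
        assert a.equals(b) and np.array_equal(la, lb)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            synthio.StageChemistryModel("I", 10, 1, 5, 1, 40, 2, 20, 2, 0)
        with pytest.raises(ConfigurationError):
            synthio.StageChemistryModel("I", -1, 1, 5, 1, 40, 2, 20, 2, 10)
        with pytest.raises(ConfigurationError):
            SynthConfig(n_channels=1)
        with pytest.raises(ConfigurationError):
            SynthConfig(noise_sd=-0.1)


class TestSpectra:
    def test_grid_step_and_channel_count(self, default_config):
        wl = default_config.wavelengths
        assert wl.size == 1507
        step = np.diff(wl)
        assert np.allclose(step, (1029 - 400) / 1506)
        assert step[0] == pytest.approx(0.4176, abs=1e-4)

    def test_replicates_identical_without_randomness(self):
        cfg = SynthConfig(
            scatter_slope_sd=0.0,
            scatter_offset_sd=0.0,
            noise_sd=0.0,
            replicates_per_sample=3,
            seed=7,
        )
        chem, labels = synthio.generate_chemistry(cfg)
        reps = synthio.generate_spectra(chem, labels, cfg)
        assert reps.n_replicates == 3
        np.testing.assert_array_equal(reps.values[:, 0], reps.values[:, 1])
        np.testing.assert_array_equal(reps.values[:, 0], reps.values[:, 2])

    def test_spectra_determinism_and_bounds(self, default_config, default_dataset):
        chem, labels, reps = default_dataset
        again = synthio.generate_spectra(chem, labels, default_config)
        np.testing.assert_array_equal(reps.values, again.values)
        assert reps.values.min() >= 0.0 and reps.values.max() <= 1.5

    def test_stage_contrast_concentrated_below_780nm(self):
        """With only the 535/680 bands stage-linked, the stage-I vs stage-V
        mean-spectrum difference lives inside 400-780 nm (the generator's
        own band definitions are the oracle)."""
        bands = [
            synthio.SpectralBand(535.0, 22.0, "tp", 1, 0.18),
            synthio.SpectralBand(680.0, 18.0, "chlorophyll_stage", 1, 0.22),
        ]
        cfg = SynthConfig(
            bands=bands,
            scatter_slope_sd=0.0,
            scatter_offset_sd=0.0,
            noise_sd=0.0,
            replicates_per_sample=1,
            seed=3,
        )
        chem, labels = synthio.generate_chemistry(cfg)
        reps = synthio.generate_spectra(chem, labels, cfg)
        spectra = reps.values[:, 0, :]
        diff = np.abs(
            spectra[labels == 0].mean(axis=0) - spectra[labels == 4].mean(axis=0)
        )
        wl = cfg.wavelengths
        visible = diff[wl <= 780].mean()
        nir = diff[wl > 780].mean()
        assert visible > 10 * nir

    def test_misaligned_chemistry_rejected(self, default_config, default_dataset):
        chem, labels, _ = default_dataset
        with pytest.raises(ConfigurationError):
            synthio.generate_spectra(chem.iloc[:-1], labels, default_config)

    def test_msc_consistency_with_scatter_disabled(self):
        """Without the scatter layer, MSC perturbs generated spectra by at
        most the additive-noise scale (generator/preprocess consistency)."""
        cfg = SynthConfig(
            scatter_slope_sd=0.0,
            scatter_offset_sd=0.0,
            noise_sd=0.002,
            replicates_per_sample=1,
            seed=11,
        )
        chem, labels = synthio.generate_chemistry(cfg)
        reps = synthio.generate_spectra(chem, labels, cfg)
        spectra, _ = preprocess.representative_spectrum(reps)
        corrected, _ = preprocess.msc_fit_apply(spectra)
        rms = np.sqrt(((corrected.values - spectra.values) ** 2).mean())
        assert rms < 10 * cfg.noise_sd

    def test_informative_mask_covers_bands_only(self, default_config):
        mask = synthio.informative_channel_mask(default_config)
        wl = default_config.wavelengths
        assert mask.any() and not mask.all()
        for b in default_config.bands:
            assert mask[np.abs(wl - b.center) <= 2 * b.width].all()
        far = np.ones_like(mask)
        for b in default_config.bands:
            far &= np.abs(wl - b.center) > 2 * b.width
        assert not mask[far].any()


class TestIO:
    def test_chemistry_csv_roundtrip(self, tmp_path, default_dataset):
        chem, _, _ = default_dataset
        path = tmp_path / "chem.csv"
        synthio.write_chemistry_csv(chem, path)
        back = synthio.read_chemistry_csv(path)
        np.testing.assert_allclose(back["ssc_brix"], chem["ssc_brix"])
        assert list(back["sample_id"]) == list(chem["sample_id"])

    def test_spectra_csv_roundtrip(self, tmp_path):
        cfg = SynthConfig(n_channels=41, replicates_per_sample=2, seed=5)
        chem, labels = synthio.generate_chemistry(cfg)
        reps = synthio.generate_spectra(chem.iloc[:6], labels[:6], cfg)
        path = tmp_path / "spec.csv"
        synthio.write_spectra_csv(reps, path)
        back = synthio.read_spectra_csv(path)
        np.testing.assert_allclose(back.values, reps.values, atol=1e-10)
        np.testing.assert_allclose(back.wavelengths, reps.wavelengths, atol=1e-4)

    def test_yaml_roundtrip(self, tmp_path, default_config):
        path = tmp_path / "cfg.yaml"
        default_config.to_yaml(path)
        back = SynthConfig.from_yaml(path)
        assert back == default_config
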