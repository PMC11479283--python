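"""Synthetic generator: trait distributions, OJIP transients, R/T spectra."""

import numpy as np
import pytest

import spectraleaf as sl
from spectraleaf.simulate import (
    GREEN,
    PURPLE,
    ConfigurationError,
    SignatureTable,
    TraitSpec,
    default_species_profiles,
    default_trait_specs,
    species_labels,
)

LAYER_MEANS = {"adaxial_epidermis_um": 102.7, "adaxial_hypodermis_um": 323.4,
               "parenchyma_um": 252.6, "abaxial_hypodermis_um": 170.5}


def _quiet_config(**kw):
    """Config with all noise sources and trait-spectrum couplings off."""
    kw.setdefault("signatures", SignatureTable(spectral={"parenchyma_um": []},
                                               fluorescence={}))
    kw.setdefault("noise_sd", {"fluorescence": 0.0, "reflectance": 0.0,
                               "transmittance": 0.0})
    kw.setdefault("signature_jitter_sd", 0.0)
    kw.setdefault("water_coupling", 0.0)
    return sl.GeneratorConfig(**kw)


class TestTraits:
    def test_pooled_means_recover_configured_means(self):
        # mean matching is exact by construction; sample means must sit
        # within Monte-Carlo error of the configured values
        cfg = sl.default_config(n_samples=2000)
        traits = sl.generate_traits(cfg, np.random.default_rng(11))
        stats = sl.describe(traits)
        for name, spec in cfg.trait_specs.items():
            if name == "total_thickness_um":
                continue
            se = stats.loc[name, "mean"] * stats.loc[name, "cv_percent"] / 100 / np.sqrt(2000)
            assert abs(stats.loc[name, "mean"] - spec.mean) < 3 * se, name

    def test_cv_recovery_when_bounds_are_loose(self):
        # with wide truncation bounds the moment match is exact in both
        # moments, so the sample CV must also land on the configured value
        spec = TraitSpec(name="granum_height_nm", unit="nm", mean=500.0,
                         cv_percent=20.0, min_bound=1.0, max_bound=2500.0,
                         species_effect={GREEN: 0.0, PURPLE: 0.0})
        specs = default_trait_specs()
        specs["granum_height_nm"] = spec
        cfg = _quiet_config(n_samples=2000, trait_specs=specs)
        traits = sl.generate_traits(cfg, np.random.default_rng(3))
        x = traits.trait("granum_height_nm")
        cv = 100 * x.std(ddof=1) / x.mean()
        se_cv = 20.0 / np.sqrt(2 * 2000)
        assert abs(cv - 20.0) < 3 * se_cv

    def test_adaxial_epidermis_mean_within_2se(self):
        cfg = sl.default_config()
        traits = sl.generate_traits(cfg, np.random.default_rng(21))
        x = traits.trait("adaxial_epidermis_um")
        se = x.std(ddof=1) / np.sqrt(x.size)
        assert abs(x.mean() - 102.7) < 2 * se

    def test_degenerate_cv_zero_returns_exact_means(self):
        specs = {}
        for name, spec in default_trait_specs().items():
            specs[name] = TraitSpec(name=name, unit=spec.unit, mean=spec.mean,
                                    cv_percent=0.0, min_bound=spec.min_bound,
                                    max_bound=spec.max_bound,
                                    species_effect={GREEN: 0.0, PURPLE: 0.0})
        cfg = _quiet_config(n_samples=8, trait_specs=specs)
        traits = sl.generate_traits(cfg, np.random.default_rng(0))
        for name, spec in specs.items():
            if name == "total_thickness_um":
                continue
            np.testing.assert_array_equal(traits.trait(name), spec.mean)
        np.testing.assert_allclose(traits.trait("total_thickness_um"),
                                   sum(LAYER_MEANS.values()))

    def test_layer_means_sum_matches_configured_total(self):
        # additive-total design: the four configured layer means add up to
        # (within rounding) the configured total-thickness mean
        configured = sum(LAYER_MEANS.values())
        assert configured == pytest.approx(849.2)
        assert abs(configured - default_trait_specs()["total_thickness_um"].mean) < 0.15

    def test_total_is_exact_layer_sum(self, default_data):
        df = default_data.traits.data
        np.testing.assert_array_equal(
            df["total_thickness_um"],
            sum(df[t] for t in sl.LAYER_TRAITS),
        )

    def test_total_has_lower_relative_spread_than_major_layers(self, default_data):
        stats = sl.describe(default_data.traits)
        total_cv = stats.loc["total_thickness_um", "cv_percent"]
        for layer in ("adaxial_epidermis_um", "adaxial_hypodermis_um",
                      "abaxial_hypodermis_um"):
            assert total_cv < stats.loc[layer, "cv_percent"]

    def test_bounds_respected(self, default_data):
        cfg = sl.default_config()
        for name, spec in cfg.trait_specs.items():
            if name == "total_thickness_um":
                continue
            x = default_data.traits.trait(name)
            assert x.min() >= spec.min_bound and x.max() <= spec.max_bound

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            TraitSpec(name="x", unit="um", mean=-1.0, cv_percent=5.0,
                      min_bound=0.0, max_bound=10.0)
        with pytest.raises(ConfigurationError):
            TraitSpec(name="x", unit="um", mean=5.0, cv_percent=5.0,
                      min_bound=6.0, max_bound=10.0)


class TestOjip:
    def test_zero_amplitudes_give_flat_curve_at_o_level(self):
        cfg = _quiet_config(n_samples=8)
        profile = default_species_profiles()[GREEN]
        profile.ojip.amplitudes = dict.fromkeys(("J", "I", "P"), 0.0)
        # bypass the P>O validation by constructing the curve directly
        traits = {k: s.mean for k, s in cfg.trait_specs.items()}
        curve = sl.simulate_ojip(traits, profile, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(curve, profile.ojip.o_level)

    def test_noiseless_relative_variable_fluorescence_closed_form(self):
        cfg = _quiet_config(n_samples=8)
        profile = default_species_profiles()[PURPLE]
        traits = {k: s.mean for k, s in cfg.trait_specs.items()}
        curve = sl.simulate_ojip(traits, profile, cfg, np.random.default_rng(0))
        t = cfg.time_grid
        o, amps, taus = profile.ojip.o_level, profile.ojip.amplitudes, profile.ojip.times
        f_first = o + sum(amps[k] * (1 - np.exp(-t[0] / taus[k])) for k in amps)
        f_last = o + sum(amps[k] * (1 - np.exp(-t[-1] / taus[k])) for k in amps)
        expected = (f_last - f_first) / f_last
        observed = (curve[-1] - curve[0]) / curve[-1]
        assert observed == pytest.approx(expected, abs=1e-12)

    def test_curve_nondecreasing_without_noise(self):
        cfg = _quiet_config(n_samples=8)
        profile = default_species_profiles()[GREEN]
        traits = {k: s.mean for k, s in cfg.trait_specs.items()}
        curve = sl.simulate_ojip(traits, profile, cfg, np.random.default_rng(0))
        assert (np.diff(curve) >= 0).all()
        assert profile.ojip.o_level < curve[-1] <= profile.ojip.p_level

    def test_green_archetype_mean_curve_exceeds_purple_everywhere(self):
        # Monte-Carlo mean over >= 100 draws per species
        cfg = sl.default_config(n_samples=8)
        rng = np.random.default_rng(17)
        profiles = default_species_profiles()
        traits = {k: s.mean for k, s in cfg.trait_specs.items()}
        curves = {}
        for name, profile in profiles.items():
            draws = [sl.simulate_ojip(traits, profile, cfg, rng) for _ in range(150)]
            curves[name] = np.mean(draws, axis=0)
        assert (curves[GREEN] > curves[PURPLE]).all()


class TestRT:
    def test_zero_signatures_and_noise_reproduce_baselines(self):
        cfg = _quiet_config(n_samples=8)
        profile = default_species_profiles()[PURPLE]
        traits = {k: s.mean for k, s in cfg.trait_specs.items()}
        r, t = sl.simulate_rt(traits, profile, cfg, np.random.default_rng(0))
        r0, t0 = profile.baseline_rt(cfg.wavelength_grid)
        np.testing.assert_allclose(r, r0)
        np.testing.assert_allclose(t, t0)

    def test_clipping_contract(self, default_data):
        r, t = default_data.reflectance.values, default_data.transmittance.values
        assert r.min() >= 0 and t.min() >= 0
        assert (r + t).max() <= 1 + 1e-12

    def test_anthocyanin_depresses_green_region_reflectance(self):
        cfg = _quiet_config(n_samples=8)
        traits = {k: s.mean for k, s in cfg.trait_specs.items()}
        profiles = default_species_profiles()
        i544 = int(np.argmin(np.abs(cfg.wavelength_grid - 544)))
        values = []
        for anth in (0.0, 1.0):
            profile = profiles[GREEN]
            profile.pigment_levels = {"chlorophyll": 1.0, "anthocyanin": anth}
            r, _ = sl.simulate_rt(traits, profile, cfg, np.random.default_rng(0))
            values.append(r[i544])
        assert values[1] < values[0]

    def test_feature_center_outside_grid_rejected(self):
        sig = SignatureTable(
            spectral={"parenchyma_um": [sl.SpectralFeature(3000, 10, 0.01, "reflectance")]},
        )
        with pytest.raises(ConfigurationError, match="3000"):
            sl.GeneratorConfig(signatures=sig)


class TestDataset:
    def test_same_seed_is_bit_identical(self, small_data):
        cfg = sl.GeneratorConfig(n_samples=24, wavelength_step=100.0, n_time_points=15)
        again = sl.generate_dataset(cfg, seed=5)
        for mode, ds in small_data.modes.items():
            np.testing.assert_array_equal(ds.values, again.modes[mode].values)
        assert small_data.traits.data.equals(again.traits.data)

    def test_outputs_aligned(self):
        cfg = sl.GeneratorConfig(n_samples=10, wavelength_step=200.0, n_time_points=10)
        data = sl.generate_dataset(cfg, seed=2)
        ids = data.traits.sample_ids
        assert len(ids) == 10
        for ds in data.modes.values():
            assert ds.sample_ids == ids
            assert ds.species == data.species

    def test_absorbance_is_one_minus_r_plus_t(self, small_data):
        np.testing.assert_allclose(
            small_data.absorbance.values,
            1.0 - (small_data.reflectance.values + small_data.transmittance.values),
            atol=1e-12,
        )

    def test_species_blocks(self):
        cfg = sl.GeneratorConfig(n_samples=10, species_fraction=0.3,
                                 wavelength_step=500.0, n_time_points=5)
        labels = species_labels(cfg)
        assert labels.count(GREEN) == 3 and labels.count(PURPLE) == 7

    def test_weak_traits_less_band_correlated_than_strong(self, default_data):
        # encoded-vs-unencoded contrast: parenchyma (no spectral signature)
        # must correlate less with single wavelengths than adaxial hypodermis
        refl = default_data.reflectance.values
        def max_abs_r(y):
            yc = y - y.mean()
            xc = refl - refl.mean(axis=0)
            r = (xc * yc[:, None]).sum(0) / np.sqrt((xc ** 2).sum(0) * (yc ** 2).sum())
            return np.abs(r).max()
        weak = max_abs_r(default_data.traits.trait("parenchyma_um"))
        strong = max_abs_r(default_data.traits.trait("adaxial_hypodermis_um"))
        assert weak < strong
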