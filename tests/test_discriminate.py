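"""Species discrimination: ANOVA F, region peaks, kappa, classification, clustering."""

import numpy as np
import pandas as pd
import pytest

import spectraleaf as sl
from spectraleaf.core import ValidationError
from spectraleaf.simulate import GREEN, SignatureTable


def _dataset(values, labels, axis=None, mode="reflectance"):
    values = np.asarray(values, float)
    if axis is None:
        axis = np.arange(values.shape[1], dtype=float) * 10 + 400
    ids = [f"s{i}" for i in range(values.shape[0])]
    return sl.SpectralDataset(np.asarray(axis, float), values, mode, ids, list(labels))


class TestPerChannelF:
    def test_hand_arithmetic(self):
        vals = np.array([[0.1], [0.2], [0.3], [0.4], [0.5], [0.6]])
        ds = _dataset(vals * 1.0, ["a"] * 3 + ["b"] * 3)
        # groups {1,2,3} and {4,5,6} in units of 0.1: F is scale-invariant
        f = sl.per_channel_f(ds)
        assert f[0] == pytest.approx(13.5)

    def test_identical_group_means_give_zero(self):
        vals = np.array([[0.1], [0.3], [0.1], [0.3]])
        f = sl.per_channel_f(_dataset(vals, ["a", "a", "b", "b"]))
        assert f[0] == pytest.approx(0.0)

    def test_matches_anova_formula(self, rng):
        x = rng.uniform(0.1, 0.9, size=(14, 5))
        labels = ["a"] * 6 + ["b"] * 8
        f = sl.per_channel_f(_dataset(x, labels))
        for c in range(5):
            g1, g2 = x[:6, c], x[6:, c]
            grand = x[:, c].mean()
            ssb = 6 * (g1.mean() - grand) ** 2 + 8 * (g2.mean() - grand) ** 2
            ssw = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
            assert f[c] == pytest.approx(ssb / (ssw / 12), rel=1e-10)

    def test_shift_invariance_per_channel(self, rng):
        x = rng.uniform(0.1, 0.5, size=(10, 3))
        labels = ["a"] * 5 + ["b"] * 5
        f1 = sl.per_channel_f(_dataset(x, labels))
        x2 = x.copy()
        x2[:, 1] += 0.3
        f2 = sl.per_channel_f(_dataset(x2, labels))
        np.testing.assert_allclose(f1, f2, rtol=1e-10)


class TestRegionPeaks:
    def test_single_spike(self):
        axis = np.arange(350.0, 2501.0, 1.0)
        f = np.zeros(axis.size)
        f[axis == 544] = 10.0
        peaks = sl.region_peaks(f, axis)
        assert peaks["UV-VIS"] == 544.0

    def test_monotone_series_peaks_at_region_ends(self):
        axis = np.arange(350.0, 2501.0, 50.0)
        f = np.linspace(0, 1, axis.size)
        peaks = sl.region_peaks(f, axis)
        # half-open intervals: the last channel strictly below the bound
        assert peaks["UV-VIS"] == 650.0
        assert peaks["NIR"] == 1250.0
        assert peaks["SWIR1"] == 1750.0
        assert peaks["SWIR2"] == 2500.0  # top region keeps its upper edge

    def test_recovers_generator_anthocyanin_contrast(self):
        # species differ only in pigments: the strongest UV-VIS separation
        # must appear near the anthocyanin band at 544 nm
        cfg = sl.GeneratorConfig(
            n_samples=60,
            signatures=SignatureTable(spectral={"parenchyma_um": []}, fluorescence={}),
        )
        data = sl.generate_dataset(cfg, seed=1)
        f = sl.per_channel_f(data.reflectance)
        peaks = sl.region_peaks(f, data.reflectance.axis)
        assert abs(peaks["UV-VIS"] - 544.0) <= 30.0


class TestKappa:
    def test_perfect_agreement(self):
        assert sl.cohen_kappa([[25, 0], [0, 25]]) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        kappa = sl.cohen_kappa([[13, 12], [12, 13]])
        assert kappa == pytest.approx(0.04)

    def test_chance_level_agreement_is_zero(self):
        # p_o equals p_e exactly for independent marginals
        assert sl.cohen_kappa([[20, 20], [20, 20]]) == pytest.approx(0.0)

    def test_label_swap_invariance(self, rng):
        c = rng.integers(1, 30, size=(2, 2))
        swapped = c[::-1, ::-1]
        assert sl.cohen_kappa(c) == pytest.approx(sl.cohen_kappa(swapped))

    def test_degenerate_marginals_undefined(self):
        assert np.isnan(sl.cohen_kappa([[10, 0], [0, 0]]))


class TestClassification:
    def test_separable_species_classified_perfectly(self, rng):
        n = 40
        labels = ["a"] * 20 + ["b"] * 20
        base = rng.uniform(0.2, 0.4, size=(n, 6))
        base[20:] += 0.3  # well-separated offset
        acc, kappa, conf = sl.classify_species(_dataset(base, labels), seed=0)
        assert acc == 1.0 and kappa == 1.0

    def test_permuted_labels_have_no_skill(self):
        kappas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0.2, 0.8, size=(200, 10))
            labels = list(rng.permutation(["a"] * 100 + ["b"] * 100))
            _, kappa, _ = sl.classify_species(_dataset(x, labels), seed=seed)
            kappas.append(abs(kappa))
        assert max(kappas) <= 0.15

    def test_confusion_closed_form(self):
        conf = np.array([[13, 12], [12, 13]])
        acc = np.trace(conf) / conf.sum()
        assert acc == pytest.approx(0.52)
        assert sl.cohen_kappa(conf) == pytest.approx(0.04)

    def test_fluorescence_mode_separates_default_species(self, default_data):
        acc, kappa, _ = sl.classify_species(default_data.fluorescence, seed=1)
        assert acc > 0.9
        assert kappa > 0.8

    def test_single_class_rejected(self, rng):
        x = rng.uniform(0.2, 0.8, size=(12, 4))
        with pytest.raises(ValidationError):
            sl.classify_species(_dataset(x, ["a"] * 12))


class TestClusterTraits:
    @staticmethod
    def _table(values, columns, species=None):
        values = np.asarray(values, float)
        df = pd.DataFrame(values, columns=columns,
                          index=[f"s{i}" for i in range(values.shape[0])])
        return sl.TraitTable(data=df, species=species or ["green"] * values.shape[0])

    def test_duplicated_trait_columns_merge_first(self, rng):
        x = rng.uniform(1, 2, size=(10, 1))
        vals = np.hstack([x, x, rng.uniform(5, 9, size=(10, 1))])
        table = self._table(vals, ["adaxial_epidermis_um", "adaxial_hypodermis_um",
                                   "parenchyma_um"])
        res = sl.cluster_traits(table)
        first_merge = res.trait_linkage[0]
        assert set(first_merge[:2].astype(int)) == {0, 1}
        assert first_merge[2] == pytest.approx(0.0, abs=1e-12)

    def test_sample_tree_top_split_matches_species(self):
        # strongly opposed species effects with small within-species spread:
        # the two-cluster cut must reproduce the species exactly
        from spectraleaf.simulate import default_trait_specs
        specs = default_trait_specs()
        for name in ("adaxial_epidermis_um", "adaxial_hypodermis_um",
                     "abaxial_hypodermis_um", "chloroplast_count"):
            sign = -1.0 if name == "adaxial_epidermis_um" else 1.0
            specs[name].species_effect = {GREEN: 0.3 * sign, "purple": -0.3 * sign}
        cfg = sl.GeneratorConfig(n_samples=40, wavelength_step=500.0,
                                 n_time_points=5, trait_specs=specs)
        data = sl.generate_dataset(cfg, seed=4)
        res = sl.cluster_traits(data.traits)
        from scipy.cluster.hierarchy import fcluster
        assign = fcluster(res.sample_linkage, t=2, criterion="maxclust")
        species = np.array(data.species)
        # adjusted-Rand = 1 means the two clusters are exactly the species
        groups = [set(np.flatnonzero(assign == g)) for g in (1, 2)]
        truth = [set(np.flatnonzero(species == s)) for s in (GREEN, "purple")]
        assert groups == truth or groups == truth[::-1]

    def test_topology_invariant_under_sample_permutation(self, rng):
        vals = rng.uniform(1, 9, size=(12, 3))
        cols = ["adaxial_epidermis_um", "parenchyma_um", "chloroplast_count"]
        t1 = self._table(vals, cols)
        res1 = sl.cluster_traits(t1)
        perm = rng.permutation(12)
        t2 = self._table(vals[perm], cols)
        res2 = sl.cluster_traits(t2)
        # merge heights are permutation invariant even if leaf ids are not
        np.testing.assert_allclose(sorted(res1.sample_linkage[:, 2]),
                                   sorted(res2.sample_linkage[:, 2]), atol=1e-9)

    def test_newick_rendering_has_all_leaves(self, rng):
        vals = rng.uniform(1, 9, size=(6, 3))
        cols = ["adaxial_epidermis_um", "parenchyma_um", "chloroplast_count"]
        res = sl.cluster_traits(self._table(vals, cols))
        from spectraleaf.discriminate import linkage_to_newick
        nwk = linkage_to_newick(res.trait_linkage, cols)
        assert nwk.endswith(";")
        for c in cols:
            assert c in nwk
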