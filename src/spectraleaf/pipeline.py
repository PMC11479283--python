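"""End-to-end orchestration: simulate → preprocess → PCA → index maps →
PLSR → discrimination → reports.

Every stage writes plain-text artifacts (CSV/JSON/YAML/Newick); a manifest
listing the configuration echo, seeds and every written file is emitted
last so a run can be audited and reproduced.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import core, discriminate, indices, pca, plsr
from .simulate import GeneratorConfig, LeafDataset, generate_dataset

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything an end-to-end run needs (generator mode or file mode)."""

    out_dir: str
    generator: GeneratorConfig | None = None
    input_files: dict[str, str] | None = None  # modes + "traits" → CSV paths
    seed: int = 0
    split_fraction: float = 0.75
    max_factors: int = plsr.MAX_FACTORS_DEFAULT
    n_folds: int = 10
    hvi_step: int = 1          # channel thinning for the index maps
    pca_components: int = 3
    plsr_traits: list[str] | None = None
    hvi_traits: list[str] | None = None

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.input_files is None):
            raise StageError("config: provide either a generator config or input files")
        if self.input_files is not None:
            needed = {"fluorescence", "reflectance", "transmittance", "traits"}
            missing = needed - set(self.input_files)
            if missing:
                raise StageError(f"config: missing input files for {sorted(missing)}")
            for key, path in self.input_files.items():
                if not Path(path).exists():
                    raise StageError(f"config: input file for {key!r} not found: {path}")


@dataclass
class RunManifest:
    config_echo: dict
    seed: int
    outputs: list[str] = field(default_factory=list)
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        payload = {
            "config": self.config_echo,
            "seed": self.seed,
            "outputs": sorted(self.outputs),
            "stage_seconds": self.stage_seconds,
        }
        path.write_text(json.dumps(payload, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _config_echo(config: RunConfig) -> dict:
    echo = {
        "seed": config.seed,
        "split_fraction": config.split_fraction,
        "max_factors": config.max_factors,
        "n_folds": config.n_folds,
        "hvi_step": config.hvi_step,
        "pca_components": config.pca_components,
    }
    if config.generator is not None:
        gen = config.generator
        echo["generator"] = {
            "n_samples": gen.n_samples,
            "species_fraction": gen.species_fraction,
            "seed": gen.seed,
            "wavelength_step": gen.wavelength_step,
            "n_time_points": gen.n_time_points,
            "noise_sd": gen.noise_sd,
            "signature_jitter_sd": gen.signature_jitter_sd,
        }
    else:
        echo["input_files"] = dict(config.input_files)
    return echo


def _load_inputs(config: RunConfig) -> LeafDataset:
    files = config.input_files
    ds_r = core.read_dataset(files["reflectance"], "reflectance")
    ds_t = core.read_dataset(files["transmittance"], "transmittance")
    ds_f = core.read_dataset(files["fluorescence"], "fluorescence", axis_unit="s")
    traits = core.read_traits(files["traits"])
    ds_a = core.compute_absorbance(ds_r, ds_t)
    return LeafDataset(fluorescence=ds_f, reflectance=ds_r, transmittance=ds_t,
                       absorbance=ds_a, traits=traits)


def run_all(config: RunConfig) -> RunManifest:
    """Execute all stages in order; stage failures abort with a stage-named error."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_echo=_config_echo(config), seed=config.seed)

    def _stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest.stage_seconds[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                return False
        return _Timer()

    def _emit(path: Path) -> Path:
        manifest.outputs.append(str(path.relative_to(out)))
        return path

    with _stage("simulate"):
        if config.generator is not None:
            data = generate_dataset(config.generator, seed=config.seed)
            for mode, ds in data.modes.items():
                core.write_dataset(ds, _emit(out / f"{mode}.csv"))
            core.write_traits(data.traits, _emit(out / "traits.csv"))
            echo_path = _emit(out / "generator_config.yaml")
            echo_path.write_text(yaml.safe_dump(manifest.config_echo, sort_keys=True))
        else:
            data = _load_inputs(config)

    with _stage("describe"):
        stats = core.describe(data.traits)
        stats.to_csv(_emit(out / "descriptive_stats.csv"), float_format="%.6g")

    with _stage("cluster"):
        cluster = discriminate.cluster_traits(data.traits)
        (_emit(out / "trait_dendrogram.nwk")).write_text(
            discriminate.linkage_to_newick(cluster.trait_linkage,
                                           list(data.traits.data.columns))
        )
        (_emit(out / "sample_dendrogram.nwk")).write_text(
            discriminate.linkage_to_newick(cluster.sample_linkage,
                                           data.traits.sample_ids)
        )

    with _stage("split"):
        split = core.split_calibration_prediction(
            data.traits.sample_ids, data.species,
            fraction=config.split_fraction, seed=config.seed,
        )

    with _stage("pca"):
        pca_summary = {}
        for mode, ds in data.modes.items():
            k = min(config.pca_components, ds.n_samples - 1, ds.n_channels)
            res = pca.fit_pca(ds, k)
            corr, influential = pca.correlation_loadings(res, ds)
            pca_summary[mode] = {
                "explained_variance_percent": res.explained_variance_percent.tolist(),
                "influential_channels": ds.axis[influential].tolist(),
            }
            np.savetxt(_emit(out / f"pca_{mode}_scores.csv"), res.scores,
                       delimiter=",", fmt="%.10g")
            np.savetxt(_emit(out / f"pca_{mode}_loadings.csv"), res.loadings,
                       delimiter=",", fmt="%.10g")
        (_emit(out / "pca_summary.json")).write_text(
            json.dumps(pca_summary, indent=2))

    with _stage("hvi"):
        hvi_traits = config.hvi_traits or list(data.traits.data.columns)
        for mode, ds in data.modes.items():
            thin = ds.subset(np.arange(ds.n_samples))
            if config.hvi_step > 1:
                sel = np.arange(0, ds.n_channels, config.hvi_step)
                thin = core.SpectralDataset(
                    ds.axis[sel], ds.values[:, sel], ds.mode,
                    list(ds.sample_ids), list(ds.species), ds.axis_unit,
                )
            for name in hvi_traits:
                imap = indices.r2_map(thin, data.traits.trait(name), trait_name=name)
                indices.export_contour(
                    imap,
                    _emit(out / f"hvi_{name}_{mode}_r2.csv"),
                    _emit(out / f"hvi_{name}_{mode}_best_pair.json"),
                )

    with _stage("plsr"):
        report = plsr.run_trait_models(
            data.modes, data.traits, split,
            max_factors=config.max_factors, n_folds=config.n_folds,
            seed=config.seed, trait_names=config.plsr_traits,
        )
        report.to_csv(_emit(out / "plsr_report.csv"), index=False,
                      float_format="%.6g")

    with _stage("discriminate"):
        disc_summary = {}
        for mode, ds in data.modes.items():
            res = discriminate.discriminate_mode(ds, seed=config.seed,
                                                 n_folds=config.n_folds)
            disc_summary[mode] = {
                "accuracy": res.accuracy,
                "kappa": res.kappa,
                "confusion": res.confusion.tolist(),
                "region_peaks": res.region_peaks,
            }
            np.savetxt(_emit(out / f"f_series_{mode}.csv"),
                       np.column_stack([res.axis, res.f_series]),
                       delimiter=",", header="channel,F", comments="", fmt="%.10g")
        (_emit(out / "discrimination.json")).write_text(
            json.dumps(disc_summary, indent=2, default=_jsonable))

    manifest.write(out / "manifest.json")
    return manifest
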