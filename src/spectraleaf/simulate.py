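"""Seeded synthetic generator for two-species leaf spectroscopy datasets.

No public dataset accompanies the analysis this package implements, so this
module fabricates one with the statistical structure the downstream stages
assume: two *Tradescantia*-like archetypes (a green-leaf and a purple-leaf
form) with opposing patterns in eight structural/ultrastructural traits,
species-distinct OJIP chlorophyll-fluorescence transients on a logarithmic
time axis, and reflectance/transmittance spectra over 350–2500 nm whose
features are tied to the traits at known wavelengths.

Model sketch
------------
Traits. Each independently drawn trait follows a truncated normal per
species. The printed pooled coefficient of variation is partitioned into a
between-species component (the opposed species shifts) and a within-species
spread; the parent normal is then *moment-matched* so the truncated
distribution's mean equals the target exactly and its SD comes as close to
the target as the truncation bounds permit. Total leaf thickness is never
drawn: it is the exact per-sample sum of the four layer traits.

Fluorescence. F(t) = O + Σ_k A_k (1 − exp(−t/τ_k)) over the three rise
phases (J, I, P) with characteristic times ≈ 4·10⁻⁴, 2·10⁻², 2·10⁻¹ s.
Phase amplitudes are modulated by standardized trait values and scaled per
species; noise is multiplicative.

Optics. A wavelength-dependent absorption budget (chlorophyll-like and
anthocyanin-like pigments plus water bands scaled by total thickness) is
split into reflected and transmitted shares; trait-linked Gaussian features
are added on top, then additive noise; results are clipped so that
0 ≤ R, T and R + T ≤ 1 everywhere.

A per-sample, per-trait "coupling jitter" (a standardized-unit Gaussian
added to the trait value the optics actually respond to) caps how well any
regression can recover a trait from spectra, emulating the imperfect
anatomy–optics coupling of real leaves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .core import LAYER_TRAITS, TRAIT_COLUMNS, SpectralDataset, TraitTable, compute_absorbance

logger = logging.getLogger(__name__)

GREEN = "green"    # green-leaf archetype (T. spathacea-like)
PURPLE = "purple"  # purple-leaf archetype (T. pallida-like)

OJIP_PHASES = ("J", "I", "P")


class ConfigurationError(ValueError):
    """Generator configuration violates a precondition."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class TraitSpec:
    """Target marginal distribution of one trait.

    ``mean``/``cv_percent`` describe the pooled (two-species) sample;
    ``species_effect`` maps species name to a signed fractional shift of the
    mean, so that with a balanced design the pooled mean is preserved.
    """

    name: str
    unit: str
    mean: float
    cv_percent: float
    min_bound: float
    max_bound: float
    species_effect: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ConfigurationError(f"{self.name}: mean must be positive")
        if self.cv_percent < 0:
            raise ConfigurationError(f"{self.name}: cv_percent must be nonnegative")
        if not self.min_bound <= self.mean <= self.max_bound:
            raise ConfigurationError(
                f"{self.name}: require min_bound <= mean <= max_bound"
            )

    @property
    def sd(self) -> float:
        return self.mean * self.cv_percent / 100.0


@dataclass
class OjipParams:
    """O-level plus amplitudes and characteristic times of the J, I, P phases."""

    o_level: float
    amplitudes: dict[str, float]
    times: dict[str, float] = field(
        default_factory=lambda: {"J": 4e-4, "I": 2e-2, "P": 2e-1}
    )

    def __post_init__(self) -> None:
        taus = [self.times[k] for k in OJIP_PHASES]
        if not (taus[0] < taus[1] < taus[2]):
            raise ConfigurationError("OJIP phase times must be strictly increasing")
        if self.o_level <= 0:
            raise ConfigurationError("O-level must be positive")
        if self.p_level <= self.o_level:
            raise ConfigurationError("P-level must exceed O-level")

    @property
    def p_level(self) -> float:
        return self.o_level + sum(self.amplitudes.get(k, 0.0) for k in OJIP_PHASES)


@dataclass
class SpeciesProfile:
    """Pigment levels and fluorescence kinetics of one leaf archetype."""

    name: str
    pigment_levels: dict[str, float]  # keys: chlorophyll, anthocyanin
    ojip: OjipParams

    def baseline_rt(self, wavelengths: np.ndarray, water_scale: float = 1.0):
        """Noise-free baseline reflectance and transmittance spectra.

        The absorption budget combines a small achromatic floor, pigment
        absorption in the VIS, and water bands in the SWIR (scaled by
        ``water_scale``); the remaining light is split into reflected and
        transmitted shares, guaranteeing R + T < 1.
        """
        lam = np.asarray(wavelengths, dtype=float)
        chl = self.pigment_levels.get("chlorophyll", 0.0)
        anth = self.pigment_levels.get("anthocyanin", 0.0)
        absorb = (
            0.06
            + chl * (0.85 * _gauss(lam, 430, 28) + 0.75 * _gauss(lam, 662, 24)
                     + 0.40 * _gauss(lam, 490, 45))
            + anth * 0.45 * _gauss(lam, 544, 45)
            + water_scale * (0.50 * _gauss(lam, 1450, 50) + 0.70 * _gauss(lam, 1940, 80)
                             + 0.20 * _gauss(lam, 1200, 55) + 0.55 * _gauss(lam, 2400, 180))
        )
        absorb = np.clip(absorb, 0.0, 0.95)
        r_share = 0.52 - 0.04 * (lam - 350.0) / 2150.0
        refl = r_share * (1.0 - absorb)
        trans = (1.0 - r_share) * (1.0 - absorb)
        return refl, trans


@dataclass
class SpectralFeature:
    """One Gaussian feature added per standardized trait unit."""

    center_nm: float
    width_nm: float
    amplitude: float          # reflectance/transmittance units per SD of trait
    applies_to: str           # "reflectance" | "transmittance"


@dataclass
class SignatureTable:
    """How each trait imprints on the optical spectra and the OJIP phases."""

    spectral: dict[str, list[SpectralFeature]] = field(default_factory=dict)
    fluorescence: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self, lam_min: float, lam_max: float) -> None:
        for trait, feats in self.spectral.items():
            for f in feats:
                if not lam_min <= f.center_nm <= lam_max:
                    raise ConfigurationError(
                        f"{trait}: feature center {f.center_nm} nm outside "
                        f"[{lam_min}, {lam_max}] nm"
                    )
                if f.applies_to not in ("reflectance", "transmittance"):
                    raise ConfigurationError(
                        f"{trait}: applies_to must be reflectance or transmittance"
                    )


@dataclass
class GeneratorConfig:
    """Full recipe for one synthetic dataset (everything seeded and explicit)."""

    n_samples: int = 200
    species_fraction: float = 0.5       # share of green-archetype samples
    seed: int = 0
    wavelength_start: float = 350.0
    wavelength_end: float = 2500.0
    wavelength_step: float = 5.0
    n_time_points: int = 70
    time_start: float = 1e-5
    time_end: float = 1.0
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "fluorescence": 0.015,    # multiplicative
            "reflectance": 0.005,     # additive
            "transmittance": 0.005,   # additive
        }
    )
    signature_jitter_sd: float = 0.35   # SD of the anatomy–optics coupling jitter
    water_coupling: float = 0.15        # water-band scaling per SD of total thickness
    trait_specs: dict[str, TraitSpec] = field(default_factory=dict)
    species_profiles: dict[str, SpeciesProfile] = field(default_factory=dict)
    signatures: SignatureTable = field(default_factory=SignatureTable)

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ConfigurationError("n_samples must be at least 4")
        if not 0.0 < self.species_fraction < 1.0:
            raise ConfigurationError("species_fraction must lie in (0, 1)")
        if self.wavelength_step <= 0 or self.wavelength_end <= self.wavelength_start:
            raise ConfigurationError("wavelength grid must be strictly increasing")
        if self.time_end <= self.time_start or self.n_time_points < 2:
            raise ConfigurationError("time grid must be strictly increasing")
        if not self.trait_specs:
            self.trait_specs = default_trait_specs()
        if not self.species_profiles:
            self.species_profiles = default_species_profiles()
        if not self.signatures.spectral and not self.signatures.fluorescence:
            self.signatures = default_signatures()
        missing = set(TRAIT_COLUMNS) - set(self.trait_specs)
        if missing:
            raise ConfigurationError(f"trait specs missing for {sorted(missing)}")
        self.signatures.validate(self.wavelength_start, self.wavelength_end)

    @property
    def wavelength_grid(self) -> np.ndarray:
        n = int(round((self.wavelength_end - self.wavelength_start) / self.wavelength_step)) + 1
        return self.wavelength_start + self.wavelength_step * np.arange(n)

    @property
    def time_grid(self) -> np.ndarray:
        return np.geomspace(self.time_start, self.time_end, self.n_time_points)

    def standardize(self, trait: str, value) -> np.ndarray:
        """Trait value in standardized units relative to its pooled spec."""
        spec = self.trait_specs[trait]
        if spec.sd == 0:
            return np.zeros_like(np.asarray(value, dtype=float))
        return (np.asarray(value, dtype=float) - spec.mean) / spec.sd


@dataclass
class LeafRecord:
    """One simulated leaf: traits plus its three measured curves."""

    sample_id: str
    species: str
    traits: dict[str, float]
    ojip: np.ndarray
    reflectance: np.ndarray
    transmittance: np.ndarray


@dataclass
class LeafDataset:
    """Bundle of the four spectral datasets plus the trait table."""

    fluorescence: SpectralDataset
    reflectance: SpectralDataset
    transmittance: SpectralDataset
    absorbance: SpectralDataset
    traits: TraitTable

    @property
    def species(self) -> list[str]:
        return list(self.traits.species)

    @property
    def modes(self) -> dict[str, SpectralDataset]:
        return {
            "fluorescence": self.fluorescence,
            "reflectance": self.reflectance,
            "transmittance": self.transmittance,
            "absorbance": self.absorbance,
        }

    def records(self):
        for i, sid in enumerate(self.traits.sample_ids):
            yield LeafRecord(
                sample_id=sid,
                species=self.traits.species[i],
                traits=dict(self.traits.data.iloc[i]),
                ojip=self.fluorescence.values[i],
                reflectance=self.reflectance.values[i],
                transmittance=self.transmittance.values[i],
            )


# ---------------------------------------------------------------------------
# defaults: the study conditions
# ---------------------------------------------------------------------------

def default_trait_specs() -> dict[str, TraitSpec]:
    """Trait roster with pooled mean/CV/min/max and opposed species shifts.

    The purple archetype has the thicker parenchyma and adaxial epidermis;
    the green archetype the thicker hypodermis layers, more chloroplasts and
    taller grana. Parenchyma, granum and thylakoid shifts are kept small so
    those traits stay only weakly tied to species (and hence to spectra).
    """
    rows = [
        # name, unit, mean, cv%, min, max, green effect, purple effect
        ("adaxial_epidermis_um", "um", 102.7, 23.94, 61.0, 162.0, -0.18, +0.18),
        ("adaxial_hypodermis_um", "um", 323.4, 25.79, 212.0, 452.0, +0.15, -0.15),
        ("parenchyma_um", "um", 252.6, 3.80, 224.0, 296.0, -0.012, +0.012),
        ("abaxial_hypodermis_um", "um", 170.5, 25.53, 117.0, 246.0, +0.12, -0.12),
        ("total_thickness_um", "um", 849.1, 7.02, 735.0, 978.0, 0.0, 0.0),
        ("chloroplast_count", "count", 21.2, 22.23, 14.0, 32.0, +0.12, -0.12),
        ("granum_height_nm", "nm", 522.5, 37.29, 75.0, 1000.0, +0.05, -0.05),
        ("thylakoid_layer_granum", "dimensionless", 25.2, 33.80, 4.0, 53.0, +0.05, -0.05),
    ]
    return {
        name: TraitSpec(
            name=name, unit=unit, mean=mean, cv_percent=cv,
            min_bound=lo, max_bound=hi,
            species_effect={GREEN: eg, PURPLE: ep},
        )
        for name, unit, mean, cv, lo, hi, eg, ep in rows
    }


def default_species_profiles() -> dict[str, SpeciesProfile]:
    """Green vs purple archetypes.

    The green form carries little anthocyanin (hence the higher green-region
    reflectance around 544 nm), a slightly higher O-level, and OJIP phase
    amplitudes scaled 1.3× relative to the purple form, so its mean
    fluorescence transient sits above the purple one at every time point.
    """
    base_amps = {"J": 2.0, "I": 1.0, "P": 1.0}
    return {
        GREEN: SpeciesProfile(
            name=GREEN,
            pigment_levels={"chlorophyll": 1.0, "anthocyanin": 0.05},
            ojip=OjipParams(
                o_level=1.1, amplitudes={k: 1.3 * v for k, v in base_amps.items()}
            ),
        ),
        PURPLE: SpeciesProfile(
            name=PURPLE,
            pigment_levels={"chlorophyll": 0.8, "anthocyanin": 1.0},
            ojip=OjipParams(o_level=1.0, amplitudes=dict(base_amps)),
        ),
    }


def default_signatures() -> SignatureTable:
    """Trait → spectrum/fluorescence couplings.

    Hypodermis traits carry strong features (red edge, green region, water
    and SWIR bands) well above the noise floor; the epidermis a moderate
    blue-region feature; chloroplast count rides on the chlorophyll bands
    and scales the fluorescence rise. Parenchyma and the two ultrastructural
    traits are left without usable signal (zero or sub-noise amplitudes), so
    downstream models must — correctly — fail to predict them.
    """
    R, T = "reflectance", "transmittance"
    spectral = {
        "adaxial_hypodermis_um": [
            SpectralFeature(700, 25, +0.020, R),
            SpectralFeature(1441, 45, -0.016, R),
            SpectralFeature(700, 25, +0.012, T),
            SpectralFeature(1607, 45, -0.018, T),
        ],
        "abaxial_hypodermis_um": [
            SpectralFeature(544, 30, +0.016, R),
            SpectralFeature(2488, 40, -0.016, R),
            SpectralFeature(1125, 55, +0.020, T),
        ],
        "adaxial_epidermis_um": [
            SpectralFeature(450, 30, +0.007, R),
            SpectralFeature(400, 30, -0.007, T),
        ],
        "chloroplast_count": [
            SpectralFeature(662, 25, -0.012, R),
            SpectralFeature(662, 25, -0.010, T),
        ],
    }
    fluorescence = {
        # the transient is measured from the adaxial surface, so only the
        # adaxial-side layers and the chloroplast population imprint on it
        "adaxial_hypodermis_um": {"J": +0.18},
        "chloroplast_count": {"I": +0.12},
        "adaxial_epidermis_um": {"P": +0.04},
        "granum_height_nm": {"J": +0.004},  # deliberately below the noise floor
    }
    return SignatureTable(spectral=spectral, fluorescence=fluorescence)


def default_config(**overrides) -> GeneratorConfig:
    """The study conditions: n = 200, balanced species, 5 nm grid, 70 time points."""
    return GeneratorConfig(**overrides)


# ---------------------------------------------------------------------------
# moment-matched truncated normal
# ---------------------------------------------------------------------------

def _gauss(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


@lru_cache(maxsize=256)
def _match_truncnorm(target_mean: float, target_sd: float, lo: float, hi: float):
    """Parent (mu, sigma) whose [lo, hi]-truncation matches the targets.

    The truncated mean is matched exactly (it is monotone in mu and spans
    (lo, hi)); sigma is solved so the truncated SD equals target_sd where
    attainable, otherwise the closest attainable SD is used.
    """
    if not lo < target_mean < hi:
        raise ConfigurationError(
            f"target mean {target_mean} outside truncation bounds ({lo}, {hi})"
        )
    if target_sd <= 0:
        return target_mean, 0.0

    def trunc_stats(mu, sigma):
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # far-tail moments
            m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
            return float(m), float(np.sqrt(v))

    def mu_for(sigma):
        # when sigma >> (hi - lo) the truncated density is ~ exp(mu x / sigma²),
        # so reaching a mean near a bound needs mu to scale like sigma²/distance
        edge = min(target_mean - lo, hi - target_mean)
        reach = 8.0 * sigma + 8.0 * sigma ** 2 / edge
        lo_b, hi_b = lo - reach, hi + reach
        return brentq(
            lambda mu: trunc_stats(mu, sigma)[0] - target_mean,
            lo_b, hi_b, xtol=1e-9 * max(1.0, abs(target_mean)),
        )

    def sd_gap(sigma):
        return trunc_stats(mu_for(sigma), sigma)[1] - target_sd

    # the attainable SD saturates as sigma grows (the truncated density tends
    # to a tilted-exponential limit), and scipy's far-tail moments eventually
    # turn NaN — so double sigma only while the SD keeps improving cleanly
    s_lo = 1e-3 * target_sd
    sigma_try = target_sd
    best_sigma, best_sd = None, -np.inf
    bracket_hi = None
    for _ in range(10):
        try:
            sd_try = trunc_stats(mu_for(sigma_try), sigma_try)[1]
        except ValueError:
            break
        if not np.isfinite(sd_try):
            break
        if sd_try > best_sd:
            best_sd, best_sigma = sd_try, sigma_try
        if sd_try >= target_sd:
            bracket_hi = sigma_try
            break
        sigma_try *= 2.0
    if bracket_hi is None:
        if best_sigma is None:
            raise ConfigurationError(
                f"cannot calibrate truncated normal for mean {target_mean}, "
                f"SD {target_sd} on ({lo}, {hi})"
            )
        sigma = best_sigma  # bounds too tight for the requested SD
        logger.info(
            "truncation bounds (%g, %g) cannot support SD %g around mean %g; "
            "using closest attainable (%g)", lo, hi, target_sd, target_mean, best_sd,
        )
    else:
        sigma = brentq(sd_gap, s_lo, bracket_hi, xtol=1e-8 * target_sd)
    return mu_for(sigma), sigma


def _within_species_sd(spec: TraitSpec, fractions: dict[str, float]) -> float:
    """Partition the pooled variance into between-species and within parts."""
    total_var = spec.sd ** 2
    means = {s: spec.mean * (1.0 + spec.species_effect.get(s, 0.0)) for s in fractions}
    grand = sum(fractions[s] * means[s] for s in fractions)
    between = sum(fractions[s] * (means[s] - grand) ** 2 for s in fractions)
    floor = (0.15 * spec.sd) ** 2
    return float(np.sqrt(max(total_var - between, floor)))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def species_labels(config: GeneratorConfig) -> list[str]:
    """Deterministic block assignment: green archetype first, then purple."""
    n_green = int(round(config.n_samples * config.species_fraction))
    n_green = min(max(n_green, 2), config.n_samples - 2)
    return [GREEN] * n_green + [PURPLE] * (config.n_samples - n_green)


def generate_traits(config: GeneratorConfig, rng: np.random.Generator) -> TraitTable:
    """Draw the trait table: calibrated truncated normals per species, plus
    total thickness as the exact per-sample sum of the four layer traits."""
    labels = species_labels(config)
    for spec in config.trait_specs.values():
        for s in (GREEN, PURPLE):
            if s not in spec.species_effect:
                raise ConfigurationError(f"{spec.name}: no species effect for {s!r}")
    n = config.n_samples
    fractions = {
        GREEN: labels.count(GREEN) / n,
        PURPLE: labels.count(PURPLE) / n,
    }
    lab_arr = np.asarray(labels)
    data = {}
    for name in TRAIT_COLUMNS:
        if name == "total_thickness_um":
            continue
        spec = config.trait_specs[name]
        col = np.empty(n)
        for s in (GREEN, PURPLE):
            idx = np.flatnonzero(lab_arr == s)
            mean_s = spec.mean * (1.0 + spec.species_effect[s])
            if not spec.min_bound <= mean_s <= spec.max_bound:
                raise ConfigurationError(
                    f"{name}: species-shifted mean {mean_s:g} outside bounds"
                )
            sd_s = _within_species_sd(spec, fractions)
            if sd_s == 0 or spec.cv_percent == 0:
                col[idx] = mean_s
                continue
            mu, sigma = _match_truncnorm(mean_s, sd_s, spec.min_bound, spec.max_bound)
            if sigma == 0:
                col[idx] = mean_s
            else:
                a, b = (spec.min_bound - mu) / sigma, (spec.max_bound - mu) / sigma
                col[idx] = truncnorm.rvs(a, b, loc=mu, scale=sigma,
                                         size=idx.size, random_state=rng)
        data[name] = col
    data["total_thickness_um"] = sum(data[t] for t in LAYER_TRAITS)
    ids = [f"s{i + 1:04d}" for i in range(n)]
    df = pd.DataFrame(data, index=pd.Index(ids, name="sample_id"))[list(TRAIT_COLUMNS)]
    return TraitTable(data=df, species=labels)


def _jittered_z(config: GeneratorConfig, traits: dict[str, float],
                rng: np.random.Generator) -> dict[str, float]:
    """Standardized trait values plus the anatomy–optics coupling jitter."""
    out = {}
    for name in TRAIT_COLUMNS:
        z = float(config.standardize(name, traits[name]))
        out[name] = z + rng.normal(0.0, config.signature_jitter_sd)
    return out


def simulate_ojip(traits: dict[str, float], species: SpeciesProfile,
                  config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """One OJIP transient on the configured log-spaced time grid."""
    t = config.time_grid
    z = _jittered_z(config, traits, rng)
    amps = {}
    for k in OJIP_PHASES:
        amp = species.ojip.amplitudes.get(k, 0.0)
        mod = 1.0
        for trait, effects in config.signatures.fluorescence.items():
            mod += effects.get(k, 0.0) * z[trait]
        amp *= mod
        if amp < 0:
            logger.warning("OJIP %s amplitude went negative after modulation; clipped", k)
            amp = 0.0
        amps[k] = amp
    curve = species.ojip.o_level + sum(
        amps[k] * (1.0 - np.exp(-t / species.ojip.times[k])) for k in OJIP_PHASES
    )
    sd = config.noise_sd.get("fluorescence", 0.0)
    if sd > 0:
        curve = curve * (1.0 + rng.normal(0.0, sd, size=t.size))
    return np.clip(curve, 0.0, None)


def simulate_rt(traits: dict[str, float], species: SpeciesProfile,
                config: GeneratorConfig, rng: np.random.Generator):
    """One (reflectance, transmittance) spectrum pair for a single leaf."""
    lam = config.wavelength_grid
    z = _jittered_z(config, traits, rng)
    water_scale = 1.0 + config.water_coupling * z["total_thickness_um"]
    refl, trans = species.baseline_rt(lam, water_scale=max(water_scale, 0.0))
    refl, trans = refl.copy(), trans.copy()
    for trait, feats in config.signatures.spectral.items():
        for f in feats:
            bump = f.amplitude * z[trait] * _gauss(lam, f.center_nm, f.width_nm)
            if f.applies_to == "reflectance":
                refl += bump
            else:
                trans += bump
    sd_r = config.noise_sd.get("reflectance", 0.0)
    sd_t = config.noise_sd.get("transmittance", 0.0)
    if sd_r > 0:
        refl += rng.normal(0.0, sd_r, size=lam.size)
    if sd_t > 0:
        trans += rng.normal(0.0, sd_t, size=lam.size)
    clipped = (refl < 0).sum() + (trans < 0).sum()
    refl = np.clip(refl, 0.0, 1.0)
    trans = np.clip(trans, 0.0, 1.0)
    total = refl + trans
    over = total > 1.0
    if over.any():
        scale = np.where(over, 1.0 / total, 1.0)
        refl, trans = refl * scale, trans * scale
        clipped += int(over.sum())
    if clipped:
        logger.debug("clipped %d out-of-range R/T values", clipped)
    return refl, trans


def generate_dataset(config: GeneratorConfig, seed: int | None = None) -> LeafDataset:
    """Full synthetic dataset: traits, OJIP, R, T, and derived A.

    Identical configuration and seed reproduce every output bit-for-bit;
    sample ids align across all five outputs.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    traits = generate_traits(config, rng)
    labels = traits.species
    lam, t = config.wavelength_grid, config.time_grid
    n = config.n_samples
    fluor = np.empty((n, t.size))
    refl = np.empty((n, lam.size))
    trans = np.empty((n, lam.size))
    for i in range(n):
        row = {k: float(traits.data.iloc[i][k]) for k in TRAIT_COLUMNS}
        profile = config.species_profiles[labels[i]]
        fluor[i] = simulate_ojip(row, profile, config, rng)
        refl[i], trans[i] = simulate_rt(row, profile, config, rng)
    ids = traits.sample_ids
    ds_f = SpectralDataset(t, fluor, "fluorescence", ids, labels, axis_unit="s")
    ds_r = SpectralDataset(lam, refl, "reflectance", ids, labels, axis_unit="nm")
    ds_t = SpectralDataset(lam, trans, "transmittance", ids, labels, axis_unit="nm")
    ds_a = compute_absorbance(ds_r, ds_t)
    return LeafDataset(
        fluorescence=ds_f, reflectance=ds_r, transmittance=ds_t,
        absorbance=ds_a, traits=traits,
    )
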