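"""Synthetic RGBC datasets with the statistical structure of the oil study.

The generator emulates the study design: 25 replicates of pure avocado oil
plus blends with canola, sunflower, corn, olive and soybean oil at 5, 10,
20, 35 and 50 % (five replicates each) for classification, and 0–50 % in
5 % steps × 5 replicates (55 samples per oil pair) for calibration.

Mixing model
------------
Each (oil, illuminant) pair has an endmember chromaticity: the triple of
clear-normalized reflectance factors the sensor would report for the pure
oil. A blend of fraction ``f`` interpolates between count-space linear
mixing and absorbance-like (log-domain) mixing::

    linear  = (1 - f) * c_avocado + f * c_adulterant
    logmix  = exp((1 - f) * ln c_avocado + f * ln c_adulterant)
    c_blend = (1 - w) * linear + w * logmix,   w = min(nonlinearity, 1)

With ``nonlinearity = 0`` blends are exactly affine in ``f`` (so a linear
regression recovers fractions perfectly); at the default ``nonlinearity = 1``
mixing follows Beer–Lambert-style absorbance additivity, which is mildly
curved in count space — enough that a kernel model has a genuine edge over a
linear one, as colour responses of real oil blends do.

Noise is multiplicative Gaussian per raw reading (relative sd ``noise_sd``,
doubled under UV where the weak 395 nm LED yields poorer photon statistics),
and 10 raw readings are averaged per sample, matching the acquisition
protocol. The clear channel is simulated directly and R, G, B are generated
as bounded fractions of it, so C >= max(R, G, B) holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import (
    ConfigurationError,
    Dataset,
    Illuminant,
    OilIdentity,
    RawReading,
    Task,
)
from .ingest import make_sample

#: Blend fractions used for the classification design.
CLASSIFICATION_FRACTIONS = (0.05, 0.10, 0.20, 0.35, 0.50)
#: Blend fractions used for the per-oil calibration design (0–50 % in 5 % steps).
CALIBRATION_FRACTIONS = tuple(round(0.05 * i, 2) for i in range(11))

N_PURE_REPLICATES = 25
N_BLEND_REPLICATES = 5

Chromaticity = tuple[float, float, float]

# Endmember chromaticities (r, g, b as fractions of the clear count).
# Virgin avocado oil is green-dominant (chlorophyll pigments); the refined
# seed oils are paler and mutually distinct; olive sits nearest avocado.
# Under UV the palette is compressed: blue-shifted fluorescence-like
# profiles with much smaller between-oil contrast.
DEFAULT_CHROMATICITIES: dict[tuple[OilIdentity, Illuminant], Chromaticity] = {
    (OilIdentity.AVOCADO, Illuminant.WHITE): (0.30, 0.55, 0.15),
    (OilIdentity.CANOLA, Illuminant.WHITE): (0.50, 0.45, 0.35),
    (OilIdentity.SUNFLOWER, Illuminant.WHITE): (0.55, 0.60, 0.20),
    (OilIdentity.CORN, Illuminant.WHITE): (0.60, 0.50, 0.12),
    (OilIdentity.OLIVE, Illuminant.WHITE): (0.35, 0.65, 0.28),
    (OilIdentity.SOYBEAN, Illuminant.WHITE): (0.45, 0.35, 0.40),
    (OilIdentity.AVOCADO, Illuminant.UV): (0.20, 0.30, 0.45),
    (OilIdentity.CANOLA, Illuminant.UV): (0.24, 0.32, 0.47),
    (OilIdentity.SUNFLOWER, Illuminant.UV): (0.26, 0.33, 0.44),
    (OilIdentity.CORN, Illuminant.UV): (0.23, 0.29, 0.48),
    (OilIdentity.OLIVE, Illuminant.UV): (0.21, 0.34, 0.46),
    (OilIdentity.SOYBEAN, Illuminant.UV): (0.25, 0.31, 0.45),
}


@dataclass(frozen=True)
class BlendSpec:
    """One specimen to simulate: adulterant, mass fraction and replicate."""

    adulterant: OilIdentity
    fraction: float
    replicate: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 0.5):
            raise ConfigurationError(f"fraction {self.fraction} outside [0, 0.5]")
        if self.fraction > 0 and self.adulterant is OilIdentity.AVOCADO:
            raise ConfigurationError("a blend's adulterant cannot be avocado itself")
        if self.replicate < 1:
            raise ConfigurationError("replicate must be a positive integer")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    noise_sd is the relative standard deviation of a single raw reading
    (about 1 % for a TCS34725-class sensor at 24 ms integration); UV
    acquisitions get ``uv_noise_multiplier`` times that. clear_scale is the
    magnitude of the clear-channel count. nonlinearity in [0, 1] blends
    count-space linear mixing (0) into absorbance-domain mixing (1).
    """

    endmember_chromaticities: Mapping[tuple[OilIdentity, Illuminant], Chromaticity] = (
        field(default_factory=lambda: dict(DEFAULT_CHROMATICITIES))
    )
    clear_scale: float = 2000.0
    noise_sd: float = 0.01
    nonlinearity: float = 1.0
    n_readings_per_sample: int = 10
    uv_noise_multiplier: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.nonlinearity < 0:
            raise ConfigurationError("nonlinearity must be >= 0")
        if self.n_readings_per_sample < 1:
            raise ConfigurationError("n_readings_per_sample must be >= 1")
        if self.clear_scale <= 0:
            raise ConfigurationError("clear_scale must be positive")
        if self.uv_noise_multiplier <= 0:
            raise ConfigurationError("uv_noise_multiplier must be positive")
        for oil in OilIdentity:
            for illum in Illuminant:
                key = (oil, illum)
                if key not in self.endmember_chromaticities:
                    raise ConfigurationError(
                        f"missing endmember chromaticity for ({oil.value}, {illum.value})"
                    )
                triple = self.endmember_chromaticities[key]
                if len(triple) != 3 or any(not (0 < v < 1) for v in triple):
                    raise ConfigurationError(
                        f"chromaticity for ({oil.value}, {illum.value}) must be "
                        "three factors strictly inside (0, 1)"
                    )


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The package's default acquisition profile."""
    return SyntheticConfig(seed=seed, **overrides)


def high_noise_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A deliberately degraded acquisition profile (50x the default
    single-reading noise, as from ambient-light leakage or an unstable LED).

    Under this profile the pure and blended classes overlap heavily, which
    is the regime where a linear discriminant with empirical priors
    collapses onto the majority (blended) class: the prior log-odds of the
    84 %-majority blended class dominate the washed-out Mahalanobis term.
    """
    overrides.setdefault("noise_sd", 0.50)
    return SyntheticConfig(seed=seed, **overrides)


def _effective_noise_sd(cfg: SyntheticConfig, illum: Illuminant) -> float:
    if illum is Illuminant.UV:
        return cfg.noise_sd * cfg.uv_noise_multiplier
    return cfg.noise_sd


def _blend_chromaticity(
    spec: BlendSpec, illum: Illuminant, cfg: SyntheticConfig
) -> np.ndarray:
    base = np.asarray(cfg.endmember_chromaticities[(OilIdentity.AVOCADO, illum)], float)
    other = np.asarray(cfg.endmember_chromaticities[(spec.adulterant, illum)], float)
    f = spec.fraction
    linear = (1.0 - f) * base + f * other
    logmix = np.exp((1.0 - f) * np.log(base) + f * np.log(other))
    w = min(cfg.nonlinearity, 1.0)
    return (1.0 - w) * linear + w * logmix


def simulate_sample(
    spec: BlendSpec,
    illum: Illuminant,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> RawReading:
    """Simulate one averaged acquisition of a blend.

    Per raw reading, the clear count and the three channel fractions each
    receive independent multiplicative Gaussian noise; channel fractions are
    clipped to [0, 1] so every raw reading satisfies C >= max(R, G, B), a
    bound the channel-wise average then inherits.
    """
    if (spec.adulterant, illum) not in cfg.endmember_chromaticities:
        raise ConfigurationError(
            f"no endmember for ({spec.adulterant.value}, {illum.value})"
        )
    chroma = _blend_chromaticity(spec, illum, cfg)
    sd = _effective_noise_sd(cfg, illum)
    n = cfg.n_readings_per_sample

    clear = cfg.clear_scale * (1.0 + sd * rng.standard_normal(n))
    clear = np.clip(clear, 1e-6, None)
    ratios = chroma[None, :] * (1.0 + sd * rng.standard_normal((n, 3)))
    ratios = np.clip(ratios, 0.0, 1.0)
    rgb = ratios * clear[:, None]

    mean_rgb = rgb.mean(axis=0)
    mean_c = clear.mean()
    return RawReading(
        R=float(mean_rgb[0]),
        G=float(mean_rgb[1]),
        B=float(mean_rgb[2]),
        C=float(mean_c),
        illuminant=illum,
    )


def _dataset_rng(cfg: SyntheticConfig, illum: Illuminant, stream: int) -> np.random.Generator:
    illum_ix = list(Illuminant).index(illum)
    return np.random.default_rng([cfg.seed % (2**31), illum_ix, stream])


def generate_classification_dataset(
    cfg: SyntheticConfig, illum: Illuminant = Illuminant.WHITE
) -> Dataset:
    """The 150-sample classification design.

    25 replicates of pure avocado oil plus 5 adulterants x fractions
    {5, 10, 20, 35, 50 %} x 5 replicates = 125 blends. Deterministic for a
    fixed config seed.
    """
    rng = _dataset_rng(cfg, illum, stream=0)
    samples = []
    for rep in range(1, N_PURE_REPLICATES + 1):
        spec = BlendSpec(OilIdentity.AVOCADO, 0.0, rep)
        raw = simulate_sample(spec, illum, cfg, rng)
        samples.append(
            make_sample(f"avocado-000-r{rep:02d}", OilIdentity.AVOCADO, 0.0, rep, raw)
        )
    for oil in OilIdentity.adulterants():
        for frac in CLASSIFICATION_FRACTIONS:
            for rep in range(1, N_BLEND_REPLICATES + 1):
                spec = BlendSpec(oil, frac, rep)
                raw = simulate_sample(spec, illum, cfg, rng)
                sid = f"{oil.value}-{int(round(frac * 100)):03d}-r{rep:02d}"
                samples.append(make_sample(sid, oil, frac, rep, raw))
    return Dataset(
        samples=samples,
        task=Task.MULTICLASS,
        provenance=f"synthetic classification seed={cfg.seed} illuminant={illum.value}",
    )


def generate_calibration_dataset(
    adulterant: OilIdentity,
    cfg: SyntheticConfig,
    illum: Illuminant = Illuminant.WHITE,
) -> Dataset:
    """The 55-sample per-oil calibration design: 0–50 % in 5 % steps x 5 reps.

    Fraction-0 rows are pure avocado oil; every sample carries its true
    fraction as the regression target.
    """
    if adulterant is OilIdentity.AVOCADO:
        raise ValueError("calibration datasets quantify an adulterant, not avocado")
    stream = 1 + list(OilIdentity).index(adulterant)
    rng = _dataset_rng(cfg, illum, stream=stream)
    samples = []
    for frac in CALIBRATION_FRACTIONS:
        oil = OilIdentity.AVOCADO if frac == 0.0 else adulterant
        for rep in range(1, N_BLEND_REPLICATES + 1):
            spec = BlendSpec(oil, frac, rep)
            raw = simulate_sample(spec, illum, cfg, rng)
            sid = f"{adulterant.value}-{int(round(frac * 100)):03d}-r{rep:02d}"
            samples.append(make_sample(sid, oil, frac, rep, raw))
    return Dataset(
        samples=samples,
        task=Task.REGRESSION,
        provenance=(
            f"synthetic calibration adulterant={adulterant.value} "
            f"seed={cfg.seed} illuminant={illum.value}"
        ),
    )
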