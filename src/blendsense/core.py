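"""Core domain types for colour-sensor oil-blend chemometrics.

The experimental unit is a cuvette of oil read by a TCS34725-class RGBC
sensor under one of two illuminants (the sensor's white LED or a 395 nm UV
LED). Each acquisition yields four nonnegative channel counts — red, green,
blue and clear — and the clear channel is used downstream as the
normalization denominator, giving three dimensionless colour descriptors
per sample.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence


class BlendSenseError(Exception):
    """Base class for package errors."""


class ConfigurationError(BlendSenseError, ValueError):
    """Invalid generator or experiment configuration."""


class ParseError(BlendSenseError, ValueError):
    """Malformed raw sensor log input."""


class SchemaError(BlendSenseError, ValueError):
    """Dataset file violating the interchange CSV schema."""


class DegenerateReadingError(BlendSenseError, ValueError):
    """A reading that cannot be normalized (e.g. clear channel of zero)."""


class FittingError(BlendSenseError, RuntimeError):
    """Model fitting failed (singular or rank-deficient system)."""


class OilIdentity(str, enum.Enum):
    """The six oils in the study: avocado is the base oil of every blend."""

    AVOCADO = "avocado"
    CANOLA = "canola"
    SUNFLOWER = "sunflower"
    CORN = "corn"
    OLIVE = "olive"
    SOYBEAN = "soybean"

    @classmethod
    def adulterants(cls) -> tuple["OilIdentity", ...]:
        return tuple(o for o in cls if o is not cls.AVOCADO)

    @classmethod
    def parse(cls, token: str) -> "OilIdentity":
        try:
            return cls(token.strip().lower())
        except ValueError:
            raise ConfigurationError(f"unknown oil identity: {token!r}") from None


class Illuminant(str, enum.Enum):
    """Lighting condition during acquisition: white LED or 395 nm UV LED."""

    WHITE = "white"
    UV = "uv"

    @classmethod
    def parse(cls, token: str) -> "Illuminant":
        try:
            return cls(token.strip().lower())
        except ValueError:
            raise ConfigurationError(f"unknown illuminant: {token!r}") from None


@dataclass(frozen=True)
class RawReading:
    """One (possibly averaged) sensor acquisition.

    Channel values are kept real-valued: averaging integer counts yields
    fractional means and rounding them back to integers would introduce
    quantization the sensor itself does not have.
    """

    R: float
    G: float
    B: float
    C: float
    illuminant: Illuminant
    integration_ms: float = 24.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        for name in ("R", "G", "B", "C"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"channel {name} must be nonnegative, got {v}")
        if self.integration_ms <= 0 or self.gain <= 0:
            raise ValueError("integration_ms and gain must be positive")

    def channels(self) -> tuple[float, float, float, float]:
        return (self.R, self.G, self.B, self.C)


#: Ratios above this bound indicate a corrupt reading (R/G/B should not
#: exceed the clear channel by anywhere near this much).
FEATURE_BOUND = 2.0


@dataclass(frozen=True)
class ColourFeature:
    """Clear-normalized colour descriptors r = R/C, g = G/C, b = B/C."""

    r: float
    g: float
    b: float

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            v = getattr(self, name)
            if not (0.0 <= v <= FEATURE_BOUND):
                raise DegenerateReadingError(
                    f"feature {name}={v} outside [0, {FEATURE_BOUND}]; corrupt reading?"
                )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.r, self.g, self.b)


@dataclass(frozen=True)
class OilSample:
    """A labelled specimen: oil identity, blend fraction and colour features.

    ``oil`` is the adulterant identity (or avocado for the pure oil);
    ``fraction`` is the adulterant mass fraction, zero iff the sample is
    pure avocado oil.
    """

    sample_id: str
    oil: OilIdentity
    fraction: float
    replicate: int
    illuminant: Illuminant
    raw: RawReading
    features: ColourFeature

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 0.5):
            raise ValueError(f"fraction {self.fraction} outside [0, 0.5]")
        if (self.fraction == 0.0) != (self.oil is OilIdentity.AVOCADO):
            raise ValueError(
                "fraction must be 0 exactly for pure avocado samples "
                f"(oil={self.oil.value}, fraction={self.fraction})"
            )
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        if self.illuminant is not self.raw.illuminant:
            raise ValueError("sample and raw reading illuminants disagree")

    @property
    def is_pure(self) -> bool:
        return self.fraction == 0.0


class Task(str, enum.Enum):
    BINARY = "binary"
    MULTICLASS = "multiclass"
    REGRESSION = "regression"


@dataclass
class Dataset:
    """An ordered collection of samples sharing one illuminant.

    For regression all samples additionally share one adulterant (pure
    avocado rows count as fraction-0 members of that adulterant's series).
    """

    samples: list[OilSample]
    task: Task
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("dataset must be nonempty")
        illums = {s.illuminant for s in self.samples}
        if len(illums) != 1:
            raise ValueError("all samples in a dataset must share one illuminant")
        if self.task is Task.REGRESSION:
            oils = {s.oil for s in self.samples if not s.is_pure}
            if len(oils) > 1:
                raise ValueError("regression dataset must hold a single adulterant")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def illuminant(self) -> Illuminant:
        return self.samples[0].illuminant

    def feature_matrix(self):
        import numpy as np

        return np.array([s.features.as_tuple() for s in self.samples], dtype=float)

    def fractions(self):
        import numpy as np

        return np.array([s.fraction for s in self.samples], dtype=float)

    def binary_labels(self) -> list[str]:
        """Pure-vs-blended labels derived from the blend fraction."""
        return ["pure" if s.is_pure else "blended" for s in self.samples]

    def multiclass_labels(self) -> list[str]:
        """Six-class labels: the adulterant identity, 'pure' for fraction 0."""
        return ["pure" if s.is_pure else s.oil.value for s in self.samples]

    def subset(self, indices: Sequence[int], task: Task | None = None) -> "Dataset":
        return Dataset(
            samples=[self.samples[i] for i in indices],
            task=task or self.task,
            provenance=self.provenance,
        )
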