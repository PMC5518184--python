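"""Core value types shared across the pipeline.

The analysis moves between three representations of a stimulus:

* a reflectance (or radiance) spectrum on a 300--700 nm grid,
* a set of quantum catches for the four avian single cones (UV, SW, MW,
  LW) plus the double cone (D, assumed to drive achromatic vision), and
* derived colour attributes (tetrahedral coordinates, saturation, hue
  ratios, JND contrasts).

Everything downstream of the camera works in catch space, so the catch
container and the receptor-noise vector live here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

#: Default wavelength grid, nm: UV band 300-400 plus visible 400-700.
DEFAULT_WAVELENGTHS = np.arange(300.0, 701.0, 1.0)

#: Names of the four chromatic receptor channels, in canonical order.
CONE_CHANNELS = ("UV", "SW", "MW", "LW")

#: All receptor channels including the achromatic double cone.
RECEPTOR_CHANNELS = CONE_CHANNELS + ("D",)

#: Cone-catch columns used in tabular interchange (CSV) files.
CATCH_COLUMNS = ("qUV", "qSW", "qMW", "qLW", "qD")

#: JND band inside which two stimuli are likely indistinguishable to the
#: modelled avian observer; used only to annotate reports.
JND_INDISTINGUISHABLE_BAND = (1.0, 3.0)


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class SpectralCurve:
    """A non-negative function of wavelength (reflectance, radiance or
    sensitivity) sampled on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.shape != vals.shape:
            raise ValidationError("wavelengths and values must be equal-length 1-D arrays")
        if wl.size < 2:
            raise ValidationError("a spectral curve needs at least two samples")
        if np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if np.any(vals < 0):
            raise ValidationError("spectral values must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    def same_grid(self, other: "SpectralCurve") -> bool:
        return self.wavelengths.shape == other.wavelengths.shape and np.array_equal(
            self.wavelengths, other.wavelengths
        )


@dataclass(frozen=True)
class SensorSet:
    """A bank of spectral sensitivities (camera channels or receptor
    classes).

    Receptor sets additionally carry the relative abundance ``eta_i`` of
    each class and the Weber fraction ``nu`` of the noisiest-free
    (most abundant) class, from which noise-to-signal ratios are
    derived.
    """

    names: tuple[str, ...]
    sensitivities: tuple[SpectralCurve, ...]
    abundances: np.ndarray | None = None
    weber_fraction: float | None = None

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValidationError("channel names must be unique")
        if len(self.names) != len(self.sensitivities):
            raise ValidationError("one sensitivity per channel required")
        grid = self.sensitivities[0].wavelengths
        for curve in self.sensitivities[1:]:
            if not np.array_equal(curve.wavelengths, grid):
                raise ValidationError("all sensitivities must share one wavelength grid")
        if self.abundances is not None:
            ab = np.asarray(self.abundances, dtype=float)
            if ab.shape != (len(self.names),):
                raise ValidationError("need one abundance per channel")
            if np.any(ab <= 0):
                raise ValidationError("abundances must be positive")
            object.__setattr__(self, "abundances", ab)
        if self.weber_fraction is not None and self.weber_fraction <= 0:
            raise ValidationError("Weber fraction must be positive")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.sensitivities[0].wavelengths

    def matrix(self) -> np.ndarray:
        """Sensitivities stacked as a (n_channels, n_wavelengths) array."""
        return np.stack([c.values for c in self.sensitivities])

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class ConeCatch:
    """Quantum catches of the four single cones plus the double cone."""

    q_uv: float
    q_sw: float
    q_mw: float
    q_lw: float
    q_d: float

    def __post_init__(self) -> None:
        if min(self.q_uv, self.q_sw, self.q_mw, self.q_lw, self.q_d) <= 0:
            raise ValidationError("cone catches must be strictly positive")

    def chromatic(self) -> np.ndarray:
        """The four single-cone catches in (UV, SW, MW, LW) order."""
        return np.array([self.q_uv, self.q_sw, self.q_mw, self.q_lw])

    def as_array(self) -> np.ndarray:
        return np.array([self.q_uv, self.q_sw, self.q_mw, self.q_lw, self.q_d])

    @classmethod
    def from_array(cls, q: np.ndarray) -> "ConeCatch":
        q = np.asarray(q, dtype=float)
        if q.shape != (5,):
            raise ValidationError("expected five catches (UV, SW, MW, LW, D)")
        return cls(*q)


@dataclass(frozen=True)
class NoiseVector:
    """Noise-to-signal ratios omega_i per receptor channel."""

    omega: np.ndarray  # (4,) for UV, SW, MW, LW
    omega_d: float

    def __post_init__(self) -> None:
        om = np.asarray(self.omega, dtype=float)
        if om.shape != (4,):
            raise ValidationError("expected four chromatic noise ratios")
        if np.any(om <= 0) or self.omega_d <= 0:
            raise ValidationError("noise ratios must be positive")
        object.__setattr__(self, "omega", om)


@dataclass(frozen=True)
class TetraPoint:
    """Cartesian position of a colour in avian tetrahedral colour space."""

    x: float
    y: float
    z: float

    @property
    def saturation(self) -> float:
        """Euclidean distance to the achromatic centre at the origin."""
        return float(np.sqrt(self.x**2 + self.y**2 + self.z**2))

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class HuePair:
    """The two channel-sum hue ratios H1 = (LW+MW)/(UV+SW) and
    H2 = (UV+LW)/(MW+SW)."""

    h1: float
    h2: float


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the synthetic generators so downstream
    estimates can be checked against what was simulated."""

    seed: int
    species_labels: list[str] = field(default_factory=list)
    species_means: dict[str, np.ndarray] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def load_sensor_config(name: str = "bluetit_like") -> dict:
    """Load a shipped sensor-constant file (peaks, widths, abundances,
    Weber fraction) by stem name."""
    with resources.files("aposematrix.data").joinpath(f"{name}.json").open() as fh:
        return json.load(fh)
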