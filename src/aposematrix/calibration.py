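"""Camera-to-cone-catch image calibration.

Raw multichannel images are linearized (single-gamma model), normalized
to reflectance against the grey standards photographed in frame (one
standard gives a per-channel scale, a pair gives an affine map), mapped
to predicted cone-catch images with a polynomial regression trained on
a library of reflectance spectra, and measured per region with glossy
(specular) pixels excluded by a luminance-percentile rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import PolynomialFeatures

from . import visual
from .types import (
    ConeCatch,
    SensorSet,
    SpectralCurve,
    ValidationError,
)

__all__ = [
    "CalibrationModel",
    "RegionMeasurement",
    "FittingError",
    "linearize",
    "normalize_reflectance",
    "fit_cone_mapping",
    "map_to_cone_image",
    "measure_region",
]

#: Floor applied to predicted cone catches so the downstream log-form
#: discrimination model stays defined.
CATCH_FLOOR = 1e-6


class FittingError(RuntimeError):
    """Raised when the polynomial mapping cannot be fitted."""


@dataclass(frozen=True)
class CalibrationModel:
    """Polynomial map from camera-channel reflectances to cone catches."""

    camera_channels: tuple[str, ...]
    receptor_channels: tuple[str, ...]
    degree: int
    coefficients: np.ndarray  # (n_receptors, n_poly_features)
    r_squared: dict[str, float]
    powers: np.ndarray  # (n_poly_features, n_camera_channels)

    def design(self, responses: np.ndarray) -> np.ndarray:
        """Polynomial feature expansion of camera responses (..., n_cam)."""
        flat = np.asarray(responses, float).reshape(-1, len(self.camera_channels))
        feats = np.prod(flat[:, None, :] ** self.powers[None, :, :], axis=2)
        return feats

    def predict(self, responses: np.ndarray) -> np.ndarray:
        """Predicted catches, shape (..., n_receptors)."""
        responses = np.asarray(responses, float)
        out = self.design(responses) @ self.coefficients.T
        return out.reshape(responses.shape[:-1] + (len(self.receptor_channels),))


@dataclass(frozen=True)
class RegionMeasurement:
    """Mean cone catch over a region after specular exclusion."""

    catch: ConeCatch
    n_used: int
    n_excluded: int


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, float)
    if img.ndim != 3:
        raise ValidationError("expected an (H, W, channels) image")
    return img


def linearize(raw_image: np.ndarray, gamma: float) -> np.ndarray:
    """Undo the camera transfer curve: ``linear = raw ** gamma``."""
    if gamma <= 0:
        raise ValidationError("gamma must be positive")
    raw = _check_image(raw_image)
    if raw.min() < 0 or raw.max() > 1:
        raise ValidationError("raw values must lie in [0, 1]")
    return raw**gamma


def normalize_reflectance(
    linear_image: np.ndarray,
    standard_masks: list[np.ndarray],
    standard_reflectances: list[float],
) -> np.ndarray:
    """Convert a linear image to reflectance using in-frame standards.

    One standard: per-channel scaling so the standard's mean pixel maps
    to its known reflectance.  Two standards: per-channel affine map
    through both (mean pixel, reflectance) points, which also removes
    any additive offset (stray light, sensor black level).
    """
    img = _check_image(linear_image)
    if len(standard_masks) != len(standard_reflectances) or not standard_masks:
        raise ValidationError("need 1 or 2 standards with matching masks")
    if len(standard_masks) > 2:
        raise ValidationError("at most two standards are supported")
    means = []
    for mask in standard_masks:
        if not mask.any():
            raise ValidationError("empty standard mask")
        means.append(img[mask].mean(axis=0))
    if len(means) == 1:
        m = means[0]
        if np.any(m <= 0):
            raise ValidationError("standard region mean must be positive")
        return img * (standard_reflectances[0] / m)
    m1, m2 = means
    r1, r2 = standard_reflectances
    if np.any(np.abs(m2 - m1) < 1e-12):
        raise ValidationError(
            "degenerate calibration: the two standards have equal mean pixel values"
        )
    slope = (r2 - r1) / (m2 - m1)
    return (img - m1) * slope + r1


def fit_cone_mapping(
    camera: SensorSet,
    receptors: SensorSet,
    spectra: list[SpectralCurve],
    illuminant: SpectralCurve,
    degree: int = 2,
) -> CalibrationModel:
    """Fit the polynomial camera-to-cone-catch mapping.

    For each training spectrum the camera responses and the true cone
    catches are computed by integration; each receptor channel is then
    regressed on a polynomial expansion (with cross terms for degree
    >= 2) of the camera responses by ordinary least squares.
    """
    if degree not in (1, 2, 3):
        raise ValidationError("degree must be 1, 2 or 3")
    if len(spectra) < 20:
        raise FittingError(
            f"need at least 20 training spectra, got {len(spectra)}"
        )
    cam_resp = np.array(
        [visual.catches_from_spectrum(s, camera, illuminant) for s in spectra]
    )
    true_catch = np.array(
        [visual.catches_from_spectrum(s, receptors, illuminant) for s in spectra]
    )
    poly = PolynomialFeatures(degree=degree, include_bias=True)
    design = poly.fit_transform(cam_resp)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FittingError(
            "rank-deficient polynomial design; cannot fit any receptor channel "
            f"({', '.join(receptors.names)})"
        )
    coefs = np.empty((len(receptors.names), design.shape[1]))
    r2 = {}
    for i, name in enumerate(receptors.names):
        y = true_catch[:, i]
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        coefs[i] = beta
        resid = y - design @ beta
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            raise FittingError(f"constant true catches for channel {name}")
        r2[name] = 1.0 - float((resid**2).sum()) / ss_tot
    return CalibrationModel(
        camera_channels=camera.names,
        receptor_channels=receptors.names,
        degree=degree,
        coefficients=coefs,
        r_squared=r2,
        powers=poly.powers_,
    )


def map_to_cone_image(
    reflectance_image: np.ndarray,
    model: CalibrationModel,
    floor: float = CATCH_FLOOR,
) -> np.ndarray:
    """Evaluate the calibration polynomial per pixel, flooring negative
    predictions at ``floor`` so every catch stays strictly positive."""
    img = _check_image(reflectance_image)
    if img.shape[-1] != len(model.camera_channels):
        raise ValidationError(
            f"image has {img.shape[-1]} channels but the model expects "
            f"{len(model.camera_channels)} ({', '.join(model.camera_channels)})"
        )
    pred = model.predict(img)
    return np.maximum(pred, floor)


def measure_region(
    cone_image: np.ndarray,
    mask: np.ndarray,
    specular_percentile: float = 99.0,
    luminance_channel: int = -1,
) -> RegionMeasurement:
    """Mean cone catch over a masked region, excluding specular pixels.

    Pixels whose double-cone (luminance) value exceeds the region's
    ``specular_percentile`` are discarded before averaging, emulating
    the rule of measuring only areas without specular reflectance.
    """
    img = _check_image(cone_image)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValidationError("empty region mask")
    if not 50.0 < specular_percentile <= 100.0:
        raise ValidationError("specular percentile must lie in (50, 100]")
    pixels = img[mask]
    lum = pixels[:, luminance_channel]
    keep = lum <= np.percentile(lum, specular_percentile)
    if not keep.any():
        raise ValidationError("all pixels excluded as specular")
    mean = pixels[keep].mean(axis=0)
    return RegionMeasurement(
        catch=ConeCatch.from_array(np.maximum(mean, CATCH_FLOOR)),
        n_used=int(keep.sum()),
        n_excluded=int((~keep).sum()),
    )
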