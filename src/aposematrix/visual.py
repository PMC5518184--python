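"""Avian visual modelling: cone-catch integration, tetrahedral colour
space, hue ratios, and the log-form receptor-noise-limited (RNL)
discrimination model.

The discrimination model follows the standard tetrachromatic
receptor-noise formulation: contrasts are log catch ratios
``Delta f_i = ln(q_i^a / q_i^b)`` and the perceptual distance (in
just-noticeable differences, JND) combines them weighted by the
noise-to-signal ratio ``omega_i`` of each receptor class.  Because the
model works on log ratios, a uniform intensity change of either
stimulus leaves the chromatic distance unchanged; chromatic and
achromatic (double-cone) distances are computed separately.
"""

from __future__ import annotations

import numpy as np

from .types import (
    CONE_CHANNELS,
    ConeCatch,
    HuePair,
    NoiseVector,
    SensorSet,
    SpectralCurve,
    TetraPoint,
    ValidationError,
)

__all__ = [
    "integrate_cone_catch",
    "catches_from_spectrum",
    "noise_ratios",
    "chromatic_jnd",
    "achromatic_jnd",
    "internal_contrast",
    "tetra_point",
    "tetra_vertices",
    "hue_ratios",
    "pca_channel_loadings",
]


def integrate_cone_catch(
    reflectance: SpectralCurve,
    sensitivity: SpectralCurve,
    illuminant: SpectralCurve,
) -> float:
    """Quantum catch of one receptor for a reflecting surface.

    Trapezoidal integral of R(lambda) I(lambda) S(lambda), von-Kries
    normalized by the catch of a perfect (R == 1) reflector, so the
    white point yields exactly 1 in every channel.
    """
    if not (reflectance.same_grid(sensitivity) and reflectance.same_grid(illuminant)):
        raise ValidationError("reflectance, sensitivity and illuminant must share one grid")
    wl = reflectance.wavelengths
    num = np.trapezoid(reflectance.values * illuminant.values * sensitivity.values, wl)
    den = np.trapezoid(illuminant.values * sensitivity.values, wl)
    if den <= 0:
        raise ValidationError("illuminant x sensitivity integrates to zero")
    return float(num / den)


def catches_from_spectrum(
    reflectance: SpectralCurve, receptors: SensorSet, illuminant: SpectralCurve
) -> np.ndarray:
    """Catches for every channel of a sensor set, in the set's order."""
    return np.array(
        [integrate_cone_catch(reflectance, s, illuminant) for s in receptors.sensitivities]
    )


def noise_ratios(receptors: SensorSet) -> NoiseVector:
    """Noise-to-signal ratio per receptor class.

    ``omega_i = nu / sqrt(eta_i)`` with relative abundances ``eta``
    rescaled so the most abundant class has ``eta = 1`` and therefore
    ``omega = nu`` (the Weber fraction, 0.05 by default) exactly.
    """
    if receptors.abundances is None or receptors.weber_fraction is None:
        raise ValidationError("receptor set must carry abundances and a Weber fraction")
    eta = receptors.abundances / receptors.abundances.max()
    omega_all = receptors.weber_fraction / np.sqrt(eta)
    chrom_idx = [receptors.index(c) for c in CONE_CHANNELS]
    if "D" in receptors.names:
        omega_d = float(omega_all[receptors.index("D")])
    else:
        omega_d = float(receptors.weber_fraction)
    return NoiseVector(omega=omega_all[chrom_idx], omega_d=omega_d)


def _chromatic_arrays(a, b) -> tuple[np.ndarray, np.ndarray]:
    qa = a.chromatic() if isinstance(a, ConeCatch) else np.asarray(a, dtype=float)
    qb = b.chromatic() if isinstance(b, ConeCatch) else np.asarray(b, dtype=float)
    if qa.shape[-1] != 4 or qb.shape[-1] != 4:
        raise ValidationError("chromatic catches must have four channels (UV, SW, MW, LW)")
    if np.any(qa <= 0) or np.any(qb <= 0):
        raise ValidationError("cone catches must be strictly positive")
    return qa, qb


def chromatic_jnd(a, b, noise: NoiseVector) -> float | np.ndarray:
    """Chromatic RNL distance Delta S between two stimuli, in JND.

    Uses the closed-form tetrachromatic expression whose numerator sums
    ``(w_j w_k)^2 (df_l - df_m)^2`` over the six channel pairs and whose
    denominator sums ``(w_j w_k w_l)^2`` over the four channel triples.
    Accepts ``ConeCatch`` objects or arrays of shape (..., 4); broadcasts
    over leading dimensions.
    """
    qa, qb = _chromatic_arrays(a, b)
    df = np.log(qa) - np.log(qb)
    w = noise.omega
    f = [df[..., i] for i in range(4)]
    w1, w2, w3, w4 = w
    num = (
        (w1 * w2) ** 2 * (f[3] - f[2]) ** 2
        + (w1 * w3) ** 2 * (f[3] - f[1]) ** 2
        + (w1 * w4) ** 2 * (f[2] - f[1]) ** 2
        + (w2 * w3) ** 2 * (f[3] - f[0]) ** 2
        + (w2 * w4) ** 2 * (f[2] - f[0]) ** 2
        + (w3 * w4) ** 2 * (f[1] - f[0]) ** 2
    )
    den = (
        (w1 * w2 * w3) ** 2
        + (w1 * w2 * w4) ** 2
        + (w1 * w3 * w4) ** 2
        + (w2 * w3 * w4) ** 2
    )
    ds = np.sqrt(num / den)
    return float(ds) if ds.ndim == 0 else ds


def achromatic_jnd(a_d, b_d, omega_d: float) -> float | np.ndarray:
    """Achromatic (double cone) RNL distance |ln(a/b)| / omega_D."""
    a_d = np.asarray(a_d, dtype=float)
    b_d = np.asarray(b_d, dtype=float)
    if np.any(a_d <= 0) or np.any(b_d <= 0):
        raise ValidationError("double-cone catches must be strictly positive")
    if omega_d <= 0:
        raise ValidationError("omega_D must be positive")
    ds = np.abs(np.log(a_d) - np.log(b_d)) / omega_d
    return float(ds) if ds.ndim == 0 else ds


def internal_contrast(spot: ConeCatch, elytra: ConeCatch, omega_d: float) -> float:
    """Luminance contrast of the pattern spot against the elytra field."""
    return achromatic_jnd(spot.q_d, elytra.q_d, omega_d)


#: Circumradius of the colour tetrahedron: a pure single-channel colour
#: sits at distance 0.75 from the achromatic centre.
TETRA_RADIUS = 0.75


def tetra_vertices() -> np.ndarray:
    """Vertices of the regular colour tetrahedron, rows in (UV, SW, MW,
    LW) order.  UV points along +Z; the other three channels sit on a
    circle below the centre.  All vertices are at distance 0.75 from the
    origin (the achromatic centre), and the orientation is a pure
    convention -- saturation does not depend on it.
    """
    r = TETRA_RADIUS
    rho = r * 2.0 * np.sqrt(2.0) / 3.0  # radius of the lower circle
    z_low = -r / 3.0
    angles = np.array([np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3])
    lower = np.stack(
        [rho * np.cos(angles), rho * np.sin(angles), np.full(3, z_low)], axis=1
    )
    return np.vstack([[0.0, 0.0, r], lower])


_VERTICES = tetra_vertices()


def tetra_point(c) -> TetraPoint:
    """Map a catch to tetrahedral colour space via its channel
    proportions; equal proportions land on the achromatic origin."""
    q = c.chromatic() if isinstance(c, ConeCatch) else np.asarray(c, dtype=float)
    if q.shape != (4,):
        raise ValidationError("expected four chromatic catches")
    total = q.sum()
    if total <= 0:
        raise ValidationError("total catch must be positive")
    p = q / total
    xyz = p @ _VERTICES
    return TetraPoint(*map(float, xyz))


def hue_ratios(c) -> HuePair:
    """Channel-sum hue ratios computed on raw catches.

    H1 = (LW + MW) / (UV + SW); H2 = (UV + LW) / (MW + SW).  Both are
    invariant to uniform scaling of the catch vector.
    """
    q = c.chromatic() if isinstance(c, ConeCatch) else np.asarray(c, dtype=float)
    uv, sw, mw, lw = q
    if uv + sw <= 0 or mw + sw <= 0:
        raise ValidationError("hue denominators must be positive")
    return HuePair(h1=float((lw + mw) / (uv + sw)), h2=float((uv + lw) / (mw + sw)))


def attribute_table(specimens, noise: NoiseVector):
    """Per-specimen colour attribute table from a catch table.

    Expects ``elytra_qUV..qD`` and ``spot_qUV..qD`` columns and returns
    the specimen metadata plus elytra H1/H2 and saturation, spot H1,
    saturation and luminance (double-cone catch), and the achromatic
    internal contrast of spot against elytra in JND.
    """
    import pandas as pd

    el = specimens.loc[:, [f"elytra_q{c}" for c in ("UV", "SW", "MW", "LW")]].to_numpy()
    sp = specimens.loc[:, [f"spot_q{c}" for c in ("UV", "SW", "MW", "LW")]].to_numpy()
    el_d = specimens["elytra_qD"].to_numpy()
    sp_d = specimens["spot_qD"].to_numpy()
    if np.any(el <= 0) or np.any(sp <= 0):
        raise ValidationError("catch columns must be strictly positive")
    verts = tetra_vertices()

    def sat(q):
        p = q / q.sum(axis=1, keepdims=True)
        return np.linalg.norm(p @ verts, axis=1)

    out = pd.DataFrame(
        {
            "elytra_h1": (el[:, 3] + el[:, 2]) / (el[:, 0] + el[:, 1]),
            "elytra_h2": (el[:, 0] + el[:, 3]) / (el[:, 2] + el[:, 1]),
            "elytra_saturation": sat(el),
            "spot_luminance": sp_d,
            "spot_saturation": sat(sp),
            "spot_h1": (sp[:, 3] + sp[:, 2]) / (sp[:, 0] + sp[:, 1]),
            "internal_contrast": achromatic_jnd(sp_d, el_d, noise.omega_d),
        }
    )
    meta_cols = [
        c
        for c in ("specimen_id", "species", "habitat_use", "melanic", "site", "body_length_mm")
        if c in specimens.columns
    ]
    out = pd.concat([specimens.loc[:, meta_cols].reset_index(drop=True), out], axis=1)
    if "spot_area_fraction" in specimens.columns:
        out["spot_area_pct"] = 100.0 * specimens["spot_area_fraction"].to_numpy()
    return out


def pca_channel_loadings(catches: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the standardized per-channel catches.

    This is the diagnostic used to motivate opponent-style hue ratios:
    an eigendecomposition of the covariance of z-scored channel catches
    across individuals.  Returns (loadings, variance_explained_percent)
    with components in columns, sorted by decreasing variance.  Hue
    values themselves always use the fixed printed ratios.
    """
    x = np.asarray(catches, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValidationError("need a 2-D table with at least three rows")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValidationError("constant channel column; cannot standardize")
    z = (x - x.mean(axis=0)) / sd
    cov = np.cov(z, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    var_pct = 100.0 * evals / evals.sum()
    return evecs, var_pct
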