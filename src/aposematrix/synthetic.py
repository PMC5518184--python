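"""Synthetic study generators.

The photographs behind the original ladybird study are not publicly
deposited, so this module generates every input the pipeline needs with
known ground truth: smooth reflectance spectra, Gaussian receptor and
camera sensitivity banks, multispectral specimen images with grey
standards and specular highlights, clustered specimen populations
(16 colour forms x 20 individuals by default), green/brown/own-site
background samples in cone-catch space, and Brownian-motion traits on
simulated Yule trees.

Two population generators cover the two analysis arms:

* :func:`gen_specimen_population` draws per-species attribute clusters
  for the discriminant "uniqueness" arm, with a tunable ratio of
  between-species mean spread to within-species SD.
* :func:`gen_conspicuousness_study` builds the background-contrast arm:
  species elytra colours are placed, in log-catch space, equidistant
  (in the receptor-noise metric) from the average green and average
  brown backgrounds, and each species' own-site background can be
  pushed further from its elytra colour by a habitat-dependent factor,
  emulating local tuning of conspicuousness in habitat specialists.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy.special import expit

from .types import (
    CATCH_COLUMNS,
    CONE_CHANNELS,
    DEFAULT_WAVELENGTHS,
    NoiseVector,
    SensorSet,
    SpectralCurve,
    SyntheticTruth,
    ValidationError,
    load_sensor_config,
)
from . import visual

__all__ = [
    "gen_spectra",
    "gen_sensor_sets",
    "default_sensor_sets",
    "d65_like_illuminant",
    "gen_specimen_population",
    "gen_background_set",
    "gen_conspicuousness_study",
    "render_specimen_image",
    "gen_tree_traits",
    "simulate_contrast_response",
    "RenderedImage",
    "ConspicuousnessStudy",
    "BACKGROUND_TEMPLATES",
]


# ---------------------------------------------------------------------------
# Spectra and sensors
# ---------------------------------------------------------------------------

def d65_like_illuminant(wavelengths: np.ndarray | None = None) -> SpectralCurve:
    """A smooth daylight-like illuminant (6500 K Planck radiator,
    peak-normalized).  Broad and UV-containing, standing in for the
    arc-lamp/daylight spectra used in calibrated UV photography."""
    wl = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)
    lam_m = wl * 1e-9
    c2 = 1.4388e-2  # m K
    b = lam_m**-5 / np.expm1(c2 / (lam_m * 6500.0))
    return SpectralCurve(wl, b / b.max())


def gen_spectra(
    n: int,
    smoothness: float = 140.0,
    seed: int = 0,
    *,
    mean: float = -1.2,
    amplitude: float = 0.8,
    wavelengths: np.ndarray | None = None,
) -> list[SpectralCurve]:
    """Draw ``n`` smooth, strictly positive reflectance spectra.

    Spectra are logistic-transformed Gaussian-process draws with a
    squared-exponential kernel (length scale ``smoothness`` in nm,
    default 140: natural reflectances are broadband, well described by
    a handful of smooth basis functions).  The logistic link keeps
    every reflectance strictly inside (0, 1), as physical reflectances
    are; the defaults put typical reflectance between roughly 0.05 and
    0.65 with a median near 0.25.
    """
    if n < 1:
        raise ValidationError("n must be at least 1")
    if smoothness <= 0:
        raise ValidationError("smoothness (length scale) must be positive")
    wl = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)
    rng = np.random.default_rng(seed)
    d2 = (wl[:, None] - wl[None, :]) ** 2
    cov = amplitude**2 * np.exp(-0.5 * d2 / smoothness**2)
    cov[np.diag_indices_from(cov)] += 1e-10
    chol = np.linalg.cholesky(cov)
    draws = mean + rng.standard_normal((n, wl.size)) @ chol.T
    values = expit(draws)
    return [SpectralCurve(wl, v) for v in values]


def _gaussian_bank(
    names: tuple[str, ...],
    peaks: np.ndarray,
    widths: np.ndarray,
    wavelengths: np.ndarray,
) -> tuple[SpectralCurve, ...]:
    if np.any(peaks < wavelengths[0]) or np.any(peaks > wavelengths[-1]):
        raise ValidationError("sensitivity peaks must lie inside the wavelength grid")
    curves = []
    for peak, width in zip(peaks, widths):
        v = np.exp(-0.5 * ((wavelengths - peak) / width) ** 2)
        area = np.trapezoid(v, wavelengths)
        curves.append(SpectralCurve(wavelengths, v / area))
    return tuple(curves)


def gen_sensor_sets(
    receptor_peaks: dict[str, float] | None = None,
    camera_peaks: dict[str, float] | None = None,
    receptor_widths: dict[str, float] | None = None,
    camera_widths: dict[str, float] | None = None,
    abundances: dict[str, float] | None = None,
    weber: float | None = None,
    wavelengths: np.ndarray | None = None,
) -> tuple[SensorSet, SensorSet]:
    """Build (receptor, camera) sensor sets of unit-area Gaussians.

    Defaults come from the shipped "blue-tit-like" constants file: four
    single cones (UV, SW, MW, LW) plus the double cone D, and a
    six-channel UV-converted-camera-like bank.  Receptor abundances and
    the Weber fraction are attached to the receptor set.
    """
    cfg = load_sensor_config()
    wl = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)
    rp = {k: v["peak"] for k, v in cfg["receptors"].items()} | (receptor_peaks or {})
    rw = {k: v["width"] for k, v in cfg["receptors"].items()} | (receptor_widths or {})
    cp = {k: v["peak"] for k, v in cfg["camera"].items()} | (camera_peaks or {})
    cw = {k: v["width"] for k, v in cfg["camera"].items()} | (camera_widths or {})
    ab = dict(cfg["abundances"]) | (abundances or {})
    nu = cfg["weber_fraction"] if weber is None else weber
    rnames = tuple(rp)
    if len(rnames) != 5:
        raise ValidationError("receptor set needs four single cones plus the double cone")
    if len(cp) < 4:
        raise ValidationError("camera needs at least four channels")
    receptors = SensorSet(
        names=rnames,
        sensitivities=_gaussian_bank(
            rnames, np.array([rp[c] for c in rnames]), np.array([rw[c] for c in rnames]), wl
        ),
        abundances=np.array([ab[c] for c in rnames]),
        weber_fraction=float(nu),
    )
    cnames = tuple(cp)
    camera = SensorSet(
        names=cnames,
        sensitivities=_gaussian_bank(
            cnames, np.array([cp[c] for c in cnames]), np.array([cw[c] for c in cnames]), wl
        ),
    )
    return receptors, camera


def default_sensor_sets() -> tuple[SensorSet, SensorSet]:
    """The shipped blue-tit-like receptors and six-channel camera."""
    return gen_sensor_sets()


# ---------------------------------------------------------------------------
# Specimen population for the uniqueness (discriminant) arm
# ---------------------------------------------------------------------------

#: Attribute dimensions generated per specimen, in log / transformed space.
_POP_DIMS = (
    "ln_elytra_qUV", "ln_elytra_qSW", "ln_elytra_qMW", "ln_elytra_qLW", "ln_elytra_qD",
    "ln_spot_qUV", "ln_spot_qSW", "ln_spot_qMW", "ln_spot_qLW", "ln_spot_qD",
    "ln_body_length", "logit_spot_frac",
)

_POP_CENTER = np.array(
    [np.log(0.10), np.log(0.15), np.log(0.25), np.log(0.35), np.log(0.30),
     np.log(0.06), np.log(0.08), np.log(0.12), np.log(0.15), np.log(0.12),
     np.log(5.0), -1.0]
)

_POP_WITHIN_SD = np.array(
    [0.08, 0.08, 0.08, 0.08, 0.08,
     0.08, 0.08, 0.08, 0.08, 0.08,
     0.06, 0.25]
)


def gen_specimen_population(
    k_species: int = 16,
    n_per_species: int = 20,
    separation: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a clustered specimen population for the discriminant arm.

    Species means are multivariate normal around a common centre with SD
    ``separation`` times the within-species SD, per attribute dimension;
    individuals are normal around their species mean.  ``separation=0``
    gives identically distributed classes (the chance-level reference).
    Habitat-use labels, melanic flags and collection sites are attached
    as metadata at roughly the proportions of the original survey
    (7 of 16 colour forms generalist; 2 of 16 melanic).
    """
    if k_species < 2 or n_per_species < 2:
        raise ValidationError("need at least 2 species and 2 individuals per species")
    if separation < 0:
        raise ValidationError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    d = len(_POP_DIMS)
    species = [f"sp{i+1:02d}" for i in range(k_species)]
    means = _POP_CENTER + separation * _POP_WITHIN_SD * rng.standard_normal((k_species, d))
    n_gen = int(round(k_species * 7 / 16))
    n_mel = max(1, int(round(k_species * 2 / 16)))
    rows = []
    truth = SyntheticTruth(seed=seed, species_labels=species)
    for i, sp in enumerate(species):
        truth.species_means[sp] = means[i]
        x = means[i] + _POP_WITHIN_SD * rng.standard_normal((n_per_species, d))
        for j in range(n_per_species):
            v = dict(zip(_POP_DIMS, x[j]))
            spot_frac = 1.0 / (1.0 + np.exp(-v["logit_spot_frac"]))
            rows.append(
                {
                    "specimen_id": f"{sp}_{j+1:03d}",
                    "species": sp,
                    "habitat_use": "generalist" if i < n_gen else "specialist",
                    "melanic": i >= k_species - n_mel,
                    "site": f"site{i+1:02d}",
                    "body_length_mm": float(np.exp(v["ln_body_length"])),
                    "spot_area_fraction": float(spot_frac),
                    **{
                        f"elytra_{c}": float(np.exp(v[f"ln_elytra_{c}"]))
                        for c in CATCH_COLUMNS
                    },
                    **{
                        f"spot_{c}": float(np.exp(v[f"ln_spot_{c}"]))
                        for c in CATCH_COLUMNS
                    },
                }
            )
    truth.extras["separation"] = separation
    truth.extras["within_sd"] = _POP_WITHIN_SD
    truth.extras["dims"] = _POP_DIMS
    truth.extras["true_means"] = means
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Backgrounds
# ---------------------------------------------------------------------------

#: Mean cone catches of the background classes: green foliage is
#: MW-dominant, brown substrate LW-dominant.
BACKGROUND_TEMPLATES = {
    "green": np.array([0.06, 0.12, 0.35, 0.14, 0.28]),
    "brown": np.array([0.05, 0.10, 0.18, 0.35, 0.30]),
    "own-site": np.array([0.055, 0.11, 0.26, 0.24, 0.29]),
}


def gen_background_set(
    kind: str, n: int = 10, seed: int = 0, *, jitter_sd: float = 0.12
) -> pd.DataFrame:
    """Draw ``n`` background samples of one class as lognormal jitter
    around the class's catch template."""
    if kind not in BACKGROUND_TEMPLATES:
        raise ValidationError(f"unknown background kind {kind!r}")
    if n < 1:
        raise ValidationError("n must be at least 1")
    rng = np.random.default_rng(seed)
    base = np.log(BACKGROUND_TEMPLATES[kind])
    draws = np.exp(base + jitter_sd * rng.standard_normal((n, 5)))
    df = pd.DataFrame(draws, columns=list(CATCH_COLUMNS))
    df.insert(0, "kind", kind)
    df.insert(0, "sample_id", [f"{kind}_{i+1:02d}" for i in range(n)])
    return df


# ---------------------------------------------------------------------------
# Conspicuousness study (contrast arm)
# ---------------------------------------------------------------------------

@dataclass
class ConspicuousnessStudy:
    """Inputs for the background-contrast arm with known ground truth."""

    specimens: pd.DataFrame
    site_backgrounds: pd.DataFrame
    green_samples: pd.DataFrame
    brown_samples: pd.DataFrame
    truth: SyntheticTruth


def _rnl_precision(noise: NoiseVector) -> np.ndarray:
    """Quadratic form A with Delta S^2 = df' A df: inverse-noise weights
    with the achromatic (all-equal) direction projected out."""
    w = 1.0 / noise.omega**2
    W = np.diag(w)
    return W - np.outer(w, w) / w.sum()


def _rnl_isotropic(A: np.ndarray, sd: float, rng: np.random.Generator,
                   size: int = 1) -> np.ndarray:
    """Chromatic log-catch jitter that is isotropic in the
    receptor-noise metric: covariance sd^2 * pseudo-inverse(A), so a
    draw perturbs any chromatic direction by sd JND on average and
    carries no achromatic component."""
    evals, evecs = np.linalg.eigh(A)
    keep = evals > 1e-9 * evals.max()
    half_inv = evecs[:, keep] / np.sqrt(evals[keep])
    out = sd * rng.standard_normal((size, keep.sum())) @ half_inv.T
    return out


def gen_conspicuousness_study(
    k_species: int = 16,
    n_per_species: int = 20,
    target_jnd: float = 25.0,
    specialist_own_boost: float = 1.65,
    generalist_own_boost: float = 1.0,
    n_background_samples: int = 10,
    seed: int = 0,
    *,
    noise: NoiseVector | None = None,
    indiv_jnd_sd: float = 2.0,
    bg_sample_jnd_sd: float = 0.5,
    species_log_jnd_sd: float = 0.15,
    brightness_sd: float = 0.03,
) -> ConspicuousnessStudy:
    """Simulate the contrast experiment: specimens, their own-site
    backgrounds, and shared green/brown background samples.

    Species elytra log-catches are placed on the surface equidistant (in
    the receptor-noise metric) from the green and the brown template, at
    a species-specific distance around ``target_jnd``, so green-vs-brown
    contrast is null by construction.  Each species' own-site background
    starts from its habitat template (green or brown) and is moved away
    from the species' elytra colour, along the log-catch line joining
    them, by the habitat-dependent ``own_boost`` factor: a boost of 1
    leaves the own background at the template (no tuning), the default
    specialist boost of 1.65 raises own-background contrast by about 0.5
    natural-log units -- emulating specialists whose signal is tuned
    against their own substrate.  Individual and background-sample
    chromatic jitter is isotropic in the receptor-noise metric (scaled
    in JND units), which keeps the green/brown null free of
    direction-dependent curvature bias; brightness jitter is separate
    and cancels from chromatic contrasts.  Melanic species get dark
    elytra and are analysed achromatically downstream.
    """
    if k_species < 2 or n_per_species < 1:
        raise ValidationError("need at least 2 species and 1 individual per species")
    if specialist_own_boost < 0 or generalist_own_boost < 0:
        raise ValidationError("own-background boosts must be non-negative")
    if noise is None:
        noise = visual.noise_ratios(default_sensor_sets()[0])
    rng = np.random.default_rng(seed)
    A = _rnl_precision(noise)
    ln_g = np.log(BACKGROUND_TEMPLATES["green"][:4])
    ln_b = np.log(BACKGROUND_TEMPLATES["brown"][:4])
    mid, h = (ln_g + ln_b) / 2.0, (ln_g - ln_b) / 2.0
    h_norm2 = float(h @ A @ h)
    if target_jnd**2 <= h_norm2:
        raise ValidationError(
            "target_jnd too small: templates are farther apart than the target"
        )
    # basis of directions orthogonal (Euclidean) to both the achromatic
    # axis and A h: species placed there are equidistant from the green
    # and brown templates and share their mean brightness.
    constraints = np.stack([np.ones(4), A @ h])
    _, _, vt = np.linalg.svd(constraints)
    basis = vt[2:]  # (2, 4)

    species = [f"sp{i+1:02d}" for i in range(k_species)]
    n_gen = int(round(k_species * 7 / 16))
    n_mel = max(1, int(round(k_species * 2 / 16)))
    melanic_set = set(species[-n_mel:])
    truth = SyntheticTruth(seed=seed, species_labels=species)
    truth.extras.update(
        target_jnd=target_jnd,
        specialist_own_boost=specialist_own_boost,
        generalist_own_boost=generalist_own_boost,
    )

    spec_rows, site_rows = [], []
    qd_bg = {"green": BACKGROUND_TEMPLATES["green"][4], "brown": BACKGROUND_TEMPLATES["brown"][4]}

    def _draw_samples(ln_chrom: np.ndarray, qd_mean: float) -> np.ndarray:
        """Background samples whose arithmetic mean is calibrated to the
        class template exactly: the template is defined as the class's
        population-average cone catch, which is the quantity the
        analysis averages."""
        eps = _rnl_isotropic(A, bg_sample_jnd_sd, rng, n_background_samples)
        bright = brightness_sd * rng.standard_normal((n_background_samples, 1))
        chrom = np.exp(ln_chrom + eps + bright)
        qd = qd_mean * np.exp(0.05 * rng.standard_normal((n_background_samples, 1)))
        q = np.hstack([chrom, qd])
        return q * (np.append(np.exp(ln_chrom), qd_mean) / q.mean(axis=0))
    for i, sp in enumerate(species):
        habitat = "generalist" if i < n_gen else "specialist"
        base_kind = "green" if i % 2 == 0 else "brown"
        melanic = sp in melanic_set
        sp_target = target_jnd * np.exp(species_log_jnd_sd * rng.standard_normal())
        sp_target = max(sp_target, np.sqrt(h_norm2) * 1.05 + 0.5)
        d = np.sqrt(sp_target**2 - h_norm2)
        coeff = rng.standard_normal(2) @ basis
        coeff /= np.sqrt(coeff @ A @ coeff)
        ln_e = mid + d * coeff
        if melanic:
            ln_e = np.log(0.03) + 0.1 * rng.standard_normal(4)
        ln_qd = np.log(0.04 if melanic else 0.22) + 0.15 * rng.standard_normal()
        boost = specialist_own_boost if habitat == "specialist" else generalist_own_boost
        ln_base = ln_g if base_kind == "green" else ln_b
        ln_own = ln_e + boost * (ln_base - ln_e)
        site = f"site{i+1:02d}"
        truth.species_means[sp] = np.concatenate([ln_e, [ln_qd]])
        own_samples = _draw_samples(ln_own, qd_bg[base_kind])
        for s in range(n_background_samples):
            site_rows.append(
                {"site": site, "kind": "own", "sample_id": f"{site}_{s+1:02d}",
                 **dict(zip(CATCH_COLUMNS, own_samples[s]))}
            )
        ind_eps = _rnl_isotropic(A, indiv_jnd_sd, rng, n_per_species)
        for j in range(n_per_species):
            chrom = np.exp(ln_e + ind_eps[j] + brightness_sd * rng.standard_normal())
            qd = np.exp(ln_qd + 0.05 * rng.standard_normal())
            spec_rows.append(
                {
                    "specimen_id": f"{sp}_{j+1:03d}",
                    "species": sp,
                    "habitat_use": habitat,
                    "melanic": melanic,
                    "site": site,
                    **{f"elytra_{c}": float(v)
                       for c, v in zip(CATCH_COLUMNS, np.append(chrom, qd))},
                }
            )

    def _shared_samples(kind: str, ln_t: np.ndarray) -> pd.DataFrame:
        q = _draw_samples(ln_t, qd_bg[kind])
        rows = [
            {"sample_id": f"{kind}_{s+1:02d}", "kind": kind,
             **dict(zip(CATCH_COLUMNS, q[s]))}
            for s in range(n_background_samples)
        ]
        return pd.DataFrame(rows)

    return ConspicuousnessStudy(
        specimens=pd.DataFrame(spec_rows),
        site_backgrounds=pd.DataFrame(site_rows),
        green_samples=_shared_samples("green", ln_g),
        brown_samples=_shared_samples("brown", ln_b),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderedImage:
    """A synthetic multichannel photograph with region masks and truth."""

    image: np.ndarray  # (H, W, n_channels), raw values in [0, 1]
    channel_names: tuple[str, ...]
    masks: dict[str, np.ndarray]
    truth_linear: dict[str, np.ndarray]  # region -> per-channel linear value
    standards: tuple[float, ...]
    gamma: float


def render_specimen_image(
    elytra_spectrum: SpectralCurve,
    spot_spectrum: SpectralCurve,
    standards: list[float],
    camera: SensorSet,
    illuminant: SpectralCurve,
    gamma: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    specular_fraction: float = 0.0,
    specular_multiplier: float = 10.0,
    background_reflectance: float = 0.02,
) -> RenderedImage:
    """Render a specimen photograph: elytra patch with an inset spot,
    one flat grey patch per reflectance standard, and a dark backdrop.

    The camera response is reflectance-referenced (a perfect reflector
    reads 1.0 in every channel), passed through a single gamma
    (``raw = linear ** (1/gamma) + noise``) and clipped to [0, 1].  A
    ``specular_fraction`` of elytra/spot pixels is multiplied by
    ``specular_multiplier`` before the gamma, emulating glossy
    highlights that the measurement stage must exclude.
    """
    if gamma <= 0:
        raise ValidationError("gamma must be positive")
    if not standards or any(not (0 < s <= 1) for s in standards):
        raise ValidationError("standards must be a non-empty list of reflectances in (0, 1]")
    if len(standards) > 3:
        raise ValidationError("at most three standard patches fit the layout")
    rng = np.random.default_rng(seed)
    H, W = 48, 64
    n_ch = len(camera.names)
    linear = np.full((H, W, n_ch), background_reflectance, dtype=float)

    def region_values(spectrum: SpectralCurve) -> np.ndarray:
        return visual.catches_from_spectrum(spectrum, camera, illuminant)

    elytra_vals = region_values(elytra_spectrum)
    spot_vals = region_values(spot_spectrum)
    elytra_rect = np.zeros((H, W), bool)
    elytra_rect[4:40, 4:40] = True
    spot_mask = np.zeros((H, W), bool)
    spot_mask[16:28, 16:28] = True
    elytra_mask = elytra_rect & ~spot_mask
    linear[elytra_mask] = elytra_vals
    linear[spot_mask] = spot_vals
    masks = {"elytra": elytra_mask, "spot": spot_mask}
    truth = {"elytra": elytra_vals, "spot": spot_vals}
    for i, refl in enumerate(standards):
        m = np.zeros((H, W), bool)
        m[4 + 14 * i : 14 + 14 * i, 46:62] = True
        linear[m] = refl
        masks[f"standard_{i}"] = m
        truth[f"standard_{i}"] = np.full(n_ch, refl)

    if specular_fraction > 0:
        body = elytra_mask | spot_mask
        idx = np.flatnonzero(body.ravel())
        n_spec = int(round(specular_fraction * idx.size))
        if n_spec:
            chosen = rng.choice(idx, size=n_spec, replace=False)
            flat = linear.reshape(-1, n_ch)
            flat[chosen] *= specular_multiplier
    raw = linear ** (1.0 / gamma)
    if noise_sd > 0:
        raw = raw + noise_sd * rng.standard_normal(raw.shape)
    raw = np.clip(raw, 0.0, 1.0)
    return RenderedImage(
        image=raw,
        channel_names=camera.names,
        masks=masks,
        truth_linear=truth,
        standards=tuple(standards),
        gamma=gamma,
    )


# ---------------------------------------------------------------------------
# Trees and traits
# ---------------------------------------------------------------------------

def gen_tree_traits(
    n_tips: int,
    lambda_true: float = 1.0,
    sigma2: float = 1.0,
    seed: int = 0,
    n_traits: int = 1,
) -> tuple[str, pd.DataFrame, SyntheticTruth]:
    """Simulate a unit-height Yule tree and traits with covariance
    ``sigma2 * C(lambda)``, where C holds shared root-to-tip branch
    lengths and off-diagonals are scaled by ``lambda_true``.

    Returns (newick, trait table indexed by tip label, truth).
    """
    if n_tips < 4:
        raise ValidationError("need at least 4 tips")
    if not 0.0 <= lambda_true <= 1.0:
        raise ValidationError("lambda must lie in [0, 1]")
    if sigma2 <= 0:
        raise ValidationError("sigma2 must be positive")
    sim_rng = _random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=sim_rng,
    )
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None:  # pragma: no cover - dendropy labels extant tips
            raise RuntimeError("unlabelled tip in simulated tree")
    # the simulator stops at a speciation event, leaving zero-length
    # pendant edges; extend every tip by one waiting time of the n-tip
    # pure-birth process so the tree stays ultrametric and C stays
    # positive definite
    extension = sim_rng.expovariate(1.0 * n_tips)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extension
    # unit total height
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()

    from .phylo import read_newick, lambda_cov  # local import avoids a cycle

    ptree = read_newick(newick)
    cov = sigma2 * lambda_cov(ptree.C, lambda_true)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n_tips))
    traits = chol @ rng.standard_normal((n_tips, n_traits))
    table = pd.DataFrame(
        traits, index=pd.Index(ptree.taxa, name="tip"),
        columns=[f"trait{i+1}" for i in range(n_traits)],
    )
    truth = SyntheticTruth(seed=seed)
    truth.extras.update(lambda_true=lambda_true, sigma2=sigma2, C=ptree.C)
    return newick, table, truth


# ---------------------------------------------------------------------------
# Direct response simulator for mixed-model calibration
# ---------------------------------------------------------------------------

def simulate_contrast_response(
    k_species: int = 16,
    n_per_species: int = 20,
    type_effects: dict[str, float] | None = None,
    habitat_type_effects: dict[tuple[str, str], float] | None = None,
    sigma_species: float = 0.3,
    sigma_indiv: float = 0.3,
    sigma_resid: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a log-contrast response table directly from the mixed
    model (species and individual random intercepts, background-type
    fixed effects), for calibrating the inference machinery at known
    truth.  ``type_effects`` maps background type to its fixed shift;
    ``habitat_type_effects`` maps (habitat, type) to an extra shift.
    """
    rng = np.random.default_rng(seed)
    types = ("brown", "green", "own")
    effects = {t: 0.0 for t in types} | (type_effects or {})
    hab_eff = habitat_type_effects or {}
    n_gen = int(round(k_species * 7 / 16))
    rows = []
    for i in range(k_species):
        sp = f"sp{i+1:02d}"
        habitat = "generalist" if i < n_gen else "specialist"
        b_sp = sigma_species * rng.standard_normal()
        for j in range(n_per_species):
            ind = f"{sp}_{j+1:03d}"
            b_ind = sigma_indiv * rng.standard_normal()
            for t in types:
                y = (
                    3.0
                    + effects[t]
                    + hab_eff.get((habitat, t), 0.0)
                    + b_sp
                    + b_ind
                    + sigma_resid * rng.standard_normal()
                )
                rows.append(
                    {
                        "specimen_id": ind,
                        "species": sp,
                        "habitat_use": habitat,
                        "bg_type": t,
                        "log_chromatic": y,
                    }
                )
    return pd.DataFrame(rows)
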