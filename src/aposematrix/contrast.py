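"""Conspicuousness against natural backgrounds.

Every specimen's elytra colour is contrasted, in receptor-noise JND
units, against three backgrounds: the average of its own collection
site's samples, an average green background and an average brown
background.  Chromatic JNDs are not computed for melanic (black)
specimens, whose low-reflectance colour measurements are noise
dominated; their achromatic contrast is retained.  Contrast is analysed
with linear mixed models (individual, and optionally species, random
intercepts) and pairwise post hoc comparisons of the background types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import visual
from .types import CATCH_COLUMNS, ConeCatch, NoiseVector, ValidationError

__all__ = [
    "classify_habitat",
    "average_background",
    "contrast_table",
    "fit_contrast_lmm",
    "MixedModelSummary",
]

#: Floor for chromatic JNDs before the natural-log transform.
JND_FLOOR = 1e-6

BACKGROUND_TYPES = ("brown", "green", "own")


def classify_habitat(substrate_count: int) -> str:
    """Generalist if found on more than three substrates/plants."""
    if substrate_count < 1:
        raise ValidationError("substrate count must be at least 1")
    return "generalist" if substrate_count > 3 else "specialist"


def average_background(samples: pd.DataFrame, kind: str | None = None) -> ConeCatch:
    """Arithmetic mean cone catch over background samples (optionally
    filtered to one kind)."""
    df = samples
    if kind is not None:
        df = df[df["kind"] == kind]
    if df.empty:
        raise ValidationError(f"no background samples{f' of kind {kind!r}' if kind else ''}")
    return ConeCatch.from_array(df.loc[:, list(CATCH_COLUMNS)].mean().to_numpy())


def contrast_table(
    specimens: pd.DataFrame,
    site_backgrounds: pd.DataFrame,
    green_avg: ConeCatch,
    brown_avg: ConeCatch,
    noise: NoiseVector,
) -> pd.DataFrame:
    """JND contrasts of every specimen against own/green/brown backgrounds.

    Three rows per specimen.  Chromatic JND (and its natural log,
    floored at 1e-6) is left missing for melanic specimens; achromatic
    (double cone) JND is always present.
    """
    required = {"specimen_id", "species", "site", "melanic"}
    missing = required - set(specimens.columns)
    if missing:
        raise ValidationError(f"specimen table lacks columns: {sorted(missing)}")
    own_means = (
        site_backgrounds.groupby("site")[list(CATCH_COLUMNS)].mean()
    )
    missing_sites = sorted(set(specimens["site"]) - set(own_means.index))
    if missing_sites:
        raise ValidationError(f"no own-background samples for sites: {missing_sites}")

    elytra = specimens.loc[:, [f"elytra_{c}" for c in CATCH_COLUMNS]].to_numpy()
    bg_values = {
        "own": own_means.loc[specimens["site"]].to_numpy(),
        "green": np.tile(green_avg.as_array(), (len(specimens), 1)),
        "brown": np.tile(brown_avg.as_array(), (len(specimens), 1)),
    }
    melanic = specimens["melanic"].to_numpy(dtype=bool)
    frames = []
    for bg_type in BACKGROUND_TYPES:
        bg = bg_values[bg_type]
        chrom = visual.chromatic_jnd(elytra[:, :4], bg[:, :4], noise)
        achro = visual.achromatic_jnd(elytra[:, 4], bg[:, 4], noise.omega_d)
        chrom = np.where(melanic, np.nan, chrom)
        frames.append(
            pd.DataFrame(
                {
                    "specimen_id": specimens["specimen_id"].to_numpy(),
                    "species": specimens["species"].to_numpy(),
                    "habitat_use": specimens.get(
                        "habitat_use", pd.Series(["unknown"] * len(specimens))
                    ).to_numpy(),
                    "melanic": melanic,
                    "bg_type": bg_type,
                    "chromatic_jnd": chrom,
                    "achromatic_jnd": achro,
                    "log_chromatic": np.log(np.maximum(chrom, JND_FLOOR)),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["specimen_id", "bg_type"], kind="stable").reset_index(drop=True)


@dataclass
class MixedModelSummary:
    """REML mixed-model fit with post hoc background-type contrasts."""

    formula: str
    fixed_effects: pd.DataFrame  # estimate, se, t, df, p
    random_variances: dict[str, float]
    loglik: float
    posthoc: pd.DataFrame  # group, pair, estimate, se, df, t, p, p_holm
    n_obs: int
    converged: bool = True
    notes: dict = field(default_factory=dict)


def _paired_contrast(
    df: pd.DataFrame, response: str, b1: str, b2: str
) -> dict:
    """Within-individual difference between two background types, with a
    species-cluster-robust standard error.

    Because every individual is measured once against each background,
    the pairwise background contrast is a paired design: the mean of the
    per-individual differences estimates the contrast, and clustering
    the variance at species level keeps the test calibrated even when
    the individual-level covariance across background types is not
    compound-symmetric (it generally is not, since different background
    directions project individual colour noise differently).
    """
    piv = df.pivot_table(
        index=["specimen_id", "species"], columns="bg_type", values=response
    )
    if b1 not in piv.columns or b2 not in piv.columns:
        raise ValidationError(f"missing background types for pair {b1} vs {b2}")
    d = (piv[b1] - piv[b2]).dropna()
    species = d.index.get_level_values("species")
    n = len(d)
    n_clusters = species.nunique()
    est = float(d.mean())
    resid = d - est
    cluster_sums = resid.groupby(species).sum()
    var = float((cluster_sums**2).sum()) / n**2
    if n_clusters > 1:
        var *= n_clusters / (n_clusters - 1)
    dof = max(n_clusters - 1, 1)
    if var == 0.0:
        t = 0.0 if est == 0.0 else np.inf * np.sign(est)
        p = 1.0 if est == 0.0 else 0.0
    else:
        t = est / np.sqrt(var)
        p = float(2 * stats.t.sf(abs(t), dof))
    return {
        "pair": f"{b1} vs {b2}",
        "estimate": est,
        "se": float(np.sqrt(var)),
        "df": dof,
        "t": float(t),
        "p": p,
        "n_pairs": n,
    }


def fit_contrast_lmm(
    table: pd.DataFrame,
    model: str = "species",
    response: str = "log_chromatic",
) -> MixedModelSummary:
    """Fit the contrast mixed model and pairwise post hoc comparisons.

    ``model='species'``: fixed species x background-type effects with a
    random intercept per individual; post hoc contrasts compare the
    three background types averaged over species.  ``model='habitat'``:
    fixed habitat-use x background-type effects with random intercepts
    for species and for individual (nested in species); post hoc
    contrasts compare background types within each habitat-use level.

    Post hoc inference uses within-individual paired differences with
    species-cluster-robust standard errors (t with clusters - 1 degrees
    of freedom); Holm-adjusted P-values are reported next to the raw
    ones.  Fixed effects from the REML fit are reported with
    large-sample t statistics.
    """
    if model not in ("species", "habitat"):
        raise ValidationError("model must be 'species' or 'habitat'")
    df = table.dropna(subset=[response]).copy()
    if df.empty:
        raise ValidationError(f"no usable rows for response {response!r}")
    for col in ("bg_type",) + (("habitat_use",) if model == "habitat" else ("species",)):
        if df[col].nunique() < 2:
            raise ValidationError(f"fixed factor {col!r} has fewer than two levels")

    if model == "species":
        formula = f"{response} ~ C(species) * C(bg_type)"
        md = smf.mixedlm(formula, df, groups=df["specimen_id"], re_formula="1")
    else:
        formula = f"{response} ~ C(habitat_use) * C(bg_type)"
        # individual codes recoded within species so the variance
        # component design stays small per group
        df["indiv_code"] = (
            df.groupby("species")["specimen_id"].transform(lambda s: pd.factorize(s)[0]).astype(str)
        )
        md = smf.mixedlm(
            formula,
            df,
            groups=df["species"],
            re_formula="1",
            vc_formula={"individual": "0 + C(indiv_code)"},
        )
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell", "cg"):
            try:
                fit = md.fit(reml=True, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(fit.fe_params).all() and np.isfinite(fit.bse_fe).all():
                break
    if fit is None or not (np.isfinite(fit.fe_params).all() and np.isfinite(fit.bse_fe).all()):
        raise ValidationError(
            "mixed model did not produce a usable fit; optimizer trace: "
            f"{getattr(fit, 'hist', None)}"
        )
    k_fe = md.k_fe
    fe = fit.fe_params
    df_resid = len(df) - k_fe
    fixed = pd.DataFrame(
        {
            "estimate": fe,
            "se": fit.bse_fe,
            "t": fe / fit.bse_fe,
            "df": df_resid,
            "p": 2 * stats.t.sf(np.abs(fe / fit.bse_fe), df_resid),
        }
    )

    rows = []
    groups = [None] if model == "species" else sorted(df["habitat_use"].unique())
    for group in groups:
        sub = df if group is None else df[df["habitat_use"] == group]
        for b1, b2 in combinations(sorted(df["bg_type"].unique()), 2):
            rec = _paired_contrast(sub, response, b1, b2)
            rows.append({"group": group if group is not None else "all", **rec})
    posthoc = pd.DataFrame(rows)
    posthoc["p_holm"] = multipletests(posthoc["p"], method="holm")[1]

    rand = {"group_var": float(np.asarray(fit.cov_re).ravel()[0]) if md.k_re else np.nan}
    if getattr(fit, "vcomp", None) is not None and len(fit.vcomp):
        rand["individual_var"] = float(fit.vcomp[0])
    rand["residual_var"] = float(fit.scale)
    return MixedModelSummary(
        formula=formula,
        fixed_effects=fixed,
        random_variances=rand,
        loglik=float(fit.llf),
        posthoc=posthoc,
        n_obs=len(df),
        converged=bool(fit.converged),
        notes={"model": model, "response": response, "reml": True},
    )
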