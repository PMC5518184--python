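"""End-to-end orchestration: simulate -> calibrate -> attributes ->
uniqueness -> contrast -> phylogenetic signal, from one configuration,
with a manifest recording seeds, inputs and output checksums."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, contrast, phylo, plots, synthetic, uniqueness, visual
from .types import ValidationError


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    All analysis stages run on synthetic inputs unless
    ``cone_catch_csv`` points at a user-supplied catch table, in which
    case the image-calibration stage is skipped and noted in the
    manifest.
    """

    seed: int = 0
    out_dir: str = "aposematrix_run"
    k_species: int = 16
    n_per_species: int = 20
    separation: float = 10.0
    mapping_degree: int = 2
    specular_percentile: float = 99.0
    standards: tuple[float, ...] = (0.4,)
    priors: str = "equal"
    n_tips: int = 16
    n_calibration_spectra: int = 200
    cone_catch_csv: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a flat ``key: value`` config file (YAML-style subset)."""
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition(":")
            key = key.strip()
            value = value.strip()
            if key not in cls.__dataclass_fields__:
                raise ValidationError(f"unknown config key {key!r}")
            kind = cls.__dataclass_fields__[key].type
            if key == "standards":
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif kind in ("int", int):
                kwargs[key] = int(value)
            elif kind in ("float", float):
                kwargs[key] = float(value)
            elif value.lower() in ("none", "null", ""):
                kwargs[key] = None
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest dictionary.

    Writes, under ``config.out_dir``: the simulated tables, the
    calibration report and cone-catch CSV, the attribute table, the
    uniqueness report (confusion matrix, per-class uniqueness,
    per-variable power), the contrast table with both mixed-model
    summaries, the phylogenetic-signal table, and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "checksums": {}}
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(2**31)) for name in
             ("population", "study", "spectra", "render", "tree")}
    manifest["seeds"] = seeds

    receptors, camera = synthetic.default_sensor_sets()
    illuminant = synthetic.d65_like_illuminant()
    noise = visual.noise_ratios(receptors)

    # --- stage 1: simulate -------------------------------------------------
    population, _ = synthetic.gen_specimen_population(
        config.k_species, config.n_per_species, config.separation, seeds["population"]
    )
    study = synthetic.gen_conspicuousness_study(
        config.k_species, config.n_per_species, seed=seeds["study"]
    )
    population.to_csv(out / "population.csv", index=False)
    study.specimens.to_csv(out / "study_specimens.csv", index=False)
    study.site_backgrounds.to_csv(out / "site_backgrounds.csv", index=False)
    pd.concat([study.green_samples, study.brown_samples]).to_csv(
        out / "shared_backgrounds.csv", index=False
    )
    manifest["stages"]["simulate"] = {"n_specimens": len(population)}

    # --- stage 2: calibrate ------------------------------------------------
    if config.cone_catch_csv is None:
        spectra = synthetic.gen_spectra(config.n_calibration_spectra, seed=seeds["spectra"])
        model = calibration.fit_cone_mapping(
            camera, receptors, spectra, illuminant, degree=config.mapping_degree
        )
        demo_spectra = synthetic.gen_spectra(4, seed=seeds["render"])
        rows = []
        for i in range(0, len(demo_spectra), 2):
            img = synthetic.render_specimen_image(
                demo_spectra[i], demo_spectra[i + 1], list(config.standards),
                camera, illuminant, gamma=2.2, noise_sd=0.0,
                seed=seeds["render"] + i, specular_fraction=0.01,
            )
            linear = calibration.linearize(img.image, img.gamma)
            refl = calibration.normalize_reflectance(
                linear,
                [img.masks[f"standard_{j}"] for j in range(len(config.standards))],
                list(config.standards),
            )
            cone = calibration.map_to_cone_image(refl, model)
            for region in ("elytra", "spot"):
                meas = calibration.measure_region(
                    cone, img.masks[region], config.specular_percentile
                )
                rows.append(
                    {
                        "specimen_id": f"render_{i//2+1}",
                        "region": region,
                        **dict(zip(("qUV", "qSW", "qMW", "qLW", "qD"),
                                   meas.catch.as_array())),
                        "n_pixels_used": meas.n_used,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "cone_catches.csv", index=False)
        manifest["stages"]["calibrate"] = {
            "skipped": False,
            "degree": config.mapping_degree,
            "training_r2": model.r_squared,
        }
    else:
        pd.read_csv(config.cone_catch_csv).to_csv(out / "cone_catches.csv", index=False)
        manifest["stages"]["calibrate"] = {
            "skipped": True,
            "reason": "user-supplied cone-catch table",
            "source": config.cone_catch_csv,
        }

    # --- stage 3: attributes -----------------------------------------------
    attrs = visual.attribute_table(population, noise)
    attrs.to_csv(out / "attributes.csv", index=False)
    manifest["stages"]["attributes"] = {"columns": list(attrs.columns)}

    # --- stage 4: uniqueness -----------------------------------------------
    fm = uniqueness.build_features(attrs)
    report = uniqueness.loocv_lda(fm, priors=config.priors)
    power = uniqueness.variable_discrimination(fm)
    report.confusion.to_csv(out / "confusion_matrix.csv")
    report.uniqueness.to_csv(out / "uniqueness.csv")
    power.to_csv(out / "variable_power.csv")
    plots.discriminant_scatter(fm, out / "discriminant_plot.png")
    manifest["stages"]["uniqueness"] = {
        "mean_uniqueness_pct": float(report.uniqueness.mean())
    }

    # --- stage 5: contrast -------------------------------------------------
    green_avg = contrast.average_background(study.green_samples, "green")
    brown_avg = contrast.average_background(study.brown_samples, "brown")
    ctab = contrast.contrast_table(
        study.specimens, study.site_backgrounds, green_avg, brown_avg, noise
    )
    ctab.to_csv(out / "contrast_table.csv", index=False)
    plots.contrast_boxplot(ctab, out / "contrast_boxplot.png")
    summaries = {}
    for model_kind in ("species", "habitat"):
        summ = contrast.fit_contrast_lmm(ctab, model=model_kind)
        summ.posthoc.to_csv(out / f"posthoc_{model_kind}.csv", index=False)
        summaries[model_kind] = {
            "loglik": summ.loglik,
            "converged": summ.converged,
        }
    manifest["stages"]["contrast"] = summaries

    # --- stage 6: phylogenetic signal --------------------------------------
    newick, _, _ = synthetic.gen_tree_traits(config.n_tips, seed=seeds["tree"])
    (out / "tree.nwk").write_text(newick + "\n")
    tree = phylo.read_newick(newick)
    sp_means = attrs.groupby("species").mean(numeric_only=True)
    sp_means.index = list(tree.taxa)[: len(sp_means)]
    uniq_by_species = report.uniqueness.copy()
    uniq_by_species.index = sp_means.index
    signal_rows = []
    for col in ("elytra_h1", "elytra_saturation", "spot_luminance",
                "spot_saturation", "spot_h1", "internal_contrast", "spot_area_pct"):
        trait = sp_means[col]
        lam = phylo.pagel_lambda(tree, trait)
        kres = phylo.blomberg_k(tree, trait, n_perm=199, seed=config.seed)
        reg = phylo.pgls(tree, uniq_by_species, sp_means[[col]])
        signal_rows.append(
            {
                "attribute": col,
                "lambda": lam.lambda_,
                "lambda_p": lam.pvalue,
                "K": kres.k,
                "K_p": kres.pvalue,
                "pgls_F": reg.fvalue,
                "pgls_p": reg.f_pvalue,
            }
        )
    pd.DataFrame(signal_rows).to_csv(out / "phylo_signal.csv", index=False)
    manifest["stages"]["phylosignal"] = {"n_tips": config.n_tips}

    for path in sorted(out.glob("*.csv")) + [out / "tree.nwk"]:
        manifest["checksums"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
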