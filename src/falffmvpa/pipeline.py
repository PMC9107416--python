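"""End-to-end orchestration: features -> SFFS/LOOCV -> controls -> regression.

A run takes its input from one of three sources — a synthetic cohort
spec, a directory of per-subject pre/post NIfTI volumes plus a
phenotype table, or a ready-made feature CSV — and produces a
classification summary, both permutation-control summaries, stepwise
regression results for the hunger and satiety rating differences, and
a JSON manifest tying everything to the master seed and configuration.

Every stochastic step (cohort generation, both controls) draws from a
child of the single master seed, so a run is fully reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .classify import encode_labels, loocv, sffs
from .falff import LOW_FREQ_BAND, VolumeSeries, falff_map, session_difference, zscore_map
from .permutation import fsc_control, traditional_control
from .regression import build_candidates, stepwise_select
from .roi import ROISet, bundled_catalog, extract_features
from .synth import Cohort, CohortSpec, cohort_features, generate_cohort

logger = logging.getLogger("falffmvpa.pipeline")

__all__ = ["RunConfig", "run_analysis", "load_config"]


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Exactly one data source must be set: ``synth`` (a
    :class:`~falffmvpa.synth.CohortSpec`), ``data_dir`` +
    ``phenotype_csv`` + ``roi_catalog`` (NIfTI mode), or
    ``features_csv``.  Defaults keep permutation counts at a
    desk-scale profile; raise ``n_perm_traditional`` to 10000 and
    ``n_perm_fsc`` to 500 for a full-scale run.
    """

    out_dir: str = "falffmvpa_run"
    # --- data source (one of) ---
    synth: CohortSpec | None = None
    data_dir: str | None = None
    phenotype_csv: str | None = None
    features_csv: str | None = None
    roi_catalog: str | None = None  # path or bundled name ('rsn', 'brainstem')
    network: str | None = None      # restrict a catalog to one network
    gm_mask: str | None = None      # optional analysis (grey-matter) mask NIfTI
    # --- analysis parameters ---
    band: tuple[float, float] = LOW_FREQ_BAND
    ratio: str = "sum"
    discard: int = 10
    c_reg: float = 1.0
    max_subset_size: int | None = None
    n_perm_traditional: int = 200
    n_perm_fsc: int = 100
    relabel: str = "half"
    stepwise_criterion: str = "aic"
    seed: int = 0

    def __post_init__(self) -> None:
        sources = [self.synth is not None, self.data_dir is not None,
                   self.features_csv is not None]
        if sum(sources) != 1:
            raise ValueError("set exactly one of synth, data_dir, features_csv")
        if self.n_perm_traditional < 1 or self.n_perm_fsc < 1:
            raise ValueError("permutation counts must be >= 1")


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if "synth" in raw and raw["synth"] is not None:
        raw["synth"] = CohortSpec(**raw["synth"])
    if "band" in raw:
        raw["band"] = tuple(raw["band"])
    return RunConfig(**raw)


def _child_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def _load_catalog(config: RunConfig) -> ROISet | None:
    if config.roi_catalog is None:
        return None
    if config.roi_catalog in {"rsn", "brainstem"}:
        cat = bundled_catalog(config.roi_catalog)
    else:
        cat = ROISet.from_tsv(config.roi_catalog)
    if config.network:
        df = pd.read_csv(config.roi_catalog, sep="\t", comment="#") \
            if config.roi_catalog not in {"rsn", "brainstem"} else None
        keep = [r for r in cat if r.name.startswith(config.network + "_")]
        if df is not None and "network" in df.columns:
            wanted = set(df[df["network"] == config.network]["name"])
            keep = [r for r in cat if r.name in wanted]
        if not keep:
            raise ValueError(f"network {config.network!r} matches no catalog rows")
        cat = ROISet(keep)
    return cat


def _features_from_nifti(config: RunConfig
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    import nibabel as nib

    pheno = pd.read_csv(config.phenotype_csv)
    catalog = _load_catalog(config)
    if catalog is None:
        raise ValueError("NIfTI mode needs a roi_catalog")
    data_dir = Path(config.data_dir)
    gm = None
    if config.gm_mask:
        gm = np.asarray(nib.load(config.gm_mask).dataobj) > 0
    maps, groups = {}, {}
    for _, row in pheno.iterrows():
        sid = str(row["subject_id"])
        z = {}
        for session in ("pre", "post"):
            path = data_dir / f"{sid}_{session}_bold.nii.gz"
            series = VolumeSeries.from_nifti(path, discard=config.discard)
            fmap = falff_map(series, band=config.band, ratio=config.ratio)
            z[session] = zscore_map(fmap, mask=gm)
        maps[sid] = session_difference(z["post"], z["pre"])
        groups[sid] = row["group"]
    features = extract_features(maps, catalog, groups=groups,
                                analysis_mask=gm)
    return features, pheno


def _acquire_features(config: RunConfig
                      ) -> tuple[pd.DataFrame, pd.DataFrame | None, Cohort | None]:
    """Returns (features incl. group column, phenotypes or None, cohort)."""
    if config.synth is not None:
        spec = config.synth
        cohort = generate_cohort(spec)
        features = cohort_features(cohort, discard=config.discard,
                                   band=config.band, ratio=config.ratio)
        return features, cohort.phenotypes, cohort
    if config.features_csv is not None:
        features = pd.read_csv(config.features_csv, index_col=0)
        if "group" not in features.columns:
            raise ValueError("features CSV must carry a 'group' column")
        pheno = pd.read_csv(config.phenotype_csv) if config.phenotype_csv else None
        return features, pheno, None
    features, pheno = _features_from_nifti(config)
    return features, pheno, None


def _rating_diffs(pheno: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame({"subject_id": pheno["subject_id"].astype(str)})
    for scale in ("hunger", "satiety"):
        if f"{scale}_post" in pheno and f"{scale}_pre" in pheno:
            out[f"{scale}_diff"] = pheno[f"{scale}_post"] - pheno[f"{scale}_pre"]
    return out.set_index("subject_id")


def run_analysis(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline and write reports under ``out_dir``.

    Writes ``classification.csv`` (subset ratio, CA, sensitivity,
    specificity, balanced accuracy), ``permutation.csv`` (experimental
    CA, control mean (SD), p, d_z per control), ``regression.csv``
    (selected stepwise models per rating scale) and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 3)
    if config.synth is not None:
        config = dataclasses.replace(
            config, synth=dataclasses.replace(config.synth, seed=seeds[0]))

    timings: dict[str, float] = {}

    def stage(name: str):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()

    def done(name: str):
        timings[name] = round(time.perf_counter() - timings[name], 3)
        logger.info("stage %s done in %.2fs", name, timings[name])

    stage("features")
    features, pheno, _cohort = _acquire_features(config)
    features.to_csv(out / "features.csv")
    done("features")

    y = encode_labels(features["group"])
    roi_cols = [c for c in features.columns if c != "group"]

    stage("sffs")
    trace, best = sffs(features, y, max_size=config.max_subset_size,
                       c_reg=config.c_reg)
    full = loocv(features, y, subset=roi_cols, c_reg=config.c_reg)
    done("sffs")

    cls_rows = []
    for res in (best, full):
        cls_rows.append({
            "feature_ratio": f"{len(res.subset)}/{len(roi_cols)}",
            "experimental_ca_pct": round(res.ca, 2),
            "sensitivity": round(res.sensitivity, 2),
            "specificity": round(res.specificity, 2),
            "balanced_accuracy": round(res.balanced_accuracy, 2),
            "dor": round(res.dor, 2),
            "subset": " ".join(res.subset),
        })
    pd.DataFrame(cls_rows).to_csv(out / "classification.csv", index=False)
    (out / "sffs_trace.json").write_text(json.dumps(
        {"trace": trace.to_dict(), "best": best.to_dict()}, indent=2))

    stage("traditional_control")
    trad = traditional_control(features, y, fixed_subset=best.subset,
                               n_perm=config.n_perm_traditional,
                               c_reg=config.c_reg, seed=seeds[1],
                               relabel=config.relabel)
    done("traditional_control")

    stage("fsc_control")
    fsc = fsc_control(features, y, n_perm=config.n_perm_fsc,
                      max_size=config.max_subset_size, c_reg=config.c_reg,
                      seed=seeds[2], relabel=config.relabel,
                      experimental=best)
    done("fsc_control")

    perm_rows = []
    for res in (trad, fsc):
        perm_rows.append({
            "control": res.control_kind,
            "feature_ratio": f"{len(best.subset)}/{len(roi_cols)}",
            "experimental_ca_pct": round(res.experimental_ca, 2),
            "n_perm": res.n_perm,
            "control_mean_pct": round(res.mean_ca, 2),
            "control_sd_pct": round(res.sd_ca, 2),
            "p_value": round(res.p_value, 4),
            "d_z": round(res.d_z, 2) if np.isfinite(res.d_z) else "",
            "overfitting_pct": round(res.overfitting_pct, 2)
            if res.overfitting_pct is not None else "",
        })
    pd.DataFrame(perm_rows).to_csv(out / "permutation.csv", index=False)
    trad.to_json(out / "control_traditional.json")
    fsc.to_json(out / "control_fsc.json")

    reg_rows, reg_log = [], {}
    if pheno is not None and len(best.subset) > 0:
        stage("regression")
        diffs = _rating_diffs(pheno)
        aligned = diffs.reindex(features.index.astype(str))
        candidates = build_candidates(features, y, rois=list(best.subset))
        for col in aligned.columns:
            fit, log = stepwise_select(
                aligned[col].to_numpy(), candidates,
                criterion=config.stepwise_criterion, response=col)
            reg_log[col] = log
            if fit.terms:
                for t in fit.terms:
                    reg_rows.append({
                        "response": col,
                        "model": " + ".join(fit.terms),
                        "adj_r_squared": round(fit.adj_r_squared, 3),
                        "f_statistic": round(fit.f_statistic, 3),
                        "df": f"({fit.df_model},{fit.df_resid})",
                        "model_p": round(fit.p_value, 4),
                        "term": t,
                        "beta": round(fit.coefficients[t], 3),
                        "term_p": round(fit.term_p_values[t], 4),
                    })
            else:
                reg_rows.append({"response": col, "model": "(intercept only)",
                                 "adj_r_squared": 0.0, "f_statistic": "",
                                 "df": "", "model_p": "", "term": "",
                                 "beta": "", "term_p": ""})
        pd.DataFrame(reg_rows).to_csv(out / "regression.csv", index=False)
        (out / "regression_steps.json").write_text(json.dumps(reg_log, indent=2))
        done("regression")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "child_seeds": seeds,
        "n_subjects": int(len(features)),
        "n_rois": len(roi_cols),
        "band_hz": list(config.band),
        "c_reg": config.c_reg,
        "n_perm_traditional": config.n_perm_traditional,
        "n_perm_fsc": config.n_perm_fsc,
        "relabel": config.relabel,
        "stepwise_criterion": config.stepwise_criterion,
        "timings_s": timings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {"features": features, "best": best, "full": full, "trace": trace,
            "traditional": trad, "fsc": fsc, "regression": reg_rows,
            "manifest": manifest}
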