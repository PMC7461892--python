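"""End-to-end orchestration: extract features from a cohort manifest and
run the univariate, ROC, multivariate and reliability stages.

Stage outputs are plain CSV/JSON files with self-describing headers, so
each stage can be re-run from the previous stage's output:

* ``features.csv`` — one row per case: case_id, group, 24 features.
* ``covariates.csv`` — clinical covariate group comparisons.
* ``univariate.csv`` — per-feature test, group summaries, p-value.
* ``roc.csv`` — AUC, 95% CI, Youden cutoff, sensitivity/specificity for
  each univariately significant feature, plus ``delong.csv`` with the
  pairwise DeLong p-value matrix.
* ``model.json`` — VIF screen, per-predictor odds ratios and Spearman
  correlations, independent predictors, combined-model ROC.
* ``icc.csv`` — per-feature two-rater ICC(2,1) when second-rater masks
  are available.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import group_stats, model, roc, texture
from .errors import DegenerateDataError, PipelineStageError, RectexError
from .roi_io import load_slice
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger("rectex")

FEATURE_COLUMNS = [
    f"{p}_{f}" for p in ("sag", "tra") for f in texture.FEATURE_NAMES
]

_CATEGORICAL_COVARIATES = ("sex", "location", "differentiation", "n_stage")
_QUANTITATIVE_COVARIATES = ("age", "diameter_cm")


@dataclass
class RunConfig:
    """Settings of one full pipeline run."""

    out_dir: Path
    manifest: Optional[Path] = None     # None -> simulate a cohort
    cohort: CohortConfig = field(default_factory=CohortConfig)
    ng: int = 32
    alpha: float = 0.05
    vif_threshold: float = 10.0
    seed: int = 0
    image_format: str = "png"
    figures: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.vif_threshold <= 1:
            raise ValueError("VIF threshold must exceed 1")

    def digest(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def extract_features(manifest, base_dir, ng: int = 32,
                     rater: int = 1,
                     glcm_scaled_levels: bool = False) -> pd.DataFrame:
    """24 texture features per manifest row.

    ``rater=2`` switches to the second-rater mask columns
    (``sag_mask_r2`` / ``tra_mask_r2``).  Paths are resolved relative to
    ``base_dir``.  ``glcm_scaled_levels`` maps GLCM level indices to
    (0, 1] for users mimicking small printed DISS magnitudes.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    base_dir = Path(base_dir)
    suffix = "" if rater == 1 else "_r2"
    rows = []
    for rec in manifest.itertuples(index=False):
        rec = rec._asdict()
        sag = load_slice(
            base_dir / rec["sag_image"],
            base_dir / rec["sag_mask" + suffix],
            sequence_type="sagittal_fs",
            case_id=rec["case_id"],
        )
        tra = load_slice(
            base_dir / rec["tra_image"],
            base_dir / rec["tra_mask" + suffix],
            sequence_type="transverse",
            case_id=rec["case_id"],
        )
        row = {"case_id": rec["case_id"], "group": rec["group"]}
        row.update(texture.extract_case_features(
            sag, tra, ng=ng, glcm_scaled_levels=glcm_scaled_levels))
        rows.append(row)
    return pd.DataFrame(rows, columns=["case_id", "group"] + FEATURE_COLUMNS)


def _group_split(features: pd.DataFrame, column: str):
    low = features.loc[features["group"] == "T12", column].to_numpy(float)
    high = features.loc[features["group"] == "T34", column].to_numpy(float)
    return low, high


def simulate_features(cohort: CohortConfig, ng: int = 32,
                      rater: int = 1) -> pd.DataFrame:
    """Feature table of a simulated cohort without touching disk.

    Produces exactly the features that :func:`generate_cohort` +
    :func:`extract_features` would (images are integral-valued, so the
    16-bit round-trip is lossless).  ``rater=2`` extracts from the
    perturbed second-rater masks instead.
    """
    from .roi_io import SliceROI
    from .synthetic import GROUPS, generate_case, perturb_mask

    rows = []
    case_index = 0
    for group, count in zip(GROUPS, (cohort.n_low, cohort.n_high)):
        for _ in range(count):
            case_index += 1
            case = generate_case(cohort, group, case_index)
            pairs = {"sag": (case.sag_image, case.sag_mask),
                     "tra": (case.tra_image, case.tra_mask)}
            if rater == 2:
                aux = np.random.default_rng([cohort.seed, case_index, 7])
                for tag in ("sag", "tra"):
                    img, msk = pairs[tag]
                    r2, _ = perturb_mask(msk, cohort.rater_jitter,
                                         int(aux.integers(0, 2 ** 31)))
                    pairs[tag] = (img, r2)
            sag = SliceROI(pairs["sag"][0], pairs["sag"][1], "sagittal_fs")
            tra = SliceROI(pairs["tra"][0], pairs["tra"][1], "transverse")
            row = {"case_id": f"case_{case_index:04d}", "group": group}
            row.update(texture.extract_case_features(sag, tra, ng=ng))
            rows.append(row)
    return pd.DataFrame(rows, columns=["case_id", "group"] + FEATURE_COLUMNS)


def analyze_features(features: pd.DataFrame, alpha: float = 0.05,
                     vif_threshold: float = 10.0) -> dict:
    """Univariate -> ROC -> multivariate on an extracted feature table.

    Returns the in-memory stage results (no files written); the
    pairwise DeLong matrix is left to :func:`roc_report`.
    """
    univariate = univariate_report(features, alpha=alpha)
    significant = list(univariate.loc[univariate["significant"], "feature"])
    labels = (features["group"] == "T34").to_numpy(int)
    roc_results = {
        col: roc.roc_analysis(features[col].to_numpy(float), labels)
        for col in (significant or FEATURE_COLUMNS)
    }
    mv = multivariate_report(features, significant, roc_results,
                             alpha=alpha, vif_threshold=vif_threshold)
    return {
        "univariate": univariate,
        "significant": significant,
        "roc_results": roc_results,
        "multivariate": mv,
    }


# ---------------------------------------------------------------------------
# univariate stage
# ---------------------------------------------------------------------------

def univariate_report(features: pd.DataFrame,
                      alpha: float = 0.05,
                      fdr: bool = False) -> pd.DataFrame:
    """Normality-dispatched group comparison of every texture feature.

    Raw p-values only by default (matching the emulated workflow, which
    applies no multiple-testing correction); ``fdr=True`` appends a
    Benjamini-Hochberg q-value column as a clearly-optional extension —
    the ``significant`` flag always uses the raw p-values.
    """
    rows = []
    for col in FEATURE_COLUMNS:
        low, high = _group_split(features, col)
        res = group_stats.compare_feature(low, high, name=col, alpha=alpha)
        rows.append({
            "feature": col,
            "test": res.test,
            "t12_summary": res.low_summary,
            "t34_summary": res.high_summary,
            "p_value": res.p_value,
            "significant": res.significant,
        })
    report = pd.DataFrame(rows)
    if fdr:
        from scipy.stats import false_discovery_control

        report["fdr_q"] = false_discovery_control(report["p_value"])
    return report


def covariate_report(manifest: pd.DataFrame,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Group comparison of the clinical covariates (chi-square/Fisher for
    categoricals, KS-dispatched t/MWU for quantitative)."""
    rows = []
    for cov in _CATEGORICAL_COVARIATES:
        table = pd.crosstab(manifest[cov], manifest["group"]).to_numpy()
        p = group_stats.categorical_tests(table)
        rows.append({"covariate": cov, "test": "categorical",
                     "p_value": p, "significant": p < alpha})
    for cov in _QUANTITATIVE_COVARIATES:
        low = manifest.loc[manifest["group"] == "T12", cov].to_numpy(float)
        high = manifest.loc[manifest["group"] == "T34", cov].to_numpy(float)
        res = group_stats.compare_feature(low, high, name=cov, alpha=alpha)
        rows.append({"covariate": cov, "test": res.test,
                     "p_value": res.p_value,
                     "significant": res.significant})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROC stage
# ---------------------------------------------------------------------------

def roc_report(features: pd.DataFrame, feature_names):
    """Per-feature ROC analysis plus the pairwise DeLong p-value matrix.

    Returns (table, results, delong) where ``results`` maps feature name
    to its :class:`~rectex.roc.ROCResult`.
    """
    labels = (features["group"] == "T34").to_numpy(int)
    results = {}
    rows = []
    for col in feature_names:
        r = roc.roc_analysis(features[col].to_numpy(float), labels)
        results[col] = r
        rows.append({
            "feature": col,
            "auc": r.auc,
            "sensitivity_pct": 100 * r.sensitivity,
            "specificity_pct": 100 * r.specificity,
            "ci_low": r.ci95[0],
            "ci_high": r.ci95[1],
            "cutoff": r.cutoff,
            "orientation": r.orientation,
        })
    table = pd.DataFrame(rows)
    names = list(feature_names)
    dl = pd.DataFrame(np.ones((len(names), len(names))),
                      index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            try:
                _, p = roc.delong_paired_test(
                    features[a].to_numpy(float),
                    features[b].to_numpy(float), labels,
                )
            except DegenerateDataError:
                p = math.nan  # e.g. two perfect markers on a tiny cohort
            dl.loc[a, b] = dl.loc[b, a] = p
    return table, results, dl


# ---------------------------------------------------------------------------
# multivariate stage
# ---------------------------------------------------------------------------

def multivariate_report(features: pd.DataFrame, significant,
                        roc_results: dict, alpha: float = 0.05,
                        vif_threshold: float = 10.0) -> dict:
    """VIF screen, dichotomized logistic model, Spearman correlations,
    and the combined-model ROC.

    ``significant`` is the univariately significant feature pool.  When
    it is empty the combined model degenerates to intercept-only
    (combined AUC 0.5), which is the honest answer on a null cohort.
    """
    labels = (features["group"] == "T34").to_numpy(int)
    significant = list(significant)
    report = {"entered": significant}
    if significant:
        vif = model.vif_screen(features[significant],
                               threshold=vif_threshold)
        retained = vif.retained
        report["vif"] = {k: (v if math.isfinite(v) else "inf")
                         for k, v in vif.vif.items()}
        report["vif_excluded"] = [
            [name, (v if math.isfinite(v) else "inf")]
            for name, v in vif.excluded
        ]
        design = model.dichotomize(features[retained],
                                  {k: roc_results[k] for k in retained})
    else:
        retained = []
        report["vif"] = {}
        report["vif_excluded"] = []
        design = pd.DataFrame(index=features.index)
    fit = model.fit_logistic(design, labels)
    pred_rows = []
    for i, name in enumerate(fit.predictors):
        rho, rho_p = model.spearman_rho(
            features[name].to_numpy(float), labels
        )
        pred_rows.append({
            "feature": name,
            "beta": float(fit.beta[i]),
            "odds_ratio": float(fit.odds_ratio[i]),
            "or_ci_low": float(fit.or_ci[i, 0]),
            "or_ci_high": float(fit.or_ci[i, 1]),
            "p_value": float(fit.p_values[i]),
            "spearman_rho": rho,
            "spearman_p": rho_p,
            "independent": bool(fit.p_values[i] < alpha),
        })
    independent = [r["feature"] for r in pred_rows if r["independent"]]
    if len(independent) == len(retained):
        final = fit
    else:
        # the combined model keeps the independent predictors only; with
        # none, it degenerates to intercept-only (combined AUC 0.5)
        final = model.fit_logistic(design[independent], labels)
    combined = model.combined_model_roc(final, labels)
    report.update({
        "full_model": {
            "predictors": pred_rows,
            "intercept": fit.intercept,
            "converged": fit.converged,
            "separated": fit.separated,
            "iterations": fit.iterations,
        },
        "independent_predictors": independent,
        "combined_roc": {
            "auc": combined.auc,
            "ci_low": combined.ci95[0],
            "ci_high": combined.ci95[1],
            "cutoff": combined.cutoff,
            "sensitivity": combined.sensitivity,
            "specificity": combined.specificity,
            "orientation": combined.orientation,
        },
    })
    return report


# ---------------------------------------------------------------------------
# reliability stage
# ---------------------------------------------------------------------------

def icc_report(features_r1: pd.DataFrame,
               features_r2: pd.DataFrame) -> pd.DataFrame:
    """Per-feature two-rater ICC(2,1) between the two segmentations."""
    ids1 = list(features_r1["case_id"])
    ids2 = list(features_r2["case_id"])
    if ids1 != ids2:
        unmatched = sorted(set(ids1).symmetric_difference(ids2)) or ids1[:5]
        raise RectexError(f"rater feature tables do not align: {unmatched}")
    rows = []
    for col in FEATURE_COLUMNS:
        res = group_stats.icc_two_rater(
            features_r1[col].to_numpy(float),
            features_r2[col].to_numpy(float),
        )
        rows.append({"feature": col, "icc": res.icc, "band": res.band})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _to_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format="%.10g")


def run_full_pipeline(config: RunConfig) -> dict:
    """Run simulate (optional) -> extract -> univariate -> ROC ->
    multivariate -> ICC, writing every stage output under
    ``config.out_dir``.  Returns the in-memory stage results.

    Identical config and seed give byte-identical outputs.  A stage
    failure raises :class:`PipelineStageError` naming the stage; files
    already written are renamed with a ``.partial`` suffix.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    stage = "setup"

    def emit(name, writer):
        path = out / name
        writer(path)
        written.append(path)

    try:
        stage = "simulate"
        if config.manifest is None:
            cohort_dir = out / "cohort"
            cohort = CohortConfig(**{
                **config.cohort.__dict__, "seed": config.seed,
            })
            manifest = generate_cohort(cohort, cohort_dir,
                                       fmt=config.image_format)
            base_dir = cohort_dir
        else:
            manifest = pd.read_csv(config.manifest)
            base_dir = Path(config.manifest).parent
        logger.info("cohort: %d cases (%s)", len(manifest),
                    manifest["group"].value_counts().to_dict())

        stage = "extract"
        features = extract_features(manifest, base_dir, ng=config.ng)
        emit("features.csv", lambda p: _to_csv(features, p))

        stage = "covariates"
        have_covariates = all(
            c in manifest.columns
            for c in _CATEGORICAL_COVARIATES + _QUANTITATIVE_COVARIATES
        )
        covariates = None
        if have_covariates:
            covariates = covariate_report(manifest, alpha=config.alpha)
            emit("covariates.csv", lambda p: _to_csv(covariates, p))

        stage = "univariate"
        univariate = univariate_report(features, alpha=config.alpha)
        emit("univariate.csv", lambda p: _to_csv(univariate, p))
        significant = list(
            univariate.loc[univariate["significant"], "feature"]
        )
        logger.info("univariately significant: %s", significant)

        stage = "roc"
        roc_table, roc_results, delong = roc_report(
            features, significant or FEATURE_COLUMNS
        )
        emit("roc.csv", lambda p: _to_csv(roc_table, p))
        emit("delong.csv",
             lambda p: delong.to_csv(p, float_format="%.10g"))

        stage = "multivariate"
        mv = multivariate_report(features, significant, roc_results,
                                 alpha=config.alpha,
                                 vif_threshold=config.vif_threshold)
        emit("model.json", lambda p: p.write_text(
            json.dumps(mv, indent=2, sort_keys=True) + "\n"))

        stage = "icc"
        icc = None
        if {"sag_mask_r2", "tra_mask_r2"}.issubset(manifest.columns):
            features_r2 = extract_features(manifest, base_dir,
                                           ng=config.ng, rater=2)
            icc = icc_report(features, features_r2)
            emit("icc.csv", lambda p: _to_csv(icc, p))

        stage = "figures"
        if config.figures:
            _roc_figure(features, significant or FEATURE_COLUMNS,
                        out / "roc_curves.svg")
            written.append(out / "roc_curves.svg")

        stage = "log"
        (out / "run_log.txt").write_text(
            f"seed={config.seed}\nconfig_hash={config.digest()}\n"
            f"config={config!r}\n"
            f"n_cases={len(manifest)}\n"
            f"significant={significant}\n"
        )
    except RectexError as exc:
        for path in written:
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        raise PipelineStageError(f"stage {stage!r} failed: {exc}") from exc

    return {
        "manifest": manifest,
        "features": features,
        "covariates": covariates,
        "univariate": univariate,
        "significant": significant,
        "roc_table": roc_table,
        "roc_results": roc_results,
        "delong": delong,
        "multivariate": mv,
        "icc": icc,
    }


def _roc_figure(features: pd.DataFrame, feature_names, path: Path):
    """Empirical ROC curves of the listed markers, one panel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = (features["group"] == "T34").to_numpy(int)
    fig, ax = plt.subplots(figsize=(5, 5))
    for col in feature_names:
        scores = features[col].to_numpy(float)
        r = roc.roc_auc(scores, labels)
        s = scores if r.orientation == roc.GREATER else -scores
        order = np.argsort(-s, kind="stable")
        tp = np.cumsum(labels[order])
        fp = np.cumsum(1 - labels[order])
        ax.plot(np.r_[0, fp / fp[-1]], np.r_[0, tp / tp[-1]],
                label=f"{col} (AUC {r.auc:.3f})", lw=1)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
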