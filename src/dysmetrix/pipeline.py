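"""End-to-end orchestration: features -> PCA -> linear SVM -> report.

Per recording, the 14-slot feature vector combines the best statistic of
each method family:

====================  ===========================  ====
slot                  source                       band
====================  ===========================  ====
template_score        matched filter               0.08-5 Hz
threshold_surface     threshold-based surface      0.08-5 Hz
dispen                dispersion entropy           0.08-5 Hz
h2                    nonlinear correlation L/R    0.08-5 Hz
mde_s1 .. mde_s10     multiscale DispEn profile    0.08-25 Hz
====================  ===========================  ====

Classification standardizes the features, reduces them with PCA to the
smallest component count reaching the target cumulative explained variance
(default 95%), and fits a linear SVM under stratified k-fold cross-validation.
Standardization and PCA are fitted inside each training fold only, so no
test-fold statistics leak into the fit.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import connectivity, irregularity, multiscale, preprocess
from . import stats as gstats
from . import template as tmpl
from .synthetic import GazeRecording, read_recording

FEATURE_NAMES = (["template_score", "threshold_surface", "dispen", "h2"]
                 + [f"mde_s{s}" for s in range(1, 11)])

POSITIVE_LABEL = "dysmetric"


@dataclass(frozen=True)
class PipelineConfig:
    band_low: tuple = preprocess.BAND_LOW
    band_wide: tuple = preprocess.BAND_WIDE
    fir_order: int = 200
    median_order: int = 200
    thr_pos: float = 0.35
    thr_neg: float = -0.35
    template_hold_s: float = 1.5
    template_rise_s: float = 0.05
    entropy: irregularity.EntropyParams = field(
        default_factory=irregularity.EntropyParams)
    tau_max: int = 10
    h2_bins: int = 10
    variance_target: float = 0.95
    k_folds: int = 10
    svm_c: float = 1.0
    min_duration_s: float = 42.0
    channel_mode: str = "mean"  # mean of eyes | "left" | "right"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["entropy"] = dataclasses.asdict(self.entropy)
        return d


@dataclass
class FeatureVector:
    subject_id: str
    label: str | None
    values: dict  # name -> float (NaN if the stage failed)
    missing: list = field(default_factory=list)

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES])


@dataclass
class ClassifierReport:
    accuracy: float
    sensitivity: float
    specificity: float
    n_components: int
    explained_variance: float
    per_fold_accuracy: list
    confusion: dict  # tp / fp / tn / fn, dysmetric positive
    mean_fold_accuracy: float
    k_folds: int
    n_subjects: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _per_eye(fn, left: np.ndarray, right: np.ndarray, mode: str) -> float:
    if mode == "left":
        return fn(left)
    if mode == "right":
        return fn(right)
    return 0.5 * (fn(left) + fn(right))


def extract_features(rec: GazeRecording,
                     config: PipelineConfig | None = None) -> FeatureVector:
    """Compute the 14 features of one recording.

    Any stage failure is recorded as a NaN slot and listed in ``missing``
    rather than silently imputed.
    """
    cfg = config or PipelineConfig()
    values = {n: float("nan") for n in FEATURE_NAMES}
    missing: list[str] = []

    def run(names, fn):
        try:
            out = fn()
        except Exception as exc:  # flagged-missing, never fatal
            warnings.warn(f"feature stage {names} failed: {exc}")
            missing.extend(names)
            return
        for n, v in (out.items() if isinstance(out, dict) else [(names[0], out)]):
            values[n] = float(v)

    lo_l = preprocess.preprocess_channel(rec.left_x, rec.fs, cfg.band_low,
                                         cfg.fir_order, cfg.median_order)
    lo_r = preprocess.preprocess_channel(rec.right_x, rec.fs, cfg.band_low,
                                         cfg.fir_order, cfg.median_order)
    wide_l = preprocess.preprocess_channel(rec.left_x, rec.fs, cfg.band_wide,
                                           cfg.fir_order, cfg.median_order)
    wide_r = preprocess.preprocess_channel(rec.right_x, rec.fs, cfg.band_wide,
                                           cfg.fir_order, cfg.median_order)

    templ = tmpl.ideal_template(rec.fs, hold_s=cfg.template_hold_s,
                                rise_s=cfg.template_rise_s)
    run(["template_score"], lambda: _per_eye(
        lambda x: tmpl.matched_filter_score(x, templ, rec.fs).score,
        lo_l, lo_r, cfg.channel_mode))
    run(["threshold_surface"], lambda: _per_eye(
        lambda x: tmpl.threshold_surface(x, cfg.thr_pos, cfg.thr_neg, rec.fs),
        lo_l, lo_r, cfg.channel_mode))
    run(["dispen"], lambda: _per_eye(
        lambda x: irregularity.dispersion_entropy(
            x, m=cfg.entropy.m, c=cfg.entropy.c, d=cfg.entropy.d),
        lo_l, lo_r, cfg.channel_mode))
    run(["h2"], lambda: connectivity.nonlinear_correlation_h2(
        lo_l, lo_r, n_bins=cfg.h2_bins))

    def mde():
        prof = _per_eye(
            lambda x: multiscale.multiscale_profile(
                x, "MDE", cfg.entropy, cfg.tau_max, band=cfg.band_wide).values,
            wide_l, wide_r, cfg.channel_mode)
        return {f"mde_s{s}": v for s, v in zip(range(1, cfg.tau_max + 1), prof)}

    run([f"mde_s{s}" for s in range(1, cfg.tau_max + 1)], mde)

    return FeatureVector(subject_id=rec.meta.get("subject_id", ""),
                         label=rec.label, values=values, missing=missing)


def feature_table(recordings, config: PipelineConfig | None = None
                  ) -> pd.DataFrame:
    """Feature vectors for a cohort as a DataFrame (id, label, 14 columns)."""
    rows = []
    for rec in recordings:
        fv = extract_features(rec, config)
        row = {"subject_id": fv.subject_id, "label": fv.label}
        row.update({n: fv.values[n] for n in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def reduce_pca(features: np.ndarray, variance_target: float = 0.95
               ) -> tuple[np.ndarray, PCA]:
    """PCA keeping the smallest component count with cumulative explained
    variance >= target.  Expects standardized input."""
    if not (0 < variance_target <= 1):
        raise ValueError("variance_target must lie in (0, 1]")
    if variance_target == 1.0:
        pca = PCA(svd_solver="full")
    else:
        pca = PCA(n_components=variance_target, svd_solver="full")
    reduced = pca.fit_transform(np.asarray(features, dtype=float))
    return reduced, pca


def fit_evaluate(features: np.ndarray, labels, k_folds: int = 10,
                 variance_target: float = 0.95, seed: int = 0,
                 svm_c: float = 1.0) -> ClassifierReport:
    """Stratified k-fold linear-SVM evaluation with fold-internal PCA.

    Metrics are pooled over test folds; sensitivity treats the dysmetric
    class as positive.  Per-fold accuracies and their mean are also reported.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray([1 if l == POSITIVE_LABEL else 0 for l in labels])
    if np.isnan(x).any():
        raise ValueError("feature matrix contains missing values")
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    per_fold = []
    for train, test in skf.split(x, y):
        clf = Pipeline([
            ("scale", StandardScaler()),
            ("pca", PCA(n_components=variance_target, svd_solver="full")),
            ("svm", SVC(kernel="linear", C=svm_c)),
        ])
        clf.fit(x[train], y[train])
        pred = clf.predict(x[test])
        y_pred[test] = pred
        per_fold.append(float((pred == y[test]).mean()))

    tp = int(((y_pred == 1) & (y == 1)).sum())
    tn = int(((y_pred == 0) & (y == 0)).sum())
    fp = int(((y_pred == 1) & (y == 0)).sum())
    fn = int(((y_pred == 0) & (y == 1)).sum())
    # component count reported from a fit on the full standardized matrix
    _, pca_full = reduce_pca(StandardScaler().fit_transform(x), variance_target)
    return ClassifierReport(
        accuracy=(tp + tn) / len(y),
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        n_components=int(pca_full.n_components_),
        explained_variance=float(pca_full.explained_variance_ratio_.sum()),
        per_fold_accuracy=per_fold,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        mean_fold_accuracy=float(np.mean(per_fold)),
        k_folds=k_folds, n_subjects=len(y))


def compare_feature_table(df: pd.DataFrame, by: str = "label",
                          positive: str = POSITIVE_LABEL) -> pd.DataFrame:
    """Per-feature two-group statistics (U, p, Hedges' g, descriptives)."""
    groups = df[by].unique()
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    other = [g for g in groups if g != positive][0]
    rows = []
    for name in [c for c in df.columns if c not in ("subject_id", by)]:
        a = df.loc[df[by] == positive, name].dropna().to_numpy()
        b = df.loc[df[by] == other, name].dropna().to_numpy()
        cmp_ = gstats.compare_groups(a, b, feature=name)
        rows.append(dataclasses.asdict(cmp_))
    return pd.DataFrame(rows)


def run_pipeline(input_dir: str | Path, config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None, seed: int = 0):
    """Read recordings from a directory and run the full analysis.

    Recordings shorter than the configured minimum duration are excluded
    (with the count logged), mirroring the study's inclusion rule.  Writes
    features.csv, group_stats.csv, classifier_report.json and params.json
    when ``out_dir`` is given; returns (features, report, stats, log).
    """
    cfg = config or PipelineConfig()
    input_dir = Path(input_dir)
    recordings = []
    excluded = []
    for path in sorted(input_dir.glob("*.csv")):
        try:
            rec = read_recording(path)
        except Exception as exc:
            excluded.append({"file": path.name, "reason": str(exc)})
            continue
        if rec.duration < cfg.min_duration_s:
            excluded.append({"file": path.name,
                             "reason": f"shorter than {cfg.min_duration_s} s"})
            continue
        rec.meta.setdefault("subject_id", path.stem)
        recordings.append(rec)
    if not recordings:
        raise ValueError(f"no usable recordings in {input_dir}")

    df = feature_table(recordings, cfg)
    stats_df = compare_feature_table(df) if df["label"].nunique() == 2 else None
    report = None
    complete = df.dropna(subset=list(FEATURE_NAMES))
    if complete["label"].nunique() == 2:
        # folds cannot exceed the smaller class
        folds = min(cfg.k_folds, int(complete["label"].value_counts().min()))
        if folds < cfg.k_folds:
            warnings.warn(f"reducing cross-validation folds to {folds} "
                          f"(small cohort)")
        if folds >= 2:
            report = fit_evaluate(complete[list(FEATURE_NAMES)].to_numpy(),
                                  complete["label"], k_folds=folds,
                                  variance_target=cfg.variance_target,
                                  seed=seed, svm_c=cfg.svm_c)
    log = {"n_used": len(recordings), "n_excluded": len(excluded),
           "excluded": excluded, "seed": seed, "config": cfg.to_dict()}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "features.csv", index=False)
        if stats_df is not None:
            stats_df.to_csv(out_dir / "group_stats.csv", index=False)
        if report is not None:
            (out_dir / "classifier_report.json").write_text(
                json.dumps(report.to_dict(), indent=1))
        (out_dir / "params.json").write_text(json.dumps(log, indent=1))
    return df, report, stats_df, log
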