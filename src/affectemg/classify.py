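"""Six-class SVM classification of windowed EMG feature vectors.

Feature rows (five affect categories plus BASELINE) are standardized,
classified with a Gaussian-kernel support vector machine in a one-vs-one
multiclass scheme, and assessed by stratified 10-fold cross-validation
repeated 10 times with fresh fold assignments.  The figure of merit is the
per-class success rate: held-out predictions are pooled over the folds of a
repeat and each class's correct fraction is computed; the mean and SD of
those rates across repeats form an accuracy table.

Hyper-parameters: box constraint (C) 1; the kernel scale defaults to the
dimension-aware heuristic ``sqrt(n_features * var(X))`` (a fixed scale of 1
makes every kernel entry vanish in 32 standardized dimensions and the
classifier collapses to majority voting); a fixed numeric scale remains
available.  Standardization is per-fold by default (fit on the training
partition only); a global mode is available for pipelines that standardize
the full table up front.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as sk_confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import META_COLUMNS, EntropyParams, extract_feature_table, feature_columns
from .synthetic import AFFECT_CATEGORIES, BASELINE, SubjectRecording
from .windowing import WINDOW_CONDITIONS, WindowCondition, extract_segments

__all__ = [
    "CLASS_ORDER",
    "CvConfig",
    "CvResult",
    "StratificationError",
    "standardize",
    "cross_validate",
    "summarize",
    "run_experiment",
]

#: Column order of accuracy tables.
CLASS_ORDER: tuple[str, ...] = (BASELINE,) + AFFECT_CATEGORIES

GROUP_FILTERS = ("all", "young", "senior", "female", "male")


class StratificationError(ValueError):
    """A class has fewer members than folds; stratified CV is impossible."""


@dataclass(frozen=True)
class CvConfig:
    """Cross-validation and SVM settings."""

    folds: int = 10
    repeats: int = 10
    kernel_scale: float | None = None
    box_constraint: float = 1.0
    stratified: bool = True
    standardize_mode: str = "per-fold"  # or "global"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("need folds >= 2 and repeats >= 1")
        if self.standardize_mode not in ("per-fold", "global"):
            raise ValueError("standardize_mode must be 'per-fold' or 'global'")
        if self.kernel_scale is not None and self.kernel_scale <= 0:
            raise ValueError("kernel_scale must be > 0")
        if self.box_constraint <= 0:
            raise ValueError("box_constraint must be > 0")


@dataclass
class CvResult:
    """Per-repeat per-class success rates (fractions) and pooled confusions."""

    rates: pd.DataFrame            # index: repeat, columns: class labels
    confusions: list[pd.DataFrame]  # one pooled confusion matrix per repeat
    classes: tuple[str, ...]


def standardize(
    table: pd.DataFrame, mode: str = "global"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Column-wise z-scoring of the feature columns.

    Returns the transformed table and the scaler parameters (mean, scale per
    column).  Constant columns pass through unchanged (scale set to 1) with
    a warning.  ``mode='per-fold'`` is handled inside ``cross_validate``;
    calling this function always scales over all rows.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows")
    feats = [c for c in table.columns if c not in META_COLUMNS]
    mu = table[feats].mean()
    sd = table[feats].std(ddof=0)
    constant = [c for c in feats if table[c].nunique() == 1]
    if constant:
        warnings.warn(f"constant feature columns passed through: {constant}")
        sd[constant] = 1.0
        mu[constant] = 0.0  # pass through unchanged
    out = table.copy()
    out[feats] = (table[feats] - mu) / sd
    params = pd.DataFrame({"mean": mu, "scale": sd})
    if mode not in ("global", "per-fold"):
        raise ValueError("mode must be 'global' or 'per-fold'")
    return out, params


def _fit_predict(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, cfg: CvConfig
) -> np.ndarray:
    # Gaussian kernel exp(-||u-v||^2 / kernel_scale^2); SVC is one-vs-one.
    # kernel_scale=None uses the dimension-aware heuristic scale
    # sqrt(n_features * var(X)) — a fixed scale of 1 degenerates in 32
    # standardized dimensions (all kernel values ~0, majority voting).
    gamma = "scale" if cfg.kernel_scale is None else 1.0 / cfg.kernel_scale**2
    clf = SVC(C=cfg.box_constraint, kernel="rbf", gamma=gamma)
    clf.fit(X_train, y_train)
    return clf.predict(X_test)


def cross_validate(table: pd.DataFrame, cfg: CvConfig = CvConfig()) -> CvResult:
    """Repeated stratified k-fold CV; pooled per-class success rates per repeat.

    Each repeat draws a fresh seeded fold assignment; within a repeat every
    fold trains its own SVM (and, in per-fold mode, its own scaler fit on
    the training rows only — held-out rows never leak into scaling).
    """
    feats = [c for c in table.columns if c not in META_COLUMNS]
    y = table["class"].to_numpy()
    X_raw = table[feats].to_numpy(dtype=float)
    present = set(y)
    classes = tuple(c for c in CLASS_ORDER if c in present) + tuple(
        sorted(present - set(CLASS_ORDER))
    )
    counts = pd.Series(y).value_counts()
    too_small = counts[counts < cfg.folds]
    if cfg.stratified and len(too_small) > 0:
        raise StratificationError(
            f"classes {dict(too_small)} have fewer rows than folds={cfg.folds}; "
            "reduce folds or enlarge the cohort"
        )
    if cfg.standardize_mode == "global":
        X_global, _ = standardize(table)
        X_global = X_global[feats].to_numpy(dtype=float)

    rng = np.random.default_rng(cfg.seed)
    rate_rows = []
    confusions = []
    for _rep in range(cfg.repeats):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        splitter = StratifiedKFold(
            n_splits=cfg.folds, shuffle=True, random_state=fold_seed
        )
        y_pred = np.empty(len(y), dtype=object)
        for train_idx, test_idx in splitter.split(X_raw, y):
            if cfg.standardize_mode == "per-fold":
                mu = X_raw[train_idx].mean(axis=0)
                sd = X_raw[train_idx].std(axis=0)
                sd[sd == 0] = 1.0
                X_train = (X_raw[train_idx] - mu) / sd
                X_test = (X_raw[test_idx] - mu) / sd
            else:
                X_train, X_test = X_global[train_idx], X_global[test_idx]
            y_pred[test_idx] = _fit_predict(X_train, y[train_idx], X_test, cfg)
        cm = sk_confusion_matrix(y, y_pred.astype(str), labels=list(classes))
        conf = pd.DataFrame(cm, index=list(classes), columns=list(classes))
        confusions.append(conf)
        rates = {c: conf.loc[c, c] / conf.loc[c].sum() for c in classes}
        rate_rows.append(rates)
    return CvResult(
        rates=pd.DataFrame(rate_rows, columns=list(classes)),
        confusions=confusions,
        classes=classes,
    )


def summarize(result: CvResult, **metadata: str) -> pd.DataFrame:
    """Per-class mean and SD of success rates across repeats, in percent."""
    mean = result.rates.mean() * 100.0
    sd = result.rates.std(ddof=1).fillna(0.0) * 100.0
    out = pd.DataFrame({"class": list(result.classes),
                        "mean_pct": mean.values, "sd_pct": sd.values})
    for k, v in metadata.items():
        out[k] = v
    return out


def _filter_cohort(cohort: list[SubjectRecording], group: str) -> list[SubjectRecording]:
    if group == "all":
        return cohort
    if group in ("young", "senior"):
        return [s for s in cohort if s.group.get("age_group") == group]
    if group in ("female", "male"):
        return [s for s in cohort if s.group.get("gender") == group]
    raise ValueError(f"unknown group filter {group!r}")


def run_experiment(
    cohort: list[SubjectRecording],
    conditions: list[WindowCondition] | None = None,
    channel_sets: tuple[str, ...] = ("both", "corrugator", "zygomaticus"),
    groups: tuple[str, ...] = ("all",),
    cfg: CvConfig = CvConfig(),
    entropy_params: EntropyParams = EntropyParams(),
) -> dict[tuple[str, str], pd.DataFrame]:
    """Full factorial sweep: conditions x channel sets x subject groups.

    ``cohort`` must contain preprocessed recordings.  Features are computed
    once per condition on the two-channel table and sliced per channel set.
    Returns accuracy tables keyed by ``(group, channel_set)``, each with one
    row per (condition, class) — the shape of a published accuracy table.
    """
    if conditions is None:
        conditions = list(WINDOW_CONDITIONS.values())
    results: dict[tuple[str, str], list[pd.DataFrame]] = {
        (g, cs): [] for g in groups for cs in channel_sets
    }
    for cond in conditions:
        segments = []
        for subj in cohort:
            segments.extend(
                extract_segments(subj.recording, subj.schedule, cond, subj.subject_id)
            )
        fs = cohort[0].recording.sampling_rate
        table = extract_feature_table(segments, fs, entropy_params, channel_set="both")
        for group in groups:
            members = {s.subject_id for s in _filter_cohort(cohort, group)}
            if not members:
                raise ValueError(f"group {group!r} is empty after filtering")
            sub = table[table["subject"].isin(members)]
            for cs in channel_sets:
                cols = list(META_COLUMNS) + feature_columns(cs)
                res = cross_validate(sub[cols], cfg)
                results[(group, cs)].append(
                    summarize(res, condition=cond.label, channel_set=cs, group=group)
                )
    return {
        key: pd.concat(tables, ignore_index=True) for key, tables in results.items()
    }
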