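"""Evaluation of wake/sleep classification: confusion metrics, Cohen's
kappa, ROC/AUC, Mann-Whitney feature screening and leave-one-subject-out
cross-validation (LOOCV).

Wake is the positive class throughout.  In LOOCV each subject's recording
is held out once while the classifier is trained on the pooled epochs of
all other subjects; features are normalized within each recording before
pooling, so no statistic of the held-out subject ever reaches the training
fold.  Headline numbers are per-subject means +/- SD; pooled-epoch numbers
(summed confusion cells, pooled ROC) are reported separately and never
mixed with the per-subject aggregation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .classifier import SLEEP, WAKE, BayesianLDA
from .exceptions import InvalidInputError, UndefinedMetricError, UnderdeterminedModelError
from .features import EpochGrid, compute_features

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "CVReport",
    "confusion",
    "metrics",
    "cohen_kappa",
    "roc_auc",
    "mann_whitney_u",
    "loocv",
    "LeaveOneSubjectOut",
    "compare_feature_sets",
    "FEATURE_SETS",
]

#: The feature-set configurations evaluated in the study design:
#: activity alone, sleep-possibility alone, and their combination.
FEATURE_SETS = {
    "mact": ("mact_norm",),
    "pslp": ("pslp_norm",),
    "mact+pslp": ("mact_norm", "pslp_norm"),
}


@dataclass(frozen=True)
class ConfusionMatrix:
    """Epoch counts with wake as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass
class MetricSet:
    """Classification metrics; undefined ratios are NaN and listed in
    ``undefined`` rather than silently coerced to zero."""

    precision: float
    sensitivity: float
    specificity: float
    accuracy: float
    kappa: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "kappa": self.kappa,
        }


def confusion(pred, truth) -> ConfusionMatrix:
    """Tally the four confusion cells from wake/sleep label sequences."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise InvalidInputError(
            f"prediction and truth lengths differ: {pred.shape} vs {truth.shape}"
        )
    pw, tw = pred == WAKE, truth == WAKE
    return ConfusionMatrix(
        tp=int(np.sum(pw & tw)),
        fp=int(np.sum(pw & ~tw)),
        fn=int(np.sum(~pw & tw)),
        tn=int(np.sum(~pw & ~tw)),
    )


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Precision, sensitivity, specificity, accuracy and kappa from the
    confusion cells."""
    if cm.total == 0:
        raise InvalidInputError("empty confusion matrix")
    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    prec = ratio(cm.tp, cm.tp + cm.fp, "precision")
    sens = ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    spec = ratio(cm.tn, cm.tn + cm.fp, "specificity")
    acc = (cm.tp + cm.tn) / cm.total
    kap = cohen_kappa(cm)
    return MetricSet(prec, sens, spec, acc, kap, undefined=tuple(undefined))


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement between predictions and reference.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed accuracy and
    p_e the agreement expected from the marginals.  When p_e = 1 (both
    marginals concentrated on one class) the convention kappa = 0 applies.
    """
    n = cm.total
    if n == 0:
        raise InvalidInputError("empty confusion matrix")
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / n**2
    if p_e == 1.0:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def roc_auc(scores, truth) -> tuple[pd.DataFrame, float]:
    """ROC curve (threshold sweep over the observed scores) and its area.

    The trapezoidal area equals the tie-corrected pairwise concordance
    probability (concordant + 0.5 * tied) / (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(truth) == WAKE).astype(int) if np.asarray(truth).dtype.kind in "UO" \
        else np.asarray(truth, dtype=int)
    if scores.shape != y.shape:
        raise InvalidInputError("scores and truth lengths differ")
    if y.min() == y.max():
        raise UndefinedMetricError("AUC undefined: only one class present in truth")
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    curve = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return curve, float(_sk_auc(fpr, tpr))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of stochastic equality.

    Exact permutation null when the pooled sample is small (<= 20) and has
    no ties; otherwise the normal approximation with tie and continuity
    corrections.  Returns (U of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    exact = (x.size + y.size) <= 20 and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Leave-one-subject-out cross-validation
# ---------------------------------------------------------------------------

_STAGE_TO_BINARY = {"W": WAKE, "N1": SLEEP, "N2": SLEEP, "N3": SLEEP, "R": SLEEP, "U": "excluded"}


def _subject_table(recording, grid: EpochGrid, percentile: float,
                   smoothing_window_min: float, binary_mact: bool) -> pd.DataFrame:
    """Featurize one recording and attach binarized labels.

    ``recording`` needs ``.actigraphy`` (an ActigraphySignal) and
    ``.hypnogram`` (per-epoch stage labels W/N1/N2/N3/R/U).
    """
    feats = compute_features(
        recording.actigraphy, grid, percentile=percentile,
        smoothing_window_min=smoothing_window_min, binary_mact=binary_mact,
    )
    stages = np.asarray(recording.hypnogram)
    n = min(feats.n_epochs, len(stages))
    df = feats.to_frame()[:n].copy()
    try:
        df["binary"] = [_STAGE_TO_BINARY[s] for s in stages[:n]]
    except KeyError as e:
        raise InvalidInputError(f"unknown hypnogram label {e.args[0]!r}") from e
    df["stage"] = stages[:n]
    return df


@dataclass
class CVReport:
    """LOOCV results: per-subject metrics, pooled confusion, ROC curves.

    ``per_subject`` has one row per held-out subject with epoch counts,
    wake prevalence, threshold-0.5 metrics and the subject's AUC.  The
    per-subject mean +/- SD (sample SD, NaNs excluded with a count) is the
    headline aggregation; pooled-epoch quantities are kept separate.
    """

    feature_set: str
    per_subject: pd.DataFrame
    pooled_confusion: ConfusionMatrix
    pooled_metrics: MetricSet
    pooled_roc: pd.DataFrame
    pooled_auc: float
    subject_rocs: dict = field(default_factory=dict)

    _METRICS = ("precision", "sensitivity", "specificity", "accuracy", "kappa", "auc")

    def aggregate(self) -> pd.DataFrame:
        """Mean +/- sample SD of each metric across subjects."""
        rows = []
        for m in self._METRICS:
            vals = self.per_subject[m].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            rows.append(
                {
                    "metric": m,
                    "mean": float(np.mean(vals[ok])) if ok.any() else float("nan"),
                    "sd": float(np.std(vals[ok], ddof=1)) if ok.sum() > 1 else float("nan"),
                    "n_subjects": int(ok.sum()),
                    "n_undefined": int((~ok).sum()),
                }
            )
        return pd.DataFrame(rows)

    def per_subject_table(self) -> pd.DataFrame:
        """Per-infant epoch count, wake prevalence, accuracy and kappa."""
        df = self.per_subject
        return df[["subject", "n_epochs", "pct_wake", "accuracy", "kappa"]].copy()

    def summary(self) -> str:
        cm = self.pooled_confusion
        agg = self.aggregate().set_index("metric")
        buf = io.StringIO()
        buf.write(f"LOOCV wake/sleep classification -- feature set: {self.feature_set}\n")
        buf.write("=" * 60 + "\n")
        buf.write("Pooled confusion (all epochs, wake positive):\n")
        buf.write(f"  TP={cm.tp}  FP={cm.fp}  FN={cm.fn}  TN={cm.tn}  (N={cm.total})\n")
        buf.write(f"Pooled AUC: {self.pooled_auc:.3f}\n")
        buf.write("Per-subject mean +/- SD:\n")
        for m in self._METRICS:
            r = agg.loc[m]
            line = f"  {m:<12s} {r['mean']:.3f} +/- {r['sd']:.3f}"
            if r["n_undefined"]:
                line += f"  ({int(r['n_undefined'])} subject(s) undefined, excluded)"
            buf.write(line + "\n")
        return buf.getvalue()


class LeaveOneSubjectOut:
    """Subject-independent cross-validation of the wake/sleep pipeline.

    Parameters
    ----------
    cohort : mapping of subject id -> recording
        Each recording exposes ``.actigraphy`` and ``.hypnogram``.
    feature_set : str or sequence of feature column names
        One of 'mact', 'pslp', 'mact+pslp', or explicit column names.
    """

    def __init__(self, cohort, feature_set="mact+pslp", *,
                 grid: EpochGrid | None = None, percentile: float = 95.0,
                 smoothing_window_min: float = 10.0, binary_mact: bool = False,
                 threshold: float = 0.5, ridge_fraction: float = 1e-6):
        if len(cohort) < 2:
            raise InvalidInputError("LOOCV needs at least 2 subjects")
        self.cohort = dict(cohort)
        if isinstance(feature_set, str):
            if feature_set not in FEATURE_SETS:
                raise InvalidInputError(
                    f"unknown feature set {feature_set!r}; choose from {sorted(FEATURE_SETS)}"
                )
            self.feature_columns = FEATURE_SETS[feature_set]
            self.feature_set_name = feature_set
        else:
            self.feature_columns = tuple(feature_set)
            self.feature_set_name = "+".join(self.feature_columns)
        self.grid = grid or EpochGrid()
        self.percentile = percentile
        self.smoothing_window_min = smoothing_window_min
        self.binary_mact = binary_mact
        self.threshold = threshold
        self.ridge_fraction = ridge_fraction

    def fit(self) -> CVReport:
        cols = list(self.feature_columns)
        tables = {
            sid: _subject_table(rec, self.grid, self.percentile,
                                self.smoothing_window_min, self.binary_mact)
            for sid, rec in self.cohort.items()
        }
        rows = []
        pooled_cm = ConfusionMatrix(0, 0, 0, 0)
        pooled_scores, pooled_truth = [], []
        subject_rocs = {}

        for sid in tables:
            train = pd.concat(
                [t for other, t in tables.items() if other != sid], ignore_index=True
            )
            train = train[train["binary"] != "excluded"]
            if train["binary"].nunique() < 2:
                raise UnderdeterminedModelError(
                    f"training fold for held-out subject {sid!r} has a single class"
                )
            res = BayesianLDA(
                train[cols].to_numpy(), train["binary"].to_numpy(),
                feature_names=tuple(cols),
            ).fit(ridge_fraction=self.ridge_fraction)

            test = tables[sid]
            test = test[test["binary"] != "excluded"]
            scores = np.atleast_1d(res.predict_proba(test[cols].to_numpy()))
            preds = np.where(scores >= self.threshold, WAKE, SLEEP)
            truth = test["binary"].to_numpy()
            cm = confusion(preds, truth)
            ms = metrics(cm)
            try:
                curve, auc_val = roc_auc(scores, truth)
                subject_rocs[sid] = curve
            except UndefinedMetricError:
                auc_val = float("nan")
            rows.append(
                {
                    "subject": sid,
                    "n_epochs": len(test),
                    "pct_wake": float(np.mean(truth == WAKE)),
                    **ms.as_dict(),
                    "auc": auc_val,
                    "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
                }
            )
            pooled_cm = pooled_cm + cm
            pooled_scores.append(scores)
            pooled_truth.append(truth)

        all_scores = np.concatenate(pooled_scores)
        all_truth = np.concatenate(pooled_truth)
        pooled_roc, pooled_auc = roc_auc(all_scores, all_truth)
        return CVReport(
            feature_set=self.feature_set_name,
            per_subject=pd.DataFrame(rows),
            pooled_confusion=pooled_cm,
            pooled_metrics=metrics(pooled_cm),
            pooled_roc=pooled_roc,
            pooled_auc=pooled_auc,
            subject_rocs=subject_rocs,
        )


def loocv(cohort, feature_set="mact+pslp", **kwargs) -> CVReport:
    """Functional wrapper around :class:`LeaveOneSubjectOut`."""
    return LeaveOneSubjectOut(cohort, feature_set, **kwargs).fit()


def compare_feature_sets(cohort, feature_sets=("mact", "pslp", "mact+pslp"),
                         **kwargs) -> tuple[pd.DataFrame, dict]:
    """Run LOOCV for several feature sets and tabulate the results side by
    side: pooled confusion cells plus per-subject mean +/- SD metrics, one
    column per feature set."""
    reports = {fs: loocv(cohort, fs, **kwargs) for fs in feature_sets}
    rows = {}
    for fs, rep in reports.items():
        cm = rep.pooled_confusion
        agg = rep.aggregate().set_index("metric")
        col = {
            "TP": cm.tp, "FP": cm.fp, "FN": cm.fn, "TN": cm.tn,
        }
        for m in ("precision", "sensitivity", "specificity", "accuracy", "kappa"):
            col[f"{m}_mean"] = agg.loc[m, "mean"]
            col[f"{m}_sd"] = agg.loc[m, "sd"]
        col["pooled_auc"] = rep.pooled_auc
        rows[fs] = col
    return pd.DataFrame(rows), reports
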