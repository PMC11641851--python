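"""ROC analysis, confusion metrics, and leave-one-out cross-validation.

The decision threshold on the discriminant score is chosen by sweeping the
midpoints between adjacent sorted unique scores (plus ±infinity sentinels)
and maximising Youden's J = sensitivity + specificity − 1.  Classification
is positive when the score is at or above the cutoff.

LOOCV refits the discriminant (and, optionally, the stepwise feature
selection) on each n−1 training fold, picks the Youden cutoff on the
training scores alone, and classifies the held-out subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discriminant import DiscriminantModel, fit_lda, stepwise_select
from .features import FeatureTable

__all__ = ["ROCResult", "ConfusionMetrics", "CVResult", "roc", "confusion", "loocv"]


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    best_cutoff: float

    @property
    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float


def _check_two_classes(labels: np.ndarray) -> None:
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValueError("both classes must be present")


def _rate(num: int, den: int) -> float:
    return num / den if den else float("nan")


def confusion(scores, labels, cutoff: float) -> ConfusionMetrics:
    """Counts and the five standard proportions at a score cutoff.

    Scores at or above the cutoff are classified positive.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_two_classes(y)
    pred = (s >= cutoff).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        accuracy=(tp + tn) / len(y),
        ppv=_rate(tp, tp + fp),
        npv=_rate(tn, tn + fn),
    )


def roc(scores, labels) -> ROCResult:
    """Threshold sweep with Youden-optimal cutoff selection.

    Candidate thresholds are the midpoints between adjacent sorted unique
    scores plus −inf/+inf sentinels.  AUC is the Mann–Whitney probability
    (ties count one half).  Youden ties are broken toward the candidate
    nearest the pooled score median.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_two_classes(y)
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    pos, neg = s[y == 1], s[y == 0]
    for i, th in enumerate(thresholds):
        sens[i] = np.mean(pos >= th)
        spec[i] = np.mean(neg < th)
    j = sens + spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    if len(best) > 1:
        med = float(np.median(s))
        finite = thresholds[best]
        dist = np.where(np.isfinite(finite), np.abs(finite - med), np.inf)
        best = best[[int(np.argmin(dist))]]
    auc = float(
        ((pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum())
        / (len(pos) * len(neg))
    )
    return ROCResult(thresholds=thresholds, sensitivity=sens, specificity=spec,
                     auc=auc, best_cutoff=float(thresholds[best[0]]))


@dataclass
class CVResult:
    """Held-out predictions (one row per subject) plus pooled metrics."""

    fold_predictions: pd.DataFrame
    metrics: ConfusionMetrics


def _prior_cutoff(train_scores: np.ndarray, y: np.ndarray) -> float:
    """Posterior-odds decision boundary with training priors.

    The fitted DS has unit pooled within-class variance, so under the
    equal-covariance normal model the boundary between the two class score
    distributions is the midpoint of the class mean scores shifted by
    ``log(prior_neg/prior_pos) / (mean_pos - mean_neg)`` — the
    classification rule of classical discriminant software, which predicts
    the majority class when the groups barely separate.
    """
    m1 = train_scores[y == 1].mean()
    m0 = train_scores[y == 0].mean()
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if m1 == m0:
        return np.inf if n0 > n1 else -np.inf
    return float((m1 + m0) / 2.0 + np.log(n0 / n1) / (m1 - m0))


def loocv(table: FeatureTable, feature_names=None, refit_selection: bool = False,
          cutoff_policy: str = "youden", **stepwise_kwargs) -> CVResult:
    """Leave-one-out cross-validation of the discriminant pipeline.

    Parameters
    ----------
    table
        Labelled feature table with n >= 6 and >= 3 subjects per class.
    feature_names
        Fixed feature subset to fit in every fold.  Required unless
        ``refit_selection`` is set.
    refit_selection
        Re-run stepwise selection inside every training fold (the fully
        honest variant); ``feature_names`` is then ignored.
    cutoff_policy
        ``"youden"`` (default) picks the Youden-optimal cutoff on the
        training scores, mirroring the ROC stage of the main pipeline;
        ``"prior"`` uses the posterior-odds boundary with training priors,
        the convention of classical discriminant software.
    """
    if cutoff_policy not in ("youden", "prior"):
        raise ValueError("cutoff_policy must be 'youden' or 'prior'")
    n_pos, n_neg = table.class_counts()
    if table.n_subjects < 6 or n_pos < 3 or n_neg < 3:
        raise ValueError("LOOCV needs n >= 6 with >= 3 subjects per class")
    if feature_names is None and not refit_selection:
        raise ValueError("either give feature_names or set refit_selection")
    rows = []
    for sid in table.data.index:
        train = table.drop_subject(sid)
        t_pos, t_neg = train.class_counts()
        if t_pos < 2 or t_neg < 2:
            raise ValueError(f"fold holding out {sid!r} loses a class")
        if refit_selection:
            sel = stepwise_select(train, **stepwise_kwargs).selected
            if not sel:
                # nothing survived entry: predict the training majority class
                rows.append({"subject_id": sid, "true": int(table.data.at[sid, "label"]),
                             "score": np.nan, "cutoff": np.nan,
                             "predicted": int(t_pos > t_neg)})
                continue
            names = sel
        else:
            names = tuple(feature_names)
        model = fit_lda(train, names)
        train_scores = model.score_table(train).to_numpy()
        if cutoff_policy == "youden":
            cut = roc(train_scores, train.labels).best_cutoff
        else:
            cut = _prior_cutoff(train_scores, train.labels)
        ds = model.score(table.data.loc[sid])
        rows.append({
            "subject_id": sid,
            "true": int(table.data.at[sid, "label"]),
            "score": ds,
            "cutoff": cut,
            "predicted": int(ds >= cut),
        })
    preds = pd.DataFrame(rows).set_index("subject_id")
    cm = _confusion_from_pred(preds["predicted"].to_numpy(), preds["true"].to_numpy())
    return CVResult(fold_predictions=preds, metrics=cm)


def _confusion_from_pred(pred: np.ndarray, y: np.ndarray) -> ConfusionMetrics:
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        accuracy=(tp + tn) / len(y),
        ppv=_rate(tp, tp + fp),
        npv=_rate(tn, tn + fn),
    )
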