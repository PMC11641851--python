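"""Two-class Fisher linear discriminant analysis with stepwise selection.

The multivariate stage builds a discriminant score (DS)

    DS = constant + sum_j  coefficient_j * feature_j,

where the coefficient vector is proportional to ``S_w^{-1} (m_pos - m_neg)``
(``S_w`` the pooled within-class covariance), scaled so the pooled
within-class variance of DS is one, and the constant centres the weighted
grand-mean DS at zero — the unstandardised canonical-coefficient
convention of classical discriminant software.  Subjects are classified
positive (pCR) when DS is at or above a decision cutoff.

Feature subsets are chosen by forward stepwise selection minimising Wilks'
lambda, with F-to-enter / F-to-remove thresholds (defaults 3.84 / 2.71).

``reference_model()`` ships a previously reported four-variable pCR model
for post-treatment rectal MRI as a worked-example fixture, together with
the group-mean feature values it is conventionally evaluated on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureTable

__all__ = [
    "DiscriminantModel",
    "fit_lda",
    "stepwise_select",
    "StepwiseResult",
    "reference_model",
    "REFERENCE_GROUP_MEANS",
]

# SPSS-style stepwise defaults
F_ENTER_DEFAULT = 3.84
F_REMOVE_DEFAULT = 2.71
_TOLERANCE_MIN = 1e-3


@dataclass
class DiscriminantModel:
    """Affine discriminant score plus a decision cutoff.

    ``positive_side`` records which side of the cutoff is called positive;
    scores exactly at the cutoff are classified positive.
    """

    feature_names: tuple[str, ...]
    coefficients: np.ndarray
    constant: float
    cutoff: float = 0.0
    positive_side: str = "above"

    def __post_init__(self) -> None:
        self.feature_names = tuple(self.feature_names)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.feature_names) != len(self.coefficients):
            raise ValueError("one coefficient per feature required")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be distinct")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")
        if self.positive_side not in ("above", "below"):
            raise ValueError("positive_side must be 'above' or 'below'")

    def score(self, fv: Mapping[str, float] | pd.Series) -> float:
        """Evaluate DS on one feature vector (affine map)."""
        vals = []
        for name in self.feature_names:
            try:
                vals.append(float(fv[name]))
            except KeyError:
                raise KeyError(f"feature vector is missing model feature {name!r}")
        return float(self.constant + self.coefficients @ np.asarray(vals))

    def score_table(self, table: FeatureTable) -> pd.Series:
        """DS for every subject in a feature table."""
        missing = [n for n in self.feature_names if n not in table.data.columns]
        if missing:
            raise KeyError(f"feature table is missing model features: {missing}")
        X = table.data[list(self.feature_names)].to_numpy(dtype=float)
        return pd.Series(self.constant + X @ self.coefficients,
                         index=table.data.index, name="DS")

    def classify(self, ds: float | np.ndarray) -> np.ndarray:
        """1 = positive (pCR) side of the cutoff, cutoff itself positive."""
        ds = np.asarray(ds, dtype=float)
        if self.positive_side == "above":
            return (ds >= self.cutoff).astype(int)
        return (ds <= self.cutoff).astype(int)

    # --- serialisation (flat JSON, full precision) -------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "coefficients": [repr(float(c)) for c in self.coefficients],
            "constant": repr(float(self.constant)),
            "cutoff": repr(float(self.cutoff)),
            "positive_side": self.positive_side,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscriminantModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=tuple(d["feature_names"]),
            coefficients=np.array([float(c) for c in d["coefficients"]]),
            constant=float(d["constant"]),
            cutoff=float(d["cutoff"]),
            positive_side=d["positive_side"],
        )


def _class_stats(table: FeatureTable, names: Sequence[str]):
    X = table.data[list(names)].to_numpy(dtype=float)
    y = table.labels
    X1, X0 = X[y == 1], X[y == 0]
    if len(X1) < 2 or len(X0) < 2:
        raise ValueError("each class needs >= 2 subjects to fit a discriminant")
    return X, y, X1, X0


def fit_lda(table: FeatureTable, feature_names: Sequence[str]) -> DiscriminantModel:
    """Fit the two-class Fisher discriminant on a feature subset.

    Raises
    ------
    ValueError
        If a class has fewer than two members, the subset is too large for
        the cohort (p must be < n - 2), or the pooled within-class
        covariance is singular (collinear features are named).
    """
    names = list(feature_names)
    if not names:
        raise ValueError("feature_names is empty")
    X, y, X1, X0 = _class_stats(table, names)
    n, p = X.shape
    if p >= n - 2:
        raise ValueError(f"{p} features for {n} subjects: need p < n - 2")
    m1, m0 = X1.mean(axis=0), X0.mean(axis=0)
    Sw = (X1 - m1).T @ (X1 - m1) + (X0 - m0).T @ (X0 - m0)
    S = Sw / (n - 2)  # pooled within-class covariance
    if np.linalg.matrix_rank(S, tol=1e-10 * max(1.0, float(np.trace(S)))) < p:
        # name the offending features via near-perfect within-class correlation
        d = np.sqrt(np.maximum(np.diag(S), 1e-300))
        C = S / np.outer(d, d)
        pairs = [
            (names[i], names[j])
            for i in range(p) for j in range(i + 1, p)
            if abs(C[i, j]) > 1 - 1e-8
        ]
        zero_var = [names[i] for i in range(p) if S[i, i] <= 0]
        raise ValueError(
            "singular pooled within-class covariance; "
            f"collinear pairs: {pairs or 'n/a'}; zero-variance: {zero_var or 'n/a'}"
        )
    v = np.linalg.solve(S, m1 - m0)
    scale = float(np.sqrt(v @ S @ v))
    w = v / scale  # pooled within-class DS variance = 1
    constant = -float(w @ X.mean(axis=0))  # weighted grand-mean DS = 0
    return DiscriminantModel(tuple(names), w, constant)


# ---------------------------------------------------------------------------
# stepwise selection by Wilks' lambda
# ---------------------------------------------------------------------------

def _wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """det(W)/det(T) for the two-group one-way layout on columns of X."""
    X1, X0 = X[y == 1], X[y == 0]
    m1, m0, mg = X1.mean(axis=0), X0.mean(axis=0), X.mean(axis=0)
    W = (X1 - m1).T @ (X1 - m1) + (X0 - m0).T @ (X0 - m0)
    T = (X - mg).T @ (X - mg)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        return np.nan
    return float(np.exp(logdet_w - logdet_t))


@dataclass
class StepwiseResult:
    selected: tuple[str, ...]
    trace: list[dict] = field(default_factory=list)


def _tolerance(X: np.ndarray, y: np.ndarray, j_new: np.ndarray,
               included: np.ndarray | None) -> float:
    """Within-groups tolerance of a candidate given the included set."""
    if included is None or included.shape[1] == 0:
        return 1.0
    # center within groups
    def center(v):
        out = v.astype(float).copy()
        for g in (0, 1):
            out[y == g] -= out[y == g].mean(axis=0)
        return out
    Z = center(included)
    z = center(j_new[:, None])[:, 0]
    denom = float(z @ z)
    if denom == 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(Z, z, rcond=None)
    resid = z - Z @ beta
    return float(resid @ resid) / denom


def stepwise_select(table: FeatureTable,
                    f_enter: float = F_ENTER_DEFAULT,
                    f_remove: float = F_REMOVE_DEFAULT,
                    max_features: int | None = None) -> StepwiseResult:
    """Forward stepwise feature selection minimising Wilks' lambda.

    At each step the candidate with the largest F-to-enter is added if it
    exceeds ``f_enter``; included variables whose F-to-remove falls below
    ``f_remove`` are then dropped.  Entry is capped at ``n - 4`` variables
    (so the final fit remains well-posed) or ``max_features``.  The
    ``trace`` records every step's candidate F values, so an empty
    selection is explainable rather than an error.
    """
    names = table.features
    X_all = table.X.to_numpy(dtype=float)
    y = table.labels
    n = len(y)
    n_pos, n_neg = table.class_counts()
    if n_pos < 4 or n_neg < 4:
        raise ValueError("stepwise selection needs >= 4 subjects per class")
    cap = min(max_features or n - 4, n - 4)
    g = 2

    included: list[int] = []
    trace: list[dict] = []

    def lam(idx: list[int]) -> float:
        if not idx:
            return 1.0
        return _wilks_lambda(X_all[:, idx], y)

    while True:
        changed = False
        p = len(included)
        # --- entry ---------------------------------------------------------
        if p < cap:
            lam_p = lam(included)
            best_j, best_f = None, -np.inf
            f_values = {}
            inc_mat = X_all[:, included] if included else None
            for j in range(X_all.shape[1]):
                if j in included:
                    continue
                if _tolerance(X_all, y, X_all[:, j], inc_mat) < _TOLERANCE_MIN:
                    continue
                lam_new = lam(included + [j])
                if not np.isfinite(lam_new) or lam_new <= 0:
                    continue
                f = (n - g - p) / (g - 1) * (lam_p / lam_new - 1.0)
                f_values[names[j]] = f
                if f > best_f:
                    best_j, best_f = j, f
            trace.append({"action": "enter-candidates", "p": p, "F": f_values})
            if best_j is not None and best_f >= f_enter:
                included.append(best_j)
                trace.append({"action": "enter", "feature": names[best_j], "F": best_f})
                changed = True
        # --- removal -------------------------------------------------------
        p = len(included)
        if p > 1:
            lam_p = lam(included)
            worst_j, worst_f = None, np.inf
            for j in included:
                reduced = [k for k in included if k != j]
                lam_red = lam(reduced)
                f = (n - g - (p - 1)) / (g - 1) * (lam_red / lam_p - 1.0)
                if f < worst_f:
                    worst_j, worst_f = j, f
            if worst_j is not None and worst_f < f_remove:
                included.remove(worst_j)
                trace.append({"action": "remove", "feature": names[worst_j], "F": worst_f})
                changed = True
        if not changed:
            break
    return StepwiseResult(selected=tuple(names[j] for j in included), trace=trace)


# ---------------------------------------------------------------------------
# published worked-example fixture
# ---------------------------------------------------------------------------

#: Group-mean feature values the reference model is evaluated on in the
#: worked example (pCR-present vs pCR-absent group means of the four
#: model features, as printed in the source report).
REFERENCE_GROUP_MEANS: dict[str, dict[str, float]] = {
    "pcr_present": {
        "db2dec2sd": 191.107,
        "bior33dec1max": 428.362,
        "bior33dec3mn": 846.84,
        "sym5dec2mn": 508.66,
    },
    "pcr_absent": {
        "db2dec2sd": 165.39,
        "bior33dec1max": 424.91,
        "bior33dec3mn": 819.92,
        "sym5dec2mn": 516.83,
    },
}


def reference_model() -> DiscriminantModel:
    """The previously reported four-variable pCR discriminant model.

    Coefficients, constant and ROC-optimal cutoff are taken at full printed
    precision.  Note the sign convention: the ``sym5dec2mn`` coefficient is
    negative as in the published score formula (the accompanying
    coefficient table reports its magnitude with a positive sign; only the
    negative sign places the two group-mean scores on opposite sides of the
    published cutoff, so the formula's sign is authoritative here).
    """
    return DiscriminantModel(
        feature_names=("db2dec2sd", "bior33dec1max", "bior33dec3mn", "sym5dec2mn"),
        coefficients=np.array([0.2456044, 1.1709781, 0.0399379, -0.0691719]),
        constant=-541.1768021,
        cutoff=-0.6299,
        positive_side="above",
    )
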