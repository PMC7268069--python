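"""ROC diagnostics with DeLong confidence intervals and Youden cutoffs.

Univariate ROC on a concentration measure (disease marked by *lower* values,
matching glutathione depletion: scores are negated internally when the
positive class has the lower mean so AUC >= 0.5 and the reported cutoff stays
in concentration units), and multivariate ROC on the predicted probabilities
of a binary logistic regression over two regional measures plus age and sex.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = ["RocResult", "roc_univariate", "roc_multivariate"]


@dataclass
class RocResult:
    """AUC, DeLong 95% CI and Youden-optimal operating point.

    ``youden_cutoff`` is a threshold in the units of the input scores;
    ``direction`` says which side of it is called diseased.  ``youden_j`` is
    the J statistic (sensitivity + specificity - 1) at that cutoff; both are
    reported because published "Youden index" columns sometimes print the
    cutoff value rather than J.  Sensitivity/specificity/accuracy are in %.
    """

    auc: float
    auc_ci_95: tuple[float, float]
    auc_se: float
    p_value: float
    youden_cutoff: float
    youden_j: float
    direction: str  # "<=" (low score = disease) or ">=" (high score = disease)
    sensitivity: float
    specificity: float
    accuracy: float
    n_negative: int
    n_positive: int
    flags: list = field(default_factory=list)


def _auc_and_delong(neg: np.ndarray, pos: np.ndarray) -> tuple[float, float]:
    """AUC (Mann-Whitney with half-weight ties) + DeLong variance.

    Structural components: V10[i] = mean_j psi(pos_i, neg_j),
    V01[j] = mean_i psi(pos_i, neg_j) with psi = 1, 1/2, 0 for pos > = < neg;
    var(AUC) = S10/m + S01/n with sample variances of the components.
    Convention: higher score indicates the positive class.
    """
    m, n = len(pos), len(neg)
    psi = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    return auc, var


def roc_univariate(scores, labels, positive_label=None) -> RocResult:
    """Empirical ROC of a single score with DeLong CI and Youden cutoff.

    ``labels`` may be boolean (True = diseased) or any 2-level vector with
    ``positive_label`` naming the disease class.  The Youden criterion
    maximizes sensitivity + specificity - 1 over the observed score values;
    ties are broken toward higher specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if positive_label is None:
        uniq = np.unique(labels)
        if set(uniq.tolist()) <= {0, 1, True, False}:
            positive = labels.astype(bool)
        elif len(uniq) == 2:
            raise ValueError("positive_label required for non-boolean labels")
        else:
            raise ValueError("labels must be binary")
    else:
        positive = labels == positive_label
    pos = scores[positive]
    neg = scores[~positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")

    flags = []
    # orient so AUC >= 0.5: negate when the disease class scores lower
    flip = pos.mean() < neg.mean()
    s_pos, s_neg = (-pos, -neg) if flip else (pos, neg)
    auc, var = _auc_and_delong(s_neg, s_pos)
    se = math.sqrt(var)
    if se > 0:
        z = (auc - 0.5) / se
        p = 2.0 * float(sps.norm.sf(abs(z)))
        ci = (max(0.0, auc - 1.959963984540054 * se),
              min(1.0, auc + 1.959963984540054 * se))
    else:
        p = 0.0 if auc != 0.5 else 1.0
        ci = (auc, auc)
        flags.append("degenerate_variance")

    # Youden scan in oriented space: disease called when oriented score >= cutoff
    cands = np.unique(np.concatenate([s_pos, s_neg]))
    best = None
    for c in cands:
        sens = float(np.mean(s_pos >= c))
        spec = float(np.mean(s_neg < c))
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    (_, _), cutoff, sens, spec = best[0], best[1], best[2], best[3]
    n_pos, n_neg = len(pos), len(neg)
    accuracy = (sens * n_pos + spec * n_neg) / (n_pos + n_neg)

    if flip:
        direction = "<="
        cutoff = -cutoff  # back to concentration units: disease if value <= cutoff
    else:
        direction = ">="
    return RocResult(
        auc=auc, auc_ci_95=ci, auc_se=se, p_value=p,
        youden_cutoff=float(cutoff), youden_j=float(sens + spec - 1.0),
        direction=direction,
        sensitivity=100.0 * sens, specificity=100.0 * spec,
        accuracy=100.0 * accuracy, n_negative=n_neg, n_positive=n_pos,
        flags=flags)


def roc_multivariate(features, labels, positive_label=None,
                     maxiter: int = 50, tol: float = 1e-8
                     ) -> tuple[RocResult, pd.Series]:
    """Binary logistic regression, then ROC on the predicted probabilities.

    ``features`` is a DataFrame (or 2-D array) of complete cases, e.g. the
    ACC and PCC concentrations plus age and numeric sex.  Fitting is
    maximum-likelihood IRLS; complete separation is detected (all fitted
    probabilities at 0/1) and flagged instead of left to diverge silently.
    Returns (RocResult, fitted coefficients).
    """
    X = pd.DataFrame(features).copy()
    for col in X.columns:
        if not np.issubdtype(X[col].dtype, np.number):
            levels = sorted(X[col].unique())
            if len(levels) > 2:
                raise ValueError(f"non-numeric feature {col!r} with > 2 levels")
            X[col] = (X[col] == levels[-1]).astype(float)
    labels = np.asarray(labels)
    if positive_label is not None:
        y = (labels == positive_label).astype(float)
    else:
        y = labels.astype(float)
    if X.isna().any().any() or np.isnan(y).any():
        raise ValueError("complete cases required")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    Xc = sm.add_constant(X.astype(float), has_constant="add")
    flags = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, Xc, family=sm.families.Binomial())
        fit = model.fit(maxiter=maxiter, tol=tol)
    probs = np.asarray(fit.fittedvalues)
    eps = 1e-8
    if np.all((probs < eps) | (probs > 1 - eps)):
        flags.append("complete_separation")
    roc = roc_univariate(probs, y.astype(bool))
    roc.flags = list(dict.fromkeys(roc.flags + flags))
    coefs = pd.Series(np.asarray(fit.params), index=Xc.columns)
    return roc, coefs
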