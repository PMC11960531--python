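"""Statistical layer: correlations, per-position group contrasts, linear
SVM separation, regularized feature ranking, and seed-region base
composition.

IC50 values censored at the assay limit never enter correlations or
regressions; they participate only in activity classification.  All
results carry their sample sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.linear_model import RidgeCV
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .dataset import DuplexPair, ModifiedStrand, classify_activity

__all__ = [
    "CorrelationResult",
    "pearson_with_p",
    "group_contrast",
    "linear_svm_separator",
    "feature_ranking",
    "seed_composition",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    subset: str = "all"


def pearson_with_p(x, y, subset: str = "all") -> CorrelationResult:
    """Sample Pearson r with the two-sided t-transform p-value.

    p comes from t = r sqrt((n-2)/(1-r^2)) against Student's t with
    n-2 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, p=p, n=n, subset=subset)


def group_contrast(values: np.ndarray, labels: np.ndarray) -> list[dict]:
    """Per-position Welch contrast between active and inactive groups.

    ``values`` is (n_samples, n_positions); ``labels`` holds
    "active"/"inactive" per sample.  Returns one record per position
    with group means/SDs, Cohen's d (pooled SD), raw Welch p, and
    Benjamini-Hochberg adjusted p, ranked by |d| descending.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    a = values[labels == "active"]
    b = values[labels == "inactive"]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    records = []
    raw_p = []
    for j in range(values.shape[1]):
        xa, xb = a[:, j], b[:, j]
        ma, mb = float(xa.mean()), float(xb.mean())
        sa = float(xa.std(ddof=1)) if len(xa) > 1 else 0.0
        sb = float(xb.std(ddof=1)) if len(xb) > 1 else 0.0
        if len(xa) > 1 and len(xb) > 1:
            pooled = np.sqrt(
                ((len(xa) - 1) * sa**2 + (len(xb) - 1) * sb**2)
                / (len(xa) + len(xb) - 2)
            )
            d = (ma - mb) / pooled if pooled > 0 else 0.0
            if np.allclose(xa, xa[0]) and np.allclose(xb, xb[0]) and np.isclose(xa[0], xb[0]):
                p = 1.0
            else:
                p = float(sps.ttest_ind(xa, xb, equal_var=False).pvalue)
                if np.isnan(p):
                    p = 1.0
        else:
            d = np.nan if (sa == 0 and sb == 0) else (ma - mb) / max(sa, sb)
            p = np.nan  # unavailable for singleton groups
        records.append(
            {
                "position": j + 1,
                "mean_active": ma,
                "sd_active": sa,
                "n_active": len(xa),
                "mean_inactive": mb,
                "sd_inactive": sb,
                "n_inactive": len(xb),
                "cohen_d": float(d),
                "p_raw": p,
            }
        )
        raw_p.append(p)
    raw = np.array(raw_p, float)
    finite = np.isfinite(raw)
    adj = np.full_like(raw, np.nan)
    if finite.any():
        adj[finite] = multipletests(raw[finite], method="fdr_bh")[1]
    for rec, pa in zip(records, adj):
        rec["p_bh"] = float(pa) if np.isfinite(pa) else np.nan
    records.sort(key=lambda r: -abs(r["cohen_d"]) if np.isfinite(r["cohen_d"]) else 0.0)
    return records


def linear_svm_separator(X: np.ndarray, labels: np.ndarray, C: float = 1.0) -> dict:
    """Soft-margin linear SVM separating active from inactive points.

    Returns weights, bias, geometric half-margin 1/||w||, training
    accuracy, and a ``separable`` flag (training accuracy == 1).
    """
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    y = np.where(labels == "active", 1, -1)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least one point per class")
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    w = clf.coef_[0]
    b = float(clf.intercept_[0])
    acc = float(clf.score(X, y))
    margin = 1.0 / np.linalg.norm(w) if np.linalg.norm(w) > 0 else np.inf
    return {
        "weights": w,
        "bias": b,
        "margin": float(margin),
        "accuracy": acc,
        "separable": acc == 1.0,
        "predict": lambda pts: clf.predict(np.atleast_2d(pts)),
    }


def feature_ranking(
    features: dict[str, np.ndarray] | np.ndarray,
    response: np.ndarray,
    feature_names: list[str] | None = None,
    alphas: np.ndarray | None = None,
) -> dict:
    """Ridge-regularized linear fit ranking features by |standardized weight|.

    Features are standardized internally; the penalty is chosen by
    leave-one-out cross-validation.  Zero-variance features are dropped
    with a warning.  Rank ties break by column order.
    """
    if isinstance(features, dict):
        feature_names = list(features)
        X = np.column_stack([features[k] for k in feature_names])
    else:
        X = np.asarray(features, float)
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(X.shape[1])]
    y = np.asarray(response, float)
    keep = np.flatnonzero(~np.isnan(y))
    if len(keep) < max(2, len(y) - len(keep)):
        raise ValueError("more censored/missing responses than usable rows")
    X, y = X[keep], y[keep]
    sd = X.std(axis=0)
    usable = sd > 0
    if not usable.all():
        dropped = [feature_names[j] for j in np.flatnonzero(~usable)]
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
    X = X[:, usable]
    kept_names = [n for n, u in zip(feature_names, usable) if u]
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    ys = y - y.mean()
    if alphas is None:
        alphas = np.logspace(-3, 3, 25)
    model = RidgeCV(alphas=alphas, store_cv_results=True)  # efficient LOO-CV
    model.fit(Xs, ys)
    coefs = model.coef_
    # round away float noise so exact duplicates tie-break by column order
    order = sorted(range(len(kept_names)), key=lambda j: (-round(abs(coefs[j]), 10), j))
    cv_err = float(model.cv_results_.mean(axis=0)[np.argmin(model.cv_results_.mean(axis=0))])
    return {
        "ranking": [kept_names[j] for j in order],
        "weights": {kept_names[j]: float(coefs[j]) for j in range(len(kept_names))},
        "alpha": float(model.alpha_),
        "cv_error": cv_err,
        "n": len(y),
    }


def seed_composition(
    pairs: list[DuplexPair],
    positions: range = range(2, 9),
) -> dict[int, dict[str, dict[str, int]]]:
    """Guide-strand base tallies over seed positions by activity group.

    Returns {position: {"active": {base: count}, "inactive": {...},
    "au_fraction": {"active": f, "inactive": f}}} for the modified
    duplexes of the given pairs.
    """
    out: dict[int, dict] = {}
    labelled: list[tuple[ModifiedStrand, str]] = [
        (p.modified.guide, classify_activity(p).label) for p in pairs
    ]
    for pos in positions:
        tally = {"active": {b: 0 for b in "ACGU"}, "inactive": {b: 0 for b in "ACGU"}}
        for guide, label in labelled:
            tally[label][guide.residues[pos - 1].base] += 1
        au_frac = {}
        for grp in ("active", "inactive"):
            tot = sum(tally[grp].values())
            au = tally[grp]["A"] + tally[grp]["U"]
            au_frac[grp] = au / tot if tot else np.nan
        out[pos] = {**tally, "au_fraction": au_frac}
    return out
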