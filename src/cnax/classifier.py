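"""Logistic signature model over candidate-gene expression.

The model is a plain maximum-likelihood logistic regression (optionally
with a small ridge penalty on the gene coefficients to stabilize separable
fits). The linear score intercept + sum(coef * log2 expression) is
thresholded at exactly 0: positive scores are called "IBC-like" (class 1),
non-positive "nIBC-like" (class 0). Robustness is assessed by
leave-one-out cross-validation; application to an external cohort first
collapses multiple probes per gene by the highest within-dataset variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = ["SignatureModel", "fit_signature", "loocv_accuracy", "apply_signature"]

COEF_CAP = 30.0  # |coefficient| beyond this flags (near-)perfect separation


@dataclass
class SignatureModel:
    genes: list[str]
    intercept: float
    coefficients: np.ndarray
    ridge: float
    converged: bool = True
    metadata: dict = field(default_factory=dict)

    def score(self, expression: pd.DataFrame) -> pd.Series:
        """Linear score per sample; ``expression``: samples x genes."""
        x = expression[self.genes].to_numpy(dtype=float)
        return pd.Series(self.intercept + x @ self.coefficients, index=expression.index)

    def predict(self, expression: pd.DataFrame) -> pd.Series:
        """Class per sample: 1 ("IBC-like") iff score > 0."""
        return (self.score(expression) > 0).astype(int)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"term": "(intercept)", "coefficient": self.intercept}]
        rows += [
            {"term": g, "coefficient": float(c)} for g, c in zip(self.genes, self.coefficients)
        ]
        return pd.DataFrame(rows)


def _neg_log_lik(beta: np.ndarray, x: np.ndarray, y: np.ndarray, ridge: float):
    z = beta[0] + x @ beta[1:]
    # log(1 + e^z) computed stably
    nll = np.sum(np.logaddexp(0.0, z) - y * z)
    nll += 0.5 * ridge * np.dot(beta[1:], beta[1:])
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
    grad = np.empty_like(beta)
    resid = p - y
    grad[0] = resid.sum()
    grad[1:] = x.T @ resid + ridge * beta[1:]
    return nll, grad


def fit_signature(
    expression: pd.DataFrame,
    labels: np.ndarray,
    ridge: float = 1e-3,
    max_iter: int = 500,
) -> SignatureModel:
    """Fit the logistic signature; ``expression``: samples x genes,
    ``labels``: 0/1 per sample (1 = IBC). Deterministic given inputs.

    With ridge = 0 on linearly separable data the likelihood has no finite
    maximizer; the optimizer stops at capped coefficients and the model is
    flagged unconverged with a warning.
    """
    x = expression.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("labels must align with expression rows")
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least two samples in each class")
    beta0 = np.zeros(x.shape[1] + 1)
    res = minimize(
        _neg_log_lik,
        beta0,
        args=(x, y, ridge),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    beta = res.x
    converged = bool(res.success)
    if ridge == 0.0:
        z = beta[0] + x @ beta[1:]
        if np.all((z > 0) == (y == 1)) and np.all(z != 0):
            # perfect separation: the unpenalized likelihood has no finite
            # maximizer, so the optimizer's stopping point is arbitrary
            warnings.warn(
                "perfect separation with ridge=0: coefficients capped at "
                f"{COEF_CAP}; consider a small ridge penalty"
            )
            beta = np.clip(beta, -COEF_CAP, COEF_CAP)
            converged = False
    if np.any(np.abs(beta[1:]) > COEF_CAP):
        warnings.warn(
            "coefficients exceed the separation cap; data may be perfectly "
            "separable -- capping"
        )
        beta = np.clip(beta, -COEF_CAP, COEF_CAP)
        converged = False
    return SignatureModel(
        genes=list(expression.columns),
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        ridge=ridge,
        converged=converged,
        metadata={"n_samples": int(len(y)), "n_positive": int(y.sum())},
    )


def loocv_accuracy(
    expression: pd.DataFrame, labels: np.ndarray, ridge: float = 1e-3
) -> tuple[float, pd.DataFrame]:
    """Leave-one-out cross-validation of the signature.

    Each sample is predicted by a model fit on all others. Returns
    (accuracy percentage, per-sample frame with score/prediction/truth).
    """
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("each class needs >= 2 samples for leave-one-out folds")
    preds = np.empty(n, dtype=int)
    scores = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = fit_signature(expression.iloc[mask], y[mask], ridge=ridge)
        s = float(model.score(expression.iloc[[i]]).iloc[0])
        scores[i] = s
        preds[i] = int(s > 0)
        mask[i] = True
    acc = 100.0 * float((preds == y).mean())
    detail = pd.DataFrame(
        {"score": scores, "predicted": preds, "label": y}, index=expression.index
    )
    return acc, detail


def apply_signature(
    model: SignatureModel,
    expression: pd.DataFrame,
    probe_to_gene: pd.Series | None = None,
    min_mapped: float = 0.70,
) -> pd.DataFrame:
    """Apply the signature to an external cohort.

    ``expression``: samples x probes (or samples x genes when
    ``probe_to_gene`` is None). When several probes map to one model gene,
    the probe with the highest variance within this dataset represents it.
    Refuses to classify when fewer than ``min_mapped`` of the model genes
    are available; classifies on the mapped subset (with a warning) above
    that floor. Returns a frame (score, predicted) per sample.
    """
    if probe_to_gene is not None:
        var = expression.var(axis=0, ddof=1)
        cols = {}
        for gene, group in probe_to_gene.groupby(probe_to_gene):
            probes = [p for p in group.index if p in expression.columns]
            if not probes:
                continue
            best = sorted(probes, key=lambda p: (-var[p], p))[0]
            cols[str(gene)] = expression[best]
        mapped = pd.DataFrame(cols, index=expression.index)
    else:
        mapped = expression
    available = [g for g in model.genes if g in mapped.columns]
    frac = len(available) / len(model.genes)
    if frac < min_mapped:
        raise ValueError(
            f"only {len(available)}/{len(model.genes)} model genes mappable "
            f"({100 * frac:.0f}% < {100 * min_mapped:.0f}%); refusing to classify"
        )
    if len(available) < len(model.genes):
        warnings.warn(
            f"applying model on {len(available)} of {len(model.genes)} genes"
        )
    keep = [i for i, g in enumerate(model.genes) if g in mapped.columns]
    sub = SignatureModel(
        genes=[model.genes[i] for i in keep],
        intercept=model.intercept,
        coefficients=model.coefficients[keep],
        ridge=model.ridge,
        converged=model.converged,
    )
    scores = sub.score(mapped)
    return pd.DataFrame({"score": scores, "predicted": (scores > 0).astype(int)})
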