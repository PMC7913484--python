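"""Canonical linear discriminant analysis with Wilks' lambda diagnostics.

Fits the generalized eigenproblem of between-group vs pooled within-group
scatter, scales axes so canonical scores have unit pooled within-group
variance, and reports the per-function diagnostics used in classical
statistical packages: eigenvalue, relative percentage, canonical
correlation, Wilks' lambda chain, Bartlett chi-square, degrees of freedom
and p-value. Classification is nearest group centroid in canonical space
with a log-prior adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy import stats as sps


class DiscriminantError(ValueError):
    """Degenerate grouping or singular scatter without fallback."""


@dataclass
class DiscriminantModel:
    variables: list[str]
    groups: list[str]
    eigenvalues: np.ndarray          # (m,), descending, m = min(g-1, p)
    axes: np.ndarray                 # (p, m) discriminant axes
    x_mean: np.ndarray               # (p,) grand mean
    centroids: np.ndarray            # (g, m) group centroids in canonical space
    priors: np.ndarray               # (g,)
    n_samples: int
    group_sizes: np.ndarray

    @property
    def n_functions(self) -> int:
        return self.eigenvalues.size

    def canonical_scores(self, features: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(features) - self.x_mean) @ self.axes


@dataclass
class FunctionDiagnostics:
    k: int
    eigenvalue: float
    relative_pct: float
    canonical_correlation: float
    wilks_lambda: float
    chi_square: float
    df: int
    p_value: float


@dataclass
class ConfusionReport:
    groups: list[str]
    matrix: np.ndarray               # (g, g) counts, rows = true
    row_pcts: np.ndarray
    per_class_correct_pct: np.ndarray
    overall_correct_pct: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, index=self.groups, columns=self.groups)
        df.insert(0, "N", self.matrix.sum(axis=1))
        return df


def _as_features(features, variables=None):
    if isinstance(features, pd.DataFrame):
        if variables is not None:
            missing = [v for v in variables if v not in features.columns]
            if missing:
                raise DiscriminantError(f"missing variables: {missing}")
            features = features[list(variables)]
        return features.to_numpy(dtype=float), list(features.columns)
    x = np.atleast_2d(np.asarray(features, float))
    names = (list(variables) if variables is not None
             else [f"x{i}" for i in range(x.shape[1])])
    return x, names


def fit_lda(features, labels, priors: str | np.ndarray = "proportional",
            ridge: float | None = None) -> DiscriminantModel:
    """Canonical LDA of groups on features.

    ``priors`` is ``"proportional"`` (group sizes), ``"equal"``, or an
    explicit vector over the sorted group labels. A singular pooled
    within-group scatter raises unless ``ridge`` is given, in which case
    ``ridge * trace/p`` is added to the diagonal (with a warning).
    """
    x, names = _as_features(features)
    labels = np.asarray(labels)
    n, p = x.shape
    if labels.size != n:
        raise DiscriminantError("labels length does not match feature rows")
    groups = sorted(set(labels.tolist()))
    g = len(groups)
    if g < 2:
        raise DiscriminantError("need at least 2 groups")
    sizes = np.array([int(np.sum(labels == grp)) for grp in groups])
    if np.any(sizes < 2):
        bad = groups[int(np.argmin(sizes))]
        raise DiscriminantError(f"group {bad!r} has fewer than 2 samples")

    grand = x.mean(axis=0)
    within = np.zeros((p, p))
    between = np.zeros((p, p))
    means = np.zeros((g, p))
    for i, grp in enumerate(groups):
        xg = x[labels == grp]
        means[i] = xg.mean(axis=0)
        dev = xg - means[i]
        within += dev.T @ dev
        dm = means[i] - grand
        between += sizes[i] * np.outer(dm, dm)

    # pooled within-group SSCP may be singular under exact collinearity
    cond = np.linalg.cond(within)
    if not np.isfinite(cond) or cond > 1e12:
        if ridge is None:
            raise DiscriminantError(
                "singular pooled within-group scatter (collinear variables); "
                "pass ridge=1e-8 to regularize")
        warnings.warn("within-group scatter near-singular; applying ridge",
                      RuntimeWarning, stacklevel=2)
        within = within + ridge * (np.trace(within) / p) * np.eye(p)

    m = min(g - 1, p)
    evals, evecs = linalg.eigh(between, within)
    order = np.argsort(evals)[::-1][:m]
    eigenvalues = np.clip(evals[order], 0.0, None)
    axes = evecs[:, order]
    # eigh(b=within) normalizes a' W a = 1; rescale so that the pooled
    # within-group covariance (W / (n - g)) of canonical scores is identity
    axes = axes * math.sqrt(n - g)
    # deterministic sign: largest-|coefficient| entry positive
    for j in range(axes.shape[1]):
        lead = np.argmax(np.abs(axes[:, j]))
        if axes[lead, j] < 0:
            axes[:, j] = -axes[:, j]

    if isinstance(priors, str):
        if priors == "proportional":
            pri = sizes / n
        elif priors == "equal":
            pri = np.full(g, 1.0 / g)
        else:
            raise DiscriminantError(f"unknown priors {priors!r}")
    else:
        pri = np.asarray(priors, float)
        if pri.shape != (g,) or np.any(pri < 0):
            raise DiscriminantError("priors must be a non-negative g-vector")
        pri = pri / pri.sum()

    centroids = (means - grand) @ axes
    return DiscriminantModel(
        variables=names, groups=[str(grp) for grp in groups],
        eigenvalues=eigenvalues, axes=axes, x_mean=grand,
        centroids=centroids, priors=pri, n_samples=n, group_sizes=sizes,
    )


def diagnostics_from_eigenvalues(eigenvalues, n_samples: int,
                                 n_predictors: int,
                                 n_groups: int) -> list[FunctionDiagnostics]:
    """Per-function diagnostics from canonical eigenvalues alone.

    For function k (1-based): relative % = lambda_k / sum(lambda) * 100;
    canonical correlation = sqrt(lambda_k / (1 + lambda_k));
    Wilks' lambda_k = prod_{i>=k} 1/(1+lambda_i);
    Bartlett chi-square = -(N - 1 - (p + g)/2) * ln(lambda_k);
    df_k = (p - k + 1)(g - k).
    """
    lam = np.asarray(eigenvalues, float).ravel()
    total = float(lam.sum())
    mult = n_samples - 1 - (n_predictors + n_groups) / 2.0
    out = []
    for k in range(1, lam.size + 1):
        wilks = float(np.prod(1.0 / (1.0 + lam[k - 1:])))
        chi2 = -mult * math.log(wilks) if wilks > 0 else math.inf
        df = (n_predictors - k + 1) * (n_groups - k)
        p_val = float(sps.chi2.sf(chi2, df)) if math.isfinite(chi2) else 0.0
        out.append(FunctionDiagnostics(
            k=k,
            eigenvalue=float(lam[k - 1]),
            relative_pct=float(lam[k - 1] / total * 100.0) if total > 0 else 0.0,
            canonical_correlation=math.sqrt(lam[k - 1] / (1.0 + lam[k - 1])),
            wilks_lambda=wilks,
            chi_square=chi2,
            df=df,
            p_value=p_val,
        ))
    return out


def function_diagnostics(model: DiscriminantModel) -> list[FunctionDiagnostics]:
    return diagnostics_from_eigenvalues(
        model.eigenvalues, model.n_samples, len(model.variables),
        len(model.groups))


def diagnostics_frame(diags: list[FunctionDiagnostics]) -> pd.DataFrame:
    return pd.DataFrame([{
        "Discriminant Function": d.k,
        "Eigenvalue": d.eigenvalue,
        "Relative Percentage": d.relative_pct,
        "Canonical Correlation": d.canonical_correlation,
        "Wilks Lambda": d.wilks_lambda,
        "Chi-Square": d.chi_square,
        "DF": d.df,
        "p": d.p_value,
    } for d in diags])


def classify(model: DiscriminantModel, features):
    """Assign each sample to the nearest group centroid in canonical space,
    penalized by -2 ln(prior). Ties break by group order."""
    x, names = _as_features(features, model.variables)
    if x.shape[1] != len(model.variables):
        raise DiscriminantError(
            f"expected {len(model.variables)} variables, got {x.shape[1]}")
    scores = model.canonical_scores(x)
    with np.errstate(divide="ignore"):
        penalty = -2.0 * np.log(model.priors)
    d2 = ((scores[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    crit = d2 + penalty[None, :]
    idx = np.argmin(crit, axis=1)  # argmin takes the first minimum: group order
    labels = np.array(model.groups, dtype=object)[idx]
    return labels, scores


def confusion_report(true_labels, predicted_labels,
                     groups: list[str] | None = None) -> ConfusionReport:
    true_labels = np.asarray(true_labels, dtype=object)
    predicted_labels = np.asarray(predicted_labels, dtype=object)
    if true_labels.size != predicted_labels.size:
        raise DiscriminantError("label vectors differ in length")
    if groups is None:
        groups = sorted(set(true_labels.tolist()))
    unknown = set(predicted_labels.tolist()) - set(groups)
    if unknown:
        raise DiscriminantError(f"predicted labels outside class set: {unknown}")
    g = len(groups)
    pos = {grp: i for i, grp in enumerate(groups)}
    matrix = np.zeros((g, g), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        matrix[pos[t], pos[p]] += 1
    row_sums = matrix.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_pcts = np.where(row_sums[:, None] > 0,
                            matrix / row_sums[:, None] * 100.0, 0.0)
    per_class = np.where(row_sums > 0, np.diag(matrix) / np.maximum(row_sums, 1)
                         * 100.0, 0.0)
    overall = 100.0 * np.trace(matrix) / true_labels.size
    return ConfusionReport([str(grp) for grp in groups], matrix, row_pcts,
                           per_class, overall)
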