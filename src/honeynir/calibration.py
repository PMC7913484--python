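"""Chemometric calibration: PCA outlier screening, modified PLS regression,
grouped cross-validation, chemical-outlier elimination and the standard
calibration / external-validation statistics (SEC, RSQ, SECV, RPD, SEP...).

The "modified" PLS (MPLS) variant re-standardizes the X and y residuals
after each extracted factor (Shenk–Westerhaus modification); with the
modification disabled the algorithm is textbook NIPALS PLS1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .preprocess import MathTreatment, apply_treatment
from .spectra import SpectraSet


class CalibrationError(ValueError):
    """Degenerate input or invalid calibration request."""


# ---------------------------------------------------------------------------
# PCA + Mahalanobis H screening
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    n_components: int
    mean: np.ndarray                 # (channels,)
    loadings: np.ndarray             # (channels, components), orthonormal
    scores: np.ndarray               # (samples, components)
    explained_variance_pct: np.ndarray  # cumulative %, (components,)
    singular_values: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(x) - self.mean) @ self.loadings


@dataclass
class HScreenResult:
    h_values: np.ndarray
    threshold: float
    outlier_idx: np.ndarray  # positions with H > threshold

    @property
    def retained_idx(self) -> np.ndarray:
        mask = np.ones(self.h_values.size, dtype=bool)
        mask[self.outlier_idx] = False
        return np.flatnonzero(mask)


def fit_pca(x: np.ndarray, n_components: int) -> PCAModel:
    """Principal components of mean-centred rows via SVD."""
    x = np.atleast_2d(np.asarray(x, float))
    n = x.shape[0]
    if n < 2:
        raise CalibrationError("PCA needs at least 2 samples")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = s[0] * max(xc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if n_components > rank:
        raise CalibrationError(
            f"n_components={n_components} exceeds data rank {rank}")
    total = float(np.sum(s ** 2))
    cum = np.cumsum(s[:n_components] ** 2) / total * 100.0
    return PCAModel(
        n_components=n_components,
        mean=mean,
        loadings=vt[:n_components].T,
        scores=u[:, :n_components] * s[:n_components],
        explained_variance_pct=cum,
        singular_values=s[:n_components],
    )


def screen_h(pca: PCAModel, threshold: float = 3.0) -> HScreenResult:
    """Flag spectral outliers by the H statistic.

    H_i is the squared Mahalanobis distance of sample i in score space
    (each component standardized by its score variance) divided by the
    number of components; H > threshold flags the sample.
    """
    scores = pca.scores
    k = pca.n_components
    var = scores.var(axis=0, ddof=1)
    if np.any(var <= 0):
        raise CalibrationError(
            "singular score covariance; reduce n_components")
    d2 = np.sum(scores ** 2 / var, axis=1)
    h = d2 / k
    return HScreenResult(h, threshold, np.flatnonzero(h > threshold))


# ---------------------------------------------------------------------------
# Modified PLS (PLS1)
# ---------------------------------------------------------------------------

@dataclass
class CalibrationModel:
    """Fitted (M)PLS regression for one physicochemical parameter."""

    parameter: str
    treatment: MathTreatment | None
    n_factors: int
    modified: bool
    x_mean: np.ndarray
    y_mean: float
    coefficients: np.ndarray     # per-channel weights on centred X
    coef_path: np.ndarray        # (channels, n_factors): coefficients after k+1 factors
    retained_ids: list[str] = field(default_factory=list)
    msc_reference: np.ndarray | None = None  # fixed MSC reference, raw channels

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coefficients)

    def predict(self, x: np.ndarray, n_factors: int | None = None) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        coef = (self.coefficients if n_factors is None
                else self.coef_path[:, n_factors - 1])
        return self.y_mean + (x - self.x_mean) @ coef


def fit_mpls(x: np.ndarray, y: np.ndarray, n_factors: int,
             modified: bool = True, parameter: str = "",
             treatment: MathTreatment | None = None) -> CalibrationModel:
    """NIPALS PLS1 with optional per-factor residual re-standardization.

    When ``modified`` is true, after each factor the X-residual columns and
    the y residual are divided by their standard deviations before the next
    factor is computed; the scalings are folded into the returned linear
    coefficients so prediction is a single dot product, exact by linearity.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.asarray(y, float).ravel()
    n, p = x.shape
    if y.size != n:
        raise CalibrationError("X and y sample counts differ")
    if n_factors < 1:
        raise CalibrationError("n_factors must be >= 1")
    if n_factors > min(n - 1, p):
        raise CalibrationError(
            f"n_factors={n_factors} exceeds min(samples-1, channels)="
            f"{min(n - 1, p)}")
    if np.std(y) == 0:
        raise CalibrationError("zero-variance reference values")

    x_mean = x.mean(axis=0)
    y_mean = float(y.mean())
    xr = x - x_mean
    yr = y - y_mean

    coef = np.zeros(p)
    coef_path = np.zeros((p, n_factors))
    basis = np.eye(p)       # maps centred original X to current residual space
    y_scale = 1.0           # cumulative y rescaling factor (original units)
    eps = np.finfo(float).eps

    for k in range(n_factors):
        if modified and k > 0:
            sx = xr.std(axis=0, ddof=1)
            sx[sx < eps] = 1.0
            sy = yr.std(ddof=1)
            sy = sy if sy > eps else 1.0
            xr = xr / sx
            yr = yr / sy
            basis = basis / sx          # column-wise
            y_scale *= sy
        w = xr.T @ yr
        wn = np.linalg.norm(w)
        if wn < eps:
            coef_path[:, k:] = coef[:, None]
            break
        w /= wn
        t = xr @ w
        tt = float(t @ t)
        if tt < eps:
            coef_path[:, k:] = coef[:, None]
            break
        p_load = xr.T @ t / tt
        q = float(yr @ t) / tt
        xr = xr - np.outer(t, p_load)
        yr = yr - q * t
        w_eff = basis @ w
        coef = coef + y_scale * q * w_eff
        basis = basis - np.outer(w_eff, p_load)
        coef_path[:, k] = coef

    return CalibrationModel(
        parameter=parameter, treatment=treatment, n_factors=n_factors,
        modified=modified, x_mean=x_mean, y_mean=y_mean,
        coefficients=coef, coef_path=coef_path,
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    factor_counts: np.ndarray
    secv: np.ndarray          # per factor count, sqrt(sum e^2 / N)
    rmsecv: np.ndarray        # alias scale of secv (identical definition)
    y_cv: np.ndarray          # (samples, max_factors) out-of-fold predictions
    folds: list[np.ndarray]

    def best_factors(self, parsimony_tol: float = 0.0) -> int:
        """Factor count with minimum SECV; with a tolerance, the smallest
        count whose SECV is within ``parsimony_tol`` (relative) of the min."""
        best = float(np.min(self.secv))
        if parsimony_tol > 0:
            ok = np.flatnonzero(self.secv <= best * (1 + parsimony_tol))
            return int(self.factor_counts[ok[0]])
        return int(self.factor_counts[int(np.argmin(self.secv))])


def make_folds(n: int, n_groups: int, seed) -> list[np.ndarray]:
    if n_groups < 2 or n_groups > n:
        raise CalibrationError(
            f"n_groups must be in [2, {n}], got {n_groups}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, n_groups)]


def cross_validate(x: np.ndarray, y: np.ndarray, max_factors: int,
                   n_groups: int = 8, seed=0, modified: bool = True) -> CVResult:
    """Grouped cross-validation SECV curve over factor counts.

    Samples are partitioned into ``n_groups`` random folds; each fold is
    predicted by a model calibrated on the remaining samples, so every
    sample is predicted exactly once per factor count.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.asarray(y, float).ravel()
    n = y.size
    folds = make_folds(n, n_groups, seed)
    max_factors = min(max_factors, min(n - math.ceil(n / n_groups) - 1, x.shape[1]))
    if max_factors < 1:
        raise CalibrationError("not enough samples for any factors in CV")
    y_cv = np.empty((n, max_factors))
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        model = fit_mpls(x[train], y[train], max_factors, modified=modified)
        for f in range(1, max_factors + 1):
            y_cv[fold, f - 1] = model.predict(x[fold], n_factors=f)
    err = y_cv - y[:, None]
    secv = np.sqrt(np.sum(err ** 2, axis=0) / n)
    return CVResult(np.arange(1, max_factors + 1), secv, secv.copy(), y_cv, folds)


# ---------------------------------------------------------------------------
# T-criterion chemical outlier elimination
# ---------------------------------------------------------------------------

@dataclass
class TEliminationResult:
    model: CalibrationModel
    retained_idx: np.ndarray      # positions into the input arrays
    removed_idx: np.ndarray
    passes: int


def eliminate_t_outliers(x: np.ndarray, y: np.ndarray, n_factors: int,
                         threshold: float = 2.5, max_passes: int = 2,
                         modified: bool = True) -> TEliminationResult:
    """Iteratively drop samples whose standardized residual T = |e|/SEC
    is at or above ``threshold``, refitting after each pass."""
    x = np.atleast_2d(np.asarray(x, float))
    y = np.asarray(y, float).ravel()
    keep = np.arange(y.size)
    model = fit_mpls(x, y, n_factors, modified=modified)
    passes = 0
    for _ in range(max_passes):
        resid = y[keep] - model.predict(x[keep])
        dof = keep.size - n_factors - 1
        if dof <= 0:
            break
        sec = math.sqrt(float(resid @ resid) / dof)
        if sec == 0:
            break
        t = np.abs(resid) / sec
        bad = t >= threshold
        if not bad.any():
            break
        keep = keep[~bad]
        if keep.size <= n_factors + 1:
            raise CalibrationError(
                "T-criterion elimination would remove too many samples")
        model = fit_mpls(x[keep], y[keep], n_factors, modified=modified)
        passes += 1
    removed = np.setdiff1d(np.arange(y.size), keep)
    return TEliminationResult(model, keep, removed, passes)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass
class CalibrationStats:
    N: int
    mean: float
    SD: float
    est_min: float
    est_max: float
    SEC: float
    RSQ: float
    SECV: float
    RMSECV: float
    RPD: float
    n_factors: int


def calibration_stats(y_ref: np.ndarray, y_fit: np.ndarray,
                      y_cv: np.ndarray | None, n_factors: int,
                      nonnegative: bool = False,
                      rpd_on: str = "sec") -> CalibrationStats:
    """Calibration-set descriptors.

    SEC uses the degrees-of-freedom denominator N - n_factors - 1; SECV
    uses N. RPD defaults to SD/SEC (``rpd_on="secv"`` switches the
    denominator). Estimated range is mean +/- 3 SD, floored at 0 for
    non-negative parameters.
    """
    y_ref = np.asarray(y_ref, float).ravel()
    y_fit = np.asarray(y_fit, float).ravel()
    n = y_ref.size
    if n <= n_factors + 1:
        raise CalibrationError(
            f"need N > n_factors+1 samples (N={n}, factors={n_factors})")
    mean = float(y_ref.mean())
    sd = float(y_ref.std(ddof=1))
    e = y_ref - y_fit
    sec = math.sqrt(float(e @ e) / (n - n_factors - 1))
    sstot = float(np.sum((y_ref - mean) ** 2))
    rsq = 1.0 - float(e @ e) / sstot if sstot > 0 else 1.0
    if y_cv is not None:
        ecv = y_ref - np.asarray(y_cv, float).ravel()
        secv = math.sqrt(float(ecv @ ecv) / n)
    else:
        secv = float("nan")
    denom = sec if rpd_on == "sec" else secv
    rpd = sd / denom if denom > 0 else float("inf")
    est_min = mean - 3 * sd
    if nonnegative:
        est_min = max(est_min, 0.0)
    return CalibrationStats(
        N=n, mean=mean, SD=sd, est_min=est_min, est_max=mean + 3 * sd,
        SEC=sec, RSQ=rsq, SECV=secv, RMSECV=secv, RPD=rpd,
        n_factors=n_factors,
    )


@dataclass
class ValidationStats:
    n: int
    mean_abs_residual: float
    RMSE: float
    bias: float
    SEP: float
    SEP_C: float
    t_statistic: float
    t_p_value: float
    comparable: bool


def external_validate(y_ref: np.ndarray, y_pred: np.ndarray,
                      alpha: float = 0.05) -> ValidationStats:
    """External-validation errors and paired Student test."""
    y_ref = np.asarray(y_ref, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    n = y_ref.size
    if n < 3:
        raise CalibrationError("external validation needs at least 3 pairs")
    e = y_pred - y_ref
    bias = float(e.mean())
    rmse = math.sqrt(float(e @ e) / n)
    sep = math.sqrt(float(e @ e) / (n - 1))
    sep_c = math.sqrt(float(np.sum((e - bias) ** 2)) / (n - 1))
    if sep_c == 0:
        t_stat = 0.0 if bias == 0 else math.copysign(math.inf, bias)
        p = 1.0 if bias == 0 else 0.0
    else:
        t_stat = bias / (sep_c / math.sqrt(n))
        p = float(2 * sps.t.sf(abs(t_stat), n - 1))
    return ValidationStats(
        n=n, mean_abs_residual=float(np.abs(e).mean()), RMSE=rmse,
        bias=bias, SEP=sep, SEP_C=sep_c, t_statistic=float(t_stat),
        t_p_value=p, comparable=p > alpha,
    )


# ---------------------------------------------------------------------------
# Treatment-grid model selection
# ---------------------------------------------------------------------------

DEFAULT_TREATMENT_GRID = tuple(
    f"{scatter} {code}"
    for scatter in ("None", "SNV", "MSC", "Detrend only", "SNV-DT")
    for code in ("0,0,1,1", "1,4,4,1", "2,4,4,1", "2,8,6,1", "2,10,10,1")
)


@dataclass
class GridEntry:
    treatment: MathTreatment
    model: CalibrationModel | None
    stats: CalibrationStats | None
    h_removed: list[str]
    t_removed: list[str]
    error: str | None = None


@dataclass
class SelectionResult:
    parameter: str
    best: GridEntry
    grid: list[GridEntry]


def select_best_model(spectra: SpectraSet, y: np.ndarray, parameter: str = "",
                      treatment_grid=DEFAULT_TREATMENT_GRID,
                      n_groups: int = 8, max_factors: int = 16, seed=0,
                      h_threshold: float = 3.0, t_threshold: float = 2.5,
                      max_t_passes: int = 2, pca_components: int = 10,
                      modified: bool = True, nonnegative: bool = False,
                      parsimony_tol: float = 0.0,
                      rpd_on: str = "sec") -> SelectionResult:
    """Run the full calibration pipeline over a treatment grid and pick the
    winner lexicographically: highest RSQ (rounded to 4 dp), then lowest
    SECV, then fewer factors.

    Pipeline per candidate: preprocess -> PCA / H>threshold spectral
    screening -> grouped CV for the factor count -> T-criterion chemical
    elimination -> refit -> statistics.
    """
    y = np.asarray(y, float).ravel()
    ids = np.asarray(spectra.sample_ids)
    entries: list[GridEntry] = []
    for spec_str in treatment_grid:
        treatment = (spec_str if isinstance(spec_str, MathTreatment)
                     else MathTreatment.parse(spec_str))
        try:
            entries.append(_run_candidate(
                spectra, y, ids, treatment, n_groups, max_factors, seed,
                h_threshold, t_threshold, max_t_passes, pca_components,
                modified, nonnegative, parsimony_tol, rpd_on, parameter))
        except CalibrationError as exc:
            entries.append(GridEntry(treatment, None, None, [], [], str(exc)))
    usable = [e for e in entries if e.stats is not None]
    if not usable:
        raise CalibrationError(
            f"treatment grid exhausted by degenerate fits for {parameter!r}")
    best = min(usable, key=lambda e: (-round(e.stats.RSQ, 4), e.stats.SECV,
                                      e.stats.n_factors))
    return SelectionResult(parameter, best, entries)


def _run_candidate(spectra, y, ids, treatment, n_groups, max_factors, seed,
                   h_threshold, t_threshold, max_t_passes, pca_components,
                   modified, nonnegative, parsimony_tol, rpd_on, parameter):
    # fix the MSC reference to this (calibration) set's mean so the same
    # correction applies to future prediction samples
    msc_ref = (spectra.values.mean(axis=0)
               if treatment.scatter == "msc" else None)
    treated = apply_treatment(spectra, treatment, msc_reference=msc_ref)
    x = treated.values
    k = min(pca_components, x.shape[0] - 1, x.shape[1])
    if math.isfinite(h_threshold):
        pca = fit_pca(x, _safe_rank_components(x, k))
        screen = screen_h(pca, h_threshold)
        keep = screen.retained_idx
        h_removed = [str(s) for s in ids[screen.outlier_idx]]
    else:
        keep = np.arange(x.shape[0])
        h_removed = []
    x_k, y_k, ids_k = x[keep], y[keep], ids[keep]
    cv = cross_validate(x_k, y_k, max_factors, n_groups=n_groups, seed=seed,
                        modified=modified)
    nf = cv.best_factors(parsimony_tol)
    if math.isfinite(t_threshold):
        elim = eliminate_t_outliers(x_k, y_k, nf, threshold=t_threshold,
                                    max_passes=max_t_passes, modified=modified)
        retained, t_removed = elim.retained_idx, elim.removed_idx
        model = elim.model
    else:
        retained = np.arange(y_k.size)
        t_removed = np.array([], int)
        model = fit_mpls(x_k, y_k, nf, modified=modified)
    x_r, y_r = x_k[retained], y_k[retained]
    cv_final = cross_validate(x_r, y_r, nf, n_groups=min(n_groups, y_r.size),
                              seed=seed, modified=modified)
    nf_eff = min(nf, cv_final.y_cv.shape[1])
    stats = calibration_stats(
        y_r, model.predict(x_r), cv_final.y_cv[:, nf_eff - 1], nf,
        nonnegative=nonnegative, rpd_on=rpd_on)
    model.parameter = parameter
    model.treatment = treatment
    model.retained_ids = [str(s) for s in ids_k[retained]]
    model.msc_reference = msc_ref
    return GridEntry(treatment, model, stats, h_removed,
                     [str(s) for s in ids_k[t_removed]])


def _safe_rank_components(x: np.ndarray, k: int) -> int:
    xc = x - x.mean(axis=0)
    s = np.linalg.svd(xc, compute_uv=False)
    tol = s[0] * max(xc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if rank < 1:
        raise CalibrationError("spectra matrix has zero rank after centring")
    return min(k, rank)
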