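"""Kernel-weighted elastic-net varying-coefficient regression.

A personalized (sample-specific) gene network is estimated by regressing each
target gene on the remaining genes, with samples weighted by a Gaussian kernel
on a continuous per-sample characteristic (the *modulator*, e.g. a drug
sensitivity Z-score).  For target sample ``alpha`` the estimator solves

    min_beta  1/2 * sum_i k_i (y_i - r_i' beta)^2
              + lam * sum_j [ (1-pi)/2 * beta_j^2 + pi * |beta_j| ]

where ``k_i = exp(-(m_i - m_alpha)^2 / h)``.  Absorbing ``sqrt(k_i)`` into the
rows of the response and design turns this into an ordinary elastic-net
problem on the transformed pair ``(y*, R*)``, which is how the solvers here
operate.

The model has no intercept: expression columns are mean-centered (and by
default unit-scaled) when an :class:`ExpressionDataset` is built.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

from ._exceptions import (
    ConvergenceError,
    DegenerateFitError,
    DegenerateWeightingError,
    InvalidBandwidthError,
    NetgicError,
)

__all__ = [
    "ExpressionDataset",
    "ModulatorProfile",
    "KernelWeighting",
    "PenaltyConfig",
    "WeightedDesign",
    "CoefficientVector",
    "NoiseScale",
    "gaussian_kernel_weights",
    "build_weighted_design",
    "fit_weighted_elastic_net",
    "fit_by_lqa",
    "estimate_noise_scale",
]

#: Kernel weights below this value contribute nothing numerically; the
#: corresponding samples are dropped from the local fit.
WEIGHT_FLOOR = 1e-8

#: Minimum number of retained samples for a local fit to be attempted.
MIN_RETAINED = 2

SOLVER_TOL = 1e-7
SOLVER_MAX_ITER = 100_000
LQA_DROP_THRESHOLD = 1e-6


class ExpressionDataset:
    """Expression matrix (samples x genes) with identifiers.

    Columns are mean-centered and, with ``scale=True`` (default), scaled to
    unit standard deviation at construction.  Fits run on the processed
    values; per-column means/scales are kept so coefficients can be reported
    on the original scale.

    Parameters
    ----------
    values : (n, g) array
        Log-scale expression, samples as rows.
    gene_ids, sample_ids : sequences of str
        Unique identifiers for columns and rows.
    center, scale : bool
        Column preprocessing flags.
    """

    def __init__(self, values, gene_ids, sample_ids, *, center=True, scale=True):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise NetgicError("expression values must be a 2-D matrix")
        n, g = values.shape
        if n < 2:
            raise NetgicError("need at least 2 samples")
        gene_ids = [str(x) for x in gene_ids]
        sample_ids = [str(x) for x in sample_ids]
        if len(gene_ids) != g:
            raise NetgicError("gene_ids length does not match number of columns")
        if len(sample_ids) != n:
            raise NetgicError("sample_ids length does not match number of rows")
        if len(set(gene_ids)) != g:
            raise NetgicError("gene_ids must be unique")
        if len(set(sample_ids)) != n:
            raise NetgicError("sample_ids must be unique")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise NetgicError(
                f"non-finite expression value at sample "
                f"{sample_ids[bad[0]]!r}, gene {gene_ids[bad[1]]!r}"
            )

        self.gene_ids = gene_ids
        self.sample_ids = sample_ids
        self.col_means = values.mean(axis=0) if center else np.zeros(g)
        sds = values.std(axis=0, ddof=0)
        if scale:
            if np.any(sds == 0):
                j = int(np.argwhere(sds == 0)[0])
                raise NetgicError(f"gene {gene_ids[j]!r} has zero variance; cannot scale")
            self.col_scales = sds
        else:
            self.col_scales = np.ones(g)
        self.values = (values - self.col_means) / self.col_scales
        self.raw_values = values

    @property
    def n_samples(self):
        return self.values.shape[0]

    @property
    def n_genes(self):
        return self.values.shape[1]

    def gene_index(self, gene):
        try:
            return self.gene_ids.index(str(gene))
        except ValueError:
            raise NetgicError(f"unknown gene {gene!r}") from None

    def sample_index(self, sample):
        try:
            return self.sample_ids.index(str(sample))
        except ValueError:
            raise NetgicError(f"unknown sample {sample!r}") from None

    def regression_view(self, target_gene):
        """Split into target response and regulator matrix (no self-edge).

        Returns ``(y, R, regulator_ids, coef_rescale)`` on the processed
        scale; multiplying a fitted coefficient vector elementwise by
        ``coef_rescale`` maps it back to the original expression scale.
        """
        ell = self.gene_index(target_gene)
        mask = np.ones(self.n_genes, dtype=bool)
        mask[ell] = False
        y = self.values[:, ell]
        R = self.values[:, mask]
        regulator_ids = [g for j, g in enumerate(self.gene_ids) if mask[j]]
        coef_rescale = self.col_scales[ell] / self.col_scales[mask]
        return y, R, regulator_ids, coef_rescale


@dataclass
class ModulatorProfile:
    """Continuous per-sample characteristic indexing the varying coefficients.

    ``m[i]`` is e.g. the IC50 Z-score of sample ``i``; ``target_indices``
    are the samples whose personalized networks are to be estimated.
    """

    m: np.ndarray
    target_indices: np.ndarray | None = None

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float).ravel()
        if not np.all(np.isfinite(self.m)):
            raise NetgicError("modulator values must be finite")
        if self.target_indices is None:
            self.target_indices = np.arange(self.m.size)
        else:
            self.target_indices = np.asarray(self.target_indices, dtype=int)


@dataclass
class KernelWeighting:
    """Gaussian-kernel sample weights for one target sample.

    ``raw_weights`` hold k_i = exp(-(m_i - m_alpha)^2 / h) for every sample;
    samples with k_i below ``floor`` are dropped, and the weights of the
    retained samples are rescaled to sum to their count n', keeping the
    weighted likelihood on a comparable scale across bandwidths.
    """

    h: float
    raw_weights: np.ndarray
    retained: np.ndarray
    normalized_weights: np.ndarray
    floor: float = WEIGHT_FLOOR

    @property
    def n_retained(self):
        return self.retained.size


@dataclass
class PenaltyConfig:
    """Elastic-net penalty: strength ``lam`` and L1 mixing weight ``pi``."""

    lam: float
    pi: float

    def __post_init__(self):
        if self.lam < 0:
            raise NetgicError(f"lam must be >= 0, got {self.lam}")
        if not 0.0 <= self.pi <= 1.0:
            raise NetgicError(f"pi must be in [0, 1], got {self.pi}")


@dataclass
class WeightedDesign:
    """Row-scaled response/design pair absorbing the kernel weights.

    Row ``i`` equals ``sqrt(w_i) * (y_i, r_i)`` over the retained samples, so
    the plain residual sum of squares on ``(y_star, R_star)`` equals the
    kernel-weighted residual sum of squares on the original data.
    """

    y_star: np.ndarray
    R_star: np.ndarray
    weights: KernelWeighting

    @property
    def n(self):
        return self.y_star.size

    @property
    def p(self):
        return self.R_star.shape[1]


@dataclass
class CoefficientVector:
    """Estimated coefficients with their support.

    ``beta0`` is the reference value used for local quadratic approximation
    of the L1 penalty; it defaults to the estimate itself (one-step plug-in).
    """

    beta: np.ndarray
    active_set: np.ndarray = None
    beta0: np.ndarray = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if not np.all(np.isfinite(self.beta)):
            raise NetgicError("coefficients must be finite")
        if self.active_set is None:
            self.active_set = np.flatnonzero(self.beta)
        else:
            self.active_set = np.asarray(self.active_set, dtype=int)
        if self.beta0 is None:
            self.beta0 = self.beta.copy()

    @property
    def df(self):
        return int(self.active_set.size)


@dataclass
class NoiseScale:
    """Residual variance of a local fit.

    ``sigma2`` is the variance on the original (unweighted) scale; sample
    ``i`` of the transformed response has variance ``w_i * sigma2``.
    """

    sigma2: float
    per_sample: np.ndarray


def gaussian_kernel_weights(m, m_alpha, h, *, floor=WEIGHT_FLOOR, min_retained=MIN_RETAINED):
    """Gaussian kernel weights k_i = exp(-(m_i - m_alpha)^2 / h).

    Samples whose raw weight falls below ``floor`` are dropped; retained
    weights are rescaled to sum to the retained count.
    """
    if not np.isfinite(h) or h <= 0:
        raise InvalidBandwidthError(f"bandwidth must be positive, got {h}")
    m = np.asarray(m, dtype=float).ravel()
    if not np.all(np.isfinite(m)):
        raise NetgicError("modulator values must be finite")
    raw = np.exp(-((m - m_alpha) ** 2) / h)
    retained = np.flatnonzero(raw >= floor)
    if retained.size < min_retained:
        raise DegenerateWeightingError(
            f"only {retained.size} samples retain weight >= {floor} at h={h}"
        )
    kept = raw[retained]
    normalized = kept * (retained.size / kept.sum())
    return KernelWeighting(
        h=float(h), raw_weights=raw, retained=retained,
        normalized_weights=normalized, floor=floor,
    )


def build_weighted_design(y, R, w: KernelWeighting) -> WeightedDesign:
    """Absorb kernel weights into the rows of ``(y, R)``.

    Scaling row ``i`` by ``sqrt(w_i)`` makes the plain RSS on the transformed
    pair equal the weighted RSS ``sum_i w_i (y_i - r_i' beta)^2``.
    """
    y = np.asarray(y, dtype=float).ravel()
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != y.size:
        raise NetgicError(f"shape mismatch: y has {y.size} rows, R has shape {R.shape}")
    if w.raw_weights.size != y.size:
        raise NetgicError("weighting was computed for a different number of samples")
    if w.n_retained < 2:
        raise DegenerateWeightingError("fewer than 2 retained samples")
    root = np.sqrt(w.normalized_weights)
    y_star = root * y[w.retained]
    R_star = root[:, None] * R[w.retained]
    return WeightedDesign(y_star=y_star, R_star=R_star, weights=w)


def fit_weighted_elastic_net(d: WeightedDesign, pen: PenaltyConfig,
                             *, tol=SOLVER_TOL, max_iter=SOLVER_MAX_ITER) -> CoefficientVector:
    """Minimize 1/2 ||y* - R* b||^2 + lam * sum_j [(1-pi)/2 b_j^2 + pi |b_j|].

    ``lam = 0`` returns the weighted least-squares solution; ``pi = 0`` the
    ridge solution in closed form; otherwise coordinate descent is used.
    """
    n = d.n
    if pen.lam == 0.0:
        beta, *_ = np.linalg.lstsq(d.R_star, d.y_star, rcond=None)
        return CoefficientVector(beta=beta)
    if pen.pi == 0.0:
        G = d.R_star.T @ d.R_star + pen.lam * np.eye(d.p)
        beta = np.linalg.solve(G, d.R_star.T @ d.y_star)
        return CoefficientVector(beta=beta, active_set=np.arange(d.p))
    # sklearn scales the quadratic loss by 1/(2n): alpha = lam / n, l1_ratio = pi
    model = ElasticNet(alpha=pen.lam / n, l1_ratio=pen.pi,
                       fit_intercept=False, tol=tol, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(d.R_star, d.y_star)
        except ConvergenceWarning as exc:
            raise ConvergenceError(
                f"coordinate descent did not converge (lam={pen.lam}, pi={pen.pi})",
                last_iterate=getattr(model, "coef_", None),
            ) from exc
    return CoefficientVector(beta=model.coef_)


def fit_by_lqa(d: WeightedDesign, pen: PenaltyConfig, beta_init: CoefficientVector,
               *, tol=SOLVER_TOL, max_iter=5000,
               drop_threshold=LQA_DROP_THRESHOLD) -> CoefficientVector:
    """Solve the same elastic-net problem by local quadratic approximation.

    The L1 term is replaced around the current iterate ``b0`` by
    ``pi/(2|b0_j|) * b_j^2`` (+const), giving a ridge system with curvature
    ``lam * [(1-pi) + pi/|b0_j|]`` per coordinate, iterated to a fixed point.
    Coefficients whose reference value drops below ``drop_threshold`` are
    frozen at zero.  Serves as an independent cross-check of the coordinate
    descent solver.
    """
    beta = np.asarray(beta_init.beta, dtype=float).copy()
    p = d.p
    if beta.size != p:
        raise NetgicError("beta_init has wrong length")
    RtR = d.R_star.T @ d.R_star
    Rty = d.R_star.T @ d.y_star
    active = np.abs(beta) >= drop_threshold
    beta[~active] = 0.0
    for _ in range(max_iter):
        if not active.any():
            return CoefficientVector(beta=np.zeros(p), beta0=np.zeros(p))
        idx = np.flatnonzero(active)
        curv = pen.lam * ((1.0 - pen.pi) + pen.pi / np.abs(beta[idx]))
        G = RtR[np.ix_(idx, idx)] + np.diag(curv)
        try:
            sol = np.linalg.solve(G, Rty[idx])
        except np.linalg.LinAlgError:
            warnings.warn("singular LQA system; applying ridge jitter")
            sol = np.linalg.solve(G + 1e-10 * np.eye(idx.size), Rty[idx])
        new_beta = np.zeros(p)
        new_beta[idx] = sol
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        active = np.abs(beta) >= drop_threshold
        beta[~active] = 0.0
        if delta < tol:
            return CoefficientVector(beta=beta)
    raise ConvergenceError("LQA did not converge", last_iterate=beta)


def estimate_noise_scale(d: WeightedDesign, b: CoefficientVector) -> NoiseScale:
    """Residual variance sigma^2 = RSS* / (n' - |active|).

    RSS* is the residual sum of squares on the weight-absorbed scale, which
    equals the kernel-weighted RSS on the original data.  Sample ``i`` of the
    transformed response then has variance ``w_i * sigma2``.
    """
    dof = d.n - b.df
    if dof < 1:
        raise DegenerateFitError(f"no residual degrees of freedom (n'={d.n}, df={b.df})")
    resid = d.y_star - d.R_star @ b.beta
    sigma2 = float(resid @ resid) / dof
    if sigma2 <= 0.0:
        raise DegenerateFitError("zero residual variance; criteria are undefined")
    return NoiseScale(sigma2=sigma2, per_sample=d.weights.normalized_weights * sigma2)
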