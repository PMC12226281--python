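"""Hyperparameter selection for personalized network fits.

For each (target gene, target sample) pair the bandwidth ``h``, penalty
strength ``lam`` and L1 mixing ``pi`` are chosen by exhaustive minimization
of a model-selection criterion over a grid.  The lambda path for a given
``(h, pi)`` is solved in a single warm-started coordinate-descent sweep, and
every requested criterion is evaluated from the shared path coefficients, so
comparing criteria costs little more than evaluating one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.linear_model import enet_path

from ._exceptions import DegenerateWeightingError, NetgicError, SelectionError
from .criteria import CLASSICAL_CRITERIA, CriterionReport
from .network import PersonalizedNetwork
from .weighted_model import (
    CoefficientVector,
    ExpressionDataset,
    ModulatorProfile,
    build_weighted_design,
    gaussian_kernel_weights,
)

__all__ = ["SearchGrid", "FitResult", "select_hyperparameters",
           "fit_personalized_network", "evaluate_grid", "GridEvaluation"]

#: Tolerance for the coordinate-descent path solves during selection.
PATH_TOL = 1e-7
#: Looser tolerance for cross-validation fold fits (prediction error only).
CV_FOLD_TOL = 1e-4


@dataclass
class SearchGrid:
    """Grid over (lam, pi, h).

    The lambda path is data-driven: for each ``(h, pi)`` it descends
    log-linearly over ``n_lambdas`` values from ``lam_max``, the smallest
    strength that zeroes every coefficient, down to
    ``lambda_min_ratio * lam_max``.  Bandwidths default to ``n_bandwidths``
    log-spaced values spanning ``bandwidth_range`` times the standard
    deviation of the modulator.  Explicit ``lambdas`` / ``bandwidths``
    override the automatic choices.
    """

    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-3
    lambdas: np.ndarray | None = None
    pis: tuple = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
    bandwidths: np.ndarray | None = None
    n_bandwidths: int = 8
    bandwidth_range: tuple = (0.05, 2.0)

    def __post_init__(self):
        if len(self.pis) == 0:
            raise NetgicError("pis must be nonempty")
        for pi in self.pis:
            if not 0.0 <= pi <= 1.0:
                raise NetgicError(f"pi must be in [0, 1], got {pi}")

    @classmethod
    def benchmark(cls) -> "SearchGrid":
        """Compact grid used by the Monte Carlo benchmark.

        25 lambdas x 3 mixing values x 5 bandwidths keeps a repeated-fit
        study tractable while still spanning the sparse-to-dense and
        local-to-global regimes.
        """
        return cls(n_lambdas=25, pis=(0.1, 0.5, 1.0), n_bandwidths=5)

    def bandwidth_values(self, m):
        if self.bandwidths is not None:
            bw = np.asarray(self.bandwidths, dtype=float)
        else:
            sd = float(np.std(np.asarray(m, dtype=float)))
            if sd == 0:
                raise NetgicError("modulator has zero spread; supply bandwidths explicitly")
            lo, hi = self.bandwidth_range
            bw = np.geomspace(lo * sd, hi * sd, self.n_bandwidths)
        if np.any(bw <= 0):
            raise NetgicError("bandwidths must be positive")
        return bw

    def lambda_path(self, R_star, y_star, pi):
        if self.lambdas is not None:
            lams = np.sort(np.asarray(self.lambdas, dtype=float))[::-1]
            if np.any(lams <= 0):
                raise NetgicError("explicit lambdas must be positive")
            return lams
        lam_max = np.max(np.abs(R_star.T @ y_star)) / max(pi, 1e-3)
        if lam_max <= 0:
            lam_max = 1.0
        return np.geomspace(lam_max, self.lambda_min_ratio * lam_max, self.n_lambdas)


@dataclass
class FitResult:
    """Winning fit for one (target gene, target sample) pair.

    ``beta`` is on the preprocessed (standardized) scale used by the solver;
    ``coef`` maps it back to the original expression scale.
    """

    beta: CoefficientVector
    coef: np.ndarray
    hyper: tuple            # (lam, pi, h)
    criterion: CriterionReport
    target_gene: str | None = None
    target_sample: str | None = None
    regulator_ids: list | None = None
    trace: pd.DataFrame | None = None


@dataclass
class GridEvaluation:
    """Full per-point criterion trace plus the winner for each criterion."""

    trace: pd.DataFrame
    best: dict   # criterion name -> dict(beta, lam, pi, h, value, df)


def _classical_values(name, m2ll, df, n, p):
    """Vectorized classical criteria over a lambda path."""
    df = df.astype(float)
    if name == "aic":
        return m2ll + 2.0 * df
    if name == "aicc":
        out = m2ll + 2.0 * df + 2.0 * df * (df + 1) / (n - df - 1)
        out[df >= n - 1] = np.inf
        return out
    if name == "bic":
        return m2ll + df * math.log(n)
    if name == "hqc":
        return m2ll + 2.0 * df * math.log(math.log(n))
    if name == "ebic":
        log_comb = gammaln(p + 1) - gammaln(df + 1) - gammaln(p - df + 1)
        return m2ll + df * math.log(n) + 2.0 * 0.5 * log_comb
    if name == "bicp":
        return m2ll + df * (math.log(n) + 2.0 * math.log(p))
    raise NetgicError(f"unknown criterion {name!r}")


def _gic_values(d, coefs, resid_mat, sigma2, df, valid, lams, pi, logliks):
    """GIC along a lambda path; shares the residual matrix with the caller.

    Inlined equivalent of :func:`netgic.criteria.compute_gic` (asserted equal
    in the tests), kept lean because it runs for every grid point.
    """
    out = np.full(lams.size, np.inf)
    w = d.weights.normalized_weights
    n = d.n
    R = d.R_star
    for li in np.flatnonzero(valid):
        beta = coefs[:, li]
        active = np.flatnonzero(beta)
        if active.size == 0:
            out[li] = -2.0 * logliks[li]
            continue
        resid = resid_mat[:, li]
        lam_diag = resid / (w * sigma2[li])          # Lam_ii
        d_diag = resid * lam_diag                    # e*_i^2 / sigma*_i^2
        RA = R[:, active]
        slam = lams[li] * ((1.0 - pi) + pi / np.abs(beta[active])) / n
        R_hat = RA.T @ RA / n
        R_hat[np.diag_indices_from(R_hat)] += slam
        Q_hat = RA.T @ (d_diag[:, None] * RA) / n
        Q_hat -= np.outer(slam * beta[active], lam_diag @ RA) / n
        try:
            bias = float(np.trace(np.linalg.solve(R_hat, Q_hat)))
        except np.linalg.LinAlgError:
            R_hat[np.diag_indices_from(R_hat)] += 1e-10
            bias = float(np.trace(np.linalg.solve(R_hat, Q_hat)))
        out[li] = -2.0 * logliks[li] + 2.0 * bias
    return out


def evaluate_grid(y, R, m, m_alpha, grid: SearchGrid, criteria=("gic",),
                  cv_folds: int = 10, seed: int = 0,
                  solver_tol: float = PATH_TOL) -> GridEvaluation:
    """Evaluate every grid point for one local fit, for all given criteria.

    Returns the per-point trace and, per criterion, the minimizing point
    (ties broken toward larger lam, then larger h, then larger pi).
    Points with no residual degrees of freedom are skipped.
    """
    y = np.asarray(y, dtype=float).ravel()
    R = np.asarray(R, dtype=float)
    n, p = R.shape
    criteria = [c.lower() for c in criteria]
    for c in criteria:
        if c not in ("gic", "cv") + CLASSICAL_CRITERIA:
            raise NetgicError(f"unknown criterion {c!r}")
    want_cv = "cv" in criteria
    rng = np.random.default_rng(seed)

    frames = []
    blocks = []      # (h, pi, lams, coefs) per (h, pi) pair
    for h in grid.bandwidth_values(m):
        try:
            w = gaussian_kernel_weights(m, m_alpha, h)
        except DegenerateWeightingError:
            continue
        d = build_weighted_design(y, R, w)
        n_ret = d.n
        X = np.asfortranarray(d.R_star)
        log_w_sum = float(np.sum(np.log(w.normalized_weights)))
        if want_cv:
            order = rng.permutation(n_ret)
            folds = np.array_split(order, cv_folds)
            root_w = np.sqrt(w.normalized_weights)
            y_ret, R_ret = y[w.retained], R[w.retained]
        for pi in grid.pis:
            lams = grid.lambda_path(d.R_star, d.y_star, pi)
            L = lams.size
            # arrays are built float64/Fortran-ordered here, so input
            # re-validation inside the path solver is safely skipped
            _, coefs, _ = enet_path(X, np.ascontiguousarray(d.y_star),
                                    l1_ratio=pi, alphas=lams / n_ret,
                                    tol=solver_tol, max_iter=100_000,
                                    check_input=False)
            resid_mat = d.y_star[:, None] - d.R_star @ coefs
            rss = np.einsum("il,il->l", resid_mat, resid_mat)
            df = np.count_nonzero(coefs, axis=0)
            dof = n_ret - df
            valid = (dof >= 1) & (rss > 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                sigma2 = np.where(valid, rss / np.maximum(dof, 1), np.nan)
                # Gaussian loglik under per-sample variances w_i * sigma2;
                # its exponent sum_i resid*_i^2/(w_i s2) is the unweighted
                # RSS over the local variance
                rss_unw = np.einsum("il,il,i->l", resid_mat, resid_mat,
                                    1.0 / w.normalized_weights)
                logliks = -0.5 * (n_ret * np.log(2 * np.pi * sigma2)
                                  + log_w_sum + rss_unw / sigma2)
                # Classical criteria see the kernel-absorbed data the way
                # off-the-shelf tooling does: a homoscedastic Gaussian fit
                # with the MLE variance rss/n.  Ignoring the kernel structure
                # is precisely the misuse of maximum-likelihood criteria that
                # the sample-specific GIC corrects.
                loglik_naive = -0.5 * n_ret * (np.log(2 * np.pi * rss / n_ret)
                                               + 1.0)
            m2ll = -2.0 * loglik_naive
            frame = pd.DataFrame({
                "h": h, "pi": pi, "lam": lams, "df": df,
                "n_retained": n_ret, "sigma2": sigma2, "loglik": logliks,
                "loglik_naive": loglik_naive,
                "block": len(blocks), "lam_index": np.arange(L),
                "valid": valid,
            })
            for c in criteria:
                if c == "gic":
                    vals = _gic_values(d, coefs, resid_mat, sigma2, df, valid,
                                       lams, pi, logliks)
                elif c == "cv":
                    cv_err = np.zeros(L)
                    for fold in folds:
                        mask = np.ones(n_ret, dtype=bool)
                        mask[fold] = False
                        Xtr = np.asfortranarray(root_w[mask, None] * R_ret[mask])
                        ytr = root_w[mask] * y_ret[mask]
                        _, fold_coefs, _ = enet_path(
                            Xtr, np.ascontiguousarray(ytr), l1_ratio=pi,
                            alphas=lams / n_ret, tol=CV_FOLD_TOL,
                            max_iter=100_000, check_input=False)
                        resid = y_ret[fold][:, None] - R_ret[fold] @ fold_coefs
                        w_test = w.normalized_weights[fold]
                        cv_err += (w_test @ resid ** 2) / w_test.sum()
                    vals = cv_err / len(folds)
                else:
                    vals = _classical_values(c, m2ll, df, n_ret, p)
                vals = np.where(valid, vals, np.inf)
                frame[c] = vals
            frames.append(frame)
            blocks.append((float(h), float(pi), lams, coefs))
    if not frames:
        raise SelectionError("no valid grid point produced a fit")
    trace = pd.concat(frames, ignore_index=True)
    if not trace["valid"].any():
        raise SelectionError("no valid grid point produced a fit")

    best = {}
    for c in criteria:
        vals = trace[c].to_numpy()
        if not np.any(np.isfinite(vals)):
            raise SelectionError(f"criterion {c!r} undefined everywhere on the grid")
        # tie-break: smaller value, then larger lam, larger h, larger pi
        order = np.lexsort((-trace["pi"].to_numpy(), -trace["h"].to_numpy(),
                            -trace["lam"].to_numpy(), vals))
        i = order[0]
        row = trace.iloc[i]
        _, _, lams, coefs = blocks[int(row["block"])]
        best[c] = {"beta": coefs[:, int(row["lam_index"])].copy(),
                   "lam": float(row["lam"]), "pi": float(row["pi"]),
                   "h": float(row["h"]), "value": float(row[c]),
                   "df": int(row["df"])}
    return GridEvaluation(trace=trace.drop(columns=["block", "lam_index"]),
                          best=best)


def select_hyperparameters(data: ExpressionDataset, mod: ModulatorProfile,
                           target_gene, target_sample, grid: SearchGrid,
                           criterion_name: str = "gic", seed: int = 0) -> FitResult:
    """Choose (lam, pi, h) minimizing ``criterion_name`` for one local fit."""
    if mod.m.size != data.n_samples:
        raise NetgicError("modulator length does not match sample count")
    alpha = data.sample_index(target_sample)
    y, R, regulator_ids, rescale = data.regression_view(target_gene)
    ev = evaluate_grid(y, R, mod.m, mod.m[alpha], grid,
                       criteria=(criterion_name,), seed=seed)
    win = ev.best[criterion_name.lower()]
    b = CoefficientVector(beta=win["beta"])
    report = CriterionReport(name=criterion_name.lower(), value=win["value"],
                             df=win["df"])
    return FitResult(beta=b, coef=win["beta"] * rescale,
                     hyper=(win["lam"], win["pi"], win["h"]),
                     criterion=report, target_gene=str(target_gene),
                     target_sample=str(target_sample),
                     regulator_ids=regulator_ids, trace=ev.trace)


def fit_personalized_network(data: ExpressionDataset, mod: ModulatorProfile,
                             target_samples, grid: SearchGrid,
                             criterion_name: str = "gic",
                             seed: int = 0) -> PersonalizedNetwork:
    """Fit every gene on all others, for every target sample.

    Per-pair failures are collected in ``net.failures`` rather than aborting
    the remaining fits.
    """
    target_samples = list(target_samples)
    if not target_samples:
        raise NetgicError("need at least one target sample")
    q = data.n_genes
    T = len(target_samples)
    coef = np.zeros((q, q, T))
    failures = []
    sample_idx = [data.sample_index(s) for s in target_samples]
    for ell, gene in enumerate(data.gene_ids):
        y, R, _, rescale = data.regression_view(gene)
        reg_pos = [j for j in range(q) if j != ell]
        for t, (sid, a) in enumerate(zip(target_samples, sample_idx)):
            try:
                ev = evaluate_grid(y, R, mod.m, mod.m[a], grid,
                                   criteria=(criterion_name,), seed=seed)
                win = ev.best[criterion_name.lower()]
                coef[ell, reg_pos, t] = win["beta"] * rescale
            except NetgicError as exc:
                failures.append((gene, str(sid), str(exc)))
    net = PersonalizedNetwork(
        coef=coef, gene_ids=list(data.gene_ids),
        target_sample_ids=[str(s) for s in target_samples],
        modulator_values=mod.m[sample_idx],
    )
    net.failures = failures
    return net
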