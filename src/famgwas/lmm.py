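"""Gaussian linear mixed model with a single family random intercept.

The model for sample j of family i is

    y_ij = x_ij' beta + tau_i + e_ij,
    tau_i ~ N(0, var_family),  e_ij ~ N(0, var_resid),

the workhorse of family-based association testing in this package. The
fit profiles the likelihood: for a fixed variance ratio
``lambda = var_family / var_resid`` the GLS solution for beta and the
residual variance are closed-form (the covariance is block diagonal, so
everything reduces to per-family sums), and lambda is optimized by
bounded scalar minimization on the log scale. Boundary estimates
(var_family = 0) are accepted as-is.

``FamilyLMM`` is a scikit-learn style estimator (``fit`` / ``predict`` /
``get_params``); :func:`fit_lmm` and :func:`lrt_pvalue` are the thin
functional surface used by the association scan.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["FamilyLMM", "fit_lmm", "lrt_pvalue"]

_LAMBDA_LO, _LAMBDA_HI = 1e-8, 1e8


def _as_design(X, n: int) -> np.ndarray:
    if X is None:
        return np.empty((n, 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


class FamilyLMM(BaseEstimator, RegressorMixin):
    """Linear mixed model with one random intercept per family.

    Parameters
    ----------
    criterion : {"ml", "reml"}
        Objective used to estimate the variance ratio. The stored
        ``loglik_`` is always the ML log-likelihood (evaluated at the
        chosen variance ratio), so BIC and likelihood-ratio tests are
        comparable across fits regardless of criterion.
    fit_intercept : bool
        Prepend a constant column to the design.

    Attributes
    ----------
    beta_ : ndarray — fixed-effect estimates (intercept first if fitted).
    se_ : ndarray — Wald standard errors of ``beta_``.
    var_family_, var_resid_ : float — variance components (ML scale).
    loglik_ : float — ML log-likelihood.
    bic_ : float — ``-2 loglik + (n_fixed + 2) log n``.
    blups_ : dict family_id -> shrunken family deviation (BLUP).
    """

    def __init__(self, criterion: str = "ml", fit_intercept: bool = True):
        self.criterion = criterion
        self.fit_intercept = fit_intercept

    # ------------------------------------------------------------------
    def fit(self, X, y, groups=None):
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        if n == 0:
            raise ValueError("empty response")
        X = _as_design(X, n)
        if self.fit_intercept:
            X = np.column_stack([np.ones(n), X])
        p = X.shape[1]
        if X.shape[0] != n:
            raise ValueError("X and y have different lengths")
        if n < p + 1:
            raise ValueError(f"need n >= {p + 1} samples for {p} fixed effects")
        if p:
            rank = np.linalg.matrix_rank(X)
            if rank < p:
                bad = _collinear_columns(X)
                raise ValueError(
                    f"rank-deficient fixed-effect design (rank {rank} < {p}); "
                    f"collinear columns {bad}"
                )
        if self.criterion not in ("ml", "reml"):
            raise ValueError("criterion must be 'ml' or 'reml'")

        if groups is None:
            fam_codes, fam_names, counts = None, [], None
        else:
            groups = np.asarray(groups)
            if groups.size != n:
                raise ValueError("groups and y have different lengths")
            fam_names, fam_codes = np.unique(groups, return_inverse=True)
            counts = np.bincount(fam_codes).astype(float)
            if len(fam_names) == 1:
                warnings.warn(
                    "single family: the family variance is weakly identified"
                )

        if fam_codes is None:
            lam = 0.0
        else:
            def objective(t: float) -> float:
                return -self._profiled(np.exp(t), y, X, fam_codes, counts)[0]

            res = optimize.minimize_scalar(
                objective,
                bounds=(np.log(_LAMBDA_LO), np.log(_LAMBDA_HI)),
                method="bounded",
                options={"xatol": 1e-7},
            )
            lam = float(np.exp(res.x))
            # accept the lower boundary as var_family = 0
            if objective(np.log(_LAMBDA_LO)) <= res.fun:
                lam = 0.0

        self._finalize(lam, y, X, fam_codes, counts, fam_names)
        return self

    # ------------------------------------------------------------------
    def _profiled(self, lam, y, X, fam, counts, criterion=None):
        """Profiled log-likelihood at variance ratio ``lam``.

        Returns (objective, beta, sigma2_ml, XtViX, resid) where the
        objective is ML or REML per ``criterion``.
        """
        criterion = criterion or self.criterion
        n, p = X.shape
        if fam is None or lam == 0.0:
            w = None
            Vy, VX = y, X
            logdet = 0.0
        else:
            w = lam / (1.0 + lam * counts)
            Vy = _v_inv(y, fam, counts, w)
            VX = _v_inv(X, fam, counts, w)
            logdet = float(np.log1p(lam * counts).sum())
        XtViX = X.T @ VX
        XtViy = X.T @ Vy
        if p:
            beta = np.linalg.solve(XtViX, XtViy)
            resid = y - X @ beta
        else:
            beta = np.zeros(0)
            resid = y
        if w is None:
            q = float(resid @ resid)
        else:
            q = float(resid @ _v_inv(resid, fam, counts, w))
        q = max(q, 1e-300)
        sigma2 = q / n
        ll_ml = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
        if criterion == "ml":
            return ll_ml, beta, sigma2, XtViX, resid
        dof = n - p
        s2r = q / dof
        sign, ld_xx = np.linalg.slogdet(XtViX) if p else (1.0, 0.0)
        ll_reml = -0.5 * (dof * np.log(2 * np.pi * s2r) + logdet + ld_xx + dof)
        return ll_reml, beta, sigma2, XtViX, resid

    def _finalize(self, lam, y, X, fam, counts, fam_names):
        n, p = X.shape
        ll_ml, beta, sigma2, XtViX, resid = self._profiled(
            lam, y, X, fam, counts, criterion="ml"
        )
        if self.criterion == "reml":
            # variance components on the REML scale, likelihood on ML scale
            q = sigma2 * n
            sigma2_rep = q / max(n - p, 1)
        else:
            sigma2_rep = sigma2
        self.n_ = n
        self.n_fixed_ = p
        self.lambda_ = lam
        self.var_resid_ = float(sigma2_rep)
        self.var_family_ = float(lam * sigma2_rep)
        self.beta_ = beta
        cov = sigma2_rep * np.linalg.inv(XtViX) if p else np.empty((0, 0))
        self.se_ = np.sqrt(np.clip(np.diag(cov), 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se_ > 0, beta / self.se_, np.inf * np.sign(beta))
        self.wald_p_ = 2 * stats.norm.sf(np.abs(z))
        self.loglik_ = float(ll_ml)
        self.bic_ = float(-2 * ll_ml + (p + 2) * np.log(n))
        if fam is None:
            self.blups_ = {}
        else:
            S = np.bincount(fam, weights=resid, minlength=len(counts))
            b = lam * S / (1.0 + lam * counts)
            self.blups_ = {str(f): float(v) for f, v in zip(fam_names, b)}
        self._X = X
        self._y = y
        return self

    # ------------------------------------------------------------------
    def predict(self, X, groups=None):
        """Fixed-effect prediction plus the family BLUP when known.

        A family absent from training contributes nothing (its BLUP is 0).
        """
        n = np.asarray(X).shape[0] if np.ndim(X) >= 1 else 1
        X = _as_design(X, n)
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        if X.shape[1] != self.n_fixed_:
            raise ValueError(
                f"predictor has {X.shape[1]} columns; model fitted with "
                f"{self.n_fixed_}"
            )
        yhat = X @ self.beta_ if self.n_fixed_ else np.zeros(X.shape[0])
        if groups is not None:
            groups = np.asarray(groups)
            yhat = yhat + np.array(
                [self.blups_.get(str(g), 0.0) for g in groups]
            )
        return yhat


def _v_inv(M, fam, counts, w):
    """Apply (I + lambda Z Z')^{-1} to a vector or matrix, blockwise."""
    if M.ndim == 1:
        S = np.bincount(fam, weights=M, minlength=len(counts))
        return M - (w * S)[fam]
    S = np.zeros((len(counts), M.shape[1]))
    np.add.at(S, fam, M)
    return M - (w[:, None] * S)[fam]


def _collinear_columns(X: np.ndarray) -> list[int]:
    """Indices of columns involved in exact collinearity (via QR)."""
    _, R = np.linalg.qr(X)
    d = np.abs(np.diag(R))
    tol = d.max() * X.shape[0] * np.finfo(float).eps if d.size else 0.0
    return [int(i) for i in np.flatnonzero(d <= tol)]


def fit_lmm(y, X, family_ids=None, criterion: str = "ml",
            add_intercept: bool = True) -> FamilyLMM:
    """Fit the family random-intercept model; returns the fitted estimator."""
    model = FamilyLMM(criterion=criterion, fit_intercept=add_intercept)
    return model.fit(X, y, groups=family_ids)


def lrt_pvalue(fit_full: FamilyLMM, fit_null: FamilyLMM) -> float:
    """Likelihood-ratio p-value for nested fixed-effect structures.

    Both fits must be on the same samples with the same random structure;
    the chi-square reference has df = difference in fixed-effect counts.
    """
    if fit_full.n_ != fit_null.n_:
        raise ValueError("fits use different sample sizes; not comparable")
    df = fit_full.n_fixed_ - fit_null.n_fixed_
    if df < 0:
        raise ValueError("null model has more fixed effects than the full")
    if not _nested(fit_null._X, fit_full._X):
        raise ValueError("models are not nested (null design not in full span)")
    if df == 0:
        return 1.0
    stat = max(0.0, 2.0 * (fit_full.loglik_ - fit_null.loglik_))
    return float(np.clip(stats.chi2.sf(stat, df), 0.0, 1.0))


def _nested(X_null: np.ndarray, X_full: np.ndarray, tol: float = 1e-8) -> bool:
    """True when every null design column lies in the full design's span."""
    if X_null.shape[1] == 0:
        return True
    proj, *_ = np.linalg.lstsq(X_full, X_null, rcond=None)
    resid = X_null - X_full @ proj
    scale = np.linalg.norm(X_null) + 1.0
    return bool(np.linalg.norm(resid) <= tol * scale)
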