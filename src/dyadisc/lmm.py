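"""Crossed-random-intercepts mixed model for doubled dyadic data.

Model (per parcel)::

    y = X beta + b1[participant_1] + b2[participant_2] + eps
    b1 ~ N(0, s1^2 I),  b2 ~ N(0, s2^2 I),  eps ~ N(0, se^2 I)

fit by REML.  The fixed part is an intercept plus either a 3-level dyad
group factor (treatment-coded against a reference level, default NN) or a
continuous dyad trait (e.g. maximum loneliness), plus optional covariates.
The response and continuous predictors are z-scored using moments computed
over *unique* dyads, so the redundant doubling does not bias the scale.

Because each dyad enters the doubled data twice with an identical response,
the model-based covariance of the fixed effects understates the true
sampling covariance; with ``redundancy_correction=True`` (default) the
covariance is replaced by the sandwich implied by the symmetric dyadic
truth (for dyad-level covariates this is exactly twice the model-based
covariance), and all t tests use the manually corrected degrees of freedom
``N_unique - k``.

Estimation profiles the fixed effects and the residual variance out of the
REML criterion and optimizes the two variance *ratios* (s1^2/se^2,
s2^2/se^2) with bounded L-BFGS-B; the Woodbury identity keeps every
evaluation at the cost of one (m1+m2) x (m1+m2) Cholesky, where m1, m2 are
the numbers of random-intercept levels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_solve
from sklearn.base import BaseEstimator

from .errors import (
    DegenerateCovariateError,
    InsufficientDataError,
    NotConvergedError,
    SingularDesignError,
    ValidationError,
)

__all__ = [
    "CrossedLMM",
    "corrected_df",
    "standardize_variables",
    "fit_crossed_lmm",
    "planned_contrasts",
    "fit_continuous_model",
]

CONTRAST_PAIRS = (("LL", "NN"), ("LL", "NL"), ("NL", "NN"))


def corrected_df(n_unique: int, k: int) -> int:
    """Manually corrected degrees of freedom: unique dyads minus fixed effects."""
    if n_unique <= k:
        raise InsufficientDataError(
            f"N_unique={n_unique} must exceed the number of fixed effects k={k}"
        )
    return int(n_unique) - int(k)


def standardize_variables(values, mask=None, ddof: int = 1) -> np.ndarray:
    """Center/scale by the sample moments of ``values[mask]``.

    ``mask`` selects the unique-dyad rows of a doubled column so replication
    leaves the moments untouched; by default all rows are used.
    """
    x = np.asarray(values, dtype=float)
    ref = x if mask is None else x[np.asarray(mask)]
    sd = ref.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateCovariateError("zero-variance continuous column")
    return (x - ref.mean()) / sd


def _is_binary(x: np.ndarray) -> bool:
    return set(np.unique(x)).issubset({0.0, 1.0})


class _REMLResult:
    __slots__ = ("beta", "vcov_model", "vcov_sandwich", "gamma", "sigma2",
                 "loglik", "converged")

    def __init__(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)


def _sandwich_vcov(X, c1, c2, m1, m2, partner, gamma, sigma2, ZtZ, ZtX):
    """Covariance of the GLS fixed effects under the symmetric dyadic truth.

    The doubled-data model treats the two mirrored rows of a dyad as
    independent and puts no covariance between rows that share a subject
    across roles; the data-generating truth has duplicate rows perfectly
    correlated and a single per-subject intercept.  This propagates the
    model-implied truth  V = sigma_a^2 G G' + sigma_e^2 (I + D)  (G = subject
    incidence over both roles, D = duplicate-row pairing) through the GLS
    estimator:  A^-1 X'W^-1 V W^-1 X A^-1.  With both variance components at
    zero it reduces exactly to doubling the model-based covariance.
    """
    n, p = X.shape
    m = m1 + m2
    g1, g2 = gamma
    sd = np.sqrt(np.concatenate([np.full(m1, g1), np.full(m2, g2)]))
    M = np.eye(m) + sd[:, None] * ZtZ * sd[None, :]
    L = np.linalg.cholesky(M)
    C = cho_solve((L, True), sd[:, None] * ZtX)
    sdC = sd[:, None] * C
    U = X - sdC[c1] - sdC[m1 + c2]          # W^-1 X, N x p
    A = X.T @ U                              # X'W^-1X
    GtU = np.zeros((m1, p))                  # G'U with shared level coding
    np.add.at(GtU, c1, U)
    np.add.at(GtU, c2, U)
    gamma_a = 0.5 * (g1 + g2)
    B = gamma_a * (GtU.T @ GtU) + U.T @ U + U.T @ U[partner]
    Ainv = np.linalg.inv(A)
    return sigma2 * (Ainv @ B @ Ainv.T)


def _reml_crossed(X, y, c1, c2, m1, m2, partner=None, var_ratios="estimate",
                  tol=1e-9):
    """Profiled REML for two crossed random-intercept factors.

    ``c1``/``c2`` are integer level codes of the two factors; returns fixed
    effects, their (model-based, unscaled-by-2) covariance, the variance
    ratios gamma = (s1^2/se^2, s2^2/se^2), and the residual variance.
    """
    n, p = X.shape
    m = m1 + m2
    # cross-products involving Z = [Z1 | Z2] built without forming Z
    ZtZ = np.zeros((m, m))
    np.add.at(ZtZ, (c1, c1), 1.0)
    np.add.at(ZtZ, (m1 + c2, m1 + c2), 1.0)
    np.add.at(ZtZ, (c1, m1 + c2), 1.0)
    np.add.at(ZtZ, (m1 + c2, c1), 1.0)
    ZtX = np.zeros((m, p))
    np.add.at(ZtX, c1, X)
    np.add.at(ZtX, m1 + c2, X)
    Zty = np.zeros(m)
    np.add.at(Zty, c1, y)
    np.add.at(Zty, m1 + c2, y)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    if yty == 0.0:  # degenerate all-zero response
        beta = np.zeros(p)
        return _REMLResult(beta=beta, vcov_model=np.zeros((p, p)),
                           vcov_sandwich=np.zeros((p, p)),
                           gamma=np.zeros(2), sigma2=0.0, loglik=np.inf,
                           converged=True)

    def profiled(gamma):
        g1, g2 = np.maximum(gamma, 0.0)
        sd = np.sqrt(np.concatenate([np.full(m1, g1), np.full(m2, g2)]))
        M = np.eye(m) + sd[:, None] * ZtZ * sd[None, :]
        L = np.linalg.cholesky(M)
        DZtX = sd[:, None] * ZtX
        DZty = sd * Zty
        MiDZtX = cho_solve((L, True), DZtX)
        MiDZty = cho_solve((L, True), DZty)
        XtWiX = XtX - DZtX.T @ MiDZtX
        XtWiy = Xty - DZtX.T @ MiDZty
        ytWiy = yty - DZty @ MiDZty
        Lx = np.linalg.cholesky(XtWiX)
        beta = cho_solve((Lx, True), XtWiy)
        ssr = max(ytWiy - XtWiy @ beta, 1e-300)
        sigma2 = ssr / (n - p)
        logdet_w = 2.0 * np.log(np.diag(L)).sum()
        logdet_xwx = 2.0 * np.log(np.diag(Lx)).sum()
        crit = logdet_w + (n - p) * np.log(sigma2) + logdet_xwx
        return crit, beta, XtWiX, sigma2

    if var_ratios == "estimate":
        best = None
        converged = False
        for x0 in ((0.05, 0.05), (1.0, 1.0)):
            res = optimize.minimize(
                lambda g: profiled(g)[0], x0=np.asarray(x0),
                method="L-BFGS-B", bounds=[(0.0, 1e6)] * 2,
                options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
            converged = converged or bool(res.success)
        gamma = np.maximum(best.x, 0.0)
    else:
        gamma = np.asarray(var_ratios, dtype=float)
        if gamma.shape != (2,) or (gamma < 0).any():
            raise ValidationError("var_ratios must be two non-negative values")
        converged = True
    crit, beta, XtWiX, sigma2 = profiled(gamma)
    vcov = sigma2 * np.linalg.inv(XtWiX)
    sandwich = (
        _sandwich_vcov(X, c1, c2, m1, m2, partner, gamma, sigma2, ZtZ, ZtX)
        if partner is not None else None
    )
    loglik = -0.5 * (crit + (n - p) * (1.0 + np.log(2.0 * np.pi)))
    return _REMLResult(beta=beta, vcov_model=vcov, vcov_sandwich=sandwich,
                       gamma=gamma, sigma2=sigma2, loglik=loglik,
                       converged=converged)


class CrossedLMM(BaseEstimator):
    """Dyadic mixed model with crossed random intercepts (sklearn-style).

    Parameters
    ----------
    group_col : str or None
        Name of the 3-level AK group column in X ({"LL", "NL", "NN"}).
        Ignored when ``continuous_col`` is given.
    continuous_col : str or None
        Name of a continuous dyad trait (e.g. ``"max_loneliness"``) used
        instead of the group factor.
    covariates : sequence of str
        Extra fixed-effect columns; continuous ones are z-scored over
        unique dyads, 0/1 indicators are left as is.
    role_cols : (str, str)
        Columns holding the two member roles of the doubled design.
    reference : str
        Reference level of the group factor (estimates are differences
        from this level).
    standardize : bool
        Z-score the response (and continuous predictors) over unique dyads
        so coefficients are standardized betas.
    redundancy_correction : bool
        Use the symmetric-truth sandwich covariance, undoing the
        information double-counting of the redundant doubled rows (see
        module docs and :func:`_sandwich_vcov`).
    var_ratios : "estimate" or (float, float)
        Estimate the two variance ratios by REML, or fix them (e.g. (0, 0)
        reduces the fit to GLS at the null = OLS).
    alternative : {"two-sided", "less", "greater"}
        Sidedness of the reported p-values; the estimate's sign is always
        reported separately.

    Attributes (after fit)
    ----------------------
    beta_, beta_names_, vcov_ : fixed effects and their covariance
    var_participant1_, var_participant2_, var_resid_ : variance components
    reml_loglik_, n_unique_, k_, df_, converged_
    """

    def __init__(self, *, group_col="group", continuous_col=None,
                 covariates=(), role_cols=("participant_1", "participant_2"),
                 reference="NN", standardize=True,
                 redundancy_correction=True, var_ratios="estimate",
                 alternative="two-sided", tol=1e-9):
        self.group_col = group_col
        self.continuous_col = continuous_col
        self.covariates = covariates
        self.role_cols = role_cols
        self.reference = reference
        self.standardize = standardize
        self.redundancy_correction = redundancy_correction
        self.var_ratios = var_ratios
        self.alternative = alternative
        self.tol = tol

    # -- design construction -------------------------------------------------
    def _build_design(self, X: pd.DataFrame, y: np.ndarray):
        r1, r2 = self.role_cols
        p1, p2 = X[r1].to_numpy(), X[r2].to_numpy()
        unique_mask = p1 < p2
        n = len(X)
        if n % 2 or unique_mask.sum() != n // 2:
            raise ValidationError(
                "X does not look like a doubled design: expected each dyad "
                "once per orientation"
            )
        if self.standardize:
            y = standardize_variables(y, unique_mask)
        cols, names = [np.ones(n)], ["Intercept"]
        if self.continuous_col is not None:
            x = X[self.continuous_col].to_numpy(dtype=float)
            cols.append(standardize_variables(x, unique_mask)
                        if self.standardize else x)
            names.append(self.continuous_col)
        elif self.group_col is not None:
            levels = sorted(pd.unique(X[self.group_col]))
            if self.reference not in levels:
                raise ValidationError(
                    f"reference level {self.reference!r} absent from "
                    f"{self.group_col!r} (levels: {levels})"
                )
            for lev in levels:
                if lev == self.reference:
                    continue
                cols.append((X[self.group_col] == lev).to_numpy(float))
                names.append(f"{self.group_col}[{lev}]")
        for cov in self.covariates:
            x = X[cov].to_numpy(dtype=float)
            if not _is_binary(x):
                x = (standardize_variables(x, unique_mask)
                     if self.standardize else x)
            elif x.std() == 0:
                raise DegenerateCovariateError(
                    f"covariate {cov!r} has zero variance"
                )
            cols.append(x)
            names.append(cov)
        design = np.column_stack(cols)
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            rdiag = np.abs(np.diag(np.linalg.qr(design)[1]))
            aliased = [names[i]
                       for i in np.argsort(rdiag)[: design.shape[1] - rank]]
            raise SingularDesignError(aliased)
        # shared level coding across both roles so components are comparable
        cats = pd.unique(np.concatenate([p1, p2]))
        cats = pd.Index(sorted(cats))
        c1 = cats.get_indexer(p1)
        c2 = cats.get_indexer(p2)
        # pair each row with its mirrored duplicate (order-independent)
        lo = np.minimum(c1, c2)
        hi = np.maximum(c1, c2)
        codes = pd.factorize(pd.Series(list(zip(lo, hi))))[0]
        partner = np.full(n, -1)
        first_seen = {}
        for i, code in enumerate(codes):
            if code in first_seen:
                j = first_seen[code]
                if partner[j] != -1:
                    raise ValidationError(
                        "doubled design has more than two rows for a dyad"
                    )
                partner[i], partner[j] = j, i
            else:
                first_seen[code] = i
        if (partner < 0).any():
            raise ValidationError("doubled design has unpaired dyad rows")
        return design, names, y, c1, c2, len(cats), partner, unique_mask

    # -- estimation ----------------------------------------------------------
    def fit(self, X: pd.DataFrame, y):
        """Fit the model on a doubled design ``X`` and aligned response ``y``."""
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValidationError("X and y have different lengths")
        design, names, yz, c1, c2, m, partner, unique_mask = \
            self._build_design(X, y)
        res = _reml_crossed(design, yz, c1, c2, m, m, partner=partner,
                            var_ratios=self.var_ratios, tol=self.tol)
        vcov = (res.vcov_sandwich if self.redundancy_correction
                else res.vcov_model)
        self.beta_ = pd.Series(res.beta, index=names, name="beta")
        self.beta_names_ = list(names)
        self.vcov_ = pd.DataFrame(vcov, index=names, columns=names)
        self.var_participant1_ = float(res.gamma[0] * res.sigma2)
        self.var_participant2_ = float(res.gamma[1] * res.sigma2)
        self.var_resid_ = float(res.sigma2)
        self.reml_loglik_ = float(res.loglik)
        self.n_unique_ = int(unique_mask.sum())
        self.k_ = len(names)
        self.df_ = corrected_df(self.n_unique_, self.k_)
        self.converged_ = bool(res.converged)
        self._levels_ = [n.split("[")[1][:-1] for n in names
                         if n.startswith(f"{self.group_col}[")] \
            if self.continuous_col is None and self.group_col else []
        return self

    # -- inference -----------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "beta_"):
            raise ValidationError("model is not fitted")
        if not self.converged_:
            raise NotConvergedError(
                "REML did not converge; refusing to compute contrasts"
            )

    def _p_from_t(self, t):
        if self.alternative == "two-sided":
            return 2.0 * stats.t.sf(abs(t), self.df_)
        if self.alternative == "less":
            return stats.t.cdf(t, self.df_)
        if self.alternative == "greater":
            return stats.t.sf(t, self.df_)
        raise ValidationError(f"unknown alternative {self.alternative!r}")

    def _test(self, name: str, cvec: np.ndarray) -> dict:
        est = float(cvec @ self.beta_.to_numpy())
        se = float(np.sqrt(cvec @ self.vcov_.to_numpy() @ cvec))
        t = est / se
        return {
            "contrast": name, "estimate": est, "se": se, "t": t,
            "df": self.df_, "p": float(self._p_from_t(t)),
            "direction": int(np.sign(est)),
        }

    def _level_vector(self, level: str) -> np.ndarray:
        """EMM-style indicator of a group level on the coefficient scale.

        Covariate terms are held at their means in every level and cancel
        in pairwise differences, so only group dummies appear.
        """
        v = np.zeros(self.k_)
        col = f"{self.group_col}[{level}]"
        if col in self.beta_names_:
            v[self.beta_names_.index(col)] = 1.0
        elif level != self.reference:
            raise ValidationError(f"group level {level!r} not in the fit")
        return v

    def contrasts(self) -> pd.DataFrame:
        """Planned pairwise contrasts LL-NN, LL-NL, NL-NN with corrected-df t."""
        self._check_fitted()
        if self.continuous_col is not None or not self.group_col:
            raise ValidationError("contrasts require the group-factor model")
        rows = []
        for hi, lo in CONTRAST_PAIRS:
            cvec = self._level_vector(hi) - self._level_vector(lo)
            rows.append(self._test(f"{hi}_vs_{lo}", cvec))
        return pd.DataFrame(rows)

    def slope_test(self) -> pd.DataFrame:
        """Corrected-df t test of the continuous trait's standardized slope."""
        self._check_fitted()
        if self.continuous_col is None:
            raise ValidationError("slope_test requires a continuous model")
        cvec = np.zeros(self.k_)
        cvec[self.beta_names_.index(self.continuous_col)] = 1.0
        return pd.DataFrame([self._test(f"{self.continuous_col}_slope", cvec)])


# -- thin functional wrappers ------------------------------------------------

def fit_crossed_lmm(doubled: pd.DataFrame, response, **params) -> CrossedLMM:
    """Fit the group-factor model; ``response`` is a column name or vector."""
    y = doubled[response] if isinstance(response, str) else response
    return CrossedLMM(**params).fit(doubled, y)


def planned_contrasts(fit: CrossedLMM) -> pd.DataFrame:
    return fit.contrasts()


def fit_continuous_model(doubled: pd.DataFrame, response,
                         continuous_col: str = "max_loneliness",
                         **params) -> tuple[CrossedLMM, pd.DataFrame]:
    """Fit the continuous (max-loneliness) variant; returns (fit, slope test)."""
    y = doubled[response] if isinstance(response, str) else response
    fit = CrossedLMM(continuous_col=continuous_col, **params).fit(doubled, y)
    return fit, fit.slope_test()
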