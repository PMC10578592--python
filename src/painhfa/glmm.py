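"""Generalized linear mixed models with crossed random intercepts and slopes.

Implements the two-factor random-intercept-and-slope model

    y ~ 1 + A + (1 + A | B) + (1 + A | C)

for a binomial (logit link) or gaussian (identity link) response, the model
family used throughout the sliding-window analysis.  Estimation maximizes the
Laplace approximation to the marginal likelihood: for a candidate set of
variance components the random-effect modes and fixed effects are found by
penalized iteratively reweighted least squares (PIRLS), and the variance
components (log standard deviations) are optimized by a derivative-free outer
search.  Random-effect covariances are diagonal (independent intercept and
slope variances per factor).

The solver is written for speed on small problems (hundreds of trials, tens
of group levels): a warm-started refit at fixed variance components costs on
the order of a millisecond, which is what makes permutation testing with
hundreds of refits per window practical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

__all__ = ["MixedGLM", "MixedGLMResults"]

_LOGSD_MIN = -8.0
_LOGSD_MAX = 4.0
# |eta| beyond this on the logit scale indicates (quasi-)complete separation
_SEPARATION_ETA = 20.0


def _log1pexp(x):
    """Numerically stable log(1 + exp(x))."""
    out = np.empty_like(x)
    big = x > 30
    out[big] = x[big]
    out[~big] = np.log1p(np.exp(x[~big]))
    return out


@dataclass
class MixedGLMResults:
    """Estimates from a :class:`MixedGLM` fit.

    Attributes
    ----------
    params : ndarray
        Fixed-effect coefficients ``[intercept, beta_A]``.
    bse : ndarray
        Wald standard errors of the fixed effects (conditional on the
        estimated variance components).
    tvalues : ndarray
        ``params / bse``.
    re_sds : dict
        Estimated random-effect standard deviations keyed by
        ``(factor, "intercept"|"slope")``.
    scale : float
        Residual standard deviation (gaussian family; 1.0 for binomial).
    fitted_conditional : ndarray
        Predicted response per observation including the random-effect
        modes (probabilities for the binomial family).
    converged, separated : bool
        Inner-solver convergence and complete-separation flags.
    """

    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    re_sds: dict
    scale: float
    fitted_conditional: np.ndarray
    converged: bool
    separated: bool
    loglik: float
    family: str
    nobs: int
    theta: np.ndarray = field(repr=False)
    random_effects: np.ndarray = field(repr=False)
    model: "MixedGLM" = field(repr=False, default=None)

    @property
    def beta(self) -> float:
        """Fixed-effect coefficient of the HFA covariate A."""
        return float(self.params[1])

    @property
    def se_beta(self) -> float:
        return float(self.bse[1])

    @property
    def t_stat(self) -> float:
        """Wald t-statistic of the A coefficient."""
        return float(self.tvalues[1])

    def conf_int(self, alpha: float = 0.05):
        """Wald confidence interval for [intercept, beta_A]."""
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return np.column_stack([lo, hi])

    def summary(self) -> str:
        lines = [
            f"MixedGLM ({self.family}, Laplace)  nobs={self.nobs}  "
            f"loglik={self.loglik:.2f}  converged={self.converged}",
            f"{'term':<12}{'coef':>10}{'se':>10}{'t':>10}",
        ]
        for name, b, s, t in zip(
            ("Intercept", "A"), self.params, self.bse, self.tvalues
        ):
            lines.append(f"{name:<12}{b:>10.4f}{s:>10.4f}{t:>10.3f}")
        lines.append("Random-effect SDs:")
        for (fac, what), sd in self.re_sds.items():
            lines.append(f"  {fac} {what:<10} {sd:.4f}")
        if self.family == "gaussian":
            lines.append(f"Residual SD: {self.scale:.4f}")
        if self.separated:
            lines.append("WARNING: complete or quasi-complete separation detected")
        return "\n".join(lines)


class MixedGLM:
    """Crossed random-intercept-and-slope model for a scalar covariate.

    Parameters
    ----------
    y : array
        Response: 0/1 for ``family="binomial"``, real for ``"gaussian"``.
    a : array
        The scalar covariate (mean windowed HFA amplitude, z units).
    groups : dict of str -> array of int
        Grouping factors; each value holds integer level codes per
        observation.  Each factor contributes a random intercept and a
        random slope on ``a``.
    family : {"binomial", "gaussian"}
    """

    def __init__(self, y, a, groups: dict, family: str = "binomial"):
        y = np.asarray(y, dtype=float).ravel()
        a = np.asarray(a, dtype=float).ravel()
        if y.shape != a.shape:
            raise ValueError("y and a must have the same length")
        if family not in ("binomial", "gaussian"):
            raise ValueError(f"unknown family: {family!r}")
        if family == "binomial" and not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("binomial family requires 0/1 responses")
        if not groups:
            raise ValueError("at least one grouping factor is required")
        self.family = family
        self.y = y
        self.a = a
        self.nobs = y.size
        self.factor_names = list(groups)
        self._codes = {}
        self._n_levels = {}
        for name, codes in groups.items():
            codes = np.asarray(codes)
            if codes.shape != y.shape:
                raise ValueError(f"group codes for {name!r} have wrong length")
            _, codes = np.unique(codes, return_inverse=True)
            self._codes[name] = codes
            self._n_levels[name] = codes.max() + 1

        self.X = np.column_stack([np.ones(self.nobs), a])
        z_blocks, comp_of_col = [], []
        comp = 0
        for name in self.factor_names:
            codes, n_lev = self._codes[name], self._n_levels[name]
            onehot = np.zeros((self.nobs, n_lev))
            onehot[np.arange(self.nobs), codes] = 1.0
            z_blocks.append(onehot)
            comp_of_col.extend([comp] * n_lev)
            z_blocks.append(onehot * a[:, None])
            comp_of_col.extend([comp + 1] * n_lev)
            comp += 2
        self.Z = np.hstack(z_blocks)
        self.n_comp = comp
        self._comp_of_col = np.asarray(comp_of_col)
        self.q = self.Z.shape[1]
        self.p = 2
        self.C = np.hstack([self.X, self.Z])
        self._v_warm = np.zeros(self.p + self.q)

    # ------------------------------------------------------------------ #
    # inner problem: (beta, u) at fixed variance components
    # ------------------------------------------------------------------ #

    def _penalty(self, log_sd_comp):
        sd = np.exp(np.clip(log_sd_comp, _LOGSD_MIN, _LOGSD_MAX))
        pen_u = 1.0 / sd[self._comp_of_col] ** 2
        return sd, np.concatenate([np.zeros(self.p), pen_u])

    def _pirls(self, pen, y, sigma_e=1.0, v0=None, tol=1e-8, maxiter=100):
        """Penalized IRLS; returns (v, H, n_iter, converged)."""
        C = self.C
        v = np.zeros(self.p + self.q) if v0 is None else v0.copy()
        if self.family == "gaussian":
            w = 1.0 / sigma_e**2
            H = w * (C.T @ C)
            H[np.diag_indices_from(H)] += pen
            cf = cho_factor(H, lower=True, check_finite=False)
            v = cho_solve(cf, w * (C.T @ y), check_finite=False)
            return v, H, 1, True
        # binomial: Newton with step halving on the penalized log-likelihood
        eta = C @ v

        def pll(eta_, v_):
            return float(y @ eta_ - _log1pexp(eta_).sum() - 0.5 * (pen * v_**2).sum())

        f = pll(eta, v)
        H = None
        converged = False
        for it in range(maxiter):
            mu = expit(eta)
            w = mu * (1.0 - mu) + 1e-10
            g = C.T @ (y - mu) - pen * v
            gnorm = np.abs(g).max()
            H = (C.T * w) @ C
            H[np.diag_indices_from(H)] += pen
            if gnorm < tol * max(1.0, np.abs(f)):
                converged = True
                break
            cf = cho_factor(H, lower=True, check_finite=False)
            step = cho_solve(cf, g, check_finite=False)
            t = 1.0
            for _ in range(20):
                v_new = v + t * step
                eta_new = C @ v_new
                f_new = pll(eta_new, v_new)
                if f_new >= f - 1e-12:
                    break
                t *= 0.5
            v, eta, f = v_new, eta_new, f_new
        else:
            converged = np.abs(g).max() < 1e-4 * max(1.0, np.abs(f))
        return v, H, it + 1, converged

    def _laplace_deviance(self, theta, y, warm=True):
        """-2 * Laplace log marginal likelihood at variance components theta."""
        log_sd = theta[: self.n_comp]
        sigma_e = float(np.exp(theta[self.n_comp])) if self.family == "gaussian" else 1.0
        sd, pen = self._penalty(log_sd)
        v0 = self._v_warm if warm else None
        v, H, _, ok = self._pirls(pen, y, sigma_e=sigma_e, v0=v0)
        if warm:
            self._v_warm = v
        u = v[self.p:]
        eta = self.C @ v
        if self.family == "binomial":
            ll_data = float(y @ eta - _log1pexp(eta).sum())
        else:
            r = y - eta
            ll_data = float(
                -0.5 * self.nobs * np.log(2 * np.pi * sigma_e**2)
                - 0.5 * (r @ r) / sigma_e**2
            )
        pen_u = pen[self.p:]
        quad = 0.5 * float(pen_u @ u**2)
        logdet_d = float(np.log(sd[self._comp_of_col]).sum()) * 2.0
        H_uu = H[self.p:, self.p:]
        cf = cho_factor(H_uu, lower=True, check_finite=False)
        logdet_h = 2.0 * float(np.log(np.diag(cf[0])).sum())
        ll = ll_data - quad - 0.5 * logdet_d - 0.5 * logdet_h
        if not ok:
            ll -= 1e4  # penalize inner failures so the search avoids them
        return -2.0 * ll

    # ------------------------------------------------------------------ #
    # public fitting API
    # ------------------------------------------------------------------ #

    def _default_start(self):
        theta0 = np.full(self.n_comp, np.log(0.3))
        if self.family == "gaussian":
            beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
            resid_sd = max(np.std(self.y - self.X @ beta), 1e-3)
            theta0 = np.append(theta0, np.log(resid_sd))
        return theta0

    def fit(
        self,
        start_theta=None,
        maxfev: int = 500,
        xatol: float = 0.02,
        fatol: float = 1e-3,
        re_sd=None,
    ) -> MixedGLMResults:
        """Fit the model.

        Parameters
        ----------
        start_theta : array, optional
            Starting log standard deviations (plus log residual SD for the
            gaussian family); used to warm-start the variance-component
            search.
        maxfev : int
            Cap on outer objective evaluations.
        re_sd : array, optional
            Fix the random-effect standard deviations at these values
            instead of estimating them.  All zeros reduces the model to an
            ordinary GLM/OLS fit of ``y ~ 1 + A``.
        """
        y = self.y
        if re_sd is not None:
            re_sd = np.asarray(re_sd, dtype=float)
            if re_sd.shape != (self.n_comp,):
                raise ValueError(f"re_sd must have length {self.n_comp}")
            if np.all(re_sd == 0):
                return self._fit_fixed_only()
            theta = np.log(np.maximum(re_sd, np.exp(_LOGSD_MIN)))
            if self.family == "gaussian":
                theta = np.append(theta, self._default_start()[-1])
                # still profile the residual SD
                res = optimize.minimize_scalar(
                    lambda ls: self._laplace_deviance(np.append(theta[:-1], ls), y),
                    bounds=(-6, 4),
                    method="bounded",
                )
                theta[-1] = res.x
            return self._results_at(theta, y)
        theta0 = self._default_start() if start_theta is None else np.asarray(start_theta, float)
        self._v_warm = np.zeros(self.p + self.q)
        res = optimize.minimize(
            self._laplace_deviance,
            theta0,
            args=(y,),
            method="Nelder-Mead",
            options=dict(maxfev=maxfev, xatol=xatol, fatol=fatol),
        )
        return self._results_at(res.x, y)

    def refit_responses(self, y_new, theta) -> MixedGLMResults:
        """Refit fixed effects and random-effect modes to a new response
        vector at fixed variance components ``theta`` (the fast path used
        by the permutation test)."""
        y_new = np.asarray(y_new, dtype=float).ravel()
        if y_new.shape != self.y.shape:
            raise ValueError("response length mismatch")
        return self._results_at(np.asarray(theta, float), y_new, warm=True)

    def _fit_fixed_only(self) -> MixedGLMResults:
        """Degenerate model with all random-effect variances at zero."""
        X, y = self.X, self.y
        if self.family == "gaussian":
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            dof = self.nobs - self.p
            s2 = float(resid @ resid) / dof
            cov = s2 * np.linalg.inv(X.T @ X)
            eta = X @ beta
            scale = np.sqrt(s2)
            ll = float(
                -0.5 * self.nobs * (np.log(2 * np.pi * s2) + 1)
            )
        else:
            beta = np.zeros(self.p)
            for _ in range(100):
                eta = X @ beta
                mu = expit(eta)
                w = mu * (1 - mu) + 1e-10
                g = X.T @ (y - mu)
                H = (X.T * w) @ X
                step = np.linalg.solve(H, g)
                beta = beta + step
                if np.abs(g).max() < 1e-10:
                    break
            eta = X @ beta
            cov = np.linalg.inv((X.T * (expit(eta) * (1 - expit(eta)) + 1e-10)) @ X)
            scale = 1.0
            ll = float(y @ eta - _log1pexp(eta).sum())
        bse = np.sqrt(np.diag(cov))
        fitted = expit(eta) if self.family == "binomial" else eta
        re_sds = {
            (name, what): 0.0
            for name in self.factor_names
            for what in ("intercept", "slope")
        }
        return MixedGLMResults(
            params=beta,
            bse=bse,
            tvalues=beta / bse,
            re_sds=re_sds,
            scale=scale,
            fitted_conditional=fitted,
            converged=True,
            separated=bool(np.abs(eta).max() > _SEPARATION_ETA),
            loglik=ll,
            family=self.family,
            nobs=self.nobs,
            theta=np.full(self.n_comp, -np.inf),
            random_effects=np.zeros(self.q),
            model=self,
        )

    def _results_at(self, theta, y, warm=False) -> MixedGLMResults:
        log_sd = theta[: self.n_comp]
        sigma_e = float(np.exp(theta[self.n_comp])) if self.family == "gaussian" else 1.0
        sd, pen = self._penalty(log_sd)
        v0 = self._v_warm if warm else None
        v, H, _, ok = self._pirls(pen, y, sigma_e=sigma_e, v0=v0)
        eta = self.C @ v
        cf = cho_factor(H, lower=True, check_finite=False)
        eye2 = np.zeros((self.p + self.q, self.p))
        eye2[: self.p, : self.p] = np.eye(self.p)
        cov_fe = cho_solve(cf, eye2, check_finite=False)[: self.p, : self.p]
        bse = np.sqrt(np.maximum(np.diag(cov_fe), 0.0))
        beta = v[: self.p]
        fitted = expit(eta) if self.family == "binomial" else eta
        re_sds = {}
        comp = 0
        for name in self.factor_names:
            re_sds[(name, "intercept")] = float(sd[comp])
            re_sds[(name, "slope")] = float(sd[comp + 1])
            comp += 2
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(bse > 0, beta / bse, np.nan)
        return MixedGLMResults(
            params=beta,
            bse=bse,
            tvalues=tvals,
            re_sds=re_sds,
            scale=sigma_e,
            fitted_conditional=fitted,
            converged=bool(ok and np.isfinite(tvals).all()),
            separated=bool(
                self.family == "binomial" and np.abs(eta).max() > _SEPARATION_ETA
            ),
            loglik=-0.5 * self._laplace_deviance(theta, y, warm=False),
            family=self.family,
            nobs=self.nobs,
            theta=np.asarray(theta, float),
            random_effects=v[self.p:],
            model=self,
        )
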