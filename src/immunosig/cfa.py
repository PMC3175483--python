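"""Confirmatory factor analysis and structural equation models.

The measurement model is the canonical linear CFA

    x = Λ ξ + δ,      Σ(θ) = Λ Φ Λ' + Θ

with pattern constraints on Λ (each factor scaled by one fixed loading or a
fixed variance), free residual variances Θ = diag(θ), and a free/fixed
factor covariance matrix Φ.  Estimation minimizes the ML discrepancy

    F_ML = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − v

by quasi-Newton with analytic gradients; χ² = (n−1)·F_ML at the optimum.
Fit is judged by χ², RMSEA = sqrt(max(0, (χ²/df − 1)/(n − 1))) and SRMR.

Structural models regress disease status on the latent factors: the default
two-stage route takes Bartlett factor scores into a logistic/multinomial
regression; the joint route integrates the latent factors out by
Gauss–Hermite quadrature.  A second-order variant lets first-order factors
load on a common higher factor, which is how a shared-construct hypothesis
is put to the test (poor fit rejects it).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .testing import RegressionResult, fit_logistic, fit_multinomial

__all__ = [
    "CfaSpec",
    "CfaResult",
    "FitIndices",
    "StructuralResult",
    "CFAModel",
    "model_df",
    "cfa_fit",
    "fit_indices",
    "cfa_classify",
    "sem_fit",
    "second_order_fit",
    "parse_spec_text",
]

_VAR_FLOOR = 1e-8
_LOG_FLOOR = np.log(_VAR_FLOOR)


@dataclass
class CfaSpec:
    """Pattern constraints of a confirmatory factor model.

    Parameters
    ----------
    factors : factor id -> ordered indicator ids loading on it.
    fixed : (indicator, factor) -> fixed loading value.  When a factor has
        neither a fixed loading nor a fixed variance, its first indicator's
        loading is fixed to 1 (the usual scaling constraint).
    fixed_variance : factor id -> fixed variance value.
    covary : pairs of factors with a free covariance; ``"all"`` (default)
        frees every pair; ``"none"`` fixes all covariances to zero.
    second_order : optional name of a higher-order factor on which every
        first-order factor loads (shared-construct test).
    outcome, link, reference_level : optional structural part — regress
        *outcome* (a per-sample label) on the latent factors with a
        ``logistic`` or ``multinomial`` link.
    """

    factors: dict[str, list[str]]
    fixed: dict[tuple[str, str], float] = field(default_factory=dict)
    fixed_variance: dict[str, float] = field(default_factory=dict)
    covary: object = "all"
    second_order: str | None = None
    outcome: str | None = None
    link: str = "logistic"
    reference_level: str | None = None

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("spec needs at least one factor")
        self.factor_ids = list(self.factors)
        seen: dict[str, None] = {}
        for f, inds in self.factors.items():
            if not inds:
                raise ValueError(f"factor {f!r} has no indicators")
            for i in inds:
                seen.setdefault(str(i), None)
        self.indicator_ids = list(seen)
        # default scaling: first indicator loading fixed to 1
        for f, inds in self.factors.items():
            has_fixed = any((i, f) in self.fixed and self.fixed[(i, f)] != 0
                            for i in inds)
            if not has_fixed and f not in self.fixed_variance:
                self.fixed[(inds[0], f)] = 1.0
        for (i, f), val in self.fixed.items():
            if f not in self.factors or i not in self.factors[f]:
                raise ValueError(f"fixed loading {i}@{f} not in the pattern")
        if isinstance(self.covary, str) and self.covary not in ("all", "none"):
            raise ValueError("covary must be 'all', 'none', or a list of pairs")

    # -- pattern matrices ---------------------------------------------------
    def loading_pattern(self):
        """(fixed-value matrix, free mask) of shape v x m."""
        v, m = len(self.indicator_ids), len(self.factor_ids)
        fixed = np.zeros((v, m))
        free = np.zeros((v, m), dtype=bool)
        idx = {i: r for r, i in enumerate(self.indicator_ids)}
        for j, f in enumerate(self.factor_ids):
            for i in self.factors[f]:
                r = idx[i]
                if (i, f) in self.fixed:
                    fixed[r, j] = self.fixed[(i, f)]
                else:
                    free[r, j] = True
        return fixed, free

    def covary_pairs(self) -> list[tuple[int, int]]:
        m = len(self.factor_ids)
        if self.covary == "all":
            return [(i, j) for i in range(m) for j in range(i + 1, m)]
        if self.covary == "none":
            return []
        fi = {f: j for j, f in enumerate(self.factor_ids)}
        pairs = []
        for a, b in self.covary:
            i, j = sorted((fi[a], fi[b]))
            pairs.append((i, j))
        return pairs

    def n_free_parameters(self) -> int:
        _, free = self.loading_pattern()
        n = int(free.sum()) + len(self.indicator_ids)  # loadings + residuals
        m = len(self.factor_ids)
        if self.second_order is None:
            n += sum(1 for f in self.factor_ids if f not in self.fixed_variance)
            n += len(self.covary_pairs())
        else:
            # Phi = Γ φ_g Γ' + diag(ψ).  Identification: with two
            # first-order factors both Γ are fixed to 1 and φ_g is free;
            # with three or more, φ_g is fixed to 1 and all Γ are free.
            n += m                   # disturbances ψ
            n += 1 if m == 2 else m  # φ_g, or free second-order loadings
        return n


def model_df(spec: CfaSpec, v: int | None = None) -> int:
    """Degrees of freedom: v(v+1)/2 unique covariance moments minus free
    parameters (covariance structure only, no mean structure)."""
    if v is None:
        v = len(spec.indicator_ids)
    df = v * (v + 1) // 2 - spec.n_free_parameters()
    if df < 0:
        raise ValueError(
            f"model under-identified: {spec.n_free_parameters()} free "
            f"parameters exceed {v * (v + 1) // 2} covariance moments"
        )
    return df


@dataclass
class FitIndices:
    chi_square: float
    df: int
    p_value: float
    rmsea: float
    srmr: float
    n: int

    def summary(self) -> str:
        p = "n/a" if np.isnan(self.p_value) else f"{self.p_value:.4f}"
        r = "n/a" if np.isnan(self.rmsea) else f"{self.rmsea:.4f}"
        return (f"Chi-Sq = {self.chi_square:.3f}, df = {self.df}, p = {p}, "
                f"RMSEA = {r}, SRMR = {self.srmr:.4f}, n = {self.n}")


def fit_indices(chi_square: float, df: int, n: int,
                S: np.ndarray, Sigma: np.ndarray) -> FitIndices:
    """χ² tail p, RMSEA and SRMR.

    RMSEA is based on the non-centrality estimate (χ²/df − 1)/(n − 1),
    clamped at zero; with df = 0 (just-identified model) RMSEA and p are
    reported as NaN markers while SRMR — a pure residual summary — is still
    computed over the v(v+1)/2 unique elements of the correlation-scaled
    residual matrix (diagonal included).
    """
    if df < 0:
        raise ValueError("df must be >= 0")
    if n <= 1:
        raise ValueError("n must exceed 1")
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    d = np.sqrt(np.outer(np.diag(S), np.diag(S)))
    resid = (S - Sigma) / d
    iu = np.triu_indices_from(resid)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    if df == 0:
        return FitIndices(float(chi_square), 0, np.nan, np.nan, srmr, int(n))
    p = float(stats.chi2.sf(chi_square, df))
    rmsea = float(np.sqrt(max(0.0, (chi_square / df - 1.0) / (n - 1))))
    return FitIndices(float(chi_square), int(df), p, rmsea, srmr, int(n))


@dataclass
class CfaResult:
    """Estimates of a fitted confirmatory factor model."""

    spec: CfaSpec
    loadings: pd.DataFrame            # v x m estimated Λ (fixed values included)
    residual_variances: pd.Series     # Θ diagonal
    factor_covariance: pd.DataFrame   # Φ
    standardized_loadings: pd.DataFrame
    std_errors: pd.DataFrame          # SEs for free loadings (NaN where fixed)
    fmin: float
    converged: bool
    n: int
    fit: FitIndices | None = None
    factor_scores: pd.DataFrame | None = None   # Bartlett scores per sample
    second_order_loadings: pd.Series | None = None
    disturbances: pd.Series | None = None
    at_bound: np.ndarray | None = None
    n_iterations: int = 0

    def implied_covariance(self) -> np.ndarray:
        L = self.loadings.to_numpy()
        return (L @ self.factor_covariance.to_numpy() @ L.T
                + np.diag(self.residual_variances.to_numpy()))

    def summary(self) -> str:
        lines = [
            "Confirmatory factor analysis (ML)",
            f"indicators: {len(self.spec.indicator_ids)}  "
            f"factors: {len(self.spec.factor_ids)}  n = {self.n}  "
            f"converged: {self.converged}",
        ]
        if self.fit is not None:
            lines.append(self.fit.summary())
        lines += ["", "Loadings (standardized in brackets):"]
        for f in self.spec.factor_ids:
            for i in self.spec.factors[f]:
                est = self.loadings.loc[i, f]
                std = self.standardized_loadings.loc[i, f]
                se = self.std_errors.loc[i, f]
                tag = "fixed" if np.isnan(se) else f"se {se:.3f}"
                lines.append(f"  {i} <- {f}: {est:.4f} [{std:.4f}] ({tag})")
        lines += ["", "Factor covariance:",
                  self.factor_covariance.round(4).to_string()]
        if self.second_order_loadings is not None:
            lines += ["", "Second-order loadings:",
                      self.second_order_loadings.round(4).to_string()]
        return "\n".join(lines)


def _prepare_cov(data, indicator_ids):
    """Return (S, n, obs matrix or None, means) for the listed indicators."""
    if isinstance(data, tuple):
        S, n = data
        S = np.asarray(S, dtype=float)
        return S, int(n), None, None
    if hasattr(data, "to_frame") and hasattr(data, "values"):
        frame = data.to_frame()
    elif isinstance(data, pd.DataFrame):
        frame = data
    else:
        arr = np.asarray(data, dtype=float)
        frame = pd.DataFrame(arr, columns=indicator_ids)
    missing = [i for i in indicator_ids if i not in frame.columns]
    if missing:
        raise KeyError(f"indicators not found in data: {missing}")
    X = frame[indicator_ids].to_numpy(dtype=float)
    n = X.shape[0]
    S = np.cov(X, rowvar=False, ddof=1)
    return S, n, X, X.mean(axis=0)


class CFAModel:
    """Confirmatory factor model bound to data.

    Parameters
    ----------
    spec : CfaSpec
    data : a NormalizedMatrix / DataFrame / array of observations, or a
        tuple ``(S, n)`` of sample covariance and sample size.

    ``fit()`` returns a :class:`CfaResult` with fit indices attached.
    """

    def __init__(self, spec: CfaSpec, data):
        self.spec = spec
        self.S, self.n, self.X, self.means = _prepare_cov(data, spec.indicator_ids)
        v = len(spec.indicator_ids)
        if self.S.shape != (v, v):
            raise ValueError("covariance shape does not match indicator count")
        w = np.linalg.eigvalsh(self.S)
        if w.min() < 1e-10 * max(w.max(), 1.0):
            raise ValueError(
                "sample covariance is (near-)singular; use fewer indicators "
                "or more observations"
            )
        if self.n <= spec.n_free_parameters():
            raise ValueError(
                f"n = {self.n} must exceed the {spec.n_free_parameters()} "
                "free parameters"
            )
        self.df = model_df(spec, v)
        self._logdetS = float(np.linalg.slogdet(self.S)[1])
        self._lam_fixed, self._lam_free = spec.loading_pattern()
        self._pairs = spec.covary_pairs()
        self._m = len(spec.factor_ids)
        self._v = v

    # -- parameter packing --------------------------------------------------
    def _free_var_factors(self):
        return [j for j, f in enumerate(self.spec.factor_ids)
                if f not in self.spec.fixed_variance]

    def _n_gamma_free(self):
        # m == 2: Γ fixed to ones, φ_g free; m >= 3: φ_g fixed, Γ free
        return 0 if self._m == 2 else self._m

    def _start(self) -> np.ndarray:
        """Start values: moderate loadings on the observed scale, half the
        observed variance as residual, modest positive factor covariances."""
        sd = np.sqrt(np.diag(self.S))
        parts = []
        lam0 = np.zeros_like(self._lam_fixed)
        scale = np.ones(self._m)
        for j, f in enumerate(self.spec.factor_ids):
            inds = [self.spec.indicator_ids.index(i) for i in self.spec.factors[f]]
            ref = [i for i in inds if self._lam_fixed[i, j] != 0]
            scale[j] = sd[ref[0]] * abs(self._lam_fixed[ref[0], j]) if ref else 1.0
        for i in range(self._v):
            for j in range(self._m):
                if self._lam_free[i, j]:
                    lam0[i, j] = 0.7 * sd[i] / max(scale[j], 1e-6)
        parts.append(lam0[self._lam_free])
        parts.append(np.log(np.maximum(0.5 * np.diag(self.S), _VAR_FLOOR)))
        if self.spec.second_order is None:
            fv = self._free_var_factors()
            parts.append(np.log(np.maximum(0.5 * scale[fv] ** 2, _VAR_FLOOR)))
            parts.append(np.array([0.2 * scale[i] * scale[j] * 0.5
                                   for i, j in self._pairs]))
        else:
            if self._m == 2:
                parts.append(np.array([np.log(0.5)]))          # φ_g
            else:
                parts.append(np.full(self._m, 0.7))            # Γ free
            parts.append(np.log(np.full(self._m, 0.3)))        # ψ disturbances
        return np.concatenate([np.atleast_1d(p) for p in parts])

    def _unpack(self, params: np.ndarray):
        k = int(self._lam_free.sum())
        lam = self._lam_fixed.copy()
        lam[self._lam_free] = params[:k]
        pos = k
        theta = np.exp(params[pos:pos + self._v])
        pos += self._v
        if self.spec.second_order is None:
            phi = np.zeros((self._m, self._m))
            for j, f in enumerate(self.spec.factor_ids):
                if f in self.spec.fixed_variance:
                    phi[j, j] = self.spec.fixed_variance[f]
            fv = self._free_var_factors()
            for j, val in zip(fv, params[pos:pos + len(fv)]):
                phi[j, j] = np.exp(val)
            pos += len(fv)
            for (i, j), val in zip(self._pairs, params[pos:pos + len(self._pairs)]):
                phi[i, j] = phi[j, i] = val
            pos += len(self._pairs)
            extra = None
        else:
            if self._m == 2:
                gamma = np.ones(2)
                phi_g = np.exp(params[pos])
                pos += 1
            else:
                gamma = params[pos:pos + self._m].copy()
                pos += self._m
                phi_g = 1.0
            psi = np.exp(params[pos:pos + self._m])
            pos += self._m
            phi = phi_g * np.outer(gamma, gamma) + np.diag(psi)
            extra = (gamma, psi, phi_g)
        return lam, theta, phi, extra

    def _fmin_grad(self, params: np.ndarray):
        lam, theta, phi, extra = self._unpack(params)
        Sigma = lam @ phi @ lam.T + np.diag(theta)
        try:
            c = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(params)
        logdet = 2.0 * float(np.log(np.diag(c)).sum())
        Sinv = np.linalg.inv(Sigma)
        F = logdet + float(np.trace(self.S @ Sinv)) - self._logdetS - self._v
        W = Sinv @ (Sigma - self.S) @ Sinv
        gl = 2.0 * W @ lam @ phi
        M = lam.T @ W @ lam
        grads = [gl[self._lam_free], np.diag(W) * theta]
        if self.spec.second_order is None:
            fv = self._free_var_factors()
            grads.append(np.array([M[j, j] * phi[j, j] for j in fv]))
            grads.append(np.array([2.0 * M[i, j] for i, j in self._pairs]))
        else:
            gamma, psi, phi_g = extra
            if self._m == 2:
                grads.append(np.array([float(gamma @ M @ gamma) * phi_g]))
            else:
                grads.append(2.0 * phi_g * (M @ gamma))
            grads.append(np.diag(M) * psi)
        return F, np.concatenate([np.atleast_1d(g) for g in grads])

    def fit(self, start: np.ndarray | None = None, max_iter: int = 500,
            tol: float = 1e-10, robust: bool = False,
            compute_scores: bool = True) -> CfaResult:
        x0 = self._start() if start is None else np.asarray(start, dtype=float)
        k = int(self._lam_free.sum())
        bounds = [(None, None)] * k + [(_LOG_FLOOR, None)] * self._v
        nrest = x0.size - k - self._v
        if self.spec.second_order is None:
            fv = len(self._free_var_factors())
            bounds += [(_LOG_FLOOR, None)] * fv
            bounds += [(None, None)] * (nrest - fv)
        elif self._m == 2:
            bounds += [(_LOG_FLOOR, None)] * (1 + self._m)
        else:
            bounds += [(None, None)] * self._m
            bounds += [(_LOG_FLOOR, None)] * self._m
        res = optimize.minimize(
            self._fmin_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9},
        )
        params = res.x
        lam, theta, phi, extra = self._unpack(params)
        Sigma = lam @ phi @ lam.T + np.diag(theta)
        fmin = max(float(res.fun), 0.0)
        chi2 = max((self.n - 1) * fmin, 0.0)
        fi = fit_indices(chi2, self.df, self.n, self.S, Sigma)

        se_free = self._standard_errors(params, robust=robust)
        se_lam = np.full_like(lam, np.nan)
        se_lam[self._lam_free] = se_free[:k]

        sd_sigma = np.sqrt(np.diag(Sigma))
        std = lam * np.sqrt(np.diag(phi))[None, :] / sd_sigma[:, None]
        at_bound = theta <= _VAR_FLOOR * 1.001

        ids, fids = self.spec.indicator_ids, self.spec.factor_ids
        scores = None
        if compute_scores and self.X is not None:
            scores = pd.DataFrame(
                _bartlett_scores(self.X - self.means, lam, theta),
                columns=fids,
            )
        second, dist = None, None
        if extra is not None:
            gamma, psi, phi_g = extra
            gamma = gamma * np.sqrt(phi_g)  # loading scale of the higher factor
            second = pd.Series(gamma, index=fids, name=self.spec.second_order)
            dist = pd.Series(psi, index=fids, name="disturbance")
        return CfaResult(
            spec=self.spec,
            loadings=pd.DataFrame(lam, index=ids, columns=fids),
            residual_variances=pd.Series(theta, index=ids),
            factor_covariance=pd.DataFrame(phi, index=fids, columns=fids),
            standardized_loadings=pd.DataFrame(std, index=ids, columns=fids),
            std_errors=pd.DataFrame(se_lam, index=ids, columns=fids),
            fmin=fmin,
            converged=bool(res.success) or fmin < 1e-10,
            n=self.n,
            fit=fi,
            factor_scores=scores,
            second_order_loadings=second,
            disturbances=dist,
            at_bound=at_bound,
            n_iterations=int(res.nit),
        ), fi

    # -- uncertainty --------------------------------------------------------
    def _standard_errors(self, params: np.ndarray, robust: bool = False) -> np.ndarray:
        """SEs of the free parameters; plain ML from the inverse Hessian of
        the discrepancy, or a Huber-White sandwich when ``robust`` and raw
        observations are available."""
        H = _numeric_hessian(lambda p: self._fmin_grad(p)[1], params)
        H = (H + H.T) / 2.0
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            Hinv = np.linalg.pinv(H)
        acov = 2.0 / (self.n - 1) * Hinv
        if robust and self.X is not None:
            acov = self._sandwich(params, Hinv)
        se = np.sqrt(np.maximum(np.diag(acov), 0.0))
        # delta-method back to the natural scale for log-parametrized terms
        k = int(self._lam_free.sum())
        jac = np.ones_like(params)
        lam, theta, phi, extra = self._unpack(params)
        jac[k:k + self._v] = theta
        if self.spec.second_order is None:
            fv = self._free_var_factors()
            jac[k + self._v:k + self._v + len(fv)] = np.diag(phi)[fv]
        return se * jac

    def _sandwich(self, params: np.ndarray, Hinv: np.ndarray) -> np.ndarray:
        """Huber-White: A⁻¹ B A⁻¹ with per-observation score outer products."""
        Xc = self.X - self.means
        n = Xc.shape[0]

        def per_obs_nll(p):
            lam, theta, phi, _ = self._unpack(p)
            Sigma = lam @ phi @ lam.T + np.diag(theta)
            c = np.linalg.cholesky(Sigma)
            logdet = 2.0 * np.log(np.diag(c)).sum()
            sol = np.linalg.solve(Sigma, Xc.T)
            quad = (Xc.T * sol).sum(axis=0)
            return 0.5 * (logdet + quad)

        eps = 1e-5
        scores = np.zeros((n, params.size))
        base = per_obs_nll(params)
        for k in range(params.size):
            pp = params.copy()
            pp[k] += eps
            scores[:, k] = (per_obs_nll(pp) - base) / eps
        B = scores.T @ scores
        Ainv = 2.0 / (n - 1) * Hinv  # inverse Hessian of the total -loglik
        return Ainv @ B @ Ainv


def _numeric_hessian(grad_fn, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    g0 = grad_fn(x)
    H = np.zeros((x.size, x.size))
    for k in range(x.size):
        xp = x.copy()
        xp[k] += eps
        H[:, k] = (grad_fn(xp) - g0) / eps
    return H


def _bartlett_scores(Xc: np.ndarray, lam: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Bartlett estimator ξ = (Λ'Θ⁻¹Λ)⁻¹ Λ'Θ⁻¹ x on centered data."""
    Ti = 1.0 / np.maximum(theta, _VAR_FLOOR)
    A = lam.T * Ti
    M = A @ lam
    return np.linalg.solve(M, A @ Xc.T).T


def cfa_fit(spec: CfaSpec, data, robust: bool = False) -> tuple[CfaResult, FitIndices]:
    """Fit a confirmatory factor model; returns (result, fit indices)."""
    return CFAModel(spec, data).fit(robust=robust)


def second_order_fit(spec: CfaSpec, data) -> tuple[CfaResult, FitIndices]:
    """Fit a hierarchical model: first-order factors load on one common
    second-order factor (variance fixed to 1; with two first-order factors
    both second-order loadings are fixed to 1 for identification).

    Used to test whether two similar factors measure one construct — a
    large RMSEA rejects the shared-construct reading.
    """
    if spec.second_order is None:
        spec = CfaSpec(
            factors=dict(spec.factors), fixed=dict(spec.fixed),
            fixed_variance=dict(spec.fixed_variance), covary="none",
            second_order="g",
        )
    for f, inds in spec.factors.items():
        if len(inds) < 3:
            raise ValueError(
                f"second-order model needs >=3 indicators per factor "
                f"({f!r} has {len(inds)})"
            )
    return CFAModel(spec, data).fit()


# -- sample classification --------------------------------------------------

@dataclass
class SampleClassification:
    sample_id: str
    loadings: pd.Series          # standardized loading on each factor
    assigned_factor: str | None
    correct: bool | None


def cfa_classify(data, labels, holdout=None, threshold: float = 0.3,
                 seed: int = 0) -> list[SampleClassification]:
    """Confirmatory classification with samples as indicators.

    The transposed data (peptides are the observations, samples the
    indicators) is fitted with one factor per disease group; one reference
    sample per factor — chosen at random under *seed* — is fixed at loading
    1, every other known sample loads freely on its group's factor only,
    and each *holdout* sample is given free loadings on **all** factors.
    A holdout is assigned to the factor with its largest standardized
    loading when that clears *threshold* (with ``threshold=0`` the argmax
    always wins); below-threshold samples stay unclassified.
    """
    frame = data.to_frame().T if hasattr(data, "to_frame") else pd.DataFrame(data).T
    sample_ids = list(frame.columns)
    labels = {s: str(g) for s, g in zip(sample_ids, labels)}
    if holdout is None:
        holdout = []
    elif isinstance(holdout, str):
        holdout = [holdout]
    holdout = [str(h) for h in holdout]
    rng = np.random.default_rng(seed)

    groups = list(dict.fromkeys(labels[s] for s in sample_ids if s not in holdout))
    members = {g: [s for s in sample_ids if s not in holdout and labels[s] == g]
               for g in groups}
    refs = {}
    for g in groups:
        if not members[g]:
            raise ValueError(f"group {g!r} has no non-holdout samples")
        refs[g] = members[g][int(rng.integers(len(members[g])))]
    for h in holdout:
        if h in refs.values():
            raise ValueError(f"holdout {h!r} is a scaling reference")

    factors = {g: list(members[g]) + holdout for g in groups}
    fixed = {(refs[g], g): 1.0 for g in groups}
    spec = CfaSpec(factors=factors, fixed=fixed, covary="all")
    result, _ = CFAModel(spec, frame).fit(compute_scores=False)

    out = []
    for s in holdout or sample_ids:
        row = result.standardized_loadings.loc[s]
        best = row.abs().idxmax()
        assigned = best if (abs(row[best]) >= threshold or threshold == 0.0) else None
        truth = labels.get(s)
        out.append(SampleClassification(
            sample_id=s,
            loadings=row,
            assigned_factor=assigned,
            correct=None if truth is None or assigned is None else assigned == truth,
        ))
    return out


# -- structural models -------------------------------------------------------

@dataclass
class StructuralResult:
    """Latent-factor regression of disease status.

    ``coefficients`` etc. have one row per latent factor (plus intercept)
    and one column per non-reference outcome level; odds ratios are per
    unit of the latent factor on its scaling metric, with a per-SD column
    as a secondary scale.
    """

    outcome_levels: list[str]
    reference_level: str
    coefficients: pd.DataFrame
    odds_ratios: pd.DataFrame
    odds_ratios_per_sd: pd.DataFrame
    std_errors: pd.DataFrame
    p_values: pd.DataFrame
    estimation_method: str
    converged: bool

    def summary(self) -> str:
        lines = [f"Structural model ({self.estimation_method}); "
                 f"reference level: {self.reference_level}"]
        for lv in self.coefficients.columns:
            lines.append(f"outcome level {lv}:")
            for f in self.coefficients.index:
                lines.append(
                    f"  {f}: coef {self.coefficients.loc[f, lv]:+.4f}  "
                    f"OR {self.odds_ratios.loc[f, lv]:.4f}  "
                    f"p {self.p_values.loc[f, lv]:.4g}"
                )
        return "\n".join(lines)


def _structural_from_regression(reg: RegressionResult, factor_ids, factor_sd,
                                method: str) -> StructuralResult:
    idx = ["intercept"] + list(factor_ids)
    coef = reg.coefficients.set_axis(idx, axis=0)
    se = reg.std_errors.set_axis(idx, axis=0)
    p = reg.p_values.set_axis(idx, axis=0)
    or_sd = np.exp(coef.mul(pd.Series({**{"intercept": 1.0},
                                       **dict(zip(factor_ids, factor_sd))}), axis=0))
    return StructuralResult(
        outcome_levels=reg.outcome_levels,
        reference_level=reg.reference_level,
        coefficients=coef,
        odds_ratios=np.exp(coef),
        odds_ratios_per_sd=or_sd,
        std_errors=se,
        p_values=p,
        estimation_method=method,
        converged=reg.converged,
    )


def sem_fit(spec: CfaSpec, data, labels, method: str = "two_stage",
            n_quadrature: int = 15):
    """Full structural equation model: measurement CFA plus a logistic /
    multinomial regression of disease status on the latent factors.

    ``two_stage`` (default): fit the measurement model, compute Bartlett
    factor scores, regress the outcome on the scores.  ``quadrature_ml``:
    joint maximum likelihood with the latent factors integrated out on a
    Gauss–Hermite grid (supported for one or two factors).

    Returns (CfaResult, FitIndices, StructuralResult).
    """
    labels = [str(g) for g in labels]
    frame = data.to_frame() if hasattr(data, "to_frame") else pd.DataFrame(data)
    if len(labels) != frame.shape[0]:
        raise ValueError("labels length does not match observation count")
    v = len(spec.indicator_ids)
    if method == "quadrature_ml" and v >= frame.shape[0]:
        raise ValueError(
            "more indicators than observations: the full joint model is not "
            "estimable — use a top-k indicator subset or method='two_stage'"
        )
    link = spec.link if spec.outcome else ("multinomial" if len(set(labels)) > 2
                                           else "logistic")
    ref = spec.reference_level

    if method == "two_stage":
        result, fi = CFAModel(spec, frame).fit()
        scores = result.factor_scores.to_numpy()
        if link == "multinomial" and len(set(labels)) > 2:
            reg = fit_multinomial(labels, scores, reference_level=ref)
        else:
            reg = fit_logistic(labels, scores, reference_level=ref)
        sd = np.sqrt(np.diag(result.factor_covariance.to_numpy()))
        struct = _structural_from_regression(reg, spec.factor_ids, sd, "two_stage")
        return result, fi, struct
    if method == "quadrature_ml":
        return _sem_quadrature(spec, frame, labels, ref, link, n_quadrature)
    raise ValueError(f"unknown method {method!r}")


def _sem_quadrature(spec: CfaSpec, frame: pd.DataFrame, labels, ref, link,
                    n_nodes: int):
    """Joint ML: x | η ~ N(μ + Λη, Θ), logit P(y | η) linear in η,
    η ~ N(0, Φ) integrated out by (tensor) Gauss–Hermite quadrature."""
    m = len(spec.factor_ids)
    if m > 2:
        raise ValueError("quadrature_ml supports at most two latent factors")
    X = frame[spec.indicator_ids].to_numpy(dtype=float)
    n, v = X.shape
    levels = list(dict.fromkeys(labels))
    if ref is None:
        ref = levels[0]
    others = [lv for lv in levels if lv != ref]
    L = len(others)
    if L == 0:
        raise ValueError("outcome has a single level")
    ycode = np.array([0 if lab == ref else others.index(lab) + 1 for lab in labels])

    # hermegauss integrates against exp(-x^2/2): E[f(Z)] = Σ w_q f(x_q)/√(2π)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    logw = np.log(weights) - 0.5 * np.log(2 * np.pi)
    if m == 1:
        grid = nodes[:, None]
        glogw = logw
    else:
        grid = np.array([[a, b] for a in nodes for b in nodes])
        glogw = np.add.outer(logw, logw).ravel()

    lam_fixed, lam_free = spec.loading_pattern()
    kfree = int(lam_free.sum())

    # parameters: mu(v), free loadings, log theta(v), structural (1+m)*L,
    # factor scale: log variances (free) + covariance if m==2
    fv = [j for j, f in enumerate(spec.factor_ids)
          if f not in spec.fixed_variance]
    ncov = 1 if m == 2 else 0

    def unpack(p):
        pos = 0
        mu = p[pos:pos + v]; pos += v
        lam = lam_fixed.copy()
        lam[lam_free] = p[pos:pos + kfree]; pos += kfree
        theta = np.exp(p[pos:pos + v]); pos += v
        beta = p[pos:pos + (1 + m) * L].reshape(L, 1 + m); pos += (1 + m) * L
        phi = np.eye(m)
        for j, f in enumerate(spec.factor_ids):
            if f in spec.fixed_variance:
                phi[j, j] = spec.fixed_variance[f]
        for j, val in zip(fv, p[pos:pos + len(fv)]):
            phi[j, j] = np.exp(val)
        pos += len(fv)
        if ncov:
            r = np.tanh(p[pos]); pos += 1
            phi[0, 1] = phi[1, 0] = r * np.sqrt(phi[0, 0] * phi[1, 1])
        return mu, lam, theta, beta, phi

    def nll(p):
        mu, lam, theta, beta, phi = unpack(p)
        try:
            C = np.linalg.cholesky(phi)
        except np.linalg.LinAlgError:
            return 1e10
        eta = grid @ C.T                             # Q x m latent values
        mean_q = mu[None, :] + eta @ lam.T           # Q x v
        resid = X[None, :, :] - mean_q[:, None, :]   # Q x n x v
        log_norm = -0.5 * (np.log(2 * np.pi * theta).sum()
                           + (resid**2 / theta[None, None, :]).sum(axis=2))
        lin = beta[:, 0][None, :] + eta @ beta[:, 1:].T   # Q x L
        # log P(y | eta): softmax over [0, lin_1..lin_L]
        full = np.concatenate([np.zeros((lin.shape[0], 1)), lin], axis=1)
        logZ = np.log(np.exp(full).sum(axis=1))
        log_py = full[:, ycode] - logZ[:, None]           # Q x n
        logjoint = glogw[:, None] + log_norm + log_py
        mx = logjoint.max(axis=0)
        ll = mx + np.log(np.exp(logjoint - mx[None, :]).sum(axis=0))
        return -float(ll.sum())

    theta0 = np.log(np.maximum(0.5 * X.var(axis=0, ddof=1), _VAR_FLOOR))
    lam0 = np.full(kfree, 0.5)
    p0 = np.concatenate([X.mean(axis=0), lam0, theta0,
                         np.zeros((1 + m) * L),
                         np.zeros(len(fv)), np.zeros(ncov)])
    res = optimize.minimize(nll, p0, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-10})
    mu, lam, theta, beta, phi = unpack(res.x)

    # observed-information SEs for the structural block
    H = _numeric_hessian(
        lambda p: optimize.approx_fprime(p, nll, 1e-6), res.x, eps=1e-4)
    H = (H + H.T) / 2.0
    try:
        acov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        acov = np.linalg.pinv(H)
    se_all = np.sqrt(np.maximum(np.diag(acov), 0.0))
    pos = v + kfree + v
    se_beta = se_all[pos:pos + (1 + m) * L].reshape(L, 1 + m)

    idx = ["intercept"] + list(spec.factor_ids)
    coef = pd.DataFrame(beta.T, index=idx, columns=others)
    se = pd.DataFrame(se_beta.T, index=idx, columns=others)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = coef.to_numpy() / se.to_numpy()
    pvals = pd.DataFrame(2 * stats.norm.sf(np.abs(z)), index=idx, columns=others)
    sd = np.sqrt(np.diag(phi))
    or_sd = np.exp(coef.mul(pd.Series({**{"intercept": 1.0},
                                       **dict(zip(spec.factor_ids, sd))}), axis=0))
    struct = StructuralResult(
        outcome_levels=levels, reference_level=ref,
        coefficients=coef, odds_ratios=np.exp(coef), odds_ratios_per_sd=or_sd,
        std_errors=se, p_values=pvals,
        estimation_method="quadrature_ml", converged=bool(res.success),
    )
    ids, fids = spec.indicator_ids, spec.factor_ids
    S = np.cov(X, rowvar=False, ddof=1)
    Sigma = lam @ phi @ lam.T + np.diag(theta)
    spec_df = model_df(spec, v)
    chi2 = np.nan
    fi = FitIndices(chi2, spec_df, np.nan, np.nan,
                    fit_indices(0.0, 0, n, S, Sigma).srmr, n)
    result = CfaResult(
        spec=spec,
        loadings=pd.DataFrame(lam, index=ids, columns=fids),
        residual_variances=pd.Series(theta, index=ids),
        factor_covariance=pd.DataFrame(phi, index=fids, columns=fids),
        standardized_loadings=pd.DataFrame(
            lam * sd[None, :] / np.sqrt(np.diag(Sigma))[:, None],
            index=ids, columns=fids),
        std_errors=pd.DataFrame(np.full_like(lam, np.nan), index=ids, columns=fids),
        fmin=float(res.fun), converged=bool(res.success), n=n, fit=fi,
        factor_scores=pd.DataFrame(_bartlett_scores(X - mu, lam, theta),
                                   columns=fids),
    )
    return result, fi, struct


# -- text spec grammar -------------------------------------------------------

def parse_spec_text(text: str) -> CfaSpec:
    """Parse the small order-insensitive model-specification grammar::

        f1: pep1 pep2 pep3          # factor with its indicators
        fix: pep1@f1 = 1            # scaling constraint (optional)
        variance: f1 = 1            # or fix a factor variance instead
        covary: f1 f2               # free factor covariance (default: all)
        covary: none                # all covariances fixed to zero
        second: g                   # second-order factor over all factors
        outcome: disease ~ f1 f2 multinomial ref=single_tumor

    Lines starting with ``#`` are comments.
    """
    factors: dict[str, list[str]] = {}
    fixed: dict[tuple[str, str], float] = {}
    fixed_variance: dict[str, float] = {}
    covary: object = None
    covary_pairs: list[tuple[str, str]] = []
    second = None
    outcome, link, ref = None, "logistic", None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, rest = line.partition(":")
        key, rest = key.strip(), rest.strip()
        if key == "fix":
            mobj = re.match(r"(\S+)@(\S+)\s*=\s*(\S+)", rest)
            if not mobj:
                raise ValueError(f"bad fix line: {raw!r}")
            fixed[(mobj.group(1), mobj.group(2))] = float(mobj.group(3))
        elif key == "variance":
            mobj = re.match(r"(\S+)\s*=\s*(\S+)", rest)
            if not mobj:
                raise ValueError(f"bad variance line: {raw!r}")
            fixed_variance[mobj.group(1)] = float(mobj.group(2))
        elif key == "covary":
            if rest == "none":
                covary = "none"
            elif rest == "all":
                covary = "all"
            else:
                parts = rest.split()
                if len(parts) != 2:
                    raise ValueError(f"bad covary line: {raw!r}")
                covary_pairs.append((parts[0], parts[1]))
        elif key == "second":
            second = rest or "g"
        elif key == "outcome":
            mobj = re.match(r"(\S+)\s*~\s*(.*)", rest)
            if not mobj:
                raise ValueError(f"bad outcome line: {raw!r}")
            outcome = mobj.group(1)
            toks = mobj.group(2).split()
            for t in list(toks):
                if t in ("logistic", "multinomial"):
                    link = t
                    toks.remove(t)
                elif t.startswith("ref="):
                    ref = t[4:]
                    toks.remove(t)
            # remaining tokens are factor names; order handled by spec
        else:
            factors[key] = rest.split()
    if covary is None:
        covary = covary_pairs if covary_pairs else "all"
    return CfaSpec(factors=factors, fixed=fixed, fixed_variance=fixed_variance,
                   covary=covary, second_order=second, outcome=outcome,
                   link=link, reference_level=ref)
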