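"""Exploratory factor mixture models.

A categorical latent class variable C with K levels indexes class-specific
parameters of a factor-analysis model: within class k an observation is

    y = V_k + Λ_k η + ε,     η ~ N(0, Ψ_k),  ε ~ N(0, Θ)

so each class is a multivariate normal with mean V_k (class-specific
intercepts) and structured covariance Λ_k Ψ_k Λ_k' + Θ.  The default,
minimal model frees only the intercepts across classes (loadings and
residual variances shared); fully class-specific loadings are available.

Estimation is EM with multiple perturbed random starts seeded from a
k-means partition; the best log-likelihood is kept and every start's LL is
logged so local solutions can be inspected.  Class enumeration uses
BIC = −2·LL + p·ln(n), and classification crispness is summarized by the
average-latent-class-probability matrix: entry (j, k) is the mean posterior
probability of class k among observations whose modal class is j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .rotation import rotate_loadings

__all__ = ["MixtureResult", "FactorMixtureModel", "fmm_fit", "bic",
           "avg_class_prob"]


def bic(LL: float, p: int, n: int) -> float:
    """Bayesian information criterion −2·LL + p·ln(n) (natural log)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if p < 0:
        raise ValueError(f"parameter count must be >= 0, got {p}")
    return -2.0 * LL + p * np.log(n)


def avg_class_prob(posteriors: np.ndarray,
                   modal_assignments: np.ndarray | None = None) -> np.ndarray:
    """K x K matrix of mean posterior probabilities by modal class.

    Row j averages the posterior vector over observations whose most likely
    class is j; a sharply classified solution has a near-identity matrix.
    Empty modal classes yield a row of NaN markers.
    """
    P = np.asarray(posteriors, dtype=float)
    if P.ndim != 2 or np.any(P < -1e-9) or \
            not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("posterior rows must be nonnegative and sum to 1")
    K = P.shape[1]
    modal = P.argmax(axis=1) if modal_assignments is None \
        else np.asarray(modal_assignments)
    out = np.full((K, K), np.nan)
    for j in range(K):
        mask = modal == j
        if mask.any():
            out[j] = P[mask].mean(axis=0)
    return out


@dataclass
class MixtureResult:
    """Fitted factor mixture: class parameters, posteriors, diagnostics."""

    K: int
    n_factors: int
    intercepts: np.ndarray          # K x v class means V_kp
    loadings: list[np.ndarray]      # per class v x m (shared => identical)
    factor_covariance: list[np.ndarray]  # Ψ_k (identity metric before rotation)
    residual_variances: np.ndarray  # v, shared Θ diagonal
    class_weights: np.ndarray       # P_k, descending
    posteriors: np.ndarray          # n x K
    modal_class: np.ndarray         # n
    log_likelihood: float
    n_parameters: int
    n_observations: int
    bic: float
    avg_class_prob: np.ndarray      # K x K
    start_log: list[float]          # best LL per random start
    converged: bool
    ll_trace: np.ndarray = field(default=None)  # type: ignore[assignment]
    empty_class_flag: bool = False
    rotation: str = "none"
    variable_ids: list[str] | None = None

    def summary(self) -> str:
        lines = [
            f"Factor mixture model: K = {self.K} classes, "
            f"{self.n_factors} factor(s), n = {self.n_observations}",
            f"LL = {self.log_likelihood:.4f}  parameters = {self.n_parameters}  "
            f"BIC = {self.bic:.4f}  converged: {self.converged}",
            "class weights: " + " ".join(f"{w:.4f}" for w in self.class_weights),
            "average latent class probabilities (rows = modal class):",
            pd.DataFrame(self.avg_class_prob).round(4).to_string(),
        ]
        if self.empty_class_flag:
            lines.append("warning: at least one class is effectively empty")
        return "\n".join(lines)


def _fa_em_step(S: np.ndarray, lam: np.ndarray, theta: np.ndarray,
                n_inner: int = 1):
    """EM update(s) for a factor model with Ψ = I fitted to scatter S;
    each update increases the Gaussian likelihood for S."""
    v, m = lam.shape
    for _ in range(n_inner):
        Sigma = lam @ lam.T + np.diag(theta)
        beta = np.linalg.solve(Sigma, lam).T           # m x v
        Ezz = np.eye(m) - beta @ lam + beta @ S @ beta.T
        lam = S @ beta.T @ np.linalg.inv(Ezz)
        theta = np.maximum(np.diag(S - lam @ beta @ S), 1e-8)
    return lam, theta


class FactorMixtureModel:
    """Mixture of factor-analysis models bound to an observation matrix.

    Parameters
    ----------
    data : observations x variables matrix (array, DataFrame, or anything
        with ``.values``); in the immunosignature pipeline the observations
        are usually samples and the variables significant peptides.
    n_classes : K >= 1.
    n_factors : common factors per class (Ψ_k fixed to the identity for
        identification; loadings can be rotated afterwards for reporting).
    class_specific_loadings : free Λ_k per class instead of a shared Λ.
    """

    def __init__(self, data, n_classes: int, n_factors: int = 1,
                 class_specific_loadings: bool = False):
        if hasattr(data, "to_frame"):
            frame = data.to_frame()
        else:
            frame = pd.DataFrame(np.asarray(data, dtype=float))
        self.X = frame.to_numpy(dtype=float)
        self.variable_ids = [str(c) for c in frame.columns]
        self.n, self.v = self.X.shape
        if n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if not 0 <= n_factors < self.v:
            raise ValueError("n_factors must be in [0, n_variables)")
        self.K = n_classes
        self.m = n_factors
        self.class_specific = class_specific_loadings
        p = self.n_parameters()
        if p >= self.n * self.v:
            raise ValueError(
                f"{p} parameters meet or exceed the {self.n * self.v} "
                "data degrees of freedom"
            )

    def n_parameters(self) -> int:
        lam_sets = self.K if self.class_specific else 1
        return (self.K * self.v                    # intercepts
                + lam_sets * self.v * self.m       # loadings
                + self.v                           # shared residuals
                + (self.K - 1))                    # class weights

    # -- likelihood ---------------------------------------------------------
    def _log_dens(self, means, lams, theta):
        """n x K log density of each observation under each class."""
        out = np.empty((self.n, self.K))
        for k in range(self.K):
            lam = lams[k]
            Sigma = lam @ lam.T + np.diag(theta)
            c = np.linalg.cholesky(Sigma)
            sol = np.linalg.solve(c, (self.X - means[k]).T)
            quad = (sol**2).sum(axis=0)
            logdet = 2.0 * np.log(np.diag(c)).sum()
            out[:, k] = -0.5 * (self.v * np.log(2 * np.pi) + logdet + quad)
        return out

    def _em(self, means, lams, theta, weights, max_iter, tol):
        ll_trace = []
        prev = -np.inf
        converged = False
        for _ in range(max_iter):
            # E step
            logd = self._log_dens(means, lams, theta) + np.log(weights)[None, :]
            ll = float(logsumexp(logd, axis=1).sum())
            if ll + 1e-9 < prev:
                raise AssertionError(
                    f"EM log-likelihood decreased: {prev} -> {ll}"
                )
            ll_trace.append(ll)
            post = np.exp(logd - logsumexp(logd, axis=1, keepdims=True))
            if abs(ll - prev) < tol:
                converged = True
                break
            prev = ll
            # M step
            nk = post.sum(axis=0)
            weights = np.maximum(nk, 1e-12) / self.n
            means = (post.T @ self.X) / np.maximum(nk, 1e-12)[:, None]
            if self.m == 0:
                scat = np.zeros(self.v)
                for k in range(self.K):
                    d = self.X - means[k]
                    scat += (post[:, k][:, None] * d * d).sum(axis=0)
                theta = np.maximum(scat / self.n, 1e-8)
            elif self.class_specific:
                # mixture-of-factor-analyzers EM with shared residuals
                new_lams = []
                theta_acc = np.zeros(self.v)
                for k in range(self.K):
                    d = self.X - means[k]
                    Sk = (d * post[:, k][:, None]).T @ d / max(nk[k], 1e-12)
                    Sigma_k = lams[k] @ lams[k].T + np.diag(theta)
                    beta_k = np.linalg.solve(Sigma_k, lams[k]).T
                    Ezz = (np.eye(self.m) - beta_k @ lams[k]
                           + beta_k @ Sk @ beta_k.T)
                    lam_new = Sk @ beta_k.T @ np.linalg.inv(Ezz)
                    theta_acc += nk[k] * np.diag(Sk - lam_new @ beta_k @ Sk)
                    new_lams.append(lam_new)
                lams = new_lams
                theta = np.maximum(theta_acc / self.n, 1e-8)
            else:
                Sw = np.zeros((self.v, self.v))
                for k in range(self.K):
                    d = self.X - means[k]
                    Sw += (d * post[:, k][:, None]).T @ d
                Sw /= self.n
                lam, theta = _fa_em_step(Sw, lams[0], theta)
                lams = [lam] * self.K
        return means, lams, theta, weights, ll, np.array(ll_trace), converged

    # -- initialization -----------------------------------------------------
    def _init(self, rng, perturb: float):
        """K-means-style partition baseline, perturbed per random start."""
        idx = rng.choice(self.n, size=self.K, replace=False)
        centers = self.X[idx].copy()
        for _ in range(10):
            d2 = ((self.X[:, None, :] - centers[None]) ** 2).sum(axis=2)
            assign = d2.argmin(axis=1)
            for k in range(self.K):
                if (assign == k).any():
                    centers[k] = self.X[assign == k].mean(axis=0)
        means = centers + perturb * self.X.std(axis=0) * \
            rng.standard_normal((self.K, self.v))
        resid_var = self.X.var(axis=0, ddof=1)
        theta = np.maximum(0.5 * resid_var, 1e-6)
        lam0 = (np.sqrt(np.maximum(resid_var, 1e-6))[:, None] *
                (0.5 + 0.1 * rng.standard_normal((self.v, self.m))))
        lams = [lam0.copy() for _ in range(self.K)] if self.class_specific \
            else [lam0] * self.K
        weights = np.full(self.K, 1.0 / self.K)
        return means, lams, theta, weights

    def fit(self, n_starts: int = 20, seed: int = 0, max_iter: int = 500,
            tol: float = 1e-8, rotation: str = "geomin") -> MixtureResult:
        """Run EM from *n_starts* perturbed initializations; keep the best.

        Class labels are normalized to descending class weight.  With more
        than one factor the reported per-class loadings are rotated
        (*rotation*: geomin by default, falling back to promax when geomin
        fails); rotation does not change LL, BIC or posteriors.
        """
        rng = np.random.default_rng(seed)
        best = None
        start_log: list[float] = []
        for s in range(n_starts):
            perturb = 0.0 if s == 0 else 0.5
            init = self._init(rng, perturb)
            try:
                out = self._em(*init, max_iter=max_iter, tol=tol)
            except np.linalg.LinAlgError:
                start_log.append(float("-inf"))
                continue
            start_log.append(out[4])
            if best is None or out[4] > best[4]:
                best = out
        if best is None:
            raise RuntimeError("every EM start failed")
        means, lams, theta, weights, ll, trace, converged = best

        # degenerate-class handling: restart flagged solutions once
        if np.min(weights) < 1.0 / self.n and self.K > 1:
            retry = self._em(*self._init(rng, 1.0), max_iter=max_iter, tol=tol)
            start_log.append(retry[4])
            if retry[4] > ll and np.min(retry[3]) >= 1.0 / self.n:
                means, lams, theta, weights, ll, trace, converged = retry
        empty = bool(np.min(weights) < 1.0 / self.n)

        order = np.argsort(weights)[::-1]
        means = means[order]
        weights = weights[order]
        lams = [lams[k] for k in order]
        logd = self._log_dens(means, lams, theta) + np.log(weights)[None, :]
        post = np.exp(logd - logsumexp(logd, axis=1, keepdims=True))
        modal = post.argmax(axis=1)

        psis = [np.eye(self.m) for _ in range(self.K)]
        rot_used = "none"
        if self.m >= 2 and rotation not in (None, "none"):
            rotated, new_psis = [], []
            try:
                for lam in lams:
                    L, phi = rotate_loadings(lam, rotation, seed=seed)
                    rotated.append(L)
                    new_psis.append(phi)
                rot_used = rotation
            except Exception:
                rotated, new_psis = [], []
                for lam in lams:
                    L, phi = rotate_loadings(lam, "promax")
                    rotated.append(L)
                    new_psis.append(phi)
                rot_used = "promax"
            lams, psis = rotated, new_psis

        p = self.n_parameters()
        return MixtureResult(
            K=self.K,
            n_factors=self.m,
            intercepts=means,
            loadings=lams,
            factor_covariance=psis,
            residual_variances=theta,
            class_weights=weights,
            posteriors=post,
            modal_class=modal,
            log_likelihood=ll,
            n_parameters=p,
            n_observations=self.n,
            bic=bic(ll, p, self.n),
            avg_class_prob=avg_class_prob(post, modal),
            start_log=start_log,
            converged=converged,
            ll_trace=trace,
            empty_class_flag=empty,
            rotation=rot_used,
            variable_ids=self.variable_ids,
        )


def fmm_fit(x, K: int, m: int = 1, n_starts: int = 20, seed: int = 0,
            **kwargs) -> MixtureResult:
    """Fit a K-class, m-factor mixture; see :class:`FactorMixtureModel`."""
    return FactorMixtureModel(x, n_classes=K, n_factors=m).fit(
        n_starts=n_starts, seed=seed, **kwargs)
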