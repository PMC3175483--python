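"""Exploratory factor analysis by principal axis factoring (PAF).

The common-factor model decomposes a correlation matrix among observed
variables as

    Rzz = A @ Rf @ A.T + D²

where A holds factor loadings, Rf the factor correlations and D² the
diagonal of unique variances; D² -> 0 recovers principal components.  For
immunosignatures the analysis is usually run *transposed* — samples as the
variables, peptides as the observations — so that serum samples load on
latent disease factors and a sample is classified to the factor carrying
its largest loading (threshold 0.3 by convention).

Model/results layout: :class:`FactorAnalysis` is built from data (or a
correlation matrix) and ``.fit()`` returns a :class:`FactorSolution` with
loadings, communalities, eigenvalues, rotation products and diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .rotation import fix_signs, rotate_loadings

__all__ = [
    "CorrelationMatrix",
    "FactorSolution",
    "ClassificationResult",
    "correlation",
    "eigen_scree",
    "suggest_n_factors",
    "FactorAnalysis",
    "paf_fit",
    "rotate",
    "classify_by_loadings",
]


@dataclass
class CorrelationMatrix:
    """Pearson correlation matrix with its orientation and sample size."""

    matrix: np.ndarray
    variable_ids: list[str]
    mode: str = "peptides_as_variables"
    n_observations: int = 0

    def __post_init__(self) -> None:
        R = np.asarray(self.matrix, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(R) > 1 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise ValueError("correlation matrix is indefinite")
        self.matrix = R

    @property
    def n_variables(self) -> int:
        return self.matrix.shape[0]


def correlation(x, mode: str = "samples_as_variables") -> CorrelationMatrix:
    """Pearson correlations of a normalized matrix in either orientation.

    ``samples_as_variables``: n_samples x n_samples correlations computed
    across printed peptides (the classification orientation).
    ``peptides_as_variables``: correlations among peptides across samples.
    Empty spots are excluded in both modes.
    """
    keep = ~x.empty_spot if getattr(x, "empty_spot", None) is not None else slice(None)
    vals = x.values[:, keep]
    if mode == "samples_as_variables":
        data = vals.T  # observations = peptides
        ids = list(x.sample_ids)
    elif mode == "peptides_as_variables":
        data = vals
        ids = [p for p, k in zip(x.peptide_ids, np.atleast_1d(keep)) if k] \
            if not isinstance(keep, slice) else list(x.peptide_ids)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n_obs, v = data.shape
    if n_obs < 3:
        raise ValueError("need at least 3 observations per correlation")
    sd = data.std(axis=0, ddof=1)
    zero = np.argwhere(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance variable {ids[int(zero[0][0])]!r}")
    R = np.corrcoef(data, rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(R, ids, mode=mode, n_observations=n_obs)


def eigen_scree(R: CorrelationMatrix | np.ndarray) -> np.ndarray:
    """Full eigenvalue spectrum of the correlation matrix, descending."""
    M = R.matrix if isinstance(R, CorrelationMatrix) else np.asarray(R, dtype=float)
    return np.sort(np.linalg.eigvalsh(M))[::-1]


def suggest_n_factors(eigenvalues: np.ndarray, min_eigenvalue: float = 1.0) -> int:
    """Advisory factor count: the largest *relative* eigenvalue drop among
    components above *min_eigenvalue* (the automated stand-in for visual
    scree inspection — an elbow is a ratio feature, so unequal factor
    strengths ahead of it do not mask it)."""
    ev = np.asarray(eigenvalues, dtype=float)
    candidates = int((ev > min_eigenvalue).sum())
    if candidates <= 1 or candidates >= ev.size:
        return max(candidates, 1)
    ratios = ev[:candidates] / np.maximum(ev[1 : candidates + 1], 1e-12)
    return int(np.argmax(ratios)) + 1


@dataclass
class FactorSolution:
    """Results of an exploratory factoring.

    ``loadings`` is the pattern matrix A (v x m); ``factor_correlation`` Rf
    is the identity for orthogonal/no rotation; ``uniquenesses`` D² and
    ``communalities`` partition each variable's unit variance (for
    non-Heywood variables h² + d² = 1).
    """

    loadings: np.ndarray
    factor_correlation: np.ndarray
    uniquenesses: np.ndarray
    communalities: np.ndarray
    eigenvalues: np.ndarray
    variable_ids: list[str]
    mode: str
    rotation: str = "none"
    heywood_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    converged: bool = True
    n_iterations: int = 0
    method: str = "paf"
    n_observations: int = 0

    def __post_init__(self) -> None:
        if self.heywood_flags is None:
            self.heywood_flags = np.zeros(self.loadings.shape[0], dtype=bool)

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def reconstruction(self) -> np.ndarray:
        """Model-implied correlation matrix A Rf A' + D²."""
        return (self.loadings @ self.factor_correlation @ self.loadings.T
                + np.diag(self.uniquenesses))

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"Factor{j+1}" for j in range(self.n_factors)]
        return pd.DataFrame(self.loadings, index=self.variable_ids, columns=cols)

    def summary(self) -> str:
        lines = [
            f"Exploratory factor analysis ({self.method.upper()}), "
            f"rotation={self.rotation}",
            f"variables: {len(self.variable_ids)}  factors: {self.n_factors}  "
            f"mode: {self.mode}",
            f"converged: {self.converged} in {self.n_iterations} iterations; "
            f"Heywood variables: {int(self.heywood_flags.sum())}",
            "",
            self.loadings_frame().round(4).to_string(),
            "",
            "Factor correlations:",
            pd.DataFrame(self.factor_correlation).round(4).to_string(),
            "",
            "Eigenvalues: " + " ".join(f"{e:.4f}" for e in self.eigenvalues[:10]),
        ]
        return "\n".join(lines)


class FactorAnalysis:
    """Exploratory factor model for a correlation matrix or normalized data.

    Parameters
    ----------
    data : CorrelationMatrix, or a NormalizedMatrix/array to correlate.
    n_factors : number of common factors m.
    mode : correlation orientation when *data* is not already a
        CorrelationMatrix (default ``samples_as_variables``).
    method : ``"paf"`` (principal axis factoring with iterated
        communalities, the default) or ``"pca"`` (uniquenesses fixed at 0).

    Examples
    --------
    >>> sol = FactorAnalysis(norm, n_factors=2).fit(rotation="promax")
    >>> sol.loadings_frame()
    """

    def __init__(self, data, n_factors: int, mode: str = "samples_as_variables",
                 method: str = "paf"):
        if isinstance(data, CorrelationMatrix):
            self.corr = data
        elif isinstance(data, np.ndarray) and data.ndim == 2 and \
                data.shape[0] == data.shape[1] and np.allclose(np.diag(data), 1.0):
            self.corr = CorrelationMatrix(data, [f"v{i+1}" for i in range(data.shape[0])],
                                          mode=mode)
        else:
            self.corr = correlation(data, mode=mode)
        if not 1 <= n_factors < self.corr.n_variables:
            raise ValueError(
                f"n_factors must be in [1, {self.corr.n_variables - 1}], got {n_factors}"
            )
        if method not in ("paf", "pca"):
            raise ValueError(f"unknown method {method!r}")
        self.n_factors = n_factors
        self.method = method

    def _smc(self, R: np.ndarray) -> np.ndarray:
        """Squared multiple correlations (initial communalities)."""
        try:
            Rinv = np.linalg.inv(R)
            smc = 1.0 - 1.0 / np.diag(Rinv)
        except np.linalg.LinAlgError:
            smc = np.full(R.shape[0], 0.5)
        return np.clip(smc, 0.0, 1.0 - 1e-6)

    def fit(self, rotation: str = "none", max_iter: int = 200, tol: float = 1e-6,
            kappa: int = 4, geomin_epsilon: float = 0.01, seed: int = 0) -> FactorSolution:
        """Estimate loadings; optionally rotate (varimax/promax/geomin)."""
        R = self.corr.matrix
        v, m = self.corr.n_variables, self.n_factors
        eigvals_full = eigen_scree(R)

        heywood = np.zeros(v, dtype=bool)
        if self.method == "pca":
            w, V = np.linalg.eigh(R)
            order = np.argsort(w)[::-1][:m]
            A = V[:, order] * np.sqrt(np.maximum(w[order], 0.0))
            converged, it = True, 0
            h2 = (A**2).sum(axis=1)
            uniq = np.zeros(v)
        else:
            h2 = self._smc(R)
            converged, it = False, 0
            A = None
            for it in range(1, max_iter + 1):
                Rr = R.copy()
                np.fill_diagonal(Rr, h2)
                w, V = np.linalg.eigh(Rr)
                order = np.argsort(w)[::-1][:m]
                A = V[:, order] * np.sqrt(np.maximum(w[order], 0.0))
                h2_new = (A**2).sum(axis=1)
                over = h2_new > 1.0
                if over.any():
                    heywood |= over
                    h2_new = np.where(over, 1.0 - 1e-6, h2_new)
                if np.max(np.abs(h2_new - h2)) < tol:
                    h2 = h2_new
                    converged = True
                    break
                h2 = h2_new
            uniq = 1.0 - h2

        A = fix_signs(A)
        sol = FactorSolution(
            loadings=A,
            factor_correlation=np.eye(m),
            uniquenesses=uniq,
            communalities=h2,
            eigenvalues=eigvals_full,
            variable_ids=list(self.corr.variable_ids),
            mode=self.corr.mode,
            rotation="none",
            heywood_flags=heywood,
            converged=converged,
            n_iterations=it,
            method=self.method,
            n_observations=self.corr.n_observations,
        )
        if rotation and rotation != "none":
            sol = rotate(sol, rotation, kappa=kappa,
                         geomin_epsilon=geomin_epsilon, seed=seed)
        return sol


def paf_fit(R: CorrelationMatrix, m: int, max_iter: int = 200,
            tol: float = 1e-6) -> FactorSolution:
    """Principal axis factoring with iterated communalities (unrotated)."""
    return FactorAnalysis(R, n_factors=m, method="paf").fit(max_iter=max_iter, tol=tol)


def rotate(sol: FactorSolution, method: str, kappa: int = 4,
           geomin_epsilon: float = 0.01, seed: int = 0) -> FactorSolution:
    """Rotate an (unrotated) solution; single-factor solutions are returned
    unchanged.  Communalities and the implied correlation structure are
    invariant under rotation."""
    if sol.n_factors < 2:
        return sol
    L, phi = rotate_loadings(sol.loadings, method, kappa=kappa,
                             geomin_epsilon=geomin_epsilon, seed=seed)
    return FactorSolution(
        loadings=L,
        factor_correlation=phi,
        uniquenesses=sol.uniquenesses.copy(),
        communalities=sol.communalities.copy(),
        eigenvalues=sol.eigenvalues.copy(),
        variable_ids=list(sol.variable_ids),
        mode=sol.mode,
        rotation=method,
        heywood_flags=sol.heywood_flags.copy(),
        converged=sol.converged,
        n_iterations=sol.n_iterations,
        method=sol.method,
        n_observations=sol.n_observations,
    )


@dataclass
class ClassificationResult:
    """Loading-threshold assignment of samples to latent group factors."""

    assigned_factor: list[int | None]
    loading_used: np.ndarray
    factor_to_group: dict[int, str]
    accuracy: float
    cross_loadings: list[str]
    variable_ids: list[str]
    n_unclassified: int = 0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.variable_ids,
                "assigned_factor": [
                    (f + 1) if f is not None else None for f in self.assigned_factor
                ],
                "assigned_group": [
                    self.factor_to_group.get(f) if f is not None else "unclassified"
                    for f in self.assigned_factor
                ],
                "loading": self.loading_used,
            }
        )


def classify_by_loadings(sol: FactorSolution, labels: list[str],
                         threshold: float = 0.3) -> ClassificationResult:
    """Assign each sample (variable of a transposed solution) to the factor
    with its largest |pattern loading| when that loading clears *threshold*.

    Factors are mapped to known group labels by the permutation maximizing
    matches; samples below threshold on every factor are unclassified and do
    not count as correct.  Accuracy is percent correct among labeled samples.
    """
    if sol.mode != "samples_as_variables":
        raise ValueError("classification requires a samples_as_variables solution")
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    labels = [str(g) for g in labels]
    if len(labels) != len(sol.variable_ids):
        raise ValueError("labels length does not match solution variables")
    groups = list(dict.fromkeys(labels))
    m = sol.n_factors
    if m != len(groups):
        raise ValueError(f"factor count {m} does not match group count {len(groups)}")

    A = sol.loadings
    best = np.argmax(np.abs(A), axis=1)
    best_load = A[np.arange(A.shape[0]), best]
    assigned = [int(b) if abs(l) >= threshold or threshold == 0.0 else None
                for b, l in zip(best, best_load)]

    # cross-loading: a second factor also clears the threshold
    cross = [vid for vid, row in zip(sol.variable_ids, np.abs(A))
             if (row >= threshold).sum() > 1]

    best_acc, best_map = -1.0, {}
    for perm in permutations(range(m)):
        mapping = {perm[j]: groups[j] for j in range(m)}
        correct = sum(
            1 for a, lab in zip(assigned, labels)
            if a is not None and mapping[a] == lab
        )
        acc = 100.0 * correct / len(labels)
        if acc > best_acc:
            best_acc, best_map = acc, mapping
    return ClassificationResult(
        assigned_factor=assigned,
        loading_used=best_load,
        factor_to_group=best_map,
        accuracy=best_acc,
        cross_loadings=cross,
        variable_ids=list(sol.variable_ids),
        n_unclassified=sum(a is None for a in assigned),
    )
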