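"""Factor rotation: varimax (orthogonal), promax and geomin (oblique).

All three operate on an unrotated loading matrix A (v variables x m
factors).  Oblique methods return a pattern matrix P and factor correlation
matrix Phi such that the common part of the reconstruction, P @ Phi @ P.T,
equals A @ A.T — rotation redistributes loadings between factors without
changing communalities or the model-implied correlation structure.
"""

from __future__ import annotations

import numpy as np

__all__ = ["varimax", "promax", "geomin", "rotate_loadings", "fix_signs"]


def fix_signs(loadings: np.ndarray, phi: np.ndarray | None = None):
    """Flip each factor so its largest-|loading| entry is positive."""
    L = loadings.copy()
    signs = np.ones(L.shape[1])
    for j in range(L.shape[1]):
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
            signs[j] = -1.0
    if phi is not None:
        phi = (signs[:, None] * phi) * signs[None, :]
        return L, phi
    return L


def varimax(A: np.ndarray, normalize: bool = True, tol: float = 1e-10,
            max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Kaiser varimax: orthogonal rotation maximizing the variance of squared
    loadings within each factor.  Returns (rotated loadings, rotation T)."""
    A = np.asarray(A, dtype=float)
    v, m = A.shape
    if m < 2:
        return A.copy(), np.eye(m)
    if normalize:
        h = np.sqrt((A**2).sum(axis=1))
        h = np.where(h > 0, h, 1.0)
        X = A / h[:, None]
    else:
        X = A.copy()
    T = np.eye(m)
    d_old = 0.0
    for _ in range(max_iter):
        L = X @ T
        # SVD form of the varimax criterion ascent step
        B = X.T @ (L**3 - L @ np.diag((L**2).sum(axis=0)) / v)
        U, s, Vt = np.linalg.svd(B)
        T = U @ Vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    L = X @ T
    if normalize:
        L = L * h[:, None]
    return L, T


def promax(A: np.ndarray, kappa: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Hendrickson-White promax: varimax, then an oblique procrustes fit to
    the element-wise |loading|^kappa (sign-preserving) target.

    Returns (pattern matrix, factor correlation Phi).
    """
    A = np.asarray(A, dtype=float)
    m = A.shape[1]
    if m < 2:
        return A.copy(), np.eye(m)
    X, _ = varimax(A)
    target = np.abs(X) ** kappa * np.sign(X)
    # least-squares transform X @ U ~= target
    U = np.linalg.solve(X.T @ X, X.T @ target)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U * np.sqrt(d)[None, :]
    pattern = X @ U
    Uinv = np.linalg.inv(U)
    phi = Uinv @ Uinv.T
    return pattern, phi


def _vgq_geomin(L: np.ndarray, eps: float) -> tuple[float, np.ndarray]:
    """Geomin criterion and gradient: sum over variables of the geometric
    mean of (loading^2 + eps) across factors."""
    m = L.shape[1]
    L2 = L**2 + eps
    pro = np.exp(np.log(L2).mean(axis=1))
    f = float(pro.sum())
    G = (2.0 / m) * (L / L2) * pro[:, None]
    return f, G


def _gpf_oblique(A: np.ndarray, T0: np.ndarray, eps: float,
                 tol: float = 1e-7, max_iter: int = 500):
    """Gradient-projection oblique rotation (Jennrich); T columns unit-length,
    pattern L = A @ inv(T).T, Phi = T.T @ T."""
    T = T0.copy()
    al = 1.0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _vgq_geomin(L, eps)
    G = -(L.T @ Gq @ Ti).T
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0, keepdims=True)
        s = np.linalg.norm(Gp)
        if s < tol:
            break
        al = 2.0 * al
        for _ in range(50):
            X = T - al * Gp
            Tt = X / np.sqrt((X**2).sum(axis=0, keepdims=True))
            try:
                Ti = np.linalg.inv(Tt)
            except np.linalg.LinAlgError:
                al /= 2.0
                continue
            L = A @ Ti.T
            ft, Gqt = _vgq_geomin(L, eps)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T = Tt
        f, Gq = ft, Gqt
        G = -(L.T @ Gq @ Ti).T
    phi = T.T @ T
    return L, phi, f


def _random_orthogonal(m: int, rng: np.random.Generator) -> np.ndarray:
    Q, R = np.linalg.qr(rng.standard_normal((m, m)))
    return Q * np.sign(np.diag(R))


def geomin(A: np.ndarray, eps: float = 0.01, n_starts: int = 30,
           seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Oblique geomin rotation by gradient projection with random orthogonal
    restarts (the criterion is multimodal); best criterion value kept.

    Returns (pattern matrix, factor correlation Phi).
    """
    A = np.asarray(A, dtype=float)
    m = A.shape[1]
    if m < 2:
        return A.copy(), np.eye(m)
    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        T0 = np.eye(m) if k == 0 else _random_orthogonal(m, rng)
        L, phi, f = _gpf_oblique(A, T0, eps)
        if best is None or f < best[2]:
            best = (L, phi, f)
    return best[0], best[1]


def rotate_loadings(A: np.ndarray, method: str, kappa: int = 4,
                    geomin_epsilon: float = 0.01, seed: int = 0):
    """Dispatch to a rotation method; returns (pattern, Phi) with the
    deterministic sign convention applied."""
    method = method.lower()
    if method in ("none", None):
        return fix_signs(A.copy(), np.eye(A.shape[1]))
    if method == "varimax":
        L, _ = varimax(A)
        return fix_signs(L, np.eye(A.shape[1]))
    if method == "promax":
        L, phi = promax(A, kappa=kappa)
        return fix_signs(L, phi)
    if method == "geomin":
        L, phi = geomin(A, eps=geomin_epsilon, seed=seed)
        return fix_signs(L, phi)
    raise ValueError(f"unknown rotation method {method!r}")
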