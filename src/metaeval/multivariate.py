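"""PCA and PLS-DA with VIP scores.

PLS-DA is a NIPALS PLS2 against the one-hot group response.  The input X is
column-mean-centered only — any scaling belongs to the processing scheme
under test, never to the model.  VIP for feature j over A components:

    VIP_j = sqrt( p * sum_a SSY_a * (w_aj / ||w_a||)^2 / sum_a SSY_a ),
    SSY_a = (t_a' t_a)(q_a' q_a),

so mean(VIP^2) = 1 identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MetDataset

__all__ = ["PCAResult", "PLSDAResult", "pca", "plsda", "vip_discriminants"]


def _fix_signs(loadings: np.ndarray, *companions: np.ndarray) -> None:
    """Deterministic sign convention: largest-|.| loading element positive, per component."""
    for a in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, a]))
        if loadings[k, a] < 0:
            loadings[:, a] *= -1
            for c in companions:
                c[:, a] *= -1


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray
    centered: bool
    unit_scaled: bool


def pca(
    d: MetDataset,
    n_components: int = 2,
    center: bool = True,
    unit_scale: bool = False,
) -> PCAResult:
    """SVD-based principal component analysis with a deterministic sign convention."""
    X = d.matrix.copy()
    if np.isnan(X).any():
        raise ValueError("PCA requires a complete matrix; run imputation first")
    n, p = X.shape
    if n_components > min(n - 1 if center else n, p):
        raise ValueError(f"n_components={n_components} exceeds min(n-1, p)")
    if center:
        X = X - X.mean(axis=0)
    if unit_scale:
        s = X.std(axis=0, ddof=1)
        if (s == 0).any():
            raise ValueError("unit scaling undefined for constant features")
        X = X / s
    U, sv, Vt = np.linalg.svd(X, full_matrices=False)
    total = (sv**2).sum()
    evr = (sv[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    loadings = Vt[:n_components].T.copy()
    scores = (U[:, :n_components] * sv[:n_components]).copy()
    _fix_signs(loadings, scores)
    comp = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=d.sample_ids, columns=comp),
        loadings=pd.DataFrame(loadings, index=d.feature_ids, columns=comp),
        explained_variance_ratio=evr,
        centered=center,
        unit_scaled=unit_scale,
    )


@dataclass
class PLSDAResult:
    n_components: int
    weights: pd.DataFrame  # W, features x A (unit-norm columns)
    x_scores: pd.DataFrame  # T, samples x A
    x_loadings: pd.DataFrame  # P, features x A
    y_loadings: pd.DataFrame  # Q, classes x A
    ssy: np.ndarray  # per-component explained Y sum of squares
    vip: pd.Series  # per-feature VIP
    classes: list[str]


def _nipals_pls2(X: np.ndarray, Y: np.ndarray, A: int, tol: float = 1e-12, max_iter: int = 500):
    n, p = X.shape
    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    Q = np.zeros((Y.shape[1], A))
    Xa, Ya = X.copy(), Y.copy()
    a = 0
    for _ in range(A):
        u = Ya[:, np.argmax(Ya.var(axis=0))].copy()
        if not np.any(u):
            break
        t_old = None
        nw = tt = 0.0
        for _ in range(max_iter):
            w = Xa.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = Xa @ w
            tt = t @ t
            if tt == 0:
                break
            q = Ya.T @ t / tt
            nq = q @ q
            if nq == 0:
                break
            u = Ya @ q / nq
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        if nw == 0 or tt == 0:
            break
        p_a = Xa.T @ t / tt
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, p_a, q
        Xa = Xa - np.outer(t, p_a)
        Ya = Ya - np.outer(t, q)
        a += 1
    return W[:, :a], T[:, :a], P[:, :a], Q[:, :a]


def plsda(
    d: MetDataset,
    n_components: int = 2,
    qc_policy: str = "exclude",
) -> PLSDAResult:
    """NIPALS PLS2 of the mean-centered matrix against one-hot group labels, with VIPs.

    QC samples are not a biological class and are excluded by default.
    """
    if qc_policy not in ("include", "exclude"):
        raise ValueError("qc_policy must be 'include' or 'exclude'")
    data = d.select_samples(~d.is_qc()) if qc_policy == "exclude" else d
    X = data.matrix.copy()
    if np.isnan(X).any():
        raise ValueError("PLS-DA requires a complete matrix; run imputation first")
    g = data.effective_group()
    classes = [str(c) for c in pd.unique(g)]
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 group levels among modeled samples")
    Y = np.column_stack([(g == c).to_numpy(float) for c in classes])

    n, p = X.shape
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    max_a = min(n - 1, p)
    A = n_components
    if A > max_a:
        warnings.warn(f"n_components truncated from {A} to {max_a} (rank limit)")
        A = max_a

    W, T, P, Q = _nipals_pls2(X, Y, A)
    A = W.shape[1]
    _fix_signs(W, T, P, Q)
    ssy = np.einsum("ia,ia->a", T, T) * np.einsum("ia,ia->a", Q, Q)
    wnorm2 = (W**2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    vip = np.sqrt(p * (W**2 / wnorm2) @ ssy / ssy.sum())

    comp = [f"LV{i + 1}" for i in range(A)]
    return PLSDAResult(
        n_components=A,
        weights=pd.DataFrame(W, index=data.feature_ids, columns=comp),
        x_scores=pd.DataFrame(T, index=data.sample_ids, columns=comp),
        x_loadings=pd.DataFrame(P, index=data.feature_ids, columns=comp),
        y_loadings=pd.DataFrame(Q, index=classes, columns=comp),
        ssy=ssy,
        vip=pd.Series(vip, index=data.feature_ids, name="vip"),
        classes=classes,
    )


def vip_discriminants(r: PLSDAResult, threshold: float = 1.5) -> list[str]:
    """Feature ids with VIP >= threshold, sorted descending by VIP."""
    sel = r.vip[r.vip >= threshold].sort_values(ascending=False)
    return [str(f) for f in sel.index]
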