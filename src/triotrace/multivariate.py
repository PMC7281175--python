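"""PCA and PLS-DA quality control from numerical primitives.

Open-math stand-ins for the proprietary SIMCA workflow used in GC-MS
metabolomics QC: PCA via singular value decomposition, two-class PLS-DA via
NIPALS PLS1 against a ±1 response, per-variable VIP scores (mean squared
VIP = 1 by construction), Q² from stratified k-fold cross-validation, and a
label-permutation test for the significance of Q². An optional
single-component orthogonal signal correction approximates OPLS-DA's
predictive/orthogonal split; for two-class models the predictive
interpretation is equivalent.

Autoscaling (centering to unit variance) is the default, the convention for
GC-MS peak tables where analyte scales span orders of magnitude. 7-fold CV
is the default, the SIMCA convention.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .tables import PeakTable

__all__ = ["LatentModel", "pca", "plsda_fit", "permutation_validate"]


@dataclasses.dataclass
class LatentModel:
    """Scores/loadings container for PCA and PLS-DA fits."""

    kind: str  # "pca" | "plsda"
    n_components: int
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # analytes x components
    explained: np.ndarray  # per-component fraction of (X) variance
    sample_ids: list[str]
    analyte_ids: list[str]
    vip: np.ndarray | None = None  # PLS-DA only
    r2y: float | None = None  # PLS-DA only
    q2: float | None = None  # PLS-DA only
    _context: dict = dataclasses.field(default_factory=dict, repr=False)


def _scale(X: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    if scaling == "center":
        sd = np.ones(X.shape[1])
    elif scaling == "autoscale":
        sd = X.std(axis=0, ddof=1)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return (X - mean) / np.where(sd > 0, sd, 1.0), mean, sd


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    # deterministic orientation: largest-magnitude loading entry positive
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1


def pca(table: PeakTable, n_components: int = 3, scaling: str = "autoscale") -> LatentModel:
    """Principal component analysis of the sample × analyte matrix.

    Deterministic up to component sign; signs are fixed so each loading
    vector's largest-magnitude entry is positive. Constant analytes are
    excluded with a warning under autoscaling (they have no defined scale).
    """
    X = table.values.to_numpy(float).T  # samples x analytes
    analytes = list(table.analyte_ids)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 analytes")
    if scaling == "autoscale":
        sd = X.std(axis=0, ddof=1)
        const = sd == 0
        if const.any():
            dropped = [a for a, c in zip(analytes, const) if c]
            warnings.warn(f"excluding constant analytes under autoscale: {dropped}")
            X = X[:, ~const]
            analytes = [a for a, c in zip(analytes, const) if not c]
    Xs, _, _ = _scale(X, scaling)
    rank = min(Xs.shape)
    k = min(n_components, rank)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    total = float((s**2).sum())
    explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    _fix_signs(loadings, scores)
    return LatentModel(
        kind="pca",
        n_components=k,
        scores=scores,
        loadings=loadings,
        explained=explained,
        sample_ids=list(table.sample_ids),
        analyte_ids=analytes,
        _context={"scaled": Xs, "singular_values": s},
    )


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS PLS1)


def _pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS PLS1 on pre-scaled X and centered y.

    Returns weights W, scores T, X-loadings P, y-loadings q (per component)
    — the deflation form where T = X_deflated W columnwise.
    """
    n, p = X.shape
    Xd = X.copy()
    yd = y.astype(float).copy()
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            W, T, P, q = W[:, :a], T[:, :a], P[:, :a], q[:a]
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            W, T, P, q = W[:, :a], T[:, :a], P[:, :a], q[:a]
            break
        pvec = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, pvec)
        yd -= qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pvec, qa
    return W, T, P, q


def _pls_predict(Xs: np.ndarray, W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    # R = W (P'W)^-1 gives direct regression weights from undeflated X
    A = W.shape[1]
    if A == 0:
        return np.zeros(Xs.shape[0])
    R = W @ np.linalg.inv(P.T @ W)
    return Xs @ (R @ q[:A])


def _vip(W: np.ndarray, T: np.ndarray, q: np.ndarray) -> np.ndarray:
    ss = (q**2) * (T**2).sum(axis=0)  # y-variance explained per component
    total = ss.sum()
    p = W.shape[0]
    if total <= 0:
        return np.ones(p)
    return np.sqrt(p * (W**2 @ ss) / total)


def _stratified_folds(y: np.ndarray, k: int) -> np.ndarray:
    """Deterministic fold assignment keeping both classes in every fold."""
    fold = np.empty(len(y), dtype=int)
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def _q2(X: np.ndarray, y: np.ndarray, n_components: int, cv_folds: int) -> float:
    folds = _stratified_folds(y, cv_folds)
    press = 0.0
    for f in range(cv_folds):
        test = folds == f
        train = ~test
        Xt = X[train]
        mean, sd = Xt.mean(axis=0), Xt.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        yt = y[train].astype(float)
        ym = yt.mean()
        W, T, P, q = _pls1((Xt - mean) / sd, yt - ym, n_components)
        pred = ym + _pls_predict((X[test] - mean) / sd, W, P, q)
        press += float(((y[test] - pred) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / tss


def _osc_deflate(Xs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Remove one y-orthogonal component (orthogonal signal correction)."""
    w = Xs.T @ y
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        return Xs
    w /= nw
    # first PCA direction of the part of X orthogonal to the predictive weight
    Xo = Xs - np.outer(Xs @ w, w)
    U, s, Vt = np.linalg.svd(Xo, full_matrices=False)
    if s[0] < 1e-12:
        return Xs
    t = U[:, 0] * s[0]
    p = Vt[0]
    return Xs - np.outer(t, p)


def plsda_fit(
    table: PeakTable,
    groups: tuple[str, str],
    n_components: int = 2,
    cv_folds: int = 7,
    orthogonal_correction: bool = False,
) -> LatentModel:
    """Two-class PLS-DA with VIP scores and cross-validated Q².

    ``groups`` names the two classes from the table's design; their samples
    are coded +1/−1. X is autoscaled. ``orthogonal_correction`` first strips
    one y-orthogonal component (OPLS-style filtering).
    """
    ga, gb = groups
    samples = table.samples_in(ga) + table.samples_in(gb)
    if not table.samples_in(ga) or not table.samples_in(gb):
        raise ValueError("both groups must have samples")
    y = np.array([1.0 if table.group_of[s] == ga else -1.0 for s in samples])
    if len(np.unique(y)) < 2:
        raise ValueError("all samples carry the same label")
    cv_folds = min(cv_folds, min((y == 1).sum(), (y == -1).sum()))
    if cv_folds < 2:
        raise ValueError("each group needs at least 2 samples for cross-validation")
    X = table.values[samples].to_numpy(float).T
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn("excluding constant analytes from PLS-DA")
        X = X[:, keep]
    analytes = [a for a, k in zip(table.analyte_ids, keep) if k]
    rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > rank:
        warnings.warn(f"n_components truncated to rank {rank}")
        n_components = rank
    Xs, _, _ = _scale(X, "autoscale")
    if orthogonal_correction:
        Xs = _osc_deflate(Xs, y - y.mean())
    yc = y - y.mean()
    W, T, P, q = _pls1(Xs, yc, n_components)
    resid = yc - T @ q[: T.shape[1]]
    tssy = float((yc**2).sum())
    r2y = 1.0 - float((resid**2).sum()) / tssy if tssy > 0 else 0.0
    ssx_total = float((Xs**2).sum())
    explained = (
        np.array([(T[:, a] ** 2).sum() * (P[:, a] ** 2).sum() for a in range(T.shape[1])])
        / ssx_total
        if ssx_total > 0
        else np.zeros(T.shape[1])
    )
    loadings = P.copy()
    scores = T.copy()
    model = LatentModel(
        kind="plsda",
        n_components=T.shape[1],
        scores=scores,
        loadings=loadings,
        explained=explained,
        sample_ids=samples,
        analyte_ids=analytes,
        vip=_vip(W, T, q),
        r2y=r2y,
        q2=_q2(X, y, n_components, cv_folds),
        _context={
            "X": X,
            "y": y,
            "n_components": n_components,
            "cv_folds": cv_folds,
        },
    )
    return model


def permutation_validate(model: LatentModel, n_perm: int = 200, seed: int = 0) -> float:
    """Permutation p-value for the observed Q² under random label swaps.

    p = (1 + #{permuted Q² ≥ observed Q²}) / (1 + n_perm); reproducible for
    a fixed seed. A small ``n_perm`` (< 20) gives a very coarse p-value and
    triggers a warning.
    """
    if model.kind != "plsda" or "X" not in model._context:
        raise ValueError("permutation_validate needs a fitted PLS-DA model")
    if n_perm < 20:
        warnings.warn("n_perm < 20 gives a very coarse permutation p-value")
    ctx = model._context
    X, y = ctx["X"], ctx["y"]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        if len(np.unique(yp)) < 2:
            continue
        if _q2(X, yp, ctx["n_components"], ctx["cv_folds"]) >= model.q2:
            hits += 1
    return (1 + hits) / (1 + n_perm)
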