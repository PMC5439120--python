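"""Modified joint DISTATIS for group-level MMR_TF analysis.

Each subject-by-condition probability surface is recast as two Gram
("cross-products") matrices — spectral (scales x scales) and temporal
(time x time) — which are double-centered with uniform masses and normalized
by their first eigenvalue.  Condition compromises are plain means of the
normalized matrices within a condition; the grand compromise is the mean of
the condition compromises, so conditions are equi-weighted regardless of how
many subjects contributed.  Eigendecomposition of the grand compromises
yields the retained weight vectors (those explaining at least 1% of the
variance, by the square-root-of-eigenvalue criterion) and the relative
contribution of the spectral vs temporal dimension; every surface is then
projected onto the retained joint basis and averaged back into condition and
grand compromise projections, min-max rescaled to [0, 1] as relative
probabilities.

A note on signs: the double-centering formula ``-1/2 Xi CP Xi^T`` applied to
a Gram matrix is negative semidefinite, so "first eigenvalue" is read as the
eigenvalue of largest magnitude.  Dividing by that (negative) eigenvalue
flips the sign, leaving a positive semidefinite S with top eigenvalue
exactly 1 — equivalent to ``+Xi CP Xi^T`` normalized by its own leading
eigenvalue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mmr import MMRSurface

__all__ = [
    "CrossProducts",
    "CompromiseSet",
    "ProjectionSet",
    "cross_products",
    "center_and_normalize",
    "build_compromise",
    "select_weights",
    "project",
    "aggregate",
    "group_analysis",
]


@dataclass
class CrossProducts:
    """Spectral/temporal Gram matrices of one surface and their centered,
    first-eigenvalue-normalized forms."""

    cp_f: np.ndarray
    cp_t: np.ndarray
    s_f: np.ndarray | None = None
    s_t: np.ndarray | None = None
    subject: str = ""
    condition: str = ""


@dataclass
class CompromiseSet:
    """Condition and grand compromises with their eigen structure."""

    condition_f: dict
    condition_t: dict
    grand_f: np.ndarray
    grand_t: np.ndarray
    evals_f: np.ndarray
    evecs_f: np.ndarray
    evals_t: np.ndarray
    evecs_t: np.ndarray
    pvaf_f: np.ndarray | None = None
    pvaf_t: np.ndarray | None = None
    w_f: np.ndarray | None = None
    w_t: np.ndarray | None = None
    rc_f: float | None = None
    rc_t: float | None = None


@dataclass
class ProjectionSet:
    """Joint projections per surface, per condition, and overall.

    ``condition_means`` and ``grand_mean`` are jointly min-max rescaled to
    [0, 1] (relative probabilities); the unscaled versions are kept in
    ``raw_condition_means`` / ``raw_grand_mean``.
    """

    projections: list
    condition_means: dict
    grand_mean: np.ndarray
    raw_condition_means: dict = field(default_factory=dict)
    raw_grand_mean: np.ndarray | None = None
    scale_freqs_hz: np.ndarray | None = None
    time_ms: np.ndarray | None = None


def cross_products(s: MMRSurface) -> CrossProducts:
    """Spectral and temporal Gram matrices of one probability surface."""
    p = np.asarray(s.p, dtype=float)
    if not np.isfinite(p).all():
        raise ValueError("surface contains non-finite values")
    return CrossProducts(cp_f=p @ p.T, cp_t=p.T @ p, subject=s.subject, condition=s.condition)


def _center_normalize_one(cp: np.ndarray) -> np.ndarray:
    n = cp.shape[0]
    if cp.shape != (n, n):
        raise ValueError("cross-products matrix must be square")
    m = np.full(n, 1.0 / n)
    xi = np.eye(n) - np.outer(np.ones(n), m)
    s0 = -0.5 * (xi @ cp @ xi.T)
    evals = np.linalg.eigvalsh(s0)
    lam1 = evals[np.argmax(np.abs(evals))]
    if lam1 == 0:
        raise ValueError("degenerate surface: first eigenvalue of the centered matrix is zero")
    s = s0 / lam1
    return 0.5 * (s + s.T)  # enforce exact symmetry


def center_and_normalize(cp: CrossProducts) -> CrossProducts:
    """Double-center (uniform masses) and normalize by the first eigenvalue.

    After the call both ``s_f`` and ``s_t`` have zero row/column means and
    largest eigenvalue exactly 1 (see the module docstring for the sign
    convention).
    """
    cp.s_f = _center_normalize_one(cp.cp_f)
    cp.s_t = _center_normalize_one(cp.cp_t)
    return cp


def _fix_sign(vecs: np.ndarray) -> np.ndarray:
    """Sign convention: largest-magnitude element of each vector positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def _eig_desc(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    evals, evecs = np.linalg.eigh(mat)
    order = np.argsort(evals)[::-1]
    return evals[order], _fix_sign(evecs[:, order])


def build_compromise(cps: list[CrossProducts]) -> CompromiseSet:
    """Condition compromises (means within condition) and grand compromises
    (mean of the condition compromises — conditions equi-weighted)."""
    by_cond_f: dict = {}
    by_cond_t: dict = {}
    for cp in cps:
        if cp.s_f is None or cp.s_t is None:
            raise ValueError("run center_and_normalize before build_compromise")
        by_cond_f.setdefault(cp.condition, []).append(cp.s_f)
        by_cond_t.setdefault(cp.condition, []).append(cp.s_t)
    if not by_cond_f or any(len(v) == 0 for v in by_cond_f.values()):
        raise ValueError("every condition must contribute at least one surface")
    cond_f = {d: np.mean(mats, axis=0) for d, mats in by_cond_f.items()}
    cond_t = {d: np.mean(mats, axis=0) for d, mats in by_cond_t.items()}
    grand_f = np.mean(list(cond_f.values()), axis=0)
    grand_t = np.mean(list(cond_t.values()), axis=0)
    evals_f, evecs_f = _eig_desc(grand_f)
    evals_t, evecs_t = _eig_desc(grand_t)
    return CompromiseSet(
        condition_f=cond_f,
        condition_t=cond_t,
        grand_f=grand_f,
        grand_t=grand_t,
        evals_f=evals_f,
        evecs_f=evecs_f,
        evals_t=evals_t,
        evecs_t=evecs_t,
    )


def _pvaf(evals: np.ndarray) -> np.ndarray:
    roots = np.sqrt(np.clip(evals, 0.0, None))
    total = roots.sum()
    return roots / total if total > 0 else roots


def select_weights(cs: CompromiseSet, pvaf_min: float = 0.01) -> CompromiseSet:
    """Retain eigenvectors with pvaf >= ``pvaf_min`` and fill rc values.

    pvaf uses the square roots of the eigenvalues; retained vectors are
    renormalized to unit L2 norm; the relative contributions split the first
    eigenvalues of the two dimensions and sum to one.
    """
    cs.pvaf_f = _pvaf(cs.evals_f)
    cs.pvaf_t = _pvaf(cs.evals_t)

    def _retain(evecs, pvaf):
        keep = pvaf >= pvaf_min
        if not keep.any():
            warnings.warn("no eigenvector met the pvaf threshold; retaining the first", stacklevel=3)
            keep[0] = True
        w = evecs[:, keep]
        return w / np.linalg.norm(w, axis=0, keepdims=True)

    cs.w_f = _retain(cs.evecs_f, cs.pvaf_f)
    cs.w_t = _retain(cs.evecs_t, cs.pvaf_t)
    lam_f, lam_t = float(cs.evals_f[0]), float(cs.evals_t[0])
    total = lam_f + lam_t
    if total <= 0:
        raise ValueError("non-positive leading eigenvalues; degenerate compromises")
    cs.rc_f = lam_f / total
    cs.rc_t = lam_t / total
    return cs


def project(s: MMRSurface, cs: CompromiseSet) -> np.ndarray:
    """Joint projection of one surface onto the retained compromise bases.

    ``P = rc_F * W_F W_F' p + (rc_T * W_T W_T' p')'``, scales x time.
    """
    if cs.w_f is None or cs.w_t is None:
        raise ValueError("run select_weights before projecting")
    p = np.asarray(s.p, dtype=float)
    if p.shape != (cs.w_f.shape[0], cs.w_t.shape[0]):
        raise ValueError(
            f"surface shape {p.shape} does not match weight dimensions "
            f"({cs.w_f.shape[0]} scales x {cs.w_t.shape[0]} time points)"
        )
    p_f = cs.w_f @ (cs.w_f.T @ p)
    p_t = cs.w_t @ (cs.w_t.T @ p.T)
    return cs.rc_f * p_f + (cs.rc_t * p_t).T


def aggregate(
    projections: list[tuple[str, str, np.ndarray]],
    scale_freqs_hz=None,
    time_ms=None,
) -> ProjectionSet:
    """Condition means and grand mean of the joint projections, min-max
    rescaled jointly to [0, 1].

    ``projections`` is a list of ``(subject, condition, P)``.  The rescaling
    uses the global min/max over the grand mean and all condition means, so
    relative ordering across conditions is preserved.
    """
    by_cond: dict = {}
    for _, cond, pmat in projections:
        by_cond.setdefault(cond, []).append(pmat)
    if not by_cond:
        raise ValueError("no projections to aggregate")
    raw_g = {d: np.mean(ps, axis=0) for d, ps in by_cond.items()}
    raw_grand = np.mean(list(raw_g.values()), axis=0)
    pool = np.concatenate([raw_grand.ravel()] + [v.ravel() for v in raw_g.values()])
    lo, hi = float(pool.min()), float(pool.max())
    span = hi - lo if hi > lo else 1.0
    g = {d: (v - lo) / span for d, v in raw_g.items()}
    grand = (raw_grand - lo) / span
    return ProjectionSet(
        projections=projections,
        condition_means=g,
        grand_mean=grand,
        raw_condition_means=raw_g,
        raw_grand_mean=raw_grand,
        scale_freqs_hz=scale_freqs_hz,
        time_ms=time_ms,
    )


def group_analysis(
    surfaces: list[MMRSurface], pvaf_min: float = 0.01
) -> tuple[CompromiseSet, ProjectionSet]:
    """Full chain: cross-products -> centering -> compromises -> weights ->
    per-surface projections -> condition/grand means."""
    cps = [center_and_normalize(cross_products(s)) for s in surfaces]
    cs = select_weights(build_compromise(cps), pvaf_min=pvaf_min)
    projections = [(s.subject, s.condition, project(s, cs)) for s in surfaces]
    ref = surfaces[0]
    return cs, aggregate(projections, scale_freqs_hz=ref.scale_freqs_hz, time_ms=ref.time_ms)
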