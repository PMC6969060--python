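"""Expectation–maximization mixture clustering of corrected VAFs.

Mutations shared and private between a lesion pair are clustered jointly
in two dimensions (one axis per lesion, coordinates are corrected VAFs; a
mutation absent but covered in a lesion sits at 0 on that axis).  The
mixture is a diagonal-covariance Gaussian mixture fit by EM, implemented
here from scratch:

* initialization: k-means++ seeding from an explicit seed;
* E step: posterior responsibilities via log-sum-exp;
* M step: weighted means/variances, variances floored at 1e-5;
* convergence: log-likelihood improvement below ``tol`` (the trace is
  recorded and is non-decreasing, the standard EM guarantee).

The number of components is selected by BIC over k = 1..6 with 5 random
restarts per k.  Cluster centers estimate, on the corrected-VAF scale, the
average cellular proportion of the subpopulation (proportion = 2 x center
under the heterozygous single-copy model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .vaf_correction import CorrectedVariant

__all__ = [
    "MixtureModel",
    "CloneCluster",
    "build_vaf_matrix",
    "fit_em",
    "select_k",
    "extract_clusters",
    "DEFAULT_SEED",
]

#: Default seed for reproducible CLI runs; every stochastic entry point
#: also takes an explicit seed.
DEFAULT_SEED = 17

VARIANCE_FLOOR = 1e-5
FLAG_DEGENERATE = "DEGENERATE"


@dataclass(frozen=True)
class MixtureModel:
    """A fitted diagonal-covariance Gaussian mixture."""

    k: int
    means: np.ndarray  # (k, d)
    variances: np.ndarray  # (k, d)
    weights: np.ndarray  # (k,)
    loglik: float
    loglik_trace: tuple[float, ...]
    n_iter: int
    converged: bool
    seed: int
    flags: tuple[str, ...] = ()

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def bic(self, n: int) -> float:
        """Bayesian information criterion: -2 loglik + p ln n with
        p = k (2 d + 1) - 1 free parameters (means, variances, weights)."""
        p = self.k * (2 * self.dim + 1) - 1
        return -2.0 * self.loglik + p * np.log(n)


@dataclass(frozen=True)
class CloneCluster:
    """A hard-assigned mixture component: one putative subpopulation."""

    cluster_id: int
    center: tuple[float, ...]
    member_variant_ids: tuple[str, ...]
    weight: float
    presence: tuple[bool, ...]  # per lesion: center coordinate >= presence_min


def build_vaf_matrix(
    lesion_a: Sequence[CorrectedVariant],
    lesion_b: Sequence[CorrectedVariant],
    depth_a: Mapping[str, int] | None = None,
    depth_b: Mapping[str, int] | None = None,
    min_depth: int = 10,
) -> tuple[list[str], np.ndarray, list[str]]:
    """Join two lesions' corrected variants into an n x 2 coordinate matrix.

    The join key is ``variant_id``.  A variant absent from one lesion gets
    coordinate 0 there — absence means VAF 0 provided the site had
    coverage.  When a per-site depth map is supplied for the lesion the
    variant is missing from, sites below ``min_depth`` are dropped instead
    (uncovered, no evidence either way) and reported.

    Returns ``(variant_ids, matrix, dropped_ids)`` with rows sorted by
    variant_id for determinism.
    """
    a = {v.variant_id: v.corrected_vaf for v in lesion_a}
    b = {v.variant_id: v.corrected_vaf for v in lesion_b}
    ids = sorted(set(a) | set(b))
    if not ids:
        raise ValueError("no variants to cluster")
    rows = []
    kept_ids = []
    dropped = []
    for vid in ids:
        if vid not in a and depth_a is not None and depth_a.get(vid, 0) < min_depth:
            dropped.append(vid)
            continue
        if vid not in b and depth_b is not None and depth_b.get(vid, 0) < min_depth:
            dropped.append(vid)
            continue
        rows.append((a.get(vid, 0.0), b.get(vid, 0.0)))
        kept_ids.append(vid)
    if not rows:
        raise ValueError("no variants to cluster after coverage filtering")
    matrix = np.clip(np.array(rows, dtype=float), 0.0, 1.0)
    return kept_ids, matrix, dropped



def _as_matrix(points) -> np.ndarray:
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("points must be an (n, d) array")
    return X

def _kmeanspp_seeds(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(k - 1):
        d2 = np.min(
            np.stack([np.sum((X - c) ** 2, axis=1) for c in centers]), axis=0
        )
        total = d2.sum()
        if total <= 0:
            centers.append(X[rng.integers(n)])
        else:
            centers.append(X[rng.choice(n, p=d2 / total)])
    return np.array(centers)


def _log_density(X: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Componentwise diagonal-Gaussian log density, shape (n, k)."""
    # (n, k, d) broadcast
    diff = X[:, None, :] - means[None, :, :]
    return -0.5 * (
        np.sum(np.log(2.0 * np.pi * variances), axis=1)[None, :]
        + np.sum(diff**2 / variances[None, :, :], axis=2)
    )


def fit_em(
    points: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 500,
    tol: float = 1e-8,
    variance_floor: float = VARIANCE_FLOOR,
) -> MixtureModel:
    """Fit a k-component diagonal Gaussian mixture by EM.

    All-identical inputs return a single degenerate component (flag
    ``DEGENERATE``) regardless of the requested k.
    """
    X = _as_matrix(points)
    n, d = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")

    if np.all(X == X[0]):
        mean = X[:1].copy()
        return MixtureModel(
            k=1,
            means=mean,
            variances=np.full((1, d), variance_floor),
            weights=np.ones(1),
            loglik=float(_log_density(X, mean, np.full((1, d), variance_floor)).sum()),
            loglik_trace=(),
            n_iter=0,
            converged=True,
            seed=seed,
            flags=(FLAG_DEGENERATE,),
        )

    rng = np.random.default_rng(seed)
    means = _kmeanspp_seeds(X, k, rng)
    variances = np.tile(np.maximum(X.var(axis=0), variance_floor), (k, 1))
    weights = np.full(k, 1.0 / k)

    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E step
        logp = _log_density(X, means, variances) + np.log(weights)[None, :]
        m = logp.max(axis=1, keepdims=True)
        logsum = m[:, 0] + np.log(np.sum(np.exp(logp - m), axis=1))
        loglik = float(logsum.sum())
        trace.append(loglik)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            break
        resp = np.exp(logp - logsum[:, None])
        # M step
        nk = resp.sum(axis=0) + 1e-300
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        second = (resp.T @ (X**2)) / nk[:, None]
        variances = np.maximum(second - means**2, variance_floor)

    return MixtureModel(
        k=k,
        means=means,
        variances=variances,
        weights=weights,
        loglik=trace[-1],
        loglik_trace=tuple(trace),
        n_iter=n_iter,
        converged=converged,
        seed=seed,
    )


def select_k(
    points: np.ndarray,
    seed: int,
    k_range: Iterable[int] = range(1, 7),
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureModel:
    """Pick the number of components by BIC over ``k_range``.

    Each k is fit ``n_restarts`` times from independent seeds derived from
    ``seed``; the best log-likelihood per k competes on BIC.
    """
    X = _as_matrix(points)
    n = X.shape[0]
    ks = [k for k in k_range if 1 <= k <= n]
    if not ks:
        raise ValueError("empty k_range (or fewer points than every k)")
    ss = np.random.SeedSequence(seed)
    best: MixtureModel | None = None
    best_bic = np.inf
    for k in ks:
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_restarts)]
        fits = [fit_em(X, k, s, max_iter=max_iter, tol=tol) for s in child_seeds]
        fit = max(fits, key=lambda f: f.loglik)
        bic = fit.bic(n)
        if bic < best_bic - 1e-12:
            best, best_bic = fit, bic
        if FLAG_DEGENERATE in fit.flags:
            break  # identical points: larger k is identical too
    assert best is not None
    return best


def extract_clusters(
    model: MixtureModel,
    points: np.ndarray,
    ids: Sequence[str],
    presence_min: float = 0.05,
) -> list[CloneCluster]:
    """Hard-assign points to components and package clusters.

    Components are re-indexed by lexicographically sorted centers so
    cluster ids are stable across seeds; posterior ties break toward the
    lower cluster id.  A cluster is "present" in a lesion when its center
    coordinate on that axis is at least ``presence_min``.
    """
    X = _as_matrix(points)
    if X.shape[0] != len(ids):
        raise ValueError("points and ids length mismatch")
    order = sorted(range(model.k), key=lambda j: tuple(model.means[j]))
    means = model.means[order]
    variances = model.variances[order]
    weights = model.weights[order]
    logp = _log_density(X, means, variances) + np.log(weights)[None, :]
    assign = np.argmax(logp, axis=1)  # argmax takes the first (lowest) on ties
    clusters = []
    for j in range(model.k):
        members = tuple(ids[i] for i in np.where(assign == j)[0])
        center = tuple(float(c) for c in means[j])
        clusters.append(
            CloneCluster(
                cluster_id=j,
                center=center,
                member_variant_ids=members,
                weight=float(weights[j]),
                presence=tuple(c >= presence_min for c in center),
            )
        )
    return clusters


def write_clusters(path, clusters: Sequence[CloneCluster]) -> None:
    """Cluster table in the canonical TSV dialect."""
    dim = len(clusters[0].center) if clusters else 2
    axis_cols = "\t".join(f"center_{i}" for i in range(dim))
    pres_cols = "\t".join(f"present_{i}" for i in range(dim))
    lines = [f"#cluster_id\t{axis_cols}\tweight\tn_members\t{pres_cols}"]
    for c in clusters:
        lines.append(
            "\t".join(
                [str(c.cluster_id)]
                + [repr(float(x)) for x in c.center]
                + [repr(float(c.weight)), str(len(c.member_variant_ids))]
                + ["true" if p else "false" for p in c.presence]
            )
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_scatter(path, ids: Sequence[str], points: np.ndarray, clusters: Sequence[CloneCluster]) -> None:
    """Per-variant scatter export (variant_id, coordinates, cluster_id)."""
    member_of = {}
    for c in clusters:
        for vid in c.member_variant_ids:
            member_of[vid] = c.cluster_id
    X = np.atleast_2d(np.asarray(points, dtype=float))
    lines = ["#variant_id\tx\ty\tcluster_id"]
    for vid, row in zip(ids, X):
        y = float(row[1]) if len(row) > 1 else 0.0
        lines.append(
            f"{vid}\t{float(row[0])!r}\t{y!r}\t{member_of.get(vid, -1)}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
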