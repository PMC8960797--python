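"""Affinity propagation exemplar clustering.

Message-passing clustering after Frey & Dueck: items exchange
*responsibility* messages r(i,k) (how well suited k is as exemplar for i)
and *availability* messages a(i,k) (how appropriate it would be for i to
choose k), damped and iterated until the exemplar set is stable.  The
*preference* (self-similarity, the diagonal of the input) controls cluster
granularity and is set here to the q-quantile of the off-diagonal
similarities, mirroring the ``q`` parameter of the R ``apcluster`` package
(q = 0 yields few clusters, q = 1 many).

A brute-force optimizer over all exemplar subsets is provided as an exact
oracle for small problems, and a greedy exemplar-merging routine produces
an agglomerative hierarchy from an affinity propagation solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence
import warnings

import numpy as np

from .datatypes import ClusteringResult, ValidationError
from .linkage import SimilarityMatrix

__all__ = [
    "APParams",
    "set_preference",
    "affinity_propagation",
    "brute_force_exemplars",
    "agglomerate_exemplars",
    "net_similarity",
]


@dataclass
class APParams:
    q_preference: float = 0.5
    damping: float = 0.9
    maxit: int = 1000
    convits: int = 100
    jitter_scale: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_preference <= 1.0:
            raise ValidationError("q_preference must be in [0, 1]")
        if not 0.5 <= self.damping < 1.0:
            raise ValidationError("damping must be in [0.5, 1)")
        if self.maxit < 1 or self.convits < 1:
            raise ValidationError("maxit and convits must be positive")
        if self.jitter_scale < 0:
            raise ValidationError("jitter_scale must be >= 0")


def _as_array(S, ids=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(S, SimilarityMatrix):
        arr, default_ids = S.values.astype(float).copy(), list(S.ids)
    else:
        arr = np.asarray(S, dtype=float).copy()
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValidationError("similarity matrix must be square")
        default_ids = [str(i) for i in range(arr.shape[0])]
    if ids is not None:
        ids = [str(i) for i in ids]
        if len(ids) != arr.shape[0]:
            raise ValidationError("ids length does not match matrix size")
        return arr, ids
    return arr, default_ids


def set_preference(S, q: float) -> np.ndarray:
    """Return a copy of S with diagonal = q-quantile of off-diagonal values
    (linear interpolation), the preference fed to affinity propagation."""
    arr, _ = _as_array(S)
    n = arr.shape[0]
    if n == 0:
        raise ValidationError("empty similarity matrix")
    if n == 1:
        np.fill_diagonal(arr, 0.0)
        return arr
    off = arr[~np.eye(n, dtype=bool)]
    off = off[np.isfinite(off)]
    if off.size == 0:
        raise ValidationError("no finite off-diagonal similarities")
    np.fill_diagonal(arr, float(np.quantile(off, q)))
    return arr


def net_similarity(S: np.ndarray, labels: np.ndarray, exemplars: np.ndarray) -> float:
    """Sum of similarities of items to their exemplar, plus the exemplar
    preferences — the objective affinity propagation maximizes."""
    total = 0.0
    for k in exemplars:
        total += S[k, k]
    for i, lab in enumerate(labels):
        k = exemplars[lab]
        if i != k:
            total += S[i, k]
    return float(total)


def _assign(S: np.ndarray, exemplars: np.ndarray) -> np.ndarray:
    """Assign each item to its most similar exemplar (exemplars to themselves);
    ties break toward the lowest exemplar index."""
    sub = S[:, exemplars]
    labels = np.argmax(sub, axis=1)
    for lab, k in enumerate(exemplars):
        labels[k] = lab
    return labels


def _result(ids: Sequence[str], S: np.ndarray, exemplars: np.ndarray,
            n_iter: int, converged: bool) -> ClusteringResult:
    exemplars = np.sort(np.asarray(exemplars))
    labels = _assign(S, exemplars)
    return ClusteringResult(
        labels={ids[i]: int(labels[i]) for i in range(len(ids))},
        exemplars={int(lab): ids[k] for lab, k in enumerate(exemplars)},
        n_iterations=n_iter,
        converged=converged,
        net_similarity=net_similarity(S, labels, exemplars),
    )


def affinity_propagation(
    S, params: APParams | None = None, ids: Sequence[str] | None = None
) -> ClusteringResult:
    """Run damped responsibility/availability message passing on a
    similarity matrix whose diagonal already holds the preferences
    (see :func:`set_preference`).

    Deterministic for a given seed: exact degeneracies are broken by a
    seeded jitter of magnitude ``jitter_scale`` times the similarity scale,
    and final assignment ties break toward the lowest item index.  If the
    exemplar set is not stable within ``maxit`` iterations the best current
    solution is returned with ``converged=False``.
    """
    params = params or APParams()
    arr, ids = _as_array(S, ids)
    n = arr.shape[0]
    if n == 0:
        raise ValidationError("empty similarity matrix")
    if n == 1:
        return ClusteringResult(
            labels={ids[0]: 0}, exemplars={0: ids[0]},
            n_iterations=0, converged=True, net_similarity=float(arr[0, 0]),
        )
    if not np.isfinite(arr).all():
        raise ValidationError("similarity matrix contains non-finite values; "
                              "set the preference diagonal first")

    work = arr.copy()
    if params.jitter_scale > 0:
        rng = np.random.default_rng(params.seed)
        scale = np.abs(work).max() or 1.0
        noise = rng.uniform(-1.0, 1.0, size=work.shape)
        noise = (noise + noise.T) / 2.0
        work = work + params.jitter_scale * scale * noise

    lam = params.damping
    R = np.zeros_like(work)
    A = np.zeros_like(work)
    e_history = np.zeros((params.convits, n), dtype=bool)
    converged = False
    it = 0
    idx = np.arange(n)
    for it in range(1, params.maxit + 1):
        # responsibilities: r(i,k) = s(i,k) - max_{k'!=k} [a(i,k') + s(i,k')]
        AS = A + work
        first_k = np.argmax(AS, axis=1)
        first = AS[idx, first_k]
        AS[idx, first_k] = -np.inf
        second = np.max(AS, axis=1)
        Rnew = work - first[:, None]
        Rnew[idx, first_k] = work[idx, first_k] - second
        R = lam * R + (1 - lam) * Rnew

        # availabilities: a(i,k) = min(0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k)))
        Rp = np.maximum(R, 0)
        np.fill_diagonal(Rp, R.diagonal())
        Anew = Rp.sum(axis=0)[None, :] - Rp
        dA = Anew.diagonal().copy()
        Anew = np.minimum(Anew, 0)
        np.fill_diagonal(Anew, dA)
        A = lam * A + (1 - lam) * Anew

        e = (A + R).diagonal() > 0
        e_history[(it - 1) % params.convits] = e
        if it >= params.convits and e.any():
            if (e_history == e_history[0]).all():
                converged = True
                break

    exemplars = np.flatnonzero((A + R).diagonal() > 0)
    if exemplars.size == 0:
        exemplars = np.array([int(np.argmax((A + R).diagonal()))])
    # refinement: within each cluster pick the member maximizing total
    # within-cluster similarity, then reassign (standard final step)
    labels = _assign(work, exemplars)
    refined = []
    for lab in range(exemplars.size):
        members = np.flatnonzero(labels == lab)
        sub = work[np.ix_(members, members)]
        refined.append(int(members[np.argmax(sub.sum(axis=0))]))
    exemplars = np.unique(refined)
    if not converged:
        warnings.warn(
            f"affinity propagation did not converge in {params.maxit} iterations",
            UserWarning,
        )
    return _result(ids, arr, exemplars, it, converged)


def brute_force_exemplars(
    S, max_n: int = 10, ids: Sequence[str] | None = None
) -> ClusteringResult:
    """Exact maximization of net similarity over all non-empty exemplar
    subsets; feasible only for tiny problems (n <= ``max_n``).

    Independent oracle for :func:`affinity_propagation`; ties break toward
    the lexicographically first exemplar subset of smallest size.
    """
    arr, ids = _as_array(S, ids)
    n = arr.shape[0]
    if n == 0:
        raise ValidationError("empty similarity matrix")
    if n > max_n:
        raise ValidationError(f"n={n} too large for brute force (max {max_n})")
    if not np.isfinite(arr).all():
        raise ValidationError("set the preference diagonal first")
    best = None
    best_net = -np.inf
    for k in range(1, n + 1):
        for subset in combinations(range(n), k):
            ex = np.asarray(subset)
            labels = _assign(arr, ex)
            # all exemplars must actually serve their own cluster
            net = net_similarity(arr, labels, ex)
            if net > best_net + 1e-12:
                best_net = net
                best = ex
    return _result(ids, arr, best, 0, True)


def agglomerate_exemplars(S, result: ClusteringResult, k_target: int):
    """Greedy exemplar-based merging of an affinity propagation solution
    down to ``k_target`` clusters (dendrogram export).

    The merge criterion for two clusters is the best achievable mean
    similarity of a joint exemplar (any member of the union) to all other
    members of the union; the pair with the highest criterion merges first.
    Returns ``(merged ClusteringResult, merge_tree)`` where the tree lists
    each merge with its criterion value and joint exemplar.
    """
    arr, ids = _as_array(S)
    id_index = {g: i for i, g in enumerate(ids)}
    clusters: dict[int, list[int]] = {}
    for item, lab in result.labels.items():
        clusters.setdefault(lab, []).append(id_index[item])
    if k_target < 1 or k_target > len(clusters):
        raise ValidationError(
            f"k_target={k_target} outside [1, {len(clusters)}]"
        )

    def joint_exemplar(members: list[int]) -> tuple[int, float]:
        members = sorted(members)
        if len(members) == 1:
            return members[0], float(arr[members[0], members[0]])
        sub = arr[np.ix_(members, members)].astype(float).copy()
        np.fill_diagonal(sub, 0.0)
        scores = sub.sum(axis=0) / (len(members) - 1)
        j = int(np.argmax(scores))
        return members[j], float(scores[j])

    merge_tree = []
    while len(clusters) > k_target:
        best_pair, best_val, best_ex = None, -np.inf, None
        for a, b in combinations(sorted(clusters), 2):
            ex, val = joint_exemplar(clusters[a] + clusters[b])
            if val > best_val + 1e-12:
                best_pair, best_val, best_ex = (a, b), val, ex
        a, b = best_pair
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
        merge_tree.append(
            {"merged": [a, b], "into": a,
             "criterion": best_val, "joint_exemplar": ids[best_ex]}
        )
    labels = {}
    exemplars = {}
    for new_lab, old_lab in enumerate(sorted(clusters)):
        members = clusters[old_lab]
        ex, _ = joint_exemplar(members)
        exemplars[new_lab] = ids[ex]
        for m in members:
            labels[ids[m]] = new_lab
    ex_idx = np.array([id_index[exemplars[lab]] for lab in sorted(exemplars)])
    lab_arr = np.array([labels[g] for g in ids])
    merged = ClusteringResult(
        labels=labels, exemplars=exemplars,
        n_iterations=result.n_iterations, converged=result.converged,
        net_similarity=net_similarity(arr, lab_arr, ex_idx),
    )
    return merged, merge_tree
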