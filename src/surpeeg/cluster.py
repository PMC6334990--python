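"""Group-level spatio-temporal cluster-based permutation test.

Family-wise error control for the mass-univariate rERP comparison follows
the standard nonparametric recipe: (i) a dependent-samples t-test at every
(electrode, sample) comparing each subject's target coefficient against the
matched null coefficient; (ii) suprathreshold points (uncorrected two-sided
p below the cluster-forming threshold) are clustered by spatio-temporal
adjacency — same electrode at consecutive samples, or neighboring electrodes
at the same sample — separately for positive and negative t, and each
cluster's t-values are summed into a mass; (iii) the per-subject
(target, null) assignment is randomly swapped (equivalently, the paired
differences are sign-flipped) many times, recording the maximum absolute
cluster mass of each permutation; (iv) an observed cluster's corrected p is
the fraction of permutation maxima at least as large as its |mass|, with the
(+1)/(+1) convention so the smallest reportable p is 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .montage import Montage

__all__ = [
    "TMap",
    "Cluster",
    "PermutationResult",
    "paired_t_map",
    "form_clusters",
    "permutation_test",
    "grid_adjacency",
]


@dataclass(frozen=True)
class TMap:
    """Pointwise paired t statistics and uncorrected two-sided p values."""

    t: np.ndarray  # (E, T)
    p: np.ndarray  # (E, T)
    df: int
    zero_variance: np.ndarray = None  # (E, T) bool; t forced to 0, p to 1


@dataclass
class Cluster:
    """A connected suprathreshold region of uniform sign."""

    members: list[tuple[int, int]]  # (electrode, sample) points
    sign: int  # +1 or -1
    mass: float  # summed t over members
    corrected_p: float | None = None

    @property
    def electrodes(self) -> set[int]:
        return {e for e, _ in self.members}

    @property
    def sample_range(self) -> tuple[int, int]:
        samples = [t for _, t in self.members]
        return min(samples), max(samples)


@dataclass
class PermutationResult:
    clusters: list[Cluster]
    null_max_mass: np.ndarray
    n_permutations: int
    alpha: float

    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.corrected_p <= self.alpha]


def paired_t_map(target: np.ndarray, null: np.ndarray) -> TMap:
    """Dependent-samples t over per-subject (target - null) at every point.

    ``target`` and ``null`` are (subjects, electrodes, samples).  Points
    where the differences have exactly zero variance get t = 0 and p = 1 and
    are flagged in ``zero_variance``.
    """
    target = np.asarray(target, float)
    null = np.asarray(null, float)
    if target.shape != null.shape:
        raise ValueError("target and null shapes differ")
    S = target.shape[0]
    if S < 3:
        raise ValueError("need at least 3 subjects")
    d = target - null
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero = sd == 0.0
    df = S - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, mean / (sd / np.sqrt(S)))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero, 1.0, p)
    return TMap(t=t, p=p, df=df, zero_variance=zero)


def grid_adjacency(montage: Montage, n_samples: int) -> csr_matrix:
    """Sparse adjacency over the flattened (electrode, sample) grid.

    Node index is ``e * n_samples + t``.  Edges connect consecutive samples
    at the same electrode and neighboring electrodes at the same sample.
    """
    E = montage.n_electrodes
    T = n_samples
    rows: list[int] = []
    cols: list[int] = []
    # temporal edges
    for e in range(E):
        base = e * T
        idx = np.arange(base, base + T - 1)
        rows.extend(idx)
        cols.extend(idx + 1)
    # spatial edges
    ee, nn = np.nonzero(np.triu(montage.adjacency))
    for a, b in zip(ee, nn):
        ta = np.arange(a * T, a * T + T)
        tb = np.arange(b * T, b * T + T)
        rows.extend(ta)
        cols.extend(tb)
    rows_np = np.array(rows)
    cols_np = np.array(cols)
    data = np.ones(len(rows_np), dtype=bool)
    adj = csr_matrix((data, (rows_np, cols_np)), shape=(E * T, E * T))
    return adj + adj.T


def _cluster_masses(
    tflat: np.ndarray, supra: np.ndarray, adj: csr_matrix
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Masses and member index lists of sign-pure connected components."""
    idx = np.flatnonzero(supra)
    if len(idx) == 0:
        return np.empty(0), []
    sub = adj[idx][:, idx].toarray()
    signs = np.sign(tflat[idx])
    sub &= signs[:, None] == signs[None, :]  # cut opposite-sign edges
    n_comp, labels = connected_components(csr_matrix(sub), directed=False)
    masses = np.zeros(n_comp)
    np.add.at(masses, labels, tflat[idx])
    members = [idx[labels == c] for c in range(n_comp)]
    return masses, members


def form_clusters(
    tmap: TMap, threshold: float, montage: Montage, adj: csr_matrix | None = None
) -> list[Cluster]:
    """Connected suprathreshold components, positive and negative separately."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    E, T = tmap.t.shape
    if adj is None:
        adj = grid_adjacency(montage, T)
    supra = (tmap.p < threshold).ravel() & (tmap.t.ravel() != 0.0)
    masses, members = _cluster_masses(tmap.t.ravel(), supra, adj)
    clusters = []
    for mass, mem in zip(masses, members):
        pts = [(int(i) // T, int(i) % T) for i in mem]
        clusters.append(Cluster(members=pts, sign=int(np.sign(mass)), mass=float(mass)))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def permutation_test(
    target: np.ndarray,
    null: np.ndarray,
    montage: Montage,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    threshold: float = 0.05,
) -> PermutationResult:
    """Cluster permutation test of target vs. matched null coefficients.

    Each permutation swaps every subject's (target, null) pair with
    probability 1/2 — a sign flip of the paired differences — and records the
    maximum absolute sign-pure cluster mass.  Observed clusters receive
    corrected p = (# permutation maxima >= |mass| + 1) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    tmap = paired_t_map(target, null)
    S, E, T = np.asarray(target).shape
    adj = grid_adjacency(montage, T)
    observed = form_clusters(tmap, threshold, montage, adj=adj)

    d = (np.asarray(target, float) - np.asarray(null, float)).reshape(S, E * T)
    msq = (d**2).mean(axis=0)  # invariant under sign flips
    t_crit = stats.t.ppf(1.0 - threshold / 2.0, S - 1)

    rng = np.random.default_rng(seed)
    max_mass = np.empty(n_perm)
    block = 200
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(b, S))
        mean = (signs @ d) / S  # (b, E*T)
        var = (msq - mean**2) * (S / (S - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            tperm = np.where(var > 0, mean / np.sqrt(var / S), 0.0)
        supra = np.abs(tperm) > t_crit
        for i in range(b):
            masses, _ = _cluster_masses(tperm[i], supra[i], adj)
            max_mass[done + i] = np.abs(masses).max() if len(masses) else 0.0
        done += b

    for c in observed:
        c.corrected_p = (np.sum(max_mass >= abs(c.mass)) + 1.0) / (n_perm + 1.0)
    return PermutationResult(
        clusters=observed, null_max_mass=max_mass, n_permutations=n_perm, alpha=alpha
    )
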