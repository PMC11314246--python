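"""Kabsch RMSD, Daura conformational clustering, entropy, and ensemble overlap.

The Daura algorithm greedily picks the frame with the most neighbours
within an RMSD cutoff (default 3 A) as a cluster centre, removes the
cluster, and repeats.  Conformational entropy is the Shannon entropy of the
cluster populations in units of kB.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KB_KCAL = 0.0019872041  # kcal / (mol K)


def kabsch_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Minimal RMSD between two conformations over rigid rotations and
    translations (proper rotations only, via SVD with determinant fix)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] < 3:
        raise ValueError("conformations must share shape (n >= 3, 3)")
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S = S.copy()
        S[-1] = -S[-1]
    msd = (np.sum(A * A) + np.sum(B * B) - 2.0 * S.sum()) / A.shape[0]
    return float(np.sqrt(max(msd, 0.0)))


def pairwise_rmsd(
    frames: np.ndarray, block: int = 256, max_memory_mb: float = 512.0
) -> np.ndarray:
    """Full pairwise minimal-RMSD matrix, computed exactly in blocks.

    Uses batched 3x3 SVDs; ``block`` bounds the temporary covariance stack
    so memory stays below roughly ``max_memory_mb``.
    """
    X = np.asarray(frames, dtype=float)
    F, n, _ = X.shape
    X = X - X.mean(axis=1, keepdims=True)
    ssd = np.einsum("fai,fai->f", X, X)
    # shrink block if needed to respect the memory cap (~72 bytes per pair)
    while block > 8 and (block * block * 9 * 8) > max_memory_mb * 1e6:
        block //= 2
    D = np.zeros((F, F))
    for i0 in range(0, F, block):
        i1 = min(i0 + block, F)
        for j0 in range(i0, F, block):
            j1 = min(j0 + block, F)
            H = np.einsum("fai,gaj->fgij", X[i0:i1], X[j0:j1])
            S = np.linalg.svd(H, compute_uv=False)
            det = np.linalg.det(H)
            trace = S.sum(axis=2) - np.where(det < 0, 2.0 * S[:, :, 2], 0.0)
            msd = (ssd[i0:i1, None] + ssd[None, j0:j1] - 2.0 * trace) / n
            d = np.sqrt(np.clip(msd, 0.0, None))
            D[i0:i1, j0:j1] = d
            D[j0:j1, i0:i1] = d.T
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class ClusterResult:
    """Daura clustering outcome.

    ``assignments`` maps each frame to a cluster id (0-based, by discovery
    order = descending initial neighbour count); ``centers`` are the
    central frame indices; ``populations`` are frame fractions summing
    to 1; ``s_conf`` is the Shannon entropy of the populations in kB units.
    """

    assignments: np.ndarray
    centers: np.ndarray
    populations: np.ndarray

    @property
    def n_conf(self) -> int:
        return len(self.centers)

    @property
    def s_conf(self) -> float:
        return conformational_entropy(self.populations)

    def to_frame(self, temperature: float = 300.0) -> pd.DataFrame:
        """Cluster table with free energies relative to the top cluster."""
        p = self.populations
        dg = -KB_KCAL * temperature * np.log(p / p.max())
        return pd.DataFrame(
            {
                "cluster": np.arange(self.n_conf),
                "center_frame": self.centers,
                "population": p,
                "delta_g_kcal": dg,
            }
        )


def daura_cluster(
    frames: np.ndarray,
    cutoff: float = 3.0,
    selection: np.ndarray | None = None,
    rmsd_matrix: np.ndarray | None = None,
) -> ClusterResult:
    """Greedy neighbour-count clustering on the pairwise RMSD matrix.

    Repeatedly the frame with the most remaining neighbours within
    ``cutoff`` (ties -> lowest frame index) becomes a centre; it and its
    neighbours form a cluster and are removed.
    """
    X = np.asarray(frames, dtype=float)
    if selection is not None:
        X = X[:, selection]
    F = X.shape[0]
    D = pairwise_rmsd(X) if rmsd_matrix is None else np.asarray(rmsd_matrix)
    adj = D <= cutoff
    np.fill_diagonal(adj, True)
    remaining = np.ones(F, dtype=bool)
    assignments = np.full(F, -1, dtype=int)
    centers = []
    cid = 0
    while remaining.any():
        counts = (adj & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = adj[center] & remaining
        assignments[members] = cid
        centers.append(center)
        remaining &= ~members
        cid += 1
    populations = np.bincount(assignments, minlength=cid) / F
    return ClusterResult(
        assignments=assignments,
        centers=np.array(centers),
        populations=populations,
    )


def conformational_entropy(populations) -> float:
    """Shannon entropy -sum p ln p of cluster populations, in kB units."""
    p = np.asarray(populations, dtype=float)
    if np.any(p < 0):
        raise ValueError("populations must be non-negative")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError("populations must sum to 1")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def combined_overlap(
    labeled_frames: dict[str, np.ndarray],
    cutoff: float = 3.0,
    selection: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float]:
    """Cluster the pooled frames of several systems and measure ensemble
    overlap.

    Returns a ranked per-cluster table of per-system occupancies and the
    overlap score sum_clusters min_systems(occupancy); the score is 1 when
    all systems populate every cluster identically and 0 when no cluster is
    shared.
    """
    labels = list(labeled_frames)
    if len(labels) < 2:
        raise ValueError("need at least two labeled trajectories")
    shapes = {np.asarray(v).shape[1:] for v in labeled_frames.values()}
    if len(shapes) != 1:
        raise ValueError("incompatible atom selections across trajectories")
    pooled = np.concatenate([np.asarray(labeled_frames[k], dtype=float) for k in labels])
    sizes = [len(labeled_frames[k]) for k in labels]
    system = np.repeat(np.arange(len(labels)), sizes)
    result = daura_cluster(pooled, cutoff=cutoff, selection=selection)
    occ = np.zeros((result.n_conf, len(labels)))
    for c in range(result.n_conf):
        members = result.assignments == c
        for s in range(len(labels)):
            occ[c, s] = np.sum(members & (system == s)) / sizes[s]
    overlap = float(occ.min(axis=1).sum())
    df = pd.DataFrame(occ, columns=labels)
    df.insert(0, "cluster", np.arange(result.n_conf))
    df["total"] = occ.sum(axis=1)
    df = df.sort_values("total", ascending=False, ignore_index=True)
    return df, overlap


def low_free_energy_threshold(
    temperature: float = 300.0, delta_g: float = 2.0
) -> float:
    """Population ratio p/pmax above which a cluster lies within
    ``delta_g`` kcal/mol of the most populated one."""
    return float(np.exp(-delta_g / (KB_KCAL * temperature)))


def equilibration_curve(
    frames: np.ndarray,
    n_windows: int = 10,
    cutoff: float = 3.0,
    selection: np.ndarray | None = None,
    temperature: float = 300.0,
    delta_g: float = 2.0,
) -> pd.DataFrame:
    """Convergence diagnostic: low-free-energy cluster count on growing
    prefixes of the trajectory.

    A cluster is low-free-energy when its population is within
    ``delta_g`` kcal/mol (at ``temperature``) of the most populated
    cluster's.  The ensemble is judged equilibrated once the count stops
    growing.
    """
    X = np.asarray(frames, dtype=float)
    if selection is not None:
        X = X[:, selection]
    F = X.shape[0]
    D = pairwise_rmsd(X)
    ratio = low_free_energy_threshold(temperature, delta_g)
    ends = np.unique(np.linspace(max(1, F // n_windows), F, n_windows).astype(int))
    rows = []
    for end in ends:
        res = daura_cluster(X[:end], cutoff=cutoff, rmsd_matrix=D[:end, :end])
        p = res.populations
        rows.append(
            dict(
                n_frames=int(end),
                n_clusters=res.n_conf,
                n_low_free_energy=int(np.sum(p / p.max() >= ratio)),
            )
        )
    return pd.DataFrame(rows)
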