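"""Adsorption geometry and residue-surface contact analysis.

All separations are measured from the surface reference plane z0 (the mean
terminal heavy-atom height), matching how the surface is defined in the
system model.  Residue-level quantities use the nearest heavy atom of each
residue; a residue is in contact when that atom lies within the contact
cutoff (default 3.5 A, approximately the van der Waals diameter of carbon)
of the plane.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import Trajectory

CONTACT_CUTOFF = 3.5  # Angstrom
HBOND_DA_CUTOFF = 3.5  # donor-acceptor heavy-atom distance, Angstrom
HBOND_ANGLE_CUTOFF = 150.0  # D-H...A angle, degrees


@dataclass
class SeparationSeries:
    """Per-frame center-of-mass and closest-residue separations."""

    com_z: np.ndarray  # (F,) mass-weighted COM height above z0
    closest_residue: np.ndarray  # (F,) author index
    closest_distance: np.ndarray  # (F,) nearest heavy atom height above z0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "com_separation": self.com_z,
                "closest_residue": self.closest_residue,
                "closest_distance": self.closest_distance,
            }
        )


def _require_surface(traj: Trajectory) -> float:
    if traj.surface is None:
        raise ValueError("analysis requires a trajectory with a surface")
    return traj.z0


def _residue_min_z(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame per-residue nearest-heavy-atom height above z0.

    Returns (dist (F, R), author_indices (R,)).
    """
    z0 = _require_surface(traj)
    heavy = traj.topology.heavy_mask()
    resids = traj.topology.residue_of_atom()
    authors = np.array([r.author_index for r in traj.topology.residues])
    z = traj.frames[:, :, 2] - z0
    dist = np.empty((traj.n_frames, len(authors)))
    for k, a in enumerate(authors):
        sel = (resids == a) & heavy
        dist[:, k] = z[:, sel].min(axis=1)
    return dist, authors


def com_separation(
    traj: Trajectory, bin_width: float = 1.0
) -> tuple[SeparationSeries, tuple[np.ndarray, np.ndarray]]:
    """Mass-weighted center-of-mass height above the plane, per frame, plus
    a normalized histogram (edges, probabilities summing to 1)."""
    z0 = _require_surface(traj)
    m = traj.topology.masses()
    com_z = (traj.frames[:, :, 2] * m).sum(axis=1) / m.sum() - z0
    dist, authors = _residue_min_z(traj)
    k = dist.argmin(axis=1)
    series = SeparationSeries(
        com_z=com_z,
        closest_residue=authors[k],
        closest_distance=dist[np.arange(len(k)), k],
    )
    lo = np.floor(com_z.min() / bin_width) * bin_width
    hi = np.ceil(com_z.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(com_z, bins=edges)
    probs = counts / counts.sum()
    return series, (edges, probs)


def closest_residue_counts(series: SeparationSeries) -> pd.DataFrame:
    """Closest-residue occurrence table (residue, count), descending."""
    vals, counts = np.unique(series.closest_residue, return_counts=True)
    df = pd.DataFrame({"residue": vals, "count": counts})
    return df.sort_values("count", ascending=False, ignore_index=True)


def residue_surface_profile(traj: Trajectory) -> pd.DataFrame:
    """Per-residue mean +- sd of the nearest-heavy-atom separation."""
    dist, authors = _residue_min_z(traj)
    res = traj.topology.residues
    return pd.DataFrame(
        {
            "residue": authors,
            "code": [r.code for r in res],
            "klass": [r.klass for r in res],
            "mean": dist.mean(axis=0),
            "sd": dist.std(axis=0),
        }
    )


def contact_probability(
    traj: Trajectory, cutoff: float = CONTACT_CUTOFF
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-residue surface contact probability and per-frame fingerprints.

    A residue is in contact when its nearest heavy atom is within ``cutoff``
    of the plane.  Fingerprints are (F, R) uint8.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    dist, authors = _residue_min_z(traj)
    finger = (dist <= cutoff).astype(np.uint8)
    res = traj.topology.residues
    table = pd.DataFrame(
        {
            "residue": authors,
            "code": [r.code for r in res],
            "klass": [r.klass for r in res],
            "probability": finger.mean(axis=0),
        }
    )
    return table, finger


def adsorbed_mask(traj: Trajectory, cutoff: float = CONTACT_CUTOFF) -> np.ndarray:
    """Frame is adsorbed iff any residue is in contact at ``cutoff``."""
    dist, _ = _residue_min_z(traj)
    return (dist <= cutoff).any(axis=1)


def adsorbed_filter(traj: Trajectory, cutoff: float = CONTACT_CUTOFF) -> Trajectory:
    """Sub-trajectory of adsorbed frames."""
    mask = adsorbed_mask(traj, cutoff)
    return Trajectory(
        topology=traj.topology,
        frames=traj.frames[mask],
        surface=traj.surface,
        frame_spacing=traj.frame_spacing,
    )


def cluster_contacts(
    fingerprints: np.ndarray,
    authors: np.ndarray | None = None,
    merge_hamming: int = 1,
) -> pd.DataFrame:
    """Group adsorbed frames by their residue-contact fingerprint.

    Identical fingerprints are grouped, then groups are merged by
    single linkage at Hamming distance <= ``merge_hamming``.  Clusters are
    ranked by population; populations are fractions of *all* frames, so they
    sum to the adsorbed-frame fraction.  Each cluster reports the residues
    in contact in the majority of its frames.
    """
    finger = np.asarray(fingerprints, dtype=np.uint8)
    n_frames = len(finger)
    ads = finger.any(axis=1)
    if not ads.any():
        warnings.warn("no adsorbed frames; empty contact clustering")
        return pd.DataFrame(
            columns=["cluster", "population", "n_frames", "residues"]
        )
    sub = finger[ads]
    uniq, inverse, counts = np.unique(
        sub, axis=0, return_inverse=True, return_counts=True
    )
    # single-linkage merge of unique fingerprints at small Hamming distance
    n_u = len(uniq)
    parent = list(range(n_u))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if merge_hamming > 0:
        ham = (uniq[:, None, :] != uniq[None, :, :]).sum(axis=2)
        for i in range(n_u):
            for j in range(i + 1, n_u):
                if ham[i, j] <= merge_hamming:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(n_u)])

    if authors is None:
        authors = np.arange(finger.shape[1])
    rows = []
    for root in np.unique(roots):
        members = np.where(roots == root)[0]
        frame_sel = np.isin(inverse, members)
        n = int(frame_sel.sum())
        # residues in contact in the majority of the cluster's frames
        freq = sub[frame_sel].mean(axis=0)
        resset = [int(a) for a, f in zip(authors, freq) if f >= 0.5]
        rows.append(
            dict(population=n / n_frames, n_frames=n, residues=resset)
        )
    df = pd.DataFrame(rows).sort_values(
        "population", ascending=False, ignore_index=True
    )
    df.insert(0, "cluster", np.arange(1, len(df) + 1))
    return df


def surface_hbonds(
    traj: Trajectory,
    d_cutoff: float = HBOND_DA_CUTOFF,
    angle_cutoff: float = HBOND_ANGLE_CUTOFF,
) -> pd.DataFrame:
    """Mean protein-surface hydrogen-bond counts per residue.

    Geometric criterion: donor-acceptor heavy-atom distance <= ``d_cutoff``
    and D-H...A angle >= ``angle_cutoff``.  A residue *donates* when its
    amide N-H bridges to a surface acceptor and *accepts* when a surface
    hydroxyl O-H bridges to its backbone O.  On a CH3 surface (no
    donor/acceptor groups) all counts are zero.
    """
    _require_surface(traj)
    topo = traj.topology
    authors = np.array([r.author_index for r in topo.residues])
    out = pd.DataFrame(
        {
            "residue": authors,
            "code": [r.code for r in topo.residues],
            "donor": 0.0,
            "acceptor": 0.0,
        }
    )
    if traj.surface.ligand != "OH":
        warnings.warn("surface ligand has no hydrogen-bonding groups; counts are zero")
        return out

    surf = traj.surface.atom_table()
    s_O = surf.loc[surf["name"] == "OT", ["x", "y", "z"]].to_numpy()
    s_H = surf.loc[surf["name"] == "HT", ["x", "y", "z"]].to_numpy()

    atoms = topo.atoms
    resids = topo.residue_of_atom()
    don_N = atoms.index[atoms["donor"]].to_numpy()
    # amide H follows its N in the atom order
    don_H = don_N + 1
    acc = atoms.index[atoms["acceptor"]].to_numpy()
    cosmin = np.cos(np.deg2rad(180.0 - angle_cutoff))  # for angle >= cutoff

    def _count(D, H, A):
        """Number of D-H...A bonds for one frame (D donors, A acceptors)."""
        dDA = np.linalg.norm(D[:, None, :] - A[None, :, :], axis=2)
        ok = dDA <= d_cutoff
        if not ok.any():
            return np.zeros(len(D))
        HD = D - H
        HA = A[None, :, :] - H[:, None, :]
        # angle D-H...A: 180 deg when HD and HA are antiparallel
        cosang = np.einsum("ij,ikj->ik", HD, HA)
        cosang /= np.linalg.norm(HD, axis=1)[:, None] * np.linalg.norm(HA, axis=2)
        ok &= -cosang >= cosmin
        return ok.sum(axis=1).astype(float)

    don_counts = np.zeros((traj.n_frames, len(don_N)))
    acc_counts = np.zeros((traj.n_frames, len(acc)))
    for f in range(traj.n_frames):
        X = traj.frames[f]
        don_counts[f] = _count(X[don_N], X[don_H], s_O)
        # surface donates: one O-H per chain, acceptors are protein O
        dDA = np.linalg.norm(s_O[:, None, :] - X[acc][None, :, :], axis=2)
        ok = dDA <= d_cutoff
        if ok.any():
            HD = s_O - s_H
            HA = X[acc][None, :, :] - s_H[:, None, :]
            cosang = np.einsum("ij,ikj->ik", HD, HA)
            cosang /= np.linalg.norm(HD, axis=1)[:, None] * np.linalg.norm(HA, axis=2)
            ok &= -cosang >= cosmin
        acc_counts[f] = ok.sum(axis=0).astype(float)

    for arr, cols, col in ((don_counts, don_N, "donor"), (acc_counts, acc, "acceptor")):
        mean = arr.mean(axis=0)
        for val, atom_idx in zip(mean, cols):
            resid = resids[atom_idx]
            out.loc[out["residue"] == resid, col] += val
    return out
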