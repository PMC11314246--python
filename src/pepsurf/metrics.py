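"""Helix/strand conformation metrics.

Implements the rational switching function used as a hydrogen-bond
collective variable, alpha/3-10 helical hydrogen-bond counts, the
beta-strand dihedral offset function, the radius of gyration and gyration
tensor shape descriptors, a simplified secondary-structure assigner, and
helical-wheel projections.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry
from .model import Topology, classify_residue
from .synthetic import Trajectory

#: beta-strand dihedral references (rad): alternating residues on opposite
#: sides of the backbone.
PHI_REF = -2.36
PSI_REF = 2.36


@dataclass(frozen=True)
class SwitchingParams:
    """Parameters of the rational switching function s(r)."""

    r0: float = 2.5  # Angstrom
    n: int = 8
    m: int = 12

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if not (self.m > self.n > 0):
            raise ValueError("require m > n > 0")


DEFAULT_SWITCHING = SwitchingParams()


def switching(r, params: SwitchingParams = DEFAULT_SWITCHING):
    """s(r) = [1 - (r/r0)^n] / [1 - (r/r0)^m], with s(r0) = n/m.

    Smoothly counts a contact: 1 at r = 0, decaying to 0 for r >> r0.  The
    removable singularity at r = r0 is evaluated as the limit n/m.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    x = r / params.r0
    num = 1.0 - x**params.n
    den = 1.0 - x**params.m
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(np.abs(den) < 1e-12, params.n / params.m, num / den)
    return s if s.shape else float(s)


def _oh_pair_distances(
    coords: np.ndarray, topology: Topology, offset: int
) -> np.ndarray:
    """|O(i) - H(i+offset)| for all valid i; (F, n_pairs)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    atoms = topology.atoms
    n_res = len(topology.residues)
    start = topology.start_index
    o_idx = {r - start: i for i, r in
             zip(atoms.index[atoms["name"] == "O"], atoms.loc[atoms["name"] == "O", "resid"])}
    h_idx = {r - start: i for i, r in
             zip(atoms.index[atoms["name"] == "H"], atoms.loc[atoms["name"] == "H", "resid"])}
    pairs = [
        (o_idx[i], h_idx[i + offset])
        for i in range(n_res - offset)
        if i in o_idx and (i + offset) in h_idx
    ]
    oi = np.array([p[0] for p in pairs], dtype=int)
    hi = np.array([p[1] for p in pairs], dtype=int)
    return np.linalg.norm(coords[:, oi] - coords[:, hi], axis=2)


def helical_hbond_counts(
    traj_or_coords,
    topology: Topology | None = None,
    params: SwitchingParams = DEFAULT_SWITCHING,
) -> pd.DataFrame:
    """Per-frame alpha (i -> i+4) and 3/10 (i -> i+3) hydrogen-bond counts.

    Each count is the sum of the switching function over all backbone
    carbonyl-O / amide-H pairs at the given sequence separation.  Pairs
    lacking an amide hydrogen (the N-terminus) are skipped.
    """
    if isinstance(traj_or_coords, Trajectory):
        coords, topology = traj_or_coords.frames, traj_or_coords.topology
    else:
        coords = traj_or_coords
        if topology is None:
            raise ValueError("topology required with raw coordinates")
    d4 = _oh_pair_distances(coords, topology, 4)
    d3 = _oh_pair_distances(coords, topology, 3)
    return pd.DataFrame(
        {
            "n_alpha": switching(d4, params).sum(axis=1),
            "n_310": switching(d3, params).sum(axis=1),
        }
    )


def dihedral_offset(phi, psi, phi_ref: float = PHI_REF, psi_ref: float = PSI_REF):
    """Strand-likeness score DH = 1/2 sum_i [(1+cos(phi_i - phi_ref)) +
    (1+cos(psi_i - psi_ref))].

    The sum runs over the N-1 interior (phi, psi) pairs of an N-residue
    chain: phi of residues 2..N and psi of residues 1..N-1, i.e. the defined
    dihedrals adjacent to each peptide bond.  NaN entries (undefined
    dihedrals) are skipped.  Range [0, 2(N-1)]; an ideal strand scores the
    maximum.
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    if phi.shape[1] < 2:
        raise ValueError("need at least 2 residues")
    tphi = 1.0 + np.cos(phi[:, 1:] - phi_ref)
    tpsi = 1.0 + np.cos(psi[:, :-1] - psi_ref)
    dh = 0.5 * (np.nansum(tphi, axis=1) + np.nansum(tpsi, axis=1))
    return dh if dh.shape[0] > 1 else float(dh[0])


@dataclass
class GyrationSummary:
    """Radius of gyration and gyration-tensor shape descriptors (Angstrom).

    Gmax >= Gmid >= Gmin are the square roots of the gyration-tensor
    eigenvalues; their squares sum to Rg^2.
    """

    rg: np.ndarray
    gmax: np.ndarray
    gmid: np.ndarray
    gmin: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rg": self.rg, "gmax": self.gmax, "gmid": self.gmid, "gmin": self.gmin}
        )


def gyration(coords, weights=None) -> GyrationSummary:
    """Radius of gyration and gyration-tensor eigenvalue roots per frame.

    Unweighted by default (each atom counts equally); pass atomic masses as
    ``weights`` for the mass-weighted variant.
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 atoms")
    if weights is None:
        w = np.ones(X.shape[1])
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    com = np.einsum("fai,a->fi", X, w)
    Y = X - com[:, None, :]
    G = np.einsum("a,fai,faj->fij", w, Y, Y)
    evals = np.linalg.eigvalsh(G)  # ascending
    evals = np.clip(evals, 0.0, None)
    g = np.sqrt(evals)
    rg = np.sqrt(evals.sum(axis=1))
    return GyrationSummary(rg=rg, gmax=g[:, 2], gmid=g[:, 1], gmin=g[:, 0])


# ---------------------------------------------------------------------------
# Simplified secondary-structure assigner
#
# This is a deliberately simple dihedral + hydrogen-bond assigner, not a
# re-implementation of STRIDE/DSSP: helix requires a switching-detected
# i -> i+4 (or i -> i+3 for 3/10) hydrogen bond covering the residue plus
# helical-basin dihedrals; strand requires near-reference dihedrals over at
# least two consecutive residues; isolated helical bonds give turns.
# ---------------------------------------------------------------------------

HELIX_BASIN = (np.deg2rad(-57.0), np.deg2rad(-47.0))
BASIN_TOL = np.deg2rad(40.0)


def _in_basin(phi, psi, ref, tol=BASIN_TOL):
    dphi = np.angle(np.exp(1j * (phi - ref[0])))
    dpsi = np.angle(np.exp(1j * (psi - ref[1])))
    return (np.abs(dphi) <= tol) & (np.abs(dpsi) <= tol)


def assign_secondary_structure(
    traj_or_coords,
    topology: Topology | None = None,
    params: SwitchingParams = DEFAULT_SWITCHING,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-residue per-frame states in {H, G, E, T, C} plus propensities.

    H: covered by an i -> i+4 hydrogen bond (switching > 0.5) with
    helical-basin dihedrals, in a run of >= 2 residues.  G: same with an
    i -> i+3 bond.  E: dihedrals within 40 degrees of the strand references
    for >= 2 consecutive residues.  T: covered by an isolated helical bond.
    C: otherwise.
    """
    if isinstance(traj_or_coords, Trajectory):
        coords, topology = traj_or_coords.frames, traj_or_coords.topology
    else:
        coords = traj_or_coords
        if topology is None:
            raise ValueError("topology required with raw coordinates")
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    F = coords.shape[0]
    n_res = len(topology.residues)
    n_idx = topology.atom_indices("N")
    ca_idx = topology.atom_indices("CA")
    c_idx = topology.atom_indices("C")
    phi, psi = geometry.measure_phi_psi(coords, n_idx, ca_idx, c_idx)

    s4 = switching(_oh_pair_distances(coords, topology, 4), params)  # (F, n-4), pair i starts at residue i (i>=1 via H)
    s3 = switching(_oh_pair_distances(coords, topology, 3), params)

    # which residues each bond covers: pair distances exist for O(i), H(i+off)
    # with i + off >= 1; given H exists for residues 1.., pair k corresponds
    # to acceptor residue index determined below.
    start = topology.start_index
    atoms = topology.atoms
    o_res = (atoms.loc[atoms["name"] == "O", "resid"].to_numpy() - start)
    h_res = (atoms.loc[atoms["name"] == "H", "resid"].to_numpy() - start)

    def bond_cover(s, offset):
        """Boolean (F, n_res): residue covered by a bond with s > 0.5."""
        cov = np.zeros((F, n_res), dtype=bool)
        pairs = [i for i in o_res if (i + offset) in set(h_res) and i + offset < n_res]
        for k, i in enumerate(pairs):
            hit = s[:, k] > 0.5
            cov[hit, i : i + offset + 1] = True
        return cov

    cov4 = bond_cover(s4, 4)
    cov3 = bond_cover(s3, 3)

    helical_basin = _in_basin(phi, psi, HELIX_BASIN)
    # termini lack one dihedral; let the defined one decide
    helical_basin[:, 0] = np.abs(np.angle(np.exp(1j * (psi[:, 0] - HELIX_BASIN[1])))) <= BASIN_TOL
    helical_basin[:, -1] = np.abs(np.angle(np.exp(1j * (phi[:, -1] - HELIX_BASIN[0])))) <= BASIN_TOL
    strand_basin = _in_basin(phi, psi, (PHI_REF, PSI_REF))
    strand_basin[:, 0] = False
    strand_basin[:, -1] = False

    h_cand = cov4 & helical_basin
    g_cand = cov3 & helical_basin & ~h_cand

    def runs_ge2(mask):
        left = np.zeros_like(mask)
        left[:, 1:] = mask[:, :-1]
        right = np.zeros_like(mask)
        right[:, :-1] = mask[:, 1:]
        return mask & (left | right)

    states = np.full((F, n_res), "C", dtype="U1")
    e_mask = runs_ge2(strand_basin)
    states[e_mask] = "E"
    t_mask = (cov4 | cov3) & ~runs_ge2(h_cand) & ~runs_ge2(g_cand)
    states[t_mask] = "T"
    states[runs_ge2(g_cand)] = "G"
    states[runs_ge2(h_cand)] = "H"

    authors = np.array([r.author_index for r in topology.residues])
    prop = pd.DataFrame({"residue": authors,
                         "code": [r.code for r in topology.residues]})
    for code in "HGETC":
        prop[code] = (states == code).mean(axis=0)
    prop["helix"] = prop["H"] + prop["G"]
    return states, prop


def helical_wheel(sequence: str, start_index: int = 0) -> pd.DataFrame:
    """Helical-wheel projection: 100 degrees per residue.

    Returns one row per residue with its wheel angle, class, and whether it
    belongs to the hydrophobic face (hydrophobic residues within 90 degrees
    of the hydrophobic moment direction).  The moment direction is stored in
    ``df.attrs['moment_deg']``.
    """
    if not sequence:
        raise ValueError("empty segment")
    angles = (100.0 * np.arange(len(sequence))) % 360.0
    klass = [classify_residue(c) for c in sequence]
    hydro = np.array([k == "hydrophobic" for k in klass])
    df = pd.DataFrame(
        {
            "residue": start_index + np.arange(len(sequence)),
            "code": list(sequence),
            "angle": angles,
            "klass": klass,
        }
    )
    if hydro.any():
        rad = np.deg2rad(angles[hydro])
        vec = np.array([np.cos(rad).sum(), np.sin(rad).sum()])
        moment = np.rad2deg(np.arctan2(vec[1], vec[0])) % 360.0
        delta = np.abs(np.angle(np.exp(1j * np.deg2rad(angles - moment))))
        df["hydrophobic_face"] = hydro & (delta <= np.pi / 2)
        df.attrs["moment_deg"] = float(moment)
    else:
        df["hydrophobic_face"] = False
        df.attrs["moment_deg"] = np.nan
    return df


def metrics_table(traj: Trajectory) -> pd.DataFrame:
    """Per-frame metric table: hydrogen-bond counts, DH, Rg and shape."""
    hb = helical_hbond_counts(traj)
    n_idx = traj.topology.atom_indices("N")
    ca_idx = traj.topology.atom_indices("CA")
    c_idx = traj.topology.atom_indices("C")
    phi, psi = geometry.measure_phi_psi(traj.frames, n_idx, ca_idx, c_idx)
    dh = dihedral_offset(phi, psi)
    gyr = gyration(traj.frames).to_frame()
    out = pd.concat([hb, gyr], axis=1)
    out.insert(2, "dh", np.atleast_1d(dh))
    out.insert(0, "frame", np.arange(traj.n_frames))
    return out
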