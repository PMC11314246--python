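"""Single-trajectory MM-PBSA adsorption energetics.

The adsorption free energy is estimated end-point style from a single
complex trajectory:

    dG_ads = G(complex) - G(protein) - G(surface)
    G = EMM + GPB + GSA,   EMM = Eint + Evdw + Eelec,   GSA = gamma * SASA

Because protein and surface coordinates are taken from the same frames, the
internal (bonded) terms cancel identically and dEMM reduces to the
inter-group van der Waals + electrostatic energy.  The polar term GPB is a
pluggable backend (default zero); conformational entropy is neglected.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .synthetic import Trajectory

COULOMB_KCAL = 332.06  # kcal A / (mol e^2)
GAMMA_DEFAULT = 0.005  # kcal / (mol A^2), nonpolar surface tension
PROBE_RADIUS = 1.4  # Angstrom, water probe

#: Bondi-type van der Waals radii (Angstrom); the pseudo-sidechain bead is
#: looked up by atom name instead and given a larger radius.
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
PSEUDO_SIDECHAIN_RADIUS = 2.00


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = PROBE_RADIUS,
    n_points: int = 960,
) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom's expanded sphere (radius + probe) is sampled with a
    deterministic point set; points buried inside any neighbour's expanded
    sphere are occluded.  Returns (total, per-atom) areas in A^2.
    """
    if n_points < 92:
        raise ValueError("n_points < 92 gives unacceptable accuracy")
    X = np.asarray(coords, dtype=float)
    r = np.asarray(radii, dtype=float) + probe
    if np.any(r <= probe):
        raise ValueError("radii must be positive")
    n = len(X)
    pts = sphere_points(n_points)
    tree = cKDTree(X)
    pairs = tree.query_ball_point(X, r + r.max())
    areas = np.empty(n)
    for i in range(n):
        neigh = [j for j in pairs[i] if j != i and np.linalg.norm(X[j] - X[i]) < r[i] + r[j]]
        surface = X[i] + r[i] * pts
        if neigh:
            nb = np.array(neigh)
            d2 = np.sum((surface[:, None, :] - X[nb][None, :, :]) ** 2, axis=2)
            buried = (d2 < (r[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * r[i] ** 2
    return float(areas.sum()), areas


def nonpolar_solvation(sasa: float, gamma: float = GAMMA_DEFAULT) -> float:
    """GSA = gamma * SASA (kcal/mol)."""
    if sasa < 0:
        raise ValueError("sasa must be non-negative")
    return gamma * sasa


def mm_energy(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    charges_a: np.ndarray,
    charges_b: np.ndarray,
    sigma_a: np.ndarray,
    sigma_b: np.ndarray,
    eps_a: np.ndarray,
    eps_b: np.ndarray,
) -> tuple[float, float]:
    """Inter-group (Evdw, Eelec) in kcal/mol: 12-6 Lennard-Jones with
    Lorentz-Berthelot combining plus Coulomb, no cutoff."""
    for arr, name in ((sigma_a, "sigma"), (eps_a, "epsilon")):
        if np.any(~np.isfinite(arr)):
            raise ValueError(f"missing {name} parameters in group A")
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
    if np.any(d <= 0):
        raise ValueError("coincident atoms between groups")
    sig = 0.5 * (np.asarray(sigma_a)[:, None] + np.asarray(sigma_b)[None, :])
    eps = np.sqrt(np.asarray(eps_a)[:, None] * np.asarray(eps_b)[None, :])
    sr6 = (sig / d) ** 6
    evdw = float(np.sum(4.0 * eps * (sr6**2 - sr6)))
    eelec = float(
        COULOMB_KCAL * np.sum(np.asarray(charges_a)[:, None] * np.asarray(charges_b)[None, :] / d)
    )
    return evdw, eelec


@dataclass
class MMPBSATerms:
    """One end-point free-energy evaluation (kcal/mol)."""

    eint: float
    evdw: float
    eelec: float
    gsa: float
    gpb: float

    @property
    def emm(self) -> float:
        return self.eint + self.evdw + self.eelec

    @property
    def g(self) -> float:
        return self.emm + self.gpb + self.gsa


@dataclass
class AdsorptionEnergy:
    """Frame-wise adsorption free energy decomposition and summary."""

    dg_ads: np.ndarray
    demm: np.ndarray
    dgsolv: np.ndarray
    devdw: np.ndarray
    deelec: np.ndarray
    dgsa: np.ndarray
    dgpb: np.ndarray

    def summary(self) -> pd.DataFrame:
        """Mean +- standard error of the mean, in the layout of an
        adsorption-energetics report table."""
        rows = []
        for name, arr in (
            ("dG_ads", self.dg_ads),
            ("dE_MM", self.demm),
            ("dG_solv", self.dgsolv),
            ("dE_vdw", self.devdw),
            ("dE_elec", self.deelec),
            ("dG_SA", self.dgsa),
            ("dG_PB", self.dgpb),
        ):
            n = len(arr)
            rows.append(
                dict(
                    term=name,
                    mean=float(np.mean(arr)),
                    sem=float(np.std(arr, ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                )
            )
        return pd.DataFrame(rows)


def coulomb_field_polar(eps_in: float = 1.0, eps_out: float = 80.0, scale: float = 0.1):
    """Crude Born-style polar solvation backend.

    Screens each group's self-interaction Coulomb energy by the dielectric
    contrast; a rough stand-in exposing the dielectric constants of a full
    Poisson-Boltzmann treatment.  Returns a callable suitable as
    ``polar_backend``.
    """

    def backend(coords: np.ndarray, charges: np.ndarray, radii: np.ndarray) -> float:
        X = np.asarray(coords, dtype=float)
        q = np.asarray(charges, dtype=float)
        r = np.asarray(radii, dtype=float)
        factor = -(1.0 / eps_in - 1.0 / eps_out)
        self_term = 0.5 * COULOMB_KCAL * factor * np.sum(q * q / r)
        if len(X) > 1:
            d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
            iu = np.triu_indices(len(X), 1)
            cross = COULOMB_KCAL * factor * np.sum(q[iu[0]] * q[iu[1]] / d[iu]) * scale
        else:
            cross = 0.0
        return float(self_term + cross)

    return backend


def _protein_params(traj: Trajectory):
    atoms = traj.topology.atoms
    radii = np.array(
        [
            PSEUDO_SIDECHAIN_RADIUS if name == "CB" else VDW_RADII[el]
            for name, el in zip(atoms["name"], atoms["element"])
        ]
    )
    return (
        atoms["charge"].to_numpy(),
        atoms["sigma"].to_numpy(),
        atoms["epsilon"].to_numpy(),
        radii,
    )


def adsorption_free_energy(
    traj: Trajectory,
    polar_backend=None,
    gamma: float = GAMMA_DEFAULT,
    n_points: int = 960,
    stride: int = 1,
) -> AdsorptionEnergy:
    """Single-trajectory MM-PBSA adsorption free energy.

    For each (strided) frame, complex / protein / surface terms are
    evaluated on the same coordinates, so internal energies cancel exactly:
    dEMM is the inter-group LJ + Coulomb energy and dG_SA comes from the
    SASA lost on contact.  ``polar_backend(coords, charges, radii) -> float``
    supplies GPB per group (default: zero).
    """
    if traj.surface is None:
        raise ValueError("adsorption energetics requires protein and surface groups")
    surf = traj.surface.atom_table()
    s_xyz = surf[["x", "y", "z"]].to_numpy()
    s_q = surf["charge"].to_numpy()
    s_sig = surf["sigma"].to_numpy()
    s_eps = surf["epsilon"].to_numpy()
    s_rad = np.array([VDW_RADII[el] for el in surf["element"]])
    p_q, p_sig, p_eps, p_rad = _protein_params(traj)

    sasa_surf, _ = shrake_rupley_sasa(s_xyz, s_rad, n_points=n_points)
    gpb_surf = polar_backend(s_xyz, s_q, s_rad) if polar_backend else 0.0

    frames = traj.frames[::stride]
    F = len(frames)
    devdw = np.empty(F)
    deelec = np.empty(F)
    dgsa = np.empty(F)
    dgpb = np.empty(F)
    all_rad = np.concatenate([p_rad, s_rad])
    all_q = np.concatenate([p_q, s_q])
    for f, X in enumerate(frames):
        evdw, eelec = mm_energy(X, s_xyz, p_q, s_q, p_sig, s_sig, p_eps, s_eps)
        devdw[f] = evdw
        deelec[f] = eelec
        complex_xyz = np.concatenate([X, s_xyz])
        sasa_cx, _ = shrake_rupley_sasa(complex_xyz, all_rad, n_points=n_points)
        sasa_p, _ = shrake_rupley_sasa(X, p_rad, n_points=n_points)
        dgsa[f] = gamma * (sasa_cx - sasa_p - sasa_surf)
        if polar_backend:
            gpb_cx = polar_backend(complex_xyz, all_q, all_rad)
            gpb_p = polar_backend(X, p_q, p_rad)
            dgpb[f] = gpb_cx - gpb_p - gpb_surf
        else:
            dgpb[f] = 0.0
    demm = devdw + deelec  # dEint = 0 identically (single-trajectory)
    dgsolv = dgpb + dgsa
    return AdsorptionEnergy(
        dg_ads=demm + dgsolv,
        demm=demm,
        dgsolv=dgsolv,
        devdw=devdw,
        deelec=deelec,
        dgsa=dgsa,
        dgpb=dgpb,
    )
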