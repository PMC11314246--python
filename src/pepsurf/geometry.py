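"""Internal-coordinate backbone construction and dihedral measurement.

Chains are built by sequential NeRF (natural extension reference frame)
placement with standard peptide bond lengths and angles, so the (phi, psi)
dihedrals measured on the output reproduce the inputs to machine precision.
All placement routines are batched: coordinates carry a leading frame axis.
"""
from __future__ import annotations

import numpy as np

# Standard backbone internal coordinates (Angstrom / radians).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010
# Pseudo-sidechain bead placed along the CA->CB direction at roughly the
# sidechain heavy-atom centroid distance.
BOND_CA_CB = 2.40

ANG_N_CA_C = np.deg2rad(111.2)
ANG_CA_C_N = np.deg2rad(116.2)
ANG_C_N_CA = np.deg2rad(121.7)
ANG_CA_C_O = np.deg2rad(120.8)
ANG_C_N_H = np.deg2rad(119.0)
ANG_N_CA_CB = np.deg2rad(110.5)
DIH_CB = np.deg2rad(-122.0)  # about the N-CA axis, referenced to C

OMEGA_TRANS = np.pi


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def place_atom(a, b, c, bond: float, angle: float, dihedral) -> np.ndarray:
    """Place atom D bonded to C with |CD| = bond, angle(B,C,D) = angle and
    dihedral(A,B,C,D) = dihedral.  Inputs broadcast over leading axes."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    dihedral = np.asarray(dihedral, dtype=float)[..., None]
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = (
        -np.cos(angle) * bc
        + np.sin(angle) * np.cos(dihedral) * m
        - np.sin(angle) * np.sin(dihedral) * n
    )
    return c + bond * d


def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsion angle in (-pi, pi] for the path p0-p1-p2-p3."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    c1 = np.cross(b0, b1)
    c2 = np.cross(b1, b2)
    x = np.sum(c1 * c2, axis=-1)
    y = np.sum(np.cross(c1, _unit(b1)) * c2, axis=-1)
    return np.arctan2(y, x)


def build_backbone(sequence: str, phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Build full-atom backbones for a batch of frames.

    Parameters
    ----------
    sequence : one-letter amino-acid string, length N
    phi, psi : arrays of shape (F, N) in radians; ``phi[:, 0]`` and
        ``psi[:, -1]``'s downstream peptide bond are unused except that
        ``psi[:, -1]`` orients the final carbonyl oxygen.

    Returns
    -------
    coords : (F, A, 3) array in the atom order produced by
        :func:`backbone_atom_order` -- per residue N, [H], CA, [CB], C, O
        (no amide H on the first residue, no CB bead on glycine).
    """
    if len(sequence) == 0:
        raise ValueError("sequence must be non-empty")
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    n_res = len(sequence)
    if phi.shape[1] != n_res or psi.shape[1] != n_res:
        raise ValueError("phi/psi shape must be (F, len(sequence))")
    if not (np.all(np.isfinite(phi)) and np.all(np.isfinite(psi))):
        raise ValueError("dihedral angles must be finite")
    n_frames = phi.shape[0]

    N = np.empty((n_frames, n_res, 3))
    CA = np.empty_like(N)
    C = np.empty_like(N)
    O = np.empty_like(N)
    H = np.full((n_frames, n_res, 3), np.nan)
    CB = np.full((n_frames, n_res, 3), np.nan)

    N[:, 0] = 0.0
    CA[:, 0] = [BOND_N_CA, 0.0, 0.0]
    C[:, 0] = CA[:, 0] + BOND_CA_C * np.array(
        [-np.cos(ANG_N_CA_C), np.sin(ANG_N_CA_C), 0.0]
    )
    for i in range(n_res):
        O[:, i] = place_atom(
            N[:, i], CA[:, i], C[:, i], BOND_C_O, ANG_CA_C_O, psi[:, i] + np.pi
        )
        if sequence[i] != "G":
            CB[:, i] = place_atom(
                C[:, i], N[:, i], CA[:, i], BOND_CA_CB, ANG_N_CA_CB, DIH_CB
            )
        if i < n_res - 1:
            N[:, i + 1] = place_atom(
                N[:, i], CA[:, i], C[:, i], BOND_C_N, ANG_CA_C_N, psi[:, i]
            )
            H[:, i + 1] = place_atom(
                O[:, i], C[:, i], N[:, i + 1], BOND_N_H, ANG_C_N_H, np.pi
            )
            CA[:, i + 1] = place_atom(
                CA[:, i], C[:, i], N[:, i + 1], BOND_N_CA, ANG_C_N_CA, OMEGA_TRANS
            )
            C[:, i + 1] = place_atom(
                C[:, i], N[:, i + 1], CA[:, i + 1], BOND_CA_C, ANG_N_CA_C,
                phi[:, i + 1],
            )

    coords = []
    for i, code in enumerate(sequence):
        coords.append(N[:, i])
        if i > 0:
            coords.append(H[:, i])
        coords.append(CA[:, i])
        if code != "G":
            coords.append(CB[:, i])
        coords.append(C[:, i])
        coords.append(O[:, i])
    return np.stack(coords, axis=1)


def backbone_atom_order(sequence: str) -> list[tuple[int, str]]:
    """(residue position, atom name) pairs matching :func:`build_backbone`."""
    order = []
    for i, code in enumerate(sequence):
        order.append((i, "N"))
        if i > 0:
            order.append((i, "H"))
        order.append((i, "CA"))
        if code != "G":
            order.append((i, "CB"))
        order.append((i, "C"))
        order.append((i, "O"))
    return order


def measure_phi_psi(
    coords: np.ndarray, n_idx, ca_idx, c_idx
) -> tuple[np.ndarray, np.ndarray]:
    """Measure backbone (phi, psi) for frames ``coords`` of shape (F, A, 3).

    ``n_idx``, ``ca_idx``, ``c_idx`` are the per-residue atom indices.  phi of
    the first residue and psi of the last are NaN (undefined at the termini).
    """
    coords = np.asarray(coords, dtype=float)
    squeeze = coords.ndim == 2
    if squeeze:
        coords = coords[None]
    n_res = len(n_idx)
    F = coords.shape[0]
    phi = np.full((F, n_res), np.nan)
    psi = np.full((F, n_res), np.nan)
    Nc = coords[:, n_idx]
    CAc = coords[:, ca_idx]
    Cc = coords[:, c_idx]
    phi[:, 1:] = dihedral_angle(Cc[:, :-1], Nc[:, 1:], CAc[:, 1:], Cc[:, 1:])
    psi[:, :-1] = dihedral_angle(Nc[:, :-1], CAc[:, :-1], Cc[:, :-1], Nc[:, 1:])
    if squeeze:
        return phi[0], psi[0]
    return phi, psi
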