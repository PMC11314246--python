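"""Peptide sequence, residue classification, topology, and SAM surface model.

The peptide studied throughout is the 31-residue amyloid-beta fragment
Abeta(10-40), indexed by author convention 10..40.  The surface is an
alkanethiol self-assembled monolayer (SAM) reduced to its anchor lattice and
terminal heavy atoms; the surface reference plane z0 is the mean z of the
terminal heavy atoms.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Abeta(10-40): residues 10..40 of the amyloid-beta peptide.
ABETA_10_40 = "YEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV"
ABETA_START_INDEX = 10

# Four-way residue classification (hydrophobic / polar / charged +-).
# Ala is treated as hydrophobic, Gly as polar; His is polar (neutral at pH 7).
CLASSIFICATION: dict[str, str] = {
    **{c: "hydrophobic" for c in "AVLIMFWCP"},
    **{c: "polar" for c in "GSTNQYH"},
    **{c: "negative" for c in "DE"},
    **{c: "positive" for c in "KR"},
}

# Approximate sidechain masses (amu) carried by the pseudo-sidechain bead.
SIDECHAIN_MASS: dict[str, float] = {
    "G": 1.008, "A": 15.03, "V": 43.09, "L": 57.12, "I": 57.12, "M": 75.15,
    "F": 91.13, "Y": 107.13, "W": 130.17, "C": 47.10, "P": 41.07, "S": 31.03,
    "T": 45.06, "N": 58.06, "Q": 72.09, "D": 59.04, "E": 73.07, "K": 72.13,
    "R": 100.14, "H": 81.10,
}

ATOM_MASS = {"N": 14.007, "C": 12.011, "O": 15.999, "H": 1.008, "S": 32.06}

# Nominal backbone partial charges (e); they sum to zero per residue so the
# chain's net charge comes from charged sidechains and the termini.
_BB_CHARGE = {"N": -0.47, "H": 0.31, "CA": 0.16, "C": 0.51, "O": -0.51}
_SIDECHAIN_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}

# Nominal LJ parameters (sigma Angstrom, epsilon kcal/mol) by atom role.
_LJ = {
    "N": (3.30, 0.17),
    "H": (1.00, 0.03),
    "CA": (3.60, 0.07),
    "C": (3.60, 0.07),
    "O": (3.00, 0.21),
    "CB": (4.50, 0.20),
}


def classify_residue(code: str) -> str:
    """Map a one-letter amino-acid code to one of
    ``{hydrophobic, polar, negative, positive}``."""
    try:
        return CLASSIFICATION[code.upper()]
    except KeyError:
        raise ValueError(f"unknown amino-acid code: {code!r}") from None


@dataclass(frozen=True)
class Residue:
    author_index: int
    code: str
    klass: str = field(default="")

    def __post_init__(self):
        if not self.klass:
            object.__setattr__(self, "klass", classify_residue(self.code))

    @property
    def label(self) -> str:
        return f"{self.code}{self.author_index}"


@dataclass
class Topology:
    """Ordered residues plus a flat atom table.

    ``atoms`` columns: name, element, resid (author index), role
    (backbone/sidechain), donor, acceptor, charge (e), sigma (A),
    epsilon (kcal/mol), mass (amu).
    """

    residues: list[Residue]
    atoms: pd.DataFrame

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def sequence(self) -> str:
        return "".join(r.code for r in self.residues)

    @property
    def start_index(self) -> int:
        return self.residues[0].author_index

    def atom_indices(self, name: str) -> np.ndarray:
        """Atom indices of ``name`` ordered by residue (may skip residues)."""
        return self.atoms.index[self.atoms["name"] == name].to_numpy()

    def heavy_mask(self) -> np.ndarray:
        return (self.atoms["element"] != "H").to_numpy()

    def residue_of_atom(self) -> np.ndarray:
        return self.atoms["resid"].to_numpy()

    def backbone_indices(self) -> np.ndarray:
        """Indices of N, CA, C, O -- the default RMSD selection."""
        return self.atoms.index[
            self.atoms["name"].isin(["N", "CA", "C", "O"])
        ].to_numpy()

    def to_tsv(self, path) -> None:
        self.atoms.to_csv(path, sep="\t", index_label="atom")

    def masses(self) -> np.ndarray:
        return self.atoms["mass"].to_numpy()


def build_sequence() -> str:
    """The Abeta(10-40) one-letter sequence (31 residues, indices 10..40)."""
    return ABETA_10_40


def build_topology(sequence: str | None = None, start_index: int = ABETA_START_INDEX) -> Topology:
    """Full-atom reduced topology: backbone N,[H],CA,[CB],C,O per residue.

    The first residue carries a protonated N-terminus (+1 on N) and the last
    a deprotonated C-terminus (-1 on O); Asp/Glu/Lys/Arg sidechain beads carry
    their formal charge, as appropriate at pH 7.
    """
    if sequence is None:
        sequence = build_sequence()
    if not sequence:
        raise ValueError("sequence must be non-empty")
    residues = [
        Residue(start_index + i, code) for i, code in enumerate(sequence)
    ]
    rows = []
    last = len(sequence) - 1
    for i, code in enumerate(sequence):
        resid = start_index + i
        names = ["N"] + (["H"] if i > 0 else []) + ["CA"]
        if code != "G":
            names.append("CB")
        names += ["C", "O"]
        for name in names:
            element = "H" if name == "H" else ("N" if name == "N" else
                                               "O" if name == "O" else "C")
            role = "sidechain" if name == "CB" else "backbone"
            charge = _BB_CHARGE.get(name, 0.0)
            if name == "CB":
                charge = _SIDECHAIN_CHARGE.get(code, 0.0)
            if name == "N" and i == 0:
                # protonated N-terminus; absorbs the absent amide-H charge so
                # the chain's net charge stays at the formal -1
                charge += 1.0 + _BB_CHARGE["H"]
            if name == "O" and i == last:
                charge -= 1.0
            sigma, eps = _LJ[name]
            mass = SIDECHAIN_MASS[code] if name == "CB" else ATOM_MASS[element]
            rows.append(
                dict(
                    name=name, element=element, resid=resid, role=role,
                    donor=(name == "N" and i > 0), acceptor=(name == "O"),
                    charge=charge, sigma=sigma, epsilon=eps, mass=mass,
                )
            )
    return Topology(residues=residues, atoms=pd.DataFrame(rows))


@dataclass
class SurfaceModel:
    """Planar SAM surface: hexagonal anchor lattice plus terminal heavy atoms.

    ``ligand`` is ``"CH3"`` (hydrophobic, methyl-terminated) or ``"OH"``
    (polar, hydroxyl-terminated).  ``z0`` is the reference plane height: the
    arithmetic mean of the terminal heavy-atom z values.
    """

    ligand: str
    chain_positions: np.ndarray  # (n, 2) anchor xy, Angstrom
    terminal_atom_z: np.ndarray  # (n,) terminal heavy-atom z, Angstrom
    lattice_constant: float

    def __post_init__(self):
        if self.ligand not in ("CH3", "OH"):
            raise ValueError("ligand must be 'CH3' or 'OH'")
        self.chain_positions = np.asarray(self.chain_positions, dtype=float)
        self.terminal_atom_z = np.asarray(self.terminal_atom_z, dtype=float)
        if len(self.chain_positions) != len(self.terminal_atom_z):
            raise ValueError("one terminal atom per chain required")

    @property
    def n_chains(self) -> int:
        return len(self.chain_positions)

    @property
    def z0(self) -> float:
        return float(np.mean(self.terminal_atom_z))

    def atom_table(self) -> pd.DataFrame:
        """Explicit atoms for energetics / hydrogen bonding.

        CH3: one united-atom methyl carbon per chain (neutral).  OH: oxygen
        (q = -0.40) plus hydroxyl hydrogen (q = +0.40) 0.96 A above it.
        """
        xy = self.chain_positions
        z = self.terminal_atom_z
        rows = []
        for i in range(self.n_chains):
            if self.ligand == "CH3":
                rows.append(dict(name="CT", element="C", chain=i,
                                 x=xy[i, 0], y=xy[i, 1], z=z[i],
                                 donor=False, acceptor=False,
                                 charge=0.0, sigma=3.90, epsilon=0.12,
                                 mass=15.03))
            else:
                rows.append(dict(name="OT", element="O", chain=i,
                                 x=xy[i, 0], y=xy[i, 1], z=z[i],
                                 donor=True, acceptor=True,
                                 charge=-0.40, sigma=3.12, epsilon=0.17,
                                 mass=15.999))
                rows.append(dict(name="HT", element="H", chain=i,
                                 x=xy[i, 0], y=xy[i, 1], z=z[i] + 0.96,
                                 donor=False, acceptor=False,
                                 charge=0.40, sigma=1.00, epsilon=0.03,
                                 mass=1.008))
        return pd.DataFrame(rows)

    def coordinates(self) -> np.ndarray:
        tab = self.atom_table()
        return tab[["x", "y", "z"]].to_numpy()


def build_sam_surface(
    nx: int,
    ny: int,
    ligand: str = "CH3",
    lattice_constant: float = 4.97,
    chain_height: float = 10.0,
) -> SurfaceModel:
    """Hexagonal (root3 x root3 R30-type) lattice of nx*ny SAM chains.

    The default lattice constant 4.97 A is the standard alkanethiol spacing
    on Au(111).  Chains are reduced to an anchor point at z = 0 and a
    terminal heavy atom at ``chain_height``; ligand internal structure is not
    modelled.
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    a = float(lattice_constant)
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    x = ii * a + (jj % 2) * (a / 2.0)
    y = jj * (a * np.sqrt(3.0) / 2.0)
    anchors = np.stack([x.ravel(), y.ravel()], axis=1)
    terminal_z = np.full(len(anchors), float(chain_height))
    return SurfaceModel(
        ligand=ligand,
        chain_positions=anchors,
        terminal_atom_z=terminal_z,
        lattice_constant=a,
    )
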