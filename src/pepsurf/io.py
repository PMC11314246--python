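"""File I/O: FASTA, multi-model PDB, extended XYZ, and annotated TSV tables."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from . import __version__
from .model import SurfaceModel, Topology


def write_fasta(sequence: str, path, name: str = "peptide", description: str = "") -> None:
    record = SeqRecord(Seq(sequence), id=name, description=description)
    SeqIO.write([record], str(path), "fasta")


def read_fasta(path) -> str:
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq)


def _atom_array_stack(coords: np.ndarray, topology: Topology) -> struc.AtomArrayStack:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_frames, n_atoms, _ = coords.shape
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = coords.astype(np.float32)
    atoms = topology.atoms
    code3 = {r.author_index: _THREE[r.code] for r in topology.residues}
    stack.chain_id = np.full(n_atoms, "A")
    stack.res_id = atoms["resid"].to_numpy()
    stack.res_name = np.array([code3[r] for r in atoms["resid"]])
    stack.atom_name = atoms["name"].to_numpy(dtype="U4")
    stack.element = atoms["element"].to_numpy(dtype="U2")
    stack.hetero = np.zeros(n_atoms, dtype=bool)
    return stack


_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def write_pdb(coords: np.ndarray, topology: Topology, path) -> None:
    """Write frames as a multi-model PDB."""
    pdb = PDBFile()
    pdb.set_structure(_atom_array_stack(coords, topology))
    pdb.write(str(path))


def read_pdb(path) -> np.ndarray:
    """Read a multi-model PDB back into a (F, A, 3) coordinate array."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    return np.asarray(stack.coord, dtype=float)


def write_surface_pdb(surface: SurfaceModel, path) -> None:
    tab = surface.atom_table()
    n = len(tab)
    arr = struc.AtomArray(n)
    arr.coord = tab[["x", "y", "z"]].to_numpy(dtype=np.float32)
    arr.chain_id = np.full(n, "S")
    arr.res_id = tab["chain"].to_numpy() + 1
    arr.res_name = np.full(n, "SAM")
    arr.atom_name = tab["name"].to_numpy(dtype="U4")
    arr.element = tab["element"].to_numpy(dtype="U2")
    arr.hetero = np.ones(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def write_xyz(coords: np.ndarray, elements, path, comment: str = "") -> None:
    """Write frames as extended XYZ (one block per frame)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    with open(path, "w") as fh:
        for f, frame in enumerate(coords):
            fh.write(f"{len(frame)}\n")
            fh.write(f'Properties=species:S:1:pos:R:3 frame={f} {comment}\n')
            for el, (x, y, z) in zip(elements, frame):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> tuple[np.ndarray, list[str]]:
    frames = []
    elements: list[str] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i])
        block = lines[i + 2 : i + 2 + n]
        parts = [ln.split() for ln in block]
        if not frames:
            elements = [p[0] for p in parts]
        frames.append([[float(p[1]), float(p[2]), float(p[3])] for p in parts])
        i += 2 + n
    return np.asarray(frames, dtype=float), elements


def write_table(df: pd.DataFrame, path, params: dict | None = None, index: bool = False) -> None:
    """Write a TSV with a provenance header recording version and parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# pepsurf {__version__}\n")
        if params:
            fh.write(f"# params: {json.dumps(params, sort_keys=True, default=str)}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
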