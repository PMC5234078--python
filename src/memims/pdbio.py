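"""Minimal PDB reading/writing for single- and multi-MODEL coordinate files.

Only the fixed-column fields needed downstream are handled: ATOM/HETATM
records (name, resname, chain, resid, xyz, element), MODEL/ENDMDL frame
boundaries and the CRYST1 box.  Element symbols fall back to the atom
name when columns 77-78 are blank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PDBModel", "read_pdb", "write_pdb"]

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "MSE",
}


@dataclass
class PDBModel:
    """One MODEL's atoms as parallel arrays."""

    atom_names: list[str]
    resnames: list[str]
    chains: list[str]
    resids: np.ndarray
    coords: np.ndarray
    elements: list[str]
    box: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def protein_mask(self) -> np.ndarray:
        return np.array([rn in _STANDARD_AA for rn in self.resnames])


def _element_from_name(name: str) -> str:
    s = name.strip()
    while s and s[0].isdigit():
        s = s[1:]
    if not s:
        return "C"
    if len(s) >= 2 and s[:2].capitalize() in ("Cl", "Br", "Na", "Mg", "Fe", "Zn"):
        return s[:2].capitalize()
    return s[0].upper()


def read_pdb(path: str | Path) -> list[PDBModel]:
    """Parse a PDB file into a list of models (one for a single-MODEL file)."""
    models: list[PDBModel] = []
    box = None
    cur: dict | None = None

    def new():
        return {"atom_names": [], "resnames": [], "chains": [],
                "resids": [], "coords": [], "elements": []}

    def flush(d):
        if d and d["atom_names"]:
            models.append(PDBModel(
                atom_names=d["atom_names"], resnames=d["resnames"],
                chains=d["chains"],
                resids=np.array(d["resids"], dtype=int),
                coords=np.array(d["coords"], dtype=float),
                elements=d["elements"], box=box,
            ))

    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "CRYST1":
                box = np.array([float(line[6:15]), float(line[15:24]),
                                float(line[24:33])])
            elif rec == "MODEL ":
                flush(cur)
                cur = new()
            elif rec in ("ATOM  ", "HETATM"):
                if cur is None:
                    cur = new()
                name = line[12:16].strip()
                cur["atom_names"].append(name)
                cur["resnames"].append(line[17:21].strip())
                cur["chains"].append(line[21].strip() or "A")
                try:
                    cur["resids"].append(int(line[22:26]))
                except ValueError:
                    cur["resids"].append(0)
                cur["coords"].append(
                    (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                )
                elem = line[76:78].strip() if len(line) >= 78 else ""
                cur["elements"].append(elem.capitalize() or _element_from_name(name))
            elif rec == "ENDMDL":
                flush(cur)
                cur = None
    flush(cur)
    # propagate box parsed anywhere in the file
    for m in models:
        if m.box is None:
            m.box = box
    return models


def write_pdb(models: list[PDBModel] | PDBModel, path: str | Path) -> None:
    """Write one or more models; multiple models get MODEL/ENDMDL framing."""
    if isinstance(models, PDBModel):
        models = [models]
    multi = len(models) > 1
    with open(path, "w") as fh:
        m0 = models[0]
        if m0.box is not None:
            fh.write(
                f"CRYST1{m0.box[0]:9.3f}{m0.box[1]:9.3f}{m0.box[2]:9.3f}"
                f"  90.00  90.00  90.00 P 1           1\n"
            )
        for imod, m in enumerate(models, start=1):
            if multi:
                fh.write(f"MODEL     {imod:4d}\n")
            for i in range(m.n_atoms):
                name = m.atom_names[i]
                pad = f" {name:<3s}" if len(name) < 4 else name[:4]
                x, y, z = m.coords[i]
                fh.write(
                    f"ATOM  {min(i + 1, 99999):5d} {pad} {m.resnames[i][:4]:<4s}"
                    f"{m.chains[i][:1]}{int(m.resids[i]) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {m.elements[i][:2]:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
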