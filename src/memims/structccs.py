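"""Monte-Carlo projection-approximation collision cross-sections.

The CCS is estimated as the orientation-averaged shadow area of a
hard-sphere atom model: for each uniformly random orientation the
structure is projected onto a plane and the projected area is measured
by hit/miss sampling of probe centers against atom disks of radius
(r_vdw + r_probe).  The result is multiplied by a configurable scale
factor (default 1.14) emulating trajectory-method calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .pdbio import PDBModel, read_pdb

__all__ = [
    "StructureModel",
    "CCSEstimate",
    "pa_ccs",
    "trajectory_ccs",
    "ccs_with_without_ligands",
    "VDW_RADII",
]

# van der Waals radii (A); unknown elements fall back to carbon.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
    "F": 1.47, "Cl": 1.75, "Br": 1.85, "Na": 2.27, "Mg": 1.73,
    "Fe": 1.94, "Zn": 1.39, "Se": 1.90,
}
DEFAULT_RADIUS = 1.70
DEFAULT_PROBE_RADIUS = 1.0
DEFAULT_SCALE_FACTOR = 1.14


@dataclass
class StructureModel:
    """A typed atom set: elements, coordinates and residue labels."""

    elements: list[str]
    coords: np.ndarray
    radii: np.ndarray | None = None
    chains: list[str] | None = None
    resids: np.ndarray | None = None
    resnames: list[str] | None = None
    atom_names: list[str] | None = None
    label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.radii is None:
            self.radii = np.array(
                [VDW_RADII.get(e, DEFAULT_RADIUS) for e in self.elements]
            )
        else:
            self.radii = np.asarray(self.radii, dtype=float)
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be positive")
        if len(self.elements) != len(self.coords):
            raise ValueError("elements and coords length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def subset(self, mask: np.ndarray, label: str | None = None) -> "StructureModel":
        mask = np.asarray(mask, dtype=bool)
        pick = lambda lst: [x for x, m in zip(lst, mask) if m] if lst else None
        return StructureModel(
            elements=[e for e, m in zip(self.elements, mask) if m],
            coords=self.coords[mask],
            radii=self.radii[mask],
            chains=pick(self.chains),
            resids=self.resids[mask] if self.resids is not None else None,
            resnames=pick(self.resnames),
            atom_names=pick(self.atom_names),
            label=label if label is not None else self.label,
        )

    def selection_mask(
        self,
        resnames: Sequence[str] | None = None,
        chains: Sequence[str] | None = None,
        invert: bool = False,
    ) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        if resnames is not None:
            if self.resnames is None:
                raise ValueError("structure carries no residue names")
            rs = set(resnames)
            mask &= np.array([r in rs for r in self.resnames])
        if chains is not None:
            if self.chains is None:
                raise ValueError("structure carries no chain ids")
            cs = set(chains)
            mask &= np.array([c in cs for c in self.chains])
        return ~mask if invert else mask

    @classmethod
    def from_pdb_model(cls, m: PDBModel, label: str = "") -> "StructureModel":
        return cls(
            elements=list(m.elements), coords=m.coords, chains=list(m.chains),
            resids=m.resids, resnames=list(m.resnames),
            atom_names=list(m.atom_names), label=label,
        )

    @classmethod
    def from_pdb(cls, path: str | Path, model: int = 0) -> "StructureModel":
        models = read_pdb(path)
        if not models:
            raise ValueError(f"no atoms found in {path}")
        return cls.from_pdb_model(models[model], label=str(path))

    @classmethod
    def frames_from_pdb(cls, path: str | Path) -> list["StructureModel"]:
        return [cls.from_pdb_model(m, label=f"{path}[{i}]")
                for i, m in enumerate(read_pdb(path))]


@dataclass
class CCSEstimate:
    ccs: float
    standard_error: float
    n_rotations: int
    n_probes_per_rotation: int
    probe_radius: float
    scale_factor: float
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "ccs": self.ccs, "standard_error": self.standard_error,
            "n_rotations": self.n_rotations,
            "n_probes_per_rotation": self.n_probes_per_rotation,
            "probe_radius": self.probe_radius,
            "scale_factor": self.scale_factor, "seed": self.seed,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _projected_area(
    xy: np.ndarray, radii: np.ndarray, n_probes: int, rng: np.random.Generator
) -> float:
    """Hit/miss estimate of the area covered by disks at ``xy``."""
    rmax = radii.max()
    lo = xy.min(axis=0) - rmax
    hi = xy.max(axis=0) + rmax
    span = hi - lo
    pts = lo + rng.random((n_probes, 2)) * span
    hits = np.zeros(n_probes, dtype=bool)
    # one KD-tree per distinct radius keeps the per-point test exact
    for r in np.unique(radii):
        centers = xy[radii == r]
        tree = cKDTree(centers)
        d, _ = tree.query(pts[~hits], k=1, distance_upper_bound=r)
        sub = np.where(~hits)[0]
        hits[sub[d <= r]] = True
    return float(span[0] * span[1] * hits.mean())


def pa_ccs(
    structure: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_rotations: int = 64,
    n_probes: int = 4096,
    scale_factor: float = DEFAULT_SCALE_FACTOR,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    use_hydrogens: bool = True,
) -> CCSEstimate:
    """Projection-approximation CCS by Monte-Carlo orientation averaging.

    Parameters mirror the conventional tool chain: ``probe_radius`` is the
    buffer-gas probe radius added to each van der Waals radius and
    ``scale_factor`` rescales the projection average to emulate
    trajectory-method results.  Fixed ``seed`` gives bit-reproducible
    output.
    """
    if structure.n_atoms == 0:
        raise ValueError("structure has no atoms")
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    if n_rotations < 1 or n_probes < 1:
        raise ValueError("sampling counts must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    coords = structure.coords
    radii = structure.radii + probe_radius
    if not use_hydrogens:
        keep = np.array([e != "H" for e in structure.elements])
        coords, radii = coords[keep], radii[keep]
    coords = coords - coords.mean(axis=0)

    areas = np.empty(n_rotations)
    for k in range(n_rotations):
        R = Rotation.random(rng=rng).as_matrix()
        xy = (coords @ R.T)[:, :2]
        areas[k] = _projected_area(xy, radii, n_probes, rng)
    mean = float(areas.mean()) * scale_factor
    se = float(areas.std(ddof=1) / np.sqrt(n_rotations)) * scale_factor \
        if n_rotations > 1 else float("nan")
    return CCSEstimate(
        ccs=mean, standard_error=se, n_rotations=n_rotations,
        n_probes_per_rotation=n_probes, probe_radius=probe_radius,
        scale_factor=scale_factor, seed=seed,
    )


def trajectory_ccs(
    frames: Sequence[StructureModel],
    window: float = 0.5,
    seed: int | None = None,
    **pa_kwargs,
) -> dict:
    """Mean +/- s.d. CCS over the trailing ``window`` fraction of frames.

    ``window=0.5`` on 10 frames uses frames 6-10 (the last half).  Each
    frame gets an independent substream of the seed.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    if not 0 < window <= 1:
        raise ValueError("window must be in (0, 1]")
    n = len(frames)
    start = n - int(round(window * n))
    used = frames[start:]
    if not used:
        raise ValueError("window selects no frames")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(used))
    estimates = [
        pa_ccs(f, rng=np.random.default_rng(child), **pa_kwargs)
        for f, child in zip(used, children)
    ]
    vals = np.array([e.ccs for e in estimates])
    return {
        "mean_ccs": float(vals.mean()),
        "sd_ccs": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        "n_frames_used": len(used),
        "first_frame_used": start,
        "per_frame": estimates,
    }


def ccs_with_without_ligands(
    frame: StructureModel,
    ligand_mask: np.ndarray,
    seed: int | None = None,
    **pa_kwargs,
) -> tuple[CCSEstimate, CCSEstimate]:
    """CCS of the full complex and of the protein-only atoms.

    Both estimates use the same seed stream so their difference reflects
    the atoms, not Monte-Carlo noise.  The conformation is unchanged:
    ligand atoms are dropped, not relaxed.
    """
    ligand_mask = np.asarray(ligand_mask, dtype=bool)
    if ligand_mask.shape != (frame.n_atoms,):
        raise ValueError("ligand mask length mismatch")
    protein = frame.subset(~ligand_mask, label=frame.label + "/protein")
    if protein.n_atoms == 0:
        raise ValueError("protein selection is empty")
    full = pa_ccs(frame, rng=np.random.default_rng(seed), **pa_kwargs)
    prot = pa_ccs(protein, rng=np.random.default_rng(seed), **pa_kwargs)
    return full, prot
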