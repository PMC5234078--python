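"""Protein--lipid geometry analysis for coordinate trajectories.

Coordinates are in A throughout; densities are converted to nm^-3 at
output (1 nm^-3 = 1e-3 A^-3).  Periodicity uses the minimum-image
convention for orthorhombic boxes only.  The membrane normal defaults
to z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .pdbio import PDBModel, read_pdb, write_pdb

__all__ = [
    "Lipid",
    "Topology",
    "Trajectory",
    "ContactTable",
    "DensityGrid",
    "ThicknessMap",
    "HBondStats",
    "align_frames",
    "detect_contacts",
    "remove_clashing_lipids",
    "assign_leaflets",
    "select_annular_shell",
    "phosphate_density",
    "threshold_density",
    "thickness_map",
    "count_hbonds",
]

DEFAULT_CONTACT_CUTOFF = 2.15   # A, density/contact criterion
DEFAULT_CLASH_CUTOFF = 0.5      # A, heavy-clash removal
GAS_SHELL_CUTOFF = 1.0          # A, gas-phase shell criterion
DEFAULT_LIPID_RESNAMES = frozenset(
    {"POPE", "POPG", "PE", "PG", "CDL", "MAG", "LIP", "POPC", "DPPC"}
)


@dataclass
class Lipid:
    lipid_id: int
    atom_indices: np.ndarray
    head_indices: np.ndarray
    phosphorus_index: int | None
    leaflet: str | None = None


@dataclass
class Topology:
    atom_names: list[str]
    elements: list[str]
    resnames: list[str]
    resids: np.ndarray
    chains: list[str]
    is_protein: np.ndarray
    lipids: list[Lipid]

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def lipid_by_id(self, lipid_id: int) -> Lipid:
        for lp in self.lipids:
            if lp.lipid_id == lipid_id:
                return lp
        raise KeyError(lipid_id)


@dataclass
class Trajectory:
    """Topology plus ordered coordinate frames with box and times (ns)."""

    topology: Topology
    coords: np.ndarray          # (n_frames, n_atoms, 3) in A
    box: np.ndarray | None = None   # orthorhombic (3,) in A
    times: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("atom count differs between topology and frames")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float) * 0.1
        else:
            self.times = np.asarray(self.times, dtype=float)
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")
        for lp in self.topology.lipids:
            if lp.phosphorus_index is None:
                continue
            if self.topology.elements[lp.phosphorus_index] != "P":
                raise ValueError(
                    f"lipid {lp.lipid_id}: phosphorus index is not a P atom"
                )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def protein_indices(self) -> np.ndarray:
        return np.where(self.topology.is_protein)[0]

    def to_multimodel_pdb(self, path: str | Path) -> None:
        top = self.topology
        models = [
            PDBModel(
                atom_names=list(top.atom_names), resnames=list(top.resnames),
                chains=list(top.chains), resids=top.resids,
                coords=self.coords[f], elements=list(top.elements),
                box=self.box,
            )
            for f in range(self.n_frames)
        ]
        write_pdb(models, path)

    @classmethod
    def from_multimodel_pdb(
        cls, path: str | Path,
        lipid_resnames: frozenset[str] | set[str] = DEFAULT_LIPID_RESNAMES,
        time_step: float = 0.1,
    ) -> "Trajectory":
        """Topology from MODEL 1, coordinates from all models."""
        models = read_pdb(path)
        if not models:
            raise ValueError(f"no models in {path}")
        m0 = models[0]
        is_lipid_atom = np.array([rn in lipid_resnames for rn in m0.resnames])
        is_protein = m0.protein_mask() & ~is_lipid_atom
        lipids: list[Lipid] = []
        keys = [
            (m0.chains[i], int(m0.resids[i]), m0.resnames[i])
            for i in range(m0.n_atoms)
        ]
        seen: dict[tuple, list[int]] = {}
        for i, k in enumerate(keys):
            if is_lipid_atom[i]:
                seen.setdefault(k, []).append(i)
        for lid, (k, idx) in enumerate(sorted(seen.items(), key=lambda kv: kv[1][0])):
            idx = np.array(idx)
            elems = [m0.elements[i] for i in idx]
            p_local = [i for i, e in zip(idx, elems) if e == "P"]
            head = idx[[e in ("P", "O", "N") for e in elems]]
            # hydrogens riding on head heavy atoms belong to the head
            h_idx = idx[[e == "H" for e in elems]]
            if head.size and h_idx.size:
                d = np.linalg.norm(
                    m0.coords[h_idx][:, None, :] - m0.coords[head][None, :, :],
                    axis=2,
                ).min(axis=1)
                head = np.sort(np.concatenate([head, h_idx[d <= 1.25]]))
            lipids.append(Lipid(
                lipid_id=lid, atom_indices=idx, head_indices=head,
                phosphorus_index=p_local[0] if p_local else None,
            ))
        top = Topology(
            atom_names=list(m0.atom_names), elements=list(m0.elements),
            resnames=list(m0.resnames), resids=m0.resids,
            chains=list(m0.chains), is_protein=is_protein, lipids=lipids,
        )
        coords = np.stack([m.coords for m in models])
        times = np.arange(len(models), dtype=float) * time_step
        return cls(top, coords, box=m0.box, times=times)


# ---------------------------------------------------------------- alignment

def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing ||R@P.T + t - Q.T||."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def align_frames(traj: Trajectory, reference_mask: np.ndarray | None = None) -> Trajectory:
    """Rigid least-squares superposition of every frame onto frame 0.

    The rotation/translation is fitted on the reference selection
    (default: protein atoms) and applied to all atoms.
    """
    if reference_mask is None:
        reference_mask = traj.topology.is_protein
    reference_mask = np.asarray(reference_mask, dtype=bool)
    n_ref = int(reference_mask.sum())
    if n_ref == 0:
        raise ValueError("reference selection is empty")
    if n_ref < 3:
        raise ValueError("need >=3 reference atoms (rotation underdetermined)")
    ref = traj.coords[0][reference_mask]
    out = traj.coords.copy()
    for f in range(1, traj.n_frames):
        R, t = _kabsch(traj.coords[f][reference_mask], ref)
        out[f] = traj.coords[f] @ R.T + t
    return replace(traj, coords=out)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ----------------------------------------------------------------- contacts

@dataclass
class ContactTable:
    lipid_ids: list[int]
    per_frame: list[set[int]]
    n_frames: int

    @property
    def occupancy(self) -> dict[int, float]:
        occ = {lid: 0 for lid in self.lipid_ids}
        for s in self.per_frame:
            for lid in s:
                occ[lid] += 1
        return {lid: c / self.n_frames for lid, c in occ.items()}


def _lipid_atom_selection(lp: Lipid, part: str) -> np.ndarray:
    if part == "headgroup":
        return lp.head_indices
    if part == "whole":
        return lp.atom_indices
    raise ValueError(f"unknown lipid part: {part!r}")


def _wrap(x: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.mod(x, box)


def detect_contacts(
    traj: Trajectory,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    lipid_part: str = "headgroup",
    heavy_only: bool = True,
    use_pbc: bool = True,
) -> ContactTable:
    """Per-frame lipid--protein contacts: min atom distance <= cutoff (inclusive).

    Uses a KD-tree; with a box present and ``use_pbc``, distances follow
    the minimum-image convention (orthorhombic only).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    top = traj.topology
    prot_idx = traj.protein_indices()
    if heavy_only:
        prot_idx = prot_idx[[top.elements[i] != "H" for i in prot_idx]]
    if prot_idx.size == 0:
        raise ValueError("no protein atoms")
    lip_sel: list[tuple[int, np.ndarray]] = []
    for lp in top.lipids:
        sel = _lipid_atom_selection(lp, lipid_part)
        if heavy_only:
            sel = sel[[top.elements[i] != "H" for i in sel]]
        if sel.size:
            lip_sel.append((lp.lipid_id, sel))
    per_frame: list[set[int]] = []
    if not lip_sel:
        return ContactTable([], [set() for _ in range(traj.n_frames)], traj.n_frames)

    all_sel = np.concatenate([sel for _, sel in lip_sel])
    bounds = np.cumsum([0] + [sel.size for _, sel in lip_sel])
    box = traj.box if (use_pbc and traj.box is not None) else None
    for f in range(traj.n_frames):
        pc = traj.coords[f][prot_idx]
        lc = traj.coords[f][all_sel]
        if box is not None:
            tree = cKDTree(_wrap(pc, box), boxsize=box)
            d, _ = tree.query(_wrap(lc, box), k=1)
        else:
            tree = cKDTree(pc)
            d, _ = tree.query(lc, k=1)
        dmin = np.minimum.reduceat(d, bounds[:-1])
        per_frame.append({
            lip_sel[i][0] for i in range(len(lip_sel)) if dmin[i] <= cutoff
        })
    return ContactTable([lid for lid, _ in lip_sel], per_frame, traj.n_frames)


def remove_clashing_lipids(
    traj: Trajectory,
    cutoff: float = DEFAULT_CLASH_CUTOFF,
    frame: int = 0,
) -> tuple[Trajectory, list[int]]:
    """Drop whole lipids with any atom within ``cutoff`` of the protein.

    The clash test runs on one frame (default the first); matching the
    usual system-preparation step.  Returns the reduced trajectory and the
    removed lipid ids.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    top = traj.topology
    prot_idx = traj.protein_indices()
    pc = traj.coords[frame][prot_idx]
    tree = cKDTree(pc)
    removed: list[int] = []
    for lp in top.lipids:
        d, _ = tree.query(traj.coords[frame][lp.atom_indices], k=1)
        if np.min(d) <= cutoff:
            removed.append(lp.lipid_id)
    if not removed:
        return traj, []
    removed_set = set(removed)
    drop = np.zeros(top.n_atoms, dtype=bool)
    for lp in top.lipids:
        if lp.lipid_id in removed_set:
            drop[lp.atom_indices] = True
    keep = ~drop
    old_to_new = np.cumsum(keep) - 1
    new_lipids = []
    for lp in top.lipids:
        if lp.lipid_id in removed_set:
            continue
        new_lipids.append(Lipid(
            lipid_id=lp.lipid_id,
            atom_indices=old_to_new[lp.atom_indices],
            head_indices=old_to_new[lp.head_indices],
            phosphorus_index=(
                int(old_to_new[lp.phosphorus_index])
                if lp.phosphorus_index is not None else None
            ),
            leaflet=lp.leaflet,
        ))
    new_top = Topology(
        atom_names=[a for a, k in zip(top.atom_names, keep) if k],
        elements=[a for a, k in zip(top.elements, keep) if k],
        resnames=[a for a, k in zip(top.resnames, keep) if k],
        resids=top.resids[keep],
        chains=[a for a, k in zip(top.chains, keep) if k],
        is_protein=top.is_protein[keep],
        lipids=new_lipids,
    )
    return replace(traj, topology=new_top, coords=traj.coords[:, keep, :]), removed


# ----------------------------------------------------------------- leaflets

def assign_leaflets(traj: Trajectory, frame: int = 0) -> dict[int, str]:
    """Tag each lipid upper/lower by phosphorus z versus the membrane midplane.

    The midplane starts at the median phosphorus z and is refined by a
    two-cluster iteration (midpoint of the two leaflet means), which keeps
    the split correct when leaflet populations are unbalanced.  A lipid
    exactly at the midplane is broken toward the leaflet whose mean
    phosphorus z is nearer.  Tags are written onto the topology and returned.
    """
    lipids = [lp for lp in traj.topology.lipids if lp.phosphorus_index is not None]
    if len(lipids) < 2:
        raise ValueError("need at least 2 phospholipids to resolve leaflets")
    z = np.array([traj.coords[frame][lp.phosphorus_index][2] for lp in lipids])
    mid = float(np.median(z))
    for _ in range(32):
        up, lo = z[z > mid], z[z < mid]
        if not up.size or not lo.size:
            break
        new_mid = 0.5 * (up.mean() + lo.mean())
        if abs(new_mid - mid) < 1e-9:
            break
        mid = new_mid
    upper = z > mid
    lower = z < mid
    tags: dict[int, str] = {}
    mean_up = z[upper].mean() if upper.any() else mid + 1.0
    mean_lo = z[lower].mean() if lower.any() else mid - 1.0
    for lp, zi in zip(lipids, z):
        if zi > mid:
            tag = "upper"
        elif zi < mid:
            tag = "lower"
        else:
            tag = "upper" if abs(zi - mean_up) <= abs(zi - mean_lo) else "lower"
        lp.leaflet = tag
        tags[lp.lipid_id] = tag
    return tags


@dataclass
class ShellSelection:
    lipid_ids: list[int]
    occupancies: dict[int, float]
    per_leaflet: dict[str, int]

    @property
    def n_lipids(self) -> int:
        return len(self.lipid_ids)


def select_annular_shell(
    contacts: ContactTable,
    occupancy_min: float = 0.9,
    leaflets: dict[int, str] | None = None,
) -> ShellSelection:
    """First annular shell: lipids with contact occupancy >= ``occupancy_min``.

    Ordering is deterministic: descending occupancy, then lipid id.
    """
    occ = contacts.occupancy
    # a shell member must have contacted at least once, so occupancy_min=0
    # means "all ever-contacting lipids"
    chosen = [lid for lid in contacts.lipid_ids
              if occ[lid] >= occupancy_min and occ[lid] > 0]
    chosen.sort(key=lambda lid: (-occ[lid], lid))
    per_leaflet: dict[str, int] = {}
    if leaflets:
        for lid in chosen:
            tag = leaflets.get(lid, "unassigned")
            per_leaflet[tag] = per_leaflet.get(tag, 0) + 1
    return ShellSelection(chosen, {lid: occ[lid] for lid in chosen}, per_leaflet)


# ------------------------------------------------------------------ density

@dataclass
class DensityGrid:
    """Regular 3-D scalar field of phosphate density in nm^-3."""

    origin: np.ndarray          # A
    spacing: float              # A
    values: np.ndarray          # (nx, ny, nz) in nm^-3
    bandwidth: np.ndarray       # per-axis Gaussian sigma, A
    n_points: int

    def integral(self) -> float:
        """Integral over the grid in point counts (voxel volume in nm^3)."""
        voxel_nm3 = (self.spacing / 10.0) ** 3
        return float(self.values.sum() * voxel_nm3)

    def argmax_position(self) -> np.ndarray:
        idx = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return self.origin + self.spacing * np.array(idx, dtype=float)

    def write_dx(self, path: str | Path) -> None:
        from .dxio import write_dx
        write_dx(self.values, self.origin, self.spacing, path,
                 comment="phosphate head-group density, values in nm^-3")


def phosphate_density(
    traj: Trajectory,
    contacts: ContactTable,
    bandwidth: float | Sequence[float] | None = None,
    spacing: float = 1.0,
    padding_sigmas: float = 4.0,
) -> DensityGrid:
    """3-D Gaussian KDE of phosphorus positions of in-contact lipids.

    Every (frame, lipid-in-contact) event contributes its phosphorus
    coordinate.  Normalization is count-density: the grid integral equals
    the number of contributing points.  Bandwidth defaults to Scott's rule
    per axis.  Output values are nm^-3.
    """
    pts = []
    for f, present in enumerate(contacts.per_frame):
        for lid in present:
            lp = traj.topology.lipid_by_id(lid)
            if lp.phosphorus_index is not None:
                pts.append(traj.coords[f][lp.phosphorus_index])
    if not pts:
        raise ValueError("no contact events: nothing to estimate")
    pts = np.asarray(pts)
    n = len(pts)
    if bandwidth is None:
        sigma = pts.std(axis=0, ddof=1) if n > 1 else np.ones(3)
        h = np.where(sigma > 0, sigma, spacing) * n ** (-1.0 / 7.0)  # Scott, d=3
    else:
        h = np.broadcast_to(np.asarray(bandwidth, dtype=float), (3,)).copy()
    h = np.maximum(h, 1e-6)

    lo = pts.min(axis=0) - padding_sigmas * h
    hi = pts.max(axis=0) + padding_sigmas * h
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 3)
    axes = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
    values = np.zeros(shape)
    # accumulate each point's separable Gaussian over a local window
    win = np.ceil(padding_sigmas * h / spacing).astype(int)
    for p in pts:
        ctr = np.round((p - lo) / spacing).astype(int)
        sl, g1d = [], []
        for k in range(3):
            a = max(ctr[k] - win[k], 0)
            b = min(ctr[k] + win[k] + 1, shape[k])
            sl.append(slice(a, b))
            x = axes[k][a:b]
            g = np.exp(-0.5 * ((x - p[k]) / h[k]) ** 2) / (h[k] * np.sqrt(2 * np.pi))
            g1d.append(g)
        values[sl[0], sl[1], sl[2]] += (
            g1d[0][:, None, None] * g1d[1][None, :, None] * g1d[2][None, None, :]
        )
    values *= 1e3  # A^-3 -> nm^-3
    return DensityGrid(origin=lo, spacing=float(spacing), values=values,
                       bandwidth=h, n_points=n)


def threshold_density(grid: DensityGrid, cutoff: float = 2e-5) -> dict:
    """Voxels >= cutoff (nm^-3) with 26-connected components ranked by volume."""
    mask = grid.values >= cutoff
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    regions = []
    for lab in range(1, n + 1):
        size = int((labels == lab).sum())
        regions.append({"label": lab, "n_voxels": size,
                        "volume_nm3": size * (grid.spacing / 10.0) ** 3})
    regions.sort(key=lambda r: -r["n_voxels"])
    return {"mask": mask, "labels": labels, "regions": regions}


# ---------------------------------------------------------------- thickness

@dataclass
class ThicknessMap:
    x_edges: np.ndarray
    y_edges: np.ndarray
    thickness: np.ma.MaskedArray   # A; masked where uncovered
    min_thickness: float
    min_location: tuple[float, float]

    @property
    def coverage(self) -> np.ndarray:
        return ~self.thickness.mask


def thickness_map(traj: Trajectory, grid_spacing: float = 4.0) -> ThicknessMap:
    """Bilayer thickness over the membrane plane from phosphate surfaces.

    Per xy cell: mean upper-leaflet phosphorus z minus mean lower-leaflet
    phosphorus z, pooled over frames.  Cells lacking either leaflet are
    masked, never zero-filled.  Requires leaflets assigned.
    """
    lipids = [lp for lp in traj.topology.lipids if lp.phosphorus_index is not None]
    if not lipids or any(lp.leaflet is None for lp in lipids):
        raise ValueError("assign_leaflets must run before thickness_map")
    if traj.box is not None:
        x0, y0 = 0.0, 0.0
        lx, ly = float(traj.box[0]), float(traj.box[1])
    else:
        allp = traj.coords[:, [lp.phosphorus_index for lp in lipids], :]
        x0, y0 = allp[..., 0].min(), allp[..., 1].min()
        lx = allp[..., 0].max() - x0 + 1e-9
        ly = allp[..., 1].max() - y0 + 1e-9
    nx = max(int(np.ceil(lx / grid_spacing)), 1)
    ny = max(int(np.ceil(ly / grid_spacing)), 1)
    x_edges = x0 + np.arange(nx + 1) * lx / nx
    y_edges = y0 + np.arange(ny + 1) * ly / ny

    sums = {"upper": np.zeros((nx, ny)), "lower": np.zeros((nx, ny))}
    counts = {"upper": np.zeros((nx, ny)), "lower": np.zeros((nx, ny))}
    p_idx = np.array([lp.phosphorus_index for lp in lipids])
    tags = [lp.leaflet for lp in lipids]
    for f in range(traj.n_frames):
        pos = traj.coords[f][p_idx]
        xy = pos[:, :2] - (x0, y0)
        if traj.box is not None:
            xy = np.mod(xy, (lx, ly))
        ix = np.clip((xy[:, 0] / (lx / nx)).astype(int), 0, nx - 1)
        iy = np.clip((xy[:, 1] / (ly / ny)).astype(int), 0, ny - 1)
        for k in range(len(lipids)):
            sums[tags[k]][ix[k], iy[k]] += pos[k, 2]
            counts[tags[k]][ix[k], iy[k]] += 1
    covered = (counts["upper"] > 0) & (counts["lower"] > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        thick = np.where(
            covered,
            sums["upper"] / np.maximum(counts["upper"], 1)
            - sums["lower"] / np.maximum(counts["lower"], 1),
            np.nan,
        )
    marr = np.ma.MaskedArray(thick, mask=~covered)
    if covered.any():
        imin = np.unravel_index(int(np.ma.argmin(marr)), marr.shape)
        min_thick = float(marr[imin])
        loc = (
            float(0.5 * (x_edges[imin[0]] + x_edges[imin[0] + 1])),
            float(0.5 * (y_edges[imin[1]] + y_edges[imin[1] + 1])),
        )
    else:
        min_thick, loc = float("nan"), (float("nan"), float("nan"))
    return ThicknessMap(x_edges, y_edges, marr, min_thick, loc)


# ------------------------------------------------------------------- hbonds

@dataclass
class HBondStats:
    bonds_per_frame: list[dict[int, list[tuple[int, int, int, float, float]]]]
    shell_ids: list[int]
    d_max: float
    angle_min: float

    @property
    def mean_per_lipid(self) -> float:
        """Mean H-bond count per shell lipid per frame."""
        total = sum(
            len(v) for frame in self.bonds_per_frame for v in frame.values()
        )
        denom = len(self.shell_ids) * len(self.bonds_per_frame)
        return total / denom if denom else 0.0

    def per_lipid_means(self) -> dict[int, float]:
        out = {lid: 0 for lid in self.shell_ids}
        for frame in self.bonds_per_frame:
            for lid, v in frame.items():
                out[lid] += len(v)
        nf = max(len(self.bonds_per_frame), 1)
        return {lid: c / nf for lid, c in out.items()}


def _infer_donors(traj: Trajectory, atom_pool: np.ndarray, frame: int = 0,
                  dh_max: float = 1.25) -> list[tuple[int, int]]:
    """(heavy donor, hydrogen) pairs: H within ``dh_max`` of an N/O atom."""
    elems = traj.topology.elements
    hyd = [i for i in atom_pool if elems[i] == "H"]
    heavy = [i for i in atom_pool if elems[i] in ("N", "O")]
    if not hyd or not heavy:
        return []
    tree = cKDTree(traj.coords[frame][heavy])
    d, j = tree.query(traj.coords[frame][hyd], k=1)
    return [(heavy[jj], hh) for hh, dd, jj in zip(hyd, d, j) if dd <= dh_max]


def count_hbonds(
    traj: Trajectory,
    shell_ids: Sequence[int],
    d_max: float = 3.5,
    angle_min: float = 150.0,
) -> HBondStats:
    """Geometric H-bond statistics between shell-lipid head groups and protein.

    A bond is counted iff donor--acceptor distance <= ``d_max`` and the
    donor-hydrogen-acceptor angle >= ``angle_min`` degrees; both lipid->
    protein and protein->lipid bonds count toward the lipid's tally.
    """
    top = traj.topology
    elems = top.elements
    prot_idx = traj.protein_indices()
    prot_acceptors = np.array([i for i in prot_idx if elems[i] in ("N", "O")])
    prot_donors = _infer_donors(traj, prot_idx)
    shell = [top.lipid_by_id(lid) for lid in shell_ids]
    if not shell:
        raise ValueError("empty lipid shell")
    lip_donors = {lp.lipid_id: _infer_donors(traj, lp.head_indices) for lp in shell}
    lip_acceptors = {
        lp.lipid_id: np.array(
            [i for i in lp.head_indices if elems[i] in ("N", "O")]
        )
        for lp in shell
    }
    if prot_acceptors.size == 0 and all(a.size == 0 for a in lip_acceptors.values()):
        raise ValueError("no polar atoms available for H-bonding")
    cos_min = np.cos(np.deg2rad(angle_min))

    def angle_ok(c, don, hyd, acc) -> tuple[float, float] | None:
        dvec = c[don] - c[hyd]
        avec = c[acc] - c[hyd]
        da = float(np.linalg.norm(c[don] - c[acc]))
        if da > d_max:
            return None
        cosang = float(
            np.dot(dvec, avec)
            / (np.linalg.norm(dvec) * np.linalg.norm(avec) + 1e-12)
        )
        # angle >= angle_min <=> cos(angle) <= cos(angle_min)
        if cosang > cos_min:
            return None
        return da, float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))

    bonds_per_frame = []
    for f in range(traj.n_frames):
        c = traj.coords[f]
        frame_bonds: dict[int, list] = {lp.lipid_id: [] for lp in shell}
        ptree = cKDTree(c[prot_acceptors]) if prot_acceptors.size else None
        for lp in shell:
            # lipid donor -> protein acceptor
            if ptree is not None:
                for don, hyd in lip_donors[lp.lipid_id]:
                    for jj in ptree.query_ball_point(c[don], d_max):
                        acc = int(prot_acceptors[jj])
                        res = angle_ok(c, don, hyd, acc)
                        if res is not None:
                            frame_bonds[lp.lipid_id].append(
                                (don, hyd, acc, res[0], res[1])
                            )
            # protein donor -> lipid acceptor
            accs = lip_acceptors[lp.lipid_id]
            if accs.size and prot_donors:
                atree = cKDTree(c[accs])
                for don, hyd in prot_donors:
                    for jj in atree.query_ball_point(c[don], d_max):
                        acc = int(accs[jj])
                        res = angle_ok(c, don, hyd, acc)
                        if res is not None:
                            frame_bonds[lp.lipid_id].append(
                                (don, hyd, acc, res[0], res[1])
                            )
        bonds_per_frame.append(frame_bonds)
    return HBondStats(bonds_per_frame, [lp.lipid_id for lp in shell],
                      d_max, angle_min)
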