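"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is deterministic under a fixed seed and returns the
dataset together with a :class:`GroundTruth` record sufficient to
regenerate it bit-identically.  A single root seed fans out to
independent per-generator substreams via ``SeedSequence([GEN_ID, seed])``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import poisson

from .imccs import Calibrant, CCSCalibration, fit_calibration
from .msdecon import MassSpectrum, SpeciesModel
from .memtraj import Lipid, Topology, Trajectory
from .structccs import StructureModel

__all__ = [
    "GroundTruth",
    "gen_spectrum",
    "gen_dissociation_series",
    "gen_ciu",
    "gen_membrane",
    "gen_toy_structure",
    "synthetic_calibration",
]

# fixed substream ids so generators are independent of call order
_GEN_IDS = {"spectrum": 11, "ciu": 23, "membrane": 37, "structure": 53,
            "calibration": 71}


def _rng(generator: str, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([_GEN_IDS[generator], 0 if seed is None else seed])
    )


@dataclass
class GroundTruth:
    """Planted parameters serialized next to every generated dataset."""

    generator: str
    seed: int | None
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None, **kw) -> str:
        s = json.dumps(
            {"generator": self.generator, "seed": self.seed, "params": self.params},
            default=_jsonable, **kw,
        )
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, s: str | Path) -> "GroundTruth":
        text = Path(s).read_text() if Path(str(s)).exists() else str(s)
        d = json.loads(text)
        return cls(d["generator"], d["seed"], d["params"])


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON-serializable: {type(o)}")


# ---------------------------------------------------------------- spectra

def gen_spectrum(
    species: Sequence[SpeciesModel],
    abundances: Sequence[float] | None = None,
    adduct_lambda: float = 0.0,
    adduct_weights: Sequence[float] | None = None,
    snr: float = 100.0,
    seed: int | None = None,
    peak_sigma: float = 3.0,
    grid_step: float = 0.5,
    charge_envelope_sigma: float = 1.5,
    metadata: dict | None = None,
) -> tuple[MassSpectrum, GroundTruth]:
    """Profile spectrum with Gaussian peaks for each (species, charge, adducts).

    Adduct intensities follow a truncated Poisson of mean ``adduct_lambda``
    unless explicit ``adduct_weights`` are given; the charge envelope is a
    Gaussian over each species' charge range; baseline noise has standard
    deviation ``max_peak / snr``.
    """
    if not species:
        raise ValueError("empty species list")
    if adduct_lambda < 0 or snr <= 0:
        raise ValueError("adduct_lambda must be >=0 and snr > 0")
    rng = _rng("spectrum", seed)
    abund = np.ones(len(species)) if abundances is None else np.asarray(abundances, float)

    sticks: list[tuple[float, float]] = []
    for sp, a in zip(species, abund):
        zlo, zhi = sp.charge_range
        zs = np.arange(zlo, zhi + 1)
        zmid = 0.5 * (zlo + zhi)
        zw = np.exp(-0.5 * ((zs - zmid) / charge_envelope_sigma) ** 2)
        zw /= zw.sum()
        if adduct_weights is not None:
            aw = np.asarray(adduct_weights, float)[: sp.max_adducts + 1]
        else:
            aw = poisson.pmf(np.arange(sp.max_adducts + 1), adduct_lambda)
        aw = aw / aw.sum() if aw.sum() > 0 else np.ones(1)
        for z, wz in zip(zs, zw):
            for n, wn in enumerate(aw):
                sticks.append((sp.theoretical_mz(z, n), a * wz * wn))

    mzs = np.array([s[0] for s in sticks])
    lo = mzs.min() - 20 * peak_sigma
    hi = mzs.max() + 20 * peak_sigma
    grid = np.arange(lo, hi + grid_step, grid_step)
    inten = np.zeros_like(grid)
    for mz0, amp in sticks:
        inten += amp * np.exp(-0.5 * ((grid - mz0) / peak_sigma) ** 2)
    noise_sd = inten.max() / snr if inten.max() > 0 else 0.0
    inten = np.clip(inten + rng.normal(0, noise_sd, grid.size), 0, None)

    meta = {"label": "synthetic", **(metadata or {})}
    gt = GroundTruth("spectrum", seed, {
        "species": [
            {"base_mass": sp.base_mass, "oligomer_state": sp.oligomer_state,
             "adduct_mass": sp.adduct_mass, "max_adducts": sp.max_adducts,
             "charge_range": list(sp.charge_range), "label": sp.name}
            for sp in species
        ],
        "abundances": list(map(float, abund)),
        "adduct_lambda": adduct_lambda,
        "adduct_weights": None if adduct_weights is None
        else list(map(float, adduct_weights)),
        "snr": snr, "peak_sigma": peak_sigma,
    })
    return MassSpectrum(grid, inten, meta), gt


def gen_dissociation_series(
    species: SpeciesModel,
    cv50: float,
    width: float,
    voltages: Sequence[float],
    snr: float = 200.0,
    seed: int | None = None,
) -> tuple[list[MassSpectrum], GroundTruth]:
    """Spectra at increasing collision voltage with a logistic bound fraction."""
    if species.max_adducts < 1:
        raise ValueError("species must allow >=1 adduct")
    spectra = []
    for i, v in enumerate(voltages):
        f = 1.0 / (1.0 + np.exp((v - cv50) / width))
        spec, _ = gen_spectrum(
            [species], adduct_weights=[1.0 - f, f], snr=snr,
            seed=None if seed is None else seed * 1000 + i,
            metadata={"collision_voltage": float(v)},
        )
        spectra.append(spec)
    gt = GroundTruth("spectrum", seed, {
        "cv50": cv50, "width": width, "voltages": list(map(float, voltages)),
    })
    return spectra, gt


# -------------------------------------------------------------------- CIU

def synthetic_calibration(
    A: float = 800.0, B: float = 0.5, dead_time: float = 0.0,
    seed: int | None = None, noise: float = 0.0,
) -> CCSCalibration:
    """A power-law calibration fitted to points generated from (A, B)."""
    rng = _rng("calibration", seed)
    cals = []
    specs = [("ADH", 24, 147000.0, 6830.0), ("ConA", 20, 103000.0, 5550.0),
             ("PK", 31, 237000.0, 9150.0), ("AmtB", 14, 127000.0, 6100.0),
             ("pfMATE", 10, 52000.0, 3500.0)]
    from .imccs import reduced_mass
    for name, z, m, ccs in specs:
        ccs_prime = ccs * np.sqrt(reduced_mass(m)) / z
        t = (ccs_prime / A) ** (1.0 / B) + dead_time
        t *= 1.0 + (noise * rng.normal() if noise else 0.0)
        cals.append(Calibrant(name, z, m, ccs, float(t)))
    return fit_calibration(cals, dead_time=dead_time)


def _compact_weight(E, onset, midpoint):
    """Logistic compact-state weight: 0.9 at onset, 0.5 at midpoint."""
    if midpoint < onset:
        raise ValueError("need onset <= midpoint")
    s = max((midpoint - onset) / np.log(9.0), 1e-9)
    return 1.0 / (1.0 + np.exp((np.asarray(E, float) - midpoint) / s))


def gen_ciu(
    compact_ccs: float,
    unfolded_ccs: float,
    onset: float,
    midpoint: float,
    mode: str = "two_state",
    charge: int = 11,
    mass: float = 82450.0,
    cal: CCSCalibration | None = None,
    voltages: Sequence[float] | None = None,
    n_times: int = 240,
    ccs_sigma_frac: float = 0.015,
    noise: float = 0.0,
    seed: int | None = None,
) -> dict:
    """Arrival-time-distribution stack emulating an unfolding experiment.

    ``two_state`` transfers population between two CCS modes along a
    logistic in lab-frame energy (weight 0.9 at ``onset``, 0.5 at
    ``midpoint``); ``gradual`` ramps the mean CCS of a single mode along
    the same logistic.  ATDs are rendered through the inverse calibration
    into arrival times.
    """
    if unfolded_ccs <= compact_ccs:
        raise ValueError("unfolded_ccs must exceed compact_ccs")
    if mode not in ("two_state", "gradual"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = _rng("ciu", seed)
    if cal is None:
        cal = synthetic_calibration()
    if voltages is None:
        voltages = np.arange(60.0, 220.0, 10.0)
    voltages = np.asarray(voltages, float)
    energies = charge * voltages

    t_lo = float(cal.invert(compact_ccs * 0.9, charge, mass))
    t_hi = float(cal.invert(unfolded_ccs * 1.1, charge, mass))
    times = np.linspace(t_lo, t_hi, n_times)
    ccs_of_t = np.asarray(cal.predict(times, charge, mass))
    sigma = ccs_sigma_frac * compact_ccs

    w = _compact_weight(energies, onset, midpoint)
    atd = np.zeros((n_times, voltages.size))
    for j in range(voltages.size):
        if mode == "two_state":
            col = (
                w[j] * np.exp(-0.5 * ((ccs_of_t - compact_ccs) / sigma) ** 2)
                + (1 - w[j]) * np.exp(-0.5 * ((ccs_of_t - unfolded_ccs) / sigma) ** 2)
            )
        else:
            mean = compact_ccs + (unfolded_ccs - compact_ccs) * (1 - w[j])
            col = np.exp(-0.5 * ((ccs_of_t - mean) / sigma) ** 2)
        if noise:
            col = np.clip(col + rng.normal(0, noise * col.max(), col.shape), 0, None)
        atd[:, j] = col

    gt = GroundTruth("ciu", seed, {
        "compact_ccs": compact_ccs, "unfolded_ccs": unfolded_ccs,
        "percent_expansion": 100.0 * (unfolded_ccs - compact_ccs) / compact_ccs,
        "onset": onset, "midpoint": midpoint, "mode": mode,
        "charge": charge, "mass": mass, "noise": noise,
        "voltages": list(map(float, voltages)),
    })
    return {"times": times, "atd": atd, "voltages": voltages, "cal": cal,
            "charge": charge, "mass": mass, "ground_truth": gt}


# --------------------------------------------------------------- membrane

def _surface_z(xy: np.ndarray, half_thickness: float, depression: dict | None,
               sign: int) -> np.ndarray:
    """Leaflet z offset from the membrane center; depression pulls inward."""
    z = np.full(len(xy), half_thickness, dtype=float)
    if depression is not None:
        cx, cy = depression["center"]
        r2 = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2
        z -= 0.5 * depression["depth"] * np.exp(-r2 / (2 * depression["sigma"] ** 2))
    return sign * z


def gen_membrane(
    n_lipids: int = 120,
    box: Sequence[float] = (120.0, 95.0, 80.0),
    half_thickness: float = 19.0,
    n_frames: int = 8,
    n_shell_upper: int = 13,
    n_shell_lower: int = 10,
    n_transient: int = 6,
    transient_occupancy: float = 0.5,
    depression: dict | None = None,
    n_clashes: int = 0,
    hbonds_per_lipid: int = 3,
    jitter: float = 0.03,
    contact_gap: float = 1.8,
    seed: int | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Planar bilayer around a rigid toy helical-bundle protein.

    Plants, with exact geometry: an annular shell of persistent lipids
    (contact gap below the 2.15 A criterion in every frame, split between
    leaflets), transient lipids contacting a stated fraction of frames,
    an optional radial thickness depression, ``n_clashes`` lipids with one
    atom at 0.3 A from the protein, and ``hbonds_per_lipid`` ideal
    donor-H-acceptor triplets (d = 2.8 A, angle 180 deg) per shell lipid.
    Frame 0 is the unjittered reference; later frames add Gaussian jitter.
    """
    box = np.asarray(box, float)
    cx, cy, cz = box[0] / 2, box[1] / 2, box[2] / 2
    n_shell = n_shell_upper + n_shell_lower
    if n_lipids < n_shell + n_transient + n_clashes:
        raise ValueError("n_lipids too small for the planted populations")
    rng = _rng("membrane", seed)

    names: list[str] = []
    elements: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    chains: list[str] = []
    coords0: list[np.ndarray] = []

    def add_atom(name, element, resname, resid, chain, xyz):
        names.append(name)
        elements.append(element)
        resnames.append(resname)
        resids.append(resid)
        chains.append(chain)
        coords0.append(np.asarray(xyz, float))

    # --- rigid cylinder-shell protein (radius 6 A, spanning the membrane)
    prot_radius = 6.0
    angles = np.arange(0, 2 * np.pi, np.pi / 9)      # 18 columns
    zlevels = np.arange(-half_thickness - 3, half_thickness + 3.001, 2.0)
    resid = 1
    for ai, a in enumerate(angles):
        for zi, z in enumerate(zlevels):
            add_atom("CA", "C", "ALA", resid, "A",
                     (cx + prot_radius * np.cos(a),
                      cy + prot_radius * np.sin(a), cz + z))
            resid += 1
    n_protein_core = len(names)

    # --- lipid placement bookkeeping
    lipid_records: list[dict] = []   # per lipid: role, leaflet, angle/position
    shell_slots = []
    for k in range(n_shell_upper):
        shell_slots.append(("upper", 2 * np.pi * k / n_shell_upper))
    for k in range(n_shell_lower):
        shell_slots.append(("lower", 2 * np.pi * (k + 0.5) / n_shell_lower))
    trans_slots = [
        ("upper" if k % 2 == 0 else "lower",
         2 * np.pi * (k + 0.25) / max(n_transient, 1))
        for k in range(n_transient)
    ]
    clash_slots = [
        ("upper" if k % 2 == 0 else "lower",
         2 * np.pi * (k + 0.6) / max(n_clashes, 1))
        for k in range(n_clashes)
    ]

    # bulk lipids in upper/lower pairs on an xy grid outside the protein
    # footprint, so every covered thickness cell sees both leaflets
    n_bulk = n_lipids - n_shell - n_transient - n_clashes
    n_pairs = n_bulk // 2
    exclusion = prot_radius + 14.0
    avail = box[0] * box[1] - np.pi * exclusion ** 2
    step = max(np.sqrt(avail / max(n_pairs, 1)), 4.0)
    bulk_positions: list[tuple[float, float]] = []
    while step >= 3.0:
        bulk_positions = [
            (x, y)
            for x in np.arange(step / 2, box[0], step)
            for y in np.arange(step / 2, box[1], step)
            if (x - cx) ** 2 + (y - cy) ** 2 > exclusion ** 2
        ]
        if len(bulk_positions) >= n_pairs:
            break
        step *= 0.92
    if len(bulk_positions) < n_pairs:
        raise ValueError("overcrowded box: not enough bulk lipid sites")
    # evenly strided subset keeps coverage spread and deterministic
    order = np.unique(
        np.linspace(0, len(bulk_positions) - 1, max(n_pairs, 1)).astype(int)
    ) if n_pairs else np.array([], dtype=int)

    # snap the depression center onto the nearest occupied bulk site so the
    # planted minimum is attainable by the discrete lipid field; the snapped
    # center is what the ground truth records
    if depression is not None and len(order):
        sites = np.array([bulk_positions[k] for k in order])
        c0 = np.asarray(depression["center"], float)
        nearest = sites[np.argmin(((sites - c0) ** 2).sum(axis=1))]
        depression = {**depression, "center": (float(nearest[0]), float(nearest[1]))}

    def leaflet_sign(tag):
        return 1 if tag == "upper" else -1

    def surface_at(x, y, tag):
        return cz + float(_surface_z(np.array([[x, y]]), half_thickness,
                                     depression, leaflet_sign(tag))[0])

    lipid_objs: list[Lipid] = []
    shell_truth: dict[int, str] = {}
    transient_truth: dict[int, float] = {}
    clash_truth: list[int] = []
    transient_schedule: dict[int, np.ndarray] = {}
    transient_geo: dict[int, tuple] = {}

    lid = 0
    lres = 1000

    def build_lipid(role, tag, angle=None, xy=None):
        nonlocal lid, lres
        sgn = leaflet_sign(tag)
        atom_start = len(names)
        if role in ("shell", "transient", "clash"):
            u = np.array([np.cos(angle), np.sin(angle), 0.0])
            zl = surface_at(cx + 9.5 * u[0], cy + 9.5 * u[1], tag)
            # dedicated protein surface atom anchoring the planted geometry
            anchor = np.array([cx, cy, zl]) + prot_radius * u
            add_atom("AN", "C", "ALA", 800 + lid, "A", anchor)
            oc = anchor + contact_gap * u
            p_pos = np.array([cx, cy, zl]) + 9.5 * u
            add_atom("P", "P", "LIP", lres, "L", p_pos)
            add_atom("OC", "O", "LIP", lres, "L", oc)
            if role == "shell":
                for j in range(hbonds_per_lipid):
                    # 2 A vertical spacing keeps neighbouring triplets
                    # outside the geometric H-bond criterion
                    zd = zl - sgn * (1.6 + 2.0 * j)
                    od = np.array([cx, cy, zd]) + 8.8 * u
                    h = np.array([cx, cy, zd]) + 7.8 * u
                    acc = np.array([cx, cy, zd]) + 6.0 * u
                    add_atom("OD", "O", "LIP", lres, "L", od)
                    add_atom("HD", "H", "LIP", lres, "L", h)
                    # acceptor belongs to the protein
                    add_atom("OX", "O", "ALA", 900 + lid, "A", acc)
            # tail carbons toward the membrane center
            for j in range(3):
                add_atom(f"C{j+1}", "C", "LIP", lres, "L",
                         np.array([cx, cy, zl - sgn * (3.0 + 2.0 * (j + 1))]) + 9.5 * u)
            if role == "clash":
                # one atom in heavy clash (0.3 A) with the protein anchor
                add_atom("C4", "C", "LIP", lres, "L", anchor + 0.3 * u)
        else:  # bulk
            x, y = xy
            zl = surface_at(x, y, tag)
            add_atom("P", "P", "LIP", lres, "L", (x, y, zl))
            add_atom("O1", "O", "LIP", lres, "L", (x + 0.8, y, zl + sgn * 0.5))
            for j in range(3):
                add_atom(f"C{j+1}", "C", "LIP", lres, "L",
                         (x, y, zl - sgn * (2.0 + 2.0 * (j + 1))))
        idx = np.arange(atom_start, len(names))
        own = [i for i in idx if resnames[i] == "LIP"]
        head = np.array([i for i in own if elements[i] in ("P", "O", "N")
                         or names[i] == "HD"])
        p_index = next(i for i in own if elements[i] == "P")
        lipid_objs.append(Lipid(
            lipid_id=lid, atom_indices=np.array(own), head_indices=head,
            phosphorus_index=int(p_index),
        ))
        lres += 1
        lid += 1
        return lid - 1

    for tag, ang in shell_slots:
        this = build_lipid("shell", tag, angle=ang)
        shell_truth[this] = tag
    for k, (tag, ang) in enumerate(trans_slots):
        this = build_lipid("transient", tag, angle=ang)
        transient_truth[this] = transient_occupancy
        n_in = int(round(transient_occupancy * n_frames))
        frames_in = rng.permutation(n_frames)[:n_in]
        transient_schedule[this] = np.zeros(n_frames, dtype=bool)
        transient_schedule[this][frames_in] = True
        transient_geo[this] = (ang, tag)
    for tag, ang in clash_slots:
        this = build_lipid("clash", tag, angle=ang)
        clash_truth.append(this)
    for k in order:
        build_lipid("bulk", "upper", xy=bulk_positions[k])
        build_lipid("bulk", "lower", xy=bulk_positions[k])
    if n_bulk % 2:  # odd leftover: a single unpaired upper lipid
        spare = bulk_positions[(order[-1] + 1) % len(bulk_positions)] \
            if len(order) else bulk_positions[0]
        build_lipid("bulk", "upper", xy=spare)

    coords0 = np.asarray(coords0)
    n_atoms = len(names)
    is_protein = np.array([rn == "ALA" for rn in resnames])

    top = Topology(
        atom_names=names, elements=elements, resnames=resnames,
        resids=np.array(resids), chains=chains, is_protein=is_protein,
        lipids=lipid_objs,
    )

    frames = np.empty((n_frames, n_atoms, 3))
    out_shift = 6.0  # radial displacement taking a transient lipid out of contact
    for f in range(n_frames):
        c = coords0.copy()
        for tlid, sched in transient_schedule.items():
            if not sched[f]:
                ang, tag = transient_geo[tlid]
                u = np.array([np.cos(ang), np.sin(ang), 0.0])
                lp = top.lipid_by_id(tlid)
                c[lp.atom_indices] += out_shift * u
        if f > 0 and jitter > 0:
            c += rng.normal(0, jitter, c.shape)
        frames[f] = c

    traj = Trajectory(top, frames, box=box,
                      times=np.arange(n_frames, dtype=float) * 0.1)
    gt = GroundTruth("membrane", seed, {
        "box": box, "half_thickness": half_thickness,
        "base_thickness": 2 * half_thickness,
        "depression": depression,
        "min_thickness": (2 * half_thickness - depression["depth"]
                          if depression else 2 * half_thickness),
        "shell": {str(k): v for k, v in shell_truth.items()},
        "n_shell_upper": n_shell_upper, "n_shell_lower": n_shell_lower,
        "transient_occupancy": {
            str(k): float(transient_schedule[k].mean())
            for k in transient_schedule
        },
        "clash_ids": clash_truth,
        "hbonds_per_lipid": hbonds_per_lipid,
        "contact_gap": contact_gap, "jitter": jitter,
        "n_frames": n_frames, "n_lipids": n_lipids,
        "membrane_center_z": cz,
    })
    return traj, gt


# -------------------------------------------------------------- structures

def gen_toy_structure(kind: str, params: dict | None = None,
                      seed: int | None = None) -> tuple[StructureModel, GroundTruth]:
    """Toy atomic structures with analytically known or oracle-checkable CCS.

    Kinds: ``sphere_cluster`` (n atoms in a ball), ``diatomic`` (two atoms
    at a given separation), ``bundle`` (helical-bundle point model with an
    optional ``collapse`` factor scaling coordinates toward the center).
    """
    params = dict(params or {})
    rng = _rng("structure", seed)
    if kind == "sphere_cluster":
        n = int(params.get("n", 1))
        r = float(params.get("radius", 2.0))
        spread = float(params.get("spread", 10.0))
        if n == 1:
            coords = np.zeros((1, 3))
        else:
            coords = rng.normal(0, spread, (n, 3))
        sm = StructureModel(elements=["C"] * n, coords=coords,
                            radii=np.full(n, r), label="sphere_cluster")
        gt = GroundTruth("structure", seed, {
            "kind": kind, "n": n, "radius": r, "spread": spread,
            "analytic_area": float(np.pi * r ** 2) if n == 1 else None,
        })
        return sm, gt
    if kind == "diatomic":
        d = float(params.get("distance", 5.0))
        r = float(params.get("radius", 2.0))
        coords = np.array([[0.0, 0.0, -d / 2], [0.0, 0.0, d / 2]])
        sm = StructureModel(elements=["C", "C"], coords=coords,
                            radii=np.full(2, r), label="diatomic")
        gt = GroundTruth("structure", seed,
                         {"kind": kind, "distance": d, "radius": r})
        return sm, gt
    if kind == "bundle":
        n_helices = int(params.get("n_helices", 4))
        length = float(params.get("length", 40.0))
        helix_radius = float(params.get("bundle_radius", 7.0))
        collapse = float(params.get("collapse", 1.0))
        coords = []
        for h in range(n_helices):
            a = 2 * np.pi * h / n_helices
            z = np.arange(-length / 2, length / 2, 1.5)
            x = helix_radius * np.cos(a) + 2.3 * np.cos(z / 1.5)
            y = helix_radius * np.sin(a) + 2.3 * np.sin(z / 1.5)
            coords.append(np.column_stack([x, y, z]))
        coords = np.vstack(coords) * collapse
        sm = StructureModel(elements=["C"] * len(coords), coords=coords,
                            label="bundle")
        gt = GroundTruth("structure", seed, {
            "kind": kind, "n_helices": n_helices, "length": length,
            "bundle_radius": helix_radius, "collapse": collapse,
        })
        return sm, gt
    raise ValueError(f"unknown toy structure kind: {kind!r}")


def membrane_frame_structure(traj: Trajectory, frame: int = 0) -> StructureModel:
    """A trajectory frame as a StructureModel (for CCS with/without lipids)."""
    top = traj.topology
    return StructureModel(
        elements=list(top.elements), coords=traj.coords[frame],
        chains=list(top.chains), resids=top.resids,
        resnames=list(top.resnames), atom_names=list(top.atom_names),
        label=f"membrane_frame_{frame}",
    )
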