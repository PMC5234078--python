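"""Traveling-wave ion-mobility CCS calibration and unfolding quantification.

Calibration follows the standard TWIMS chain: arrival times are
dead-time corrected, reference cross-sections are reduced-mass and
charge corrected (``ccs' = ccs * sqrt(mu) / z`` with ``mu`` the
ion/drift-gas reduced mass, N2 by default), and a power law
``ccs' = A * t'**B`` is fitted in log-log space.

Collision-induced unfolding is quantified on fingerprints: intensity
over (lab-frame energy x CCS), each energy column normalized to unit
sum.  Lab-frame energy is charge x collision voltage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.signal import find_peaks

N2_MASS = 28.0134

__all__ = [
    "Calibrant",
    "CCSCalibration",
    "CIUFingerprint",
    "UnfoldingResult",
    "StabilizationShift",
    "fit_calibration",
    "apply_calibration",
    "build_fingerprint",
    "unfolding_metrics",
    "stabilization_shift",
]


def reduced_mass(ion_mass: float, gas_mass: float = N2_MASS) -> float:
    return ion_mass * gas_mass / (ion_mass + gas_mass)


@dataclass(frozen=True)
class Calibrant:
    name: str
    charge: int
    mass: float          # Da
    reference_ccs: float  # A^2
    arrival_time: float   # ms


@dataclass
class CCSCalibration:
    """Power-law map from corrected arrival time to corrected CCS."""

    calibrants: list[Calibrant]
    A: float
    B: float
    dead_time: float
    gas_mass: float
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def max_relative_residual(self) -> float:
        return float(np.max(np.abs(self.residuals))) if self.residuals.size else 0.0

    def corrected_time(self, arrival_time: float | np.ndarray) -> np.ndarray:
        t = np.asarray(arrival_time, dtype=float) - self.dead_time
        if np.any(t <= 0):
            raise ValueError("arrival time must exceed the dead time")
        return t

    def predict(self, arrival_time, charge: int, mass: float):
        """CCS (A^2) for an arrival time of an ion of given charge and mass."""
        tprime = self.corrected_time(arrival_time)
        ccs_prime = self.A * tprime ** self.B
        mu = reduced_mass(mass, self.gas_mass)
        return ccs_prime * charge / np.sqrt(mu)

    def invert(self, ccs, charge: int, mass: float):
        """Arrival time (ms) producing a given CCS; inverse of :meth:`predict`."""
        mu = reduced_mass(mass, self.gas_mass)
        ccs_prime = np.asarray(ccs, dtype=float) * np.sqrt(mu) / charge
        return (ccs_prime / self.A) ** (1.0 / self.B) + self.dead_time

    def to_dict(self) -> dict:
        return {
            "A": self.A, "B": self.B, "dead_time": self.dead_time,
            "gas_mass": self.gas_mass,
            "calibrants": [c.__dict__ for c in self.calibrants],
            "relative_residuals": list(map(float, self.residuals)),
        }


def fit_calibration(
    calibrants: Sequence[Calibrant],
    dead_time: float = 0.0,
    gas_mass: float = N2_MASS,
) -> CCSCalibration:
    """Fit the power law ``ccs' = A * t'**B`` to >=3 calibrant points."""
    calibrants = list(calibrants)
    if len(calibrants) < 3:
        raise ValueError("need at least 3 calibrant points")
    t = np.array([c.arrival_time for c in calibrants], dtype=float) - dead_time
    if np.any(t <= 0):
        raise ValueError("non-positive corrected arrival time in calibrants")
    ccs_prime = np.array([
        c.reference_ccs * np.sqrt(reduced_mass(c.mass, gas_mass)) / c.charge
        for c in calibrants
    ])
    B, logA = np.polyfit(np.log(t), np.log(ccs_prime), 1)
    A = float(np.exp(logA))
    if B <= 0:
        raise ValueError("calibration slope must be positive")
    pred = A * t ** B
    residuals = (pred - ccs_prime) / ccs_prime
    return CCSCalibration(calibrants, A, float(B), dead_time, gas_mass, residuals)


def apply_calibration(cal: CCSCalibration, arrival_time, charge: int, mass: float):
    """Functional form of :meth:`CCSCalibration.predict`."""
    return cal.predict(arrival_time, charge, mass)


@dataclass
class CIUFingerprint:
    """Unfolding fingerprint: column-normalized intensity over energy x CCS."""

    energy_axis: np.ndarray   # lab-frame eV, one per column
    ccs_axis: np.ndarray      # A^2, one per row
    intensity: np.ndarray     # (n_ccs, n_energy)
    charge: int

    def __post_init__(self):
        self.energy_axis = np.asarray(self.energy_axis, dtype=float)
        self.ccs_axis = np.asarray(self.ccs_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.ccs_axis.size, self.energy_axis.size):
            raise ValueError("intensity shape must be (n_ccs, n_energy)")
        if np.any(np.diff(self.energy_axis) <= 0) or np.any(np.diff(self.ccs_axis) <= 0):
            raise ValueError("axes must be strictly increasing")

    @property
    def empty_columns(self) -> np.ndarray:
        return self.intensity.sum(axis=0) == 0

    def normalized(self) -> "CIUFingerprint":
        out = self.intensity.copy()
        colsum = out.sum(axis=0)
        nz = colsum > 0
        out[:, nz] /= colsum[nz]
        return CIUFingerprint(self.energy_axis, self.ccs_axis, out, self.charge)

    def to_json(self, matrix_path=None) -> str:
        d = {
            "charge": self.charge,
            "energy_axis": list(map(float, self.energy_axis)),
            "ccs_axis": list(map(float, self.ccs_axis)),
        }
        if matrix_path is None:
            d["intensity"] = self.intensity.tolist()
        else:
            np.savetxt(matrix_path, self.intensity)
            d["matrix_file"] = str(matrix_path)
        return json.dumps(d)


def build_fingerprint(
    arrival_times: np.ndarray,
    atd_matrix: np.ndarray,
    voltages: Sequence[float],
    cal: CCSCalibration,
    charge: int,
    mass: float,
) -> CIUFingerprint:
    """Assemble a fingerprint from per-voltage arrival-time distributions.

    ``atd_matrix`` has one column per collision voltage on a common
    arrival-time axis.  The energy axis is ``charge * voltage`` (lab-frame
    eV); the arrival-time axis is calibrated to CCS; columns are normalized
    to unit sum (all-zero columns are left zero and flagged via
    :attr:`CIUFingerprint.empty_columns`).
    """
    arrival_times = np.asarray(arrival_times, dtype=float)
    atd_matrix = np.asarray(atd_matrix, dtype=float)
    voltages = np.asarray(voltages, dtype=float)
    if len(voltages) < 3:
        raise ValueError("need ATDs at >=3 collision voltages")
    if atd_matrix.shape != (arrival_times.size, voltages.size):
        raise ValueError("atd_matrix shape must be (n_times, n_voltages)")
    ccs = np.asarray(cal.predict(arrival_times, charge, mass), dtype=float)
    energy = charge * voltages
    order = np.argsort(energy)
    fp = CIUFingerprint(energy[order], ccs, atd_matrix[:, order], charge)
    return fp.normalized()


@dataclass
class UnfoldingResult:
    compact_ccs: float
    unfolded_ccs: float
    percent_expansion: float
    onset_energy: float | None
    midpoint_energy: float | None
    n_states: int
    classification: str
    onset_censored: bool = False
    midpoint_censored: bool = False
    energy_max: float = float("nan")
    compact_weights: np.ndarray = field(default_factory=lambda: np.array([]))
    intermediate_occupancy: float = 0.0

    def to_dict(self) -> dict:
        return {
            "compact_ccs": self.compact_ccs,
            "unfolded_ccs": self.unfolded_ccs,
            "percent_expansion": self.percent_expansion,
            "onset_energy": self.onset_energy,
            "midpoint_energy": self.midpoint_energy,
            "n_states": self.n_states,
            "classification": self.classification,
            "onset_censored": self.onset_censored,
            "midpoint_censored": self.midpoint_censored,
            "intermediate_occupancy": self.intermediate_occupancy,
        }


def _column_peak_ccs(ccs_axis: np.ndarray, col: np.ndarray) -> float:
    i = int(np.argmax(col))
    if 0 < i < col.size - 1:
        y0, y1, y2 = col[i - 1], col[i], col[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            delta = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
            step = 0.5 * (ccs_axis[min(i + 1, col.size - 1)] - ccs_axis[max(i - 1, 0)])
            return float(ccs_axis[i] + delta * step)
    return float(ccs_axis[i])


def unfolding_metrics(
    fp: CIUFingerprint,
    compact_threshold: float = 0.9,
    intermediate_bound: float = 0.10,
    band_margin: float = 0.25,
    mode_persistence: float = 0.2,
    min_expansion: float = 0.02,
) -> UnfoldingResult:
    """Quantify an unfolding fingerprint.

    Each energy column is decomposed (non-negative least squares) onto two
    templates taken from the lowest- and highest-energy columns, seeding
    compact and extended populations.  The onset is the first energy at
    which the compact weight drops below ``compact_threshold``; the
    midpoint is where it crosses 0.5.  Classification is ``two_state``
    when the occupancy of the CCS band between the two modes never exceeds
    ``intermediate_bound``, else ``gradual``.  Censored onsets/midpoints
    (no transition in range) are reported as ``None`` with the censoring
    flag set and ``energy_max`` recording the energy range limit.
    """
    fp = fp.normalized()
    I = fp.intensity
    n_e = fp.energy_axis.size
    compact_t = I[:, 0]
    extended_t = I[:, -1]
    T = np.column_stack([compact_t, extended_t])

    w = np.empty(n_e)
    for j in range(n_e):
        coef, _ = nnls(T, I[:, j])
        s = coef.sum()
        w[j] = coef[0] / s if s > 0 else np.nan

    compact_ccs = _column_peak_ccs(fp.ccs_axis, compact_t)
    unfolded_ccs = _column_peak_ccs(fp.ccs_axis, extended_t)
    if unfolded_ccs < compact_ccs:
        unfolded_ccs = compact_ccs
    percent = 100.0 * (unfolded_ccs - compact_ccs) / compact_ccs

    emax = float(fp.energy_axis[-1])
    if percent < 100.0 * min_expansion:
        # first and last columns are indistinguishable: no transition in
        # range, the two-template decomposition is ill-posed
        return UnfoldingResult(
            compact_ccs=compact_ccs, unfolded_ccs=unfolded_ccs,
            percent_expansion=percent, onset_energy=None,
            midpoint_energy=None, n_states=1, classification="two_state",
            onset_censored=True, midpoint_censored=True, energy_max=emax,
            compact_weights=np.ones(n_e), intermediate_occupancy=0.0,
        )
    below = np.where(w < compact_threshold)[0]
    onset = float(fp.energy_axis[below[0]]) if below.size else None
    half = np.where(w < 0.5)[0]
    if half.size:
        j = half[0]
        if j > 0 and w[j - 1] != w[j]:
            # linear interpolation of the 0.5 crossing
            frac = (w[j - 1] - 0.5) / (w[j - 1] - w[j])
            midpoint = float(
                fp.energy_axis[j - 1]
                + frac * (fp.energy_axis[j] - fp.energy_axis[j - 1])
            )
        else:
            midpoint = float(fp.energy_axis[j])
    else:
        midpoint = None

    # occupancy of the inter-mode CCS band
    gap = unfolded_ccs - compact_ccs
    if gap > 0:
        lo = compact_ccs + band_margin * gap
        hi = unfolded_ccs - band_margin * gap
        band = (fp.ccs_axis > lo) & (fp.ccs_axis < hi)
        inter = float(I[band, :].sum(axis=0).max()) if band.any() else 0.0
    else:
        inter = 0.0
    classification = "two_state" if inter <= intermediate_bound else "gradual"

    # persistent-mode counting across columns
    positions: list[float] = []
    for j in range(n_e):
        idx, _ = find_peaks(I[:, j], height=0.05 * I[:, j].max() if I[:, j].max() > 0 else 1)
        positions.extend(fp.ccs_axis[idx])
    n_states = 0
    if positions:
        positions = np.sort(positions)
        tol = max(0.02 * float(np.ptp(fp.ccs_axis)), 1e-9)
        clusters: list[list[float]] = [[positions[0]]]
        for p in positions[1:]:
            if p - clusters[-1][-1] <= tol:
                clusters[-1].append(p)
            else:
                clusters.append([p])
        n_states = sum(1 for cl in clusters if len(cl) >= mode_persistence * n_e)

    return UnfoldingResult(
        compact_ccs=compact_ccs,
        unfolded_ccs=unfolded_ccs,
        percent_expansion=percent,
        onset_energy=onset,
        midpoint_energy=midpoint,
        n_states=max(n_states, 1),
        classification=classification,
        onset_censored=onset is None,
        midpoint_censored=midpoint is None,
        energy_max=emax,
        compact_weights=w,
        intermediate_occupancy=inter,
    )


@dataclass
class StabilizationShift:
    """Signed onset/expansion differences; positive onset shift = stabilization."""

    delta_onset: float | None
    delta_percent_expansion: float
    censored: bool = False
    delta_onset_lower_bound: float | None = None

    def to_dict(self) -> dict:
        return {
            "delta_onset": self.delta_onset,
            "delta_percent_expansion": self.delta_percent_expansion,
            "censored": self.censored,
            "delta_onset_lower_bound": self.delta_onset_lower_bound,
        }


def stabilization_shift(a: UnfoldingResult, b: UnfoldingResult) -> StabilizationShift:
    """Shift of b relative to a (b - a); censored onsets propagate as bounds."""
    d_pct = b.percent_expansion - a.percent_expansion
    if a.onset_censored and b.onset_censored:
        return StabilizationShift(None, d_pct, censored=True)
    if b.onset_censored:
        # b never unfolds in range: onset_b > energy_max
        return StabilizationShift(
            None, d_pct, censored=True,
            delta_onset_lower_bound=b.energy_max - a.onset_energy,
        )
    if a.onset_censored:
        return StabilizationShift(
            None, d_pct, censored=True,
            delta_onset_lower_bound=None,
        )
    return StabilizationShift(b.onset_energy - a.onset_energy, d_pct)
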