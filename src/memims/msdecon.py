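"""Charge-state envelope deconvolution and lipid-binding quantification.

Works on profile-mode spectra stored as two-column m/z--intensity arrays.
Peaks are picked as local maxima above a noise floor and centroided by
local quadratic interpolation; theoretical m/z values for candidate
species (oligomer x charge x adduct count) are matched within a ppm
tolerance.  Positive-ion mode is assumed; charging uses the proton mass
1.00728 Da.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

PROTON_MASS = 1.00728

__all__ = [
    "MassSpectrum",
    "SpeciesModel",
    "PeakAssignment",
    "BindingCurve",
    "DeconvolutionResult",
    "deconvolve",
    "adduct_profile",
    "titration_analysis",
    "dissociation_curve",
    "rank_by_cv50",
]


@dataclass
class MassSpectrum:
    """Profile-mode spectrum: ascending m/z, non-negative intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def collision_voltage(self) -> float | None:
        v = self.metadata.get("collision_voltage")
        return None if v is None else float(v)

    def to_text(self, path: str | Path | None = None) -> str | None:
        """Write as two-column text with a ``# key=value`` header."""
        buf = io.StringIO()
        for k, v in self.metadata.items():
            buf.write(f"# {k}={v}\n")
        for m, i in zip(self.mz, self.intensity):
            buf.write(f"{m:.6f}\t{i:.6g}\n")
        if path is None:
            return buf.getvalue()
        Path(path).write_text(buf.getvalue())
        return None

    @classmethod
    def from_text(cls, source: str | Path) -> "MassSpectrum":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        meta: dict = {}
        mz, inten = [], []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    try:
                        meta[k.strip()] = float(v)
                    except ValueError:
                        meta[k.strip()] = v.strip()
                continue
            a, b = line.replace(",", " ").split()[:2]
            mz.append(float(a))
            inten.append(float(b))
        return cls(np.array(mz), np.array(inten), meta)


@dataclass(frozen=True)
class SpeciesModel:
    """A candidate species: oligomer of a protomer plus lipid adducts."""

    base_mass: float
    oligomer_state: int = 1
    adduct_mass: float = 0.0
    max_adducts: int = 0
    charge_range: tuple[int, int] = (1, 1)
    label: str = ""

    def __post_init__(self):
        if self.base_mass <= 0:
            raise ValueError("base_mass must be positive")
        if self.oligomer_state < 1:
            raise ValueError("oligomer_state must be >= 1")

    @property
    def neutral_mass(self) -> float:
        return self.oligomer_state * self.base_mass

    def theoretical_mz(self, charge: int, n_adducts: int = 0) -> float:
        m = self.neutral_mass + n_adducts * self.adduct_mass
        return (m + charge * PROTON_MASS) / charge

    @property
    def name(self) -> str:
        return self.label or f"{self.oligomer_state}mer@{self.base_mass:.0f}"


@dataclass(frozen=True)
class PeakAssignment:
    species: SpeciesModel
    oligomer_state: int
    charge: int
    n_adducts: int
    theoretical_mz: float
    matched_mz: float
    matched_intensity: float
    ppm_error: float

    def to_dict(self) -> dict:
        return {
            "species": self.species.name,
            "oligomer_state": self.oligomer_state,
            "charge": self.charge,
            "n_adducts": self.n_adducts,
            "theoretical_mz": self.theoretical_mz,
            "matched_mz": self.matched_mz,
            "matched_intensity": self.matched_intensity,
            "ppm_error": self.ppm_error,
        }


@dataclass
class DeconvolutionResult:
    assignments: list[PeakAssignment]
    abundances: dict[str, float]
    recovered_masses: dict[str, float]
    unmatched_peaks: list[tuple[float, float]]

    def for_species(self, species: SpeciesModel) -> list[PeakAssignment]:
        return [a for a in self.assignments if a.species == species]

    def to_dict(self) -> dict:
        return {
            "assignments": [a.to_dict() for a in self.assignments],
            "abundances": self.abundances,
            "recovered_masses": self.recovered_masses,
            "unmatched_peaks": self.unmatched_peaks,
        }


def pick_peaks(
    spectrum: MassSpectrum,
    noise_fraction: float = 0.01,
    min_prominence_fraction: float = 0.005,
) -> list[tuple[float, float]]:
    """Local maxima above a noise floor, centroided by quadratic interpolation.

    Returns ``(centroid_mz, apex_intensity)`` pairs.
    """
    y = spectrum.intensity
    if y.size == 0 or y.max() <= 0:
        return []
    floor = noise_fraction * y.max()
    idx, _ = find_peaks(y, height=floor, prominence=min_prominence_fraction * y.max())
    out = []
    for i in idx:
        if 0 < i < y.size - 1:
            # quadratic vertex through the apex and its neighbours
            y0, y1, y2 = y[i - 1], y[i], y[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            dx = 0.5 * (spectrum.mz[i + 1] - spectrum.mz[i - 1])
            out.append((float(spectrum.mz[i] + delta * dx), float(y1)))
        else:
            out.append((float(spectrum.mz[i]), float(y[i])))
    return out


def deconvolve(
    spectrum: MassSpectrum,
    candidates: Sequence[SpeciesModel],
    tolerance_ppm: float = 150.0,
    noise_fraction: float = 0.01,
) -> DeconvolutionResult:
    """Match picked peaks to candidate species within a ppm tolerance.

    Each peak is assigned to the candidate (oligomer, charge, adduct count)
    with the smallest ppm error; per-species abundance is the sum of matched
    apex intensities.  Recovered neutral masses are intensity-weighted means
    over the assigned charge states after subtracting adducts and protons.
    """
    if not candidates:
        raise ValueError("need at least one candidate species")
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    peaks = pick_peaks(spectrum, noise_fraction=noise_fraction)
    if not peaks:
        warnings.warn("no peaks above the noise floor; empty assignment")
        return DeconvolutionResult([], {}, {}, [])

    peak_mz = np.array([p[0] for p in peaks])
    best: dict[int, PeakAssignment] = {}
    for sp in candidates:
        zlo, zhi = sp.charge_range
        for z in range(zlo, zhi + 1):
            for n in range(sp.max_adducts + 1):
                theo = sp.theoretical_mz(z, n)
                j = int(np.argmin(np.abs(peak_mz - theo)))
                ppm = (peak_mz[j] - theo) / theo * 1e6
                if abs(ppm) <= tolerance_ppm:
                    cand = PeakAssignment(
                        species=sp,
                        oligomer_state=sp.oligomer_state,
                        charge=z,
                        n_adducts=n,
                        theoretical_mz=theo,
                        matched_mz=peak_mz[j],
                        matched_intensity=peaks[j][1],
                        ppm_error=float(ppm),
                    )
                    if j not in best or abs(cand.ppm_error) < abs(best[j].ppm_error):
                        best[j] = cand

    assignments = [best[j] for j in sorted(best)]
    abundances: dict[str, float] = {}
    mass_num: dict[str, float] = {}
    mass_den: dict[str, float] = {}
    for a in assignments:
        key = a.species.name
        abundances[key] = abundances.get(key, 0.0) + a.matched_intensity
        neutral = a.charge * (a.matched_mz - PROTON_MASS) - a.n_adducts * a.species.adduct_mass
        mass_num[key] = mass_num.get(key, 0.0) + neutral * a.matched_intensity
        mass_den[key] = mass_den.get(key, 0.0) + a.matched_intensity
    recovered = {k: mass_num[k] / mass_den[k] for k in mass_num if mass_den[k] > 0}
    matched_idx = set(best)
    unmatched = [p for j, p in enumerate(peaks) if j not in matched_idx]
    return DeconvolutionResult(assignments, abundances, recovered, unmatched)


def adduct_profile(assignments: Sequence[PeakAssignment]) -> dict:
    """Intensity-weighted adduct-count histogram and mean occupancy."""
    if not assignments:
        raise ValueError("no assignments to profile")
    weights: dict[int, float] = {}
    for a in assignments:
        weights[a.n_adducts] = weights.get(a.n_adducts, 0.0) + a.matched_intensity
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("all matched intensities are zero")
    dist = {n: w / total for n, w in sorted(weights.items())}
    mean = sum(n * w for n, w in dist.items())
    return {"distribution": dist, "mean_occupancy": mean}


@dataclass
class BindingCurve:
    """A binding or dissociation curve with its fitted model."""

    x: np.ndarray
    y: np.ndarray
    model_fit: dict
    classification: str
    cv50: float | None = None
    cv50_censored: bool = False
    cv50_lower_bound: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "x": list(map(float, self.x)),
            "y": list(map(float, self.y)),
            "model_fit": self.model_fit,
            "classification": self.classification,
            "cv50": self.cv50,
            "cv50_censored": self.cv50_censored,
            "cv50_lower_bound": self.cv50_lower_bound,
            "flags": self.flags,
        }


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def titration_analysis(
    profiles: Sequence[tuple[float, float]],
    delta_aicc: float = 2.0,
) -> BindingCurve:
    """Classify a titration as saturating (single site) or non-saturating.

    Fits occupancy = Bmax*c/(Kd+c) and a linear model, compares by
    small-sample-corrected information criterion; the saturation model must
    win by at least ``delta_aicc`` AND place Kd inside the sampled
    concentration range (otherwise no curvature was actually observed) to
    call specific binding.
    """
    pts = sorted(profiles)
    if len(pts) < 4:
        raise ValueError("need at least 4 concentrations")
    c = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.allclose(c, c[0]):
        raise ValueError("degenerate titration: all concentrations equal")

    # linear (non-specific) model through the origin region
    A = np.vstack([c, np.ones_like(c)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope, intercept = coef
    rss_lin = float(np.sum((A @ coef - y) ** 2))
    aicc_lin = _aicc(rss_lin, len(c), 2)

    def hill1(cc, bmax, kd):
        return bmax * cc / (kd + cc)

    aicc_sat = np.inf
    sat_params = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p0 = (max(y.max(), 1e-6), max(np.median(c), 1e-6))
            popt, _ = curve_fit(hill1, c, y, p0=p0, maxfev=10000,
                                bounds=([0, 1e-12], [np.inf, np.inf]))
        rss_sat = float(np.sum((hill1(c, *popt) - y) ** 2))
        aicc_sat = _aicc(rss_sat, len(c), 2)
        sat_params = {"Bmax": float(popt[0]), "Kd": float(popt[1]), "rss": rss_sat}
    except RuntimeError:
        pass

    saturating = (
        sat_params is not None
        and aicc_sat + delta_aicc <= aicc_lin
        and sat_params["Kd"] <= float(c.max())
    )
    fit = {
        "linear": {"slope": float(slope), "intercept": float(intercept), "rss": rss_lin,
                   "aicc": aicc_lin},
        "saturation": ({**sat_params, "aicc": float(aicc_sat)} if sat_params else None),
    }
    return BindingCurve(
        x=c, y=y, model_fit=fit,
        classification="saturating" if saturating else "non_saturating",
    )


def _logistic_decay(v, cv50, width):
    return 1.0 / (1.0 + np.exp((v - cv50) / width))


def bound_fraction(result: DeconvolutionResult, species_label: str) -> float:
    """Fraction of a species' intensity carrying at least one adduct."""
    tot = bound = 0.0
    for a in result.assignments:
        if a.species.name == species_label or species_label == "*":
            tot += a.matched_intensity
            if a.n_adducts >= 1:
                bound += a.matched_intensity
    if tot <= 0:
        raise ValueError(f"no intensity assigned to species {species_label!r}")
    return bound / tot


def dissociation_curve(
    spectra: Sequence[MassSpectrum],
    species: SpeciesModel,
    tolerance_ppm: float = 150.0,
    noise_tolerance: float = 0.05,
) -> BindingCurve:
    """Bound fraction vs collision voltage with a logistic fit and CV50.

    The species model must allow at least one adduct so that bound and
    unbound populations are resolvable.  If the bound fraction never falls
    below 0.5 in range, the CV50 is censored and reported as a lower bound.
    """
    if len(spectra) < 4:
        raise ValueError("need spectra at >=4 collision voltages")
    if species.max_adducts < 1:
        raise ValueError("species model must allow >=1 adduct")
    volts, fracs = [], []
    for sp in spectra:
        v = sp.collision_voltage
        if v is None:
            raise ValueError("every spectrum needs collision_voltage metadata")
        res = deconvolve(sp, [species], tolerance_ppm=tolerance_ppm)
        volts.append(v)
        fracs.append(bound_fraction(res, species.name))
    order = np.argsort(volts)
    v = np.asarray(volts, float)[order]
    f = np.asarray(fracs, float)[order]

    flags = []
    rises = np.diff(f)
    if np.any(rises > noise_tolerance):
        flags.append("non_monotonic")

    vspan = v[-1] - v[0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _logistic_decay, v, f,
                p0=(float(np.median(v)), max(vspan / 10, 1.0)),
                bounds=([v[0] - 2 * vspan, 1e-3], [v[-1] + 2 * vspan, 10 * vspan]),
                maxfev=10000,
            )
        cv50, width = float(popt[0]), float(popt[1])
        rss = float(np.sum((_logistic_decay(v, *popt) - f) ** 2))
    except RuntimeError:
        cv50, width, rss = float("nan"), float("nan"), float("nan")
        flags.append("fit_failed")

    censored = f.min() > 0.5 or not (v[0] <= cv50 <= v[-1])
    fit = {"cv50": cv50, "width": width, "rss": rss}
    return BindingCurve(
        x=v, y=f, model_fit=fit,
        classification="sigmoidal" if not censored else "censored",
        cv50=None if censored else cv50,
        cv50_censored=censored,
        cv50_lower_bound=float(v[-1]) if censored else None,
        flags=flags,
    )


def rank_by_cv50(curves: dict[str, BindingCurve]) -> list[str]:
    """Gas-phase stability ranking: higher CV50 (or censored) first."""
    def key(item):
        name, c = item
        val = c.cv50 if c.cv50 is not None else (c.cv50_lower_bound or 0) + 1e9
        return -val
    return [name for name, _ in sorted(curves.items(), key=key)]
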