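"""Boltzmann inversion, harmonic fits and characteristic frequencies.

An angle distribution p(θ) sampled at temperature T is inverted to a free
energy profile G(θ) = −k_B·T·ln p(θ) (minimum shifted to zero). If the well
is parabolic, a weighted quadratic fit G = ½·k·(θ−θ₀)² yields the torsional
force constant k (kcal·mol⁻¹·rad⁻²; degrees are a display unit only). With
a reduced moment of inertia I for the two rigid bodies rotating against
each other about the torsion axis, the undamped characteristic frequency is

    f = (1/2π) · √(k/I)

For a Gaussian (harmonic/Ornstein–Uhlenbeck) distribution with standard
deviation σ the identity k = k_B·T/σ² links the fit to the sample width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .constants import AMU_A2_IN_KG_M2, KCAL_PER_MOL_IN_J, kbt_kcal_per_mol
from .errors import (
    DegenerateDistributionError,
    DegenerateGeometryError,
    InsufficientDataError,
    NonParabolicError,
    ValidationError,
)
from .series import AngleSeries
from .spectral import unwrap_periodic
from .structure import StructureFrame


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Boltzmann-inverted free energy over angle bins (empty bins dropped)."""

    bin_centers_deg: np.ndarray
    g_kcal_per_mol: np.ndarray   # min-shifted to 0
    counts: np.ndarray
    temperature_k: float
    n_samples: int

    def __post_init__(self):
        if self.counts.sum() != self.n_samples:
            raise ValidationError("profile counts must sum to the sample count")
        if self.g_kcal_per_mol.size and abs(self.g_kcal_per_mol.min()) > 1e-12:
            raise ValidationError("profile minimum must be shifted to zero")


@dataclass(frozen=True)
class HarmonicFit:
    """Quadratic fit G = ½·k·(θ−θ₀)² of a free-energy profile."""

    k_kcal_per_mol_rad2: float
    theta0_deg: float
    r_squared: float
    fit_window_kcal_per_mol: float
    n_bins_used: int


@dataclass(frozen=True)
class FrequencyEstimate:
    """Undamped harmonic-oscillator frequency from (k, I)."""

    f_ghz: float
    k_kcal_per_mol_rad2: float
    inertia_amu_a2: float


def free_energy_profile(series: AngleSeries, cfg: AnalysisConfig | None = None
                        ) -> FreeEnergyProfile:
    """Histogram a series and Boltzmann-invert it.

    Periodic series are unwrapped first so a well straddling ±180° stays a
    single well. Needs ≥ 100 samples; a distribution confined to a single
    bin cannot be inverted.
    """
    cfg = cfg or AnalysisConfig()
    series.require_min_length(100)
    x = unwrap_periodic(series).values
    w = cfg.histogram_bin_width_deg
    lo = np.floor(x.min() / w) * w
    hi = np.ceil(x.max() / w) * w
    if hi <= lo + w:  # all samples inside one bin span
        raise DegenerateDistributionError(
            f"series '{series.name}' spans a single {w}° bin")
    edges = np.arange(lo, hi + 0.5 * w, w)
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    counts, centers = counts[keep], centers[keep]
    if counts.size < 2:
        raise DegenerateDistributionError(
            f"series '{series.name}': fewer than two occupied bins")
    p = counts / counts.sum()
    g = -kbt_kcal_per_mol(cfg.temperature_k) * np.log(p)
    g -= g.min()
    return FreeEnergyProfile(bin_centers_deg=centers, g_kcal_per_mol=g,
                             counts=counts, temperature_k=cfg.temperature_k,
                             n_samples=int(counts.sum()))


def fit_harmonic(profile: FreeEnergyProfile,
                 cfg: AnalysisConfig | None = None) -> HarmonicFit:
    """Weighted least-squares parabola over the bins within the fit window.

    Only bins with G no more than ``fit_window_kbt``·k_B·T above the minimum
    enter the fit (the harmonic-approximation regime); weights are per-bin
    counts. θ is converted to radians internally so k comes out per rad².
    An r² below ~0.9 flags a profile that is not credibly parabolic.
    """
    cfg = cfg or AnalysisConfig()
    window = cfg.fit_window_kbt * kbt_kcal_per_mol(profile.temperature_k)
    sel = profile.g_kcal_per_mol <= window
    if sel.sum() < 5:
        raise InsufficientDataError(
            f"only {int(sel.sum())} bins inside the {window:.3f} kcal/mol window")
    theta = np.radians(profile.bin_centers_deg[sel])
    g = profile.g_kcal_per_mol[sel]
    wgt = profile.counts[sel].astype(float)
    coeffs = np.polynomial.polynomial.polyfit(theta, g, deg=2, w=np.sqrt(wgt))
    c0, c1, c2 = coeffs
    if c2 <= 0:
        raise NonParabolicError("fitted curvature is not positive")
    k = 2.0 * c2
    theta0 = -c1 / (2.0 * c2)
    fitted = c0 + c1 * theta + c2 * theta**2
    gbar = np.average(g, weights=wgt)
    ss_res = np.sum(wgt * (g - fitted) ** 2)
    ss_tot = np.sum(wgt * (g - gbar) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    lo, hi = profile.bin_centers_deg.min(), profile.bin_centers_deg.max()
    theta0_deg = float(np.degrees(theta0))
    if not lo <= theta0_deg <= hi:
        raise NonParabolicError(
            f"fitted minimum {theta0_deg:.2f}° outside the data range")
    return HarmonicFit(k_kcal_per_mol_rad2=float(k), theta0_deg=theta0_deg,
                       r_squared=float(max(0.0, min(1.0, r2))),
                       fit_window_kcal_per_mol=float(window),
                       n_bins_used=int(sel.sum()))


def torsional_inertia(frame: StructureFrame, group_a: np.ndarray,
                      group_b: np.ndarray, axis_point1, axis_point2) -> float:
    """Reduced moment of inertia (amu·Å²) of two atom groups about an axis.

    Each group's inertia is Σ mᵢ·dᵢ² with dᵢ the perpendicular distance to
    the axis line; the two-body reduced value I_a·I_b/(I_a+I_b) is returned,
    the classical-mechanics inertia for two rigid bodies counter-rotating
    about a shared axis.
    """
    p1 = np.asarray(axis_point1, dtype=float)
    p2 = np.asarray(axis_point2, dtype=float)
    u = p2 - p1
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        raise DegenerateGeometryError("torsion axis points coincide")
    u = u / nu

    def group_inertia(indices) -> float:
        indices = np.asarray(indices, dtype=int)
        if indices.size == 0:
            raise ValidationError("empty atom group")
        r = frame.coords[indices] - p1
        perp = r - np.outer(r @ u, u)
        d2 = np.einsum("ij,ij->i", perp, perp)
        return float(np.dot(frame.masses[indices], d2))

    ia, ib = group_inertia(group_a), group_inertia(group_b)
    if ia <= 0 or ib <= 0:
        raise DegenerateGeometryError("a group lies entirely on the axis")
    return ia * ib / (ia + ib)


def characteristic_frequency(k_kcal_per_mol_rad2: float,
                             inertia_amu_a2: float) -> FrequencyEstimate:
    """Undamped oscillator frequency f = (1/2π)·√(k/I), in GHz."""
    if not k_kcal_per_mol_rad2 > 0:
        raise ValidationError("force constant must be positive")
    if not inertia_amu_a2 > 0:
        raise ValidationError("inertia must be positive")
    k_si = k_kcal_per_mol_rad2 * KCAL_PER_MOL_IN_J          # J / rad²
    i_si = inertia_amu_a2 * AMU_A2_IN_KG_M2                 # kg m²
    omega = np.sqrt(k_si / i_si)                            # rad / s
    return FrequencyEstimate(
        f_ghz=float(omega / (2.0 * np.pi) / 1e9),
        k_kcal_per_mol_rad2=k_kcal_per_mol_rad2,
        inertia_amu_a2=inertia_amu_a2,
    )
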