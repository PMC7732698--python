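"""Synthetic inputs with known ground truth.

Three generators stand in for molecular-dynamics data:

* :func:`simulate_ou` — stationary Ornstein–Uhlenbeck angle series: Gaussian
  fluctuations in a parabolic free-energy well of force constant k at
  temperature T, with correlation time τ. The exact discretization is used,
  so the stationary variance k_B·T/k is exact at any sampling interval.
* :func:`simulate_harmonic` — a deterministic, frictionless harmonic
  torsional oscillation at the characteristic frequency implied by (k, I).
* :func:`build_toy_fab` / :func:`animate_toy_fab` — rigid four-domain bead
  models whose elbow torsion, C_H1–C_L torsion and V_H–V_L pose evaluate
  exactly to prescribed values, together with the matching domain partition.
  These are geometric oracles only; they carry no force-field physics and no
  claim of conformational realism.

All randomness is owned by a seed field on the parameter objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.signal import lfilter
from scipy.spatial.transform import Rotation

from .config import AnalysisConfig, FabPartition
from .constants import kbt_kcal_per_mol
from .errors import ConstructionError, ValidationError
from .geometry import ReferenceFrame, load_reference, torsion_angle, wrap_angle
from .series import AngleSeries
from .structure import ResidueSelection, StructureFrame, write_pdb
from .thermo import characteristic_frequency


# ---------------------------------------------------------------------------
# Stochastic and deterministic angle series


@dataclass(frozen=True)
class OUParams:
    """Ornstein–Uhlenbeck parameters: force constant k (kcal·mol⁻¹·rad⁻²),
    well minimum θ₀ (deg), temperature (K), correlation time τ (ps),
    sampling interval (ps), sample count and seed."""

    k_kcal_per_mol_rad2: float
    theta0_deg: float = 0.0
    temperature_k: float = 300.0
    tau_ps: float = 100.0
    dt_ps: float = 1.0
    n: int = 100_000
    seed: int = 0

    def __post_init__(self):
        for name in ("k_kcal_per_mol_rad2", "temperature_k", "tau_ps", "dt_ps"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"OU parameter {name} must be positive")
        if self.n < 2:
            raise ValidationError("OU series needs n >= 2")

    @property
    def sigma_deg(self) -> float:
        """Stationary standard deviation √(k_B·T/k), in degrees."""
        sigma_rad = np.sqrt(kbt_kcal_per_mol(self.temperature_k)
                            / self.k_kcal_per_mol_rad2)
        return float(np.degrees(sigma_rad))


def simulate_ou(p: OUParams) -> AngleSeries:
    """Exact-discretization OU updates:

    θ_{t+dt} = θ₀ + (θ_t − θ₀)·e^(−dt/τ) + σ·√(1 − e^(−2dt/τ))·z,

    started from a stationary draw, so every marginal is N(θ₀, σ²) with
    σ² = k_B·T/k (in radians internally).
    """
    if p.dt_ps >= p.tau_ps / 2:
        warnings.warn(
            f"dt = {p.dt_ps} ps does not resolve tau = {p.tau_ps} ps "
            "(dt < tau/2 recommended)", stacklevel=2)
    rng = np.random.default_rng(p.seed)
    phi = np.exp(-p.dt_ps / p.tau_ps)
    sigma = p.sigma_deg  # work in degrees; the process is linear
    z = rng.standard_normal(p.n)
    innovations = np.empty(p.n)
    innovations[0] = sigma * z[0]
    innovations[1:] = sigma * np.sqrt(1.0 - phi * phi) * z[1:]
    centered = lfilter([1.0], [1.0, -phi], innovations)
    return AngleSeries(values=p.theta0_deg + centered, dt_ps=p.dt_ps,
                       periodic=True, name="ou")


def simulate_harmonic(k_kcal_per_mol_rad2: float, inertia_amu_a2: float,
                      amplitude_deg: float, dt_ps: float, n: int,
                      theta0_deg: float = 0.0) -> AngleSeries:
    """Deterministic θ(t) = θ₀ + A·cos(2π f t) with f the undamped
    characteristic frequency of (k, I)."""
    if amplitude_deg < 0 or dt_ps <= 0 or n < 2:
        raise ValidationError("amplitude >= 0, dt > 0 and n >= 2 required")
    est = characteristic_frequency(k_kcal_per_mol_rad2, inertia_amu_a2)
    f_per_ps = est.f_ghz / 1000.0
    t = np.arange(n) * dt_ps
    values = theta0_deg + amplitude_deg * np.cos(2.0 * np.pi * f_per_ps * t)
    return AngleSeries(values=values, dt_ps=dt_ps, periodic=True,
                       name="harmonic")


# ---------------------------------------------------------------------------
# Toy Fab construction


@dataclass(frozen=True)
class ToyFabSpec:
    """Prescription for a rigid four-domain bead Fab.

    ``beads_per_domain`` and ``bead_mass_amu`` default to 24 beads of
    500 amu — a ~12 kDa immunoglobulin domain at coarse resolution, which
    puts torsional inertias in the 10⁶–10⁷ amu·Å² range of real Fab modules.
    """

    elbow_deg: float = 160.0
    ch1cl_deg: float = 100.0
    vhvl_rotation_deg: float = 0.0
    dc_angstrom: float = 16.0
    beads_per_domain: int = 24
    bead_mass_amu: float = 500.0
    domain_radius_angstrom: float = 8.0
    seed: int = 0

    def __post_init__(self):
        for name, val in (("elbow_deg", self.elbow_deg),
                          ("ch1cl_deg", self.ch1cl_deg)):
            if not -180.0 < val <= 180.0:
                raise ConstructionError(
                    f"{name} = {val} outside (-180, 180]")
        if not self.dc_angstrom > 0:
            raise ConstructionError("dc must be positive")
        if self.beads_per_domain < 8:
            raise ConstructionError("need at least 8 beads per domain")
        if not self.bead_mass_amu > 0:
            raise ConstructionError("bead mass must be positive")


# geometric layout constants (Å): hinge separation, module COM offsets
_HINGE_SEP = 12.0
_MODULE_RADIAL = 28.0
_V_AXIAL = -20.0
_C_AXIAL_OFFSET = 20.0
_CH1_CL_SEP = 22.0
_LOOP_RADIAL = 10.0


def _azimuth_torsion_sign() -> float:
    """Sign s such that torsion(p1, a, b, p4) = s·γ when the central bond is
    +z, p1 sits at azimuth 0 and p4 at azimuth γ."""
    t = torsion_angle((1.0, 0.0, -1.0), (0.0, 0.0, 0.0),
                      (0.0, 0.0, 1.0), (np.cos(0.5), np.sin(0.5), 2.0))
    return 1.0 if t > 0 else -1.0


def _cluster_with_com(rng, n: int, com: np.ndarray, radius: float) -> np.ndarray:
    """n >= 2 beads scattered around `com` whose exact mean is `com`
    (equal masses assumed): the last bead balances the others."""
    if n < 2:
        raise ConstructionError("cluster needs at least 2 beads")
    pts = com + rng.uniform(-radius, radius, size=(n - 1, 3))
    balance = n * com - pts.sum(axis=0)
    if np.linalg.norm(balance - com) > 50.0 * radius:
        raise ConstructionError("balancing bead unreasonably far from cluster")
    return np.vstack([pts, balance])


def _loop_triplet(com: np.ndarray) -> np.ndarray:
    """Three beads with exact COM `com` (offset pair along x plus center)."""
    d = np.array([1.5, 0.0, 0.0])
    return np.vstack([com + d, com - d, com])


class ToyFab:
    """A built toy Fab: frame + partition plus the construction metadata
    needed to animate the elbow (hinge axis and base elbow value)."""

    def __init__(self, frame: StructureFrame, partition: FabPartition,
                 spec: ToyFabSpec, c_module_indices: np.ndarray,
                 hinge_point: np.ndarray, hinge_dir: np.ndarray):
        self.frame = frame
        self.partition = partition
        self.spec = spec
        self.c_module_indices = c_module_indices
        self.hinge_point = hinge_point
        self.hinge_dir = hinge_dir


def build_toy_fab(spec: ToyFabSpec,
                  ref: ReferenceFrame | None = None) -> ToyFab:
    """Construct a rigid bead Fab realizing the prescription exactly.

    The variable module carries the packaged Fv reference cores in the
    prescribed mutual pose (rotation about C and dc), so the ABangle-style
    measures recover the prescription; module COMs are placed so the elbow
    and C_H1–C_L torsions equal the prescribed values by construction.
    """
    ref = ref or load_reference()
    rng = np.random.default_rng(spec.seed)
    s = _azimuth_torsion_sign()
    nb = spec.beads_per_domain
    n_core = len(ref.h_labels)
    if nb < n_core:
        raise ConstructionError(
            f"beads_per_domain must be >= the reference core size {n_core}")

    # --- variable module (local build, then translated onto its COM target)
    l_core = ref.l_coords.copy()
    c_hat = ref.h_frame.origin - ref.l_frame.origin
    c_hat = c_hat / np.linalg.norm(c_hat)
    origin_h = ref.l_frame.origin + spec.dc_angstrom * c_hat
    h_core = ref.h_coords + (origin_h - ref.h_frame.origin)
    if abs(spec.vhvl_rotation_deg) > 0:
        rot = Rotation.from_rotvec(np.radians(spec.vhvl_rotation_deg) * c_hat)
        h_core = rot.apply(h_core - origin_h) + origin_h

    n_fill = nb - n_core
    r = spec.domain_radius_angstrom
    h_fill = origin_h + rng.uniform(-r, r, size=(n_fill, 3))
    l_fill = ref.l_frame.origin + rng.uniform(-r, r, size=(n_fill, 3))
    vh_pts = np.vstack([h_core, h_fill]) if n_fill else h_core
    vl_pts = np.vstack([l_core, l_fill]) if n_fill else l_core

    # --- constant module (local build with the prescribed internal torsion)
    p_ch1 = np.array([0.0, 0.0, 0.0])
    p_cl = np.array([0.0, 0.0, _CH1_CL_SEP])
    p_loop_h = np.array([_LOOP_RADIAL, 0.0, -6.0])
    g_c = np.radians(s * spec.ch1cl_deg)
    p_loop_l = np.array([_LOOP_RADIAL * np.cos(g_c),
                         _LOOP_RADIAL * np.sin(g_c), _CH1_CL_SEP + 6.0])
    n_rest = nb - 3

    def constant_domain(p_com, p_loop):
        # rest beads around q so that (3·p_loop + n_rest·q)/nb = p_com
        q = (nb * p_com - 3 * p_loop) / n_rest
        return _cluster_with_com(rng, n_rest, q, 4.0), _loop_triplet(p_loop)

    ch1_rest, ch1_loops = constant_domain(p_ch1, p_loop_h)
    cl_rest, cl_loops = constant_domain(p_cl, p_loop_l)

    # --- global assembly about the hinge axis (z)
    hinge_h = np.zeros(3)
    hinge_l = np.array([0.0, 0.0, _HINGE_SEP])
    v_target = np.array([_MODULE_RADIAL, 0.0, _V_AXIAL])
    g_e = np.radians(s * spec.elbow_deg)
    c_target = np.array([_MODULE_RADIAL * np.cos(g_e),
                         _MODULE_RADIAL * np.sin(g_e),
                         _HINGE_SEP + _C_AXIAL_OFFSET])

    v_all = np.vstack([vh_pts, vl_pts])
    v_shift = v_target - v_all.mean(axis=0)
    vh_pts, vl_pts = vh_pts + v_shift, vl_pts + v_shift

    c_all = np.vstack([ch1_rest, ch1_loops, cl_rest, cl_loops])
    c_shift = c_target - c_all.mean(axis=0)
    ch1_rest, ch1_loops = ch1_rest + c_shift, ch1_loops + c_shift
    cl_rest, cl_loops = cl_rest + c_shift, cl_loops + c_shift

    hh_pts = _loop_triplet(hinge_h)
    hl_pts = _loop_triplet(hinge_l)

    # --- residue numbering: per chain V, switch, C(rest..loops last)
    def chain_blocks(vpts, swpts, rest, loops):
        coords = np.vstack([vpts, swpts, rest, loops])
        res = np.arange(1, len(coords) + 1)
        return coords, res

    h_coords, h_res = chain_blocks(vh_pts, hh_pts, ch1_rest, ch1_loops)
    l_coords, l_res = chain_blocks(vl_pts, hl_pts, cl_rest, cl_loops)

    n_atoms = len(h_coords) + len(l_coords)
    frame = StructureFrame(
        chain_ids=np.array(["H"] * len(h_coords) + ["L"] * len(l_coords)),
        res_ids=np.concatenate([h_res, l_res]),
        ins_codes=np.full(n_atoms, "", dtype="U2"),
        res_names=np.full(n_atoms, "ALA", dtype="U5"),
        atom_names=np.full(n_atoms, "CA", dtype="U6"),
        elements=np.full(n_atoms, "C", dtype="U4"),
        masses=np.full(n_atoms, spec.bead_mass_amu),
        coords=np.vstack([h_coords, l_coords]),
    )

    def sel(chain, lo, hi, name):
        return ResidueSelection(chain_id=chain, ranges=((lo, hi),), name=name)

    sw_lo, sw_hi = nb + 1, nb + 3
    cdom_lo, cdom_hi = nb + 4, 2 * nb + 3
    loops_lo = cdom_lo + n_rest
    core_res = tuple(range(1, n_core + 1))
    nrest_pairs = min(n_rest, 8)
    partition = FabPartition(
        vh=sel("H", 1, nb, "vh"),
        vl=sel("L", 1, nb, "vl"),
        switch_heavy=sel("H", sw_lo, sw_hi, "switch_heavy"),
        switch_light=sel("L", sw_lo, sw_hi, "switch_light"),
        ch1=sel("H", cdom_lo, cdom_hi, "ch1"),
        cl=sel("L", cdom_lo, cdom_hi, "cl"),
        ch1_cterm_loops=sel("H", loops_lo, cdom_hi, "ch1_cterm_loops"),
        cl_cterm_loops=sel("L", loops_lo, cdom_hi, "cl_cterm_loops"),
        v_pairs=tuple((("H", i), ("L", i)) for i in core_res),
        c_pairs=tuple((("H", cdom_lo + i), ("L", cdom_lo + i))
                      for i in range(nrest_pairs)),
        vh_core_residues=core_res,
        vl_core_residues=core_res,
    )

    c_module_indices = np.nonzero(
        ((frame.chain_ids == "H") | (frame.chain_ids == "L"))
        & (frame.res_ids >= cdom_lo) & (frame.res_ids <= cdom_hi))[0]
    return ToyFab(frame=frame, partition=partition, spec=spec,
                  c_module_indices=c_module_indices,
                  hinge_point=hinge_h, hinge_dir=np.array([0.0, 0.0, 1.0]))


def iter_animated_frames(fab: ToyFab, elbow_series: AngleSeries
                         ) -> Iterator[StructureFrame]:
    """Lazily yield frames in which the constant module is rotated about the
    hinge axis so the measured elbow torsion equals the series exactly."""
    s = _azimuth_torsion_sign()
    base = fab.spec.elbow_deg
    idx = fab.c_module_indices
    for i, theta in enumerate(elbow_series.values):
        phi = np.radians(s * (wrap_angle(theta) - base))
        rot = Rotation.from_rotvec(phi * fab.hinge_dir)
        coords = fab.frame.coords.copy()
        coords[idx] = rot.apply(coords[idx] - fab.hinge_point) + fab.hinge_point
        yield fab.frame.with_coords(coords, frame_index=i,
                                    time_ps=i * elbow_series.dt_ps)


def animate_toy_fab(spec: ToyFabSpec, elbow_series: AngleSeries,
                    out_pdb=None) -> list[StructureFrame]:
    """Materialized trajectory of a toy Fab following an elbow-angle series;
    optionally written as a standard multi-model PDB."""
    fab = build_toy_fab(spec)
    frames = list(iter_animated_frames(fab, elbow_series))
    if out_pdb is not None:
        write_pdb(frames, out_pdb)
    return frames


# ---------------------------------------------------------------------------
# Classic-elbow fixture


def build_classic_elbow_fixture(elbow_deg: float, rotation_v_deg: float = 170.0,
                                rotation_c_deg: float = 165.0, seed: int = 0
                                ) -> tuple[StructureFrame, FabPartition]:
    """A four-domain point structure whose pseudo-two-fold axes realize a
    prescribed classical elbow angle (feasible range here: 70°–290°).

    The V and C dyad axes are constructed analytically with the prescribed
    mutual angle and dihedral sign, and each light-side core is the exact
    image of its heavy-side core under a rotation about the corresponding
    axis, so the least-squares superposition recovers the axes exactly.
    """
    if not 70.0 <= elbow_deg <= 290.0:
        raise ConstructionError(
            f"elbow {elbow_deg}° outside the feasible range [70°, 290°]")
    psi = elbow_deg if elbow_deg <= 180.0 else 360.0 - elbow_deg

    com_v = np.zeros(3)
    com_c = np.array([0.0, 0.0, 40.0])
    m = np.array([0.0, 0.0, 1.0])  # unit(com_c - com_v)

    theta_v, theta_c = np.radians(55.0), np.radians(125.0)
    u_v = np.array([np.sin(theta_v), 0.0, np.cos(theta_v)])
    cos_phi = ((np.cos(np.radians(psi)) - np.cos(theta_v) * np.cos(theta_c))
               / (np.sin(theta_v) * np.sin(theta_c)))
    if not -1.0 <= cos_phi <= 1.0:
        raise ConstructionError(f"elbow {elbow_deg}° not realizable here")
    phi = np.arccos(np.clip(cos_phi, -1.0, 1.0))
    # dihedral sign: positive keeps psi, negative flips to 360 - psi
    s = _azimuth_torsion_sign()
    want_negative = elbow_deg > 180.0
    phi_signed = phi if (s > 0) != want_negative else -phi
    u_c = np.array([np.sin(theta_c) * np.cos(phi_signed),
                    np.sin(theta_c) * np.sin(phi_signed), np.cos(theta_c)])

    base = np.array([
        (9, 0, 0.2), (6.3, 3.5, -0.2), (0, 5, 0.2), (-6.3, 3.5, -0.2),
        (-9, 0, 0.2), (-6.3, -3.5, -0.2), (0, -5, 0.2), (6.3, -3.5, -0.2)],
        dtype=float)
    rng = np.random.default_rng(seed)

    def dyad_pair(axis, angle_deg, com, offset):
        r0 = Rotation.random(rng=rng)
        a_pts = r0.apply(base) + (com + offset)
        rot = Rotation.from_rotvec(np.radians(angle_deg) * axis)
        b_pts = rot.apply(a_pts)
        b_pts = b_pts + ((com - offset) - b_pts.mean(axis=0))
        return a_pts, b_pts

    vh_pts, vl_pts = dyad_pair(u_v, rotation_v_deg, com_v,
                               np.array([6.0, 0.0, 0.0]))
    ch_pts, cl_pts = dyad_pair(u_c, rotation_c_deg, com_c,
                               np.array([-6.0, 0.0, 0.0]))

    n = 8
    coords = np.vstack([vh_pts, ch_pts, vl_pts, cl_pts])
    res_h = np.concatenate([np.arange(1, n + 1), np.arange(101, 101 + n)])
    res_l = res_h.copy()
    n_atoms = 4 * n
    frame = StructureFrame(
        chain_ids=np.array(["H"] * 2 * n + ["L"] * 2 * n),
        res_ids=np.concatenate([res_h, res_l]),
        ins_codes=np.full(n_atoms, "", dtype="U2"),
        res_names=np.full(n_atoms, "ALA", dtype="U5"),
        atom_names=np.full(n_atoms, "CA", dtype="U6"),
        elements=np.full(n_atoms, "C", dtype="U4"),
        masses=np.full(n_atoms, 500.0),
        coords=coords,
    )

    def sel(chain, lo, hi, name):
        return ResidueSelection(chain_id=chain, ranges=((lo, hi),), name=name)

    partition = FabPartition(
        vh=sel("H", 1, n, "vh"), vl=sel("L", 1, n, "vl"),
        switch_heavy=sel("H", 50, 52, "switch_heavy"),
        switch_light=sel("L", 50, 52, "switch_light"),
        ch1=sel("H", 101, 100 + n, "ch1"), cl=sel("L", 101, 100 + n, "cl"),
        ch1_cterm_loops=sel("H", 105, 100 + n, "ch1_cterm_loops"),
        cl_cterm_loops=sel("L", 105, 100 + n, "cl_cterm_loops"),
        v_pairs=tuple((("H", i), ("L", i)) for i in range(1, n + 1)),
        c_pairs=tuple((("H", i), ("L", i)) for i in range(101, 101 + n)),
    )
    return frame, partition
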