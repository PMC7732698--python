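"""Classical Fab elbow angle from pseudo-two-fold screw axes.

A Fab's variable module is related to itself by an approximate two-fold
rotation carrying V_H onto V_L; likewise C_H1 onto C_L. The classical elbow
angle is the angle between these two pseudo-dyad axes, reported on a
(0°, 360°) scale as is customary for Fabs (a fully extended Fab is 180°).

Convention fixed here (the literature states none precisely enough to
reproduce):

* each dyad axis is taken from the least-squares superposition of the
  heavy-side core onto the paired light-side core (rotation angle in
  (0°, 180°] from the rotation vector);
* the V axis is oriented toward the constant module (non-negative dot with
  the V-COM → C-COM direction), the C axis toward the variable module;
  exact ties fall back to +x, +y, +z;
* the elbow is the angle between the oriented axes, replaced by 360° minus
  that angle when the dihedral (V axis, V-COM → C-COM, C axis) is negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .config import AnalysisConfig, FabPartition
from .errors import (
    DegenerateGeometryError,
    IllDefinedAxisError,
    InsufficientCoreError,
)
from .geometry import _fix_sign, superpose, torsion_angle, vector_angle
from .structure import StructureFrame, center_of_mass, resolve_selection

#: rotations smaller than this do not define a stable axis
MIN_ROTATION_DEG = 5.0


@dataclass(frozen=True)
class PseudoTwofold:
    """Axis and magnitude of the rotation relating two homologous domains."""

    axis: np.ndarray
    rotation_deg: float

    def __post_init__(self):
        if not np.isclose(np.linalg.norm(self.axis), 1.0, atol=1e-9):
            raise DegenerateGeometryError("pseudo-two-fold axis must be unit length")
        if not 0.0 < self.rotation_deg < 360.0:
            raise IllDefinedAxisError(
                f"rotation {self.rotation_deg:.2f}° outside (0°, 360°)")


def _paired_ca(frame: StructureFrame, pairs):
    """Cα coordinates for each (heavy, light) residue pair."""
    a_pts, b_pts = [], []
    is_ca = frame.atom_names == "CA"
    for (ca_chain, ca_res), (cb_chain, cb_res) in pairs:
        ia = np.nonzero((frame.chain_ids == ca_chain)
                        & (frame.res_ids == int(ca_res)) & is_ca)[0]
        ib = np.nonzero((frame.chain_ids == cb_chain)
                        & (frame.res_ids == int(cb_res)) & is_ca)[0]
        if ia.size and ib.size:
            a_pts.append(frame.coords[ia[0]])
            b_pts.append(frame.coords[ib[0]])
    if len(a_pts) < 3:
        raise InsufficientCoreError(
            f"only {len(a_pts)} of {len(pairs)} Cα pairs resolvable")
    return np.array(a_pts), np.array(b_pts)


def pseudo_twofold_axis(domain_a: np.ndarray, domain_b: np.ndarray) -> PseudoTwofold:
    """Rotation axis/angle of the least-squares superposition of paired
    point set A onto point set B (≥ 3 non-collinear pairs)."""
    rot, _, _ = superpose(domain_a, domain_b)
    rotvec = rot.as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))
    if angle < MIN_ROTATION_DEG:
        raise IllDefinedAxisError(
            f"rotation {angle:.2f}° < {MIN_ROTATION_DEG}°: axis ill-defined")
    return PseudoTwofold(axis=rotvec / np.linalg.norm(rotvec),
                         rotation_deg=angle)


def classic_elbow_angle(frame: StructureFrame, part: FabPartition,
                        cfg: AnalysisConfig | None = None) -> float:
    """Classical elbow angle of one structure, degrees in (0°, 360°).

    Requires ``v_pairs`` and ``c_pairs`` in the partition (explicit
    heavy↔light Cα pairings for the two pseudo-dyads).
    """
    cfg = cfg or AnalysisConfig()
    if not part.v_pairs or not part.c_pairs:
        raise InsufficientCoreError(
            "partition defines no v_pairs / c_pairs for the pseudo-dyads")
    vh_pts, vl_pts = _paired_ca(frame, part.v_pairs)
    ch_pts, cl_pts = _paired_ca(frame, part.c_pairs)
    v_dyad = pseudo_twofold_axis(vh_pts, vl_pts)
    c_dyad = pseudo_twofold_axis(ch_pts, cl_pts)

    idx_v = np.concatenate([resolve_selection(frame, part.vh),
                            resolve_selection(frame, part.vl)])
    idx_c = np.concatenate([resolve_selection(frame, part.ch1),
                            resolve_selection(frame, part.cl)])
    com_v = center_of_mass(frame, idx_v, cfg.com_weighting)
    com_c = center_of_mass(frame, idx_c, cfg.com_weighting)
    m = com_c - com_v
    nm = np.linalg.norm(m)
    if nm < 1e-9:
        raise DegenerateGeometryError("coincident module COMs")
    m = m / nm

    v_axis = _fix_sign(v_dyad.axis, m)      # toward the constant module
    c_axis = _fix_sign(c_dyad.axis, -m)     # toward the variable module
    psi = vector_angle(v_axis, c_axis)
    # at (anti)parallel axes the dihedral is undefined and unnecessary
    if psi < 1e-6 or psi > 180.0 - 1e-6:
        return psi
    chi = torsion_angle(com_v + 20.0 * v_axis, com_v, com_c,
                        com_c + 20.0 * c_axis)
    return psi if chi >= 0 else 360.0 - psi
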