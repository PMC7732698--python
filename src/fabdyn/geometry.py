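"""Angle measures on Fab structures.

Three families of measures characterize a Fab's internal pose:

* the elbow torsion — dihedral of COM(variable module), COM(hinge heavy),
  COM(hinge light), COM(constant module);
* the C_H1–C_L interface torsion — dihedral of COM(C_H1 C-terminal loops),
  COM(C_H1), COM(C_L), COM(C_L C-terminal loops);
* six ABangle-style V_H–V_L orientation measures (HL, HC1, HC2, LC1, LC2,
  dc) built from planes fitted to a packaged idealized Fv reference core.

Torsion sign convention is IUPAC: looking along the central bond (from the
second to the third point), a clockwise rotation of the far bond is positive;
values lie in (−180°, +180°].

The packaged reference core is NOT the consensus data of the original
ABangle tool, so absolute measure values are not comparable with published
ABangle numbers — differences, shifts and distribution widths are. A custom
reference may be supplied to reproduce another convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .config import AnalysisConfig, FabPartition
from .errors import (
    DegenerateGeometryError,
    InsufficientCoreError,
    SamplingError,
    ValidationError,
)
from .series import AngleSeries
from .structure import StructureFrame, center_of_mass, resolve_selection

#: ratio of 2nd to 3rd singular value below which a point cloud is judged
#: too thick (or too linear) to define a plane
PLANE_CONDITION_MIN = 10.0

MEASURES = ("elbow", "ch1cl", "HL", "HC1", "HC2", "LC1", "LC2", "dc")


def torsion_angle(p1, p2, p3, p4) -> float:
    """Dihedral of four points, degrees in (−180, +180], IUPAC sign.

    Raises DegenerateGeometryError when consecutive points coincide or the
    middle three points are collinear (the half-planes are then undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    scale = max(np.linalg.norm(b) for b in (b1, b2, b3))
    if scale == 0.0:
        raise DegenerateGeometryError("torsion: coincident points")
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-12 * scale:
            raise DegenerateGeometryError("torsion: consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    tol = 1e-12 * scale * scale
    if np.linalg.norm(n1) < tol or np.linalg.norm(n2) < tol:
        raise DegenerateGeometryError("torsion: collinear points")
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 + 1e-15 else float(ang)


def vector_angle(u, v) -> float:
    """Unsigned angle between two vectors, degrees in [0, 180]."""
    u, v = np.asarray(u, dtype=float), np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateGeometryError("angle with a zero vector")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def wrap_angle(deg: float) -> float:
    """Map an angle to (−180, +180]."""
    wrapped = (float(deg) + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


# ---------------------------------------------------------------------------
# Domain planes and the ABangle-style reference


@dataclass(frozen=True)
class DomainFrame:
    """Origin plus an orthonormal (axis1, axis2, normal) triad of a domain."""

    origin: np.ndarray
    plane_normal: np.ndarray
    axis1: np.ndarray
    axis2: np.ndarray

    def __post_init__(self):
        triad = np.stack([self.axis1, self.axis2, self.plane_normal])
        if not np.allclose(triad @ triad.T, np.eye(3), atol=1e-9):
            raise ValidationError("DomainFrame axes must be orthonormal")

    def transformed(self, rot: Rotation, translation: np.ndarray) -> "DomainFrame":
        return DomainFrame(
            origin=rot.apply(self.origin) + translation,
            plane_normal=rot.apply(self.plane_normal),
            axis1=rot.apply(self.axis1),
            axis2=rot.apply(self.axis2),
        )


_TIE_BREAK_DIRS = (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]),
                   np.array([0, 0, 1.0]))


def _fix_sign(axis: np.ndarray, preferred) -> np.ndarray:
    """Flip `axis` so it points along `preferred`; ties fall through the
    fixed +x, +y, +z sequence."""
    candidates = ([preferred] if preferred is not None else []) + list(_TIE_BREAK_DIRS)
    for d in candidates:
        dot = float(np.dot(axis, d))
        if abs(dot) > 1e-12:
            return axis if dot > 0 else -axis
    return axis


def fit_domain_plane(coords, ref_dir1=None, ref_dir2=None) -> DomainFrame:
    """Least-squares plane through a point cloud via PCA.

    The in-plane axes are the first two principal axes of the centered
    coordinates; the normal is their cross product. Axis signs are flipped
    toward the supplied reference directions (default tie-break +x, +y, +z).
    The cloud must be plate-like: the ratio of the 2nd to the 3rd singular
    value must exceed ``PLANE_CONDITION_MIN``.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 3:
        raise ValidationError("plane fit needs an (n>=3, 3) coordinate array")
    origin = coords.mean(axis=0)
    centered = coords - origin
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-12 or s[1] < 1e-9 * s[0]:
        raise DegenerateGeometryError("plane fit: points are collinear")
    if s[2] > 1e-12 * s[0] and s[1] / s[2] <= PLANE_CONDITION_MIN:
        raise DegenerateGeometryError(
            f"plane fit: cloud not planar enough "
            f"(s2/s3 = {s[1] / s[2]:.2f} <= {PLANE_CONDITION_MIN})")
    axis1 = _fix_sign(vt[0], ref_dir1)
    axis2 = _fix_sign(vt[1], ref_dir2)
    normal = np.cross(axis1, axis2)
    return DomainFrame(origin=origin, plane_normal=normal,
                       axis1=axis1, axis2=axis2)


@dataclass(frozen=True)
class ReferenceFrame:
    """Idealized Fv core: labelled Cα positions per variable domain plus the
    canonical plane frame fitted through each."""

    h_labels: tuple[int, ...]
    h_coords: np.ndarray
    l_labels: tuple[int, ...]
    l_coords: np.ndarray
    h_frame: DomainFrame
    l_frame: DomainFrame

    @classmethod
    def from_cores(cls, h_labels, h_coords, l_labels, l_coords) -> "ReferenceFrame":
        h_coords = np.asarray(h_coords, dtype=float)
        l_coords = np.asarray(l_coords, dtype=float)
        if len(h_labels) != len(h_coords) or len(l_labels) != len(l_coords):
            raise ValidationError("reference labels/coordinates length mismatch")
        if len(h_coords) < 3 or len(l_coords) < 3:
            raise InsufficientCoreError("reference core needs >= 3 positions per domain")
        return cls(
            h_labels=tuple(int(x) for x in h_labels), h_coords=h_coords,
            l_labels=tuple(int(x) for x in l_labels), l_coords=l_coords,
            h_frame=fit_domain_plane(h_coords),
            l_frame=fit_domain_plane(l_coords),
        )


def load_reference(path=None) -> ReferenceFrame:
    """Load the packaged idealized Fv reference core (or a user file).

    File format: whitespace-separated columns ``domain label x y z`` with
    domain H or L; lines starting with ``#`` are comments.
    """
    if path is None:
        text = resources.files("fabdyn").joinpath(
            "data/fv_reference.txt").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cores = {"H": ([], []), "L": ([], [])}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 5 or parts[0] not in cores:
            raise ValidationError(f"malformed reference line: {line!r}")
        cores[parts[0]][0].append(int(parts[1]))
        cores[parts[0]][1].append([float(x) for x in parts[2:5]])
    return ReferenceFrame.from_cores(
        cores["H"][0], np.array(cores["H"][1]),
        cores["L"][0], np.array(cores["L"][1]))


def superpose(ref_coords: np.ndarray, obs_coords: np.ndarray
              ) -> tuple[Rotation, np.ndarray, float]:
    """Least-squares rigid superposition of ``ref_coords`` onto
    ``obs_coords``; returns (rotation, translation, rmsd) with
    ``obs ≈ rot.apply(ref) + translation``."""
    ref = np.asarray(ref_coords, dtype=float)
    obs = np.asarray(obs_coords, dtype=float)
    if ref.shape != obs.shape or ref.shape[0] < 3:
        raise ValidationError("superposition needs matching (n>=3, 3) arrays")
    ref_c, obs_c = ref.mean(axis=0), obs.mean(axis=0)
    rot, rssd = Rotation.align_vectors(obs - obs_c, ref - ref_c)
    translation = obs_c - rot.apply(ref_c)
    return rot, translation, float(rssd / np.sqrt(ref.shape[0]))


# ---------------------------------------------------------------------------
# COM torsions


def _com_of(frame, part, sel_names, cfg) -> np.ndarray:
    idx = np.concatenate([
        resolve_selection(frame, getattr(part, name)) for name in sel_names
    ])
    return center_of_mass(frame, idx, cfg.com_weighting)


def elbow_angle(frame: StructureFrame, part: FabPartition,
                cfg: AnalysisConfig | None = None) -> float:
    """COM-torsion elbow: variable-module COM, hinge-heavy COM, hinge-light
    COM, constant-module COM (degrees)."""
    cfg = cfg or AnalysisConfig()
    return torsion_angle(
        _com_of(frame, part, ("vh", "vl"), cfg),
        _com_of(frame, part, ("switch_heavy",), cfg),
        _com_of(frame, part, ("switch_light",), cfg),
        _com_of(frame, part, ("ch1", "cl"), cfg),
    )


def ch1_cl_angle(frame: StructureFrame, part: FabPartition,
                 cfg: AnalysisConfig | None = None) -> float:
    """COM-torsion of the C_H1–C_L interface: C_H1 C-terminal-loop COM,
    C_H1 COM, C_L COM, C_L C-terminal-loop COM (degrees)."""
    cfg = cfg or AnalysisConfig()
    return torsion_angle(
        _com_of(frame, part, ("ch1_cterm_loops",), cfg),
        _com_of(frame, part, ("ch1",), cfg),
        _com_of(frame, part, ("cl",), cfg),
        _com_of(frame, part, ("cl_cterm_loops",), cfg),
    )


# ---------------------------------------------------------------------------
# ABangle-style V_H–V_L measures


@dataclass(frozen=True)
class AbangleMeasures:
    """Six V_H–V_L orientation measures: the inter-plane torsion HL, four
    tilt angles of the in-plane axes against the interdomain vector C, and
    the interdomain distance dc.

    C points from the light-domain origin to the heavy-domain origin, so a
    positive rotation of the V_H frame about C increases HL by the same
    amount."""

    HL: float
    HC1: float
    HC2: float
    LC1: float
    LC2: float
    dc: float

    def __post_init__(self):
        vals = (self.HL, self.HC1, self.HC2, self.LC1, self.LC2, self.dc)
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError("ABangle measures must be finite")
        if not self.dc > 0:
            raise ValidationError("dc must be positive")

    def as_dict(self) -> dict[str, float]:
        return {"HL": self.HL, "HC1": self.HC1, "HC2": self.HC2,
                "LC1": self.LC1, "LC2": self.LC2, "dc": self.dc}


def _observed_core(frame, chain_id, core_residues, labels):
    """Cα positions of the resolvable core residues, with the matching
    reference-label indices."""
    if len(core_residues) != len(labels):
        raise ValidationError(
            "partition core residue list does not match the reference core size")
    keep_ref, obs = [], []
    is_ca = frame.atom_names == "CA"
    for i, res in enumerate(core_residues):
        hits = np.nonzero((frame.chain_ids == chain_id)
                          & (frame.res_ids == int(res)) & is_ca)[0]
        if hits.size:
            keep_ref.append(i)
            obs.append(frame.coords[hits[0]])
    if len(obs) < 3:
        raise InsufficientCoreError(
            f"only {len(obs)} of {len(labels)} core Cα positions resolvable "
            f"on chain {chain_id}")
    return np.array(keep_ref, dtype=int), np.array(obs, dtype=float)


def abangle_measures(frame: StructureFrame, part: FabPartition,
                     ref: ReferenceFrame | None = None) -> AbangleMeasures:
    """Compute the six V_H–V_L orientation measures for one frame.

    Each domain's canonical frame is carried onto the structure by the
    least-squares superposition of the reference core onto the observed core
    Cα positions (at least three per domain must resolve).
    """
    ref = ref or load_reference()
    if not part.vh_core_residues or not part.vl_core_residues:
        raise InsufficientCoreError(
            "partition defines no vh_core_residues / vl_core_residues")
    idx_h, obs_h = _observed_core(frame, part.vh.chain_id,
                                  part.vh_core_residues, ref.h_labels)
    idx_l, obs_l = _observed_core(frame, part.vl.chain_id,
                                  part.vl_core_residues, ref.l_labels)
    rot_h, t_h, _ = superpose(ref.h_coords[idx_h], obs_h)
    rot_l, t_l, _ = superpose(ref.l_coords[idx_l], obs_l)
    fh = ref.h_frame.transformed(rot_h, t_h)
    fl = ref.l_frame.transformed(rot_l, t_l)
    c_vec = fh.origin - fl.origin  # L -> H
    dc = float(np.linalg.norm(c_vec))
    if dc < 1e-9:
        raise DegenerateGeometryError("coincident domain origins (dc = 0)")
    hl = torsion_angle(fh.origin + fh.axis1, fh.origin, fl.origin,
                       fl.origin + fl.axis1)
    return AbangleMeasures(
        HL=hl,
        HC1=vector_angle(c_vec, fh.axis1),
        HC2=vector_angle(c_vec, fh.axis2),
        LC1=vector_angle(c_vec, fl.axis1),
        LC2=vector_angle(c_vec, fl.axis2),
        dc=dc,
    )


# ---------------------------------------------------------------------------
# Per-frame series


def angle_series(frames: Iterable[StructureFrame], measure: str,
                 part: FabPartition, cfg: AnalysisConfig | None = None,
                 ref: ReferenceFrame | None = None,
                 dt_ps: float | None = None) -> AngleSeries:
    """Apply one measure to every frame of a trajectory.

    ``frames`` may be any iterable (including a lazy generator); uniform
    sampling is checked from the frame times unless ``dt_ps`` is given.
    ``dc`` is flagged aperiodic, all angle measures periodic.
    """
    if measure not in MEASURES:
        raise ValidationError(f"unknown measure {measure!r}; choose from {MEASURES}")
    cfg = cfg or AnalysisConfig()
    if measure in ("HL", "HC1", "HC2", "LC1", "LC2", "dc"):
        ref = ref or load_reference()

    values, times = [], []
    for frame in frames:
        if measure == "elbow":
            values.append(elbow_angle(frame, part, cfg))
        elif measure == "ch1cl":
            values.append(ch1_cl_angle(frame, part, cfg))
        else:
            values.append(abangle_measures(frame, part, ref).as_dict()[measure])
        times.append(frame.time_ps)

    if len(values) < 2:
        raise SamplingError("angle series needs at least 2 frames")
    if dt_ps is None:
        diffs = np.diff(times)
        dt_ps = float(diffs[0])
        if dt_ps <= 0 or not np.allclose(diffs, dt_ps, rtol=1e-6, atol=1e-9):
            raise SamplingError("trajectory frames are not uniformly sampled")
    return AngleSeries(values=np.array(values), dt_ps=dt_ps,
                       periodic=(measure != "dc"), name=measure)
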