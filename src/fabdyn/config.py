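"""Fab domain partition and analysis configuration.

Both live in one YAML config file with two top-level keys, ``partition`` and
``analysis``. A documented template with Chothia-style default ranges for a
standard Fab ships as package data (``fabdyn/data/default_partition.yaml``);
the ranges are a starting point and must be checked against each structure's
actual numbering — no automatic annotation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import yaml

from .errors import ValidationError
from .structure import ResidueSelection

_DOMAIN_KEYS = ("vh", "vl", "ch1", "cl")
_ALL_KEYS = _DOMAIN_KEYS + (
    "switch_heavy", "switch_light", "ch1_cterm_loops", "cl_cterm_loops")

ResiduePair = tuple[tuple[str, int], tuple[str, int]]


@dataclass(frozen=True)
class FabPartition:
    """Explicit residue-range assignment of a Fab into its four domains,
    the two switch ("hinge") stretches and the C-terminal loop sets used by
    the C_H1–C_L torsion."""

    vh: ResidueSelection
    vl: ResidueSelection
    ch1: ResidueSelection
    cl: ResidueSelection
    switch_heavy: ResidueSelection
    switch_light: ResidueSelection
    ch1_cterm_loops: ResidueSelection
    cl_cterm_loops: ResidueSelection
    #: optional Cα pairings for the pseudo-two-fold axes (classic elbow)
    v_pairs: tuple[ResiduePair, ...] = ()
    c_pairs: tuple[ResiduePair, ...] = ()
    #: residue numbers of the ABangle reference core, per variable domain
    vh_core_residues: tuple[int, ...] = ()
    vl_core_residues: tuple[int, ...] = ()

    def __post_init__(self):
        domains = [getattr(self, k) for k in _DOMAIN_KEYS]
        for i, a in enumerate(domains):
            for b in domains[i + 1:]:
                if a.overlaps(b):
                    raise ValidationError(
                        f"domain selections {a.name!r} and {b.name!r} overlap")
        if not self.ch1.covers(self.ch1_cterm_loops):
            raise ValidationError("ch1_cterm_loops must lie inside ch1")
        if not self.cl.covers(self.cl_cterm_loops):
            raise ValidationError("cl_cterm_loops must lie inside cl")
        for sw, var, const in (
            (self.switch_heavy, self.vh, self.ch1),
            (self.switch_light, self.vl, self.cl),
        ):
            if len(sw.ranges) != 1:
                raise ValidationError(
                    f"switch selection {sw.name!r} must be one contiguous range")
            if not (sw.chain_id == var.chain_id == const.chain_id):
                raise ValidationError(
                    f"switch {sw.name!r} must share a chain with {var.name!r} "
                    f"and {const.name!r}")
            lo, hi = sw.span
            if not (var.span[1] < lo and hi < const.span[0]):
                raise ValidationError(
                    f"switch {sw.name!r} must bridge {var.name!r} and "
                    f"{const.name!r} in residue numbering")
            if sw.overlaps(var) or sw.overlaps(const):
                raise ValidationError(f"switch {sw.name!r} overlaps a domain")


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs shared across the pipeline.

    ``band_edges_ns`` are the two period edges of the three timescale bands
    (fluctuations faster than the first edge, between the edges, slower than
    the second); the defaults bracket the 0.1–10 ns (0.1–10 GHz) regime of
    collective Fab interdomain motion.
    """

    temperature_k: float = 300.0
    equilibration_frames_discarded: int = 0
    histogram_bin_width_deg: float = 0.5
    fit_window_kbt: float = 2.0
    band_edges_ns: tuple[float, float] = (0.1, 10.0)
    random_seed: int = 0
    com_weighting: str = "mass"

    def __post_init__(self):
        if not self.temperature_k > 0:
            raise ValidationError("temperature must be positive")
        if not self.histogram_bin_width_deg > 0:
            raise ValidationError("histogram bin width must be positive")
        if not self.fit_window_kbt > 0:
            raise ValidationError("fit window must be positive")
        lo, hi = self.band_edges_ns
        if not (0 < lo < hi):
            raise ValidationError(
                f"band edges must be strictly ordered positive periods, "
                f"got {self.band_edges_ns}")
        if self.equilibration_frames_discarded < 0:
            raise ValidationError("equilibration_frames_discarded must be >= 0")
        if self.com_weighting not in ("mass", "geometric"):
            raise ValidationError("com_weighting must be 'mass' or 'geometric'")


# ---------------------------------------------------------------------------
# YAML (de)serialization


def _selection_from_dict(name: str, d: dict) -> ResidueSelection:
    try:
        chain = str(d["chain"])
        ranges = tuple((int(lo), int(hi)) for lo, hi in d["ranges"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"selection {name!r}: malformed entry {d!r}") from exc
    return ResidueSelection(chain_id=chain, ranges=ranges, name=name)


def _pairs_from_list(name: str, entries) -> tuple[ResiduePair, ...]:
    pairs = []
    for entry in entries or ():
        try:
            (ca, ra), (cb, rb) = entry
            pairs.append(((str(ca), int(ra)), (str(cb), int(rb))))
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{name}: malformed pair {entry!r}") from exc
    return tuple(pairs)


def partition_from_dict(d: dict) -> FabPartition:
    missing = [k for k in _ALL_KEYS if k not in d]
    if missing:
        raise ValidationError(f"partition config missing keys: {missing}")
    sels = {k: _selection_from_dict(k, d[k]) for k in _ALL_KEYS}
    return FabPartition(
        **sels,
        v_pairs=_pairs_from_list("v_pairs", d.get("v_pairs")),
        c_pairs=_pairs_from_list("c_pairs", d.get("c_pairs")),
        vh_core_residues=tuple(int(r) for r in d.get("vh_core_residues", ())),
        vl_core_residues=tuple(int(r) for r in d.get("vl_core_residues", ())),
    )


def partition_to_dict(p: FabPartition) -> dict:
    d = {}
    for k in _ALL_KEYS:
        sel: ResidueSelection = getattr(p, k)
        d[k] = {"chain": sel.chain_id, "ranges": [list(r) for r in sel.ranges]}
    if p.v_pairs:
        d["v_pairs"] = [[list(a), list(b)] for a, b in p.v_pairs]
    if p.c_pairs:
        d["c_pairs"] = [[list(a), list(b)] for a, b in p.c_pairs]
    if p.vh_core_residues:
        d["vh_core_residues"] = list(p.vh_core_residues)
    if p.vl_core_residues:
        d["vl_core_residues"] = list(p.vl_core_residues)
    return d


def analysis_from_dict(d: dict) -> AnalysisConfig:
    kwargs = {}
    mapping = {
        "temperature": "temperature_k",
        "temperature_k": "temperature_k",
        "equilibration_frames_discarded": "equilibration_frames_discarded",
        "histogram_bin_width": "histogram_bin_width_deg",
        "histogram_bin_width_deg": "histogram_bin_width_deg",
        "fit_window_kbt": "fit_window_kbt",
        "band_edges_ns": "band_edges_ns",
        "random_seed": "random_seed",
        "com_weighting": "com_weighting",
    }
    for key, val in (d or {}).items():
        if key not in mapping:
            raise ValidationError(f"unknown analysis config key {key!r}")
        kwargs[mapping[key]] = tuple(val) if key == "band_edges_ns" else val
    return AnalysisConfig(**kwargs)


def load_config(path) -> tuple[FabPartition | None, AnalysisConfig]:
    """Load a YAML config; returns (partition or None, analysis config)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    part = partition_from_dict(doc["partition"]) if "partition" in doc else None
    cfg = analysis_from_dict(doc.get("analysis", {}))
    return part, cfg


def save_config(path, partition: FabPartition | None = None,
                analysis: AnalysisConfig | None = None) -> None:
    doc = {}
    if partition is not None:
        doc["partition"] = partition_to_dict(partition)
    if analysis is not None:
        a = analysis
        doc["analysis"] = {
            "temperature_k": a.temperature_k,
            "equilibration_frames_discarded": a.equilibration_frames_discarded,
            "histogram_bin_width_deg": a.histogram_bin_width_deg,
            "fit_window_kbt": a.fit_window_kbt,
            "band_edges_ns": list(a.band_edges_ns),
            "random_seed": a.random_seed,
            "com_weighting": a.com_weighting,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_partition_template() -> str:
    """The packaged Chothia-style partition template (YAML text)."""
    return resources.files("fabdyn").joinpath(
        "data/default_partition.yaml").read_text()
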