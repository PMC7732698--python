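import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fabdyn import AnalysisConfig, ToyFabSpec, build_toy_fab

# deterministic hypothesis runs everywhere
settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("det")


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def toy_fab():
    return build_toy_fab(ToyFabSpec(elbow_deg=160.0, ch1cl_deg=100.0,
                                    dc_angstrom=16.0, seed=3))


def make_pdb_text(models, icodes=None):
    """Hand-rolled PDB text: models is a list of atom lists, each atom a
    tuple (serial, name, resname, chain, resseq, x, y, z, element) —
    an independent writer so read tests do not depend on our own output."""
    lines = []
    multi = len(models) > 1
    for m, atoms in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {m:>4}")
        for (serial, name, resname, chain, resseq, x, y, z, elem) in atoms:
            icode = (icodes or {}).get((chain, resseq, serial), " ")
            nm = f" {name:<3}" if len(name) < 4 else name
            rec = "HETATM" if resname == "HOH" else "ATOM  "
            lines.append(
                f"{rec}{serial:>5} {nm} {resname:<3} {chain}{resseq:>4}"
                f"{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {elem:>2}")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def pdb_writer(tmp_path):
    def write(name, models, icodes=None):
        p = tmp_path / name
        p.write_text(make_pdb_text(models, icodes=icodes))
        return p
    return write


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(rng=rng)
    t = rng.uniform(-50, 50, size=3)
    return rot, t


def apply_rigid(frame, rot, t):
    return frame.with_coords(rot.apply(frame.coords) + t)
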