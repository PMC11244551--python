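import numpy as np
import pytest

from epmap import synthetic
from epmap.data_model import EAMStudy, EAPoint, Mesh, SurfaceECG


@pytest.fixture(scope="session")
def sphere_mesh():
    """Unit-ish ellipsoid mesh, 2 subdivisions (162 vertices)."""
    mesh, _ = synthetic.make_rv_mesh(n_subdivisions=2, bulge_amplitude=0.0, seed=0)
    return mesh


@pytest.fixture(scope="session")
def bulged_mesh():
    mesh, patch = synthetic.make_rv_mesh(n_subdivisions=2, bulge_amplitude=8.0, seed=1)
    return mesh, patch


@pytest.fixture(scope="session")
def small_study():
    """Noise-free 40-point study with spatially varying, sample-aligned
    AT/ARI fields (integer ms, so +-1 sample recovery is exact)."""
    mesh, _ = synthetic.make_rv_mesh(n_subdivisions=2, bulge_amplitude=0.0, seed=0)
    study, truth = synthetic.make_study(
        mesh,
        40,
        at_field=lambda p: np.round(5.0 + 0.2 * (p[:, 2] - p[:, 2].min())),
        ari_field=lambda p: np.round(220.0 + 0.8 * (p[:, 0] - p[:, 0].min())),
        jel_field=lambda p: 0.3 + 0.02 * (p[:, 1] - p[:, 1].min()),
        seed=7,
    )
    return study, truth


def random_tiny_study(rng: np.random.Generator) -> EAMStudy:
    """A structurally valid random study with short traces (round-trip
    fodder; not physiologically meaningful)."""
    verts = rng.normal(size=(6, 3))
    tris = np.array([[0, 1, 2], [1, 2, 3], [2, 3, 4], [3, 4, 5]])
    mesh = Mesh(verts, tris)
    n = int(rng.integers(0, 5))
    t_len = 40
    with_bip = rng.random() < 0.5
    points = [
        EAPoint(
            position=rng.normal(size=3),
            surface_position=rng.normal(size=3),
            unipolar=rng.normal(size=t_len),
            bipolar=rng.normal(size=t_len) if with_bip else None,
            contact_force=None if rng.random() < 0.3 else float(rng.uniform(0, 40)),
            valid=bool(rng.random() < 0.9),
            reason=str(rng.choice(["ok", "noise", "force_unknown"])),
        )
        for _ in range(n)
    ]
    ecg = SurfaceECG(
        leads={"V2": rng.normal(size=t_len), "I": rng.normal(size=t_len)},
        sampling_rate=1000.0,
    )
    return EAMStudy(
        mesh=mesh,
        points=points,
        ecg=ecg,
        sampling_rate=1000.0,
        reference_annotation=20.0,
        woi=(-10.0, 10.0),
        phase_label=str(rng.choice(["pre", "post", ""])),
    )
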