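import numpy as np
import pytest

from ulnakin import WristParams, detect_landmarks, generate_wrist
from ulnakin.synthetic import capped_cylinder, uv_sphere


@pytest.fixture(scope="session")
def default_wrist():
    return generate_wrist(WristParams())


@pytest.fixture(scope="session")
def default_landmarks(default_wrist):
    w = default_wrist
    return detect_landmarks(w.meshes["radius"], w.meshes["ulna"], w.frame)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def make_sphere(radius, center, pole=(0, 0, 1.0), polar=5.0, azimuth=10.0):
    from ulnakin import TriangleMesh

    V, F = uv_sphere(radius, np.asarray(center, float), pole, polar, azimuth)
    return TriangleMesh(V, F, "lunate")


def make_cylinder(radius, z0, z1, center_xy=(0.0, 0.0), sections=24):
    from ulnakin import TriangleMesh

    V, F = capped_cylinder(radius, z0, z1, center_xy, sections)
    return TriangleMesh(V, F, "ulna")


def random_hull(rng, label="ulna", n_points=30, scale=1.0, offset=(0, 0, 0)):
    """Random closed convex mesh (≤ ~2·n_points triangles)."""
    import trimesh

    from ulnakin import TriangleMesh

    pts = rng.normal(size=(n_points, 3)) * scale + np.asarray(offset, float)
    hull = trimesh.convex.convex_hull(pts)
    return TriangleMesh(np.asarray(hull.vertices), np.asarray(hull.faces), label)


def random_rigid(rng, max_translation=50.0):
    from ulnakin import RigidTransform

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0, np.pi)
    tf = RigidTransform.from_axis_angle(axis, angle)
    return RigidTransform(tf.rotation, rng.uniform(-max_translation, max_translation, 3))
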