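"""Shared fixtures: canonical solids, random superellipsoid specs, oracles."""

import numpy as np
import pytest
import trimesh

from olivemorph import SyntheticSpec, TriangleMesh, make_body


@pytest.fixture(scope="session")
def unit_cube() -> TriangleMesh:
    """Axis-aligned unit cube on [0, 1]^3, 12 triangles, outward-oriented."""
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriangleMesh(box.vertices + 0.5, box.faces, name="unit-cube")


@pytest.fixture(scope="session")
def icosphere() -> TriangleMesh:
    """Unit-radius icosphere, 4 subdivisions (5120 faces), centred at origin."""
    ball = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    return TriangleMesh(ball.vertices, ball.faces, name="icosphere-4")


@pytest.fixture(scope="session")
def ellipsoid_312() -> TriangleMesh:
    """Axis-aligned ellipsoid with semi-axes (1.5, 1.0, 0.5)."""
    return make_body(SyntheticSpec(semi_axes=(1.5, 1.0, 0.5), mesh_subdivisions=4))


def random_superellipsoid_spec(rng: np.random.Generator, subdivisions: int = 2) -> SyntheticSpec:
    """One random olive-scale superellipsoid body spec."""
    a = rng.uniform(0.5, 1.9)
    b = a * rng.uniform(0.4, 0.95)
    c = b * rng.uniform(0.85, 1.0)
    return SyntheticSpec(
        semi_axes=(a, b, c),
        exponents=(rng.uniform(0.6, 1.4), rng.uniform(0.7, 1.3)),
        mesh_subdivisions=subdivisions,
    )


def superellipsoid_inside(points: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Implicit inside-test of the superellipsoid body (no appendage)."""
    a, b, c = spec.semi_axes
    e1, e2 = spec.exponents
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    cross = (np.abs(y / b) ** (2 / e2) + np.abs(z / c) ** (2 / e2)) ** (e2 / e1)
    return cross + np.abs(x / a) ** (2 / e1) <= 1.0


def voxel_volume_and_cog(spec: SyntheticSpec, voxel: float = 0.01) -> tuple[float, np.ndarray]:
    """Voxelization oracle: volume and centroid from an occupancy grid of
    the implicit superellipsoid, independent of any surface mesh.
    Evaluated slab by slab along x to bound memory."""
    a, b, c = spec.semi_axes
    xs, ys, zs = (np.arange(-h - voxel, h + voxel, voxel) + voxel / 2 for h in (a, b, c))
    gy, gz = np.meshgrid(ys, zs, indexing="ij")
    yz = np.column_stack([gy.ravel(), gz.ravel()])
    count = 0
    sums = np.zeros(3)
    for x in xs:
        pts = np.column_stack([np.full(len(yz), x), yz])
        inside = superellipsoid_inside(pts, spec)
        n = int(inside.sum())
        if n:
            count += n
            sums += pts[inside].sum(axis=0)
    volume = count * voxel**3
    cog = sums / count
    return float(volume), cog


def monte_carlo_volume(
    spec: SyntheticSpec, n: int = 10_000_000, seed: int = 1234
) -> tuple[float, float]:
    """Rejection-sampling volume oracle: estimate and its standard error."""
    rng = np.random.default_rng(seed)
    a, b, c = spec.semi_axes
    box = 8.0 * a * b * c
    pts = rng.uniform(-1.0, 1.0, size=(n, 3)) * np.array([a, b, c])
    hits = superellipsoid_inside(pts, spec)
    p = hits.mean()
    volume = box * p
    se = box * np.sqrt(p * (1 - p) / n)
    return float(volume), float(se)
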