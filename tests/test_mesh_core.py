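"""Mesh and voxel primitives: I/O round trips, normals, projection,
rasterization, distance fields and smoothing."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from bscore3d.errors import (
    DegenerateFieldError,
    UnsupportedTopologyError,
    WatertightnessError,
    ZeroAreaError,
)
from bscore3d.mesh_core import (
    BinaryVolume,
    CorrespondenceWarning,
    TriangleMesh,
    closest_point_on_surface,
    rasterize,
    read_mesh,
    read_volume,
    signed_distance_field,
    taubin_smooth,
    taubin_smooth_points,
    vertex_normals,
    write_mesh,
    write_volume,
)


def icosphere_mesh(subdivisions=3, radius=1.0):
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


def tetrahedron():
    v = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fmt", ["ply", "obj"])
def test_mesh_roundtrip_preserves_order(tmp_path, fmt):
    mesh = tetrahedron()
    path = tmp_path / f"tet.{fmt}"
    write_mesh(mesh, path)
    back = read_mesh(path)
    np.testing.assert_allclose(back.vertices, mesh.vertices, atol=1e-6)
    np.testing.assert_array_equal(back.faces, mesh.faces)
    assert back.corresponded


def test_stl_roundtrip_flags_correspondence_lost(tmp_path):
    mesh = tetrahedron()
    path = tmp_path / "tet.stl"
    with pytest.warns(CorrespondenceWarning):
        write_mesh(mesh, path)
    with pytest.warns(CorrespondenceWarning):
        back = read_mesh(path)
    assert not back.corresponded
    # geometry survives even though vertex order may not
    assert back.as_trimesh().volume == pytest.approx(mesh.as_trimesh().volume,
                                                     rel=1e-6)


def test_quad_face_rejected(tmp_path):
    path = tmp_path / "quad.ply"
    path.write_text(
        "ply\nformat ascii 1.0\nelement vertex 4\n"
        "property float x\nproperty float y\nproperty float z\n"
        "element face 1\nproperty list uchar int vertex_indices\nend_header\n"
        "0 0 0\n1 0 0\n1 1 0\n0 1 0\n4 0 1 2 3\n"
    )
    with pytest.raises(UnsupportedTopologyError):
        read_mesh(path)


@pytest.mark.parametrize("ext", ["nii.gz", "mha"])
def test_volume_roundtrip(tmp_path, ext):
    occ = np.zeros((6, 7, 8), dtype=bool)
    occ[2:4, 2:5, 3:6] = True
    vol = BinaryVolume(occ, spacing=[1.0, 0.5, 2.0], origin=[-3.0, 1.0, 0.5])
    path = tmp_path / f"vol.{ext}"
    write_volume(vol, path)
    back = read_volume(path)
    np.testing.assert_array_equal(back.occupancy, vol.occupancy)
    np.testing.assert_allclose(back.spacing, vol.spacing)
    np.testing.assert_allclose(back.origin, vol.origin)


# ---------------------------------------------------------------------------
# Normals
# ---------------------------------------------------------------------------

def test_sphere_normals_point_radially():
    mesh = icosphere_mesh(3)
    n = vertex_normals(mesh)
    u = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    ang = np.degrees(np.arccos(np.clip(np.sum(n * u, axis=1), -1, 1)))
    np.testing.assert_allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-9)
    assert ang.max() < 2.0


def test_planar_patch_normals_and_flip_antisymmetry():
    # 3x3 grid triangulated in the z=0 plane
    xs, ys = np.meshgrid(np.arange(3.0), np.arange(3.0), indexing="ij")
    v = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(9)])
    faces = []
    for i in range(2):
        for j in range(2):
            a, b, c, d = 3 * i + j, 3 * i + j + 1, 3 * (i + 1) + j, 3 * (i + 1) + j + 1
            faces += [[a, b, d], [a, d, c]]
    mesh = TriangleMesh(v, np.array(faces))
    n = vertex_normals(mesh)
    np.testing.assert_allclose(np.abs(n[:, 2]), 1.0, atol=1e-12)
    flipped = TriangleMesh(v, np.array(faces)[:, ::-1])
    np.testing.assert_allclose(vertex_normals(flipped), -n, atol=1e-12)


def test_isolated_vertex_raises():
    v = np.vstack([tetrahedron().vertices, [[9.0, 9.0, 9.0]]])
    mesh = TriangleMesh(v, tetrahedron().faces)
    with pytest.raises(ZeroAreaError, match="4"):
        vertex_normals(mesh)


# ---------------------------------------------------------------------------
# Closest point on surface
# ---------------------------------------------------------------------------

def _point_triangle_distance(p, a, b, c):
    """Independent closed-form oracle: min distance point-to-triangle as the
    minimum over the plane projection (if inside) and the three edges."""

    def seg(p, a, b):
        ab = b - a
        t = np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-300), 0.0, 1.0)
        q = a + t * ab
        return np.linalg.norm(p - q), q

    n = np.cross(b - a, c - a)
    nn = np.dot(n, n)
    best = min(seg(p, a, b), seg(p, b, c), seg(p, c, a), key=lambda x: x[0])
    if nn > 1e-300:
        q = p - n * np.dot(p - a, n) / nn
        # barycentric inside test
        areas = [np.dot(np.cross(v1 - q, v2 - q), n) for v1, v2 in
                 [(a, b), (b, c), (c, a)]]
        if all(s >= -1e-12 * nn for s in areas):
            d = abs(np.dot(p - a, n)) / np.sqrt(nn)
            if d < best[0]:
                best = (d, q)
    return best


def brute_force_closest(mesh, points):
    dists = np.empty(len(points))
    for i, p in enumerate(points):
        dists[i] = min(
            _point_triangle_distance(p, *mesh.vertices[f])[0] for f in mesh.faces
        )
    return dists


def test_point_on_surface_is_fixed_point():
    mesh = tetrahedron()
    q = mesh.vertices[mesh.faces[0]].mean(axis=0)  # triangle barycenter
    proj, dist, fid = closest_point_on_surface(mesh, [q])
    np.testing.assert_allclose(proj[0], q, atol=1e-12)
    assert dist[0] == pytest.approx(0.0, abs=1e-12)
    assert fid[0] == 0


def test_projection_onto_unit_sphere():
    mesh = icosphere_mesh(3)
    proj, dist, _ = closest_point_on_surface(mesh, [[0.0, 0.0, 2.0]])
    np.testing.assert_allclose(proj[0], [0, 0, 1], atol=5e-3)
    assert dist[0] == pytest.approx(1.0, abs=5e-3)


def test_closest_point_matches_oracle(rng):
    pts = rng.normal(size=(18, 3))
    hull = trimesh.points.PointCloud(pts).convex_hull
    mesh = TriangleMesh(np.asarray(hull.vertices), np.asarray(hull.faces))
    assert len(mesh.faces) <= 50
    queries = rng.normal(scale=2.0, size=(100, 3))
    _, dists, _ = closest_point_on_surface(mesh, queries)
    np.testing.assert_allclose(dists, brute_force_closest(mesh, queries),
                               atol=1e-9)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_closest_point_oracle_property(seed):
    r = np.random.default_rng(seed)
    pts = r.normal(size=(r.integers(6, 40), 3))
    hull = trimesh.points.PointCloud(pts).convex_hull
    mesh = TriangleMesh(np.asarray(hull.vertices), np.asarray(hull.faces))
    if len(mesh.faces) > 100:
        return
    queries = r.normal(scale=2.0, size=(10, 3))
    _, dists, _ = closest_point_on_surface(mesh, queries)
    np.testing.assert_allclose(dists, brute_force_closest(mesh, queries),
                               atol=1e-9)


def test_empty_query_returns_empty():
    proj, dist, fid = closest_point_on_surface(tetrahedron(), np.zeros((0, 3)))
    assert proj.shape == (0, 3) and dist.shape == (0,) and fid.shape == (0,)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def test_rasterize_cube_phase_aligned_exact():
    box = trimesh.creation.box(extents=[10, 10, 10])
    box.apply_translation([5, 5, 5])  # corners on integers, centers at x.5
    mesh = TriangleMesh(np.asarray(box.vertices), np.asarray(box.faces))
    vol = rasterize(mesh, 1.0, padding_voxels=2)
    assert vol.occupancy.sum() == 1000
    assert 729 <= vol.occupancy.sum() <= 1331


def test_rasterize_sphere_volume():
    mesh = icosphere_mesh(4, radius=10.0)
    vol = rasterize(mesh, 1.0, padding_voxels=3)
    measured = vol.occupancy.sum() * vol.spacing.prod()
    assert measured == pytest.approx(4188.79, rel=0.05)
    # occupied region strictly inside the grid
    occ = vol.occupancy
    assert not occ[0].any() and not occ[-1].any()
    assert not occ[:, 0].any() and not occ[:, -1].any()
    assert not occ[:, :, 0].any() and not occ[:, :, -1].any()


def test_rasterize_rejects_empty_and_open_meshes():
    with pytest.raises(WatertightnessError):
        rasterize(TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int)), 1.0)
    tet = tetrahedron()
    open_mesh = TriangleMesh(tet.vertices, tet.faces[:3])
    with pytest.raises(WatertightnessError, match="3"):
        rasterize(open_mesh, 1.0)


def test_rasterize_isosurface_roundtrip_bound():
    """Original vertices stay within one voxel diagonal of the occupancy
    boundary (|SDF| <= h*sqrt(3) at the vertices)."""
    from scipy import ndimage

    mesh = icosphere_mesh(3, radius=8.0)
    h = 1.0
    vol = rasterize(mesh, h, padding_voxels=3)
    sdf = signed_distance_field(vol)
    idx = vol.world_to_index(mesh.vertices).T
    vals = ndimage.map_coordinates(sdf, idx, order=1)
    assert np.abs(vals).max() <= h * np.sqrt(3) + 1e-9


# ---------------------------------------------------------------------------
# Signed distance field
# ---------------------------------------------------------------------------

def test_sdf_sphere_center_depth():
    vol = rasterize(icosphere_mesh(4, radius=10.0), 1.0, 3)
    sdf = signed_distance_field(vol)
    center = np.round(vol.world_to_index([[0.0, 0.0, 0.0]])).astype(int)[0]
    assert sdf[tuple(center)] == pytest.approx(-10.0, abs=1.0)


def test_sdf_boundary_and_eikonal(rng):
    vol = rasterize(icosphere_mesh(4, radius=10.0), 0.5, 6)
    sdf = signed_distance_field(vol)
    occ = vol.occupancy
    # voxels adjacent to the boundary: |value| <= spacing * sqrt(3)
    boundary = occ ^ (np.roll(occ, 1, axis=0) & occ)
    shell = occ & ~(
        np.roll(occ, 1, 0) & np.roll(occ, -1, 0)
        & np.roll(occ, 1, 1) & np.roll(occ, -1, 1)
        & np.roll(occ, 1, 2) & np.roll(occ, -1, 2)
    )
    assert np.abs(sdf[shell]).max() <= np.sqrt(3) * vol.spacing.max() + 1e-9
    # eikonal |grad| ~ 1 at random outside points away from the surface
    gx, gy, gz = np.gradient(sdf, *vol.spacing)
    gmag = np.sqrt(gx**2 + gy**2 + gz**2)
    outside = np.argwhere((sdf > 2.0) & (sdf < 5.0))
    sel = outside[rng.choice(len(outside), size=100, replace=False)]
    vals = gmag[tuple(sel.T)]
    np.testing.assert_allclose(vals, 1.0, atol=0.1)
    assert boundary.any()


def test_sdf_degenerate_volume_raises():
    with pytest.raises(DegenerateFieldError):
        signed_distance_field(
            BinaryVolume(np.zeros((4, 4, 4), bool), [1, 1, 1], [0, 0, 0])
        )
    with pytest.raises(DegenerateFieldError):
        signed_distance_field(
            BinaryVolume(np.ones((4, 4, 4), bool), [1, 1, 1], [0, 0, 0])
        )


# ---------------------------------------------------------------------------
# Taubin smoothing
# ---------------------------------------------------------------------------

def test_taubin_zero_iterations_is_identity():
    mesh = icosphere_mesh(2)
    out = taubin_smooth(mesh, iterations=0)
    np.testing.assert_array_equal(out.vertices, mesh.vertices)
    np.testing.assert_array_equal(out.faces, mesh.faces)


def test_taubin_preserves_volume_where_laplacian_shrinks():
    mesh = icosphere_mesh(3)
    taubin = taubin_smooth(mesh, iterations=10, lambda_pass=0.5, mu_pass=-0.53)
    r_taubin = np.linalg.norm(taubin.vertices, axis=1).mean()
    assert abs(r_taubin - 1.0) < 0.02
    # independent pure-Laplacian reference: repeated neighbor averaging
    pts = mesh.vertices.copy()
    neigh = [[] for _ in range(len(pts))]
    for f in mesh.faces:
        for i in range(3):
            neigh[f[i]] += [f[(i + 1) % 3], f[(i + 2) % 3]]
    neigh = [np.unique(n) for n in neigh]
    for _ in range(10):
        pts = np.array([p + 0.5 * (pts[n].mean(0) - p) for p, n in zip(pts, neigh)])
    r_lap = np.linalg.norm(pts, axis=1).mean()
    assert 1.0 - r_lap > 0.02  # pure Laplacian loses > 2 % radius


def test_taubin_attenuates_spike():
    xs, ys = np.meshgrid(np.arange(7.0), np.arange(7.0), indexing="ij")
    v = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(49)])
    center = 3 * 7 + 3
    v[center, 2] = 5.0  # 5 mm spike
    faces = []
    for i in range(6):
        for j in range(6):
            a, b = 7 * i + j, 7 * i + j + 1
            c, d = 7 * (i + 1) + j, 7 * (i + 1) + j + 1
            faces += [[a, b, d], [a, d, c]]
    out = taubin_smooth_points(v, np.array(faces), iterations=20)
    assert abs(out[center, 2]) < 1.0
    assert out.shape == v.shape


def test_taubin_parameter_validation():
    mesh = icosphere_mesh(2)
    with pytest.raises(ValueError):
        taubin_smooth(mesh, iterations=-1)
    with pytest.raises(ValueError):
        taubin_smooth(mesh, lambda_pass=1.5)
    with pytest.raises(ValueError):
        taubin_smooth(mesh, mu_pass=-0.3)  # not < -lambda
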