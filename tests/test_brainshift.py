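"""Interior test, surface projection, and topology-preserving shift correction.

Projection is cross-checked against a hand-written exhaustive face-scan
oracle using the standard closest-point-on-triangle construction.
"""

import numpy as np
import pytest

from ieloc.brainshift import (SurfaceMesh, correct_brain_shift, is_inside,
                              project_to_surface, topology_term, _grid_adjacency)
from ieloc.errors import TopologyError
from ieloc.synthetic import make_grid_fixture, make_icosphere
from ieloc.table import ContactGroup, ElectrodePlan, table_from_plan


def closest_point_on_triangle(p, a, b, c):
    """Ericson's exact point-triangle closest point (oracle)."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 <= d1 and d3 <= 0:
        return a + (d1 / (d1 - d3)) * ab
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 <= d2 and d6 <= 0:
        return a + (d2 / (d2 - d6)) * ac
    va = d3 * d6 - d5 * d4
    if va <= 0 and d4 - d3 >= 0 and d5 - d6 >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return b + w * (c - b)
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    return a + ab * v + ac * w


def oracle_project(mesh, p):
    best, best_d = None, np.inf
    for f in mesh.faces:
        q = closest_point_on_triangle(p, *mesh.vertices[f])
        d = np.linalg.norm(p - q)
        if d < best_d:
            best, best_d = q, d
    return best


def test_inside_centroid_and_far_point(sphere50):
    assert is_inside(sphere50, (0.0, 0.0, 0.0))
    assert not is_inside(sphere50, (100.0, 0.0, 0.0))


def test_inside_just_under_surface(sphere50):
    # the mesh is inscribed in the analytic sphere, so test along a vertex ray
    v = sphere50.vertices[0]
    p = v * (1.0 - 0.1 / 50.0)  # 0.1 mm under the mesh surface
    assert is_inside(sphere50, p)
    assert not is_inside(sphere50, v * 1.01)


def test_inside_requires_closed_mesh(sphere50):
    open_mesh = SurfaceMesh(sphere50.vertices, sphere50.faces[:-1])
    with pytest.raises(TopologyError):
        is_inside(open_mesh, (0.0, 0.0, 0.0))


def test_project_point_on_face_is_fixed(sphere50):
    f = sphere50.faces[0]
    p = sphere50.vertices[f].mean(axis=0)  # barycenter lies on the face
    np.testing.assert_allclose(project_to_surface(sphere50, p), p, atol=1e-9)


def test_project_interior_point_near_analytic_radius(sphere50):
    got = project_to_surface(sphere50, np.array([45.0, 0.0, 0.0]))
    # within one mesh edge of the analytic projection (50, 0, 0)
    edge = np.linalg.norm(sphere50.vertices[sphere50.faces[0][0]]
                          - sphere50.vertices[sphere50.faces[0][1]])
    assert np.linalg.norm(got - np.array([50.0, 0.0, 0.0])) < edge


def test_project_matches_face_scan_oracle(sphere50, rng):
    pts = rng.uniform(-60, 60, size=(50, 3))
    got = project_to_surface(sphere50, pts)
    for p, g in zip(pts, got):
        np.testing.assert_allclose(g, oracle_project(sphere50, p), atol=1e-8)


def test_project_empty_mesh_errors():
    mesh = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
    with pytest.raises(TopologyError):
        project_to_surface(mesh, (0.0, 0.0, 0.0))


def _grid_table(mesh, inward=8.0):
    contacts, targets = make_grid_fixture(2, 4, 10.0, mesh, inward_offset=inward)
    plan = ElectrodePlan([ContactGroup("GR", "ECoG-grid", 8, grid_dims=(2, 4)),
                          ContactGroup("LA", "sEEG", 4)])
    table = table_from_plan(plan)
    for rec, c in zip(table.records[:8], contacts):
        rec.coord_native = c
    seeg = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0],
                     [7.0, 8.0, 9.0], [10.0, 11.0, 12.0]])
    for rec, c in zip(table.records[8:], seeg):
        rec.coord_native = c
    return table, plan, contacts, seeg


def test_shifted_contacts_lie_on_mesh(sphere50):
    table, plan, _, _ = _grid_table(sphere50)
    correct_brain_shift(table, plan, sphere50)
    shifted = np.array([r.coord_shifted for r in table.records[:8]])
    proj = project_to_surface(sphere50, shifted)
    assert np.linalg.norm(shifted - proj, axis=1).max() < 1e-3


def test_seeg_bit_identical(sphere50):
    table, plan, _, seeg = _grid_table(sphere50)
    correct_brain_shift(table, plan, sphere50)
    for rec, c in zip(table.records[8:], seeg):
        assert rec.coord_shifted is None
        assert np.all(rec.coord_native == c)


def test_exterior_contacts_untouched(sphere50):
    table, plan, _, _ = _grid_table(sphere50, inward=-5.0)  # pushed outside
    correct_brain_shift(table, plan, sphere50)
    assert all(r.coord_shifted is None for r in table.records)


def test_adjacent_distances_preserved_within_25pct(sphere50):
    table, plan, contacts, _ = _grid_table(sphere50)
    correct_brain_shift(table, plan, sphere50, lambda_topo=1.0)
    shifted = np.array([r.coord_shifted for r in table.records[:8]])
    for i, j in _grid_adjacency((2, 4)):
        d0 = np.linalg.norm(contacts[i] - contacts[j])
        d1 = np.linalg.norm(shifted[i] - shifted[j])
        assert abs(d1 - d0) / d0 < 0.25


def test_single_contact_lambda_zero_is_pure_projection(sphere50):
    plan = ElectrodePlan([ContactGroup("S", "ECoG-strip", 1)])
    table = table_from_plan(plan)
    p = np.array([30.0, 5.0, -4.0])
    table.records[0].coord_native = p
    correct_brain_shift(table, plan, sphere50, lambda_topo=0.0)
    np.testing.assert_allclose(table.records[0].coord_shifted,
                               project_to_surface(sphere50, p), atol=1e-9)


def test_topology_term_monotone_in_lambda(sphere50):
    """Stronger regularization never worsens the adjacency-distance term."""
    adj = _grid_adjacency((2, 4))
    terms = []
    for lam in (0.0, 1.0, 10.0):
        table, plan, contacts, _ = _grid_table(sphere50)
        correct_brain_shift(table, plan, sphere50, lambda_topo=lam)
        shifted = np.array([r.coord_shifted for r in table.records[:8]])
        terms.append(topology_term(contacts, shifted, adj))
    assert terms[0] >= terms[1] >= terms[2]


def test_closedness_detection():
    mesh = make_icosphere(radius=10.0, subdivisions=1)
    assert mesh.is_closed()
    assert not SurfaceMesh(mesh.vertices, mesh.faces[:-1]).is_closed()


def test_surface_gifti_round_trip(tmp_path, sphere50):
    from ieloc.brainshift import read_surface, write_surface_gifti

    path = tmp_path / "pial.surf.gii"
    write_surface_gifti(sphere50, path)
    back = read_surface(path)
    np.testing.assert_allclose(back.vertices, sphere50.vertices, atol=1e-4)
    np.testing.assert_array_equal(back.faces, sphere50.faces)
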