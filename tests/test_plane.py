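"""Plane projections, adaptive level-set sampling, segmentation rules."""
import numpy as np
import pytest

from camreg import reference_model
from camreg.plane import (PlaneDef, PlaneMap, adaptive_level_set,
                          default_planes, diagonal_crossings,
                          segment_robustness)


@pytest.fixture(scope="module")
def calcium_plane():
    return default_planes(reference_model())["calcium"]


def _norm_field(plane):
    """Analytic scalar field f = x/x_ref + y/y_ref (level 2 on the
    reference point, level 1 on the anti-diagonal line)."""

    def f(x, y):
        return x / plane.x_ref + y / plane.y_ref

    return f


def test_plane_partition_validation():
    ref = reference_model()
    with pytest.raises(ValueError):
        PlaneDef(("CaS",), ("CaT", "A"), ref)
    with pytest.raises(ValueError):
        PlaneDef(("CaS", "CaT", "A"), ("A", "H", "KCa", "Kd", "Leak", "NaV"),
                 ref)


def test_reference_point_maps_to_reference_model(calcium_plane):
    m = calcium_plane.model_at(calcium_plane.x_ref, calcium_plane.y_ref)
    assert np.allclose(m.gbar, reference_model().gbar)


def test_diagonal_points_scale_all_densities_uniformly(calcium_plane):
    m = calcium_plane.model_at(0.37 * calcium_plane.x_ref,
                               0.37 * calcium_plane.y_ref)
    assert np.allclose(m.gbar, 0.37 * reference_model().gbar)


def test_adaptive_sampler_recovers_analytic_level_set(calcium_plane):
    pm = adaptive_level_set(calcium_plane, level=1.0, budget=120, seed=3,
                            field_fn=_norm_field(calcium_plane))
    pts = pm.level_points()
    assert len(pts) > 10
    err = np.abs(pts[:, 0] / calcium_plane.x_ref
                 + pts[:, 1] / calcium_plane.y_ref - 1.0)
    assert err.max() < 0.05
    assert diagonal_crossings(pm) == 1


def test_refinement_concentrates_near_level_set(calcium_plane):
    """At least 60% of post-initial samples land within 5% of the target
    level (instrumented on the analytic field)."""
    n_init = 25
    pm = adaptive_level_set(calcium_plane, level=1.0, budget=300,
                            n_init=n_init, seed=3, min_edge_frac=0.005,
                            field_fn=_norm_field(calcium_plane))
    refined = pm.points[n_init + 4:]  # after corners + initial batch
    assert len(refined) > 100
    u = refined[:, 0] / calcium_plane.x_ref
    v = refined[:, 1] / calcium_plane.y_ref
    dist = np.abs(u + v - 1.0) / np.sqrt(2.0)  # distance to the true line
    near = dist < 0.05 * 2.49  # 5% of the normalised plane width
    assert near.mean() >= 0.6


def test_interpolated_classification_agrees_with_brute_force(calcium_plane):
    """Above/below-level prediction from the sampled triangulation agrees
    with the analytic truth on a 21x21 grid at >=95%."""
    from scipy.interpolate import LinearNDInterpolator

    f = _norm_field(calcium_plane)
    pm = adaptive_level_set(calcium_plane, level=1.0, budget=140, seed=5,
                            field_fn=f)
    interp = LinearNDInterpolator(pm.points, pm.values)
    xs = np.linspace(*calcium_plane.x_range, 21)
    ys = np.linspace(*calcium_plane.y_range, 21)
    agree = total = 0
    for x in xs:
        for y in ys:
            v = interp(x, y)
            if not np.isfinite(v):
                continue
            total += 1
            agree += (v > 1.0) == (f(x, y) > 1.0)
    assert total > 350
    assert agree / total >= 0.95


def test_empty_level_set_when_level_out_of_range(calcium_plane):
    with pytest.warns(UserWarning):
        pm = adaptive_level_set(calcium_plane, level=99.0, budget=40,
                                n_init=10, seed=0,
                                field_fn=_norm_field(calcium_plane))
    assert len(pm.segments) == 0
    assert diagonal_crossings(pm) == 0


def test_basin_labels_at_landmark_points(calcium_plane, ca_target,
                                         target_classifier):
    """Regulation returns diagonal (size-change) points and the reference
    itself to canonical bursting, while a high-calcium/low-rest corner is
    captured by the silent state."""
    from camreg.plane import _basin_label
    from camreg.config import QUICK

    pl = calcium_plane
    assert _basin_label(pl, 0.5 * pl.x_ref, 0.5 * pl.y_ref, ca_target,
                        target_classifier, QUICK) == "canonical"
    assert _basin_label(pl, pl.x_ref, pl.y_ref, ca_target,
                        target_classifier, QUICK) == "canonical"
    assert _basin_label(pl, 10.0 * pl.x_ref, 0.05 * pl.y_ref, ca_target,
                        target_classifier, QUICK) == "silent"


def test_segmentation_rule_application(calcium_plane):
    pts = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
    acute = PlaneMap(calcium_plane, pts, labels=[
        "canonical", "other_bursting", "other_bursting", "canonical"])
    basin = PlaneMap(calcium_plane, pts, labels=[
        "canonical", "canonical", "silent", "silent"])
    seg = segment_robustness(acute, basin)
    assert seg.labels == ["robust_restorative", "sensitive_restorative",
                          "sensitive_pathological", "robust_pathological"]


def test_segmentation_requires_shared_points(calcium_plane):
    a = PlaneMap(calcium_plane, np.array([[1.0, 1.0]]), labels=["canonical"])
    b = PlaneMap(calcium_plane, np.array([[2.0, 1.0]]), labels=["canonical"])
    with pytest.raises(ValueError):
        segment_robustness(a, b)
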