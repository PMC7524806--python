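"""2-D projections of conductance space: level sets, basins, segmentation.

A plane is defined by a two-set partition of the eight channels: moving
along x scales the group-X conductances jointly (relative to the reference
model) and likewise for y.  The diagonal through the origin and the
reference point scales *all* densities uniformly and therefore corresponds
to a change in cell size.

Level sets of mean intracellular calcium and basins of attraction of the
regulated dynamics are sampled adaptively: a Delaunay triangulation of the
sampled points is refined by subdividing, at each step, the largest triangle
whose nodes straddle the target level (or disagree in label), placing the
new sample at its centroid.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .channels import CHANNEL_ORDER
from .config import QUICK, SimTier
from .metrics import ClassifierConfig, trace_metrics
from .model import NeuronModel, SimulationDiverged, simulate
from .regulation import set_regulation_timescales

__all__ = ["PlaneDef", "PlaneMap", "default_planes", "adaptive_level_set",
           "acute_map", "basin_map", "segment_robustness",
           "diagonal_crossings"]

SEGMENT_LABELS = ("robust_restorative", "sensitive_restorative",
                  "sensitive_pathological", "robust_pathological")


@dataclass(frozen=True)
class PlaneDef:
    """Partition of the channels into the two plane axes."""

    group_x: Tuple[str, ...]
    group_y: Tuple[str, ...]
    reference: NeuronModel
    extent: Tuple[float, float] = (0.01, 2.5)  # fractions of reference

    def __post_init__(self):
        union = set(self.group_x) | set(self.group_y)
        if union != set(CHANNEL_ORDER) or set(self.group_x) & set(self.group_y):
            raise ValueError("groups must partition the 8 channels")

    @property
    def x_ref(self) -> float:
        idx = [CHANNEL_ORDER.index(n) for n in self.group_x]
        return float(self.reference.gbar[idx].sum())

    @property
    def y_ref(self) -> float:
        idx = [CHANNEL_ORDER.index(n) for n in self.group_y]
        return float(self.reference.gbar[idx].sum())

    @property
    def x_range(self) -> Tuple[float, float]:
        return (self.extent[0] * self.x_ref, self.extent[1] * self.x_ref)

    @property
    def y_range(self) -> Tuple[float, float]:
        return (self.extent[0] * self.y_ref, self.extent[1] * self.y_ref)

    def model_at(self, x: float, y: float) -> NeuronModel:
        """Map plane coordinates to a full conductance vector."""
        factors = np.empty(8)
        for i, name in enumerate(CHANNEL_ORDER):
            if name in self.group_x:
                factors[i] = x / self.x_ref
            else:
                factors[i] = y / self.y_ref
        return self.reference.scaled(np.maximum(factors, 0.0))


def default_planes(reference: NeuronModel) -> dict:
    """The three standard projections.

    ``calcium``  — channels that directly flux calcium vs the rest;
    ``arbitrary`` — an arbitrary subset split;
    ``inout``   — outward (K + leak) vs inward current carriers.
    """
    rest = tuple(n for n in CHANNEL_ORDER if n not in ("CaS", "CaT"))
    return {
        "calcium": PlaneDef(("CaS", "CaT"), rest, reference),
        "arbitrary": PlaneDef(("A", "CaT", "H", "NaV"),
                              ("CaS", "KCa", "Kd", "Leak"), reference),
        "inout": PlaneDef(("A", "KCa", "Kd", "Leak"),
                          ("CaS", "CaT", "H", "NaV"), reference),
    }


@dataclass
class PlaneMap:
    plane: PlaneDef
    points: np.ndarray  # (n, 2)
    values: Optional[np.ndarray] = None  # scalar field at points
    labels: Optional[list] = None  # state labels at points
    level: Optional[float] = None
    segments: Optional[np.ndarray] = None  # (m, 2, 2) level-set segments
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"x": self.points[:, 0], "y": self.points[:, 1]})
        if self.values is not None:
            df["value"] = self.values
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def level_points(self) -> np.ndarray:
        if self.segments is None or len(self.segments) == 0:
            return np.empty((0, 2))
        return self.segments.reshape(-1, 2)


def _mean_ca_field(plane: PlaneDef, tier: SimTier) -> Callable:
    def field_fn(x: float, y: float) -> float:
        try:
            res = simulate(plane.model_at(x, y), tier.burn_in + tier.window,
                           dt=tier.dt, burn_in=tier.burn_in)
        except SimulationDiverged:
            return np.nan
        return float(res.Ca.mean())

    return field_fn


def _initial_points(plane: PlaneDef, n_init: int, rng) -> np.ndarray:
    (x_lo, x_hi), (y_lo, y_hi) = plane.x_range, plane.y_range
    pts = rng.uniform([x_lo, y_lo], [x_hi, y_hi], size=(n_init, 2))
    corners = np.array([[x_lo, y_lo], [x_lo, y_hi], [x_hi, y_lo],
                        [x_hi, y_hi]])
    return np.vstack([corners, pts])


def _tri_areas(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = pts[simplices[:, 0]]
    b = pts[simplices[:, 1]]
    c = pts[simplices[:, 2]]
    return 0.5 * np.abs((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                        - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0]))


def _max_edge(pts: np.ndarray, simplex) -> float:
    p = pts[simplex]
    return max(np.linalg.norm(p[0] - p[1]), np.linalg.norm(p[1] - p[2]),
               np.linalg.norm(p[2] - p[0]))


def _extract_segments(pts, values, level, tri) -> np.ndarray:
    """Marching-triangles level-set extraction by edge interpolation."""
    segs = []
    for simplex in tri.simplices:
        v = values[simplex]
        if not np.all(np.isfinite(v)):
            continue
        above = v > level
        if above.all() or (~above).all():
            continue
        crossings = []
        for i, j in ((0, 1), (1, 2), (2, 0)):
            if above[i] != above[j]:
                w = (level - v[i]) / (v[j] - v[i])
                crossings.append(pts[simplex[i]]
                                 + w * (pts[simplex[j]] - pts[simplex[i]]))
        if len(crossings) == 2:
            segs.append(crossings)
    return np.array(segs) if segs else np.empty((0, 2, 2))


def adaptive_level_set(plane: PlaneDef, level: float,
                       budget: int = 140, n_init: int = 25, seed: int = 0,
                       tier: SimTier = QUICK,
                       field_fn: Optional[Callable] = None,
                       min_edge_frac: float = 0.02) -> PlaneMap:
    """Adaptive Delaunay sampling of a scalar-field level set.

    ``field_fn(x, y)`` defaults to the simulated mean intracellular calcium;
    ``level`` is then the reference model's calcium target.  At each step
    the largest triangle with at least one node above and one below the
    level is subdivided at its centroid, until the sample budget is spent
    or the largest straddling triangle's longest edge falls below
    ``min_edge_frac`` of the plane diagonal.
    """
    if budget < n_init + 4:
        raise ValueError("budget must cover the initial sample")
    rng = np.random.default_rng(seed)
    field_fn = field_fn or _mean_ca_field(plane, tier)
    pts = _initial_points(plane, n_init, rng)
    values = np.array([field_fn(x, y) for x, y in pts])
    diag = np.hypot(plane.x_range[1] - plane.x_range[0],
                    plane.y_range[1] - plane.y_range[0])
    min_edge = min_edge_frac * diag
    n_refined = 0
    while len(pts) < budget:
        tri = Delaunay(pts)
        finite = np.isfinite(values)
        above = values > level
        node_ok = finite[tri.simplices]
        node_above = above[tri.simplices]
        straddle = (node_ok.all(axis=1)
                    & node_above.any(axis=1)
                    & (~node_above).any(axis=1))
        if not straddle.any():
            if n_refined == 0:
                import warnings

                warnings.warn("target level not bracketed anywhere in the "
                              "plane; empty level set")
            break
        areas = _tri_areas(pts, tri.simplices)
        areas[~straddle] = -1.0
        best = int(np.argmax(areas))
        if _max_edge(pts, tri.simplices[best]) < min_edge:
            break
        centroid = pts[tri.simplices[best]].mean(axis=0)
        pts = np.vstack([pts, centroid])
        values = np.append(values, field_fn(*centroid))
        n_refined += 1
    tri = Delaunay(pts)
    segments = _extract_segments(pts, values, level, tri)
    return PlaneMap(plane, pts, values=values, level=level,
                    segments=segments,
                    meta={"seed": seed, "n_refined": n_refined,
                          "budget": budget})


def _classify_point(plane: PlaneDef, x: float, y: float,
                    classifier: ClassifierConfig, tier: SimTier) -> str:
    try:
        res = simulate(plane.model_at(x, y), tier.burn_in + tier.window,
                       dt=tier.dt, burn_in=tier.burn_in)
    except SimulationDiverged:
        return "divergent"
    return trace_metrics(res, classifier).state_label


def acute_map(plane: PlaneDef, points: np.ndarray,
              classifier: ClassifierConfig, tier: SimTier = QUICK
              ) -> PlaneMap:
    """Classification of the *unregulated* model at each plane point."""
    labels = [_classify_point(plane, x, y, classifier, tier)
              for x, y in points]
    return PlaneMap(plane, np.asarray(points), labels=labels,
                    meta={"kind": "acute"})


def _basin_label(plane: PlaneDef, x: float, y: float, ca_target: float,
                 classifier: ClassifierConfig, tier: SimTier,
                 checkpoint: float = 100_000.0) -> str:
    """Terminal classification of the closed-loop system from (x, y).

    The regulated system is advanced in checkpoint intervals and stopped as
    soon as the classification agrees across two successive checkpoints (or
    at the time budget; runs still flipping labels there are reported as
    ``unconverged`` and excluded from basins).
    """
    from .regulation import GrowthParams, integrate_closed_loop

    current = plane.model_at(x, y)
    reg = set_regulation_timescales(plane.reference, ca_target)
    reg.mu = current.gbar.copy()
    labels = []
    t_elapsed = 0.0
    first = True
    try:
        while t_elapsed < tier.reg_max_time:
            traj = integrate_closed_loop(current, reg, GrowthParams(),
                                         checkpoint, dt=tier.dt,
                                         burn_in=5000.0 if first else 0.0)
            first = False
            if traj.diverged:
                return "divergent"
            current = traj.end_model
            reg = traj.end_regulation
            t_elapsed += checkpoint
            res = simulate(current, tier.burn_in + tier.window, dt=tier.dt,
                           burn_in=tier.burn_in)
            labels.append(trace_metrics(res, classifier).state_label)
            if len(labels) >= 2 and labels[-1] == labels[-2]:
                return labels[-1]
    except SimulationDiverged:
        return "divergent"
    return "unconverged"


def basin_map(plane: PlaneDef, ca_target: float,
              classifier: ClassifierConfig, budget: int = 60,
              n_init: int = 20, seed: int = 0, tier: SimTier = QUICK
              ) -> PlaneMap:
    """Basins of attraction of the four dynamical states under regulation.

    Each sampled point initialises the closed-loop system (no growth) and
    is labelled by the terminal classification; refinement subdivides the
    largest triangle whose nodes carry at least two distinct labels.
    """
    rng = np.random.default_rng(seed)
    pts = _initial_points(plane, n_init, rng)

    def label_at(p):
        return _basin_label(plane, p[0], p[1], ca_target, classifier, tier)

    labels = [label_at(p) for p in pts]
    while len(pts) < budget:
        tri = Delaunay(pts)
        lab = np.array(labels)
        mixed = np.array([len(set(lab[s])) > 1 for s in tri.simplices])
        if not mixed.any():
            break
        areas = _tri_areas(pts, tri.simplices)
        areas[~mixed] = -1.0
        best = int(np.argmax(areas))
        centroid = pts[tri.simplices[best]].mean(axis=0)
        pts = np.vstack([pts, centroid])
        labels.append(label_at(centroid))
    return PlaneMap(plane, pts, labels=labels,
                    meta={"kind": "basin", "seed": seed})


def segment_robustness(acute: PlaneMap, basin: PlaneMap) -> PlaneMap:
    """Four-way robustness segmentation from paired acute and basin maps.

    acute canonical + basin canonical      -> robust_restorative
    acute other     + basin canonical      -> sensitive_restorative
    acute other     + basin other          -> sensitive_pathological
    acute canonical + basin other          -> robust_pathological
    """
    if acute.labels is None or basin.labels is None:
        raise ValueError("both maps must carry labels")
    if len(acute.points) != len(basin.points) or not np.allclose(
            acute.points, basin.points):
        raise ValueError("maps must share the same sample points")
    out = []
    for a, b in zip(acute.labels, basin.labels):
        robust = a == "canonical"
        restorative = b == "canonical"
        if robust and restorative:
            out.append("robust_restorative")
        elif restorative:
            out.append("sensitive_restorative")
        elif robust:
            out.append("robust_pathological")
        else:
            out.append("sensitive_pathological")
    return PlaneMap(acute.plane, acute.points, labels=out,
                    meta={"kind": "segmentation"})


def diagonal_crossings(pmap: PlaneMap, merge_scale: float = 0.2) -> int:
    """Number of distinct intersections of the level set with the diagonal.

    The diagonal is the ray through the origin and the reference point
    (uniform scaling of all conductances), so each intersection has a
    uniform-scale coordinate (1.0 = the reference model).  Where the field
    gradient along the diagonal is shallow, sampling noise makes the
    extracted polyline wiggle across the diagonal several times around one
    physical crossing; intersections closer than ``merge_scale`` in
    scale units are therefore counted as one.
    """
    if pmap.segments is None or len(pmap.segments) == 0:
        return 0
    plane = pmap.plane
    d = np.array([plane.x_ref, plane.y_ref])
    scales = []
    for seg in pmap.segments:
        p0, p1 = seg
        s0 = p0[0] * d[1] - p0[1] * d[0]
        s1 = p1[0] * d[1] - p1[1] * d[0]
        if s0 == s1 or s0 * s1 > 0:
            continue
        w = s0 / (s0 - s1)
        pt = p0 + w * (p1 - p0)
        scales.append(float(pt @ d / (d @ d)))  # uniform-scale coordinate
    if not scales:
        return 0
    scales = np.sort(scales)
    merged = [scales[0]]
    for s in scales[1:]:
        if s - merged[-1] > merge_scale:
            merged.append(s)
    return len(merged)
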