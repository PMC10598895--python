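"""The limiting line of sight and the signed expected glottal visibility.

The sight line leaves the upper incisor apex and must clear the obstruction
set (compressed tongue surface + lower incisor).  The obstructing tissue
lies on the ventral/counterclockwise side of its surface, so a ray is clear
exactly when every obstruction vertex lies on or ventral of it; the limiting
ray is the most ventral clear ray — the tangent through the vertex of
minimum direction angle, ties broken toward the vertex nearest the incisor.

Let L be the limiting ray's supporting line and G = [A, P] the glottal
segment (anterior, posterior commissure).  The expected glottal visibility
V is:

*  +|X - P| if L crosses G at X (the visible posterior portion of the
   cords), clamped at the full anteroposterior span when L passes clear of
   the whole segment on the visible side;
*  -(distance from P to the limiting ray) if even the posterior commissure
   is hidden — the perpendicular point-to-line distance whenever the sight
   still points past the glottis, plateauing at |P - origin| beyond that.

V is reported to 0.1 mm; screening thresholds use the unrounded value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import ModelConfig, DEFAULT_CONFIG
from .errors import ConfigError, GadasError, SimulationError
from .kinematics import (
    Scene,
    apply_head_extension,
    compress_tongue,
    lift_mandible,
    open_mandible,
    place_hyoid_larynx,
)
from .records import PatientRecord

_EPS = 1e-12
_MIN_SIGHT_ANGLE = math.radians(-89.0)  # steepest occlusion, neutral head


def _min_sight_angle(scene: Scene) -> float:
    """Steepest representable occlusion direction for this scene (rad)."""
    return _MIN_SIGHT_ANGLE + math.radians(scene.head_extension_angle)


def _cross2(a, b) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


@dataclass(frozen=True)
class Ray:
    origin: np.ndarray
    direction: np.ndarray  # unit vector

    @property
    def angle(self) -> float:
        return math.atan2(self.direction[1], self.direction[0])


@dataclass(frozen=True)
class VisibilityResult:
    """Signed expected glottal visibility and its limiting sight line."""

    visibility_mm: float  # unrounded, signed
    intersects_cords: bool
    limiting_ray: Ray
    tangent_point: np.ndarray | None  # obstruction vertex grazed, or None

    @property
    def visibility_rounded(self) -> float:
        """V to the reported 0.1 mm precision."""
        return round(self.visibility_mm, 1)


def limiting_ray(scene: Scene) -> tuple[Ray, np.ndarray | None]:
    """Most ventral ray from the upper incisor apex clearing the obstruction.

    With an empty obstruction set the ray passes straight through the
    anterior commissure (full span visible) and the tangent point is None.
    """
    origin = scene.upper_incisor_apex
    verts = scene.obstruction_vertices
    if len(verts) == 0:
        d = scene.glottis_anterior - origin
        nd = np.linalg.norm(d)
        if nd < _EPS:
            raise ConfigError("glottis coincides with the upper incisor apex")
        return Ray(origin, d / nd), None

    delta = verts - origin
    dist = np.hypot(delta[:, 0], delta[:, 1])
    keep = dist > _EPS
    delta, dist, verts_kept = delta[keep], dist[keep], verts[keep]
    angles = np.arctan2(delta[:, 1], delta[:, 0])
    # occlusion saturates just short of the mouth-frame vertical: the oral
    # aperture itself bounds how steeply the sight can dive, tissue at or
    # behind that direction hides everything up to (never beyond) it, and
    # the bound rotates with the extended head
    angles = np.maximum(angles, _min_sight_angle(scene))
    amin = angles.min()
    # tie-break: among collinear minimal vertices, the one nearest the incisor
    tied = np.flatnonzero(angles <= amin + 1e-12)
    best = tied[np.argmin(dist[tied])]
    tangent = verts_kept[best]
    d = np.array([math.cos(angles[best]), math.sin(angles[best])])
    return Ray(origin, d), tangent


def glottal_visibility(scene: Scene) -> VisibilityResult:
    """Signed expected glottal visibility (mm) of a fully transformed scene."""
    a, p = scene.glottis_anterior, scene.glottis_posterior
    span = float(np.linalg.norm(a - p))
    if span < 1e-9:
        raise ConfigError("degenerate glottis segment (zero length)")
    ray, tangent = limiting_ray(scene)
    o, d = ray.origin, ray.direction
    cross_a = _cross2(d, a - o)
    cross_p = _cross2(d, p - o)
    # visible side of the line = clockwise/dorsal (negative cross)
    if cross_p <= 0.0:
        if cross_a <= 0.0:
            v = span  # whole segment visible; clamp at the AP span
        else:
            u = cross_a / (cross_a - cross_p)  # L crosses G at A + u(P-A)
            v = (1.0 - u) * span
    else:
        # distance from P to the limiting sight ray: the perpendicular
        # point-to-line distance while the ray still points past the glottis
        # (foot of the perpendicular on the ray), else the distance to the
        # ray origin — keeps the miss distance monotone in the occlusion
        v = -cross_p if float(np.dot(d, p - o)) > 0.0 else -float(np.linalg.norm(p - o))
    v = min(v, span)
    return VisibilityResult(
        visibility_mm=float(v),
        intersects_cords=bool(v >= 0.0),
        limiting_ray=ray,
        tangent_point=tangent,
    )


def simulate_patient(record: PatientRecord, config: ModelConfig = DEFAULT_CONFIG) -> VisibilityResult:
    """Full pipeline: template -> kinematics -> sight line, deterministic."""
    scene = simulate_scene(record, config)
    return glottal_visibility(scene)


def simulate_scene(record: PatientRecord, config: ModelConfig = DEFAULT_CONFIG) -> Scene:
    """As :func:`simulate_patient` but returning the transformed scene
    (for rendering); errors name the failing stage."""
    from .template import build_template

    stage = "build_template"
    try:
        template = build_template(
            record.sex, record.height, record.weight, record.small_mandible, config
        )
        stage = "apply_head_extension"
        scene = apply_head_extension(template, record.head_up_grade, config)
        stage = "open_mandible"
        scene = open_mandible(scene, record.mouth_opening, config)
        stage = "lift_mandible"
        scene = lift_mandible(scene, record.tmj_rom, config)
        stage = "place_hyoid_larynx"
        scene = place_hyoid_larynx(scene, record.thyromental, record.hyomental, config)
        stage = "compress_tongue"
        scene = compress_tongue(scene, record.tongue_thickness, config)
    except GadasError as exc:
        raise SimulationError(stage, exc) from exc
    return scene
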