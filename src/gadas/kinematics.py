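"""Laryngoscopy kinematics: the movement and deformation rules.

The transformation order is fixed and deterministic:

    head extension -> mandible opening -> laryngoscope lift ->
    hyoid/larynx placement -> tongue compression

Head extension rotates the head (cranium *and* closed mandible) dorsally
about the atlanto-occipital pivot; the mandible then rotates open about the
displaced TMJ condyle until the inter-incisor gap equals the measured mouth
opening; the laryngoscope translates the mandible and tongue block
ventrally-caudad by the TMJ range of motion; the hyoid and larynx hang from
the neutral chin rest position along the world-fixed anterior-neck ray; and the
tongue is rebuilt as a compressed slab of retained thickness rho * measured
thickness between the lower incisor and the lifted tongue base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .config import ModelConfig, DEFAULT_CONFIG
from .errors import RangeError, UnreachableOpeningError
from .records import PatientRecord
from .template import AnatomyTemplate, build_template, rotate_about

_GAP_TOL_MM = 1e-6


@dataclass(frozen=True)
class Scene:
    """Anatomy after (some prefix of) the laryngoscopy transformations.

    All coordinates in mm, supine sagittal frame.  ``gnathion_rest`` is the
    neutral (pre-extension, normal-body-length) chin tip, the world-fixed
    anchor of the thyromental / hyomental placements: the larynx belongs to
    the cervical column, so neither head extension nor jaw movement nor a
    recessed chin drags it along (a small mandible acts through tongue
    crowding instead).  ``obstruction_vertices`` is the
    union of the compressed tongue surface and the lower incisor apex — the
    point set the sight line must clear.
    """

    sex: str
    scale_factor: float
    laryngeal_ap_diameter: float
    small_mandible: bool
    upper_incisor_apex: np.ndarray
    lower_incisor_apex: np.ndarray
    gnathion: np.ndarray
    gnathion_rest: np.ndarray
    tmj_condyle: np.ndarray
    hyoid: np.ndarray
    thyroid_notch: np.ndarray
    glottis_anterior: np.ndarray
    glottis_posterior: np.ndarray
    posterior_pharyngeal_wall: np.ndarray
    tongue_outline: np.ndarray
    compressed_tongue_surface: np.ndarray  # (k, 2) polyline, empty until compression
    obstruction_vertices: np.ndarray  # (k, 2), empty until compression
    head_extension_angle: float
    mandible_rotation_angle: float
    lift_vector: np.ndarray
    reference_body_length: float
    mandible_body_length: float


def _scene_from_template(t: AnatomyTemplate) -> Scene:
    return Scene(
        sex=t.sex,
        scale_factor=t.scale_factor,
        laryngeal_ap_diameter=t.laryngeal_ap_diameter,
        small_mandible=t.small_mandible,
        upper_incisor_apex=t.upper_incisor_apex.copy(),
        lower_incisor_apex=t.lower_incisor_apex.copy(),
        gnathion=t.gnathion.copy(),
        gnathion_rest=t.gnathion_reference.copy(),
        tmj_condyle=t.tmj_condyle.copy(),
        hyoid=t.hyoid.copy(),
        thyroid_notch=t.thyroid_notch.copy(),
        glottis_anterior=t.glottis_anterior.copy(),
        glottis_posterior=t.glottis_posterior.copy(),
        posterior_pharyngeal_wall=t.posterior_pharyngeal_wall.copy(),
        tongue_outline=t.tongue_outline.copy(),
        compressed_tongue_surface=np.empty((0, 2)),
        obstruction_vertices=np.empty((0, 2)),
        head_extension_angle=0.0,
        mandible_rotation_angle=0.0,
        lift_vector=np.zeros(2),
        reference_body_length=t.reference_body_length,
        mandible_body_length=t.mandible_body_length,
    )


def apply_head_extension(
    template: AnatomyTemplate, head_up_grade: int, config: ModelConfig = DEFAULT_CONFIG
) -> Scene:
    """Rotate the head dorsally by the extension angle of the sniffing grade.

    Grade 1 is the best extension (largest angle).  The whole head — cranium
    with the closed mandible and attached soft tissue — rotates rigidly about
    the atlanto-occipital pivot; the neck-ray frame carrying the larynx stays
    world-fixed, which is what makes extension matter downstream.
    """
    if head_up_grade not in config.head_up_angle_map:
        raise RangeError("head_up_grade", head_up_grade, "head_up_grade in 1-4")
    angle = config.head_up_angle_map[head_up_grade]
    scene = _scene_from_template(template)
    pivot = template.atlanto_occipital_pivot

    def rot(p):
        return rotate_about(p, pivot, angle)

    return replace(
        scene,
        upper_incisor_apex=rot(scene.upper_incisor_apex),
        lower_incisor_apex=rot(scene.lower_incisor_apex),
        gnathion=rot(scene.gnathion),
        tmj_condyle=rot(scene.tmj_condyle),
        tongue_outline=rot(scene.tongue_outline),
        head_extension_angle=float(angle),
    )


def _mandible_gap(scene: Scene, theta_deg: float) -> float:
    lower = rotate_about(scene.lower_incisor_apex, scene.tmj_condyle, -theta_deg)
    return float(np.linalg.norm(scene.upper_incisor_apex - lower))


def open_mandible(scene: Scene, mouth_opening: float, config: ModelConfig = DEFAULT_CONFIG) -> Scene:
    """Rotate the mandible open about the TMJ condyle to the measured gap.

    ``mouth_opening`` is in cm.  The rotation angle theta in (0°, 70°] is the
    root of |upper incisor - rotated lower incisor| = mouth opening, solved
    to a gap error below 1e-6 mm.  A gap no rotation can achieve raises
    :class:`UnreachableOpeningError`.
    """
    if mouth_opening <= 0:
        raise RangeError("mouth_opening", mouth_opening, "mouth_opening > 0")
    target = mouth_opening * 10.0  # cm -> mm
    theta_max = config.mouth_max_angle_deg
    g0, g1 = _mandible_gap(scene, 0.0), _mandible_gap(scene, theta_max)
    if abs(target - g0) <= _GAP_TOL_MM:
        return scene  # degenerate: neutral gap, zero rotation
    if not (g0 < target <= g1 + _GAP_TOL_MM):
        raise UnreachableOpeningError(target, (g0, g1))
    theta = brentq(lambda th: _mandible_gap(scene, th) - target, 0.0, theta_max, xtol=1e-10)

    def rot(p):
        return rotate_about(p, scene.tmj_condyle, -theta)

    return replace(
        scene,
        lower_incisor_apex=rot(scene.lower_incisor_apex),
        gnathion=rot(scene.gnathion),
        tongue_outline=rot(scene.tongue_outline),
        mandible_rotation_angle=float(theta),
    )


def lift_mandible(scene: Scene, tmj_rom: float, config: ModelConfig = DEFAULT_CONFIG) -> Scene:
    """Translate the mandible + tongue block by the laryngoscope lift.

    ``tmj_rom`` is in mm; the lift magnitude equals it exactly (optionally
    capped by ``config.lift_cap_mm``), directed between ventral and caudad at
    ``config.lift_direction_angle_deg``.
    """
    if tmj_rom < 0:
        raise RangeError("tmj_rom", tmj_rom, "tmj_rom >= 0")
    magnitude = tmj_rom if config.lift_cap_mm is None else min(tmj_rom, config.lift_cap_mm)
    v = np.asarray(config.lift_direction) * magnitude
    return replace(
        scene,
        lower_incisor_apex=scene.lower_incisor_apex + v,
        gnathion=scene.gnathion + v,
        tongue_outline=scene.tongue_outline + v,
        lift_vector=v,
    )


def place_hyoid_larynx(scene: Scene, thyromental: float, hyomental: float,
                       config: ModelConfig = DEFAULT_CONFIG) -> Scene:
    """Hang the hyoid and larynx from the chin along the anterior-neck ray.

    Distances in cm.  The thyroid notch sits at the thyromental distance from
    the neutral chin rest position (``gnathion_rest``), the hyoid at the
    hyomental distance on the same world-fixed ray; the anterior commissure
    anchors to the thyroid notch and the posterior commissure lies one
    laryngeal AP diameter along the glottal axis.
    """
    if thyromental <= 0:
        raise RangeError("thyromental", thyromental, "thyromental > 0")
    if hyomental <= 0:
        raise RangeError("hyomental", hyomental, "hyomental > 0")
    if thyromental <= hyomental:
        # clinically unusual but measured values are accepted as given
        warnings.warn("thyromental <= hyomental: accepted as measured", stacklevel=2)
    r = np.asarray(config.neck_ray_direction)
    g = np.asarray(config.glottal_axis_direction)
    thyroid = scene.gnathion_rest + r * thyromental * 10.0
    hyoid = scene.gnathion_rest + r * hyomental * 10.0
    glottis_a = thyroid.copy()
    glottis_p = glottis_a + g * scene.laryngeal_ap_diameter
    return replace(
        scene,
        thyroid_notch=thyroid,
        hyoid=hyoid,
        glottis_anterior=glottis_a,
        glottis_posterior=glottis_p,
    )


def compress_tongue(scene: Scene, tongue_thickness: float,
                    config: ModelConfig = DEFAULT_CONFIG) -> Scene:
    """Rebuild the tongue as the blade-compressed slab and the obstruction set.

    ``tongue_thickness`` in cm.  The compressed slab spans the mandibular
    floor from the (opened, lifted) lower incisor to the lifted tongue base
    at the hyoid; its maximal perpendicular thickness is
    rho * tongue_thickness, tapered toward both ends.  A small mandible
    crowds the same tongue into a shorter floor: thickness additionally
    scales by reference_body_length / actual_body_length (area
    conservation).
    """
    if tongue_thickness <= 0:
        raise RangeError("tongue_thickness", tongue_thickness, "tongue_thickness > 0")
    rho = config.tongue_retained_fraction
    crowding = scene.reference_body_length / scene.mandible_body_length
    h = rho * tongue_thickness * 10.0 * crowding  # mm

    e1 = scene.lower_incisor_apex
    e2 = scene.hyoid + scene.lift_vector  # tongue base rides the lifted block
    chord = e2 - e1
    length = float(np.linalg.norm(chord))
    d = chord / length
    n = np.array([-d[1], d[0]])
    mid = 0.5 * (e1 + e2)
    # the free surface faces the sight corridor, i.e. the upper-incisor side
    # of the floor chord (stable for every reachable configuration)
    side = float(np.dot(n, scene.upper_incisor_apex - mid))
    if side < 0 or (side == 0 and n[1] > 0):
        n = -n
    taper = 1.0 / config.tongue_bulge_factor
    # corridor-facing surface over the mid-to-base portion of the tongue;
    # near the teeth the corridor is bounded by the lower incisor itself
    params = (0.45, 0.65, 0.85, 1.0)
    weights = (taper, 1.0, 1.0, taper)
    surface = np.array([e1 + chord * t + n * h * w for t, w in zip(params, weights)])
    outline = np.vstack([e1, surface, e2])
    obstruction = np.vstack([surface, scene.lower_incisor_apex[None, :]])
    return replace(
        scene,
        tongue_outline=outline,
        compressed_tongue_surface=surface,
        obstruction_vertices=obstruction,
    )


def transform_patient(record: PatientRecord, config: ModelConfig = DEFAULT_CONFIG) -> Scene:
    """Run the full fixed-order transformation pipeline for one patient."""
    template = build_template(
        record.sex, record.height, record.weight, record.small_mandible, config
    )
    scene = apply_head_extension(template, record.head_up_grade, config)
    scene = open_mandible(scene, record.mouth_opening, config)
    scene = lift_mandible(scene, record.tmj_rom, config)
    scene = place_hyoid_larynx(scene, record.thyromental, record.hyomental, config)
    scene = compress_tongue(scene, record.tongue_thickness, config)
    return scene
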