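"""Sagittal anatomy template: reference landmarks scaled to the patient.

The template is a similarity-scaled copy of the reference skeleton in
:mod:`gadas.config`.  Two quantities deliberately break pure similarity:

* the laryngeal anteroposterior diameter is a fixed value per sex
  (25 mm male, 22 mm female) and is never scaled;
* a small mandible replaces the lower-incisor-to-gnathion body with a
  fixed short length (< 40 mm), whatever the patient's height.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import ModelConfig, DEFAULT_CONFIG
from .errors import RangeError
from .records import SEXES


@dataclass(frozen=True)
class AnatomyTemplate:
    """Scaled sagittal landmark set before any laryngoscopy transformation.

    All coordinates in mm in the supine sagittal frame (+x caudad,
    +y ventral, origin at the neutral upper incisor apex).
    """

    sex: str
    scale_factor: float
    laryngeal_ap_diameter: float  # mm, fixed by sex
    small_mandible: bool
    upper_incisor_apex: np.ndarray
    lower_incisor_apex: np.ndarray
    gnathion: np.ndarray
    gnathion_reference: np.ndarray  # chin position of the normal-length body
    tmj_condyle: np.ndarray
    hyoid: np.ndarray
    thyroid_notch: np.ndarray
    glottis_anterior: np.ndarray
    glottis_posterior: np.ndarray
    posterior_pharyngeal_wall: np.ndarray  # (k, 2) polyline
    tongue_outline: np.ndarray  # (k, 2) closed polyline (display)
    atlanto_occipital_pivot: np.ndarray
    mandible_body_length: float  # |lower incisor - gnathion|, mm
    reference_body_length: float  # same, for the normal-size mandible

    @property
    def neutral_interincisor_gap(self) -> float:
        """Closed-mouth distance between the incisor apices (mm)."""
        return float(np.linalg.norm(self.upper_incisor_apex - self.lower_incisor_apex))


def build_template(
    sex: str,
    height: float,
    weight: float,
    small_mandible: bool,
    config: ModelConfig = DEFAULT_CONFIG,
) -> AnatomyTemplate:
    """Build the patient-scaled anatomy template.

    Landmarks scale uniformly by ``(height / reference_height)**exponent``
    about the upper incisor apex.  Weight is accepted for interface
    completeness but has no geometric effect (no published size law uses
    it).  The glottis is given a provisional neutral placement here; its
    definitive position comes from ``place_hyoid_larynx``.
    """
    if sex not in SEXES:
        raise RangeError("sex", sex, "sex in {male, female}")
    if height <= 0:
        raise RangeError("height", height, "height > 0")

    s = (height / config.reference_height_cm) ** config.scaling_exponent
    lm = config.landmarks

    def pt(name: str) -> np.ndarray:
        return np.asarray(lm[name], dtype=float) * s

    def poly(name: str) -> np.ndarray:
        return np.asarray(lm[name], dtype=float) * s

    upper = pt("upper_incisor_apex")
    lower = pt("lower_incisor_apex")
    gnathion = pt("gnathion")
    condyle = pt("tmj_condyle")
    pivot = np.asarray(config.atlanto_occipital_pivot_mm, dtype=float) * s

    reference_body_length = float(np.linalg.norm(gnathion - lower))
    gnathion_reference = gnathion.copy()
    if small_mandible:
        # shorten the mandibular body along its own axis; the chin moves
        # toward the lower incisor, the direction is preserved
        axis = (gnathion - lower) / reference_body_length
        gnathion = lower + axis * config.small_mandible_body_length_mm
    body_length = float(np.linalg.norm(gnathion - lower))

    ap = config.laryngeal_ap_diameter_mm[sex]  # fixed, not scaled
    r = np.asarray(config.neck_ray_direction)
    g = np.asarray(config.glottal_axis_direction)
    # provisional neutral placement (typical distances), replaced downstream
    thyroid = gnathion_reference + r * 80.0 * s
    hyoid = gnathion_reference + r * 50.0 * s
    glottis_a = thyroid.copy()
    glottis_p = glottis_a + g * ap

    return AnatomyTemplate(
        sex=sex,
        scale_factor=float(s),
        laryngeal_ap_diameter=float(ap),
        small_mandible=bool(small_mandible),
        upper_incisor_apex=upper,
        lower_incisor_apex=lower,
        gnathion=gnathion,
        gnathion_reference=gnathion_reference,
        tmj_condyle=condyle,
        hyoid=hyoid,
        thyroid_notch=thyroid,
        glottis_anterior=glottis_a,
        glottis_posterior=glottis_p,
        posterior_pharyngeal_wall=poly("posterior_pharyngeal_wall"),
        tongue_outline=poly("tongue_outline"),
        atlanto_occipital_pivot=pivot,
        mandible_body_length=body_length,
        reference_body_length=reference_body_length,
    )


def rotate_about(points: np.ndarray, pivot: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate point(s) about ``pivot`` by ``angle_deg`` (counterclockwise
    positive in the +x caudad / +y ventral frame)."""
    a = math.radians(angle_deg)
    c, sn = math.cos(a), math.sin(a)
    rot = np.array([[c, -sn], [sn, c]])
    p = np.atleast_2d(points) - pivot
    out = p @ rot.T + pivot
    return out[0] if np.ndim(points) == 1 else out
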