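"""Model configuration: every tunable constant of the simulator.

The geometric rules of the simulator (head extension, mandible rotation,
laryngoscope lift, hyoid/larynx placement, tongue compression, sight line)
are fixed; everything numeric about them lives here and ships as explicit
data, so a configuration JSON fully determines the model.

Coordinate frame (all geometry in mm):
    patient supine, sagittal plane;
    origin at the neutral-position upper incisor apex;
    +x caudad (toward the feet), +y ventral (anterior, toward the ceiling —
    the laryngoscope lift direction).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

from .errors import ConfigError

Point = tuple[float, float]

# Reference sagittal landmarks for a 170 cm adult (mm, frame above).  The
# same skeleton serves both sexes; sex changes only the laryngeal AP span.
# These coordinates are free model data: they were calibrated once so that a
# favourable reference patient attains full glottic exposure and so that the
# directional behaviour of every input matches direct-laryngoscopy practice
# (see docs/methods.md).
_REFERENCE_LANDMARKS: dict[str, object] = {
    "upper_incisor_apex": (0.0, 0.0),
    "lower_incisor_apex": (2.0, -5.0),
    "tmj_condyle": (15.0, -80.0),
    "gnathion": (46.0, -16.0),
    "posterior_pharyngeal_wall": [(-40.0, -135.0), (150.0, -135.0)],
    # display-only neutral tongue; the obstructing outline is rebuilt by
    # compress_tongue from the measured thickness
    "tongue_outline": [
        (8.0, -12.0),
        (38.0, -14.0),
        (50.0, -45.0),
        (44.0, -62.0),
        (18.0, -48.0),
    ],
}


@dataclass(frozen=True)
class ModelConfig:
    """All constants of the laryngoscopy simulator.

    Parameters
    ----------
    head_up_angle_map
        Sniffing-position grade (1–4) -> dorsal head-extension angle in
        degrees.  Grade 1 is the best extension; the map must be strictly
        decreasing in grade.
    lift_direction_angle_deg
        Direction of the laryngoscope lift vector, measured from the ventral
        (+y) axis toward caudad (+x).  45° splits the "forward and downward"
        lift equally.
    tongue_retained_fraction
        Fraction rho of the measured tongue thickness retained after blade
        compression, rho in (0, 1].
    reference_height_cm, scaling_exponent
        Template landmarks are scaled by (height / reference_height)**exponent.
    small_mandible_body_length_mm
        Modelled lower-incisor-to-gnathion length when the small-mandible
        flag is set (< 40 mm by definition).
    tau_di_mm, tau_dl_mm
        Screening thresholds on V for difficult intubation / difficult
        laryngoscopy (positive call when V <= tau); tau_di <= tau_dl.
    anterior_neck_angle_deg
        Direction of the anterior-neck ray carrying the hyoid and thyroid
        notch, measured dorsally from the caudad (+x) axis, fixed in the
        world (spine) frame.
    glottal_axis_angle_deg
        Orientation of the glottal anteroposterior segment (anterior ->
        posterior commissure), same convention.
    laryngeal_ap_diameter_mm
        Fixed anteroposterior span of the glottis per sex; never scaled by
        body size.
    tongue_bulge_factor
        Mid-surface bulge of the compressed tongue relative to its end
        thickness (>= 1).
    mouth_max_angle_deg
        Upper bound of the mandible-opening rotation search.
    lift_cap_mm
        Optional cap on the lift magnitude (None: lift equals the TMJ range
        of motion exactly).
    atlanto_occipital_pivot_mm
        Pivot of head extension in the reference frame.
    landmarks
        Reference sagittal landmark coordinates (see module docstring).
    """

    head_up_angle_map: dict[int, float] = field(
        default_factory=lambda: {1: 25.0, 2: 15.0, 3: 8.0, 4: 3.0}
    )
    lift_direction_angle_deg: float = 45.0
    tongue_retained_fraction: float = 2.0 / 3.0
    reference_height_cm: float = 170.0
    scaling_exponent: float = 1.0
    small_mandible_body_length_mm: float = 35.0
    tau_di_mm: float = -4.0
    tau_dl_mm: float = -1.0
    anterior_neck_angle_deg: float = 89.0
    glottal_axis_angle_deg: float = 89.0
    laryngeal_ap_diameter_mm: dict[str, float] = field(
        default_factory=lambda: {"male": 25.0, "female": 22.0}
    )
    tongue_bulge_factor: float = 1.0
    mouth_max_angle_deg: float = 70.0
    lift_cap_mm: float | None = None
    atlanto_occipital_pivot_mm: Point = (25.0, -95.0)
    landmarks: dict[str, object] = field(
        default_factory=lambda: json.loads(json.dumps(_REFERENCE_LANDMARKS))
    )

    def __post_init__(self):
        grades = sorted(self.head_up_angle_map)
        if grades != [1, 2, 3, 4]:
            raise ConfigError("head_up_angle_map must define grades 1-4")
        angles = [self.head_up_angle_map[g] for g in grades]
        if not all(a > b for a, b in zip(angles, angles[1:])):
            raise ConfigError("head_up_angle_map must be strictly decreasing in grade")
        if not 0.0 < self.tongue_retained_fraction <= 1.0:
            raise ConfigError("tongue_retained_fraction must lie in (0, 1]")
        if self.tau_di_mm > self.tau_dl_mm:
            raise ConfigError("tau_di_mm must be <= tau_dl_mm")
        if self.reference_height_cm <= 0:
            raise ConfigError("reference_height_cm must be positive")
        for sex in ("male", "female"):
            if self.laryngeal_ap_diameter_mm.get(sex, 0) <= 0:
                raise ConfigError(f"laryngeal_ap_diameter_mm[{sex!r}] must be positive")
        if self.tongue_bulge_factor < 1.0:
            raise ConfigError("tongue_bulge_factor must be >= 1")
        if self.small_mandible_body_length_mm >= 40.0:
            raise ConfigError("small_mandible_body_length_mm must be < 40 mm")

    # -- unit-vector helpers -------------------------------------------------

    @property
    def neck_ray_direction(self) -> Point:
        """Unit vector of the anterior-neck ray (caudad-dorsal quadrant)."""
        a = math.radians(self.anterior_neck_angle_deg)
        return (math.cos(a), -math.sin(a))

    @property
    def glottal_axis_direction(self) -> Point:
        """Unit vector from anterior to posterior commissure."""
        a = math.radians(self.glottal_axis_angle_deg)
        return (math.cos(a), -math.sin(a))

    @property
    def lift_direction(self) -> Point:
        """Unit vector of the laryngoscope lift (ventral-caudad quadrant)."""
        a = math.radians(self.lift_direction_angle_deg)
        return (math.sin(a), math.cos(a))

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["head_up_angle_map"] = {str(k): v for k, v in self.head_up_angle_map.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "head_up_angle_map" in d:
            d["head_up_angle_map"] = {int(k): float(v) for k, v in d["head_up_angle_map"].items()}
        if "atlanto_occipital_pivot_mm" in d:
            d["atlanto_occipital_pivot_mm"] = tuple(d["atlanto_occipital_pivot_mm"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def with_(self, **kwargs) -> "ModelConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


DEFAULT_CONFIG = ModelConfig()
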