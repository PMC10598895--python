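"""Patient records: the bedside measurements the simulator consumes.

All lengths are in the clinical units they are measured in (cm, except the
TMJ range of motion which is measured in mm); the geometry engine converts
to mm internally.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

from .errors import MissingInputError, RangeError

SEXES = ("male", "female")

#: field -> (lower, upper, lower_inclusive, upper_inclusive)
_NUMERIC_BOUNDS: dict[str, tuple[float, float, bool, bool]] = {
    "age": (18.0, 120.0, True, True),
    "height": (120.0, 220.0, True, True),
    "weight": (30.0, 200.0, True, True),
    "mouth_opening": (0.0, 8.0, False, True),
    "thyromental": (0.0, 15.0, False, True),
    "hyomental": (0.0, 12.0, False, True),
    "tongue_thickness": (0.0, 12.0, False, True),
    "tmj_rom": (0.0, 30.0, True, True),
}

_GRADE_FIELDS = ("mallampati", "head_up_grade")

FIELD_NAMES = (
    "sex",
    "age",
    "height",
    "weight",
    "mouth_opening",
    "mallampati",
    "thyromental",
    "head_up_grade",
    "tongue_thickness",
    "hyomental",
    "tmj_rom",
    "small_mandible",
)


@dataclass(frozen=True)
class PatientRecord:
    """One patient's validated anatomical measurements.

    Units: height/thyromental/hyomental/mouth_opening/tongue_thickness in cm,
    weight in kg, tmj_rom in mm, age in years; grades are integers 1-4.
    """

    sex: str
    age: float
    height: float
    weight: float
    mouth_opening: float
    mallampati: int
    thyromental: float
    head_up_grade: int
    tongue_thickness: float
    hyomental: float
    tmj_rom: float
    small_mandible: bool

    def to_dict(self) -> dict:
        d = asdict(self)
        d["small_mandible"] = int(self.small_mandible)
        return d


def _check_range(field: str, value: float) -> float:
    lo, hi, lo_inc, hi_inc = _NUMERIC_BOUNDS[field]
    ok_lo = value >= lo if lo_inc else value > lo
    ok_hi = value <= hi if hi_inc else value < hi
    if not (ok_lo and ok_hi):
        lb, rb = ("[" if lo_inc else "("), ("]" if hi_inc else ")")
        raise RangeError(field, value, f"{field} in {lb}{lo}, {hi}{rb}")
    return float(value)


def validate_record(raw: Mapping[str, object]) -> PatientRecord:
    """Validate and coerce a raw mapping into a :class:`PatientRecord`.

    Raises :class:`~gadas.errors.MissingInputError` naming the first absent
    field and :class:`~gadas.errors.RangeError` naming the violated bound.
    """
    for name in FIELD_NAMES:
        if name not in raw or raw[name] is None or raw[name] == "":
            raise MissingInputError(name)

    sex = str(raw["sex"]).strip().lower()
    if sex not in SEXES:
        raise RangeError("sex", raw["sex"], "sex in {male, female}")

    values: dict[str, object] = {"sex": sex}
    for name in _NUMERIC_BOUNDS:
        try:
            v = float(raw[name])  # type: ignore[arg-type]
        except (TypeError, ValueError):
            raise RangeError(name, raw[name], f"{name} must be numeric") from None
        if v != v:  # NaN
            raise RangeError(name, raw[name], f"{name} must be finite")
        values[name] = _check_range(name, v)

    for name in _GRADE_FIELDS:
        try:
            g = float(raw[name])  # type: ignore[arg-type]
        except (TypeError, ValueError):
            raise RangeError(name, raw[name], f"{name} must be an integer grade") from None
        if g != int(g) or not 1 <= int(g) <= 4:
            raise RangeError(name, raw[name], f"{name} an integer in 1-4")
        values[name] = int(g)

    sm = raw["small_mandible"]
    if isinstance(sm, str):
        s = sm.strip().lower()
        if s in ("0", "false", "no"):
            sm = False
        elif s in ("1", "true", "yes"):
            sm = True
        else:
            raise RangeError("small_mandible", sm, "small_mandible in {0, 1}")
    elif isinstance(sm, (bool, int, float)) and float(sm) in (0.0, 1.0):
        sm = bool(sm)
    else:
        raise RangeError("small_mandible", sm, "small_mandible in {0, 1}")
    values["small_mandible"] = sm

    return PatientRecord(**values)  # type: ignore[arg-type]
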