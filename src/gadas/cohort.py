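"""Synthetic two-group patient cohorts.

No deposited dataset accompanies the screening study, so validation runs on
synthetic cohorts whose group-conditional marginals reproduce the published
two-group summary statistics: per-group mean/SD for the five continuous
airway measurements, categorical rates (small mandible, head-up grade,
Mallampati > 2, sex), log-normal ages fit to the published median/IQR, and
the observed prevalence of difficult intubation (56/2068).

Continuous variables are drawn independently within group from truncated
normal distributions by inverse-CDF; only marginals are published, so no
joint structure is imposed (a correlation hook exists but defaults to
independence).  Height is drawn from sex-specific population normals and
weight derived from the group's BMI distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .errors import RangeError
from .records import PatientRecord, validate_record

Group = Literal["difficult", "non_difficult"]

#: truncation bounds (same units as the variable) applied to every draw;
#: chosen inside the PatientRecord validity ranges, >= 3.7 SD from every
#: group mean so the sampled moments match the specified ones
TRUNCATION_BOUNDS: dict[str, tuple[float, float]] = {
    "thyromental": (3.0, 12.0),
    "mouth_opening": (1.5, 8.0),
    "hyomental": (2.5, 8.0),
    "tongue_thickness": (3.0, 9.0),
    "tmj_rom": (0.0, 30.0),
    "bmi": (14.0, 45.0),
    "height": (140.0, 200.0),
    "age": (18.0, 95.0),
}


@dataclass(frozen=True)
class GroupSpec:
    """Distribution parameters for one outcome group."""

    continuous: dict[str, tuple[float, float]]  # var -> (mean, sd)
    small_mandible_p: float
    head_up_grade_probs: tuple[float, float, float, float]
    mallampati_gt2_p: float
    male_p: float
    age_log_mu: float
    age_log_sigma: float
    bmi_mean: float
    bmi_sd: float

    def __post_init__(self):
        for var, (m, sd) in self.continuous.items():
            if sd <= 0:
                raise RangeError(f"{var}.sd", sd, "sd > 0")
        for name, p in (
            ("small_mandible_p", self.small_mandible_p),
            ("mallampati_gt2_p", self.mallampati_gt2_p),
            ("male_p", self.male_p),
        ):
            if not 0.0 <= p <= 1.0:
                raise RangeError(name, p, "probability in [0, 1]")
        if abs(sum(self.head_up_grade_probs) - 1.0) > 1e-9:
            raise RangeError("head_up_grade_probs", self.head_up_grade_probs, "sum to 1")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group generative model of a screening cohort."""

    difficult: GroupSpec
    non_difficult: GroupSpec
    prevalence: float
    truncation: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TRUNCATION_BOUNDS)
    )

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise RangeError("prevalence", self.prevalence, "prevalence in (0, 1)")

    def group(self, name: Group) -> GroupSpec:
        return self.difficult if name == "difficult" else self.non_difficult


def _lognormal_from_median_iqr(median: float, q25: float, q75: float) -> tuple[float, float]:
    mu = float(np.log(median))
    sigma = float((np.log(q75) - np.log(q25)) / (2.0 * stats.norm.ppf(0.75)))
    return mu, sigma


def default_spec_from_table1() -> CohortSpec:
    """The cohort spec matching the published difficult-intubation groups.

    Difficult group n = 56, non-difficult n = 2012 (prevalence 56/2068);
    continuous means/SDs, small-mandible rates, head-up grade counts,
    Mallampati > 2 rates, sex counts and age median/IQR are the published
    group summaries.
    """
    difficult = GroupSpec(
        continuous={
            "thyromental": (6.7, 0.8),
            "mouth_opening": (3.4, 0.5),
            "hyomental": (4.6, 0.4),
            "tongue_thickness": (6.3, 0.5),
            "tmj_rom": (9.5, 2.5),
        },
        small_mandible_p=15 / 56,
        head_up_grade_probs=(30 / 56, 26 / 56, 0.0, 0.0),
        mallampati_gt2_p=34 / 56,
        male_p=32 / 56,
        age_log_mu=_lognormal_from_median_iqr(62, 52, 69)[0],
        age_log_sigma=_lognormal_from_median_iqr(62, 52, 69)[1],
        bmi_mean=23.4,
        bmi_sd=3.6,
    )
    non_difficult = GroupSpec(
        continuous={
            "thyromental": (7.7, 0.9),
            "mouth_opening": (4.1, 0.6),
            "hyomental": (5.3, 0.5),
            "tongue_thickness": (5.9, 0.5),
            "tmj_rom": (14.0, 2.3),
        },
        small_mandible_p=51 / 2012,
        head_up_grade_probs=(2006 / 2012, 6 / 2012, 0.0, 0.0),
        mallampati_gt2_p=537 / 2012,
        male_p=969 / 2012,
        age_log_mu=_lognormal_from_median_iqr(50, 41, 62)[0],
        age_log_sigma=_lognormal_from_median_iqr(50, 41, 62)[1],
        bmi_mean=22.9,
        bmi_sd=3.5,
    )
    return CohortSpec(difficult=difficult, non_difficult=non_difficult, prevalence=56 / 2068)


#: sex-specific adult stature (cm): mean, sd — East-Asian surgical population
_HEIGHT_BY_SEX = {"male": (170.0, 6.5), "female": (158.0, 6.0)}


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  bounds: tuple[float, float], size: int) -> np.ndarray:
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    u = rng.random(size)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _sample_group(spec: CohortSpec, group: Group, n: int,
                  rng: np.random.Generator) -> list[PatientRecord]:
    g = spec.group(group)
    tb = spec.truncation
    cont = {
        var: _trunc_normal(rng, m, sd, tb[var], n) for var, (m, sd) in g.continuous.items()
    }
    male = rng.random(n) < g.male_p
    height = np.where(
        male,
        _trunc_normal(rng, *_HEIGHT_BY_SEX["male"], tb["height"], n),
        _trunc_normal(rng, *_HEIGHT_BY_SEX["female"], tb["height"], n),
    )
    bmi = _trunc_normal(rng, g.bmi_mean, g.bmi_sd, tb["bmi"], n)
    weight = np.clip(bmi * (height / 100.0) ** 2, 30.0, 200.0)
    lo, hi = np.log(tb["age"][0]), np.log(tb["age"][1])
    log_age = _trunc_normal(rng, g.age_log_mu, g.age_log_sigma, (lo, hi), n)
    age = np.exp(log_age)
    grade = rng.choice(4, size=n, p=np.asarray(g.head_up_grade_probs)) + 1
    small = rng.random(n) < g.small_mandible_p
    gt2 = rng.random(n) < g.mallampati_gt2_p
    # split the published >2 / <=2 rates into the four grades (fixed shares)
    mallampati = np.where(
        gt2,
        np.where(rng.random(n) < 0.8, 3, 4),
        np.where(rng.random(n) < 0.55, 1, 2),
    )
    records = []
    for i in range(n):
        records.append(
            validate_record(
                {
                    "sex": "male" if male[i] else "female",
                    "age": round(float(age[i]), 1),
                    "height": round(float(height[i]), 1),
                    "weight": round(float(weight[i]), 1),
                    "mouth_opening": float(cont["mouth_opening"][i]),
                    "mallampati": int(mallampati[i]),
                    "thyromental": float(cont["thyromental"][i]),
                    "head_up_grade": int(grade[i]),
                    "tongue_thickness": float(cont["tongue_thickness"][i]),
                    "hyomental": float(cont["hyomental"][i]),
                    "tmj_rom": float(cont["tmj_rom"][i]),
                    "small_mandible": bool(small[i]),
                }
            )
        )
    return records


def sample_group(spec: CohortSpec, group: Group, n: int, seed: int) -> list[PatientRecord]:
    """Draw ``n`` records from one group's marginals (forced-group draws)."""
    if n < 1:
        raise RangeError("n", n, "n >= 1")
    return _sample_group(spec, group, n, np.random.default_rng(seed))


def generate_cohort(spec: CohortSpec, n: int, seed: int) -> tuple[list[PatientRecord], np.ndarray]:
    """Generate a cohort of ``n`` patients with Bernoulli(prevalence) labels.

    Returns ``(records, labels)`` with ``labels[i]`` True for the difficult
    group; reproducible given ``(spec, n, seed)``.
    """
    if n < 1:
        raise RangeError("n", n, "n >= 1")
    rng = np.random.default_rng(seed)
    labels = rng.random(n) < spec.prevalence
    difficult = _sample_group(spec, "difficult", int(labels.sum()), rng)
    easy = _sample_group(spec, "non_difficult", int(n - labels.sum()), rng)
    records: list[PatientRecord | None] = [None] * n
    it_d, it_e = iter(difficult), iter(easy)
    for i, lab in enumerate(labels):
        records[i] = next(it_d) if lab else next(it_e)
    return records, labels  # type: ignore[return-value]
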