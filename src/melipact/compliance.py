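"""Threshold screening, blend flagging, and two-tier adulteration grading.

Every sample (after reclassification) is screened against the policy limits
and receives a set of violation codes.  Four parameters — sucrose, 5-HMF,
free acidity, and diastase activity — are the ones whose deviation is read
as adulteration proper (syrup addition, overheating, enzyme loss); any such
code puts the sample in the ADULTERATED tier.  The remaining codes (low
monosaccharide sum, high moisture, suspiciously low conductivity, high
insoluble matter) mark a sample as SUSPECT only.  A sample with no code is
COMPLIANT.

Flower-honey samples whose glucose+fructose sum misses the blossom floor but
still clears the honeydew floor, with conductivity just below the honeydew
cut, are additionally annotated as possible nectar/honeydew blends; the flag
is informational and never changes the grade.

All comparisons are strict inequalities: a value exactly at a limit is
compliant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

from .data_model import HoneySample, HoneyType, SampleTable, ThresholdPolicy

__all__ = [
    "ViolationCode",
    "ADULTERATION_CODES",
    "Grade",
    "ViolationReport",
    "Verdict",
    "ComplianceSummary",
    "check_sample",
    "flag_blend",
    "grade_verdict",
    "summarize_compliance",
]


class ViolationCode(str, Enum):
    HIGH_SUCROSE = "HIGH_SUCROSE"
    HIGH_HMF = "HIGH_HMF"
    HIGH_ACIDITY = "HIGH_ACIDITY"
    LOW_DIASTASE = "LOW_DIASTASE"
    LOW_SUGAR_SUM = "LOW_SUGAR_SUM"
    HIGH_MOISTURE = "HIGH_MOISTURE"
    LOW_ECOND = "LOW_ECOND"
    HIGH_INSOLUBLE = "HIGH_INSOLUBLE"


#: Codes whose presence grades a sample ADULTERATED.
ADULTERATION_CODES = frozenset(
    {
        ViolationCode.HIGH_SUCROSE,
        ViolationCode.HIGH_HMF,
        ViolationCode.HIGH_ACIDITY,
        ViolationCode.LOW_DIASTASE,
    }
)


class Grade(str, Enum):
    ADULTERATED = "ADULTERATED"
    SUSPECT = "SUSPECT"
    COMPLIANT = "COMPLIANT"


@dataclass(frozen=True)
class ViolationReport:
    sample_id: str
    codes: frozenset[ViolationCode]
    blend_suspect: bool
    sugar_sum: float


@dataclass(frozen=True)
class Verdict:
    grade: Grade
    triggering_codes: frozenset[ViolationCode]


def check_sample(
    sample: HoneySample,
    policy: ThresholdPolicy | None = None,
    pressed: bool = False,
) -> ViolationReport:
    """Screen one sample against every policy limit.

    The sample's final (post-reclassification) type selects the type-aware
    limits: the sucrose ceiling (exception types get the higher one) and the
    glucose+fructose floor (honeydew gets the lower one).
    """
    policy = policy or ThresholdPolicy()
    t = sample.effective_type
    codes: set[ViolationCode] = set()
    if sample.suc > policy.sucrose_max(t):
        codes.add(ViolationCode.HIGH_SUCROSE)
    if sample.sugar_sum < policy.sugar_sum_min(t):
        codes.add(ViolationCode.LOW_SUGAR_SUM)
    if sample.hmf > policy.hmf_max:
        codes.add(ViolationCode.HIGH_HMF)
    if sample.acid > policy.acidity_max:
        codes.add(ViolationCode.HIGH_ACIDITY)
    if sample.dia < policy.diastase_min:
        codes.add(ViolationCode.LOW_DIASTASE)
    if sample.mc > policy.moisture_max:
        codes.add(ViolationCode.HIGH_MOISTURE)
    if sample.econd < policy.econd_low_flag:
        codes.add(ViolationCode.LOW_ECOND)
    insoluble_limit = policy.insoluble_max_pressed if pressed else policy.insoluble_max
    if sample.ins > insoluble_limit:
        codes.add(ViolationCode.HIGH_INSOLUBLE)
    return ViolationReport(
        sample_id=sample.sample_id,
        codes=frozenset(codes),
        blend_suspect=flag_blend(sample, policy),
        sugar_sum=sample.sugar_sum,
    )


def flag_blend(sample: HoneySample, policy: ThresholdPolicy | None = None) -> bool:
    """True for flower honey whose sugar profile suggests a honeydew blend.

    The sample must miss the blossom monosaccharide floor while clearing the
    honeydew floor, with conductivity inside [blend_econd_min, honeydew cut).
    """
    policy = policy or ThresholdPolicy()
    if sample.effective_type is HoneyType.HONEYDEW:
        return False
    s = sample.sugar_sum
    return (
        s < policy.sugar_sum_min_blossom
        and s >= policy.sugar_sum_min_honeydew
        and policy.blend_econd_min <= sample.econd
        and sample.econd < policy.econd_flower_max
    )


def grade_verdict(report: ViolationReport) -> Verdict:
    """Collapse a violation set into the three-tier grade.

    Adulteration-grade codes dominate: a sample carrying both kinds is
    ADULTERATED (and is counted only there).
    """
    adulteration = report.codes & ADULTERATION_CODES
    if adulteration:
        return Verdict(Grade.ADULTERATED, frozenset(adulteration))
    if report.codes:
        return Verdict(Grade.SUSPECT, frozenset(report.codes))
    return Verdict(Grade.COMPLIANT, frozenset())


def _round_half_up_1dp(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ComplianceSummary:
    total: int
    grade_counts: dict[Grade, int]
    code_counts: dict[ViolationCode, int]
    #: LOW_SUGAR_SUM records whose verdict is SUSPECT (records that also carry
    #: an adulteration-grade code are accounted in the adulterated tier).
    low_sugar_sum_suspect: int
    blend_count: int
    nonconforming_pct: float
    by_final_type: dict[str, dict[Grade, int]]
    by_region: dict[str, dict[Grade, int]]
    by_year: dict[int, dict[Grade, int]]

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "grades": {g.value: n for g, n in self.grade_counts.items()},
            "codes": {c.value: n for c, n in self.code_counts.items()},
            "low_sugar_sum_suspect": self.low_sugar_sum_suspect,
            "blend_flags": self.blend_count,
            "nonconforming_pct": self.nonconforming_pct,
            "by_final_type": {
                k: {g.value: n for g, n in v.items()} for k, v in self.by_final_type.items()
            },
            "by_region": {
                k: {g.value: n for g, n in v.items()} for k, v in self.by_region.items()
            },
            "by_year": {
                k: {g.value: n for g, n in v.items()} for k, v in self.by_year.items()
            },
        }


def summarize_compliance(
    table: SampleTable, policy: ThresholdPolicy | None = None
) -> ComplianceSummary:
    """Screen a whole (reclassified) table and aggregate grades and codes.

    The non-conforming fraction is (adulterated + suspect) / total in
    percent, rounded half-up to one decimal.
    """
    if len(table) == 0:
        raise ValueError("compliance fraction is undefined for an empty table")
    policy = policy or ThresholdPolicy()
    grade_counts: Counter = Counter({g: 0 for g in Grade})
    code_counts: Counter = Counter({c: 0 for c in ViolationCode})
    by_type: dict[str, Counter] = {}
    by_region: dict[str, Counter] = {}
    by_year: dict[int, Counter] = {}
    low_sum_suspect = 0
    blends = 0
    for s in table:
        report = check_sample(s, policy)
        verdict = grade_verdict(report)
        grade_counts[verdict.grade] += 1
        for c in report.codes:
            code_counts[c] += 1
        if report.blend_suspect:
            blends += 1
        if ViolationCode.LOW_SUGAR_SUM in report.codes and verdict.grade is Grade.SUSPECT:
            low_sum_suspect += 1
        for key, bucket in (
            (s.effective_type.value, by_type),
            (s.region.value, by_region),
            (s.year, by_year),
        ):
            bucket.setdefault(key, Counter({g: 0 for g in Grade}))[verdict.grade] += 1
    nonconforming = grade_counts[Grade.ADULTERATED] + grade_counts[Grade.SUSPECT]
    pct = _round_half_up_1dp(100.0 * nonconforming / len(table))
    return ComplianceSummary(
        total=len(table),
        grade_counts=dict(grade_counts),
        code_counts=dict(code_counts),
        low_sugar_sum_suspect=low_sum_suspect,
        blend_count=blends,
        nonconforming_pct=pct,
        by_final_type={k: dict(v) for k, v in by_type.items()},
        by_region={k: dict(v) for k, v in by_region.items()},
        by_year={k: dict(v) for k, v in by_year.items()},
    )
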