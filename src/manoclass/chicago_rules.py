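"""Chicago Classification v3.0 decision tree over per-swallow labels.

A study is ten wet swallows; each contributes an IRP class (normal/high) and a
swallow-pattern label.  The study-level IRP verdict selects the elevated-IRP
branch (achalasia I–III, EGJ outflow obstruction) or the normal-IRP branch
(distal esophageal spasm, hypercontractile esophagus, ineffective motility,
fragmented peristalsis, normal).  Within each branch, fixed count thresholds
over the ten pattern labels pick the diagnosis.

Two behaviours of the literal rule order deserve attention:

* Under elevated IRP, the "no panesophageal pressurization" check runs first,
  so a study with zero panesophageal but three premature swallows is typed as
  achalasia type I, not type III.  Pass ``strict_chicago=True`` to
  :func:`diagnose` to run the premature check first instead.
* FAILED and NORMAL per-swallow labels are tallied as ``other`` and no rule
  consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Sequence

from .types import Diagnosis, IRPClass, StudyIRP, SwallowPattern

__all__ = [
    "PatternCounts",
    "RuleThresholds",
    "aggregate_irp",
    "count_patterns",
    "diagnose",
    "diagnose_with_rule",
]


@dataclass(frozen=True)
class PatternCounts:
    """Per-study tally of swallow-pattern labels."""

    panesophageal: int = 0
    premature: int = 0
    weak: int = 0
    fragmented: int = 0
    dci_gt_8000: int = 0
    other: int = 0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"negative count for {name}: {value}")

    @property
    def total(self) -> int:
        return (
            self.panesophageal
            + self.premature
            + self.weak
            + self.fragmented
            + self.dci_gt_8000
            + self.other
        )


@dataclass(frozen=True)
class RuleThresholds:
    """Minimum pattern counts that fire each diagnostic rule."""

    min_pan_type2: int = 2
    min_prem_type3: int = 3
    min_prem_des: int = 3
    min_dci_hyper: int = 2
    min_weak_iem: int = 5
    min_frag: int = 5

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 1:
                raise ValueError(f"threshold {name} must be >= 1, got {value}")


DEFAULT_THRESHOLDS = RuleThresholds()


def aggregate_irp(per_swallow: Sequence[IRPClass]) -> StudyIRP:
    """Study-level IRP verdict: strict majority of per-swallow classes.

    HIGH wins only when strictly more than half the swallows are HIGH; an
    exact tie resolves to NORMAL.
    """
    if len(per_swallow) == 0:
        raise ValueError("cannot aggregate IRP over an empty study")
    n_high = sum(1 for c in per_swallow if c is IRPClass.HIGH)
    return StudyIRP.HIGH if 2 * n_high > len(per_swallow) else StudyIRP.NORMAL


def count_patterns(labels: Iterable[SwallowPattern]) -> PatternCounts:
    """Tally pattern labels; NORMAL/FAILED (and anything else) go to other."""
    tally = Counter(labels)
    counted = {
        "panesophageal": tally.pop(SwallowPattern.PANESOPHAGEAL, 0),
        "premature": tally.pop(SwallowPattern.PREMATURE, 0),
        "weak": tally.pop(SwallowPattern.WEAK, 0),
        "fragmented": tally.pop(SwallowPattern.FRAGMENTED, 0),
        "dci_gt_8000": tally.pop(SwallowPattern.DCI_GT_8000, 0),
    }
    return PatternCounts(other=sum(tally.values()), **counted)


def diagnose_with_rule(
    study_irp: StudyIRP,
    counts: PatternCounts,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
    *,
    strict_chicago: bool = False,
) -> tuple[Diagnosis, str]:
    """Run the decision tree; return the diagnosis and the rule that fired.

    ``strict_chicago`` moves the premature-contraction check ahead of the
    type I check in the elevated-IRP branch (the clinically intended order);
    the default preserves the literal published order.
    """
    t = thresholds
    if study_irp is StudyIRP.HIGH:
        if strict_chicago and counts.premature >= t.min_prem_type3 and counts.panesophageal < t.min_pan_type2:
            return Diagnosis.ACHALASIA_TYPE_III, f"high IRP and >= {t.min_prem_type3} premature (strict order)"
        if counts.panesophageal == 0:
            return Diagnosis.ACHALASIA_TYPE_I, "high IRP and no panesophageal pressurization"
        if counts.panesophageal >= t.min_pan_type2:
            return Diagnosis.ACHALASIA_TYPE_II, f"high IRP and >= {t.min_pan_type2} panesophageal pressurization"
        if counts.premature >= t.min_prem_type3:
            return Diagnosis.ACHALASIA_TYPE_III, f"high IRP and >= {t.min_prem_type3} premature contractions"
        return Diagnosis.EGJ_OUTFLOW_OBSTRUCTION, "high IRP, no achalasia rule fired"
    if counts.premature >= t.min_prem_des:
        return Diagnosis.DISTAL_ESOPHAGEAL_SPASM, f"normal IRP and >= {t.min_prem_des} premature contractions"
    if counts.dci_gt_8000 >= t.min_dci_hyper:
        return Diagnosis.HYPERCONTRACTILE_ESOPHAGUS, f"normal IRP and >= {t.min_dci_hyper} DCI > 8000"
    if counts.weak >= t.min_weak_iem:
        return Diagnosis.INEFFECTIVE_ESOPHAGEAL_MOTILITY, f"normal IRP and >= {t.min_weak_iem} weak contractions"
    if counts.fragmented >= t.min_frag:
        return Diagnosis.FRAGMENTED_PERISTALSIS, f"normal IRP and >= {t.min_frag} fragmented contractions"
    return Diagnosis.NORMAL_MOTILITY, "normal IRP, no rule fired"


def diagnose(
    study_irp: StudyIRP,
    counts: PatternCounts,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
    *,
    strict_chicago: bool = False,
) -> Diagnosis:
    """Study-level diagnosis from the IRP verdict and pattern counts."""
    return diagnose_with_rule(
        study_irp, counts, thresholds, strict_chicago=strict_chicago
    )[0]
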