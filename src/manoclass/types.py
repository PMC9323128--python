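"""Shared domain vocabulary for high-resolution esophageal manometry (HRM).

An HRM study records esophageal pressures with a 36-sensor catheter while the
patient performs 10 wet swallows.  Each swallow is summarized by two kinds of
label:

* an IRP class — whether the integrated relaxation pressure of the
  esophago-gastric junction stays below the catheter's cutoff (28 mmHg for the
  solid-state catheter emulated here) or not, and
* a swallow-pattern class — the pressure-topography appearance of the
  peristaltic wave (panesophageal pressurization, premature contraction, weak
  contraction, fragmented contraction, hypercontractile DCI > 8000, failed, or
  normal).

The Chicago Classification v3.0 decision tree aggregates the ten per-swallow
labels into a single study-level motility diagnosis.
"""

from __future__ import annotations

import enum


class SwallowPattern(enum.Enum):
    """Pressure-topography appearance of a single wet swallow."""

    NORMAL = "normal"
    PANESOPHAGEAL = "panesophageal"
    PREMATURE = "premature"
    WEAK = "weak"
    FRAGMENTED = "fragmented"
    DCI_GT_8000 = "dci_gt_8000"
    FAILED = "failed"


#: The five appearances the swallow-pattern classifier distinguishes.  NORMAL
#: and FAILED swallows are not classifier outputs; at study level they count
#: only toward the "other" tally that no diagnostic rule consumes.
CLASSIFIER_PATTERNS: tuple[SwallowPattern, ...] = (
    SwallowPattern.PANESOPHAGEAL,
    SwallowPattern.PREMATURE,
    SwallowPattern.WEAK,
    SwallowPattern.FRAGMENTED,
    SwallowPattern.DCI_GT_8000,
)


class IRPClass(enum.Enum):
    """Per-swallow integrated relaxation pressure class.

    NORMAL is the positive class when binary classification metrics are
    reported.
    """

    NORMAL = "normal"
    HIGH = "high"


#: Study-level IRP verdict shares the same two values.
StudyIRP = IRPClass


class Diagnosis(enum.Enum):
    """The nine study-level esophageal motility diagnoses supported here.

    Four live under the elevated-IRP branch of the decision tree, five under
    the normal-IRP branch.  Absent contractility is deliberately not an
    output.
    """

    ACHALASIA_TYPE_I = "achalasia_type_1"
    ACHALASIA_TYPE_II = "achalasia_type_2"
    ACHALASIA_TYPE_III = "achalasia_type_3"
    EGJ_OUTFLOW_OBSTRUCTION = "egj_outflow_obstruction"
    DISTAL_ESOPHAGEAL_SPASM = "distal_esophageal_spasm"
    HYPERCONTRACTILE_ESOPHAGUS = "hypercontractile_esophagus"
    INEFFECTIVE_ESOPHAGEAL_MOTILITY = "ineffective_esophageal_motility"
    FRAGMENTED_PERISTALSIS = "fragmented_peristalsis"
    NORMAL_MOTILITY = "normal_motility"


HIGH_IRP_DIAGNOSES: frozenset[Diagnosis] = frozenset(
    {
        Diagnosis.ACHALASIA_TYPE_I,
        Diagnosis.ACHALASIA_TYPE_II,
        Diagnosis.ACHALASIA_TYPE_III,
        Diagnosis.EGJ_OUTFLOW_OBSTRUCTION,
    }
)

#: Upper limit of normal IRP for the emulated solid-state catheter, mmHg.
IRP_CUTOFF_MMHG: float = 28.0

#: Contractile-vigor bounds (distal contractile integral, mmHg·cm·s).
WEAK_DCI_MMHG_CM_S: float = 450.0
HYPERCONTRACTILE_DCI_MMHG_CM_S: float = 8000.0

#: Distal latency below which a contraction is premature, seconds.
PREMATURE_LATENCY_S: float = 4.5

#: Minimum break in the 20 mmHg isobaric contour for a fragmented swallow, cm.
FRAGMENT_BREAK_CM: float = 5.0

#: Isobaric contour used by the distal contractile integral, mmHg.
DCI_ISOBAR_MMHG: float = 20.0
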