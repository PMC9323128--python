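"""Composition of the clinical reference dataset this package emulates.

The pipeline was designed around a labeled corpus of high-resolution
manometry images collected at a single referral centre (192 recordings,
2014–2021) that cannot be redistributed.  The tallies below document that
corpus's composition; the synthetic generator in :mod:`manoclass.synth_hrm`
stands in for it when training and testing the pipeline.
"""

from __future__ import annotations

from .types import SwallowPattern

#: Per-class image counts of the IRP-labeled corpus.
IRP_DATASET_COMPOSITION: dict[str, int] = {
    "normal": 140,
    "high": 939,
}

#: Per-class image counts of the swallow-pattern corpus.  The failed-
#: peristalsis images exist in the corpus but are excluded from the 5-class
#: classifier.
PATTERN_DATASET_COMPOSITION: dict[SwallowPattern, int] = {
    SwallowPattern.PANESOPHAGEAL: 256,
    SwallowPattern.PREMATURE: 27,
    SwallowPattern.WEAK: 54,
    SwallowPattern.FRAGMENTED: 58,
    SwallowPattern.DCI_GT_8000: 21,
    SwallowPattern.FAILED: 1119,
}

#: Number of classified recordings behind the corpora.
N_RECORDINGS: int = 192


def irp_dataset_total() -> int:
    return sum(IRP_DATASET_COMPOSITION.values())


def pattern_dataset_total() -> int:
    return sum(PATTERN_DATASET_COMPOSITION.values())
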