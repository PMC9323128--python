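"""End-to-end orchestration: synth -> preprocess -> train -> diagnose -> evaluate.

:func:`run_diagnosis` takes ten swallow images (a directory of PNGs or an
in-memory study batch), pushes each through the preprocessing chain and both
classifiers, and aggregates the per-swallow predictions through the decision
tree into a study-level diagnosis report.

:func:`run_experiment` is the reproducible benchmark: it generates a labeled
synthetic corpus, trains the two classifiers with the three-way split
discipline, evaluates them per swallow on their validation splits, then
diagnoses a held-out set of synthetic studies end to end and scores the
study-level accuracy.  Every stochastic stage derives its seed from the one
config seed, so a fixed config reproduces its reports byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__, chicago_rules, classify, evalmetrics, preprocess, synth_hrm
from .types import (
    CLASSIFIER_PATTERNS,
    Diagnosis,
    IRPClass,
    SwallowPattern,
)

__all__ = ["PipelineConfig", "run_diagnosis", "run_experiment", "ExperimentResult"]

log = logging.getLogger("manoclass")


@dataclass(frozen=True)
class PipelineConfig:
    """One config object reaching every stage; the seed feeds all randomness."""

    seed: int = 0
    # geometry / preprocessing
    image_width: int = 600
    image_height: int = 360
    binarize_threshold: float = 128.0
    marker_offset: int = 2
    top_margin: int = 0
    bottom_margin: int = 0
    irp_window_s: float = 10.0
    les_band_fraction: float = 0.25
    # classifiers
    irp_backbone: str = "tiny_test_cnn"
    pattern_backbone: str = "tiny_test_cnn"
    dropout_rate: float = 0.20
    batch_size: int = 32
    learning_rate: float = 1e-3
    epochs: int = 30
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    # rule engine
    strict_chicago: bool = False
    irp_cutoff: float = 28.0
    # experiment sizes
    n_pattern_per_class: int = 70
    n_extra_irp_images: int = 150
    n_eval_studies: int = 200
    excluded_diagnoses: tuple[str, ...] = ()
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        d["excluded_diagnoses"] = list(self.excluded_diagnoses)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        if "split_fractions" in data:
            data["split_fractions"] = tuple(data["split_fractions"])
        if "excluded_diagnoses" in data:
            data["excluded_diagnoses"] = tuple(data["excluded_diagnoses"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def included_diagnoses(self) -> list[Diagnosis]:
        excluded = {Diagnosis(d) for d in self.excluded_diagnoses}
        return [d for d in Diagnosis if d not in excluded]


# --- per-image preprocessing + prediction -----------------------------------


def _tensors_for_image(image: preprocess.HRMImage, config: PipelineConfig):
    mask = preprocess.binarize(image, config.binarize_threshold)
    marker_x = preprocess.locate_marker(mask)
    swallow = preprocess.crop_swallow(
        image,
        marker_x,
        top=config.top_margin,
        bottom=config.bottom_margin,
        marker_offset=config.marker_offset,
    )
    irp = preprocess.extract_irp_roi(
        image,
        marker_x,
        window_s=config.irp_window_s,
        les_band_fraction=config.les_band_fraction,
    )
    return (
        preprocess.prepare_tensor(irp, preprocess.ClassifierTarget.IRP),
        preprocess.prepare_tensor(swallow, preprocess.ClassifierTarget.PATTERN),
    )


def _round_probs(class_order, probs) -> dict:
    return {
        getattr(c, "value", str(c)): round(float(p), 6)
        for c, p in zip(class_order, probs)
    }


def run_diagnosis(
    study,
    models: Mapping[str, classify.TrainedClassifier],
    config: PipelineConfig,
    *,
    study_id: str = "study",
) -> dict:
    """Diagnose one study: preprocess and classify every swallow, then apply
    the decision tree.  ``study`` is a directory of swallow PNGs (ordered by
    filename) or a :class:`~manoclass.synth_hrm.StudyBatch`.

    Unreadable images are skipped with a warning; the study fails only if no
    image is usable.
    """
    for key in ("irp", "pattern"):
        if key not in models:
            raise ValueError(f"missing {key!r} model")

    if isinstance(study, synth_hrm.StudyBatch):
        entries = [
            (f"swallow_{i:02d}", s.image) for i, s in enumerate(study.swallows)
        ]
    else:
        study_dir = Path(study)
        files = sorted(study_dir.glob("*.png")) + sorted(study_dir.glob("*.jpg"))
        if not files:
            raise ValueError(f"no swallow images found in {study_dir}")
        entries = [(f.name, f) for f in files]

    records = []
    irp_classes: list[IRPClass] = []
    patterns: list[SwallowPattern] = []
    for name, source in entries:
        try:
            image = (
                source
                if isinstance(source, preprocess.HRMImage)
                else preprocess.HRMImage.open(source)
            )
            irp_tensor, pattern_tensor = _tensors_for_image(image, config)
            irp_label, irp_probs = models["irp"].predict(irp_tensor)
            pat_label, pat_probs = models["pattern"].predict(pattern_tensor)
        except Exception as exc:  # noqa: BLE001 - per-file resilience
            log.warning("skipping swallow %s: %s", name, exc)
            continue
        irp_classes.append(irp_label)
        patterns.append(pat_label)
        records.append(
            {
                "filename": name,
                "irp_class": irp_label.value,
                "irp_probabilities": _round_probs(models["irp"].class_order, irp_probs),
                "pattern": pat_label.value,
                "pattern_probabilities": _round_probs(
                    models["pattern"].class_order, pat_probs
                ),
            }
        )
    if not records:
        raise ValueError(f"no usable swallow image in study {study_id!r}")

    study_irp = chicago_rules.aggregate_irp(irp_classes)
    counts = chicago_rules.count_patterns(patterns)
    diagnosis, fired_rule = chicago_rules.diagnose_with_rule(
        study_irp, counts, strict_chicago=config.strict_chicago
    )
    return {
        "study_id": study_id,
        "swallows": records,
        "study_irp": study_irp.value,
        "pattern_counts": dataclasses.asdict(counts),
        "diagnosis": diagnosis.value,
        "fired_rule": fired_rule,
        "tool_version": __version__,
        "config_hash": config.config_hash,
        "seed": config.seed,
    }


# --- the end-to-end experiment ----------------------------------------------


@dataclass
class ExperimentResult:
    config: PipelineConfig
    irp_classifier: classify.TrainedClassifier
    pattern_classifier: classify.TrainedClassifier
    irp_validation: evalmetrics.MetricReport
    pattern_validation: evalmetrics.MetricReport
    study_confusion: evalmetrics.ConfusionMatrix
    study_report: evalmetrics.MetricReport
    study_reports: list[dict]

    @property
    def study_accuracy(self) -> float:
        return self.study_report.accuracy

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config.config_hash,
            "seed": self.config.seed,
            "tool_version": __version__,
            "irp_validation": self.irp_validation.to_dict(),
            "pattern_validation": self.pattern_validation.to_dict(),
            "study_level": self.study_report.to_dict(),
            "study_confusion": {
                "class_order": [d.value for d in self.study_confusion.class_order],
                "counts": self.study_confusion.counts.tolist(),
            },
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "experiment_report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out / "study_reports.json", "w") as fh:
            json.dump(self.study_reports, fh, indent=2, sort_keys=True)
            fh.write("\n")
        self.irp_classifier.save(out / "models" / "irp")
        self.pattern_classifier.save(out / "models" / "pattern")


def _featurize(sample: synth_hrm.SwallowSample, config, irp_bb, pat_bb):
    irp_tensor, pattern_tensor = _tensors_for_image(sample.image, config)
    return (
        classify.extract_features(irp_tensor, irp_bb),
        classify.extract_features(pattern_tensor, pat_bb),
    )


def run_experiment(config: PipelineConfig, out_dir=None) -> ExperimentResult:
    """Generate data, train both classifiers, and score the whole pipeline.

    Training corpus: ``n_pattern_per_class`` swallows for each of the five
    classifier patterns (random per-swallow IRP class) plus
    ``n_extra_irp_images`` normal/failed swallows that only the IRP task
    sees.  Held-out evaluation: ``n_eval_studies`` fresh studies sampled
    uniformly over the included diagnoses, diagnosed end to end from pixels.
    """
    logging.basicConfig(level=config.log_level)
    rng = np.random.default_rng(config.seed)
    irp_bb = classify.get_backbone(
        classify.BackboneSpec(config.irp_backbone, seed=int(rng.integers(2**31)))
    )
    pat_bb = classify.get_backbone(
        classify.BackboneSpec(config.pattern_backbone, seed=int(rng.integers(2**31)))
    )

    log.info("generating training corpus")
    irp_feats, irp_labels = [], []
    pat_feats, pat_labels = [], []
    for pattern in CLASSIFIER_PATTERNS:
        for _ in range(config.n_pattern_per_class):
            irp_class = IRPClass.HIGH if rng.random() < 0.5 else IRPClass.NORMAL
            sample = synth_hrm.generate_swallow(
                pattern,
                irp_class,
                int(rng.integers(2**31)),
                width_px=config.image_width,
                height_px=config.image_height,
            )
            f_irp, f_pat = _featurize(sample, config, irp_bb, pat_bb)
            irp_feats.append(f_irp)
            irp_labels.append(irp_class)
            pat_feats.append(f_pat)
            pat_labels.append(pattern)
    for _ in range(config.n_extra_irp_images):
        pattern = (
            SwallowPattern.NORMAL if rng.random() < 0.5 else SwallowPattern.FAILED
        )
        irp_class = IRPClass.HIGH if rng.random() < 0.5 else IRPClass.NORMAL
        sample = synth_hrm.generate_swallow(
            pattern,
            irp_class,
            int(rng.integers(2**31)),
            width_px=config.image_width,
            height_px=config.image_height,
        )
        f_irp, _ = _featurize(sample, config, irp_bb, pat_bb)
        irp_feats.append(f_irp)
        irp_labels.append(irp_class)

    train_cfg = classify.TrainConfig(
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        seed=int(rng.integers(2**31)),
        split_fractions=config.split_fractions,
    )
    log.info("training IRP classifier (%d images)", len(irp_feats))
    irp_clf = classify.train_classifier(
        np.array(irp_feats),
        irp_labels,
        classify.HeadConfig(2, config.dropout_rate),
        train_cfg,
        class_order=(IRPClass.NORMAL, IRPClass.HIGH),
        backbone=irp_bb,
    )
    log.info("training pattern classifier (%d images)", len(pat_feats))
    pat_clf = classify.train_classifier(
        np.array(pat_feats),
        pat_labels,
        classify.HeadConfig(5, config.dropout_rate),
        dataclasses.replace(train_cfg, seed=int(rng.integers(2**31))),
        class_order=CLASSIFIER_PATTERNS,
        backbone=pat_bb,
    )
    models = {"irp": irp_clf, "pattern": pat_clf}

    log.info("diagnosing %d held-out studies", config.n_eval_studies)
    included = config.included_diagnoses()
    true_dx, pred_dx, study_reports = [], [], []
    for i in range(config.n_eval_studies):
        diagnosis = included[int(rng.integers(len(included)))]
        batch = synth_hrm.generate_study(
            diagnosis,
            seed=int(rng.integers(2**31)),
            width_px=config.image_width,
            height_px=config.image_height,
        )
        report = run_diagnosis(batch, models, config, study_id=f"study_{i:04d}")
        report["intended_diagnosis"] = diagnosis.value
        study_reports.append(report)
        true_dx.append(diagnosis)
        pred_dx.append(Diagnosis(report["diagnosis"]))

    cm = evalmetrics.confusion_matrix(true_dx, pred_dx, list(Diagnosis))
    result = ExperimentResult(
        config=config,
        irp_classifier=irp_clf,
        pattern_classifier=pat_clf,
        irp_validation=irp_clf.validation_report,
        pattern_validation=pat_clf.validation_report,
        study_confusion=cm,
        study_report=evalmetrics.classification_report(cm),
        study_reports=study_reports,
    )
    log.info(
        "study-level top-1 accuracy: %s%%",
        evalmetrics.format_pct(result.study_accuracy),
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
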