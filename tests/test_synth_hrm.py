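"""Simulator: appearance oracles, metric formulas, labels, and rendering."""

import numpy as np
import pytest
from scipy.integrate import quad

from manoclass import chicago_rules, preprocess, synth_hrm as sh
from manoclass.types import Diagnosis, IRPClass, SwallowPattern

P = SwallowPattern


# --- pressure-field appearance ----------------------------------------------


@pytest.mark.parametrize("pattern", list(P))
def test_field_shape_contract(pattern):
    field = sh.simulate_pressure_field(pattern)
    assert field.values.shape == (36, 600)
    assert np.isfinite(field.values).all() and (field.values >= 0).all()


def test_failed_swallow_body_stays_near_baseline():
    """Grid scan: no body cell rises 20 mmHg above baseline."""
    field = sh.simulate_pressure_field(P.FAILED)
    lo, hi = sh.BODY_SENSORS
    body = field.values[lo : hi + 1]
    baseline = sh.SimParams().baseline_mmHg
    assert (body - baseline < 20.0).all()


def test_panesophageal_has_isobaric_band_across_whole_body():
    """Grid scan: some time band where every body sensor exceeds 30 mmHg."""
    field = sh.simulate_pressure_field(P.PANESOPHAGEAL)
    lo, hi = sh.BODY_SENSORS
    column_min = field.values[lo : hi + 1].min(axis=0)
    assert (column_min >= 30.0).any()


def test_unknown_pattern_and_bad_sample_rate_rejected():
    with pytest.raises(ValueError):
        sh.simulate_pressure_field("spastic")
    with pytest.raises(ValueError):
        sh.simulate_pressure_field(P.NORMAL, sample_rate_hz=0)


# --- DCI --------------------------------------------------------------------


def _noise_free(pattern):
    return sh.SimParams.defaults_for(pattern, noise_sd_mmHg=0.0)


def test_dci_zero_for_all_zero_and_isobar_level_fields():
    zero = sh.PressureField(np.zeros((36, 600)))
    assert sh.compute_dci(zero) == 0.0
    flat = sh.PressureField(np.full((36, 600), 20.0))
    assert sh.compute_dci(flat) == 0.0  # strict excess over the isobar


def test_dci_matches_independent_integration_of_gaussian_ridge():
    """Closed-form traveling ridge vs numerically integrated oracle, <1%."""
    params = _noise_free(P.NORMAL)
    field = sh.simulate_pressure_field(P.NORMAL, params)
    got = sh.compute_dci(field)

    lo, hi = sh.BODY_SENSORS
    n_body = hi - lo + 1
    amp, width = params.wave_amplitude_mmHg, params.wave_width_s
    expected = 0.0
    for s in range(sh.DISTAL_SENSORS[0], sh.DISTAL_SENSORS[1] + 1):
        arrival = field.swallow_onset_s + params.distal_latency_s * (s - lo) / (
            n_body - 1
        )

        def excess(t, mu=arrival):
            base = params.baseline_mmHg + amp * np.exp(
                -((t - mu) ** 2) / (2 * width**2)
            )
            return max(base - 20.0, 0.0)

        val, _ = quad(excess, field.swallow_onset_s, field.duration_s, limit=200)
        expected += val * field.sensor_spacing_cm
    assert got == pytest.approx(expected, rel=0.01)


def test_dci_agrees_with_brute_force_sum_on_random_fields():
    rng = np.random.default_rng(4)
    for _ in range(20):
        values = rng.uniform(0, 60, size=(36, 600))
        field = sh.PressureField(values)
        onset_idx = round(field.swallow_onset_s * field.sample_rate_hz)
        brute = 0.0
        for s in range(17, 31):
            for t in range(onset_idx, 600):
                brute += max(values[s, t] - 20.0, 0.0) * 1.0 * 0.1
        assert sh.compute_dci(field) == pytest.approx(brute)


def test_dci_rejects_bad_segments():
    field = sh.PressureField(np.zeros((36, 600)))
    with pytest.raises(ValueError):
        sh.compute_dci(field, 20, 10)
    with pytest.raises(ValueError):
        sh.compute_dci(field, 0, 40)


# --- IRP --------------------------------------------------------------------


def _field_with_les(signal: np.ndarray) -> sh.PressureField:
    values = np.zeros((36, 600))
    lo, hi = sh.LES_SENSORS
    values[lo : hi + 1, :] = signal[None, :]
    return sh.PressureField(values)


def test_irp_of_constant_les_signals():
    assert sh.compute_irp(_field_with_les(np.full(600, 30.0))) == pytest.approx(30.0)
    relaxed = np.full(600, 30.0)
    relaxed[300:] = 5.0  # relaxes for the whole post-onset window
    assert sh.compute_irp(_field_with_les(relaxed)) == pytest.approx(5.0)


def test_irp_linear_ramp_matches_sort_and_average_oracle():
    signal = np.linspace(50, 10, 600)
    field = _field_with_les(signal)
    window = signal[300:400]
    oracle = np.sort(window)[:40].mean()  # lowest 4 s of the 10 s window at 10 Hz
    assert sh.compute_irp(field) == pytest.approx(oracle)


def test_irp_window_past_field_end_rejected():
    values = np.zeros((36, 600))
    field = sh.PressureField(values, swallow_onset_s=55.0)
    with pytest.raises(ValueError):
        sh.compute_irp(field, window_s=10.0)


# --- rendering --------------------------------------------------------------


def test_marker_drawn_at_linear_time_to_column_position():
    field = sh.simulate_pressure_field(P.NORMAL, swallow_onset_s=30.0)
    image = sh.render_hrm_image(field, width_px=600, height_px=360)
    assert (image.pixels[:, 300:302] == 255).all()
    mask = preprocess.binarize(image)
    assert preprocess.locate_marker(mask) == 300


def test_constant_field_renders_constant_except_marker():
    field = sh.PressureField(np.full((36, 600), 10.0))
    image = sh.render_hrm_image(field, 600, 120)
    marker = round(30.0 / 60.0 * 600)
    rest = np.delete(image.pixels, [marker, marker + 1], axis=1)
    assert (rest == rest[0, 0]).all()


def test_marker_outside_image_rejected():
    field = sh.PressureField(np.zeros((36, 600)), swallow_onset_s=59.9)
    with pytest.raises(ValueError):
        sh.render_hrm_image(field, width_px=600, height_px=100)


def test_rendered_palette_is_darker_than_binarization_threshold():
    """Only the marker may survive the 128 threshold, for any pressure."""
    values = np.linspace(0, 300, 600)[None, :].repeat(36, axis=0)
    field = sh.PressureField(values)
    image = sh.render_hrm_image(field, 600, 36)
    gray = image.pixels.astype(float).mean(axis=2)
    non_marker = np.delete(gray, [300, 301], axis=1)
    assert non_marker.max() < 128


# --- labeled generation -----------------------------------------------------


def test_generated_swallow_labels_are_measured_and_consistent():
    high = sh.generate_swallow(P.NORMAL, IRPClass.HIGH, seed=2, render=False)
    assert high.truth.irp_mmHg > 28.0
    low = sh.generate_swallow(P.WEAK, IRPClass.NORMAL, seed=2, render=False)
    assert low.truth.irp_mmHg <= 28.0
    assert low.truth.dci < 450.0


def test_label_fidelity_across_generated_batches():
    """WEAK -> DCI<450, DCI_GT_8000 -> DCI>8000, IRP classes match cutoff."""
    for seed, diagnosis in enumerate(
        (
            Diagnosis.INEFFECTIVE_ESOPHAGEAL_MOTILITY,
            Diagnosis.HYPERCONTRACTILE_ESOPHAGUS,
            Diagnosis.ACHALASIA_TYPE_II,
        )
    ):
        batch = sh.generate_study(diagnosis, seed=seed, render=False)
        for s in batch.swallows:
            if s.truth.pattern is P.WEAK:
                assert s.truth.dci < 450.0
            if s.truth.pattern is P.DCI_GT_8000:
                assert s.truth.dci > 8000.0
            if s.truth.irp_class is IRPClass.HIGH:
                assert s.truth.irp_mmHg > 28.0
            else:
                assert s.truth.irp_mmHg <= 28.0


@pytest.mark.parametrize("diagnosis", list(Diagnosis))
def test_study_ground_truth_diagnoses_as_intended(diagnosis):
    for seed in range(5):
        batch = sh.generate_study(diagnosis, seed=seed, render=False)
        verdict = chicago_rules.diagnose(
            chicago_rules.aggregate_irp(batch.irp_classes),
            chicago_rules.count_patterns(batch.patterns),
        )
        assert verdict is diagnosis


def test_achalasia_type_2_batches_meet_their_rule():
    batch = sh.generate_study(Diagnosis.ACHALASIA_TYPE_II, seed=0, render=False)
    assert batch.patterns.count(P.PANESOPHAGEAL) >= 2
    assert chicago_rules.aggregate_irp(batch.irp_classes) is IRPClass.HIGH


def test_generate_study_is_deterministic():
    a = sh.generate_study(Diagnosis.NORMAL_MOTILITY, seed=42, render=False)
    b = sh.generate_study(Diagnosis.NORMAL_MOTILITY, seed=42, render=False)
    assert a.patterns == b.patterns and a.irp_classes == b.irp_classes
    assert all(
        np.array_equal(x.field.values, y.field.values)
        for x, y in zip(a.swallows, b.swallows)
    )


def test_generate_study_rejects_bad_inputs():
    with pytest.raises(ValueError):
        sh.generate_study("achalasia", seed=0)
    with pytest.raises(ValueError):
        sh.generate_study(Diagnosis.NORMAL_MOTILITY, n_swallows=3, seed=0)


def test_save_study_writes_pngs_and_manifest(tmp_path):
    batch = sh.generate_study(Diagnosis.DISTAL_ESOPHAGEAL_SPASM, seed=1)
    manifest = sh.save_study(batch, tmp_path, "study_0000")
    assert list(manifest.columns) == sh.MANIFEST_COLUMNS
    assert len(manifest) == 10
    assert len(list(tmp_path.glob("*.png"))) == 10
    reloaded = preprocess.HRMImage.open(tmp_path / manifest.filename[0])
    assert np.array_equal(reloaded.pixels, batch.swallows[0].image.pixels)


def test_sim_params_validation():
    with pytest.raises(ValueError):
        sh.SimParams(distal_latency_s=0.0)
    with pytest.raises(ValueError):
        sh.SimParams(wave_amplitude_mmHg=-1.0)
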