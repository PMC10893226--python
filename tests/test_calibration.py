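"""Calibration targets, objective, and scaled-down parameter recovery."""

import pytest

from ioqsp import CalibrationTarget, impower131_targets, simulate_endpoints
from ioqsp.calibration import _arm_loss, calibrate
from ioqsp.response import EndpointSummary


def _summary(orr, dor):
    return EndpointSummary(arm="x", n=100, orr=orr, orr_ci=(orr, orr),
                           median_dor_months=dor, dor_ci=(dor, dor))


def test_target_validation():
    chemo, triple = impower131_targets()
    assert chemo.orr == 0.410 and triple.orr == 0.497
    assert chemo.median_dor_months == 5.2 and triple.median_dor_months == 7.3
    with pytest.raises(ValueError):
        CalibrationTarget(arm="x", orr=0.5, orr_ci=(0.6, 0.7),
                          median_dor_months=5.0, dor_ci=(4.0, 6.0))


def test_arm_loss_zero_iff_exact_match():
    chemo, _ = impower131_targets()
    assert _arm_loss(_summary(0.410, 5.2), chemo) == 0.0
    assert _arm_loss(_summary(0.45, 5.2), chemo) > 0.0
    # hand-computed fixture value
    loss = _arm_loss(_summary(0.451, 4.68), chemo)
    assert loss == pytest.approx(abs(0.451 - 0.410) / 0.410
                                 + abs(4.68 - 5.2) / 5.2)


def test_arm_loss_symmetric_in_arms():
    chemo, triple = impower131_targets()
    a = _arm_loss(_summary(0.42, 5.0), chemo) \
        + _arm_loss(_summary(0.51, 7.0), triple)
    b = _arm_loss(_summary(0.51, 7.0), triple) \
        + _arm_loss(_summary(0.42, 5.0), chemo)
    assert a == b


def test_simulate_endpoints_seed_determinism(default_spec):
    from ioqsp import chemo_backbone

    a = simulate_endpoints(default_spec, chemo_backbone(), 12, seed=3,
                           duration=200.0, n_boot=100)
    b = simulate_endpoints(default_spec, chemo_backbone(), 12, seed=3,
                           duration=200.0, n_boot=100)
    assert a.orr == b.orr and 0.0 <= a.orr <= 1.0
    assert a.median_dor_months == b.median_dor_months


def test_saturating_kill_drives_orr_to_one(default_spec):
    from ioqsp import chemo_backbone

    spec = default_spec.with_location("kC_nabp", 500.0)
    spec = spec.with_location("IC50_nabp", 1e-5)
    s = simulate_endpoints(spec, chemo_backbone(), 20, seed=9,
                           duration=120.0, n_boot=50)
    assert s.orr == 1.0


def test_self_calibration_recovers_endpoints(default_spec):
    """Perturb one calibrated mean, fit to self-generated targets, and
    recover all endpoint biases below 5%."""
    from ioqsp import chemo_backbone, triple_regimen

    n, dur, seed = 30, 250.0, 77
    truth_chemo = simulate_endpoints(default_spec, chemo_backbone(), n, seed,
                                     duration=dur, n_boot=50)
    truth_triple = simulate_endpoints(default_spec, triple_regimen(), n, seed,
                                      duration=dur, n_boot=50)
    targets = (
        CalibrationTarget("chemo", truth_chemo.orr,
                          (truth_chemo.orr * 0.9, truth_chemo.orr * 1.1),
                          truth_chemo.median_dor_months or 3.7,
                          ((truth_chemo.median_dor_months or 3.7) * 0.9,
                           (truth_chemo.median_dor_months or 3.7) * 1.1)),
        CalibrationTarget("triple", truth_triple.orr,
                          (truth_triple.orr * 0.9, truth_triple.orr * 1.1),
                          truth_triple.median_dor_months or 5.5,
                          ((truth_triple.median_dor_months or 5.5) * 0.9,
                           (truth_triple.median_dor_months or 5.5) * 1.1)),
    )
    perturbed = default_spec.with_location(
        "kC_nabp", default_spec.get("kC_nabp").location * 1.5)
    spec, report = calibrate(perturbed, targets, budget=20, seed=seed, n=n,
                             duration=dur, parameters=("kC_nabp",))
    assert all(b < 0.05 for b in report.biases.values()), report.biases


def test_already_calibrated_spec_returns_immediately(default_spec):
    """Self-targets at the current spec: calibration exits on evaluation 1."""
    from ioqsp import chemo_backbone, triple_regimen

    n, dur, seed = 24, 250.0, 58
    tc = simulate_endpoints(default_spec, chemo_backbone(), n, seed,
                            duration=dur, n_boot=50)
    tt = simulate_endpoints(default_spec, triple_regimen(), n, seed,
                            duration=dur, n_boot=50)
    assert tc.median_dor_months and tt.median_dor_months
    targets = (
        CalibrationTarget("chemo", tc.orr, (tc.orr - 0.01, tc.orr + 0.01),
                          tc.median_dor_months,
                          (tc.median_dor_months - 0.1,
                           tc.median_dor_months + 0.1)),
        CalibrationTarget("triple", tt.orr, (tt.orr - 0.01, tt.orr + 0.01),
                          tt.median_dor_months,
                          (tt.median_dor_months - 0.1,
                           tt.median_dor_months + 0.1)),
    )
    spec, report = calibrate(default_spec, targets, budget=5, seed=seed, n=n,
                             duration=dur)
    assert report.success and report.n_evaluations == 1
    assert spec is default_spec
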