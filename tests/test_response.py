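"""RECIST classification and cohort endpoint summaries."""

import numpy as np
import pytest
from scipy import stats

from ioqsp import classify_recist, compute_orr, median_dor, waterfall
from ioqsp.response import DAYS_PER_MONTH, ResponseRecord, summarise_endpoints
from tests.conftest import FakeTrajectory


def _record(best, dor_months=None, censored=False, pid=0):
    dor = dor_months * DAYS_PER_MONTH if dor_months is not None else None
    return ResponseRecord(patient_id=pid, best_response=best,
                          best_pct_change=0.0, dor_days=dor,
                          censored=censored,
                          t_response=0.0 if dor is not None else None)


# ---------------------------------------------------------------------------
# RECIST classification
# ---------------------------------------------------------------------------


def test_recist_partial_response():
    tr = FakeTrajectory([0, 56], [5.0, 3.0])          # -40%
    r = classify_recist(tr)
    assert r.best_response == "PR"
    assert r.t_response == 56.0
    assert r.best_pct_change == pytest.approx(-40.0)
    assert r.censored and r.dor_days == pytest.approx(0.0)


def test_recist_progression_from_nadir():
    tr = FakeTrajectory([0, 56, 112], [5.0, 5.0, 6.5])  # +30%, +15 mm
    r = classify_recist(tr)
    assert r.best_response == "SD"
    assert r.t_progression == 112.0
    assert not r.responder


def test_recist_stable_disease_band():
    tr = FakeTrajectory([0, 56, 112, 168], [5.0, 4.5, 4.4, 4.6])
    r = classify_recist(tr)
    assert r.best_response == "SD"
    assert r.t_progression is None and r.dor_days is None


def test_recist_pd_at_first_scan_and_small_lesion_guard():
    r = classify_recist(FakeTrajectory([0, 56], [5.0, 6.5]))
    assert r.best_response == "PD"
    # +20% but < 5 mm absolute: not progression
    r2 = classify_recist(FakeTrajectory([0, 56, 112], [1.2, 1.0, 1.3]))
    assert r2.best_response == "SD"
    with pytest.raises(ValueError):
        classify_recist(FakeTrajectory([0, 56], [0.8, 0.8]))
    with pytest.raises(ValueError):
        classify_recist(FakeTrajectory([0], [5.0]))


def test_recist_complete_response_and_dor():
    tr = FakeTrajectory([0, 56, 112, 168, 224],
                        [3.0, 1.9, 0.05, 0.06, 0.8])
    r = classify_recist(tr)
    assert r.best_response == "CR"
    assert r.t_response == 56.0                      # first PR or better
    assert r.t_progression == 224.0                  # 0.05 -> 0.8: +0.75 cm
    assert r.dor_days == pytest.approx(168.0)
    assert not r.censored


def test_recist_progression_takes_precedence_below_baseline():
    """A lesion far below baseline but +20%/+5mm above nadir is PD."""
    tr = FakeTrajectory([0, 56, 112, 168], [5.0, 2.0, 1.0, 1.6])
    r = classify_recist(tr)
    assert r.best_response == "PR"
    assert r.t_progression == 168.0
    assert r.dor_days == pytest.approx(112.0)


# ---------------------------------------------------------------------------
# ORR
# ---------------------------------------------------------------------------


def test_orr_counts():
    recs = [_record(b) for b in ["PR", "PD", "SD", "PR", "SD"]]
    orr, _ = compute_orr(recs, n_boot=100, seed=0)
    assert orr == pytest.approx(0.4)
    assert compute_orr([_record("PR")] * 5, n_boot=100, seed=0)[0] == 1.0


def test_orr_bootstrap_matches_binomial_oracle():
    """Resampling responder flags is Binomial(n, p̂); percentiles must agree."""
    recs = [_record("PR")] * 8 + [_record("SD")] * 12
    _, (lo, hi) = compute_orr(recs, n_boot=20000, seed=4)
    exact_lo = stats.binom.ppf(0.025, 20, 0.4) / 20
    exact_hi = stats.binom.ppf(0.975, 20, 0.4) / 20
    assert lo == pytest.approx(exact_lo, abs=0.01)
    assert hi == pytest.approx(exact_hi, abs=0.01)


def test_orr_invariances():
    recs = [_record(b, pid=i) for i, b in enumerate(
        ["PR", "PD", "SD", "PR", "CR", "SD"])]
    base, _ = compute_orr(recs, n_boot=50, seed=0)
    shuffled, _ = compute_orr(recs[::-1], n_boot=50, seed=0)
    assert base == shuffled
    worse, _ = compute_orr(recs + [_record("PD")], n_boot=50, seed=0)
    assert worse < base


# ---------------------------------------------------------------------------
# median DOR
# ---------------------------------------------------------------------------


def test_km_median_no_censoring_is_sample_median():
    recs = [_record("PR", m) for m in (2.0, 5.0, 8.0)]
    med, _ = median_dor(recs, n_boot=50, seed=0)
    assert med == pytest.approx(5.0)


def test_km_median_hand_computed_four_subjects():
    """Events at 3 and 6 months, censored at 4 and 8: S = 1 -> .75 -> .375,
    so the median is 6 months."""
    recs = [
        _record("PR", 3.0),
        _record("PR", 4.0, censored=True),
        _record("PR", 6.0),
        _record("PR", 8.0, censored=True),
    ]
    med, _ = median_dor(recs, n_boot=200, seed=0)
    assert med == pytest.approx(6.0)


def test_km_median_undefined_when_all_censored():
    recs = [_record("PR", 2.0, censored=True),
            _record("PR", 3.0, censored=True)]
    med, _ = median_dor(recs, n_boot=50, seed=0)
    assert med is None


def test_median_dor_requires_responders():
    with pytest.raises(ValueError):
        median_dor([_record("SD")])


def test_summary_cis_bracket_estimates():
    recs = [_record("PR", m) for m in (2.0, 4.0, 6.0, 9.0)] \
        + [_record("SD")] * 4 + [_record("PD")] * 2
    s = summarise_endpoints(recs, arm="x", n_boot=300, seed=5)
    assert s.orr_ci[0] <= s.orr <= s.orr_ci[1]
    assert s.dor_ci[0] <= s.median_dor_months <= s.dor_ci[1]
    assert s.n_responders == 4 and s.n == 10


# ---------------------------------------------------------------------------
# waterfall
# ---------------------------------------------------------------------------


def test_waterfall_ordering():
    assert waterfall([]).size == 0
    recs = [ResponseRecord(i, "SD", c) for i, c in enumerate([5.0, -40.0, -10.0])]
    assert list(waterfall(recs)) == [5.0, -10.0, -40.0]
    assert list(waterfall(recs[::-1])) == [5.0, -10.0, -40.0]
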