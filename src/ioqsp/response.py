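"""RECIST v1.1 response classification and cohort endpoints.

The model tracks a single lesion, so the RECIST "sum of diameters" is the
one diameter.  At each assessment: CR if the diameter is below 1 mm
(disappearance proxy on a continuous model), PR if the change from baseline
is ≤ −30%, PD if the change from the nadir (smallest diameter observed so
far, baseline included) is ≥ +20% with an absolute increase ≥ 5 mm, SD
otherwise.  Best overall response is the best category achieved at or before
the first PD; no confirmation scan is required.  Duration of response runs
from the first PR/CR assessment to the first PD, censored at the end of
follow-up.  Cohort ORR and Kaplan–Meier median DOR carry seeded-bootstrap
percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter

DAYS_PER_MONTH = 30.4375
CR_THRESHOLD_CM = 0.1          # 1 mm
PR_CHANGE = -0.30
PD_CHANGE = 0.20
PD_ABSOLUTE_CM = 0.5           # 5 mm

_ORDER = {"PD": 0, "SD": 1, "PR": 2, "CR": 3}


@dataclass
class ResponseRecord:
    """Per-patient RECIST outcome."""

    patient_id: int
    best_response: str                      # CR / PR / SD / PD
    best_pct_change: float                  # best % change from baseline
    t_response: Optional[float] = None      # day of first PR/CR
    t_progression: Optional[float] = None   # day of first PD
    dor_days: Optional[float] = None        # responders only
    censored: bool = False

    @property
    def responder(self) -> bool:
        return self.best_response in ("CR", "PR")


def classify_recist(trajectory, follow_up: Optional[float] = None
                    ) -> ResponseRecord:
    """Classify one tumour trajectory per RECIST v1.1.

    ``trajectory`` provides ``assess_t``/``assess_diameter`` (day, cm) with
    the baseline at index 0, plus ``patient_id``.  ``follow_up`` is the
    censoring horizon for responders without progression (defaults to the
    last assessment time).
    """
    t = np.asarray(trajectory.assess_t, dtype=float)
    d = np.asarray(trajectory.assess_diameter, dtype=float)
    if t.size < 2:
        raise ValueError("need at least one post-baseline assessment")
    baseline = d[0]
    if baseline < 1.0:
        raise ValueError("baseline lesion below 1.0 cm is not measurable")
    if follow_up is None:
        follow_up = float(t[-1])

    best = "SD"
    best_change = np.inf
    t_resp = None
    t_prog = None
    nadir = baseline
    for i in range(1, t.size):
        dia = d[i]
        change = (dia - baseline) / baseline
        best_change = min(best_change, change)
        # progression from the nadir takes precedence over the change from
        # baseline: a lesion can sit below −30% of baseline yet be progressing
        if dia < CR_THRESHOLD_CM:
            cat = "CR"
        elif nadir > 0 and (dia - nadir) / nadir >= PD_CHANGE \
                and (dia - nadir) >= PD_ABSOLUTE_CM:
            cat = "PD"
        elif change <= PR_CHANGE:
            cat = "PR"
        else:
            cat = "SD"
        if cat == "PD":
            t_prog = float(t[i])
            break
        if cat in ("PR", "CR") and t_resp is None:
            t_resp = float(t[i])
        if _ORDER[cat] > _ORDER[best]:
            best = cat
        nadir = min(nadir, dia)

    if t_prog is not None and best == "SD" and t_resp is None:
        # progressed without ever responding; check whether any pre-PD scan
        # was SD — if the very first scan progressed, BOR is PD
        first_pd_idx = int(np.where(t == t_prog)[0][0])
        if first_pd_idx == 1:
            best = "PD"

    dor = None
    censored = False
    if t_resp is not None:
        if t_prog is not None:
            dor = t_prog - t_resp
        else:
            dor = follow_up - t_resp
            censored = True

    return ResponseRecord(
        patient_id=int(getattr(trajectory, "patient_id", -1)),
        best_response=best,
        best_pct_change=float(best_change * 100.0),
        t_response=t_resp,
        t_progression=t_prog,
        dor_days=dor,
        censored=censored,
    )


@dataclass
class EndpointSummary:
    """Cohort-level ORR and median DOR with bootstrap CIs."""

    arm: str
    n: int
    orr: float
    orr_ci: tuple
    median_dor_months: Optional[float]
    dor_ci: tuple
    n_responders: int = 0
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "arm": self.arm,
            "n": self.n,
            "orr": self.orr,
            "orr_ci": list(self.orr_ci),
            "median_dor_months": self.median_dor_months,
            "dor_ci": list(self.dor_ci),
            "n_responders": self.n_responders,
            "n_excluded": self.n_excluded,
        }


def compute_orr(records: Sequence[ResponseRecord], n_boot: int = 2000,
                seed=0) -> tuple:
    """Objective response rate with a percentile-bootstrap 95% CI."""
    if not records:
        raise ValueError("need at least one record")
    flags = np.array([r.responder for r in records], dtype=float)
    orr = float(flags.mean())
    rng = np.random.default_rng(seed)
    n = flags.size
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = flags[idx].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return orr, (float(lo), float(hi))


def _km_median_months(durations: np.ndarray, observed: np.ndarray,
                      interpolate: bool = False) -> Optional[float]:
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    med = kmf.median_survival_time_
    if not np.isfinite(med):
        return None
    if not interpolate:
        return float(med) / DAYS_PER_MONTH
    # linear interpolation of the KM curve across the 0.5 crossing: with
    # sparse assessment grids the step median is quantised to the scan
    # spacing, while the interpolated median varies smoothly
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    idx = int(np.argmax(surv <= 0.5))
    t_hi, s_hi = t[idx], surv[idx]
    if idx == 0:
        return float(t_hi) / DAYS_PER_MONTH
    t_lo, s_lo = t[idx - 1], surv[idx - 1]
    if s_lo == s_hi:
        return float(t_hi) / DAYS_PER_MONTH
    med = t_lo + (s_lo - 0.5) / (s_lo - s_hi) * (t_hi - t_lo)
    return float(med) / DAYS_PER_MONTH


def median_dor(records: Sequence[ResponseRecord], n_boot: int = 2000,
               seed=0, interpolate: bool = False) -> tuple:
    """Kaplan–Meier median duration of response (months) among responders.

    Returns ``(median, (lo, hi))``; the median is None when the KM curve
    never crosses 0.5 (all responders censored early).  The CI is a
    percentile bootstrap over responders; undefined bootstrap medians are
    ignored.  ``interpolate`` reads the median off the linearly interpolated
    KM curve instead of the first step at or below 0.5 — the appropriate
    convention when events are observed on a sparse assessment grid.
    """
    resp = [r for r in records if r.responder]
    if not resp:
        raise ValueError("no responders: median DOR undefined")
    durations = np.array([r.dor_days for r in resp], dtype=float)
    observed = np.array([not r.censored for r in resp], dtype=float)
    med = _km_median_months(durations, observed, interpolate)

    rng = np.random.default_rng(seed)
    n = durations.size
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        m = _km_median_months(durations[idx], observed[idx], interpolate)
        if m is not None:
            boots.append(m)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (float(lo), float(hi))
    else:
        ci = (float("nan"), float("nan"))
    return med, ci


def summarise_endpoints(records: Sequence[ResponseRecord], arm: str,
                        n_boot: int = 2000, seed=0, n_excluded: int = 0,
                        dor_interpolate: bool = True) -> EndpointSummary:
    """ORR and median DOR for one arm, with seeded bootstrap CIs.

    Cohort-level medians default to the interpolated KM convention because
    trial assessments every 8 weeks quantise the step median to multiples of
    1.84 months.
    """
    ss = np.random.SeedSequence(seed)
    s_orr, s_dor = [int(s.generate_state(1)[0] % (2 ** 31))
                    for s in ss.spawn(2)]
    orr, orr_ci = compute_orr(records, n_boot=n_boot, seed=s_orr)
    n_resp = sum(r.responder for r in records)
    if n_resp:
        med, dor_ci = median_dor(records, n_boot=n_boot, seed=s_dor,
                                 interpolate=dor_interpolate)
    else:
        med, dor_ci = None, (float("nan"), float("nan"))
    return EndpointSummary(arm=arm, n=len(records), orr=orr, orr_ci=orr_ci,
                           median_dor_months=med, dor_ci=dor_ci,
                           n_responders=n_resp, n_excluded=n_excluded)


def waterfall(records: Sequence[ResponseRecord]) -> np.ndarray:
    """Best percent changes sorted descending (waterfall-plot ordering)."""
    return np.sort(np.array([r.best_pct_change for r in records]))[::-1]
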