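"""Event-driven integration of one virtual patient under one regimen.

Each patient is first equilibrated: a 200-day burn-in with the cancer state
clamped at its baseline burden brings the immune network to its drug-free
steady state (deterministic given parameters).  Treatment is then integrated
with a stiff solver restarted at every dose event; intravenous doses are
state jumps, carboplatin is a piecewise-constant tumour exposure.  Tumour
diameters are read off a daily grid and subsampled at the 8-week RECIST
assessment schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import (
    IntegrationError,
    ModelParameters,
    N_STATES,
    SIDX,
    STATE_NAMES,
    _rhs,
    initial_state,
    tumour_diameter,
    tumour_volume_mm3,
)
from .pharmacokinetics import Regimen, build_schedule

#: characteristic magnitude per species, used for absolute solver tolerances
#: and the negativity contract (−1e−9·scale is the error threshold)
_SPECIES_SCALE = np.array([
    1e9,    # C
    1.0,    # Ag
    1e6,    # APC
    1e5,    # mAPC
    1e5,    # mAPC_LN
    1e8,    # nT8_c
    1e8,    # nT8_p
    1e7,    # nT8_LN
    1e8,    # nT4_c
    1e8,    # nT4_p
    1e7,    # nT4_LN
    1e5,    # aT8_LN
    1e5,    # aT8_c
    1e6,    # T8_t
    1e5,    # aTh_LN
    1e5,    # aTh_c
    1e6,    # Th_t
    1e5,    # aTreg_LN
    1e5,    # aTreg_c
    1e6,    # Treg_t
    1e6,    # Texh
    1e6,    # MDSC
    1.0,    # TGFb
    1.0,    # Ang
    1.0,    # atezo_A1 (mg)
    1.0,    # atezo_A2
    1.0,    # nabp_A1
    1.0,    # nabp_A2
    1.0,    # nabp_A3
])

DEFAULT_RTOL = 1e-6
BURN_IN_DAYS = 200.0


@dataclass
class TumourTrajectory:
    """Tumour size over time for one simulated patient."""

    patient_id: int
    t: np.ndarray                      # dense daily grid, day
    diameter: np.ndarray               # cm
    volume_mm3: np.ndarray             # mm³
    assess_t: np.ndarray               # RECIST assessment times, day
    assess_diameter: np.ndarray        # cm
    baseline_diameter: float           # cm
    baseline_state: np.ndarray         # post-burn-in, pre-dose state
    params: ModelParameters

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": self.patient_id,
            "time": self.t,
            "diameter": self.diameter,
            "volume": self.volume_mm3,
        })


def _check_state(y: np.ndarray, t: float, patient_id: int) -> None:
    floor = -1e-9 * _SPECIES_SCALE
    bad = np.where(y < floor)[0]
    if bad.size:
        name = STATE_NAMES[int(bad[0])]
        raise IntegrationError(
            f"species {name} negative ({y[bad[0]]:.3e}) at t={t:.2f} "
            f"for patient {patient_id}", species=name, time=t)


def _integrate_segment(y, t0, t1, pvec, carb_conc, clamp, t_eval, rtol, atol,
                       patient_id):
    def f(t, y_):
        return _rhs(t, y_, pvec, carb_conc, clamp)

    sol = solve_ivp(f, (t0, t1), y, method="LSODA", t_eval=t_eval,
                    rtol=rtol, atol=atol, dense_output=False)
    if not sol.success:
        raise IntegrationError(
            f"solver failure for patient {patient_id} in [{t0}, {t1}]: "
            f"{sol.message}", time=t0)
    return sol


def burn_in(params: ModelParameters, days: float = BURN_IN_DAYS,
            rtol: float = DEFAULT_RTOL) -> np.ndarray:
    """Drug-free immune steady state with the cancer burden clamped."""
    y0 = initial_state(params)
    pvec = params.to_vector()
    atol = rtol * _SPECIES_SCALE
    sol = _integrate_segment(y0, 0.0, days, pvec, 0.0, 1.0,
                             np.array([days]), rtol, atol, patient_id=-1)
    y = sol.y[:, -1]
    _check_state(y, -days, -1)
    return np.maximum(y, 0.0)


def simulate_patient(patient, regimen: Regimen, duration: float = 400.0,
                     assess_interval: float = 56.0,
                     rtol: float = DEFAULT_RTOL) -> TumourTrajectory:
    """Integrate one patient under one regimen and extract the trajectory.

    ``patient`` is a :class:`~ioqsp.population.VirtualPatient` (or any object
    with ``id`` and ``params``).  Deterministic given the patient parameters.
    """
    params: ModelParameters = patient.params
    pid = int(patient.id)
    pvec = params.to_vector()
    atol = rtol * _SPECIES_SCALE

    y = burn_in(params, rtol=rtol)
    baseline_state = y.copy()
    baseline_dia = tumour_diameter(y[SIDX["C"]], params.DEN_T_cell)

    events = build_schedule(regimen, duration, bsa=params.bsa)
    carb_plateau = 0.0
    carb_times = []
    jumps: dict = {}
    for ev in events:
        if ev.drug == "carboplatin":
            carb_times.append(ev.time)
            carb_plateau = params.f_carb_map * ev.amount
        elif ev.drug == "atezolizumab":
            jumps.setdefault(ev.time, []).append((SIDX["atezo_A1"], ev.amount))
        else:  # nab-paclitaxel
            jumps.setdefault(ev.time, []).append((SIDX["nabp_A1"], ev.amount))

    breakpoints = sorted(set([0.0, duration]) | set(jumps) | set(carb_times))
    breakpoints = [b for b in breakpoints if 0.0 <= b <= duration]
    carb_times = np.asarray(carb_times, dtype=float)

    grid = np.arange(0.0, duration + 0.5, 1.0)
    out_t = [0.0]
    out_y = [y.copy()]

    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        for idx, amount in jumps.get(t0, []):
            y[idx] += amount
        if carb_times.size:
            i = np.searchsorted(carb_times, t0, side="right") - 1
            in_window = i >= 0 and (t0 - carb_times[i]) < params.carb_window
            carb_conc = carb_plateau if in_window else 0.0
        else:
            carb_conc = 0.0
        t_eval = grid[(grid > t0) & (grid <= t1)]
        if t_eval.size == 0 or t_eval[-1] < t1:
            t_eval = np.append(t_eval, t1)
        sol = _integrate_segment(y, t0, t1, pvec, carb_conc, 0.0, t_eval,
                                 rtol, atol, pid)
        y = sol.y[:, -1].copy()
        _check_state(y, t1, pid)
        keep = sol.t <= duration
        out_t.extend(sol.t[keep])
        out_y.extend(sol.y[:, keep].T)

    out_t = np.asarray(out_t)
    out_y = np.asarray(out_y)
    # deduplicate repeated segment endpoints, keep the last value
    _, uniq_idx = np.unique(out_t[::-1], return_index=True)
    order = out_t.size - 1 - uniq_idx
    out_t = out_t[order]
    out_y = out_y[order]

    c = np.maximum(out_y[:, SIDX["C"]], 0.0)
    dia = np.array([tumour_diameter(ci, params.DEN_T_cell) for ci in c])
    vol = np.array([tumour_volume_mm3(ci, params.DEN_T_cell) for ci in c])

    c_max_eff_bound = params.c_max * (1.0 + params.e_ang) * (1.0 + 1e-6)
    if np.any(c > c_max_eff_bound):
        raise IntegrationError(
            f"cancer burden exceeded effective capacity for patient {pid}",
            species="C")

    assess_t = np.arange(0.0, duration + 0.5, assess_interval)
    assess_idx = np.searchsorted(out_t, assess_t)
    assess_idx = np.clip(assess_idx, 0, out_t.size - 1)
    if not np.allclose(out_t[assess_idx], assess_t, atol=1e-6):
        raise IntegrationError("assessment times missing from dense grid")

    return TumourTrajectory(
        patient_id=pid,
        t=out_t,
        diameter=dia,
        volume_mm3=vol,
        assess_t=assess_t,
        assess_diameter=dia[assess_idx],
        baseline_diameter=baseline_dia,
        baseline_state=baseline_state,
        params=params,
    )


@dataclass
class CohortResult:
    """Trajectories plus integration-failure bookkeeping."""

    trajectories: list = field(default_factory=list)
    failures: list = field(default_factory=list)   # (patient_id, message)

    @property
    def n_excluded(self) -> int:
        return len(self.failures)


def simulate_cohort(patients, regimen: Regimen, duration: float = 400.0,
                    assess_interval: float = 56.0,
                    rtol: float = DEFAULT_RTOL) -> CohortResult:
    """Simulate a cohort patient-by-patient (order-independent results).

    Patients whose integration fails are excluded and counted rather than
    aborting the cohort.
    """
    result = CohortResult()
    for patient in patients:
        try:
            traj = simulate_patient(patient, regimen, duration=duration,
                                    assess_interval=assess_interval, rtol=rtol)
            result.trajectories.append(traj)
        except IntegrationError as exc:
            result.failures.append((patient.id, str(exc)))
    return result


def trajectories_frame(trajectories) -> pd.DataFrame:
    """Long-format export (patient_id, time, diameter, volume)."""
    if not trajectories:
        return pd.DataFrame(columns=["patient_id", "time", "diameter",
                                     "volume"])
    return pd.concat([tr.to_frame() for tr in trajectories],
                     ignore_index=True)
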