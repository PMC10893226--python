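"""Drug dosing schedules and pharmacokinetic models.

Atezolizumab follows a linear two-compartment mammillary model (label
population values); nab-paclitaxel a three-compartment model with saturable
(Michaelis–Menten) elimination from the central compartment; carboplatin is
mapped from its AUC target to a piecewise-constant effective tumour
concentration, reflecting its stable circulating exposure over a cycle.
Tumour drug concentrations are partition coefficients times central
concentration (quasi-steady tumour distribution).

Amounts are mg, volumes L, concentrations µg/mL (≡ mg/L), time days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model_core import ModelParameters


class ConfigError(ValueError):
    """Invalid regimen or run configuration."""


KNOWN_DRUGS = ("atezolizumab", "nab-paclitaxel", "carboplatin")

#: dose-unit semantics per drug component
DOSE_UNITS = ("mg", "mg_per_m2", "auc")


@dataclass(frozen=True)
class DoseEvent:
    """One administration: absolute time (day), drug, amount, infusion length.

    ``amount`` is mg after body-surface-area conversion for per-m² dosing;
    for carboplatin it carries the AUC target (mg/mL·min), which the exposure
    model maps to a tumour concentration.  ``infusion`` 0 means bolus.
    """

    time: float
    drug: str
    amount: float
    infusion: float = 0.0

    def __post_init__(self):
        if self.time < 0 or self.amount < 0 or self.infusion < 0:
            raise ConfigError("dose event fields must be non-negative")
        if self.drug not in KNOWN_DRUGS:
            raise ConfigError(f"unknown drug identifier: {self.drug!r}")


@dataclass(frozen=True)
class DrugComponent:
    """One drug's dosing pattern within a regimen."""

    drug: str
    dose: float              # mg, mg/m², or AUC target depending on unit
    unit: str                # one of DOSE_UNITS
    days: tuple              # 1-based dosing days within the cycle
    cycle_length: float      # day

    def __post_init__(self):
        if self.drug not in KNOWN_DRUGS:
            raise ConfigError(f"unknown drug identifier: {self.drug!r}")
        if self.unit not in DOSE_UNITS:
            raise ConfigError(f"unknown dose unit: {self.unit!r}")
        if self.cycle_length <= 0:
            raise ConfigError("cycle length must be positive")
        if not self.days:
            raise ConfigError("at least one dosing day required")
        for d in self.days:
            if not 1 <= d <= self.cycle_length:
                raise ConfigError("dosing days must lie in [1, cycle length]")


@dataclass(frozen=True)
class Regimen:
    """Named combination of drug components."""

    name: str
    components: tuple

    def without(self, drug: str) -> "Regimen":
        """Drop one drug (e.g. the chemo backbone = triple minus antibody)."""
        kept = tuple(c for c in self.components if c.drug != drug)
        return Regimen(name=f"{self.name}-minus-{drug}", components=kept)


def chemo_backbone() -> Regimen:
    """Carboplatin AUC 6 day 1 + nab-paclitaxel 100 mg/m² days 1, 8, 15 of a
    21-day cycle."""
    return Regimen(
        name="carboplatin+nab-paclitaxel",
        components=(
            DrugComponent("carboplatin", 6.0, "auc", (1,), 21.0),
            DrugComponent("nab-paclitaxel", 100.0, "mg_per_m2", (1, 8, 15), 21.0),
        ),
    )


def triple_regimen(atezo_mg: float = 1200.0, atezo_cycle: float = 21.0) -> Regimen:
    """Atezolizumab (flat mg every ``atezo_cycle`` days) on the chemo backbone.

    The approved alternatives are 840 mg Q2W, 1200 mg Q3W, 1680 mg Q4W.
    """
    base = chemo_backbone()
    name = f"atezolizumab-{atezo_mg:g}mg-q{atezo_cycle:g}d+chemo"
    return Regimen(
        name=name,
        components=base.components + (
            DrugComponent("atezolizumab", atezo_mg, "mg", (1,), atezo_cycle),
        ),
    )


STANDARD_REGIMENS: dict = {
    "chemo": chemo_backbone,
    "triple-q3w": lambda: triple_regimen(1200.0, 21.0),
    "triple-q2w": lambda: triple_regimen(840.0, 14.0),
    "triple-q4w": lambda: triple_regimen(1680.0, 28.0),
}


@dataclass
class PKParameters:
    """Pharmacokinetic constants, a view over :class:`ModelParameters`."""

    atezo_CL: float = 0.2
    atezo_V1: float = 3.28
    atezo_V2: float = 3.63
    atezo_Q: float = 0.546
    atezo_part: float = 0.3
    nabp_V1: float = 16.0
    nabp_V2: float = 400.0
    nabp_V3: float = 1000.0
    nabp_Q2: float = 150.0
    nabp_Q3: float = 40.0
    nabp_Vmax: float = 350.0
    nabp_Km: float = 0.5
    nabp_part: float = 2.0
    f_carb_map: float = 0.05
    bsa: float = 1.8

    def __post_init__(self):
        for name in ("atezo_CL", "atezo_V1", "atezo_V2", "atezo_Q",
                     "nabp_V1", "nabp_V2", "nabp_V3", "nabp_Vmax", "nabp_Km"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"PK parameter {name} must be positive")

    @classmethod
    def from_model(cls, params: ModelParameters) -> "PKParameters":
        names = [f for f in cls.__dataclass_fields__]
        return cls(**{n: getattr(params, n) for n in names})


def schedule_frame(events) -> "pd.DataFrame":
    """Tabular export of a dose schedule (time, drug, amount)."""
    import pandas as pd

    return pd.DataFrame([{"time": e.time, "drug": e.drug,
                          "amount": e.amount} for e in events])


def build_schedule(regimen: Regimen, duration: float,
                   bsa: float = 1.8) -> list:
    """Expand a regimen into sorted :class:`DoseEvent`s over ``duration`` days.

    Day 1 of cycle k maps to absolute day (k−1)·cycle_length (0-based time);
    only events strictly before ``duration`` are emitted.
    """
    if duration <= 0:
        raise ConfigError("duration must be positive")
    events = []
    for comp in regimen.components:
        if comp.unit == "mg":
            amount = comp.dose
        elif comp.unit == "mg_per_m2":
            amount = comp.dose * bsa
        else:  # auc: carried through, mapped by carboplatin_exposure
            amount = comp.dose
        n_cycles = int(math.ceil(duration / comp.cycle_length))
        for k in range(n_cycles):
            for day in comp.days:
                t = k * comp.cycle_length + (day - 1)
                if t < duration:
                    events.append(DoseEvent(time=t, drug=comp.drug,
                                            amount=amount))
    events.sort(key=lambda e: (e.time, e.drug))
    return events


# --------------------------------------------------------------------------
# Atezolizumab: linear two-compartment model
# --------------------------------------------------------------------------


def atezolizumab_pk_rhs(amounts: Sequence[float], pk: PKParameters) -> np.ndarray:
    """d(amounts)/dt for the central/peripheral antibody amounts (mg)."""
    a1, a2 = amounts
    if a1 < 0 or a2 < 0:
        raise ValueError("amounts must be non-negative")
    da1 = -(pk.atezo_CL / pk.atezo_V1) * a1 - (pk.atezo_Q / pk.atezo_V1) * a1 \
        + (pk.atezo_Q / pk.atezo_V2) * a2
    da2 = (pk.atezo_Q / pk.atezo_V1) * a1 - (pk.atezo_Q / pk.atezo_V2) * a2
    return np.array([da1, da2])


def atezolizumab_conc_central(t, dose: float, pk: PKParameters) -> np.ndarray:
    """Closed-form central concentration (µg/mL) after a single bolus at t=0.

    Standard biexponential solution of the two-compartment model:
    C(t) = (D/V1)·(A·e^{−αt} + B·e^{−βt}).
    """
    t = np.asarray(t, dtype=float)
    k10 = pk.atezo_CL / pk.atezo_V1
    k12 = pk.atezo_Q / pk.atezo_V1
    k21 = pk.atezo_Q / pk.atezo_V2
    s = k10 + k12 + k21
    disc = math.sqrt(s * s - 4.0 * k10 * k21)
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    a = (alpha - k21) / (alpha - beta)
    b = (k21 - beta) / (alpha - beta)
    return dose / pk.atezo_V1 * (a * np.exp(-alpha * t) + b * np.exp(-beta * t))


# --------------------------------------------------------------------------
# Nab-paclitaxel: three-compartment, saturable elimination
# --------------------------------------------------------------------------


def nabp_pk_rhs(amounts: Sequence[float], pk: PKParameters) -> np.ndarray:
    """d(amounts)/dt for the three nab-paclitaxel compartments (mg)."""
    a1, a2, a3 = amounts
    if a1 < 0 or a2 < 0 or a3 < 0:
        raise ValueError("amounts must be non-negative")
    c1 = a1 / pk.nabp_V1
    c2 = a2 / pk.nabp_V2
    c3 = a3 / pk.nabp_V3
    elim = pk.nabp_Vmax * c1 / (pk.nabp_Km + c1) if c1 > 0 else 0.0
    da1 = -elim - pk.nabp_Q2 * (c1 - c2) - pk.nabp_Q3 * (c1 - c3)
    da2 = pk.nabp_Q2 * (c1 - c2)
    da3 = pk.nabp_Q3 * (c1 - c3)
    return np.array([da1, da2, da3])


# --------------------------------------------------------------------------
# Carboplatin: AUC-target -> constant effective tumour exposure
# --------------------------------------------------------------------------


def carboplatin_exposure(auc_target: float, f_carb_map: float,
                         cycle_day_window: float = 21.0,
                         dose_times: Sequence[float] = (0.0,)
                         ) -> Callable[[float], float]:
    """Piecewise-constant tumour carboplatin concentration function.

    Concentration equals ``f_carb_map · auc_target`` (µg/mL) for
    ``cycle_day_window`` days after each dose (right-continuous at dose
    times) and 0 otherwise.
    """
    if auc_target < 0:
        raise ValueError("auc_target must be non-negative")
    plateau = f_carb_map * auc_target
    times = np.sort(np.asarray(dose_times, dtype=float))

    def conc(t: float) -> float:
        i = np.searchsorted(times, t, side="right") - 1
        if i < 0:
            return 0.0
        return plateau if (t - times[i]) < cycle_day_window else 0.0

    return conc
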