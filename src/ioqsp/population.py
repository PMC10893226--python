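"""Virtual-patient populations: parameter distributions and Latin hypercube
sampling.

Inter-individual variability is represented by marginal distributions on a
subset of model parameters (26 by default, mirroring the global sensitivity
analysis set); the remaining parameters are fixed at their population values.
Biological rates are modelled log-normally (positive, right-skewed) with
truncation at ±3 ln-SD; bounded quantities (e.g. the Treg priming fraction)
use truncated normals on the linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.stats import qmc

from .model_core import ModelParameters, PARAM_NAMES, cancer_capacity


class ConfigError(ValueError):
    """Invalid population specification."""


@dataclass(frozen=True)
class ParameterDistribution:
    """Marginal distribution of one variable parameter.

    ``scale='log'``: location is the geometric mean, spread the ln-scale SD.
    ``scale='linear'``: location is the mean, spread the SD.
    ``bounds`` truncate in natural units (defaults: ±3 SD on the sampling
    scale).
    """

    name: str
    scale: str = "log"
    location: float = 1.0
    spread: float = 0.0
    bounds: tuple | None = None

    def __post_init__(self):
        if self.scale not in ("log", "linear"):
            raise ConfigError(f"unknown scale {self.scale!r} for {self.name}")
        if self.spread < 0:
            raise ConfigError(f"spread must be >= 0 for {self.name}")
        if self.scale == "log" and self.location <= 0:
            raise ConfigError(f"log-scale location must be > 0 for {self.name}")
        if self.bounds is not None:
            lo, hi = self.bounds
            if not lo <= hi:
                raise ConfigError(f"bounds out of order for {self.name}")
            if not lo <= self.location <= hi:
                raise ConfigError(f"location outside bounds for {self.name}")

    def quantile(self, u: np.ndarray) -> np.ndarray:
        """Inverse CDF mapping uniform(0,1) draws to parameter values."""
        u = np.asarray(u, dtype=float)
        if self.spread == 0.0:
            return np.full_like(u, self.location)
        if self.scale == "log":
            lo, hi = (-3.0, 3.0)
            if self.bounds is not None:
                blo, bhi = self.bounds
                lo = max(lo, np.log(blo / self.location) / self.spread) \
                    if blo > 0 else lo
                hi = min(hi, np.log(bhi / self.location) / self.spread)
            z = stats.truncnorm.ppf(u, lo, hi)
            return self.location * np.exp(self.spread * z)
        lo, hi = (-3.0, 3.0)
        if self.bounds is not None:
            blo, bhi = self.bounds
            lo = max(lo, (blo - self.location) / self.spread)
            hi = min(hi, (bhi - self.location) / self.spread)
        z = stats.truncnorm.ppf(u, lo, hi)
        return self.location + self.spread * z


def _d(name, location, spread, scale="log", bounds=None):
    return ParameterDistribution(name=name, scale=scale, location=location,
                                 spread=spread, bounds=bounds)


def default_variable_parameters() -> list:
    """The default 26 variable parameters with their population spreads.

    The set mirrors the global-sensitivity-analysis axes: cancer growth and
    kill rates, chemo potency/exposure constants, nab-paclitaxel distribution
    volumes and maximum clearance, checkpoint binding and expression,
    APC/MDSC/Treg/Th rates, inhibition half-max constants, exhaustion,
    angiogenic induction, and the baseline tumour diameter.
    """
    return [
        _d("kC_growth", 0.012, 1.0),
        _d("kC_T", 0.70, 0.45),
        _d("kC_nabp", 0.27, 0.25),
        _d("IC50_nabp", 0.037, 0.60),
        _d("nabp_Vmax", 350.0, 0.60),
        _d("kC_carb", 0.18, 0.25),
        _d("n_clones", 100.0, 0.60),
        _d("kd_pd1_pdl1", 8.0, 0.30),
        _d("pdl1_expr", 60.0, 0.80),
        _d("k_apc_mat", 1.0, 0.40),
        _d("k_mapc_mig", 1.0, 0.30),
        _d("k_act8", 1.0e-5, 0.35),
        _d("k_act4", 1.0e-3, 0.35),
        _d("f_treg", 0.25, 0.06, scale="linear", bounds=(0.05, 0.60)),
        _d("k_tgf_treg", 0.15, 0.30),
        _d("k_mdsc_rec", 1.0e5, 0.40),
        _d("k_mdsc_d", 0.1, 0.30),
        _d("k_exh", 0.24, 0.40),
        _d("k_ang", 0.15, 0.25),
        _d("nabp_V1", 16.0, 0.25),
        _d("nabp_V2", 400.0, 0.25),
        _d("nabp_V3", 1000.0, 0.25),
        _d("K50_PD1", 20.0, 0.40),
        _d("K50_TGF", 1.0, 0.40),
        _d("K50_MDSC", 1.0e6, 0.40),
        _d("dia_0", 3.0, 0.35, bounds=(1.0, 12.0)),
    ]


@dataclass
class PopulationSpec:
    """Distributional specification of a virtual population.

    ``distributions`` define inter-individual variability; ``fixed`` carries
    the remaining model parameters at their population values.
    """

    distributions: list = field(default_factory=default_variable_parameters)
    fixed: ModelParameters = field(default_factory=ModelParameters)

    def __post_init__(self):
        names = [d.name for d in self.distributions]
        if len(set(names)) != len(names):
            dupes = {n for n in names if names.count(n) > 1}
            raise ConfigError(f"duplicate distributions: {sorted(dupes)}")
        unknown = set(names) - set(PARAM_NAMES)
        if unknown:
            raise ConfigError(f"unknown parameter names: {sorted(unknown)}")

    @property
    def names(self) -> list:
        return [d.name for d in self.distributions]

    def get(self, name: str) -> ParameterDistribution:
        for d in self.distributions:
            if d.name == name:
                return d
        raise KeyError(name)

    def with_location(self, name: str, location: float) -> "PopulationSpec":
        """Copy with one distribution's location replaced."""
        new = [dc_replace(d, location=location) if d.name == name else d
               for d in self.distributions]
        if name not in self.names:
            raise KeyError(name)
        return PopulationSpec(distributions=new, fixed=self.fixed)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "distributions": [
                {"name": d.name, "scale": d.scale, "location": d.location,
                 "spread": d.spread,
                 "bounds": list(d.bounds) if d.bounds else None}
                for d in self.distributions
            ],
            "fixed": {n: getattr(self.fixed, n) for n in PARAM_NAMES},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PopulationSpec":
        dists = [
            ParameterDistribution(
                name=d["name"], scale=d.get("scale", "log"),
                location=float(d["location"]), spread=float(d.get("spread", 0.0)),
                bounds=tuple(d["bounds"]) if d.get("bounds") else None)
            for d in data["distributions"]
        ]
        fixed = ModelParameters(**{k: float(v)
                                   for k, v in data.get("fixed", {}).items()})
        return cls(distributions=dists, fixed=fixed)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PopulationSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class VirtualPatient:
    """One sampled parameter realisation."""

    id: int
    params: ModelParameters

    @property
    def baseline_diameter(self) -> float:
        return self.params.dia_0


def lhs_sample(n: int, spec: PopulationSpec, seed) -> pd.DataFrame:
    """n × k Latin-hypercube table of variable-parameter values.

    For each parameter the n unit-interval points occupy each of the n equal
    strata exactly once before transformation through the distribution's
    quantile function; deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k = len(spec.distributions)
    sampler = qmc.LatinHypercube(d=k, seed=seed)
    u = sampler.random(n)
    cols = {d.name: d.quantile(u[:, j])
            for j, d in enumerate(spec.distributions)}
    return pd.DataFrame(cols)


@dataclass
class PopulationReport:
    """Acceptance/rejection bookkeeping from :func:`build_population`."""

    n_accepted: int = 0
    n_rejected: int = 0

    @property
    def acceptance_rate(self) -> float:
        total = self.n_accepted + self.n_rejected
        return self.n_accepted / total if total else float("nan")


def _plausible(row: pd.Series, fixed: ModelParameters) -> bool:
    if row.get("dia_0", fixed.dia_0) < 1.0:     # RECIST-measurable baseline
        return False
    for name, v in row.items():
        if name == "f_treg":
            if not 0 < v < 1:
                return False
        elif v <= 0:
            return False
    dia = row.get("dia_0", fixed.dia_0)
    dmax = row.get("DIA_T_max", fixed.DIA_T_max)
    den = row.get("DEN_T_cell", fixed.DEN_T_cell)
    return cancer_capacity(dia, den) < cancer_capacity(dmax, den)


def build_population(n: int, spec: PopulationSpec, seed):
    """Draw ``n`` plausible virtual patients by LHS.

    Rows failing the plausibility screen (baseline diameter ≥ 1 cm, positive
    rates, baseline burden below capacity) are discarded and replaced from
    fresh LHS batches.  Returns ``(patients, report)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    report = PopulationReport()
    accepted_rows = []
    batch = n
    max_draws = max(100 * n, 10000)
    while len(accepted_rows) < n:
        child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        table = lhs_sample(batch, spec, child_seed)
        for _, row in table.iterrows():
            if len(accepted_rows) >= n:
                break
            if _plausible(row, spec.fixed):
                accepted_rows.append(row)
                report.n_accepted += 1
            else:
                report.n_rejected += 1
        if report.n_accepted + report.n_rejected >= max_draws \
                and report.acceptance_rate < 0.01:
            raise ConfigError(
                "population spec implausible: acceptance rate "
                f"{report.acceptance_rate:.4f} < 1%")
    patients = [
        VirtualPatient(id=i, params=spec.fixed.replace(**row.to_dict()))
        for i, row in enumerate(accepted_rows)
    ]
    return patients, report


def population_frame(patients) -> pd.DataFrame:
    """One row per patient, one column per model parameter (CSV export)."""
    rows = []
    for p in patients:
        d = {"patient_id": p.id}
        d.update({n: getattr(p.params, n) for n in PARAM_NAMES})
        rows.append(d)
    return pd.DataFrame(rows)


#: unit annotations for the parameter-table export (rates default to 1/day)
_UNITS = {
    "IC50_nabp": "µg/mL", "IC50_carb": "µg/mL", "fc_nabp": "-", "fc_carb": "-",
    "K_C_T": "-", "K_C_Treg": "-", "DIA_T_max": "cm",
    "DEN_T_cell": "cells/cm³", "dia_0": "cm", "e_ang": "-", "K_ang": "a.u.",
    "pd1_density": "nM-eq", "pdl1_expr": "nM-eq", "kd_pd1_pdl1": "nM-eq",
    "kd_atezo_pdl1": "nM", "K50_PD1": "nM-eq", "n_PD1": "-", "K50_TGF": "a.u.",
    "K50_MDSC": "cells", "K_ag": "a.u.", "w_icd": "-", "k_apc_in": "cells/day",
    "K_mapc": "cells", "k_nT8_in": "cells/day", "k_nT4_in": "cells/day",
    "n_clones": "clones", "n_prolif8": "fold", "n_prolif4": "fold",
    "f_treg": "-", "K_rec": "cells", "w_exh_treg": "-", "K_exh_treg": "cells",
    "h_th": "-", "K_th_help": "cells", "k_mdsc_rec": "cells/day",
    "K_mdsc_C": "cells", "atezo_CL": "L/day", "atezo_V1": "L", "atezo_V2": "L",
    "atezo_Q": "L/day", "atezo_part": "-", "nabp_V1": "L", "nabp_V2": "L",
    "nabp_V3": "L", "nabp_Q2": "L/day", "nabp_Q3": "L/day",
    "nabp_Vmax": "mg/day", "nabp_Km": "µg/mL", "nabp_part": "-",
    "f_carb_map": "(µg/mL)/(mg/mL·min)", "bsa": "m²", "carb_window": "day",
    "k_ag_rel": "a.u./1e9 cells", "k_tgf_C": "a.u./day per 1e9 cells",
    "k_tgf_treg": "a.u./day per 1e6 cells", "k_ang": "a.u./day per (µg/mL)",
}

#: provenance tags: parameter values stated in the source literature vs the
#: antibody's public label vs this package's own reconstruction choices
_SOURCES = {
    "kC_growth": "paper",
    "atezo_CL": "platform-derived", "atezo_V1": "platform-derived",
    "atezo_V2": "platform-derived", "atezo_Q": "platform-derived",
    "kd_atezo_pdl1": "platform-derived",
    "bsa": "design-decision", "carb_window": "design-decision",
}


def parameter_table(spec: PopulationSpec) -> pd.DataFrame:
    """Full parameter table: name, value or distribution, units, source tag."""
    var = {d.name: d for d in spec.distributions}
    rows = []
    for name in PARAM_NAMES:
        if name in var:
            d = var[name]
            value = (f"{d.scale}-normal(loc={d.location:g}, "
                     f"spread={d.spread:g})")
        else:
            value = f"{getattr(spec.fixed, name):g}"
        rows.append({
            "name": name,
            "value": value,
            "units": _UNITS.get(name, "1/day"),
            "source": _SOURCES.get(name, "design-decision"),
        })
    return pd.DataFrame(rows)
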