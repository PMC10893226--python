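"""Mechanistic immune–tumour ODE system for checkpoint-inhibitor + chemotherapy
virtual trials in non-small-cell lung cancer.

The model tracks a single measurable lesion as a well-mixed population of
cancer cells governed by Gompertz growth toward a geometric carrying capacity,
opposed by three death channels: nab-paclitaxel, carboplatin, and effector
CD8+ T cells.  T-cell killing is attenuated by three saturating inhibition
signals — PD-1/PD-L1 engagement (relieved by atezolizumab), TGF-β, and
myeloid-derived suppressor cells.  Around the cancer balance sits a reduced
immune network spanning four physiological compartments (central blood,
peripheral tissue, tumour-draining lymph node, tumour): immunogenic cell
death releases antigen, antigen matures antigen-presenting cells, mature APCs
migrate to the lymph node and prime naive CD8+/CD4+ T cells into effector,
helper, and regulatory lineages, which traffic via the circulation into the
tumour.  Effector cells exhaust under PD-1 signalling and Treg pressure;
nab-paclitaxel induces an angiogenic factor that raises the effective
carrying capacity and drives late regrowth.

States are absolute cell counts (cells), drug amounts (mg), or arbitrary
concentration units (antigen, TGF-β, angiogenic factor); time is in days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


# --------------------------------------------------------------------------
# State layout
# --------------------------------------------------------------------------

#: Ordered state names; index into the state vector.
STATE_NAMES = (
    "C",           # cancer cells, tumour
    "Ag",          # released antigen, tumour (a.u.)
    "APC",         # immature antigen-presenting cells, tumour
    "mAPC",        # mature APC, tumour
    "mAPC_LN",     # mature APC, lymph node
    "nT8_c",       # naive CD8 T, central
    "nT8_p",       # naive CD8 T, peripheral
    "nT8_LN",      # naive CD8 T, lymph node
    "nT4_c",       # naive CD4 T, central
    "nT4_p",       # naive CD4 T, peripheral
    "nT4_LN",      # naive CD4 T, lymph node
    "aT8_LN",      # activated effector CD8, lymph node
    "aT8_c",       # activated effector CD8, central
    "T8_t",        # effector CD8, tumour
    "aTh_LN",      # activated helper CD4, lymph node
    "aTh_c",       # activated helper CD4, central
    "Th_t",        # helper CD4, tumour
    "aTreg_LN",    # activated regulatory T, lymph node
    "aTreg_c",     # activated regulatory T, central
    "Treg_t",      # regulatory T, tumour
    "Texh",        # exhausted T cells, tumour (terminal sink)
    "MDSC",        # myeloid-derived suppressor cells, tumour
    "TGFb",        # TGF-beta, tumour (a.u.)
    "Ang",         # angiogenic factor, tumour (a.u.)
    "atezo_A1",    # atezolizumab amount, central (mg)
    "atezo_A2",    # atezolizumab amount, peripheral (mg)
    "nabp_A1",     # nab-paclitaxel amount, central (mg)
    "nabp_A2",     # nab-paclitaxel amount, first peripheral (mg)
    "nabp_A3",     # nab-paclitaxel amount, second peripheral (mg)
)

N_STATES = len(STATE_NAMES)
SIDX = {name: i for i, name in enumerate(STATE_NAMES)}

#: µg/mL -> nM conversion for atezolizumab (IgG1, ~145 kDa).
ATEZO_UGML_TO_NM = 1.0e3 / 145.0


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------


@dataclass
class ModelParameters:
    """All rate constants, capacities, binding constants and PK constants.

    Units: rates 1/day unless noted; concentrations µg/mL for drugs and
    nM-equivalent arbitrary units for synapse densities; volumes L;
    diameters cm; densities cells/cm³.
    """

    # cancer balance
    kC_growth: float = 0.012    # Gompertz growth rate, 1/day
    kC_death: float = 0.003     # baseline apoptosis / NK death, 1/day
    kC_nabp: float = 0.27       # max nab-paclitaxel kill rate, 1/day
    IC50_nabp: float = 0.037    # half-max tumour nab-p conc, µg/mL
    fc_nabp: float = 0.9        # cancer fraction accessible to nab-p
    kC_carb: float = 0.18       # max carboplatin kill rate, 1/day
    IC50_carb: float = 0.60     # half-max tumour carboplatin conc, µg/mL
    fc_carb: float = 0.9        # cancer fraction accessible to carboplatin
    kC_T: float = 0.70          # max Teff kill rate, 1/day
    K_C_T: float = 0.003        # Teff–cancer engagement constant
    K_C_Treg: float = 1.0       # Treg suppression constant
    DIA_T_max: float = 15.0     # maximum tumour diameter, cm
    DEN_T_cell: float = 1.0e8   # cancer cell density, cells/cm³
    dia_0: float = 3.0          # baseline tumour diameter, cm
    # angiogenic factor (induced by nab-paclitaxel, raises capacity)
    k_ang: float = 0.15         # induction rate per (µg/mL nab-p in tumour), a.u./day
    k_ang_d: float = 0.01      # decay, 1/day
    e_ang: float = 2.0          # max fractional capacity increase
    K_ang: float = 3.0          # half-max angiogenic signal, a.u.
    # checkpoint module
    pd1_density: float = 30.0   # synapse PD-1 density, nM-equivalent
    pdl1_expr: float = 60.0     # PD-L1 per cancer cell, nM-equivalent
    kd_pd1_pdl1: float = 8.0    # PD-1:PD-L1 Kd, nM-equivalent
    kd_atezo_pdl1: float = 0.4  # atezolizumab:PD-L1 Kd, nM
    K50_PD1: float = 20.0        # half-max PD1–PDL1 complex for H_PD1
    n_PD1: float = 1.0          # Hill exponent of H_PD1
    K50_TGF: float = 1.0        # half-max TGF-β for H_TGF, a.u.
    K50_MDSC: float = 1.0e6     # half-max MDSC count for H_MDSC, cells
    # antigen module
    k_ag_rel: float = 4.0       # antigen release per 1e9 cells killed, a.u.
    k_ag_clr: float = 1.0       # antigen clearance, 1/day
    K_ag: float = 0.5           # half-max antigen for APC maturation, a.u.
    w_icd: float = 3.0          # immunogenic weight of chemo kill flux
    # APC module
    k_apc_in: float = 1.0e6     # immature APC influx, cells/day
    k_apc_d: float = 0.5        # immature APC death, 1/day
    k_apc_mat: float = 1.0      # max maturation rate, 1/day
    K_mapc: float = 1.0e6       # half-max lymph-node mAPC for priming, cells
    k_mapc_mig: float = 1.0     # mAPC migration tumour -> lymph node, 1/day
    k_mapc_d: float = 0.2       # mAPC death, 1/day
    # naive T pools
    k_nT8_in: float = 1.0e7     # thymic naive CD8 input to central, cells/day
    k_nT4_in: float = 2.0e7     # thymic naive CD4 input to central, cells/day
    k_nT_d: float = 0.01        # naive T death, 1/day
    k_nT_cp: float = 0.1        # central -> peripheral trafficking, 1/day
    k_nT_pc: float = 0.05       # peripheral -> central, 1/day
    k_nT_cln: float = 0.02      # central -> lymph node, 1/day
    k_nT_lnc: float = 0.5       # lymph node -> central, 1/day
    # priming and expansion
    n_clones: float = 100.0     # tumour-specific T-cell clone number
    k_act8: float = 1.0e-5      # naive CD8 activation per tumour-specific clone, 1/day
    k_act4: float = 1.0e-3      # naive CD4 activation rate, 1/day
    n_prolif8: float = 128.0    # clonal expansion fold, CD8
    n_prolif4: float = 64.0     # clonal expansion fold, CD4
    f_treg: float = 0.25        # fraction of CD4 priming into Tregs
    # effector trafficking and turnover
    k_egress: float = 1.0       # lymph node egress, 1/day
    k_aT_d: float = 0.05        # circulating activated-T death, 1/day
    k_infil: float = 0.3        # tumour infiltration rate, 1/day
    K_rec: float = 1.0e8        # half-max tumour burden for recruitment, cells
    k_T_d_t: float = 0.02       # intratumoural Teff death, 1/day
    k_th_d_t: float = 0.02      # intratumoural Th death, 1/day
    k_treg_d_t: float = 0.014    # intratumoural Treg death, 1/day
    # exhaustion
    k_exh: float = 0.24         # max exhaustion rate, 1/day
    w_exh_treg: float = 0.75    # Treg contribution to exhaustion drive
    K_exh_treg: float = 1.0e6   # half-max Treg count for exhaustion, cells
    k_exh_d: float = 0.01       # exhausted-cell death, 1/day
    h_th: float = 0.85           # weight of Th-help gating of Teff killing, in [0,1]
    K_th_help: float = 2.0e7    # half-max tumour Th count for help, cells
    # MDSC module
    k_mdsc_rec: float = 1.0e5   # max MDSC recruitment, cells/day
    K_mdsc_C: float = 1.0e8     # half-max tumour burden for recruitment
    k_mdsc_d: float = 0.1       # MDSC death, 1/day
    # TGF-β module
    k_tgf_C: float = 0.10       # secretion per 1e9 cancer cells, a.u./day
    k_tgf_treg: float = 0.15    # secretion per 1e6 Tregs, a.u./day
    k_tgf_clr: float = 1.0      # clearance, 1/day
    # atezolizumab PK (linear two-compartment; label population values)
    atezo_CL: float = 0.2       # clearance, L/day
    atezo_V1: float = 3.28      # central volume, L
    atezo_V2: float = 3.63      # peripheral volume, L
    atezo_Q: float = 0.546      # inter-compartment flow, L/day
    atezo_part: float = 0.3     # tumour:plasma partition coefficient
    # nab-paclitaxel PK (three-compartment, saturable elimination)
    nabp_V1: float = 16.0       # central volume, L
    nabp_V2: float = 400.0       # first peripheral volume, L
    nabp_V3: float = 1000.0      # second peripheral volume, L
    nabp_Q2: float = 150.0       # flow to first peripheral, L/day
    nabp_Q3: float = 40.0       # flow to second peripheral, L/day
    nabp_Vmax: float = 350.0    # max elimination rate, mg/day
    nabp_Km: float = 0.5        # Michaelis constant, µg/mL
    nabp_part: float = 2.0      # tumour:plasma partition coefficient
    # carboplatin exposure mapping
    f_carb_map: float = 0.05    # tumour conc per unit AUC target, (µg/mL)/(mg/mL·min)
    bsa: float = 1.8            # body surface area, m²
    carb_window: float = 21.0   # carboplatin effective window, day
    # angiogenic vascular abnormalisation: loss of chemo accessibility
    e_del: float = 1.0          # max fractional loss of chemo-accessible fraction
    n_ang_del: float = 6.0      # Hill exponent of the delivery-erosion switch
    # growth-fraction dependence of cytotoxic kill (Norton–Simon):
    # chemotherapy efficacy saturates in the tumour's specific growth activity
    K_prolif: float = 0.10      # half-max specific growth rate for chemo kill, 1/day

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Enforce sign/interval invariants on every parameter."""
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite: {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
        for name in ("fc_nabp", "fc_carb", "f_treg"):
            if getattr(self, name) > 1.0:
                raise ValueError(f"fraction {name} must lie in [0, 1]")
        if self.n_PD1 < 1.0:
            raise ValueError("Hill exponent n_PD1 must be >= 1")
        if self.DIA_T_max <= 0 or self.DEN_T_cell <= 0:
            raise ValueError("DIA_T_max and DEN_T_cell must be positive")

    def to_vector(self) -> np.ndarray:
        """Flatten to the ordered float vector consumed by the ODE kernel."""
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    def replace(self, **updates) -> "ModelParameters":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(updates)
        return ModelParameters(**d)

    @property
    def c_max(self) -> float:
        """Carrying capacity of the lesion, cells."""
        return cancer_capacity(self.DIA_T_max, self.DEN_T_cell)


PARAM_NAMES = tuple(f.name for f in fields(ModelParameters))
PIDX = {name: i for i, name in enumerate(PARAM_NAMES)}


@dataclass(frozen=True)
class InhibitionSignals:
    """Saturating inhibition factors multiplying the Teff kill rate."""

    H_PD1: float
    H_TGF: float
    H_MDSC: float


# --------------------------------------------------------------------------
# Tumour geometry
# --------------------------------------------------------------------------


def cancer_capacity(dia_t_max: float, den_t_cell: float) -> float:
    """Maximal cancer-cell capacity: sphere volume at ``dia_t_max`` × density.

    Parameters are the maximum tumour diameter (cm) and the cancer cell
    density (cells/cm³); the result is in cells.
    """
    if dia_t_max < 0 or den_t_cell < 0:
        raise ValueError("diameter and density must be non-negative")
    return (4.0 / 3.0) * math.pi * (dia_t_max / 2.0) ** 3 * den_t_cell


def tumour_diameter(c_total: float, den_t_cell: float) -> float:
    """Equivalent spherical diameter (cm) of ``c_total`` cells at a density.

    Inverse of :func:`cancer_capacity`; RECIST assessment operates on
    diameters while the ODE tracks cell counts.
    """
    if den_t_cell <= 0:
        raise ValueError("den_t_cell must be positive")
    if c_total < 0:
        raise ValueError("c_total must be non-negative")
    return 2.0 * (3.0 * (c_total / den_t_cell) / (4.0 * math.pi)) ** (1.0 / 3.0)


def tumour_volume_mm3(c_total: float, den_t_cell: float) -> float:
    """Tumour volume in mm³ for ``c_total`` cells at ``den_t_cell`` cells/cm³."""
    if den_t_cell <= 0:
        raise ValueError("den_t_cell must be positive")
    return c_total / den_t_cell * 1.0e3


# --------------------------------------------------------------------------
# Checkpoint quasi-equilibrium
# --------------------------------------------------------------------------


@njit(cache=True)
def _pd1_complex(pd1: float, pdl1: float, atezo_nm: float,
                 kd1: float, kd2: float) -> float:
    """Equilibrium PD1–PDL1 complex density under competitive atezolizumab.

    Atezolizumab (free concentration ``atezo_nm``, assumed unbound excess)
    binds PD-L1 with Kd ``kd2``; PD-1 binds remaining PD-L1 with Kd ``kd1``.
    Solves the mass-balance quadratic for the synapse complex x:
        x² − x·(P + L + a·kd1) + P·L = 0,   a = 1 + atezo/kd2,
    and returns the physical (smaller) root.
    """
    if pd1 <= 0.0 or pdl1 <= 0.0:
        return 0.0
    a = 1.0 + atezo_nm / kd2
    b = pd1 + pdl1 + a * kd1
    disc = b * b - 4.0 * pd1 * pdl1
    if disc < 0.0:
        disc = 0.0
    x = 0.5 * (b - math.sqrt(disc))
    if x < 0.0:
        x = 0.0
    elif x > min(pd1, pdl1):
        x = min(pd1, pdl1)
    return x


def checkpoint_occupancy(pd1_density: float, pdl1_density: float,
                         atezo_tumour_conc: float, kd_pd1_pdl1: float,
                         kd_atezo_pdl1: float, K50_PD1: float,
                         n_PD1: float = 1.0) -> float:
    """PD-1 inhibition signal H_PD1 ∈ [0, 1].

    ``atezo_tumour_conc`` is the tumour atezolizumab concentration in nM.
    The PD1–PDL1 complex from the competitive quasi-equilibrium is passed
    through a Hill function with half-max ``K50_PD1`` and exponent ``n_PD1``.
    Monotone decreasing in atezolizumab; monotone increasing in PD-L1.
    """
    for v in (pd1_density, pdl1_density, atezo_tumour_conc, kd_pd1_pdl1,
              kd_atezo_pdl1, K50_PD1):
        if v < 0:
            raise ValueError("densities and constants must be non-negative")
    x = _pd1_complex(pd1_density, pdl1_density, atezo_tumour_conc,
                     kd_pd1_pdl1, kd_atezo_pdl1)
    if x == 0.0:
        return 0.0
    xn = x ** n_PD1
    return xn / (xn + K50_PD1 ** n_PD1)


def inhibition_terms(state: np.ndarray, params: ModelParameters) -> InhibitionSignals:
    """Evaluate all three inhibition signals at a model state."""
    atezo_nm = (state[SIDX["atezo_A1"]] / params.atezo_V1) * params.atezo_part \
        * ATEZO_UGML_TO_NM
    h_pd1 = checkpoint_occupancy(params.pd1_density, params.pdl1_expr, atezo_nm,
                                 params.kd_pd1_pdl1, params.kd_atezo_pdl1,
                                 params.K50_PD1, params.n_PD1)
    tgf = max(state[SIDX["TGFb"]], 0.0)
    mdsc = max(state[SIDX["MDSC"]], 0.0)
    h_tgf = tgf / (tgf + params.K50_TGF) if tgf > 0 else 0.0
    h_mdsc = mdsc / (mdsc + params.K50_MDSC) if mdsc > 0 else 0.0
    return InhibitionSignals(H_PD1=h_pd1, H_TGF=h_tgf, H_MDSC=h_mdsc)


# --------------------------------------------------------------------------
# Right-hand side kernel
# --------------------------------------------------------------------------


@njit(cache=True)
def _rhs(t: float, y: np.ndarray, p: np.ndarray, carb_conc: float,
         clamp_c: float) -> np.ndarray:
    """Full model right-hand side.

    ``carb_conc`` is the (piecewise-constant) tumour carboplatin
    concentration on the current integration segment.  ``clamp_c`` != 0
    freezes the cancer state (burn-in to the immune steady state).
    """
    kC_growth = p[0]
    kC_death = p[1]
    kC_nabp = p[2]
    IC50_nabp = p[3]
    fc_nabp = p[4]
    kC_carb = p[5]
    IC50_carb = p[6]
    fc_carb = p[7]
    kC_T = p[8]
    K_C_T = p[9]
    K_C_Treg = p[10]
    DIA_T_max = p[11]
    DEN_T_cell = p[12]
    # p[13] = dia_0 (initial condition, not used in the RHS)
    k_ang = p[14]
    k_ang_d = p[15]
    e_ang = p[16]
    K_ang = p[17]
    pd1_density = p[18]
    pdl1_expr = p[19]
    kd_pd1_pdl1 = p[20]
    kd_atezo_pdl1 = p[21]
    K50_PD1 = p[22]
    n_PD1 = p[23]
    K50_TGF = p[24]
    K50_MDSC = p[25]
    k_ag_rel = p[26]
    k_ag_clr = p[27]
    K_ag = p[28]
    w_icd = p[29]
    k_apc_in = p[30]
    k_apc_d = p[31]
    k_apc_mat = p[32]
    K_mapc = p[33]
    k_mapc_mig = p[34]
    k_mapc_d = p[35]
    k_nT8_in = p[36]
    k_nT4_in = p[37]
    k_nT_d = p[38]
    k_nT_cp = p[39]
    k_nT_pc = p[40]
    k_nT_cln = p[41]
    k_nT_lnc = p[42]
    n_clones = p[43]
    k_act8 = p[44]
    k_act4 = p[45]
    n_prolif8 = p[46]
    n_prolif4 = p[47]
    f_treg = p[48]
    k_egress = p[49]
    k_aT_d = p[50]
    k_infil = p[51]
    K_rec = p[52]
    k_T_d_t = p[53]
    k_th_d_t = p[54]
    k_treg_d_t = p[55]
    k_exh = p[56]
    w_exh_treg = p[57]
    K_exh_treg = p[58]
    k_exh_d = p[59]
    h_th = p[60]
    K_th_help = p[61]
    k_mdsc_rec = p[62]
    K_mdsc_C = p[63]
    k_mdsc_d = p[64]
    k_tgf_C = p[65]
    k_tgf_treg = p[66]
    k_tgf_clr = p[67]
    atezo_CL = p[68]
    atezo_V1 = p[69]
    atezo_V2 = p[70]
    atezo_Q = p[71]
    atezo_part = p[72]
    nabp_V1 = p[73]
    nabp_V2 = p[74]
    nabp_V3 = p[75]
    nabp_Q2 = p[76]
    nabp_Q3 = p[77]
    nabp_Vmax = p[78]
    nabp_Km = p[79]
    nabp_part = p[80]
    # p[81] = f_carb_map, p[82] = bsa, p[83] = carb_window: used by the
    # dosing layer, not inside the RHS (carb_conc arrives pre-computed).
    e_del = p[84]
    n_ang_del = p[85]
    K_prolif = p[86]

    dy = np.zeros(29)

    C = y[0] if y[0] > 0.0 else 0.0
    Ag = y[1] if y[1] > 0.0 else 0.0
    APC = y[2] if y[2] > 0.0 else 0.0
    mAPC = y[3] if y[3] > 0.0 else 0.0
    mAPC_LN = y[4] if y[4] > 0.0 else 0.0
    nT8_c = y[5] if y[5] > 0.0 else 0.0
    nT8_p = y[6] if y[6] > 0.0 else 0.0
    nT8_LN = y[7] if y[7] > 0.0 else 0.0
    nT4_c = y[8] if y[8] > 0.0 else 0.0
    nT4_p = y[9] if y[9] > 0.0 else 0.0
    nT4_LN = y[10] if y[10] > 0.0 else 0.0
    aT8_LN = y[11] if y[11] > 0.0 else 0.0
    aT8_c = y[12] if y[12] > 0.0 else 0.0
    T8_t = y[13] if y[13] > 0.0 else 0.0
    aTh_LN = y[14] if y[14] > 0.0 else 0.0
    aTh_c = y[15] if y[15] > 0.0 else 0.0
    Th_t = y[16] if y[16] > 0.0 else 0.0
    aTreg_LN = y[17] if y[17] > 0.0 else 0.0
    aTreg_c = y[18] if y[18] > 0.0 else 0.0
    Treg_t = y[19] if y[19] > 0.0 else 0.0
    Texh = y[20] if y[20] > 0.0 else 0.0
    MDSC = y[21] if y[21] > 0.0 else 0.0
    TGFb = y[22] if y[22] > 0.0 else 0.0
    Ang = y[23] if y[23] > 0.0 else 0.0
    atezo_A1 = y[24] if y[24] > 0.0 else 0.0
    atezo_A2 = y[25] if y[25] > 0.0 else 0.0
    nabp_A1 = y[26] if y[26] > 0.0 else 0.0
    nabp_A2 = y[27] if y[27] > 0.0 else 0.0
    nabp_A3 = y[28] if y[28] > 0.0 else 0.0

    # ---- pharmacokinetics -------------------------------------------------
    atezo_C1 = atezo_A1 / atezo_V1                     # µg/mL
    dy[24] = -(atezo_CL / atezo_V1) * atezo_A1 \
        - (atezo_Q / atezo_V1) * atezo_A1 + (atezo_Q / atezo_V2) * atezo_A2
    dy[25] = (atezo_Q / atezo_V1) * atezo_A1 - (atezo_Q / atezo_V2) * atezo_A2

    nabp_C1 = nabp_A1 / nabp_V1
    nabp_C2 = nabp_A2 / nabp_V2
    nabp_C3 = nabp_A3 / nabp_V3
    elim = nabp_Vmax * nabp_C1 / (nabp_Km + nabp_C1) if nabp_C1 > 0.0 else 0.0
    dy[26] = -elim - nabp_Q2 * (nabp_C1 - nabp_C2) - nabp_Q3 * (nabp_C1 - nabp_C3)
    dy[27] = nabp_Q2 * (nabp_C1 - nabp_C2)
    dy[28] = nabp_Q3 * (nabp_C1 - nabp_C3)

    nabp_tum = nabp_part * nabp_C1                     # µg/mL in tumour
    atezo_tum_nm = atezo_part * atezo_C1 * (1.0e3 / 145.0)

    # ---- inhibition signals ----------------------------------------------
    x = _pd1_complex(pd1_density, pdl1_expr, atezo_tum_nm,
                     kd_pd1_pdl1, kd_atezo_pdl1)
    if x > 0.0:
        xn = x ** n_PD1
        H_PD1 = xn / (xn + K50_PD1 ** n_PD1)
    else:
        H_PD1 = 0.0
    H_TGF = TGFb / (TGFb + K50_TGF) if TGFb > 0.0 else 0.0
    H_MDSC = MDSC / (MDSC + K50_MDSC) if MDSC > 0.0 else 0.0

    # ---- cancer balance ---------------------------------------------------
    c_max = (4.0 / 3.0) * math.pi * (DIA_T_max / 2.0) ** 3 * DEN_T_cell
    h_ang = Ang / (Ang + K_ang) if Ang > 0.0 else 0.0
    c_max_eff = c_max * (1.0 + e_ang * h_ang)
    c_total = C

    # vascular abnormalisation erodes the chemo-accessible cancer fraction
    # (sigmoidal: quiet early in treatment, dominant once Ang accumulates)
    if Ang > 0.0:
        ang_n = Ang ** n_ang_del
        h_del = ang_n / (ang_n + K_ang ** n_ang_del)
    else:
        h_del = 0.0
    f_deliv = 1.0 - e_del * h_del
    # growth-fraction gating: proliferative tumours are chemo-sensitive
    if C > 0.0:
        prolif = kC_growth * math.log(c_max_eff / C)
        norton = prolif / (prolif + K_prolif) if prolif > 0.0 else 0.0
    else:
        norton = 0.0
    f_chemo = f_deliv * norton
    kill_nabp = kC_nabp * nabp_tum / (nabp_tum + IC50_nabp) * fc_nabp * f_chemo \
        if nabp_tum > 0.0 else 0.0
    kill_carb = kC_carb * carb_conc / (carb_conc + IC50_carb) * fc_carb * f_chemo \
        if carb_conc > 0.0 else 0.0
    if T8_t > 0.0 and c_total > 0.0:
        engage = T8_t / (T8_t + K_C_T * c_total)
        suppress = T8_t / (T8_t + K_C_Treg * Treg_t)
        help_f = (1.0 - h_th) + h_th * Th_t / (Th_t + K_th_help)
        kill_T = kC_T * engage * suppress * help_f \
            * (1.0 - H_PD1) * (1.0 - H_TGF) * (1.0 - H_MDSC)
    else:
        kill_T = 0.0

    death_rate = kC_death + kill_nabp + kill_carb + kill_T
    if C > 0.0 and c_total > 0.0:
        growth = kC_growth * C * math.log(c_max_eff / c_total)
    else:
        growth = 0.0
    if clamp_c == 0.0:
        dy[0] = growth - death_rate * C

    # ---- antigen ----------------------------------------------------------
    chemo_flux = (kill_nabp + kill_carb) * C
    other_flux = (kC_death + kill_T) * C
    ag_src = k_ag_rel * (other_flux + w_icd * chemo_flux) * 1.0e-9
    dy[1] = ag_src - k_ag_clr * Ag

    # ---- APC --------------------------------------------------------------
    s_ag = Ag / (Ag + K_ag) if Ag > 0.0 else 0.0
    mat = k_apc_mat * s_ag * APC
    dy[2] = k_apc_in - k_apc_d * APC - mat
    dy[3] = mat - (k_mapc_mig + k_mapc_d) * mAPC
    dy[4] = k_mapc_mig * mAPC - k_mapc_d * mAPC_LN

    # ---- naive T trafficking and priming ----------------------------------
    s_mapc = mAPC_LN / (mAPC_LN + K_mapc) if mAPC_LN > 0.0 else 0.0
    # the clone number counts tumour-specific (neoantigen) clones and limits
    # CD8 priming; CD4 helper/Treg priming is not neoantigen-limited
    act8 = k_act8 * n_clones * s_mapc * nT8_LN
    act4 = k_act4 * s_mapc * nT4_LN

    dy[5] = k_nT8_in - k_nT_d * nT8_c - k_nT_cp * nT8_c + k_nT_pc * nT8_p \
        - k_nT_cln * nT8_c + k_nT_lnc * nT8_LN
    dy[6] = k_nT_cp * nT8_c - k_nT_pc * nT8_p - k_nT_d * nT8_p
    dy[7] = k_nT_cln * nT8_c - k_nT_lnc * nT8_LN - k_nT_d * nT8_LN - act8

    dy[8] = k_nT4_in - k_nT_d * nT4_c - k_nT_cp * nT4_c + k_nT_pc * nT4_p \
        - k_nT_cln * nT4_c + k_nT_lnc * nT4_LN
    dy[9] = k_nT_cp * nT4_c - k_nT_pc * nT4_p - k_nT_d * nT4_p
    dy[10] = k_nT_cln * nT4_c - k_nT_lnc * nT4_LN - k_nT_d * nT4_LN - act4

    # ---- effector / helper / regulatory chains ----------------------------
    s_rec = c_total / (c_total + K_rec) if c_total > 0.0 else 0.0

    dy[11] = n_prolif8 * act8 - (k_egress + k_aT_d) * aT8_LN
    dy[12] = k_egress * aT8_LN - (k_infil * s_rec + k_aT_d) * aT8_c
    treg_h = Treg_t / (Treg_t + K_exh_treg) if Treg_t > 0.0 else 0.0
    exh_drive = H_PD1 + w_exh_treg * treg_h
    exh_flux = k_exh * exh_drive * T8_t
    dy[13] = k_infil * s_rec * aT8_c - k_T_d_t * T8_t - exh_flux

    act_th = n_prolif4 * (1.0 - f_treg) * act4
    dy[14] = act_th - (k_egress + k_aT_d) * aTh_LN
    dy[15] = k_egress * aTh_LN - (k_infil * s_rec + k_aT_d) * aTh_c
    dy[16] = k_infil * s_rec * aTh_c - k_th_d_t * Th_t

    act_treg = n_prolif4 * f_treg * act4
    dy[17] = act_treg - (k_egress + k_aT_d) * aTreg_LN
    dy[18] = k_egress * aTreg_LN - (k_infil * s_rec + k_aT_d) * aTreg_c
    dy[19] = k_infil * s_rec * aTreg_c - k_treg_d_t * Treg_t

    dy[20] = exh_flux - k_exh_d * Texh

    # ---- MDSC, TGF-β, angiogenic factor ------------------------------------
    # tumour-burden- and angiogenic-factor-driven recruitment (VEGF-MDSC axis)
    mdsc_drive = h_ang
    if c_total > 0.0:
        mdsc_drive = mdsc_drive + c_total / (c_total + K_mdsc_C)
    dy[21] = k_mdsc_rec * mdsc_drive - k_mdsc_d * MDSC
    dy[22] = k_tgf_C * c_total * 1.0e-9 + k_tgf_treg * Treg_t * 1.0e-6 \
        - k_tgf_clr * TGFb
    dy[23] = k_ang * nabp_tum - k_ang_d * Ang

    return dy


class IntegrationError(RuntimeError):
    """Raised when the right-hand side or the solver produces invalid values."""

    def __init__(self, message: str, species: str | None = None,
                 time: float | None = None):
        super().__init__(message)
        self.species = species
        self.time = time


def full_rhs(t: float, state: np.ndarray, params: ModelParameters,
             carb_conc: float = 0.0, clamp_c: bool = False) -> np.ndarray:
    """Assembled model right-hand side with flux validation.

    ``carb_conc`` is the tumour carboplatin concentration at ``t`` (the dosing
    layer holds it piecewise-constant between events).  Raises
    :class:`IntegrationError` naming the offending species on NaN/Inf.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATES,):
        raise ValueError(f"state must have shape ({N_STATES},)")
    dy = _rhs(float(t), y, params.to_vector(), float(carb_conc),
              1.0 if clamp_c else 0.0)
    if not np.all(np.isfinite(dy)):
        bad = int(np.argmin(np.isfinite(dy)))
        raise IntegrationError(
            f"non-finite flux for species {STATE_NAMES[bad]} at t={t}",
            species=STATE_NAMES[bad], time=t)
    return dy


def cancer_rhs(state: np.ndarray, params: ModelParameters,
               drug_concentrations: dict | None = None) -> float:
    """Cancer-cell balance dC/dt (cells/day).

    ``drug_concentrations`` may carry tumour concentrations under keys
    ``nabp`` and ``carb`` (µg/mL) and ``atezo_nm`` (nM); concentrations
    implied by the PK states are used for drugs not overridden.
    """
    y = np.asarray(state, dtype=float).copy()
    drugs = drug_concentrations or {}
    for v in drugs.values():
        if v < 0:
            raise ValueError("drug concentrations must be non-negative")
    c = y[SIDX["C"]]
    if c < 0:
        raise IntegrationError("total cancer count inconsistent with C > 0",
                               species="C")
    if "nabp" in drugs:
        y[SIDX["nabp_A1"]] = drugs["nabp"] / params.nabp_part * params.nabp_V1
    if "atezo_nm" in drugs:
        y[SIDX["atezo_A1"]] = drugs["atezo_nm"] / ATEZO_UGML_TO_NM \
            / params.atezo_part * params.atezo_V1
    carb = drugs.get("carb", 0.0)
    dy = full_rhs(0.0, y, params, carb_conc=carb)
    return float(dy[SIDX["C"]])


def initial_state(params: ModelParameters) -> np.ndarray:
    """Pre-burn-in state: tumour seeded at the baseline diameter, immune
    pools at rough analytic steady states (refined by the burn-in), drugs 0.
    """
    y = np.zeros(N_STATES)
    y[SIDX["C"]] = cancer_capacity(params.dia_0, params.DEN_T_cell)
    # naive pools: balance thymic input against death (ignoring trafficking
    # asymmetry, corrected during burn-in)
    y[SIDX["nT8_c"]] = params.k_nT8_in / max(params.k_nT_d, 1e-12) * 0.5
    y[SIDX["nT8_p"]] = y[SIDX["nT8_c"]]
    y[SIDX["nT8_LN"]] = y[SIDX["nT8_c"]] * 0.04
    y[SIDX["nT4_c"]] = params.k_nT4_in / max(params.k_nT_d, 1e-12) * 0.5
    y[SIDX["nT4_p"]] = y[SIDX["nT4_c"]]
    y[SIDX["nT4_LN"]] = y[SIDX["nT4_c"]] * 0.04
    y[SIDX["APC"]] = params.k_apc_in / max(params.k_apc_d, 1e-12)
    return y


def gompertz_solution(t: np.ndarray, c0: float, kc_growth: float,
                      c_max: float) -> np.ndarray:
    """Closed-form Gompertz trajectory C(t) = Cmax·exp(ln(C0/Cmax)·e^(−k·t))."""
    t = np.asarray(t, dtype=float)
    return c_max * np.exp(np.log(c0 / c_max) * np.exp(-kc_growth * t))
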