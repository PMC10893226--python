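"""Core ODE system: tumour geometry, checkpoint equilibrium, cancer balance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from ioqsp import (
    ModelParameters,
    cancer_capacity,
    cancer_rhs,
    checkpoint_occupancy,
    full_rhs,
    gompertz_solution,
    inhibition_terms,
    tumour_diameter,
)
from ioqsp.model_core import N_STATES, SIDX, initial_state


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def test_capacity_examples():
    assert cancer_capacity(0.0, 1e8) == 0.0
    # sphere of diameter 2 cm at 1e8 cells/cm^3
    assert cancer_capacity(2.0, 1e8) == pytest.approx(4.18879e8, rel=1e-5)
    # cubic scaling in diameter
    assert cancer_capacity(4.0, 1e8) == pytest.approx(
        8 * cancer_capacity(2.0, 1e8))
    with pytest.raises(ValueError):
        cancer_capacity(-1.0, 1e8)


def test_diameter_examples():
    assert tumour_diameter(0.0, 1e8) == 0.0
    assert tumour_diameter(4.18879e8, 1e8) == pytest.approx(2.0, abs=1e-3)
    with pytest.raises(ValueError):
        tumour_diameter(1.0, 0.0)


@settings(derandomize=True, max_examples=100)
@given(d=st.floats(0.01, 30.0), rho=st.floats(1e6, 1e10))
def test_capacity_diameter_roundtrip(d, rho):
    assert tumour_diameter(cancer_capacity(d, rho), rho) == pytest.approx(
        d, rel=1e-10)


# ---------------------------------------------------------------------------
# checkpoint quasi-equilibrium
# ---------------------------------------------------------------------------


def _complex_oracle(p_tot, l_tot, atezo, kd1, kd2):
    """Bisection on the synapse mass balances (independent of the quadratic)."""
    a = 1.0 + atezo / kd2

    def f(x):
        # free PD-1 = P - x; free PD-L1 = (L - x)/a; complex = P_f*L_f/kd1
        return (p_tot - x) * (l_tot - x) / a / kd1 - x

    return brentq(f, 0.0, min(p_tot, l_tot), xtol=1e-14, rtol=1e-14)


def test_checkpoint_limits():
    p = ModelParameters()
    # saturating antibody removes the signal entirely
    h_inf = checkpoint_occupancy(p.pd1_density, p.pdl1_expr, 1e9,
                                 p.kd_pd1_pdl1, p.kd_atezo_pdl1, p.K50_PD1)
    assert h_inf < 1e-3
    # half-max by construction: choose K50 equal to the drug-free complex
    x0 = _complex_oracle(p.pd1_density, p.pdl1_expr, 0.0, p.kd_pd1_pdl1,
                         p.kd_atezo_pdl1)
    h = checkpoint_occupancy(p.pd1_density, p.pdl1_expr, 0.0,
                             p.kd_pd1_pdl1, p.kd_atezo_pdl1, K50_PD1=x0)
    assert h == pytest.approx(0.5, rel=1e-9)


def test_checkpoint_matches_bisection_oracle():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        p_tot = rng.uniform(1, 100)
        l_tot = rng.uniform(1, 200)
        atezo = rng.uniform(0, 500)
        kd1 = rng.uniform(0.5, 50)
        kd2 = rng.uniform(0.05, 5)
        x = _complex_oracle(p_tot, l_tot, atezo, kd1, kd2)
        h = checkpoint_occupancy(p_tot, l_tot, atezo, kd1, kd2, K50_PD1=10.0)
        assert h == pytest.approx(x / (x + 10.0), abs=1e-8)


def test_checkpoint_monotonicity():
    p = ModelParameters()
    concs = np.linspace(0, 400, 30)
    h = [checkpoint_occupancy(p.pd1_density, p.pdl1_expr, c, p.kd_pd1_pdl1,
                              p.kd_atezo_pdl1, p.K50_PD1) for c in concs]
    assert all(a >= b for a, b in zip(h, h[1:]))          # decreasing in drug
    assert h[0] > max(h[1:])                              # strictly higher drug-free
    pdl1 = np.linspace(1, 300, 30)
    h2 = [checkpoint_occupancy(p.pd1_density, l, 10.0, p.kd_pd1_pdl1,
                               p.kd_atezo_pdl1, p.K50_PD1) for l in pdl1]
    assert all(b >= a - 1e-12 for a, b in zip(h2, h2[1:]))  # increasing in PD-L1


def test_inhibition_terms_limits(default_params):
    y = initial_state(default_params)
    y[SIDX["TGFb"]] = 0.0
    y[SIDX["MDSC"]] = 0.0
    y[SIDX["atezo_A1"]] = 1e7          # saturating antibody
    sig = inhibition_terms(y, default_params)
    assert sig.H_TGF == 0.0 and sig.H_MDSC == 0.0 and sig.H_PD1 < 1e-3
    y[SIDX["TGFb"]] = default_params.K50_TGF
    assert inhibition_terms(y, default_params).H_TGF == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# cancer balance
# ---------------------------------------------------------------------------


def test_cancer_rhs_empty_tumour_is_fixed_point(default_params):
    y = initial_state(default_params)
    y[SIDX["C"]] = 0.0
    assert cancer_rhs(y, default_params) == 0.0


def test_cancer_rhs_gompertz_sign(default_params):
    p = default_params.replace(kC_death=0.0, kC_T=0.0)
    y = np.zeros(N_STATES)
    y[SIDX["C"]] = 0.5 * p.c_max
    dc = cancer_rhs(y, p)
    expected = p.kC_growth * y[SIDX["C"]] * math.log(p.c_max / y[SIDX["C"]])
    assert dc == pytest.approx(expected, rel=1e-12)
    assert dc > 0


def test_cancer_rhs_term_by_term_oracle():
    """One full evaluation with every channel active vs a hand computation."""
    p = ModelParameters()
    y = initial_state(p)
    c = y[SIDX["C"]]
    y[SIDX["T8_t"]] = 5e6
    y[SIDX["Th_t"]] = 1e7
    y[SIDX["Treg_t"]] = 2e6
    y[SIDX["TGFb"]] = 0.8
    y[SIDX["MDSC"]] = 5e5
    y[SIDX["Ang"]] = 1.2
    nabp, carb, atezo_nm = 0.4, 0.3, 50.0

    dc = cancer_rhs(y, p, {"nabp": nabp, "carb": carb, "atezo_nm": atezo_nm})

    # independent spreadsheet-style recomputation
    h_ang = 1.2 / (1.2 + p.K_ang)
    c_max_eff = p.c_max * (1 + p.e_ang * h_ang)
    h_del = 1.2 ** p.n_ang_del / (1.2 ** p.n_ang_del + p.K_ang ** p.n_ang_del)
    prolif = p.kC_growth * math.log(c_max_eff / c)
    f_chemo = (1 - p.e_del * h_del) * prolif / (prolif + p.K_prolif)
    kill_nabp = p.kC_nabp * nabp / (nabp + p.IC50_nabp) * p.fc_nabp * f_chemo
    kill_carb = p.kC_carb * carb / (carb + p.IC50_carb) * p.fc_carb * f_chemo
    h_pd1 = checkpoint_occupancy(p.pd1_density, p.pdl1_expr, atezo_nm,
                                 p.kd_pd1_pdl1, p.kd_atezo_pdl1, p.K50_PD1)
    h_tgf = 0.8 / (0.8 + p.K50_TGF)
    h_mdsc = 5e5 / (5e5 + p.K50_MDSC)
    t8 = 5e6
    engage = t8 / (t8 + p.K_C_T * c)
    suppress = t8 / (t8 + p.K_C_Treg * 2e6)
    help_f = (1 - p.h_th) + p.h_th * 1e7 / (1e7 + p.K_th_help)
    kill_t = p.kC_T * engage * suppress * help_f \
        * (1 - h_pd1) * (1 - h_tgf) * (1 - h_mdsc)
    expected = p.kC_growth * c * math.log(c_max_eff / c) \
        - (p.kC_death + kill_nabp + kill_carb + kill_t) * c
    assert dc == pytest.approx(expected, rel=1e-9)


@pytest.mark.parametrize("channel", ["nabp", "carb", "T", "atezo"])
def test_cancer_rhs_monotone_nonincreasing(channel, default_params):
    """dC/dt decreases (weakly) in each kill input, all else fixed."""
    p = default_params
    base = initial_state(p)
    base[SIDX["T8_t"]] = 3e6
    vals = []
    for level in np.linspace(0.0, 1.0, 8):
        y = base.copy()
        drugs = {}
        if channel == "nabp":
            drugs["nabp"] = level
        elif channel == "carb":
            drugs["carb"] = level
        elif channel == "T":
            y[SIDX["T8_t"]] = 3e6 + level * 3e7
        else:
            drugs["atezo_nm"] = level * 500.0
        vals.append(cancer_rhs(y, p, drugs))
    assert all(b <= a + 1e-6 for a, b in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# full right-hand side
# ---------------------------------------------------------------------------


def _zero_rate_params():
    d = {f: 0.0 for f in ModelParameters.__dataclass_fields__}
    for f in ("DIA_T_max", "DEN_T_cell", "dia_0"):
        d[f] = {"DIA_T_max": 15.0, "DEN_T_cell": 1e8, "dia_0": 3.0}[f]
    for f in ("atezo_CL", "atezo_V1", "atezo_V2", "atezo_Q", "nabp_V1",
              "nabp_V2", "nabp_V3", "nabp_Q2", "nabp_Q3", "nabp_Vmax",
              "nabp_Km", "bsa"):
        d[f] = 1.0
    d["n_PD1"] = 1.0
    return ModelParameters(**d)


def test_full_rhs_zero_rates_zero_flux():
    p = _zero_rate_params()
    y = initial_state(p)
    dy = full_rhs(0.0, y, p)
    # no kinetic rates -> only the (zeroed) PK flows could move mass
    assert np.allclose(dy, 0.0, atol=1e-12)


def test_naive_t_transport_conserves_total(default_params):
    """With input, death and activation off, trafficking conserves naive T."""
    p = default_params.replace(k_nT8_in=0.0, k_nT4_in=0.0, k_nT_d=0.0,
                               k_act8=0.0, k_act4=0.0)
    y = initial_state(p)
    dy = full_rhs(0.0, y, p)
    cd8 = dy[SIDX["nT8_c"]] + dy[SIDX["nT8_p"]] + dy[SIDX["nT8_LN"]]
    cd4 = dy[SIDX["nT4_c"]] + dy[SIDX["nT4_p"]] + dy[SIDX["nT4_LN"]]
    assert cd8 == pytest.approx(0.0, abs=1e-3)
    assert cd4 == pytest.approx(0.0, abs=1e-3)


def test_gompertz_analytic_limit():
    """Growth-only dynamics match the closed-form Gompertz curve to 1e-6."""
    from ioqsp.engine import _SPECIES_SCALE, _integrate_segment

    p = ModelParameters().replace(kC_death=0.0, kC_T=0.0, kC_nabp=0.0,
                                  kC_carb=0.0, k_ang=0.0)
    y0 = initial_state(p)
    c0 = y0[SIDX["C"]]
    t_eval = np.linspace(0.0, 400.0, 21)[1:]
    sol = _integrate_segment(y0, 0.0, 400.0, p.to_vector(), 0.0, 0.0,
                             t_eval, 1e-8, 1e-8 * _SPECIES_SCALE, 0)
    expected = gompertz_solution(t_eval, c0, p.kC_growth, p.c_max)
    assert np.allclose(sol.y[SIDX["C"]], expected, rtol=1e-6)


def test_hundred_day_integration_stays_nonnegative(default_params):
    from ioqsp.engine import _SPECIES_SCALE, _integrate_segment

    y0 = initial_state(default_params)
    sol = _integrate_segment(y0, 0.0, 100.0, default_params.to_vector(), 0.0,
                             0.0, np.linspace(1, 100, 100), 1e-6,
                             1e-6 * _SPECIES_SCALE, 0)
    assert np.all(sol.y >= -1e-9 * _SPECIES_SCALE[:, None])


def test_parameter_validation():
    with pytest.raises(ValueError):
        ModelParameters(kC_growth=-0.1)
    with pytest.raises(ValueError):
        ModelParameters(fc_nabp=1.5)
    with pytest.raises(ValueError):
        ModelParameters(n_PD1=0.5)
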