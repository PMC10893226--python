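distributions:
- name: kC_growth
  scale: log
  location: 0.012
  spread: 1.0
  bounds: null
- name: kC_T
  scale: log
  location: 0.7
  spread: 0.45
  bounds: null
- name: kC_nabp
  scale: log
  location: 0.27
  spread: 0.25
  bounds: null
- name: IC50_nabp
  scale: log
  location: 0.037
  spread: 0.6
  bounds: null
- name: nabp_Vmax
  scale: log
  location: 350.0
  spread: 0.6
  bounds: null
- name: kC_carb
  scale: log
  location: 0.18
  spread: 0.25
  bounds: null
- name: n_clones
  scale: log
  location: 100.0
  spread: 0.6
  bounds: null
- name: kd_pd1_pdl1
  scale: log
  location: 8.0
  spread: 0.3
  bounds: null
- name: pdl1_expr
  scale: log
  location: 60.0
  spread: 0.8
  bounds: null
- name: k_apc_mat
  scale: log
  location: 1.0
  spread: 0.4
  bounds: null
- name: k_mapc_mig
  scale: log
  location: 1.0
  spread: 0.3
  bounds: null
- name: k_act8
  scale: log
  location: 1.0e-05
  spread: 0.35
  bounds: null
- name: k_act4
  scale: log
  location: 0.001
  spread: 0.35
  bounds: null
- name: f_treg
  scale: linear
  location: 0.25
  spread: 0.06
  bounds:
  - 0.05
  - 0.6
- name: k_tgf_treg
  scale: log
  location: 0.15
  spread: 0.3
  bounds: null
- name: k_mdsc_rec
  scale: log
  location: 100000.0
  spread: 0.4
  bounds: null
- name: k_mdsc_d
  scale: log
  location: 0.1
  spread: 0.3
  bounds: null
- name: k_exh
  scale: log
  location: 0.24
  spread: 0.4
  bounds: null
- name: k_ang
  scale: log
  location: 0.15
  spread: 0.25
  bounds: null
- name: nabp_V1
  scale: log
  location: 16.0
  spread: 0.25
  bounds: null
- name: nabp_V2
  scale: log
  location: 400.0
  spread: 0.25
  bounds: null
- name: nabp_V3
  scale: log
  location: 1000.0
  spread: 0.25
  bounds: null
- name: K50_PD1
  scale: log
  location: 20.0
  spread: 0.4
  bounds: null
- name: K50_TGF
  scale: log
  location: 1.0
  spread: 0.4
  bounds: null
- name: K50_MDSC
  scale: log
  location: 1000000.0
  spread: 0.4
  bounds: null
- name: dia_0
  scale: log
  location: 3.0
  spread: 0.35
  bounds:
  - 1.0
  - 12.0
fixed:
  kC_growth: 0.012
  kC_death: 0.003
  kC_nabp: 0.27
  IC50_nabp: 0.037
  fc_nabp: 0.9
  kC_carb: 0.18
  IC50_carb: 0.6
  fc_carb: 0.9
  kC_T: 0.7
  K_C_T: 0.003
  K_C_Treg: 1.0
  DIA_T_max: 15.0
  DEN_T_cell: 100000000.0
  dia_0: 3.0
  k_ang: 0.15
  k_ang_d: 0.01
  e_ang: 2.0
  K_ang: 3.0
  pd1_density: 30.0
  pdl1_expr: 60.0
  kd_pd1_pdl1: 8.0
  kd_atezo_pdl1: 0.4
  K50_PD1: 20.0
  n_PD1: 1.0
  K50_TGF: 1.0
  K50_MDSC: 1000000.0
  k_ag_rel: 4.0
  k_ag_clr: 1.0
  K_ag: 0.5
  w_icd: 3.0
  k_apc_in: 1000000.0
  k_apc_d: 0.5
  k_apc_mat: 1.0
  K_mapc: 1000000.0
  k_mapc_mig: 1.0
  k_mapc_d: 0.2
  k_nT8_in: 10000000.0
  k_nT4_in: 20000000.0
  k_nT_d: 0.01
  k_nT_cp: 0.1
  k_nT_pc: 0.05
  k_nT_cln: 0.02
  k_nT_lnc: 0.5
  n_clones: 100.0
  k_act8: 1.0e-05
  k_act4: 0.001
  n_prolif8: 128.0
  n_prolif4: 64.0
  f_treg: 0.25
  k_egress: 1.0
  k_aT_d: 0.05
  k_infil: 0.3
  K_rec: 100000000.0
  k_T_d_t: 0.02
  k_th_d_t: 0.02
  k_treg_d_t: 0.014
  k_exh: 0.24
  w_exh_treg: 0.75
  K_exh_treg: 1000000.0
  k_exh_d: 0.01
  h_th: 0.85
  K_th_help: 20000000.0
  k_mdsc_rec: 100000.0
  K_mdsc_C: 100000000.0
  k_mdsc_d: 0.1
  k_tgf_C: 0.1
  k_tgf_treg: 0.15
  k_tgf_clr: 1.0
  atezo_CL: 0.2
  atezo_V1: 3.28
  atezo_V2: 3.63
  atezo_Q: 0.546
  atezo_part: 0.3
  nabp_V1: 16.0
  nabp_V2: 400.0
  nabp_V3: 1000.0
  nabp_Q2: 150.0
  nabp_Q3: 40.0
  nabp_Vmax: 350.0
  nabp_Km: 0.5
  nabp_part: 2.0
  f_carb_map: 0.05
  bsa: 1.8
  carb_window: 21.0
  e_del: 1.0
  n_ang_del: 6.0
  K_prolif: 0.1
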