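cells:
  da:
    cm: 1.0
    e_ca: 140.0
    e_k: -80.0
    e_na: 55.0
    eps_ca: 5.0e-05
    g_a: 1.0
    g_ca_l: 0.3
    g_ca_n: 0.3
    g_ca_t: 0.3
    g_kdr: 45.0
    g_leak_ca: 0.02
    g_leak_k: 1.2
    g_leak_na: 0.24
    g_na: 37.5
    g_sk: 40.0
    i_app: 0.0
    i_pump_ca: 0.1
    i_pump_na: 0.05
    k_ca: 22.5
    k_ca_l: 8.0
    k_pump: 15.0
    k_sk: 15.0
    v_half_ca_l: -39.0
  gpe:
    cm: 1.0
    e_ca: 120.0
    e_k: -80.0
    e_l: -65.0
    e_na: 55.0
    eps: 0.0001
    g_ahp: 30.0
    g_ca: 0.15
    g_k: 30.0
    g_l: 0.1
    g_na: 120.0
    g_t: 0.5
    i_app: 1.2
    k1: 30.0
    k_ca: 15.0
    phi_h: 0.05
    phi_n: 0.05
    phi_r: 1.0
  gpi:
    cm: 1.0
    e_ca: 120.0
    e_k: -80.0
    e_l: -65.0
    e_na: 55.0
    eps: 0.0001
    g_ahp: 30.0
    g_ca: 0.15
    g_k: 30.0
    g_l: 0.1
    g_na: 120.0
    g_t: 0.5
    i_app: 1.2
    k1: 30.0
    k_ca: 15.0
    phi_h: 0.05
    phi_n: 0.05
    phi_r: 1.0
  py:
    cm: 1.0
    e_ca: 120.0
    e_k: -90.0
    e_leak: -70.3
    e_na: 50.0
    g_kd: 6.0
    g_lca: 0.05
    g_leak: 0.0205
    g_m: 0.075
    g_na: 56.0
    i_app: 1.2
    tau_max: 608.0
    v_t: -56.2
  stn:
    cm: 1.0
    e_ca: 140.0
    e_k: -80.0
    e_l: -60.0
    e_na: 55.0
    eps: 5.0e-05
    g_ahp: 9.0
    g_ca: 0.5
    g_k: 45.0
    g_l: 2.25
    g_na: 37.5
    g_t: 0.5
    i_app: 0.0
    k1: 15.0
    k_ca: 22.5
    phi_h: 0.75
    phi_n: 0.75
    phi_r: 0.2
  th:
    cm: 1.0
    e_k: -75.0
    e_l: -70.0
    e_na: 50.0
    e_t: 0.0
    g_k: 5.0
    g_l: 0.05
    g_na: 3.0
    g_t: 5.0
    i_app: 0.25
connection_weights:
  d1_gpi: 10.0
  d2_gpe: 10.0
  da_d1: 1.0
  da_d2: 1.0
  gpe_gpe: 0.25
  gpe_gpi: 0.35
  gpe_stn: 0.9
  gpi_gpi: 0.2
  gpi_th: 0.8
  py_d1_ampa: 1.0
  py_d1_nmda: 0.4
  py_d2_ampa: 1.0
  py_d2_nmda: 0.4
  py_stn: 0.35
  stn_gpe: 0.5
  stn_gpi: 0.6
  th_py: 0.3
msn:
  channels:
  - ca_gated: false
    feeds_ca: false
    frac_inact: 1.0
    g_dend: 30.0
    g_soma: 300.0
    ion: na
    k_act: 9.7
    k_inact: -10.7
    kd_ca: 1.0
    n_act: 3
    name: NaF
    tau_act: 0.1
    tau_inact: 2.0
    vh_act: -28.0
    vh_inact: -55.0
  - ca_gated: false
    feeds_ca: false
    frac_inact: 1.0
    g_dend: 0.015
    g_soma: 0.04
    ion: na
    k_act: 4.6
    k_inact: null
    kd_ca: 1.0
    n_act: 1
    name: NaP
    tau_act: 3.0
    tau_inact: 1.0
    vh_act: -52.6
    vh_inact: null
  - ca_gated: false
    feeds_ca: false
    frac_inact: 1.0
    g_dend: 3.0
    g_soma: 6.0
    ion: k
    k_act: 17.7
    k_inact: -10.0
    kd_ca: 1.0
    n_act: 1
    name: KAf
    tau_act: 1.0
    tau_inact: 25.0
    vh_act: -10.0
    vh_inact: -75.6
  - ca_gated: false
    feeds_ca: false
    frac_inact: 0.8
    g_dend: 0.15
    g_soma: 0.3
    ion: k
    k_act: 16.0
    k_inact: -21.5
    kd_ca: 1.0
    n_act: 1
    name: KAs
    tau_act: 10.0
    tau_inact: 1000.0
    vh_act: -27.0
    vh_inact: -33.5
  - ca_gated: false
    feeds_ca: false
    frac_inact: 1.0
    g_dend: 0.15
    g_soma: 0.15
    ion: k
    k_act: -13.0
    k_inact: null
    kd_ca: 1.0
    n_act: 1
    name: KIR
    tau_act: 1.0
    tau_inact: 1.0
    vh_act: -82.0
    vh_inact: null
  - ca_gated: false
    feeds_ca: false
    frac_inact: 0.7
    g_dend: 0.0
    g_soma: 0.3
    ion: k
    k_act: 12.1
    k_inact: -19.0
    kd_ca: 1.0
    n_act: 1
    name: KRP
    tau_act: 30.0
    tau_inact: 3000.0
    vh_act: -13.4
    vh_inact: -55.0
  - ca_gated: true
    feeds_ca: false
    frac_inact: 1.0
    g_dend: 1.0
    g_soma: 2.0
    ion: k
    k_act: 10.0
    k_inact: null
    kd_ca: 2.0
    n_act: 1
    name: BK
    tau_act: 1.0
    tau_inact: 1.0
    vh_act: -20.0
    vh_inact: null
  - ca_gated: true
    feeds_ca: false
    frac_inact: 1.0
    g_dend: 0.25
    g_soma: 0.5
    ion: k
    k_act: 1.0
    k_inact: null
    kd_ca: 0.35
    n_act: 1
    name: SK
    tau_act: 1.0
    tau_inact: 1.0
    vh_act: 0.0
    vh_inact: null
  - ca_gated: false
    feeds_ca: true
    frac_inact: 1.0
    g_dend: 0.15
    g_soma: 0.3
    ion: ca
    k_act: 6.7
    k_inact: null
    kd_ca: 1.0
    n_act: 2
    name: CaL12
    tau_act: 1.0
    tau_inact: 1.0
    vh_act: -8.9
    vh_inact: null
  - ca_gated: false
    feeds_ca: true
    frac_inact: 1.0
    g_dend: 0.1
    g_soma: 0.2
    ion: ca
    k_act: 6.7
    k_inact: null
    kd_ca: 1.0
    n_act: 2
    name: CaL13
    tau_act: 3.0
    tau_inact: 1.0
    vh_act: -33.0
    vh_inact: null
  - ca_gated: false
    feeds_ca: true
    frac_inact: 0.2
    g_dend: 0.1
    g_soma: 0.3
    ion: ca
    k_act: 7.4
    k_inact: -6.5
    kd_ca: 1.0
    n_act: 2
    name: CaN
    tau_act: 1.0
    tau_inact: 70.0
    vh_act: -8.7
    vh_inact: -74.8
  - ca_gated: false
    feeds_ca: true
    frac_inact: 1.0
    g_dend: 0.1
    g_soma: 0.3
    ion: ca
    k_act: 6.6
    k_inact: null
    kd_ca: 1.0
    n_act: 2
    name: CaQ
    tau_act: 1.5
    tau_inact: 1.0
    vh_act: -9.0
    vh_inact: null
  - ca_gated: false
    feeds_ca: true
    frac_inact: 1.0
    g_dend: 0.1
    g_soma: 0.3
    ion: ca
    k_act: 6.6
    k_inact: -17.0
    kd_ca: 1.0
    n_act: 3
    name: CaR
    tau_act: 1.7
    tau_inact: 30.0
    vh_act: -10.3
    vh_inact: -33.3
  - ca_gated: false
    feeds_ca: true
    frac_inact: 1.0
    g_dend: 0.15
    g_soma: 0.1
    ion: ca
    k_act: 6.2
    k_inact: -6.4
    kd_ca: 1.0
    n_act: 3
    name: CaT
    tau_act: 2.0
    tau_inact: 15.0
    vh_act: -51.7
    vh_inact: -80.0
  membrane:
    alpha_ca: 0.02
    cm: 1.0
    e_ca: 130.0
    e_k: -90.0
    e_leak: -75.0
    e_na: 50.0
    g_leak: 0.0075
    tau_ca: 20.0
msn_site_conductances:
  AMPA: 0.25
  DA_exc: 0.08
  DA_inh: 0.07
  NMDA: 0.02
synapse_classes:
  AMPA:
    e_syn: 0.0
    g_max: 0.15
    tau_off: 2.5
    tau_on: 0.5
  DA_exc:
    e_syn: 0.0
    g_max: 0.1
    tau_off: 95.0
    tau_on: 2.3
  DA_inh:
    e_syn: -80.0
    g_max: 0.1
    tau_off: 95.0
    tau_on: 2.3
  GABA:
    e_syn: -80.0
    g_max: 0.3
    tau_off: 6.4
    tau_on: 0.5
  NMDA:
    e_syn: 0.0
    g_max: 0.03
    tau_off: 95.0
    tau_on: 2.3
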