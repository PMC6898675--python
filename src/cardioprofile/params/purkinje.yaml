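# cardioprofile parameter file
# units: voltage mV, time ms, concentration mM, conductance mS/uF,
#        current density uA/uF; outward current positive
cell_type: Purkinje
channel_map:
  Cav1.2: g_CaL
  KCNQ1/KCNE1: g_Ks
  Kir2.1: g_K1
  Kv4.3: g_to
  Nav1.5-late: g_NaL
  Nav1.5-peak: g_Na
  hERG: g_Kr
initial_state:
  concentrations:
    Ca_i: 0.00025163247572940103
  gates:
    d: 1.4008896178130234e-05
    f: 0.9535495756234544
    h: 0.9379058609411758
    hL: 0.7250445363077392
    j: 0.9379089120999963
    m: 0.0008068747993339416
    mL: 0.00028352649958387745
    r: 0.00013162077937479814
    s: 0.9998611093613081
    xr: 0.00014669515017070697
    xs: 0.2074420164786823
  v: -86.28998371819367
model: family-v1
parameters:
  Ca_o: 1.8
  Ca_rest: 0.0002
  E_CaL: 48.0
  K_i: 145.0
  K_o: 5.4
  Na_i: 10.0
  Na_o: 140.0
  d_half: -17.0
  d_k: 6.2
  f_half: -26.0
  f_k: -6.2
  fnak_half: -70.0
  fnak_k: 25.0
  g_CaL: 0.035
  g_K1: 0.385
  g_Kr: 0.04000000000000001
  g_Ks: 0.02
  g_Na: 16.2
  g_NaL: 0.0756
  g_bCa: 0.0012
  g_bNa: 0.00225
  g_to: 0.08
  hL_floor: 0.046
  hL_half: -76.0
  hL_k: -7.0
  h_half: -70.0
  h_k: -6.0
  k1_half: -75.0
  k1_k: -9.0
  k_Ca: 3.0e-06
  mL_half: -43.0
  mL_k: 5.3
  m_half: -40.0
  m_k: 6.5
  p_NaK: 0.35
  r_half: 12.0
  r_k: 11.0
  rkr_half: 5.0
  rkr_k: -30.0
  s_half: -33.0
  s_k: -6.0
  stim_amplitude: 94.206
  tau_Ca: 70.0
  taud_amp: 4.5
  taud_base: 0.6
  taud_c: -15.0
  taud_w: 15.0
  tauf2_amp: 260.0
  tauf2_c: -85.0
  tauf2_w: 30.0
  tauf_amp: 160.0
  tauf_base: 40.0
  tauf_c: 30.0
  tauf_w: 30.0
  tauhL_amp: 60.0
  tauhL_base: 250.0
  tauhL_c: -80.0
  tauhL_w: 30.0
  tauh_amp: 6.0
  tauh_base: 0.7
  tauh_c: -52.0
  tauh_w: 16.0
  tauj_amp: 35.0
  tauj_base: 2.5
  tauj_c: -70.0
  tauj_w: 20.0
  taumL_amp: 1.5
  taumL_base: 0.6
  taumL_c: -40.0
  taumL_w: 20.0
  taum_amp: 0.12
  taum_base: 0.03
  taum_c: -45.0
  taum_w: 15.0
  taur_amp: 3.0
  taur_base: 1.0
  taur_c: -20.0
  taur_w: 25.0
  taus_amp: 40.0
  taus_base: 8.0
  taus_c: -50.0
  taus_w: 18.0
  tauxr_amp: 350.0
  tauxr_base: 40.0
  tauxr_c: -35.0
  tauxr_w: 25.0
  tauxs2_amp: 700.0
  tauxs2_c: -85.0
  tauxs2_w: 25.0
  tauxs_amp: 400.0
  tauxs_base: 120.0
  tauxs_c: 0.0
  tauxs_w: 40.0
  xr_half: -20.0
  xr_k: 7.5
  xs_half: -8.0
  xs_k: 13.0
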