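# Calibrated default parameters for the KRAS-mutant MAPK cascade model.
# Frozen output of the calibration procedure in scripts/calibrate.py; see
# docs/methods.md for the behavioural constraints and rationale.
# Units: concentrations nM, time h, first-order rates 1/h, bimolecular 1/(nM h).
units:
  concentration: nM
  time: h
  first_order_rates: 1/h
  second_order_rates: 1/(nM h)
totals:
  gs_total: 10.0        # clamped Grb2-SOS input
  ras_total: 120.0
  raf_total: 100.0
  mek_total: 300.0
  erk_total: 300.0
rates:
  # Ras GDP/GTP cycle; activation is Grb2-SOS-catalysed and SPRY-inhibited
  k_ras_act: 0.6
  k_ras_hyd: 12.0
  # RAF activation by Ras-GTP, deactivation, ppERK feedback phosphorylation
  k_raf_act: 0.041
  k_raf_deact: 1.0
  k_raf_fb: 0.10
  k_raf_fb_rec: 4.0
  # MEK phosphorylation by active RAF and ppERK feedback site
  k_mek_cat: 0.15
  k_mek_dephos: 2.0
  k_mek_fb: 0.002
  k_mek_fb_rec: 2.0
  # distributive two-step ERK phosphorylation by active MEK
  k_erk_cat: 0.05
  k_erk_dephos: 1.2
  k_dusp_cat: 0.002
  # DUSP transcriptional feedback (half-life ~3 h)
  v_dusp: 6.0
  k_half_dusp: 130.0
  hill_dusp: 2.0
  k_deg_dusp: 0.231
  # SPRY transcriptional feedback (half-life ~12 h, steep induction)
  v_spry: 5.6
  k_half_spry: 105.0
  hill_spry: 8.0
  k_deg_spry: 0.0578
  k_spry_inh: 1.8
inhibitors:
  # Effective cellular binding constants; chosen so that the simulated
  # combination matrices resolve both the drug-sensitive (RAF-decoupled)
  # and feedback-buffered (RAS-coupled) regimes on a 9-step dose ladder
  # topping out at 1000 nM. The ERK inhibitor is the weaker binder, in
  # line with the compounds' relative cellular potencies.
  - name: MEKi
    target: MEK
    kon: 3.6        # 1/(nM h) ~ 1e6 /M/s
    koff: 0.252     # Kd = 0.07 nM
  - name: ERKi
    target: ERK
    kon: 3.6
    koff: 108.0     # Kd = 30 nM
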