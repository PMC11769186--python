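# Layered finger model, dark skin (melanosome fraction 30.5%).
# Layer inventory, thicknesses and optical constants are literature-derived
# defaults for a perfused human finger; mu_s in mm^-1, thickness in mm,
# wavelength keys in nm.  The three shipped presets differ only in the
# epidermal melanosome fraction vmel.
ambient_n: 1.0
layers:
  - name: epidermis
    thickness_mm: 0.15
    mu_s_mm: {660: 10.0, 940: 7.0}
    g: {660: 0.70, 940: 0.70}
    n: 1.4
    composition: {kind: epidermis, vmel: 0.305, vw: 0.20}
  - name: dermis_1
    thickness_mm: 0.30
    mu_s_mm: {660: 8.0, 940: 5.0}
    g: {660: 0.70, 940: 0.70}
    n: 1.4
    composition: {kind: blood, va: 0.002, vv: 0.002, vw: 0.65}
  - name: dermis_2
    thickness_mm: 0.30
    mu_s_mm: {660: 8.0, 940: 5.0}
    g: {660: 0.70, 940: 0.70}
    n: 1.4
    composition: {kind: blood, va: 0.005, vv: 0.005, vw: 0.65}
  - name: dermis_3
    thickness_mm: 0.30
    mu_s_mm: {660: 8.0, 940: 5.0}
    g: {660: 0.70, 940: 0.70}
    n: 1.4
    composition: {kind: blood, va: 0.010, vv: 0.010, vw: 0.65}
  - name: dermis_4
    thickness_mm: 0.30
    mu_s_mm: {660: 8.0, 940: 5.0}
    g: {660: 0.70, 940: 0.70}
    n: 1.4
    composition: {kind: blood, va: 0.020, vv: 0.020, vw: 0.65}
  - name: fat
    thickness_mm: 2.0
    mu_s_mm: {660: 6.0, 940: 5.0}
    g: {660: 0.80, 940: 0.80}
    n: 1.4
    composition: {kind: fixed, mu_a_mm: {660: 0.010, 940: 0.012}}
  - name: muscle
    thickness_mm: 7.0
    mu_s_mm: {660: 4.0, 940: 3.0}
    g: {660: 0.80, 940: 0.80}
    n: 1.4
    composition: {kind: fixed, mu_a_mm: {660: 0.120, 940: 0.050}}
bone:
  center_depth_mm: 7.0
  center_x_mm: 0.0
  radius_mm: 2.0
  mu_a_mm: {660: 0.050, 940: 0.030}
  mu_s_mm: {660: 15.0, 940: 12.0}
  g: {660: 0.90, 940: 0.90}
  n: 1.55
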