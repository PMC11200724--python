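# Passive (orthotropic hyperelastic) and active (time-varying elastance)
# myocardial parameter sets.  Stresses in MPa, lengths in mm, times in s,
# concentrations in mM.
ventricle:
  passive:
    a: 3.9e-4
    b: 3.7
    a_f: 1.9e-3
    b_f: 14.0
    a_s: 1.1e-3
    b_s: 11.0
    a_fs: 3.6e-7
    b_fs: 7.8e-4
    tissue_label: ventricle
  active:
    Tmax: 0.2
    Ca0: 4.35
    Ca0max: 4.35
    B: 4750.0
    l0: 0.00158
    lr: 0.00185
    t0: 0.35
    m: 950.0
    b_relax: -1.5
    tissue_label: ventricle
atrium:
  passive:
    a: 1.0e-3
    b: 3.1
    a_f: 4.7e-3
    b_f: 12.0
    a_s: 2.7e-3
    b_s: 9.1
    a_fs: 9.0e-7
    b_fs: 6.7e-4
    tissue_label: atrium
  active:
    Tmax: 0.1
    Ca0: 4.35
    Ca0max: 4.35
    B: 4750.0
    l0: 0.00158
    lr: 0.00185
    t0: 0.05
    m: 1048.9
    b_relax: -1.5
    tissue_label: atrium
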