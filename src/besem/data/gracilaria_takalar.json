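{
  "rgr_max": 0.0778,
  "w_f_max": 0.951113,
  "cf_min": 0.0831,
  "cf_max": 0.202,
  "cfk": 0.180,
  "cft50": 29.5,
  "m_f": 0.872217,
  "m_sd": 0.293,
  "w_f0": 0.0724,
  "hcl": 45,
  "doy0": 1,
  "fgp_c": 30769,
  "pc_m": 0.658,
  "pc_h": 386.7,
  "l_n": 600,
  "l_l": 25,
  "l_w": 0.75,
  "l_pd": 5
}
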