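{
  "D": 5e-09,
  "b": 15.0,
  "c": 379.0,
  "A": 4.0,
  "sigma0": 700000.0,
  "alpha": 10.0,
  "beta": 1000.0,
  "lambda_opt": 1.05,
  "k": 0.3,
  "kc": 4.0,
  "ke": 5.0,
  "d": 1.45,
  "lambda_dot_m_min": -17.0,
  "S": 50.0,
  "n1": 0.0,
  "n2": 1.0,
  "t0": 0.0,
  "t1": 1000000.0
}
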