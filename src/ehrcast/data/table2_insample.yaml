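base_year: 2006
horizon_year: 2035
generations:
- stage: 0
  m: 1606.0
  p: 0.964
  q: 1.0
  tau: 0.0
- stage: 1
  m: 888.0
  p: 0.234
  q: 1.0e-09
  tau: 0.0
- stage: 2
  m: 2953.0
  p: 0.68
  q: 1.0e-09
  tau: 0.0
- stage: 3
  m: 100.0
  p: 0.255
  q: 0.12
  tau: 1.0
- stage: 4
  m: 20.0
  p: 0.015
  q: 0.505
  tau: 1.0
- stage: 5
  m: 10.0
  p: 0.043
  q: 0.354
  tau: 2.0
- stage: 6
  m: 5.0
  p: 0.064
  q: 1.0e-09
  tau: 3.0
- stage: 7
  m: 0.0
  p: 0.026
  q: 0.001
  tau: 4.0
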