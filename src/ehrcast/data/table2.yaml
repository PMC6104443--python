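base_year: 2006
horizon_year: 2035
generations:
- stage: 0
  m: 1606.0
  p: 0.964
  q: 1.0
  tau: 1.4343260791899866
- stage: 1
  m: 888.0
  p: 0.234
  q: 1.0e-09
  tau: -2.9621674347629323
- stage: 2
  m: 2953.0
  p: 0.68
  q: 1.0e-09
  tau: 0.3633240779097801
- stage: 3
  m: 100.0
  p: 0.255
  q: 0.12
  tau: 0.8730400148360322
- stage: 4
  m: 20.0
  p: 0.015
  q: 0.505
  tau: 0.5326169109253563
- stage: 5
  m: 10.0
  p: 0.043
  q: 0.354
  tau: 9.006910347077618
- stage: 6
  m: 5.0
  p: 0.064
  q: 1.0e-09
  tau: 10.872732499717943
- stage: 7
  m: 0.0
  p: 0.026
  q: 0.001
  tau: 1.5874193462383834
mid_anchors:
  0: 2008
  1: 2006
  2: 2008
  3: 2010
  4: 2014
  5: 2021
  6: 2025
  7: 2027
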