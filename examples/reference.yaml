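# Reference parameter set: K=10, a=b=1, theta=2, p=0.4, p1=0, p2=0.8
model:
  K: 10
  theta: 2
  a: 1
  b: 1
  p: 0.4
  p1: 0.0
  p2: 0.8
policy:
  gamma: 0.6
simulation:
  n_seasons: 1000
  n_reps: 10000
  seed: 1
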