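# Parameter sampling ranges for the simulation benchmark.
#
# Ranges are chosen so that adjacent model families remain distinguishable
# by a KS test at n=500: mixture components are separated by >= 3 sigma,
# zero-inflation masses are well above the base models' own zero mass, NB
# sizes are small enough to be clearly overdispersed, and censoring points
# sit where a visible point mass forms.  All intervals are sampled
# uniformly.
P:
  lambda: [2.0, 20.0]
NB:
  size: [1.5, 4.0]
  mean: [8.0, 20.0]
G:
  mu: [2.0, 8.0]
  sigma: [0.5, 2.0]
ZIP:
  pi0: [0.2, 0.5]
  lambda: [6.0, 15.0]
ZINB:
  pi0: [0.2, 0.5]
  size: [1.5, 4.0]
  mean: [8.0, 20.0]
ZIG:
  pi0: [0.2, 0.5]
  mu: [4.0, 8.0]
  sigma: [0.5, 1.2]
LTG:
  mu: [3.0, 6.0]
  sigma: [1.0, 1.5]
  zcut_offset: [-1.0, 0.0]   # zcut = mu + offset * sigma
BP:
  alpha: [0.3, 0.7]
  beta: [0.3, 0.7]   # both shapes < 1: U-shaped burst-fraction density
  scale: [30.0, 80.0]
MG:
  n_components: [2, 3]
  mu1: [0.0, 2.0]
  gap: [3.0, 5.0]            # distance between consecutive component means
  sigma: [0.4, 0.8]
  weight_floor: 0.25
ZIMG:
  pi0: [0.2, 0.5]
  n_components: [2, 2]
  mu1: [3.0, 5.0]
  gap: [3.0, 5.0]
  sigma: [0.4, 0.8]
  weight_floor: 0.25
LTMG:
  n_components: [2, 2]
  mu1: [2.0, 4.0]
  gap: [3.0, 5.0]
  sigma: [0.5, 0.8]
  zcut_offset: [-0.5, 0.5]   # zcut = mu1 + offset * sigma1
  weight_floor: 0.25
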