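# freeznet

Analysis pipeline for zebrafish alarm-substance fear studies: automated
classification of **freezing** and **erratic movement** from per-frame 3D
tracking coordinates, protocol-binned fear quantification, qPCR relative
c-fos expression, and **brain co-activation network** analysis with QAP
permutation comparison.

It is written for behavioral neuroscientists running social-buffering-style
experiments: a focal fish is recorded for a 5-min baseline, alarm substance
(or control water) is administered, and behavior is tracked for a 30-min
test.  The tracker (EthoVision or similar) exports `frame,x,y,z` tables;
this package does everything downstream of the tracker.

## What it computes

**Behavior.**  From positions `p_i` sampled at frame rate `f`, speed is
`v_i = f·‖p_i − p_{i−1}‖` (cm/s) and the turn angle `θ_i` is the unsigned
angle between consecutive horizontal-plane displacement vectors.  Freezing
is a merged run of `v < v_freeze` (default 0.5 cm/s) sustained at least
`d_min` (default 2 s); erratic movement requires `v ≥ v_err` (default
10 cm/s) together with a windowed mean turn angle ≥ 45°.  Percent time per
behavior is reported over the protocol intervals — baseline, first 5 min
after onset, and three 10-min test bins — with tracking dropouts excluded
from numerator and denominator alike.

**Validation.**  Automated per-fish freezing percentages are correlated
(Pearson r, two-sided p from the t transform) against a human observer's
event log; frame-level Cohen's κ is available as a stricter metric.

**Expression.**  Relative c-fos quantity per fish × brain nucleus
(Dm, Vv, Vs, POA) is `E^−ΔCt` with `ΔCt = Ct(c-fos) − Ct(18s)`; group
comparisons use per-nucleus one-way ANOVA plus pairwise t tests over a
declared family, Holm ("sequential Bonferroni") corrected.

**Networks.**  Per-treatment co-activation is the nucleus × nucleus Pearson
matrix of log2 relative quantities across fish, with per-edge significance.
Networks are compared with the quadratic assignment procedure: node labels
of one matrix are permuted jointly over rows and columns (all 24
permutations are enumerated for 4 nuclei) and two matrices are declared
*different* when the QAP p-value exceeds α = 0.05.  Structure is summarized
by valued-graph density (mean |r|) and eigenvector centrality of the |r|
weight matrix.

**Synthetic data.**  Because studies of this kind rarely deposit raw
trajectories or Ct tables, a first-class `synth` module generates all
three inputs with controllable structure: a 3-state continuous-time Markov
chain (swim/erratic/freeze) with onset-switched rates for trajectories,
degraded ground truth for observer logs, and multivariate-normal log
expression with a target inter-nucleus correlation matrix for qPCR tables.

## Worked example

```python
from freeznet import synth
from freeznet.behavior import (ClassifierParams, bin_behavior,
                               compute_kinematics, detect_erratic, detect_freezing)
from freeznet.trajectory_io import interpolate_gaps, smooth_positions

cfg = synth.alone_config(seed=1)            # alarm substance, no shoal cues
traj, truth = synth.simulate_trajectory(cfg)
traj = smooth_positions(interpolate_gaps(traj, 5), 5)
kin = compute_kinematics(traj)
params = ClassifierParams()
bouts = detect_freezing(kin, params) + detect_erratic(kin, params)
binned = bin_behavior(bouts, traj)
for name in ("baseline", "post5", "bin1", "bin2", "bin3"):
    print(f"{name:9s} freezing {binned.pct[('freezing', name)]:5.1f}%"
          f"   erratic {binned.pct[('erratic', name)]:4.1f}%")
```

```
baseline  freezing   0.0%   erratic  0.0%
post5     freezing  47.1%   erratic  0.2%
bin1      freezing  54.5%   erratic  0.1%
bin2      freezing  54.2%   erratic  0.0%
bin3      freezing  51.4%   erratic  0.0%
```

The fish barely freezes during baseline, then spends roughly half of every
test bin frozen after alarm-substance onset — the expected fear response of
an unbuffered fish.  The network side, comparing a fully-coupled treatment
against one with Vv decoupled from Dm–Vs–POA:

```python
from freeznet.expression import relative_expression
from freeznet.network import (coactivation_matrix, eigenvector_centrality,
                              network_density, qap_correlation)

nets = {}
for name, corr, seed in (("Alone_AS", synth.coupled_structure(), 2),
                         ("SB_AS", synth.decoupled_structure(), 3)):
    ct = synth.simulate_expression(synth.expression_config(name, corr, n_fish=10, seed=seed))
    nets[name] = coactivation_matrix(relative_expression(ct)[name], name, log2=True)

print(eigenvector_centrality(nets["SB_AS"]).round(3).to_dict())
res = qap_correlation(nets["Alone_AS"], nets["SB_AS"])
print(f"QAP: r_obs={res.r_obs:.3f} p={res.p:.3f} -> {res.verdict}")
```

```
{'Dm': 0.558, 'Vv': 0.337, 'Vs': 0.523, 'POA': 0.55}
QAP: r_obs=-0.587 p=0.958 -> different
```

Vv has the lowest centrality in the decoupled network, and QAP finds no
pattern similarity between the two treatments' matrices.

## Command line

```sh
freeznet simulate --out study/ --n-per-group 20 --seed 1
freeznet classify --traj study/trajectories --out results/
freeznet validate --auto auto.csv --human human.csv
freeznet expression --ct study/ct.csv --out results/
freeznet network --expr results/expression_rq.csv --out results/
freeznet run --config run.json       # full pipeline + manifest
```

`run` writes a manifest (config hash, seed, per-output digests); the same
config and seed reproduce every table byte-for-byte.

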