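# ifpkit

Geometric protein–ligand interaction fingerprinting and assay analysis for
structure-based drug-discovery work on methyl-reader proteins such as
Spindlin1, whose second Tudor domain encloses a cationic ligand moiety in an
aromatic cage (Phe141, Trp151, Tyr170, Tyr177) next to an Asp184 salt-bridge
anchor. The package is aimed at modellers who have MD trajectory frames of a
protein–ligand complex (as multi-model PDB), per-compound scoring tables,
and fluorescence-polarization plate data, and want the downstream analysis —
interaction occupancies, RMSD traces, score discrimination, IC50 fits — in
one tested toolkit.

## What it computes

**Per-frame interaction detection.** For every trajectory frame, boolean
detectors evaluate:

- hydrogen bond: donor–acceptor distance ≤ 3.0 Å and donor–H–acceptor angle
  ≥ 135°;
- intramolecular hydrogen bond: same angle rule, distance extended to 3.5 Å;
- salt bridge: min over declared carboxylate-O / cationic-N pairs ≤ 4.0 Å;
- cation–π: distance between the cation and the aromatic ring centroid
  ≤ 6.0 Å, and angle between the ring-plane normal and the cation–centroid
  vector ≤ 45°;
- π–π (face-to-face): ring-centroid distance ≤ 5.5 Å and interplanar angle
  ≤ 30°.

All comparisons are inclusive and every cutoff is configurable. Occupancy of
a channel is the percent of frames in which its criteria hold:
occupancy = 100 · n_events / n_frames. Occupancy reports aggregate into
compounds × channels heat-map matrices, and per-frame RMSD traces are
computed by Kabsch superposition on a fit selection followed by RMSD on a
report selection.

**Assay math.** Polarization mP = 1000·(I_S − G·I_P)/(I_S + G·I_P), percent
inhibition I = 100·(1 − (P_I − P_neg)/(P_pos − P_neg)), and four-parameter
logistic (variable-slope) dose–response fitting

    y(x) = bottom + (top − bottom) / (1 + 10^(h·(log10 IC50 − log10 x)))

via bounded least squares with asymptotic standard errors.

**Score discrimination.** Box-plot summaries (type-7 quartiles), the
between-group mean gap, and an exhaustive single-threshold separation scan
for active vs inactive compounds, per score kind, with a ranked comparison
across kinds.

**Synthetic data.** A toy aromatic-cage complex plus generators that plant
per-channel Bernoulli occupancies in multi-model PDB trajectories,
two-Gaussian score tables, and noisy 4PL dose–response plates — so the whole
pipeline is testable end-to-end without any proprietary trajectory.

## Worked example

```python
from ifpkit.synth import make_toy_complex, ChannelPlan, simulate_trajectory
from ifpkit.occupancy import build_event_matrix, occupancy

template = make_toy_complex()
plan = ChannelPlan({"amidine-Asp184": 0.94, "pyrrolidinium-Phe141": 0.541})
traj = simulate_trajectory(template, plan, n_frames=10000, seed=1)
channels, spec = template.config.build(traj)
report = occupancy(build_event_matrix(traj, channels, spec))
print({k: round(v, 1) for k, v in report.occupancy_percent.items()
       if k in plan.probabilities})
```

prints

```
{'amidine-Asp184': 94.1, 'pyrrolidinium-Phe141': 53.9}
```

i.e. a salt bridge planted in 94% of 10,000 frames and a cation–π contact
planted in 54.1% are recovered by the detectors to within binomial sampling
error. The same analysis is available from the shell:

```sh
ifpkit simulate --plan plan.yaml --seed 1 --out sim/
ifpkit analyze --traj sim/trajectory.pdb --config sim/config.yaml --out out/
ifpkit assay --csv plate.csv --out out/
ifpkit discriminate --scores scores.csv --out out/
```

Dose–response fitting:

```python
from ifpkit.synth import simulate_dose_response
from ifpkit.assay import fit_4pl

df = simulate_dose_response(ic50=182.6e-9, noise_sd=2.0, seed=2)
fit = fit_4pl(df["concentration"], df["response"])
print(f"IC50 = {fit.ic50 * 1e9:.1f} nM, Hill = {fit.hill:.2f}")
```

prints `IC50 = 185.8 nM, Hill = 0.98` — a triplicate 12-point curve planted
at 182.6 nM recovered within a few percent at 2-point noise.

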