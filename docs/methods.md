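# Methods

## Interaction criteria

Detectors operate on single frames of explicit-hydrogen coordinates in Å.

| channel kind      | rule (all comparisons inclusive)                                    | defaults      |
|-------------------|---------------------------------------------------------------------|---------------|
| hbond             | d(D,A) ≤ cutoff and angle(D–H–A) ≥ angle cutoff                     | 3.0 Å, 135°   |
| intramol_hbond    | same, extended distance cutoff                                      | 3.5 Å, 135°   |
| salt_bridge       | min over all anion-O / cation-N pairs of d(O,N) ≤ cutoff            | 4.0 Å         |
| cation_pi         | d(cation, ring centroid) ≤ cutoff and angle(normal, cation−centroid) ≤ cutoff | 6.0 Å, 45° |
| pi_pi             | d(centroid, centroid) ≤ cutoff and interplanar angle ≤ cutoff       | 5.5 Å, 30°    |

Design choices made where conventions diverge:

- **H-bond angle** is donor–hydrogen–acceptor (the CPPTRAJ convention), read
  as a minimum: 180° is ideal. Hydrogens must be explicit; a config flag
  `allow_no_hydrogen` downgrades the check to distance-only with a logged
  warning. A donor–hydrogen distance above 1.5 Å triggers a warning (the
  hydrogen is probably not covalently bound to the declared donor).
- **Inclusive cutoffs** everywhere (≤/≥). Boundary behaviour is tested with
  exactly representable geometries.
- **Fused bicyclic aromatics** (tryptophan): both rings may be declared for
  one channel; the channel is satisfied if either ring satisfies the
  criteria (OR-reduction). This treats an indole as one interaction partner
  without deciding which ring "counts".
- **Salt bridge** takes the minimum over the full declared charged-atom sets
  (both carboxylate oxygens × both amidinium nitrogens), since the chemistry
  names atom types, not individual atoms.
- **π–π** has no universal criterion; the face-to-face rule here
  (≤ 5.5 Å, ≤ 30°) is a common literature convention. Both thresholds are
  configurable and the full cutoff set is embedded in every report, so π–π
  occupancies are explicitly convention-dependent. T-shaped stacking is not
  detected.

## Geometry kernels

Ring planes are fitted by principal-axis analysis: the normal is the
eigenvector of the smallest eigenvalue of the covariance of centered ring
coordinates. This degrades gracefully for puckered rings (a cross product of
two edges does not), and the out-of-plane RMS is reported; above 0.3 Å a
warning is emitted for a declared aromatic ring. The normal's sign is
canonicalized (largest-magnitude component positive, ties x before y before
z) but all detector angles are folded into [0, 90°], so the sign convention
can never change a detection. Collinear ring atoms raise a geometry error
(relative eigenvalue threshold 1e−12).

Superposition is the standard Kabsch SVD solution restricted to proper
rotations (det = +1); RMSD traces superpose each frame onto a reference
frame using a fit selection (default: backbone N, CA, C, O) and report the
RMSD of a report selection (default: the ligand) after applying that
transform. Symmetry-equivalent atom matching is not performed.

## Occupancy statistics

Occupancy is exactly 100 · events / frames, kept as a rational number
internally and rendered to one decimal place. Frames are counted as-is: no
autocorrelation correction or block averaging, matching the plain
percent-of-frames definition. In heat-map matrices a channel absent from a
compound's report is an empty cell (NaN), deliberately distinct from an
observed 0%.

## Synthetic trajectories

The toy complex spaces its interaction clusters ≥ 15 Å apart, one cluster
per channel, each with dedicated mobile ligand atoms, so channels are
geometrically independent and planted probabilities are exact by
construction. Per frame and channel a Bernoulli(p) state is drawn from a
dedicated random stream (derived from the master seed and a hash of the
channel label, hence stable under channel reordering); ON frames place the
mobile atoms uniformly inside the satisfying region shrunk by a safety
margin (0.3 Å / 5°), OFF frames push the controlling distance beyond the
cutoff plus margin. Truncated positional jitter (|δ| ≤ 0.1 Å, drawn rigidly
per mobile group) and a global per-frame rigid rotation+translation are
applied afterwards; the sampling bands leave room for the jitter, so a
planted state can never flip, and rigid motion cannot affect any detector.

What this emulates and what it does not: the generator reproduces the
*statistics* a contact analysis consumes (independent per-channel event
streams at controlled rates) but none of the physics — no force field, no
solvent, no frame-to-frame autocorrelation, no correlated loss of multiple
contacts when a ligand dissociates. Passing recovery tests therefore
demonstrates that detection, counting and reporting are correct, not that
any MD observation is reproduced. Trajectory frame counts are configuration
parameters, not constants, because saving strides differ between studies.

## Dose–response fitting

The 4PL model y = bottom + (top − bottom)/(1 + 10^(hill·(log10 IC50 −
log10 x))) is fitted by bounded least squares (scipy `curve_fit`, TRF).
Initialization: bottom/top from the response extrema, log10 IC50 from the
concentration nearest the half-response, hill = 1. log10 IC50 is bounded to
within 3 decades of the tested concentration range and |hill| ≤ 10.
Replicates are fitted as individual points by default (averaging is a flag).
A response span below 1e−6 raises a degenerate-data error rather than
returning an arbitrary sigmoid; optimizer failure is flagged in the result
(`converged=False`), never silent. Standard errors are asymptotic, with the
IC50 error delta-method-transformed from the log scale. Fits are performed
on percent inhibition by default; any response scale works since the model
is scale-free. IC50 is reported in the unit of the input concentrations.

The synthetic plate generator uses a 12-point half-log dilution centered on
the planted IC50, in triplicate, with Gaussian noise of 2 percentage points
— a typical FP competition-assay layout.

## Score discrimination

Group summaries use type-7 (linear-interpolation) quartiles — box-plot
conventions vary between tools, so the choice is fixed and recorded in every
report. The separation scan enumerates midpoints of adjacent sorted scores
plus one candidate below the minimum and one above the maximum, classifying
a compound as active iff its score ≤ threshold (more negative = more
favourable energy); ties in the misclassification count resolve to the more
negative threshold. Activity labels are inputs, never inferred from scores.
Ranking across score kinds orders by (misclassifications ascending, mean gap
descending), keeps input order on exact ties and flags them. The synthetic
score generator draws two Gaussians; its defaults (17 actives at
−76.3 kcal/mol, 3 inactives at −60.35 kcal/mol, SD 4) emulate an
MM-GBSA-style rescoring set whose gap dwarfs that of raw docking scores.

## Problem sizes and determinism

Validation uses 10,000-frame trajectories for occupancy recovery (binomial
3·SE at p ≈ 0.5 is then ±1.5 points), 1,000 random geometries per detector
for oracle equivalence, 100 seeded replicates for the noisy IC50 Monte
Carlo, and 100 replicate tables for the score-gap estimate — sizes at which
the sampling bounds asserted by the tests are tight enough to be
informative. Every generator is reproducible bit-for-bit from a single
master seed; the CLI draws and logs a seed when none is given. Reports are
byte-stable across reruns except for the manifest timestamp.

## Known limitations

- No symmetry-corrected RMSD, periodic-boundary imaging, or binary
  trajectory formats (DCD/XTC/NetCDF); frames must be imaged, hydrogenated
  multi-model PDB.
- No water-mediated bridges, halogen bonds, hydrophobic-contact scoring, or
  interaction energies.
- Occupancies carry no error bars (no block averaging); the scan-based
  separation statistic is a single-threshold rule, not a ROC analysis.
- The synthetic generator cannot produce correlated channels.
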