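# Methods

This document records the model, the parameter defaults with their
rationale, the numerical choices, and the known limitations of the
`lariatperm` package. All design decisions noted here are the package's
own choices; problem sizes and defaults were selected for desk-scale
reproducibility on one CPU.

## 1. Model overview

The prediction chain is:

```
water ensemble  ─┐                         ┌─ D_water  (Stokes–Einstein)
                 ├─ RMSD series ─ k-means ─┤
octanol ensemble ┘        │                └─ D_octanol
                          ▼
            cluster populations p_i  ──►  W_i = -k_B T ln p_i
                          ▼
        composite-coordinate PMF W(z), z ∈ [0, 40] Å
                          ▼
        R = ∫ exp(W(z)/k_B T) / D(z) dz,  P = 1/R,  logP_calc = log10 P
```

The composite coordinate `z` is an interpretation, not a membrane normal:
its endpoints stand for the peptide's conformational state in each solvent.
The aqueous segment occupies `[0, span/2]` and the octanol segment
`[span/2, span]`, with each solvent's sorted cluster centers mapped
proportionally onto the inner 90% of its segment.

## 2. Ensemble model and topology

- A `PeptideTopology` describes a lariat peptide: a short linear tail plus a
  macrocycle closed by a depsipeptide ester between a threonine-like
  sidechain oxygen (OG) and the C-terminal carbonyl carbon. Validation
  enforces disjoint, covering tail/macrocycle residue sets, a connected bond
  graph, and that every N-methylated residue actually carries a methyl
  carbon (and therefore no amide H).
- `ConformationalEnsemble` holds `(F, n_atoms, 3)` coordinates in Å, a
  solvent specification (name, temperature, viscosity) and normalized frame
  weights.
- I/O uses MDAnalysis: multi-model PDB read/write and optional DCD
  trajectories, with a YAML topology sidecar carrying what PDB cannot
  (methylation, chirality, the ester linkage, vdW radii).

## 3. Parameters, defaults and rationale

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| temperature | 310 | K | physiological; matches the viscosity table |
| viscosity (water, 310 K) | 6.913e-4 | Pa·s | standard literature value |
| viscosity (octanol, 310 K) | 4.99e-3 | Pa·s | standard literature value |
| RMSD selector | backbone_heavy | — | N/CA/C/O + ester O; sidechain-independent coordinate |
| RMSD reference | water first frame | — | see §5 |
| k (clusters) | 5 | — | enough to resolve a handful of conformer basins |
| k-means restarts | 20 | — | 1-D k-means++ is cheap; best-of-20 is deterministic given the seed |
| population floor | 1/(10F) | — | keeps `-ln p` finite for empty clusters; below any resolvable population |
| span | 40 | Å | order of a bilayer thickness; sets the length scale of R |
| grid points | 1001 | — | see §5 |
| interface bridge | 10% of span | — | see §5 |
| probe radius | 1.4 | Å | water-sized probe (SASA convention) |
| SASA sphere points | 960 | — | <1% error on an isolated sphere |
| H-bond distance cutoff | 3.5 | Å | N···O heavy-atom convention |
| H-bond angle cutoff | 30 | deg | deviation of N–H···O from linearity |
| cis cutoff | 90 | deg | frame is cis iff |ω| < 90° |
| σ₀ (boost spread target) | 6.0 | kcal/mol | keeps boost statistics near-Gaussian for reweighting |

Physical constants: `k_B = 0.0019872041 kcal/(mol·K)` for free energies,
`k_B = 1.380649e-23 J/K` for Stokes–Einstein.

## 4. Stage-by-stage detail

**RMSD.** Kabsch superposition (own SVD implementation, proper-rotation
branch) of each frame's selected atoms onto the common reference; RMSD in Å.

**Clustering.** scikit-learn `KMeans` (k-means++, `n_init` restarts, fixed
`random_state`) on the 1-D RMSD series; clusters are relabeled in ascending
center order so downstream knot placement is deterministic. Frame weights,
when present, enter the populations but not the k-means objective.

**PMF.** Knots `(z_i, W_i)` from both solvents are merged, sorted and
linearly interpolated (`np.interp`) onto a uniform grid; the global minimum
is shifted to zero. Cluster centers are mapped affinely by
`u = (c - c_min)/(c_max - c_min)`; a single-cluster segment places its knot
mid-segment.

**R_o.** The pooled (water + octanol) all-atom coordinates are iteratively
superposed (two passes) to their mean; `R_o` is the radius of the exact
smallest enclosing sphere of that mean structure (recursive Welzl with a
seeded shuffle, radius polished to the true maximum distance).

**Resistivity.** Composite trapezoid per solvent segment, sharing the
midpoint so the two halves tile `[0, span]` exactly — a flat PMF therefore
recovers the series resistance `L_w/D_w + L_o/D_o` to machine precision.
When `βW ≥ 500` the integral is evaluated in log space (log-sum-exp over
trapezoid weights) and the result is flagged `overflow_flag = True`.

**Descriptors.** ω = CA(i)–C(i)–N(i+1)–CA(i+1) per chain linkage; the
macrocycle-closing ester has no amide N and is reported as excluded rather
than silently skipped. H-bond detection rebuilds ideal amide hydrogens
(1.01 Å along the outward bisector) when absent; N-methylated residues
contribute no donor. SASA is Shrake–Rupley with deterministic golden-spiral
test points. PCA runs either on heavy-atom Cartesians after two-pass
iterative superposition or on sin/cos-embedded backbone dihedrals
(rotation-invariant); component signs follow a largest-loading-positive
convention so results are bit-reproducible. The solvent overlap score is
the Bhattacharyya coefficient of the two solvents' (PC1, PC2) histograms on
a shared 25×25 grid, with the PCA basis fitted on the pooled frames.

**Toy GaMD.** Potentials are analytic (harmonic, quartic double well,
composites). The boost is `ΔV = ½k(E−V)²` below `E`, zero above — C¹ at the
threshold by construction. Parameters follow the lower-bound scheme:
`E = V_max`, `k0 = min(1, (σ₀/σ_V)·(V_max−V_min)/(V_max−V_avg))`,
`k = k0/(V_max−V_min)`, estimated from ≥100 unboosted samples. Sampling is
BAOAB Langevin (unit mass, kcal/mol energies); reweighting is per-bin
cumulant expansion `exp(βC₁ + β²C₂/2)` to order 1 or 2, with
under-populated bins flagged invalid (NaN), never interpolated.

## 5. Numerical design decisions

- **Interface bridge (10% of span).** If both solvents could place a knot
  exactly at the midpoint with different free energies, the interpolated
  integrand would be discontinuous and the trapezoid rule would not
  converge under grid refinement. Keeping the middle 10% of the span
  knot-free makes `W(z)` continuous (linear bridge), restoring clean
  convergence: the 1001-point default agrees with a 10⁴-point quadrature to
  about 1e-5 relative on benchmark fixtures.
- **Grid default 1001 points.** With the bridge in place, 101 points leave
  a ~1e-2 relative quadrature error on peaked PMFs; 1001 points bring it
  below 1e-3 at negligible cost (the integrand is 1-D).
- **RMSD reference = water first frame.** RMSD to an ensemble *average* is
  degenerate for multimodal ensembles: two distinct conformers can sit at
  equal distance from their mean, collapsing the clustering coordinate. The
  first water frame acts like a minimized starting structure and separates
  the basins; `pooled_mean` and explicit references remain available.
- **Population floor `1/(10F)`.** An empty cluster would give `W = ∞`; the
  floor corresponds to "less than a tenth of one frame", i.e. below
  anything the sample can resolve, and the number of floored clusters is
  reported on the PMF profile.
- **PDB-precision snapping.** Generated fixture coordinates are rounded to
  1e-3 Å at generation time so that in-memory ensembles and their PDB round
  trips are bit-identical, making end-to-end file-mediated runs exactly
  reproducible.
- **Exact Welzl sphere.** A bounding-box or ritter-style approximation can
  be several percent off, which propagates linearly into D and R; Welzl is
  exact and the final radius is re-measured against all points.

## 6. Synthetic fixtures: what they emulate, what they do not

The generator builds lariat peptides from ideal internal coordinates (NeRF
chain construction, bond table 1.33/1.46/1.52/... Å) in named template
conformers — "extended" (φ, ψ = −120°, 140°) and "compact" (−60°, −45°) —
and draws each frame from a solvent-specific weighted template mixture with
isotropic Gaussian jitter (default σ = 0.08 Å). Planted features give every
analysis stage a known ground truth: per-linkage cis probabilities (ω set
to 0° in drawn frames), H-bond occupancies (acceptor O moved onto the N–H
axis at 2.9 Å in drawn frames), N-methylation and D-residue patterns.
Water and octanol use independent RNG streams derived from the spec seed.

These ensembles are *statistically* realistic (known mixture weights,
reproducible, geometrically sane bonds) but *physically* fake: no force
field, no excluded volume, no solvent molecules, no Boltzmann-consistent
energetics, and jitter that ignores covalent constraints. They validate the
pipeline's statistics and numerics, not its chemistry.

Each benchmark pair carries a ground-truth record computed by an
independent oracle that shares no superposition, clustering or quadrature
code with the pipeline (scipy `Rotation.align_vectors`, exact template
assignments, a 10⁴-point trapezoid); only the enclosing-sphere routine is
shared, and that routine is separately verified against brute-force
support-set search.

## 7. Limitations

- `logP_calc` is a rank-ordering surrogate: the composite coordinate and
  the fixed 40 Å span make its absolute scale arbitrary.
- The per-solvent diffusion coefficient treats the peptide as a rigid
  Stokes sphere; internal friction and shape anisotropy are ignored.
- Boltzmann inversion assumes the ensembles are equilibrium samples; no
  reweighting of biased trajectories is applied at the permeability stage
  (the cumulant machinery lives in the toy GaMD module).
- The clustering coordinate is a single scalar RMSD; conformers equidistant
  from the chosen reference remain indistinguishable. Choosing a different
  reference changes cluster labels (the prediction is invariant only when
  the clusters still separate).
- H-bond geometry uses rebuilt ideal hydrogens when the topology lacks
  them; real amide-H positions deviate from the bisector by a few degrees.
- The toy GaMD engine is 1-D/low-dimensional and uses analytic potentials;
  it validates the boost/reweighting equations, not molecular sampling.
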