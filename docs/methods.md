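# Methods

`tandemrrm` re-implements, as a tested library, the quantitative analyses
used to compare tethered and isolated tandem RRM domains (TDP-43 RRM1–RRM2
and hnRNPA1 RRM1–RRM2): chemical-shift-perturbation titrations with
residue-specific ATP Kd fitting, Cα superposition of domain structures,
replica trajectory RMSD/RMSF statistics, dihedral mutual-information
coupling maps, and melt-curve Tm extraction. Because the raw NMR, DSF and
trajectory data behind the original measurements are not deposited, every
analysis ships with a seeded synthetic generator that plants known
parameters, and correctness is demonstrated by parameter recovery and
closed-form benchmarks rather than by re-deriving the experimental numbers.

## Chemical-shift perturbation and Kd fitting

For an amide cross peak the combined shift index is
`CSD = sqrt((Δ¹H)² + (Δ¹⁵N)²/4)` in ppm; the nitrogen term is divided by 2
inside the square to compensate its larger ppm dispersion. Residues are
called significantly shifted when CSD exceeds the mean plus one standard
deviation of all measured CSDs. The *sample* (n−1) standard deviation is
used both here and for aggregate Kd spreads — a deliberate small-sample
choice, since titrations typically yield only tens of significant residues;
the population convention would tighten every threshold slightly.

Binding is fit with the one-site ligand-depletion isotherm

    CSD_obs = CSDmax · ((P + L + Kd) − sqrt((P + L + Kd)² − 4·P·L)) / (2·P)

with total protein P and total ligand L in mM. The exact quadratic matters
in principle at low L even though these affinities are millimolar; at the
study design (P = 0.05 mM, L = 0.5–20 mM) the depletion correction is tiny.
Fits run bounded nonlinear least squares (both Kd and CSDmax positive) with
Kd started at the median ligand concentration, CSDmax at 1.5× the largest
observed CSD, and a multi-start over {0.1×, 1×, 10×} of the Kd start; a
flat or non-convergent trace is returned as a flagged failure, never as a
default value. Two aggregation modes exist because the published
"Kd ± error per domain" convention is ambiguous: `per_residue_mean`
(default) averages independent per-residue Kds and reports their sample SD,
`global_shared_kd` fits one Kd with per-residue CSDmax and reports the Kd
standard error. Disappeared peaks (exchange-broadened beyond detection) are
excluded from fitting, never imputed.

Numerical note on the weak-depletion limit: relative to the hyperbola
`CSDmax·L/(L+Kd)`, the exact curve deviates by up to `P/(Kd+P)` as L → 0
(≈1% at P = Kd/100), so a sub-0.5% *relative* agreement claim cannot hold
on that boundary. Measured on the scale of the observable (as a fraction of
CSDmax) the worst-case deviation is `4P/(27·Kd)` (≈0.15% at P = Kd/100),
and that is the convention the agreement tests use.

## Structure comparison

Cα traces are read from PDB files (Bio.PDB), residues are paired by
identical residue number within an inclusive domain range (an optional
fixed offset reconciles construct numbering; no sequence alignment is
attempted), and the optimal proper rotation is found by the Kabsch
algorithm (SVD with reflection correction). NMR ensembles default to model
1 because the published comparisons do not state which member was used;
`model_index` lets users scan the ensemble, and reproduction of published
RMSDs should be expected to be model-choice sensitive at the ±0.2–0.3 Å
level. Coincident or collinear coordinate sets are accepted (the RMSD is
still well defined even when the rotation is not unique); only fewer than
three pairs is an error.

## Trajectory fluctuation analyses

A `TrajectoryEnsemble` holds replicas × frames × atoms with a shared
topology, read from multi-model PDB (one MODEL per frame, one file per
replica). RMSD superposes every frame of a replica onto that replica's
first frame over the chosen selection (`--ref mean` switches to the mean
structure); the headline mean ± SD pools all frames of all replicas, the
simplest convention consistent with "averaged over three trajectories".
Domain-overlay RMSD restricts both fit and measurement to one domain's
range, excluding termini and linker. RMSF superposes frames onto the
replica mean structure (one refinement pass after a first-frame pre-fit)
and averages per-residue profiles across replicas. The tethered-minus-
isolated RMSF difference applies the same mean + one SD selection rule as
the CSD analysis, computed over in-domain residues only; linker residues
are reported separately. No burn-in is discarded by default.

## Dihedral mutual information

φ/ψ series are extracted per replica (MDAnalysis dihedral kernel, IUPAC
signs) and concatenated; no inter-replica pairs are formed. Pairwise MI
uses equal-width circular binning over (−180°, 180°], default 24 bins
(15°), in nats. Finite-sample bias is removed by subtracting the mean MI of
10 seeded permutations of one series — a deliberate simplification of the
adaptive corrections in entropy-expansion tools, adopted because the
downstream decision only needs a well-calibrated null. Corrected MI can be
slightly negative and is floored at zero for the normalized matrix.
Residue-pair scores sum the four torsion-pair MIs and are normalized by the
smaller of the two residues' summed marginal entropies, giving values in
[0, 1]; normalizing by the matrix maximum would force the largest noise
element to 1 and make the fixed coupling threshold (default 0.3)
meaningless. Side-chain χ torsions are excluded by default so the estimator
runs on backbone-only data; this makes the absolute threshold comparable
only functionally, not numerically, with side-chain-inclusive analyses.

## Melt curves

Tm is the temperature of a dF/dT peak: the signal is smoothed with a
centred moving average whose half-width shrinks symmetrically at the edges
(so linear baselines keep their slope), differentiated with centred
finite differences (one-sided at the endpoints), and peaks with prominence
≥ 0.2× the maximum derivative are refined by parabolic interpolation
through the peak and its neighbours. A curve whose derivative never rises
above numerical noise reports zero transitions. The same operations handle
coarse Trp-fluorescence melts (25–95 °C at 5 °C steps) with a smaller
smoothing window.

## Synthetic generators

All generators are pure functions of their spec (seed included).

* **Titrations** (default: 50 µM protein; ATP at 0, 0.5, 1, 2, 4, …, 20 mM
  — the study ladder): reference peaks are drawn uniformly in the amide
  region, each residue gets a CSDmax in 0.2–0.8 ppm and a random shift
  direction; positions move along that direction by the depletion-model
  prediction. Noise (default σ = 0.005 ppm, typical of assigned HSQC peak
  positions) is isotropic in the (Δ¹H, Δ¹⁵N/2) metric so the CSD noise
  scale is exactly σ per component. Peak disappearance is Bernoulli per
  residue with a random onset concentration.
* **Trajectories**: the backbone (N, CA, C; ideal bond lengths and angles,
  ω = 180°) is rebuilt each frame from per-frame φ/ψ, so planted torsion
  statistics round-trip exactly through the dihedral extractor. Baseline
  helical torsions carry wrapped-Gaussian thermal noise (default 12°);
  this field exists because constant dihedrals have zero marginal entropy
  and normalized MI would be undefined. Coupled pairs replace the φ/ψ of
  both residues with a one-factor Gaussian copula (pairwise latent
  correlation ρ, uniform circular marginals; MI = −½ln(1−ρ²) per torsion
  pair). The hinge rotates residues beyond the linker midpoint about a
  fixed axis by an AR(1) angle series. Desk-scale defaults (3 replicas ×
  500 frames, 168 residues with the TDP-43 domain ranges) keep every
  analysis runnable in seconds to minutes on one core. What this generator
  does **not** emulate: force-field energetics, anisotropic/correlated
  Cartesian fluctuation, side chains, solvent — so passing recovery tests
  demonstrates estimator correctness, not MD realism.
* **Melt curves**: sums of two-state van 't Hoff transitions
  `f(T) = 1/(1+exp((ΔH/R)(1/T − 1/Tm)))` with linear baselines, optional
  post-transition exponential decay (dye dissociation; off by default) and
  seeded noise. Default apparent ΔH = 800 kJ/mol gives dF/dT peak widths of
  ~3 °C, matching typical DSF traces of small folded domains and making the
  51/57 °C two-transition pattern resolvable; default sampling 0.5 °C
  emulates instrument reads during a 1 °C/min ramp.

## Pipelines and determinism

The titration recipe chains CSD → significance selection → per-residue Kd
fits; the coupling recipe chains full and domain-overlay RMSD, RMSF,
ΔRMSF, the MI matrix and the coupling report. All randomness derives from
the single seed recorded in the run record, timestamps never enter CSVs,
and reruns under a fixed config are byte-identical.

## Known limitations

* Peak matching is by assignment only; unassigned or reassigned titrations
  are out of scope.
* The MI threshold 0.3 is meaningful only under this package's
  min-marginal-entropy normalization and backbone-only torsion set.
* Thermal melts are treated as equilibrium two-state signals; irreversible
  aggregation-coupled unfolding only shifts the apparent Tm and is not
  modelled.
* Structure comparison assumes consistent residue numbering up to a fixed
  offset.
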