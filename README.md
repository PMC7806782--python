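# tandemrrm

Quantitative analyses for comparing **tethered vs isolated tandem RRM
domains** — the two-domain RNA-recognition-motif constructs of proteins
such as TDP-43 and hnRNPA1, whose aggregation underlies ALS and related
proteinopathies. The package is aimed at structural-biology groups who run
HSQC ligand titrations, thermal-shift assays and MD simulations on such
constructs and want the downstream numerics reproducible and tested.

It covers five analyses end to end, each with a seeded synthetic generator
so every stage is testable without the original raw data:

1. **Chemical-shift perturbation + Kd fitting.** Per-residue
   `CSD = ((Δ¹H)² + (Δ¹⁵N)²/4)^½` from assigned Sparky-style peak lists,
   significance by CSD > mean + 1 SD, and residue-specific dissociation
   constants from the one-site ligand-depletion isotherm
   `CSD_obs = CSDmax·((P+L+Kd) − √((P+L+Kd)² − 4PL))/(2P)`.
2. **Structure comparison.** Cα Kabsch superposition of tethered vs
   isolated domain structures over named residue ranges.
3. **Trajectory fluctuations.** Per-replica RMSD (full and domain-overlay),
   replica-averaged RMSF, and the tethered-minus-isolated ΔRMSF rule
   (Δ > mean + 1 SD).
4. **Dihedral coupling.** φ/ψ mutual-information matrices (circular
   binning, shuffle-null bias correction), normalized to [0, 1] by the
   minimum marginal entropy and thresholded (default 0.3) into intra- and
   inter-domain coupling pairs.
5. **Melt curves.** Tm from dF/dT peaks of DSF or Trp-fluorescence melts,
   with single- vs multi-transition detection.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

Fit a shared ATP affinity from a synthetic titration at the standard
design (50 µM protein; ATP 0.5–20 mM over 12 points):

```python
from tandemrrm import (TitrationSpec, gen_titration, csd_profile,
                       select_significant, fit_kd_profile)

spec = TitrationSpec(n_residues=40, true_kd=7.7, noise_sd=0.005, seed=1)
series, truth = gen_titration(spec)

profile = csd_profile(series, at_conc=20.0)
sig = select_significant(profile)
print(f"threshold = {sig.threshold:.3f} ppm, {len(sig.selected)} significant residues")

fit = fit_kd_profile(series, sig.selected, mode="per_residue_mean")
print(f"Kd = {fit.aggregate_kd:.1f} +/- {fit.aggregate_kd_sd:.1f} mM ({fit.n_converged} residues)")
```

prints

```
threshold = 0.478 ppm, 7 significant residues
Kd = 7.7 +/- 0.3 mM (7 residues)
```

The significance rule keeps the 7 residues whose shift trajectories rise
clear of the profile's mean + SD; fitting each of their traces with the
depletion isotherm and averaging recovers the planted affinity of 7.7 mM,
with the ±0.3 mM spread coming from the 0.005 ppm peak-position noise.

The same works from the shell, e.g. for a melt curve:

```sh
$ tandemrrm simulate melt --seed 2 --out melts
$ tandemrrm melt-tm melts/melt.csv --out tm.csv
melts/melt.csv: 1 transition(s), Tm 59.0 degC
```

Other subcommands: `csd`, `fitkd`, `rmsd-structures`, `traj-rmsd`,
`traj-rmsf`, `mutinf`, `simulate titration|trajectory|angles|melt`, and
`pipeline titration|coupling --config cfg.json` for end-to-end recipes
with run records and byte-identical reruns.

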