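# xldock

Cross-link-restrained Bayesian docking of multidomain proteins, with the two
companion biophysical analyses that tie structure to function for a guanine
nucleotide exchange factor (GEF): HDX-MS differential deuterium uptake and
mant-GDP release kinetics.

## Who this is for

Structural and chemical biologists who have (a) cross-linking-MS residue-pair
identifications for a multidomain protein plus crystal structures of its
domains, and want an ensemble of full-length arrangements consistent with the
links; (b) HDX-MS centroid tables for two states and want per-peptide
protected / deprotected / missing calls mapped onto structure; or (c) plate
reader fluorescence time courses of nucleotide release and want observed
rates, catalytic efficiencies and fold changes.

## The model

Domains are rigid bodies of one bead per residue at the Cα positions; linkers
are flexible bead strings. A model M is scored against cross-link data D by
the posterior `p(M|D,I) ∝ p(D|M,I) p(M|I)` in negative log form:

* each cross-link at Cα–Cα distance d contributes `−log[ψ + (1 − 2ψ) f(d)]`,
  with logistic forward model `f(d) = 1/(1 + e^{α(d − d0)})` switching at the
  linker chemistry's reach (34 Å for DSS/DSG, 20 Å for DSSO) and ψ ∈
  (0.01, 0.5] the sampled uncertainty that the link is a true restraint;
* a soft-sphere excluded-volume penalty and a sequence-connectivity tether
  form the prior.

Sampling is replica-exchange Gibbs / Metropolis Monte Carlo (rigid-body moves
≤ 4 Å and ≤ 0.03 rad, bead moves ≤ 5 Å, Gaussian ψ moves; 8 temperatures in
[1.0, 2.5]). The best 200 models are clustered by k-means on coordinates
after superposition of a reference domain; per cluster we report population,
precision (mean RMSD to the medoid) and three cross-link satisfaction
fractions at the 34 Å cutoff (best-scoring model, best single member,
aggregate over members). A synthetic-data module generates ground-truth toy
systems, cross-link tables with decoys, two-state HDX tables and noisy decay
traces, so the whole pipeline is testable end to end. See `docs/methods.md`
for the full model description and design rationale.

## Worked example

Fit a simulated nucleotide-release trace and compute catalytic efficiency:

```python
from xldock.synthetic import simulate_kinetics
from xldock.kinetics import fit_one_phase_decay, catalytic_efficiency

traces = simulate_kinetics(true_k={"GEF": 0.011, "no-GEF": 0.001},
                           noise_sd=0.5, n_replicates=3, seed=42,
                           enzyme_conc={"GEF": 0.5})
k_intr = sum(fit_one_phase_decay(t).k_obs for t in traces
             if t.condition == "no-GEF") / 3
t = traces[0]
fit = fit_one_phase_decay(t)
eff = catalytic_efficiency(fit.k_obs, k_intr, t.enzyme_conc)
print(f"{t.condition}: k_obs = {fit.k_obs:.5f} 1/s (R2 = {fit.r_squared:.4f}), "
      f"efficiency = {eff.value:.4f} 1/(uM*s)")
```

prints

```
GEF: k_obs = 0.01104 1/s (R2 = 0.9996), efficiency = 0.0201 1/(uM*s)
```

i.e. the observed pseudo-first-order rate recovers the simulated 0.011 s⁻¹,
and after subtracting the intrinsic rate and dividing by 0.5 μM of enzyme the
catalytic efficiency lands on the true 0.02 μM⁻¹·s⁻¹.

The docking pipeline runs from the shell:

```bash
xldock simulate --preset three-body --seed 42 --out fixtures/
xldock sample   --topology fixtures/topology.yaml --xl fixtures/crosslinks.csv \
                --config sampler.yaml --out run/
xldock analyze  --ensemble run/ --topology fixtures/topology.yaml \
                --xl fixtures/crosslinks.csv --k 3 --out analysis/
```

`analyze` prints the cluster populations, precisions (Å) and the three
satisfaction fractions per cluster, and writes a JSON report.

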