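# qtrap

Free-energy and electron-tunneling analysis of CoQ10 trapping in
mitochondrial complex I.

The LHON-causing m.3460G>A mutation substitutes Thr for Ala52 in the ND1
subunit of complex I, right at the entry of the CoQ10 binding channel.
Molecular simulation probes its consequences through three quantities: the
relative binding free energy of CoQ10 to the wild-type and mutant channel,
the extra mechanical work needed to extract CoQ10 from the mutated
channel, and the electron-tunneling rate change implied by how close the
quinone headgroup sits to the N2 iron–sulfur cluster. `qtrap` implements
the full *post-simulation* inference chain for these quantities, for
computational biophysicists who have (or simulate) the raw outputs:

* **`qtrap.smd`** — steered-pulling work analysis: binned work/PMF
  profiles W(z) with mean-work, Jarzynski
  (ΔG(z) = −k_BT·ln⟨e^{−W(z)/k_BT}⟩) and second-cumulant estimators,
  barrier differences ΔΔW, and Boltzmann rate factors e^{−ΔΔW/k_BT}.
* **`qtrap.fep`** — alchemical free energies: per-window Bennett
  acceptance ratio (the minimum-variance two-state estimator, solved from
  Σ_F f(β(ΔU_F−C)) = Σ_R f(β(C−ΔU_R))), Zwanzig exponential averaging,
  λ-schedule composition, the relative-binding thermodynamic cycle
  ΔΔG_bind = ΔG_mut^unbound − ΔG_mut^bound, and k-nearest-neighbor
  density corrections for frozen endpoints.
* **`qtrap.tunneling`** — KDE mode detection on donor–acceptor distance
  distributions and nonadiabatic (Marcus) tunneling-rate ratios,
  k_alt/k_ref = e^{β(d_ref−d_alt)} or ⟨e^{−βR}⟩_alt/⟨e^{−βR}⟩_ref.
* **`qtrap.synthetic`** — generators with analytically known answers
  (overdamped Langevin pulling in model potentials, Crooks-consistent
  Gaussian ΔU pairs, Gaussian distance mixtures) so that every estimator
  ships with a ground-truth recovery test.
* **`qtrap.io_tables`** — plain-TSV and MD-engine-dialect readers/writers
  for all of the above (see `docs/formats.md`).

The API follows the model/results idiom: build a model from data, call
`fit()`, read estimates, uncertainties and `summary()` off the results
object (`PullingWorkModel`, `AlchemicalCycleModel`,
`DistanceDistributionModel`). A `qtrap` command-line tool wraps the same
functionality (`qtrap demo --seed 1` runs the whole chain).

## Worked example

```python
from qtrap import synthetic, fep, tunneling

# --- relative binding free energy from a synthetic cycle (truth: 4 kcal/mol)
data = synthetic.generate_cycle_dataset(10.0, 6.0, sigma=1.0, n=4000, seed=1)
results = fep.AlchemicalCycleModel(data.unbound, data.bound).fit()
print(f"ddG_bind = {results.ddg_bind:.3f} +/- {results.stderr:.3f} kcal/mol")

# --- distance modes and tunneling-rate ratio
wt = synthetic.generate_distance_mixture(
    synthetic.MixtureSpec([(1.0, 14.1, 0.2)], 100_000, seed=2, label="WT"))
mut = synthetic.generate_distance_mixture(
    synthetic.MixtureSpec([(0.6, 13.5, 0.15), (0.4, 14.1, 0.15)],
                          100_000, seed=3, label="A52T"))
res_wt = tunneling.DistanceDistributionModel(wt).fit()
res_mut = tunneling.DistanceDistributionModel(mut).fit()
print("WT modes: ", [f"{p:.2f}" for p, _ in res_wt.modes])
print("A52T modes:", [f"{p:.2f}" for p, _ in res_mut.modes])
print(f"rate ratio (peaks):    {res_mut.rate_ratio_vs(res_wt):.2f}")
print(f"rate ratio (ensemble): {res_mut.rate_ratio_vs(res_wt, ensemble=True):.2f}")
```

prints

```
ddG_bind = 3.901 +/- 0.053 kcal/mol
WT modes:  ['14.11']
A52T modes: ['13.50', '14.10']
rate ratio (peaks):    3.01
rate ratio (ensemble): 2.10
```

Reading the output: the two alchemical legs (mutation with CoQ10 absent /
present, true values 10 and 6 kcal/mol, 10 λ windows, 4000 Crooks-consistent
samples per side) compose to ΔΔG_bind = 3.90 ± 0.05 kcal/mol, recovering
the built-in 4 kcal/mol within its uncertainty — positive, i.e. the mutant
binds CoQ10 less strongly. The wild-type-like distance distribution is
unimodal at 14.11 Å while the mutant-like one is bimodal with its
*prominent* mode at 13.50 Å; at a distance-decay of β = 1.8 Å⁻¹ the
0.6 Å approach corresponds to a ~3-fold faster tunneling rate at the
peaks, tempered to ~2.1-fold when averaged over the whole ensemble.

The pulling side works the same way: feed `WorkTrace` ensembles (read from
TSV/SMD logs or generated by `synthetic.simulate_pulling`) to
`smd.PullingWorkModel`, then query `results.barrier((z_lo, z_hi))` and
`smd.rate_slowdown(delta_kt)` — e.g. a 20 kT barrier difference gives a
2.06 × 10⁻⁹ rate factor. See `docs/methods.md` for the models,
assumptions and defaults.

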