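# crystalmotifs

Data-driven attribution of molecular-crystal lattice energies to atoms and
functional-group motifs.

Who it is for: computational chemists and crystal engineers who have
periodic crystal structures, the relaxed gas-phase geometries of the
constituent molecules, and total energies for both, and who want to know
*which chemical groups stabilize the crystal and by how much* — e.g. to
compare polymorphs or shortlist co-former candidates.

## The method

The lattice energy of a molecular crystal is

    Δ_c = E_c − Σ_m E_m ,     δ_c = Δ_c / n_c   (kJ per mol of atoms),

small compared with the composition-dominated spread of total energies.
The package therefore builds its regression on the **remnant descriptor**

    x^(s−g)_c = x^(s)_c − x^(g)_c ,

the difference between the crystal's atom-averaged SOAP power-spectrum
descriptor in the solid and in the gas phase, which encodes exactly what
changes on crystallization (intermolecular environment + conformational
distortion) and cancels everything that does not.  A ridge model
δ_c = x^(s−g)_c·w then decomposes exactly into per-atom contributions
δ_a = x^(s−g)_a·w, which are smoothed by a total-conserving Gaussian
filter over ≤ 2 Å neighborhoods (Σδ̃ = Σδ exactly), averaged over SMARTS
motif matches, and organized on Principal Covariates Regression (PCovR)
maps where Euclidean distance over all covariates defines motif
similarity.  Seven model variants (per-atom crystal and molecule
energies, their combination, and direct lattice-energy models on solid,
gas, concatenated and remnant features) are fitted and compared; on data
where intermolecular structure drives δ_c the errors order
remnant ≤ concat ≤ solid, with gas-only worst.

## Worked example

Everything is runnable without external data through the synthetic
generator, which plants per-atom energies that are exactly linear in the
local descriptor (see `docs/methods.md`):

```python
import numpy as np
from crystalmotifs import (SyntheticSpec, generate, collection_matrices,
    fit_energy_model, fps_select, evaluate_model, atomic_contributions,
    gaussian_filter, FilterConfig)
from crystalmotifs.descriptors import DescriptorConfig

cfg = DescriptorConfig(r_cut=4.0, n_max=2, l_max=2, sigma_atom=0.4,
                       species_list=("C", "H", "N", "O"))
data = generate(SyntheticSpec(seed=1, n_crystals=200, noise_sigma=0.5,
                              descriptor_config=cfg))
mats = collection_matrices(data.records, data.ds_solid, data.ds_gas,
                           data.ds_remnant)
train = fps_select(mats["Xr"], 160, start=0)
test = sorted(set(range(200)) - set(train))
model = fit_energy_model(mats["Xr"][train], mats["delta_c"][train],
                         feature_space="remnant")
m = evaluate_model(model.predict(mats["Xr"][test]), mats["delta_c"][test])
print(f"remnant model: test RMSE {m['rmse']:.3f} kJ/mol atom "
      f"(target SD {m['sd_truth']:.3f}, noise 0.5)")

rec = data.records[2]
att = gaussian_filter(atomic_contributions(rec, data.ds_remnant[2], model),
                      rec.crystal, FilterConfig())
print(rec.crystal.id, f"delta_c={rec.lattice_energy_per_atom:+.3f} "
      f"pred={att.prediction:+.3f}")
for el, raw, smooth in zip(rec.crystal.species, att.delta_a,
                           att.delta_a_filtered):
    print(f"  {el}: raw {raw:+7.3f}  filtered {smooth:+7.3f}")
```

prints

```
remnant model: test RMSE 0.473 kJ/mol atom (target SD 0.613, noise 0.5)
synth2 delta_c=-3.260 pred=-2.899
  C: raw  -2.296  filtered  -2.704
  O: raw  -4.493  filtered  -4.336
  O: raw  -0.978  filtered  -1.252
  H: raw  -2.471  filtered  -2.225
  H: raw  -4.875  filtered  -4.597
  O: raw  -2.925  filtered  -2.027
  H: raw  +0.393  filtered  -0.100
  H: raw  +1.098  filtered  +0.693
  C: raw  -5.267  filtered  -5.151
  O: raw  -4.864  filtered  -4.848
  H: raw  -1.584  filtered  -1.854
  H: raw  -6.523  filtered  -6.385
```

The test RMSE sits at the injected noise level (the planted signal is
fully recovered; at zero noise it drops below 10⁻⁶), the per-atom values
average exactly to the structure prediction, and the filtered column
redistributes the bonded-atom see-saw (e.g. the +1.098/−2.925 pair inside
one water) while conserving the total.  `delta_c` differs from the
prediction by the injected noise.

The same workflow runs from the shell on a run directory:

```
crystalmotifs synth     --run-dir run --seed 1 --n-crystals 50
crystalmotifs featurize --run-dir run
crystalmotifs train     --run-dir run          # 7-variant metrics table
crystalmotifs attribute --run-dir run          # per-atom/motif CSVs, H-bonds
crystalmotifs map       --run-dir run --query 0  # PCovR maps + similarity
```

Real data enter the same way: extended-XYZ or CIF structures (CIF
symmetry operations are expanded to P1), an energy CSV with columns
`id, kind ∈ {crystal, molecule}, parent_id, E_kJ_per_mol`, and optionally
a TSV motif table (`name, smarts`) and SMILES tags for bond orders.

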