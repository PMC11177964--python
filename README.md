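# topoddg

Topological featurization of protein–protein complexes for predicting
mutation-induced binding free energy changes (ΔΔG), plus an evaluation
pipeline for predicted complex structures.

**Who it is for.** Structural bioinformaticians who (a) want
persistent-Laplacian spectral features of a mutation site and a binding
interface as input to ΔΔG regression, and/or (b) need to quantify how far
predicted complexes (e.g. from modern folding servers) deviate from their
experimental references — globally, per residue, and against the
predictor's own confidence scores.

## The core method

A point mutation changes binding affinity by
ΔΔG = ΔG(mut) − ΔG(wt) = RT ln(K_d^mut / K_d^wt) (kcal/mol). To predict
ΔΔG from structure, heavy atoms around the mutation site and the interface
are partitioned into element-specific subsets (pairs over {C, N, O}) and
two opposing groups per subset; a *modified distance* D_mod assigns +∞ to
same-group atom pairs so only cross-group contacts create topology. Each
subset is filtered at scale t (Vietoris–Rips for dimension 0, Alpha for
dimensions 1–2), giving boundary matrices B_k and combinatorial Laplacians

    L_k = B_{k+1} B_{k+1}ᵀ + B_kᵀ B_k        (L_0 = B_1 B_1ᵀ).

The zero-eigenvalue multiplicity of L_k is the Betti number β_k
(combinatorial Hodge theorem); the non-zero spectrum adds geometric shape
information. A p-persistent variant couples K(t) to K(t+p) and recovers
persistent homology in its harmonic space. Spectral statistics along a
filtration grid, for wild-type, mutant, and their difference, form the
feature vector; a ridge-initialized gradient-boosted tree ensemble maps
features to ΔΔG, validated by 10-fold cross-validation (pooled Pearson R_p
and RMSE).

Structure evaluation superposes a predicted complex onto its reference
with a whole-complex Kabsch fit on Cα atoms (chains mapped by sequence),
computes per-residue backbone RMSD, joins it with crystallographic
B-factors (flexibility), and summarizes batches by RMSD and the standard
ipTM/pTM confidence bands (0.8 / 0.6 / 0.5).

## Worked example

```python
import numpy as np
from topoddg import (
    ToyDimerConfig, make_toy_dimer, perturb_structure,
    superpose_complexes, per_residue_rmsd, cross_validate,
    synth_mutation_dataset,
)
from topoddg.structeval import bfactor_rmsd_table
from scipy.stats import spearmanr

# a synthetic complex whose "predicted" copy is displaced in proportion
# to each residue's B-factor — flexible regions are modelled worst
ref = make_toy_dimer(ToyDimerConfig(residues_per_chain=60, interface_contacts=6, seed=11))
profile = {k: 0.03 * np.mean([a.b_factor for a in v]) for k, v in ref.residues().items()}
pred = perturb_structure(ref, profile, seed=5)

aln = superpose_complexes(pred, ref, chain_map={"A": "A", "B": "B"})
table = bfactor_rmsd_table(ref, per_residue_rmsd(pred, ref, aln.chain_map, aln))
rho = spearmanr(table["b_factor"], table["rmsd"]).statistic
print(f"alignment RMSD = {aln.rmsd:.3f} A")
print(f"Spearman(B-factor, residue RMSD) = {rho:.3f}")

# ΔΔG regression on a dataset with a known sparse linear effect model
ds = synth_mutation_dataset(500, seed=7, n_features=20, n_active=5, noise_sigma=0.3)
res = cross_validate(ds.X, ds.y, k_folds=10, seed=42)
print(f"10-fold CV: Rp = {res.rp:.3f}, RMSE = {res.rmse:.3f} kcal/mol")
```

Output:

```
alignment RMSD = 0.662 A
Spearman(B-factor, residue RMSD) = 0.967
10-fold CV: Rp = 0.989, RMSE = 0.332 kcal/mol
```

The alignment RMSD is the least-squares whole-complex residual (Å); the
Spearman coefficient shows per-residue model error tracking flexibility;
the CV numbers show the regressor recovering a known effect model whose
noise floor is 0.3 kcal/mol.

Featurizing real structures follows the sklearn transformer idiom:

```python
from topoddg import LaplacianFeaturizer, parse_structure, parse_mutation_code, DDGRegressor

wt = parse_structure("1CSE.pdb").with_partition({"E": "P1", "I": "P2"})
mut = parse_mutation_code("TI38F")
X = LaplacianFeaturizer().fit().transform([(wt, None, mut)])  # None -> fallback mutant
model = DDGRegressor().fit(X_train, y_train)                  # kcal/mol targets
```

A thin CLI wraps the batch operations: `topoddg parse-skempi`,
`topoddg make-fixtures`, `topoddg evaluate --manifest m.csv --out dir/`,
`topoddg train --features f.csv --records r.csv --cv 10`.

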