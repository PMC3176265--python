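# ppihotspot

Prediction of **hot-spot residues** at protein–protein interfaces.

Systematic alanine-scanning mutagenesis shows that binding free energy is
not spread evenly over an interface: a small subset of residues — hot
spots, conventionally those with ΔΔG ≥ 1 kcal/mol upon mutation to
alanine — carries most of it. `ppihotspot` is a toolkit for researchers
studying interface energetics: it extracts per-residue features from
complex structures and sequence profiles, labels alanine-scanning data,
and classifies hot spots with a radial-basis-function support vector
machine (RBF-SVM).

## What it computes

**Structure features** (per residue, from a PDB complex split into two
chain-group partners):

- Solvent-accessible surface area by Shrake–Rupley sampling (1.4 Å probe,
  deterministic golden-spiral points): ASA in the isolated partner
  ("monomer") and in the complex, the burial on complexation
  ΔASA = ASA_monomer − ASA_complex, the relative burial
  ΔASA% = 100·ΔASA/ASA_monomer, and relASA = ASA_complex over the
  residue type's reference area in an extended ALA-x-ALA tripeptide.
  A residue with ΔASA ≥ 1 Å² is an interface residue.
- Biochemical contacts across the interface: hydrogen bonds (heavy-atom
  donor–acceptor ≤ 3.5 Å with an antecedent-angle check), salt bridges
  (oppositely charged atoms < 7 Å) and atomic contacts
  (d < r_vdw(i) + r_vdw(j) + 0.25 Å).

**Sequence features**: six physicochemical constants per residue type
(AAindex accessions pinned in `seqfeat.PHYSCHEM_TABLE`), PSI-BLAST PSSM
columns squashed to (0,1) with the logistic 1/(1+e^−x), alignment-column
Shannon entropy normalized to 0–100 (0 = conserved), and a 1–9
conservation grade (9 = conserved), parsed from ConSurf-style files or
estimated from an MSA by entropy quantiles.

**Classification**: an RBF-SVM with decision function
sgn(f(x)), f(x) = Σᵢ αᵢ K(xᵢ, x) + b, K(x, x′) = exp(−γ‖x−x′‖²),
with (C, γ) chosen by grid search maximizing mean cross-validated F1.
Evaluation uses precision P = TP/(TP+FP), recall R = TP/(TP+FN),
F1 = 2PR/(P+R) and the area under the ROC curve, via self-consistency
(train = test) and stratified 10-fold cross-validation with pooled
confusion counts, plus leave-one-feature-group-out ablation and a
random-assignment baseline.

## Worked example

Features can come from real extractions (`ppihotspot extract`) or the
synthetic generator. Here a 377-row dataset with the canonical 182/195
hot/non-hot split and a modest planted signal on the sequence features is
fitted with the sequence-based feature combination:

```python
from ppihotspot import HotspotSVM, SvmConfig
from ppihotspot.synthetic import SyntheticDatasetSpec, make_synthetic_dataset

ds, truth = make_synthetic_dataset(SyntheticDatasetSpec(
    n_rows=377, prevalence=182/377, separation=0.3,
    informative_groups=("PSSM", "SE"), seed=7))
ds = ds.with_groups_removed({"ASA", "BC"})          # sequence-based model

cfg = SvmConfig(C_grid=(0.25, 1.0, 4.0, 16.0),
                gamma_grid=(1/64, 1/8, 0.5), cv_folds=10, seed=7)
print(HotspotSVM(ds, cfg).fit().summary())
```

```
RBF-SVM hot-spot classifier
===============================================
rows: 377   hot spots: 182   non-hot spots: 195
feature groups: Phy+PSSM+ECS+SE (28 columns)
selected C = 0.25, gamma = 0.015625 (scaling: zscore)
-----------------------------------------------
test                    P      R     F1     AUC
self-consistency     0.79   0.71   0.75    0.87
cross-validation     0.72   0.64   0.68    0.79
===============================================
```

Self-consistency is optimistic by construction (the model saw every row);
the cross-validated row is the honest estimate. At separation 0 both fall
to chance; the gap between them is the overfitting margin.

The command-line interface wires the same pieces together from files:

```bash
ppihotspot extract --pdb complex.pdb --partners AB:C --out features.csv
ppihotspot label   --mutations muts.csv --threshold-ddg 1.0
ppihotspot cv      --features features.csv --mutations muts.csv \
                   --combo Phy+PSSM+ECS+SE --folds 10 --seed 0
ppihotspot baseline --n 377 --pos 182 --reps 1000
```

`ppihotspot baseline` prints `P=0.48 R=0.48 F1=0.48`: predicting a random
182-residue subset of 377 interface residues as hot spots gives
E[TP] = 182²/377 ≈ 87.9, so P = R = F1 ≈ 182/377 ≈ 0.48 — the floor any
real model must clear.

## Layout

| module | contents |
| --- | --- |
| `structure_io` | PDB parsing, partner splitting, sequences |
| `sasa` | Shrake–Rupley SASA, ΔASA / ΔASA% / relASA, interface calls |
| `contacts` | hydrogen bonds, salt bridges, atomic contacts |
| `seqfeat` | physicochemical table, PSSM, entropy, conservation |
| `dataset` | hot-spot labeling, feature assembly, Ab±/balanced variants |
| `model` | `HotspotSVM`/`HotspotSVMResults`, CV, ablation, baseline, stats |
| `extract` | per-complex feature-table driver |
| `synthetic` | toy complexes, MSAs, PSSMs, planted-signal datasets |
| `cli` | `ppihotspot` console script |

See `docs/methods.md` for the modelling assumptions and numerical
conventions.
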