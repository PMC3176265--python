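# Methods

## Problem and model

A protein–protein interface residue is a *hot spot* when mutating it to
alanine costs at least a threshold of binding free energy; the package
uses the inclusive rule ΔΔG ≥ 1 kcal/mol by default and supports the
stricter ΔΔG ≥ 2 kcal/mol convention. Where only categorical
alanine-scanning annotations exist (Strong / Intermediate / Weak /
Insignificant / Negative-weak / Negative-strong), Strong and Intermediate
count as hot spots and the other four categories as non-hot spots.

Classification is a soft-margin SVM with the RBF kernel
K(x, x′) = exp(−γ‖x−x′‖²) over per-residue feature vectors drawn from six
named groups: burial (ASA, 5 columns), biochemical contacts (BC, 3),
physicochemical constants (Phy, 6), normalized PSSM (20), conservation
grade (ECS, 1) and sequence entropy (SE, 1). Any subset of groups can be
selected; "sequence-based" means Phy+PSSM+ECS+SE, "structure-based" means
Phy+ASA+BC.

## Geometry

**SASA.** Shrake–Rupley sampling with a 1.4 Å probe and a deterministic
golden-spiral point set (default 960 points/atom; the single-atom area is
then exact to well under 1 % of 4π(r+1.4)²). Radii are a per-element
Bondi-style table (C 1.70, N 1.55, O 1.52, S 1.80 Å …), overridable per
call. Hydrogens are ignored throughout — most crystal structures at ≤ 3 Å
resolution lack them — as are waters; alternate locations keep the
highest-occupancy conformer; only model 1 of multi-model files is read.
Monomer-state SASA is computed on the isolated partner with unchanged
coordinates, so ΔASA ≥ 0 up to quadrature noise; values in (−0.1, 0) Å²
clamp to 0, a more negative value raises (it indicates mismatched
coordinates, not noise). ΔASA% is undefined (missing, not 0) when the
monomer-state area is 0. relASA divides the complex-state area by the
residue type's reference area in an extended ALA-x-ALA tripeptide
(embedded table of theoretical maxima; Gly smallest at 104 Å², Trp
largest at 285 Å²). All-atom accessibility is used everywhere;
side-chain-only variants are out of scope.

**Contacts.** All three counters pair one heavy atom from each binding
partner; each cross pair contributes once to the residue on either side,
so side sums balance by construction, and all counters are invariant
under rigid motion of the whole complex. Salt bridges: oppositely charged
side-chain atoms (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2 unless excluded by
flag; Asp OD1/OD2; Glu OE1/OE2) closer than 7 Å. Histidine is treated as
positive by default so the behaviour is explicit and testable. Hydrogen
bonds: donor heavy atom within 3.5 Å of an acceptor with
antecedent–donor–acceptor angle ≥ 90°, donors/acceptors from an embedded
per-residue table; this replaces hydrogen-placement or network-optimizing
schemes, which require protons the structures do not have. Atomic
contacts: a vdW-overlap criterion, d < r_vdw(i) + r_vdw(j) + 0.25 Å. The
0.25 Å figure is a *slack on the radius sum*, not a raw distance — a raw
interatomic distance below 0.25 Å is physically impossible — and is
configurable. Neighbor search uses a KD-tree; the O(n²) all-pairs scan is
kept in the test suite as an oracle.

## Sequence features

The six physicochemical constants are pinned by AAindex accession:
KYTJ820101 (Kyte–Doolittle hydropathy), HOPT810101 (Hopp–Woods
hydrophilicity), GRAR740102 (Grantham polarity), CHAM820101 (Charton
polarizability), CHOP780202 (Chou–Fasman β-sheet propensity, filling the
"propensity" slot) and JANJ780101 (Janin average accessible surface
area). The table is an embedded constant; swap-in via configuration is
supported at the `assemble` level by supplying custom columns.

PSSM scores come from PSI-BLAST ASCII output (first 20-column score
block); each integer score x is normalized to (0,1) with the logistic
1/(1+e^−x), a strictly monotone bijection, so 0 maps to 0.5 and ±10
saturate. Sequence entropy of an alignment column is Shannon entropy over
the 20 amino acids (gaps excluded from the probabilities), scaled by
100/ln 20 so an invariant column scores 0 and a uniform column 100; an
all-gap column is a missing value, and columns with > 50 % gaps should be
treated with caution. Conservation grades follow the 1–9 colour scale
with 9 = conserved. They are parsed from ConSurf-style grade files when
available; otherwise a fallback estimator bins the protein's per-column
entropies into nine within-protein quantiles, inverted so the least
entropic ninth gets grade 9. The fallback is a monotone transform of
entropy, not a phylogenetic rate — rate inference is deliberately out of
scope — and feature provenance should be tracked accordingly.

When structure numbering and profile/alignment numbering disagree, chain
sequences are reconciled to the query by global pairwise alignment
(BLOSUM62, affine gaps); unaligned residues get missing values.

## Dataset assembly

Mutation tables join onto per-residue feature tables by
(pdb_id, chain, resseq, icode). Unresolvable keys are an error — silent
row loss would bias class counts. Rows failing the interface filter
(ΔASA ≥ 1 Å²) are dropped, since labelled alanine-scanning sets contain
interface residues only. Missing feature values are imputed with the
column mean and counted in `Dataset.imputed`. Supporting set variants:
`split_ab` separates out antigen–antibody complexes (flagged in the
mutation table — antibody loops evolve fast, which dilutes conservation
signal), and `balance_lowest_ddg` keeps all hot spots plus the n non-hot
spots with smallest ΔΔG (deterministic tie-break by (pdb_id, chain,
resseq)), the balancing used with the 2 kcal/mol definition.

## Training and evaluation

Hyper-parameters default to C ∈ 2^{−5..15}, γ ∈ 2^{−15..3} (step 2 in the
exponent); the criterion is mean F1 over stratified folds, ties resolved
toward the smallest C then the smallest γ, so selection is deterministic
for a fixed seed. Features are z-scored with parameters fit on training
data only and refit inside every fold (RBF kernels are scale-sensitive);
min-max and no scaling are selectable. Classes are unweighted by default
(the canonical sets are near-balanced). A decision score of exactly 0
predicts the positive class. Cross-validation pools confusion counts over
folds (per-fold reports are attached for fold-averaging); ROC/AUC uses
raw decision scores with tied scores grouped into one threshold step,
which makes the trapezoidal area identical to the Mann–Whitney statistic
U/(n⁺n⁻). Trained models persist as JSON (support vectors, dual
coefficients, bias, kernel width, scaler); the decision function is
evaluated from the stored arrays, so a reloaded model reproduces scores
bit-identically.

The random baseline predicts positive a uniformly random subset of size
n⁺ against fixed labels with n⁺ positives. Then P = R = F1 = TP/n⁺ per
replicate and E[TP] = n⁺²/n, giving mean F1 ≈ n⁺/n — for 182 of 377,
0.4827, i.e. 0.48 at two decimals. Group comparisons (e.g. conservation
of hot vs non-hot spots) use Welch's t-test by default, with Mann–Whitney
as the rank-based option; the test used is echoed in the report.

## Synthetic data

The generators define the package's test conditions.

*Toy complexes* are two idealized extended chains (3.8 Å Cα spacing) at a
controllable gap, with salt bridges (Lys NZ / Glu OE1) and hydrogen bonds
(Ser OG / backbone O) placed at exact requested distances. Geometry is
not rotamer-realistic; every geometric feature depends only on
interatomic distances, which the generator controls directly.

*Feature datasets* plant a standardized mean shift d on the columns of
chosen informative groups over unit-variance Gaussian noise, with
configurable prevalence (default 182/377, exact in fixed-count mode).
Unit Gaussian noise is the test model, not a biological claim: passing
recovery tests shows the estimation machinery works (chance AUC at d = 0,
monotone AUC in d, F1 > 0.9 at d = 3 with n = 400; ablation finds the
planted group), not that real interfaces are this separable — real
feature columns are correlated, heavy-tailed and partially missing.

*Mutation tables* reproduce the canonical published composition of the
two alanine-scanning sets — 377 training rows of which 84 have
ΔΔG ≥ 2 kcal/mol and 182 have ΔΔG ≥ 1; 148 categorical test rows of
which 80 are Strong/Intermediate — with synthetic residue identities.
ΔΔG values are drawn uniformly within each band and rounded away from
the thresholds, so only the marginal counts are meaningful.

*MSAs/PSSMs* have designated invariant columns (entropy 0, fallback
grade 9) and uniform free columns (entropy → 100 as the number of
sequences grows), and self-substitution-boosted integer scores in the
PSI-BLAST ASCII dialect.

All generators are deterministic under a fixed seed.

## Problem sizes and numerical conventions

Default desk-scale protocol: signal-recovery runs use n = 400 rows, 10
folds, 20 seeds and a fixed (C, γ) = (1, 1/36); grid searches in examples
use a reduced 4 × 3 grid. These sizes are the package's test conditions,
chosen so a full run completes in minutes on one CPU; the full default
grid is available for real analyses. Monotonicity checks on
cross-validated AUC allow a 0.03 slack per step, the fold-resampling
noise floor at n = 400. Quadrature noise tolerance on ΔASA is 0.1 Å²
at ≥ 240 sphere points.

## Known limitations

- Conservation grades from the entropy fallback are weaker than
  phylogenetic rates; treat ECS features from the fallback as
  approximations.
- The hydrogen-bond criterion is purely geometric; bifurcated or
  water-mediated bonds are not modelled.
- mmCIF input, biological-assembly generation and structure download are
  out of scope; partner chain groups must be supplied by the user.
- Feature extraction loops per residue over partner atoms; very large
  complexes (> ~10⁴ atoms) will be slow at 960 sphere points.
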