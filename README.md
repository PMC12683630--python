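# mbpip

Transferable many-body permutationally-invariant-polynomial (MB-PIP)
potentials with delta-machine-learning correction, for two-element chain
molecules — linear alkanes C<sub>n</sub>H<sub>2n+2</sub> being the
reference case.

## The problem

Whether a linear alkane prefers the extended chain or the self-folded
hairpin is decided by intramolecular dispersion, which cheap
electronic-structure surfaces describe poorly or not at all.  A practical
route to coupled-cluster-quality conformational energetics is to fit a
cheap *low-level* surface V<sub>LL</sub> on abundant data, then fit a small
*correction* surface ΔV on a modest number of expensive-minus-cheap energy
differences and evaluate their sum:

    V_corrected = V_LL + ΔV

Both surfaces use the same architecture: a many-body expansion over atoms
as bodies,

    V = Σᵢ V¹ᵇ(i) + Σ_{i<j} V²ᵇ(i,j) + Σ_{i<j<k} V³ᵇ(i,j,k) + Σ_{i<j<k<l} V⁴ᵇ(i,j,k,l),

with each n-body term typed by its element composition (CC, CH, HH; CCC …
HHH; CCCC … HHHH) and expressed as a linear combination of permutationally
invariant polynomials (PIPs) in Morse variables y<sub>ij</sub> =
exp(−r<sub>ij</sub>/λ).  Six symmetry types (PAIR, A₃, A₂B, A₄, A₃B, A₂B₂)
cover every composition; all coefficients are solved in one overdetermined
linear least-squares fit.  Physical range cutoffs limit the number of
contributing tuples, and energies and analytic gradients are exactly
invariant under permutations of like atoms (bitwise, by construction).

Because the correction targets span a far smaller energy range than the raw
high-level data, the reference correction basis is compact: polynomial
orders 6/7/5 for 2-/3-/4-body terms, 383 coefficients in total.

A fully specified synthetic reference system (an alkane chain builder plus
a two-level toy force field whose levels differ by exactly a damped r⁻⁶
dispersion sum) makes the entire pipeline — fitting, correction,
conformer scans, NVE dynamics, vibrational power spectra — testable with
no external data.  See `docs/methods.md` for the model details and frozen
study conditions.

## Worked example

Fit a low-level surface to toy hexane data, then a delta correction to the
high-minus-low differences, from the shell:

```bash
mbpip make-toy-data --n-carbons 6 --level low  --frames 600 --sigma 0.05 --seed 7 --out train_low.xyz
mbpip make-toy-data --n-carbons 6 --level high --frames 600 --sigma 0.05 --seed 7 --out train_high.xyz
# pairs.txt: one "index E_high E_low" row per frame (hartree)
mbpip fit       --config specs.json --train train_low.xyz --model-out low.json
mbpip delta-fit --config specs.json --frames train_low.xyz --pairs pairs.txt --model-out delta.json
```

with `specs.json` declaring the twelve composition types at orders 6/7/5.
The two fits print:

```
n_train=600  n_coeff=383  rmse=40.95 cm-1  per-atom=2.048 cm-1  max|res|=227.1 cm-1  cond=2.59e+11
n_train=600  n_coeff=383  rmse=1.851 cm-1  per-atom=0.09257 cm-1  max|res|=5.936 cm-1  cond=2.59e+11
difference span = 0.007458 hartree (raw high-level span 0.124208)
```

The same 383-function basis that leaves a 41 cm⁻¹ residual on raw
energies fits the energy *differences* to 1.9 cm⁻¹, because the
difference data span ~17× less energy — the premise of the delta
correction in one pair of numbers.

The same workflow as a library, scored against the toy ground truth:

```python
from mbpip.workflows import toy_delta_study
study = toy_delta_study(seed=1)
print(study.gap_stacked_train, study.gap_true_train)        # +2.400  +2.357 kcal/mol (C9)
print(study.gap_stacked_transfer, study.gap_true_transfer)  # +2.460  +2.218 kcal/mol (C10, unseen)
```

The stacked surface reproduces the reference hairpin−linear gap to 0.04
kcal/mol at the training length and 0.24 kcal/mol transferred to a chain
length no fit ever saw.

Other entry points: `mbpip scan` (hairpin−linear gap vs chain length, with
crossover detection), `mbpip md` (NVE, zero total angular momentum,
default step 5.0 au), `mbpip spectrum` (velocity-autocorrelation power
spectra averaged over trajectories), `mbpip basis-counts`, `mbpip convert`.

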