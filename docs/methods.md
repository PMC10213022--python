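# Methods

## Scope and model

The package models CO₂ solubility `x` (mol CO₂ / mol DES) in
choline-chloride deep eutectic solvents at ChCl:HBD molar ratios 1:3 and
1:4 as

```
ln(x) = a·ln(P) + b·T + c·D + d,        D = EEig02d(HBD)
```

with `P` in bar (P > 0), `T` in K, and `D` a dimensionless structural
descriptor of the hydrogen-bond donor. The ln–ln pressure relation is
near-linear with slope ≈ 1 across the data window (0.5–5.9 bar, 293–323 K),
temperature enters linearly with a negative coefficient, and `D` carries
the entire donor dependence. The 22 published coefficient sets (1:3 and
1:4, pooled-temperature and per-temperature, with and without the
descriptor) are transcribed into a frozen registry; the printed `±`
half-widths are stored as coefficient standard uncertainties (their
magnitudes are consistent with OLS standard errors) and are metadata only.

## The descriptor

`EEig02d` is computed on the hydrogen-depleted molecular graph. Edges are
the heavy-atom bonds; the edge-adjacency matrix `EA(G)` has entry
`(i, j) = 1` when bonds `i` and `j` share an atom, zero otherwise and on
the diagonal. Aromatic rings keep the aromatic bond class (no
kekulization), so all six benzene ring bonds are equivalent and the
descriptor is resonance-symmetric. Atom order is canonicalised at parse
time and bonds are sorted by `(min endpoint, max endpoint)`, making every
matrix reproducible; all descriptors are invariant under atom relabeling
(tested with random permutations).

Dipole weighting supports three conventions:

* **diagonal** — off-diagonal entries stay 0/1 and the diagonal entry
  `(i, i)` is bond i's dipole moment (Estrada's weighted edge matrix);
* **symmetric** — `(i, j) = √(wᵢwⱼ)` for adjacent bonds;
* **literal** — `(i, j) = wⱼ`, generally asymmetric. Since
  `A·diag(w)` is similar to `diag(w)^½·A·diag(w)^½`, literal and symmetric
  always share a spectrum; ties in calibration therefore resolve to
  symmetric, whose matrix is guaranteed real-symmetric.

`EEig0k` is the k-th largest eigenvalue in algebraic order (ties broken by
position — equal eigenvalues are interchangeable and leave the descriptor
unchanged). `ESpm0k` is the trace of the k-th matrix power; its log form is
`ln(1 + trace)`, with `1 + trace` floored at 1e−12 for the degenerate
odd-order weighted cases. The `ln(1 + x)` transform was identified by
requiring the packaged second-moment reference values to be reproduced;
it does so to the printed precision for every decodable donor.
Molecules with fewer than `k` bonds have no `EEig0k`: this is an explicit
error, not a zero, to avoid silently feeding degenerate structures into
the solubility models.

### Convention calibration and the bond-dipole table

The software that produced the reference descriptor values did not
document its matrix convention, so `calibrate_convention` evaluates all
three on the donors whose reference EEig02d is unambiguous
(1,2-propanediol, 1,4-/2,3-butanediol, diethylene glycol, guaiacol,
phenol) and picks the convention minimising the maximum absolute
deviation. With the shipped table the **diagonal** convention wins by a
wide margin (max deviation 5·10⁻⁴ versus ≈ 2 for the alternatives) and is
the package default.

The bond-dipole table (Debye) ships as an editable CSV
(`src/desqspr/data/bond_dipoles.csv`); it is calibration data, not code.
Only relative magnitudes enter the spectrum, so the Debye values are used
without normalisation. The load-bearing entries are:

| bond | weight (D) | status |
|---|---|---|
| C–C (all classes) | 0 | fixed by symmetry |
| C–O single | 0.86 | reproduces all six calibration donors to ≤ 6·10⁻⁴, plus triethylene glycol |
| C–O aromatic (in-ring, furan) | 0.476 | pinned jointly by furfuryl alcohol's eigenvalue and second-moment references — two independent equations, one parameter |
| C=O | 2.40 | classic bond-moment value; not descriptor-validated (see conflicts) |

Remaining rows (C–N, C–S, halogens …) are standard bond-moment table
values for generality and are not validated against any reference.

### Reference-table conflicts

The two source tables disagree on EEig02d for five of the nine donors. The
computed values show the disagreement is a row-label permutation in the
candidate-descriptor table (phenol → guaiacol → furfuryl alcohol 3-cycle,
levulinic acid ↔ triethylene glycol swap): the same permutation
simultaneously explains both its EEig02d and ESpm02d columns, and the
running text independently supports the summary-table values for guaiacol
(1.983) and phenol (1.521). The packaged reference carries both candidates
with the summary-table value marked authoritative. One donor resists
reconciliation: levulinic acid (the only donor with C=O bonds) computes to
3.312 with C=O = 2.40 D; its eigenvalue reference implies C=O ≈ 2.68 D
while its second-moment reference implies ≈ 2.54 D, so no single weight
satisfies both and the literature value ships instead. Levulinic acid,
triethylene glycol and furfuryl alcohol are excluded from convention
calibration.

## Regression and validation statistics

With `n` observations, `p` regressors (intercept excluded), SSE the
residual sum of squares and SST the centred total sum of squares:

* `R² = 1 − SSE/SST`; `R²adj = 1 − (1 − R²)(n − 1)/(n − p − 1)`
* `S = √(SSE/(n − p − 1))` (standard error of regression)
* `F = (R²/p)/((1 − R²)/(n − p − 1))` — this convention reproduces the
  published F values at the published R² and plausible n, and the
  `F ↔ R²` identity is enforced to 1e−8
* `RMSE = √(SSE/n)`
* `Q²LOO = 1 − PRESS/SST` with deleted residuals from the hat-matrix
  shortcut `e᷈ᵢ = eᵢ/(1 − hᵢ)`; verified against an explicit
  leave-one-out refit loop to 1e−10
* `AARD% = (100/n)·Σ|predᵢ − obsᵢ|/|obsᵢ|`, on the ln scale or, after
  exponentiation, on the natural scale. AARD is non-negative by
  definition; published non-log "AARD" entries are negative, which this
  formula cannot produce, so those numbers are not chased.

Test-set R² uses `1 − SSE/SST` about the *test* mean (the squared-
correlation alternative is deliberately not used; the sum-of-squares form
matches the near-unity published test values). External validation
requires at least two test points.

The applicability domain follows the Williams plot: leverage `hᵢ` from the
hat-matrix diagonal of the intercept-augmented design, warning leverage
`h* = 3(p + 1)/n`, standardized residual `eᵢ/S` without leverage
correction (matching the plain "standard residuals" label; a studentized
variant is selectable). Points are flagged response outliers beyond ±3
standardized residuals and structurally influential beyond `h*`.

The Golbraikh screen (`R² > 0.6` and `Q² > 0.5`) is available as a boolean
filter for one-descriptor candidate comparisons.

## Descriptor selection

`ga_select` is a small generational genetic algorithm over bit-strings on
the candidate descriptor columns: population 50, 100 generations,
tournament selection of size 3, one-point crossover at rate 0.8, bit-flip
mutation at rate 0.05, one elite, and a repair step enforcing at most one
free descriptor beyond the forced physical columns (lnP, and T in the
pooled-temperature mode) — the published models contain exactly one
structural descriptor. Fitness is Q²LOO of the OLS fit on forced +
selected columns (R² selectable). Subset fitnesses are memoized, the seed
is mandatory, and identical seeds give identical selections.

## Synthetic data

The generator emulates the study design rather than any single published
measurement: by default, 9 donors × 4 temperatures (293–323 K) × 5
pressures log-spaced over the published 0.515–5.853 bar window, responses
from the pooled-temperature 1:3 generating law with the published
coefficients, and Gaussian noise σ = 0.1 on ln(x) — the magnitude of that
model's published regression standard error. What it reproduces: the
grid structure, dynamic range and noise level of the real tables, exact
ln-linearity in the generating variables. What it does not: per-donor
pressure windows (the real compilation truncates differently per donor),
replicate structure and inter-laboratory offsets, any deviation from
ln-linearity at high pressure. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated law, not that
the law holds for new chemistry.

## Numerical choices and degeneracies

* Eigenvalues of symmetric matrices use the symmetric eigensolver;
  asymmetric (literal) matrices fall back to the general solver and any
  selected eigenvalue with imaginary part above 1e−8 is an error.
* `Q²` requires all leverages < 1 and a non-constant response.
* Rank-deficient designs, n ≤ p + 1, zero observations in AARD, empty or
  all-covering donor holdouts, and solubility/pressure values ≤ 0 are
  explicit errors.
* CSV round trips use round-trip float parsing, so write → read preserves
  every numeric value exactly.
* The PCA holdout advisory standardises descriptor columns, projects on
  up to two principal axes and ranks donors by distance from the centroid,
  tie-broken by name for determinism. It is advisory: published splits
  (diethylene glycol alone, or furfuryl alcohol + diethylene glycol) are
  available directly through `split_by_hbd`.

## Known limitations

* The levulinic acid reference value cannot be reproduced under any single
  C=O weight (see conflicts above); its computed descriptor (3.312) lies
  between the two printed candidates.
* 3-D descriptors appearing in the candidate comparison (H6m, RDF065u,
  RTm) are packaged as reference numbers only and are never computed — the
  package is deliberately 2-D (no geometry optimisation).
* The per-point experimental tables are not redistributable; full refits
  of the published equations require the optional supplementary
  spreadsheet (dropped at `supplementary/per_point_data.xlsx`), and the
  train/test composition of the pooled-temperature datasets is not
  published, so those rows are not exactly reproducible even with it.
* Models interpolate between the 1:3 and 1:4 ratios in no principled way;
  no interpolation is offered.
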