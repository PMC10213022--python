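# desqspr

QSPR modeling of CO₂ solubility in choline-chloride (ChCl) deep eutectic
solvents (DESs), driven by a single structural descriptor of the
hydrogen-bond donor (HBD): **EEig02d**, the second-largest eigenvalue of the
molecule's dipole-moment-weighted edge-adjacency matrix.

The package is for researchers screening DES formulations for CO₂ capture:
it predicts how much CO₂ a ChCl:HBD eutectic dissolves at a given pressure
and temperature directly from the donor's 2-D structure, and it ships the
full model-building workflow so the equations can be refitted, validated
and extended on new data.

## The model

CO₂ solubility `x` (mol CO₂ / mol DES) follows a ln-linear law

```
ln(x) = a·ln(P) + b·T + c·EEig02d + d
```

with `P` in bar, `T` in K, `a > 0`, `b < 0`, `c > 0`. The registry contains
22 published fits of this family — three-variable models across 293–323 K
for the 1:3 and 1:4 ChCl:HBD molar ratios, two-variable models at each
fixed temperature, and the pressure-only baselines.

`EEig02d` comes from the hydrogen-depleted molecular graph: the
edge-adjacency matrix `EA(G)` has entry 1 when two bonds share an atom;
weighting places each bond's dipole moment (Debye) on the diagonal
(Estrada's weighted edge matrix), and the descriptor is the second
eigenvalue in descending order. Donors with longer chains and more ether
oxygens score higher, tracking free volume and hence physical CO₂
absorption.

The model-building layer reproduces the workflow behind those fits:
ordinary least squares with the QSPR statistics block (R², R²adj, S, F,
RMSE, Q²LOO, AARD%), donor-wise train/test splitting with a PCA advisory,
genetic-algorithm descriptor selection, and Williams-plot applicability
domain analysis (leverage vs standardized residuals, h* = 3(p+1)/n).

## Worked example

```python
from desqspr import (BondDipoleTable, PredictionInput, eigen_descriptor,
                     parse_structure, predict_x, select_model,
                     weighted_edge_adjacency)

glycerol = parse_structure("OCC(O)CO", "Glycerol")
D = eigen_descriptor(weighted_edge_adjacency(glycerol, BondDipoleTable.default()), 2).value
model = select_model("1:3", 298.0, "auto")
result = predict_x(model, PredictionInput(P_bar=2.0, T_K=298.0, eeig02d=D))
print(D, result.eq_id, result.x)
```

prints `EEig02d = 1.2956`, model id `7` (the unfixed-temperature 1:3
equation, because 298 K matches no fixed-temperature fit) and
`x = 0.0060 mol CO₂ / mol DES` — glycerol at 2 bar and 25 °C dissolves
about 0.6 mol % CO₂ per mole of DES. Out-of-range conditions are flagged
(`result.temperature_extrapolated`, `result.pressure_extrapolated`), never
refused. The `examples/` directory has one short script per capability:
descriptor computation, prediction, model rebuilding with validation, and
GA descriptor selection.

There is also a thin CLI:

```
desqspr describe donors.smi -o descriptors.csv
desqspr predict 1:3 298 2.0 "OCC(O)CO"
desqspr simulate spec.json --seed 7 -o synthetic.csv
desqspr fit synthetic.csv -o report.json --holdout "Furfuryl alcohol,Diethylene glycol"
```

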