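"""Predict CO2 solubility in a ChCl:glycerol 1:3 deep eutectic solvent.

Glycerol is not among the donors the models were trained on, so this is the
external-prediction use case: the descriptor is computed from the structure
on the fly, the model is auto-selected for the ratio and temperature, and
extrapolation beyond the training window is flagged, not refused.
"""

from desqspr import (
    BondDipoleTable,
    PredictionInput,
    eigen_descriptor,
    parse_structure,
    predict_x,
    select_model,
    weighted_edge_adjacency,
)

glycerol = parse_structure("OCC(O)CO", "Glycerol")
dipoles = BondDipoleTable.default()
descriptor = eigen_descriptor(weighted_edge_adjacency(glycerol, dipoles), 2).value
print(f"EEig02d(glycerol) = {descriptor:.4f}")

for T, P in [(298.0, 2.0), (333.0, 10.0)]:
    model = select_model("1:3", T, "auto")
    result = predict_x(model, PredictionInput(P_bar=P, T_K=T, eeig02d=descriptor, ratio="1:3"))
    note = []
    if result.temperature_extrapolated:
        note.append("T outside 293-323 K")
    if result.pressure_extrapolated:
        note.append("P outside the training range")
    flag = f"  [extrapolating: {', '.join(note)}]" if note else ""
    print(f"T={T:.0f} K, P={P:4.1f} bar -> model {result.eq_id}: "
          f"x = {result.x:.4f} mol CO2 / mol DES (ln x = {result.ln_x:.3f}){flag}")

print("\nSolubility grows roughly linearly with pressure on the log-log scale")
print("(a ~ 1) and falls with temperature; the 333 K prediction is an")
print("extrapolation the applicability-domain analysis should accompany.")
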