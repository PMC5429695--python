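"""Single-site ITC: simulate a titration and recover its thermodynamics.

Simulates 28 x 10 µL injections with the wild-type CohScaB3-Doc1a
parameters (Ka = 1.18e8 M⁻¹, ΔH = -50.68 kcal/mol, n = 1) at Wiseman
c ≈ 100 with 1% heat noise, fits the 1:1 model, and prints the recovered
block in the layout thermodynamic tables use.
"""

import numpy as np

from cohdoc import (
    ThermoParams,
    fit_single_site,
    model_heats,
    protocol_for_c_value,
    simulate_titration,
)

truth = ThermoParams(n=1.0, Ka=1.18e8, dH=-50.68)
protocol = protocol_for_c_value(truth, c_value=100.0)
noise_sd = 0.01 * np.abs(model_heats(protocol, truth)).max()
dataset = simulate_titration(protocol, truth, noise_sd=noise_sd, seed=1)

fit = fit_single_site(dataset)
p = fit.params
print(f"simulated 28 injections at T = {protocol.temperature:.0f} K, "
      f"cell {protocol.cell_conc * 1e6:.2f} µM, noise {noise_sd:.2f} µcal")
print()
print(f"N    {p.n:8.3f} ± {p.n_se:.3f}   sites per macromolecule")
print(f"Ka   {p.Ka:8.3e} ± {p.Ka_se:.2e} M^-1   (true 1.18e+08)")
print(f"ΔG°  {fit.dG:8.2f} kcal/mol")
print(f"ΔH   {p.dH:8.2f} ± {p.dH_se:.2f} kcal/mol   (true -50.68)")
print(f"TΔS° {fit.TdS:8.2f} kcal/mol")
print()
print("ΔG = -RT·ln(Ka) and TΔS = ΔH - ΔG hold exactly by construction;")
print("enthalpy-driven binding with an entropic penalty, as for these complexes.")
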