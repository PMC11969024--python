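"""Fit dose-response curves and report potency as pEC50/pEC80/pIC50.

Simulates a noisy inhibitor dose-response, fits the 3-parameter log-logistic
model with the lower asymptote fixed at zero, and converts the midpoint to
pIC50; also demonstrates the desensitization exclusion on agonist data.
"""

import numpy as np

import mutascan as m

doses = np.logspace(-9.5, -5.5, 8)

# inhibitor curve with true IC50 = 4.5e-7 M (pIC50 = 6.35)
cfg = m.ChemotaxisSimConfig(b=1.0, c=0.0, d=100.0, e=4.5e-7, noise_sd=4.0, seed=5)
data = m.simulate_chemotaxis(cfg, doses)
fit = m.fit_ll3(data, mode="IC")
pot = m.summarize_potency(fit)
print(f"fitted IC50 = {fit.e:.3e} M -> pIC50 = {pot.pic50:.2f} (truth 6.35)")

# agonist curve with receptor desensitization at the top dose
ag_doses = np.array([1e-10, 1e-9, 3e-9, 1e-8, 1e-7, 1e-6])
responses = np.array([4.0, 26.0, 50.0, 74.0, 100.0, 60.0])
ag = m.DoseResponseData(ag_doses, responses)
kept = m.exclude_desensitized(ag)
print(f"desensitization exclusion kept doses: {sorted(set(kept.doses))}")
fit_ec = m.fit_ll3(kept, mode="EC")
print(f"EC50 = {fit_ec.e:.3e} M, EC80 = {m.derive_ecf(fit_ec, 80.0):.3e} M")
# pX = -log10(molar X); EC80 comes from the fitted curve's closed form
# x = e * ((100 - f) / f) ** (1 / b).
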