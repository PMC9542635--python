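"""Fit a one-site specific binding curve to a synthetic ELISA dataset.

Generates saturation-binding responses at a true Kd of 106.10 nM (5% Gaussian
noise, 3 replicates, 8 log-spaced concentrations) and recovers Kd and Bmax by
nonlinear least squares.
"""

from capscan import fit_one_site
from capscan.fixtures import generate_elisa_dataset

df = generate_elisa_dataset(kd_nm=106.10, bmax=1.0, noise_sd=0.05,
                            replicates=3, seed=42)
fit = fit_one_site(df.concentration_nM.to_numpy(), df.response.to_numpy())

print(f"n points          : {len(df)}")
print(f"fitted Kd         : {fit.kd_nm:.2f} nM  (true 106.10)")
print(f"fitted Bmax       : {fit.bmax:.3f}")
print(f"R^2               : {fit.r_squared:.4f}")
print(f"SE(Kd), asymptotic: {fit.se_kd_nm:.2f} nM")
print("\nKd is the concentration at half-maximal response of the")
print("y = Bmax*x/(Kd+x) saturation model, fitted jointly over replicates.")
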