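"""Ensemble alanine scan of a designed synthetic complex.

Builds a 20-model two-chain complex with three engineered cross-chain
contacts of known strength (salt bridge > hydrogen bond > nonpolar), runs the
ensemble alanine scan, and prints the ranked hot-spot table.
"""

from capscan import alanine_scan_ensemble, binding_free_energy
from capscan.fixtures import generate_complex_ensemble, preset_charge_hbond_np

ens = generate_complex_ensemble(
    preset_charge_hbond_np(), n_models=20, jitter_sd=0.2, seed=7
)
print(f"ensemble: {ens.n_models} poses, DG(pose 0) = "
      f"{binding_free_energy(ens, 0):.2f} kJ/mol\n")

print(f"{'residue':>10s} {'name':>4s} {'DDG mean':>9s} {'SD':>6s} {'rank':>4s}")
for r in sorted(alanine_scan_ensemble(ens, side='receptor'),
                key=lambda r: r.rank or 99):
    print(f"{str(r.residue):>10s} {r.res_name:>4s} {r.ddg_mean:9.2f} "
          f"{r.ddg_sd:6.2f} {r.rank:4d}")

print("\nDDG > 0 means truncating the side chain to alanine weakens binding;")
print("the salt bridge ranks first, the lone nonpolar contact last, as designed.")
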