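"""Piecewise TIP fit of a noisy synthetic DPPC-like isotherm.

Generates the packaged three-region 25 C reference with 0.02 mN/m Gaussian
noise, refits each region with the integer-exponent search, and prints the
recovered parameters next to the generating truth.
"""

from tipiso import fit_tip_piecewise
from tipiso.io import format_fit_table
from tipiso.synthetic import dppc_reference

ref = dppc_reference("25C", n_per_region=50, noise_sigma=0.02, seed=42)
fits = fit_tip_piecewise(ref.isotherm, ref.spec.region_specs())

print("Recovered parameters (noise sigma = 0.02 mN/m):\n")
print(format_fit_table(fits))
print("Generating truth:")
for phase, params in ref.spec.params_by_phase().items():
    print(f"  {phase:<18} p={params.p}  k1={params.k1}  k2'={params.k2prime}")
print(
    "\nThe condensed and expanded branches recover their exponents and\n"
    "coefficients within a few standard errors.  The coexistence plateau is\n"
    "generated with p=1, where the power-law term degenerates to 1/a_L:\n"
    "every exponent fits such data equally well, so its selected p is\n"
    "noise-determined and only the sum k1+k2' is meaningful there."
)
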