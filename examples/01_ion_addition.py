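"""Ion counts for a charged protein box: neutrality at bulk ionic strength.

Given a protein of average charge Z in a solvent volume V at bulk ionic
strength I, solve for the numbers of monovalent cations and anions that
make the box neutral while keeping the ionic strength at I, and report
the resulting whole-box ion excesses.
"""

from ionatmos import ion_addition
from ionatmos.constants import LITRE_PER_A3

Z = 12.0          # protein charge, e (a basic protein at low pH)
I = 0.1           # bulk ionic strength, M
V = 216000 * LITRE_PER_A3  # solvent volume of a 60 Å box, litres

sol = ion_addition(Z, I, V)
print(f"protein charge Z = {Z:+.1f} e, I = {I} M, V = {V:.3e} L")
print(f"cations  N+ = {sol.n_plus:.3f}  -> {sol.n_plus_int}")
print(f"anions   N- = {sol.n_minus:.3f}  -> {sol.n_minus_int}")
print(f"excesses dN+ = {sol.excess_plus:+.3f}, dN- = {sol.excess_minus:+.3f}")
print(f"identity Z + dN+ - dN- = {Z + sol.excess_plus - sol.excess_minus:.2e}")

# The excesses are ∓Z/2: the ion atmosphere neutralizes the protein by
# splitting the compensation equally between counterion accumulation and
# co-ion depletion.  The printed identity is exactly zero before rounding.
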