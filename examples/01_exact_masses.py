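"""Exact-mass arithmetic: monoisotopic masses, adduct ions, mass error.

Computes the monoisotopic masses of the six built-in internal calibrants and
the m/z of a protonated and a sodiated ion, then shows the Δm (mDa)
convention used throughout: measured minus exact, in millidaltons.
"""

from specacc import (
    ADDUCTS,
    Formula,
    default_calibrants,
    ion_mz,
    mass_accuracy,
    monoisotopic_mass,
)

print("Internal calibrants (neutral monoisotopic masses):")
for cal in default_calibrants():
    print(
        f"  {cal.name:<22} {cal.neutral.hill():<15} "
        f"{monoisotopic_mass(cal.neutral):9.4f} Da   "
        f"{cal.adduct.name} -> m/z {cal.ion_mz:.4f}"
    )

neutral = Formula.parse("C13H19NO")
mz_h = ion_mz(neutral, ADDUCTS["[M+H]+"])
print(f"\n{neutral.hill()} + H+  -> m/z {mz_h:.4f}  (electron mass subtracted)")

neutral = Formula.parse("C14H27NO3")
mz_na = ion_mz(neutral, ADDUCTS["[M+Na]+"])
print(f"C14H27NO3 + Na+ -> m/z {mz_na:.4f}")

# a measurement 1.6 mDa above the exact mass
print(f"\nmass_accuracy(280.1899, {mz_na:.4f}) = "
      f"{mass_accuracy(280.1899, mz_na)} mDa")
print("Positive Δm: the measured centroid sits above the exact mass.")
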