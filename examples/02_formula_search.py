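"""Candidate formula enumeration at an accurate mass.

Enumerates every even-electron, singly charged ion composition within
±10 mDa of two measured masses under the default ESI+ element ranges
(C 2–25, H 0–50, N 0–10, O 0–10, Na 0–1, Cl 0–5; RDBE −0.5 to 20).
The candidate count is the denominator of the 'rank/possible formulas'
statistic; fewer candidates means the accurate mass alone is more
discriminating.
"""

from specacc import enumerate_candidates

for target in (206.1538, 280.1899):
    result = enumerate_candidates(target)
    print(f"m/z {target}: {len(result)} candidate formulas within ±10 mDa")
    for i, c in enumerate(result, start=1):
        print(
            f"  {i:>2}  {c.formula.hill():<16} exact {c.exact_mz:.4f}  "
            f"dm {c.delta_m_mda:+5.1f} mDa  RDBE {c.rdbe:4.1f}"
        )
    print()
print("Candidates are ordered by |dm|; spectral accuracy re-ranks them "
      "once a calibrated profile spectrum is available (example 05).")
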