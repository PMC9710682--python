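"""THSA/RHSA from a per-residue accessibility table (no structure needed).

When only a sequence-based accessibility prediction is available (e.g. a
NetSurfP-style per-residue ASA table), THSA is the summed predicted area
of the hydrophobic residues and RHSA that sum over the total.  The largest
patch cannot be derived this way - per-residue predictions carry no
surface adjacency - so LHP is reported as None.
"""

import pandas as pd

from molpatch.measures import measures_from_asa_table

table = pd.DataFrame(
    {
        "chain": ["A"] * 6,
        "position": range(1, 7),
        "aa": ["M", "K", "L", "D", "V", "S"],
        "asa": [45.0, 120.0, 20.0, 95.0, 15.0, 70.0],
    }
)

m = measures_from_asa_table(table)
print(f"THSA {m.thsa:.1f} A^2 (M+L+V rows), TASA {m.tasa:.1f} A^2")
print(f"RHSA {m.rhsa:.3f} (= {m.rhsa_percent:.1f}% of the surface is hydrophobic)")
print(f"LHP: {m.lhp}  (unavailable from per-residue predictions)")
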