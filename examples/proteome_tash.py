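"""Expression-weighted proteome hydrophobicity: curation, deciles and TASH.

Curates a toy annotation table (length, disorder and duplicate-gene
filters), bins genes into expression deciles, and computes the
tissue-specific average surface hydrophobicity - the NX-weighted mean of a
hydrophobicity measure over the genes expressed in a tissue.
"""

import numpy as np
import pandas as pd

from molpatch.proteome import (
    ProteinAnnotation,
    curate,
    decile_bins,
    gene_max_expression,
    tash_all_tissues,
)

annotations = [
    ProteinAnnotation("g1", length=400, disorder_fraction=0.1, thsa=3100.0),
    ProteinAnnotation("g2", length=801, disorder_fraction=0.1, thsa=5200.0),  # too long
    ProteinAnnotation("g3", length=400, disorder_fraction=0.7, thsa=2800.0),  # disordered
    ProteinAnnotation("g4", length=350, disorder_fraction=0.2, thsa=4100.0),
]
kept = curate(annotations)
print(f"curation kept {len(kept)}/{len(annotations)}: {[a.gene_id for a in kept]}")

rng = np.random.default_rng(0)
genes = [f"g{i:02d}" for i in range(20)]
expr = pd.DataFrame(
    [(g, t, float(rng.lognormal(1, 1))) for g in genes for t in ("brain", "liver")],
    columns=["gene_id", "tissue", "nx"],
)
per_gene = gene_max_expression(expr)
deciles = decile_bins(per_gene)
print(f"decile sizes: {sorted(deciles.value_counts())} (balanced to within one gene)")

thsa = pd.Series({g: float(rng.uniform(1500, 6000)) for g in genes})
print("TASH-THSA per tissue (NX-weighted mean THSA, A^2):")
print(tash_all_tissues(expr, thsa).round(1).to_string())
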