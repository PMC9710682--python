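"""Proteome-scale curation, expression deciles, ranked lists and TASH.

Operates on per-protein annotations (predicted hydrophobicity measures,
disorder, length) and a gene-by-tissue normalized-expression (NX) table in
the Human-Protein-Atlas consensus layout.  The tissue-specific average
surface hydrophobicity is the expression-weighted mean

    TASH_t = sum_g NX_{g,t} * h_g / sum_g NX_{g,t}

over the genes expressed in tissue t, for any hydrophobicity measure h.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

#: Curation thresholds: drop proteins longer than this or with more than
#: half their residues predicted disordered.
MAX_LENGTH = 800
MAX_DISORDER_FRACTION = 0.5


@dataclass(frozen=True)
class ProteinAnnotation:
    gene_id: str
    length: int
    disorder_fraction: float
    thsa: float = float("nan")
    rhsa: float = float("nan")
    lhp: float = float("nan")
    transmembrane: bool = False
    multimeric: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.disorder_fraction <= 1.0:
            raise ValueError("disorder_fraction must be within [0, 1]")


def curate(annotations: Iterable[ProteinAnnotation]) -> list[ProteinAnnotation]:
    """Remove unreliable predictions.

    Drops proteins with disorder fraction > 1/2, proteins longer than 800
    residues, and among duplicate gene ids keeps only the entry with the
    highest THSA (first encountered on ties).  Idempotent.
    """
    best: dict[str, ProteinAnnotation] = {}
    order: list[str] = []
    for ann in annotations:
        if ann.disorder_fraction > MAX_DISORDER_FRACTION:
            continue
        if ann.length > MAX_LENGTH:
            continue
        if ann.gene_id not in best:
            best[ann.gene_id] = ann
            order.append(ann.gene_id)
        elif ann.thsa > best[ann.gene_id].thsa:
            best[ann.gene_id] = ann
    return [best[g] for g in order]


def gene_max_expression(expr: pd.DataFrame, how: str = "max") -> pd.Series:
    """One expression value per gene: max (default) or median over tissues.

    ``expr`` has columns ``gene_id``, ``tissue``, ``nx``.
    """
    if expr.empty:
        raise ValueError("empty expression table")
    if how not in ("max", "median"):
        raise ValueError(f"unknown aggregation {how!r}")
    grouped = expr.groupby("gene_id", sort=False)["nx"]
    return grouped.max() if how == "max" else grouped.median()


def decile_bins(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """Assign each gene to an expression decile (1 = lowest NX).

    Bin sizes are equal to within one gene; ties are broken by the stable
    input order so the assignment is deterministic.
    """
    series = pd.Series(values)
    n = len(series)
    if n < 10:
        raise ValueError("need at least 10 genes for deciles")
    order = np.argsort(series.to_numpy(), kind="stable")
    sizes = [len(chunk) for chunk in np.array_split(np.arange(n), 10)]
    labels = np.empty(n, dtype=int)
    start = 0
    for d, size in enumerate(sizes, start=1):
        labels[order[start:start + size]] = d
        start += size
    return pd.Series(labels, index=series.index, name="decile")


def tash(
    expr: pd.DataFrame,
    h: Mapping[str, float] | pd.Series,
    tissue: str,
    exclude: Optional[set[str]] = None,
) -> float:
    """Tissue-specific average surface hydrophobicity for one tissue.

    Genes without a hydrophobicity value drop out of both sums; ``exclude``
    removes e.g. transmembrane-annotated genes before averaging.
    """
    rows = expr[expr["tissue"] == tissue]
    if rows.empty:
        raise ValueError(f"tissue {tissue!r} not present in expression table")
    h = pd.Series(h)
    if exclude:
        rows = rows[~rows["gene_id"].isin(exclude)]
    rows = rows[rows["gene_id"].isin(h.index)]
    weights = rows["nx"].to_numpy(dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"zero total expression in tissue {tissue!r}")
    values = h.loc[rows["gene_id"]].to_numpy(dtype=float)
    return float((weights * values).sum() / total)


def tash_all_tissues(
    expr: pd.DataFrame,
    h: Mapping[str, float] | pd.Series,
    exclude: Optional[set[str]] = None,
) -> pd.Series:
    """TASH for every tissue in the expression table, sorted descending."""
    out = {
        t: tash(expr, h, t, exclude=exclude)
        for t in expr["tissue"].unique()
    }
    return pd.Series(out, name="tash").sort_values(ascending=False)


def rank_for_gsea(
    values: Mapping[str, float] | pd.Series,
    center: Optional[float] = None,
    scale: Optional[float] = None,
) -> pd.Series:
    """Centred/scaled scores sorted descending, ready for preranked GSEA.

    Center defaults to the median and scale to the standard deviation; the
    center is overridable because the choice of split point (e.g. between
    modes of a bimodal distribution) is dataset-dependent.  Output is a
    gene -> score series writable as a 2-column ``.rnk`` file.
    """
    series = pd.Series(values, dtype=float)
    if len(series) < 2:
        raise ValueError("need at least two genes")
    if series.nunique() < 2:
        raise ValueError("constant values cannot be ranked")
    c = float(series.median()) if center is None else float(center)
    s = float(series.std(ddof=0)) if scale is None else float(scale)
    if s <= 0:
        raise ValueError("scale must be positive")
    scores = (series - c) / s
    return scores.sort_values(ascending=False, kind="stable")


def write_rnk(scores: pd.Series, path) -> None:
    """Write a ranked gene list as 2-column tab-separated (.rnk) text."""
    scores.to_csv(path, sep="\t", header=False)
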