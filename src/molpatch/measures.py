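"""Aggregate per-residue surface areas into the three hydrophobicity measures.

THSA  total hydrophobic surface area: summed accessible surface area (ASA)
      of the hydrophobic residues {A, C, F, I, L, M, V, W, Y}, in A^2.
RHSA  relative hydrophobic surface area: THSA / TASA (fraction).
LHP   largest hydrophobic patch area, in A^2 (structure input only).
TASA  total accessible surface area of all residues, in A^2.

Works either from a 3D structure (internal surface sampling) or from a
per-residue ASA table such as the output of a sequence-based accessibility
predictor (NetSurfP-style), in which case LHP is unavailable because
residue adjacency on the surface is unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .structure_io import HYDROPHOBIC_RESIDUES, STANDARD_AA, StructureModel
from .surface import SurfaceParams, compute_point_cloud, residue_asa
from .patch_finder import find_patches

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HydrophobicityMeasures:
    thsa: float
    rhsa: float          # fraction in [0, 1]
    tasa: float
    lhp: Optional[float]  # None when computed from a per-residue ASA table
    source: str          # "structure" | "predicted"

    @property
    def rhsa_percent(self) -> float:
        return 100.0 * self.rhsa

    def to_dict(self) -> dict:
        return {
            "thsa": self.thsa,
            "rhsa": self.rhsa,
            "tasa": self.tasa,
            "lhp": self.lhp,
            "source": self.source,
        }


def measures_from_structure(
    model: StructureModel, params: SurfaceParams | None = None
) -> HydrophobicityMeasures:
    """Compute THSA/RHSA/TASA/LHP from one structure with shared geometry.

    The point cloud behind the per-residue ASAs is the same one used for
    patch detection, so LHP <= THSA <= TASA holds by construction.
    """
    params = params or SurfaceParams()
    cloud = compute_point_cloud(model, params)
    asa = residue_asa(cloud, model)
    residues = model.residues()
    tasa = sum(asa.values())
    if tasa <= 0:
        raise ValueError("total accessible surface area is zero")
    thsa = sum(asa[i] for i, r in enumerate(residues) if r.hydrophobic)
    lhp_area = find_patches(cloud, params).lhp_area
    return HydrophobicityMeasures(
        thsa=thsa, rhsa=thsa / tasa, tasa=tasa, lhp=lhp_area, source="structure"
    )


def measures_from_asa_table(table: pd.DataFrame) -> HydrophobicityMeasures:
    """Compute THSA/RHSA from a per-residue predicted-ASA table.

    Expects columns ``aa`` (one-letter code) and ``asa`` (A^2).  Rows with
    non-standard codes are skipped with a logged count.  LHP is None:
    surface adjacency cannot be derived from per-residue predictions.
    """
    if table.empty:
        raise ValueError("empty ASA table")
    ok = table["aa"].isin(sorted(STANDARD_AA))
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("skipping %d rows with non-standard residue codes", n_skipped)
    table = table[ok]
    tasa = float(table["asa"].sum())
    if tasa <= 0:
        raise ValueError("total predicted surface area is zero")
    thsa = float(table.loc[table["aa"].isin(sorted(HYDROPHOBIC_RESIDUES)), "asa"].sum())
    return HydrophobicityMeasures(
        thsa=thsa, rhsa=thsa / tasa, tasa=tasa, lhp=None, source="predicted"
    )


def read_asa_table(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a per-residue ASA table.

    ``tsv``: tab-separated with header ``chain position aa asa [disorder]``.
    ``netsurfp``: NetSurfP-2.0 CSV export column naming (``chain``, ``n``,
    ``seq``, ``asa``, and ``disorder`` if present).
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
    elif dialect == "netsurfp":
        df = pd.read_csv(path)
        df = df.rename(
            columns={"n": "position", "seq": "aa", "rsa": "relative_asa"}
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    required = {"aa", "asa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ASA table missing column(s): {sorted(missing)}")
    return df
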