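"""Deterministic synthetic structures and tables for tests and examples.

Synthetic "structures" use one atom per residue so that surface areas and
patch topology are analytically checkable: a lone atom's accessible area
is exactly 4*pi*(r+probe)^2, two atoms far apart give two disjoint clouds,
and a tightly packed line of atoms gives one connected surface.  An H in
the hydrophobicity pattern becomes an alanine-like (hydrophobic) residue,
a P an aspartate-like (hydrophilic) one.  Full-residue ALA/ASP fixtures
are provided separately for parser realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .evaluation import PredictionRecord
from .structure_io import AtomRecord, ResidueRecord, StructureModel, write_pdb
from .surface import sample_sphere

#: United-atom-style radius for single-atom pseudo-residues (Angstrom).
PSEUDO_ATOM_RADIUS = 1.9


@dataclass(frozen=True)
class FixtureSpec:
    kind: str                     # single_atom | two_atom | shell | pseudo_chain
    n_residues: int = 1
    hydrophobic_pattern: str = "H"
    spacing: float = 5.0          # Angstrom between consecutive residues
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.hydrophobic_pattern) - {"H", "P"}:
            raise ValueError("pattern may only contain H and P")
        if len(self.hydrophobic_pattern) != self.n_residues:
            raise ValueError("pattern length must equal n_residues")


def _residue(chain: str, idx: int, code: str, coords, radius: float) -> ResidueRecord:
    aa = "A" if code == "H" else "D"
    atom = AtomRecord(
        serial=idx,
        name="CB" if code == "H" else "OD1",
        element="C" if code == "H" else "O",
        coords=np.asarray(coords, dtype=float),
        vdw_radius=radius,
    )
    return ResidueRecord(
        chain_id=chain,
        seq_number=idx,
        insertion_code="",
        aa=aa,
        hydrophobic=(code == "H"),
        atoms=[atom],
    )


def make_structure(
    spec: FixtureSpec,
    pdb_path: Optional[str | Path] = None,
    atom_radius: float = PSEUDO_ATOM_RADIUS,
) -> StructureModel:
    """Build a deterministic synthetic structure model (optionally write PDB)."""
    residues: list[ResidueRecord] = []
    if spec.kind == "single_atom":
        residues.append(_residue("A", 1, spec.hydrophobic_pattern[0], (0, 0, 0), atom_radius))
    elif spec.kind == "two_atom":
        if spec.n_residues != 2:
            raise ValueError("two_atom fixture needs exactly 2 residues")
        for i, code in enumerate(spec.hydrophobic_pattern, start=1):
            residues.append(_residue("A", i, code, ((i - 1) * spec.spacing, 0, 0), atom_radius))
    elif spec.kind == "pseudo_chain":
        for i, code in enumerate(spec.hydrophobic_pattern, start=1):
            residues.append(_residue("A", i, code, ((i - 1) * spec.spacing, 0, 0), atom_radius))
    elif spec.kind == "shell":
        # n-1 shell atoms enclosing one central atom: the center contributes
        # no surface points when the shell is tight.
        if spec.n_residues < 2:
            raise ValueError("shell fixture needs >= 2 residues")
        residues.append(_residue("A", 1, spec.hydrophobic_pattern[0], (0, 0, 0), atom_radius))
        shell_pts = sample_sphere(np.zeros(3), spec.spacing, spec.n_residues - 1)
        for i, (code, pt) in enumerate(
            zip(spec.hydrophobic_pattern[1:], shell_pts), start=2
        ):
            residues.append(_residue("A", i, code, pt, atom_radius))
    else:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")

    model = StructureModel(structure_id=f"fixture_{spec.kind}", chains={"A": residues})
    if pdb_path is not None:
        write_pdb(model, pdb_path)
    return model


#: Minimal but realistic two-residue PDB text (full heavy-atom ALA + ASP)
#: for parser tests; coordinates are idealised, not from any database entry.
ALA_ASP_PDB = """\
ATOM      1  N   ALA A   1      -0.525   1.362   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.520   0.000   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.197   1.056   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1      -0.507  -0.785  -1.207  1.00  0.00           C
ATOM      6  N   ASP A   2       2.099  -1.197   0.000  1.00  0.00           N
ATOM      7  CA  ASP A   2       3.550  -1.320   0.000  1.00  0.00           C
ATOM      8  C   ASP A   2       4.060  -2.750   0.000  1.00  0.00           C
ATOM      9  O   ASP A   2       3.280  -3.710   0.000  1.00  0.00           O
ATOM     10  CB  ASP A   2       4.150  -0.590   1.210  1.00  0.00           C
ATOM     11  CG  ASP A   2       5.660  -0.640   1.260  1.00  0.00           C
ATOM     12  OD1 ASP A   2       6.290  -1.230   0.360  1.00  0.00           O
ATOM     13  OD2 ASP A   2       6.240  -0.070   2.210  1.00  0.00           O
TER
END
"""


def write_ala_asp_pdb(path: str | Path) -> Path:
    """Write the full-residue ALA+ASP parser fixture to ``path``."""
    path = Path(path)
    path.write_text(ALA_ASP_PDB)
    return path


def make_prediction_table(
    n: int, noise_fraction: float, seed: int, measure: str = "THSA"
) -> list[PredictionRecord]:
    """Synthetic prediction/reference pairs with bounded relative error.

    References are drawn from a lognormal distribution (median ~ 3000 A^2,
    geometric spread typical of chain surface areas); predictions are the
    reference scaled by 1 + Uniform(-noise_fraction, +noise_fraction), so
    every relative error is below ``noise_fraction`` by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    rng = np.random.default_rng(seed)
    reference = rng.lognormal(mean=np.log(3000.0), sigma=0.5, size=n)
    predicted = reference * (1.0 + rng.uniform(-noise_fraction, noise_fraction, size=n))
    return [
        PredictionRecord(
            chain_id=f"chain{i:05d}", measure=measure,
            predicted=float(p), reference=float(r),
        )
        for i, (p, r) in enumerate(zip(predicted, reference))
    ]


def make_regression_table(
    model_name: str, n: int, noise_fraction: float, seed: int, target: str = "THSA"
):
    """Synthetic feature/target tables for the regression harness.

    For the three-feature setting the target is a fixed linear function of
    length and hydrophobic count (area scales with size and hydrophobic
    content); for the accessibility-derived setting the target is half the
    predicted THSA (the largest patch scales with hydrophobic area).  Optional
    multiplicative uniform noise of the given fraction is applied to the
    target.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    if model_name == "TFM":
        length = np.round(rng.lognormal(np.log(250.0), 0.4, size=n)).astype(int) + 30
        hydro_frac = rng.uniform(0.25, 0.55, size=n)
        hydro = np.round(length * hydro_frac).astype(int)
        philic = length - hydro
        clean = 6.0 * length + 8.0 * hydro - 2.0 * philic
        table = pd.DataFrame(
            {"length": length, "hydrophobic_count": hydro, "hydrophilic_count": philic}
        )
    elif model_name == "NBM":
        thsa = rng.lognormal(np.log(3000.0), 0.5, size=n)
        rhsa = rng.uniform(0.1, 0.4, size=n)
        clean = 0.5 * thsa
        table = pd.DataFrame({"thsa_pred": thsa, "rhsa_pred": rhsa})
    else:
        raise ValueError(f"unsupported synthetic model {model_name!r}")
    noise = rng.uniform(-noise_fraction, noise_fraction, size=n) if noise_fraction else 0.0
    table[target] = clean * (1.0 + noise)
    return table
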