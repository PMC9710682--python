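"""PDB parsing into a validated structure model with hydrophobicity annotations.

The model keeps only standard amino-acid residues (plus a small set of
modified residues mapped back to their parent, e.g. MSE -> MET), drops
waters and other hetero records, resolves alternate locations to the
highest-occupancy conformer and excludes hydrogens by default.  Every
residue carries a boolean hydrophobicity flag following the residue set
{A, C, F, I, L, M, V, W, Y}.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

logger = logging.getLogger(__name__)

#: One-letter codes of residues treated as hydrophobic.
HYDROPHOBIC_RESIDUES = frozenset("ACFILMVWY")

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Common modified residues mapped to their parent amino acid.
NONSTANDARD_TO_PARENT = {
    "MSE": "M",   # selenomethionine
    "SEC": "C",   # selenocysteine (closest standard parent)
    "PYL": "K",
    "HYP": "P",
    "SEP": "S",
    "TPO": "T",
    "PTR": "Y",
    "CSO": "C",
    "MLY": "K",
}

#: Bondi-style van der Waals radii in Angstrom, keyed by element symbol.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    "SE": 1.90,
}

#: Fallback radius for elements missing from the table.
DEFAULT_RADIUS = 1.70


class StructureError(ValueError):
    """Raised for unparsable or empty structure input."""


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    vdw_radius: float
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")


@dataclass
class ResidueRecord:
    chain_id: str
    seq_number: int
    insertion_code: str
    aa: str
    hydrophobic: bool
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)


@dataclass
class StructureModel:
    structure_id: str
    chains: dict[str, list[ResidueRecord]]

    def residues(self) -> list[ResidueRecord]:
        """All residues in chain order, then sequence order."""
        out: list[ResidueRecord] = []
        for chain in self.chains.values():
            out.extend(chain)
        return out

    def atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues() for a in r.atoms]

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def select_chains(self, chain_ids: Iterable[str]) -> "StructureModel":
        wanted = list(chain_ids)
        missing = [c for c in wanted if c not in self.chains]
        if missing:
            raise StructureError(
                f"chain(s) {missing} not in structure {self.structure_id} "
                f"(has {sorted(self.chains)})"
            )
        return StructureModel(
            structure_id=self.structure_id,
            chains={c: self.chains[c] for c in wanted},
        )


def classify_residue(aa: str) -> bool:
    """True iff the one-letter code is in the hydrophobic residue set.

    Raises ValueError for codes outside the 20 standard amino acids so the
    caller decides the skip policy.
    """
    if aa not in STANDARD_AA:
        raise ValueError(f"non-standard amino-acid code: {aa!r}")
    return aa in HYDROPHOBIC_RESIDUES


def _resolve_altloc(bio_atom):
    """Pick the highest-occupancy conformer; ties keep the first encountered."""
    if not bio_atom.is_disordered():
        return bio_atom
    best = None
    for child in bio_atom.disordered_get_list():
        occ = child.get_occupancy() or 0.0
        if best is None or occ > (best.get_occupancy() or 0.0):
            best = child
    return best


def parse_pdb(
    path: str | Path,
    chain_filter: set[str] | None = None,
    *,
    keep_hydrogens: bool = False,
    radius_table: Mapping[str, float] | None = None,
    default_radius: float | None = DEFAULT_RADIUS,
) -> StructureModel:
    """Parse a PDB file into a cleaned :class:`StructureModel`.

    Waters and hetero records are removed, hydrogens dropped unless
    ``keep_hydrogens``, one altloc kept per atom, first model only for
    multi-model files.  Van der Waals radii are assigned from
    ``radius_table`` (Bondi-style defaults).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure(path.stem, str(path))

    try:
        model0 = next(iter(structure))
    except StopIteration:  # pragma: no cover - empty file
        raise StructureError(f"no models in {path}") from None

    table = dict(DEFAULT_RADII)
    if radius_table is not None:
        table.update({k.upper(): float(v) for k, v in radius_table.items()})

    chains: dict[str, list[ResidueRecord]] = {}
    n_dropped = 0
    serial = 0
    for chain in model0:
        chain_id = chain.id.strip() or "A"
        if chain_filter is not None and chain_id not in chain_filter:
            continue
        residues: list[ResidueRecord] = []
        seen_keys: set[tuple[str, int, str]] = set()
        for res in chain:
            hetflag, seqnum, icode = res.id
            resname = res.get_resname().strip()
            if resname == "HOH" or resname == "WAT":
                continue
            if resname in THREE_TO_ONE:
                aa = THREE_TO_ONE[resname]
            elif resname in NONSTANDARD_TO_PARENT:
                aa = NONSTANDARD_TO_PARENT[resname]
            elif hetflag.strip():
                continue  # ligand / unknown hetero record
            else:
                logger.warning("dropping unmapped residue %s %s%s", resname, chain_id, seqnum)
                n_dropped += 1
                continue
            key = (chain_id, seqnum, icode.strip())
            if key in seen_keys:
                continue
            atoms: list[AtomRecord] = []
            for bio_atom in res:
                chosen = _resolve_altloc(bio_atom)
                if chosen is None:
                    continue
                element = (chosen.element or "").strip().upper()
                if not element:
                    element = chosen.get_name().strip()[:1].upper()
                if element == "H" and not keep_hydrogens:
                    continue
                radius = table.get(element)
                if radius is None:
                    if default_radius is None:
                        raise StructureError(
                            f"no van der Waals radius for element {element!r}"
                        )
                    radius = default_radius
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=chosen.get_name(),
                        element=element,
                        coords=np.array(chosen.get_coord(), dtype=float),
                        vdw_radius=radius,
                        occupancy=float(chosen.get_occupancy() or 1.0),
                        altloc=(chosen.get_altloc() or "").strip(),
                    )
                )
            if not atoms:
                continue
            seen_keys.add(key)
            residues.append(
                ResidueRecord(
                    chain_id=chain_id,
                    seq_number=seqnum,
                    insertion_code=icode.strip(),
                    aa=aa,
                    hydrophobic=aa in HYDROPHOBIC_RESIDUES,
                    atoms=atoms,
                )
            )
        if residues:
            chains[chain_id] = residues

    if chain_filter is not None:
        missing = chain_filter - set(chains)
        if missing:
            raise StructureError(f"requested chain(s) {sorted(missing)} absent from {path}")
    if not chains:
        raise StructureError(f"no parsable ATOM records in {path}")
    return StructureModel(structure_id=path.stem, chains=chains)


def assign_radii(
    model: StructureModel,
    radius_table: Mapping[str, float],
    default_radius: float | None = None,
) -> StructureModel:
    """Reassign van der Waals radii in place from an element->radius table."""
    table = {k.upper(): float(v) for k, v in radius_table.items()}
    for atom in model.atoms():
        radius = table.get(atom.element.upper(), default_radius)
        if radius is None:
            raise StructureError(f"no radius for element {atom.element!r} and no default")
        atom.vdw_radius = radius
    return model


def read_radius_table(path: str | Path) -> dict[str, float]:
    """Read a two-column ``element<TAB>radius`` text file."""
    table: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        element, radius = line.split()[:2]
        table[element.upper()] = float(radius)
    return table


ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the cleaned model back out as minimal PDB ATOM records."""
    lines: list[str] = []
    serial = 0
    for chain_id, residues in model.chains.items():
        for res in residues:
            resname = ONE_TO_THREE[res.aa]
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.coords
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4.4s} {resname:<3s} {chain_id:1.1s}"
                    f"{res.seq_number:4d}{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
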