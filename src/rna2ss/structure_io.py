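"""Read RNA 3D structures into an ordered, globally indexed residue model.

mmCIF is the preferred input format; legacy PDB is also accepted.  Only
ribonucleotide residues are retained: standard A/C/G/U plus modified
nucleotides with a known parent base.  Protein, water, ions and ligands
are excluded.  All downstream coordinates (pairs, helices, writers) use a
1-based global index over the selected residues in file order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from ._bases import RING_ATOMS, parent_base

logger = logging.getLogger(__name__)

__all__ = [
    "NucleotideResidue",
    "RnaStructure",
    "StructureError",
    "StructureParseError",
    "ChainSelectionError",
    "EmptySelectionError",
    "read_structure",
    "write_mmcif",
]


class StructureError(Exception):
    """Base class for structure input errors."""


class StructureParseError(StructureError):
    """The file could not be parsed as mmCIF or PDB."""


class ChainSelectionError(StructureError):
    """A requested chain is absent from the file."""


class EmptySelectionError(StructureError):
    """No RNA residues remain after filtering/selection."""


@dataclass
class NucleotideResidue:
    """One RNA residue with its heavy-atom coordinates.

    ``base_code`` is the residue name as deposited (e.g. ``PSU``);
    ``parent`` is its parent base, always one of A/C/G/U.  ``atoms`` maps
    atom name to a length-3 coordinate array in angstroms.
    ``complete_base`` is true when every ring atom needed for base-frame
    fitting is present.
    """

    chain_id: str
    seq_index: int          # 1-based position within the selected chain
    auth_number: int        # author residue number from the source file
    base_code: str
    parent: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    complete_base: bool = True

    def coord(self, name: str) -> np.ndarray | None:
        return self.atoms.get(name)

    def ring_coords(self) -> np.ndarray | None:
        names = RING_ATOMS[self.parent]
        if not all(n in self.atoms for n in names):
            return None
        return np.array([self.atoms[n] for n in names])


@dataclass
class RnaStructure:
    """Ordered chains of RNA residues with a 1-based global index.

    The global index runs over all selected residues in chain order and is
    the index space used by pairs, helices, and the writers.
    """

    chains: list[tuple[str, list[NucleotideResidue]]]
    source: str = ""

    @property
    def residues(self) -> list[NucleotideResidue]:
        return [r for _, chain in self.chains for r in chain]

    @property
    def n_residues(self) -> int:
        return sum(len(chain) for _, chain in self.chains)

    @property
    def sequence(self) -> str:
        return "".join(r.parent for r in self.residues)

    @property
    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]


def _best_altloc_atoms(residue: gemmi.Residue) -> dict[str, tuple[np.ndarray, float]]:
    """Highest-occupancy conformer per atom name; ties keep first in file."""
    out: dict[str, tuple[np.ndarray, float]] = {}
    for atom in residue:
        pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
        if not np.all(np.isfinite(pos)):
            continue
        name = atom.name
        if name not in out or atom.occ > out[name][1]:
            out[name] = (pos, atom.occ)
    return out


def read_structure(
    path: str | Path,
    model_index: int = 1,
    chains: list[str] | None = None,
) -> RnaStructure:
    """Parse an mmCIF/PDB file into an :class:`RnaStructure`.

    Parameters
    ----------
    path
        Input coordinate file (format auto-detected).
    model_index
        1-based model number; crystallographic and cryo-EM depositions
        are typically single-model, hence the default of 1.
    chains
        Optional list of auth chain ids to keep; default keeps all chains
        that contain RNA.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path.name}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path.name}: file contains no models")
    if not 1 <= model_index <= len(st):
        raise StructureParseError(
            f"{path.name}: model {model_index} not present (file has {len(st)} model(s))"
        )
    model = st[model_index - 1]

    available = [ch.name for ch in model]
    if chains is not None:
        missing = [c for c in chains if c not in available]
        if missing:
            raise ChainSelectionError(
                f"chain(s) {', '.join(missing)} not in {path.name}; "
                f"available: {', '.join(available)}"
            )

    out_chains: list[tuple[str, list[NucleotideResidue]]] = []
    n_skipped = 0
    for ch in model:
        if chains is not None and ch.name not in chains:
            continue
        residues: list[NucleotideResidue] = []
        for res in ch:
            parent = parent_base(res.name)
            if parent is None:
                if res.name.strip().upper() not in {"HOH", "WAT", "MG", "K", "NA", "ZN", "CL"}:
                    n_skipped += 1
                continue
            atoms = {name: pos for name, (pos, _) in _best_altloc_atoms(res).items()}
            if not atoms:
                continue
            complete = all(a in atoms for a in RING_ATOMS[parent])
            residues.append(
                NucleotideResidue(
                    chain_id=ch.name,
                    seq_index=len(residues) + 1,
                    auth_number=res.seqid.num,
                    base_code=res.name.strip().upper(),
                    parent=parent,
                    atoms=atoms,
                    complete_base=complete,
                )
            )
        if residues:
            out_chains.append((ch.name, residues))
    if n_skipped:
        logger.warning("excluded %d non-RNA/unknown residues", n_skipped)
    structure = RnaStructure(chains=out_chains, source=str(path))
    if structure.n_residues == 0:
        raise EmptySelectionError(
            f"{path.name}: no RNA residues after filtering"
            + (f" (chains {','.join(chains)})" if chains else "")
        )
    return structure


_ELEMENTS = ("CL", "BR", "C", "N", "O", "P", "S", "H")


def _element_of(atom_name: str) -> str:
    stripped = "".join(c for c in atom_name if c.isalpha()).upper()
    for el in _ELEMENTS:
        if stripped.startswith(el):
            return el
    return stripped[:1] or "X"


def write_mmcif(structure: RnaStructure, path: str | Path, title: str = "rna2ss") -> None:
    """Write the selected residues as a minimal, deterministic mmCIF file."""
    lines = [
        f"data_{title}",
        "#",
        "loop_",
        "_atom_site.group_PDB",
        "_atom_site.id",
        "_atom_site.type_symbol",
        "_atom_site.label_atom_id",
        "_atom_site.label_alt_id",
        "_atom_site.label_comp_id",
        "_atom_site.label_asym_id",
        "_atom_site.label_entity_id",
        "_atom_site.label_seq_id",
        "_atom_site.pdbx_PDB_ins_code",
        "_atom_site.Cartn_x",
        "_atom_site.Cartn_y",
        "_atom_site.Cartn_z",
        "_atom_site.occupancy",
        "_atom_site.B_iso_or_equiv",
        "_atom_site.auth_seq_id",
        "_atom_site.auth_asym_id",
        "_atom_site.pdbx_PDB_model_num",
    ]
    serial = 0
    for entity, (chain_id, residues) in enumerate(structure.chains, start=1):
        for res in residues:
            for name in sorted(res.atoms):
                serial += 1
                x, y, z = res.atoms[name]
                atom_id = f'"{name}"' if "'" in name else name
                lines.append(
                    f"ATOM {serial} {_element_of(name)} {atom_id} . {res.base_code} "
                    f"{chain_id} {entity} {res.seq_index} ? "
                    f"{x:.3f} {y:.3f} {z:.3f} 1.00 0.00 "
                    f"{res.auth_number} {chain_id} 1"
                )
    lines.append("#")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
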