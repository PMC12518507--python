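"""Structure I/O and atom/residue selections for two-chain protein-peptide complexes.

The object model is deliberately small: a ``ComplexStructure`` holds exactly one
receptor chain and one peptide chain of amino-acid residues with heavy atoms.
Hydrogens, waters, non-polymer heteroatoms and alternate conformations other
than the highest-occupancy one are resolved away at read time, so every
downstream metric sees a single deterministic model.

Parsing of PDB and mmCIF files is delegated to :mod:`gemmi`; writing uses the
fixed-column PDB format (sufficient for fixtures and interchange).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "ComplexStructure",
    "AtomSelection",
    "read_structure",
    "write_pdb",
    "select_atoms",
    "chain_sequence",
    "peptide_length_ok",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

SelectionMode = Literal["backbone", "heavy", "CA", "CB_proxy"]


class StructureError(ValueError):
    """Raised for unparseable files, missing chains, or unusable chains."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")


@dataclass
class Residue:
    name3: str
    seq_index: int            # 0-based position within the chain
    auth_number: str          # author numbering + insertion code, e.g. "42" or "42A"
    atoms: list[Atom] = field(default_factory=list)

    @property
    def code1(self) -> str:
        return THREE_TO_ONE.get(self.name3, "X")

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_backbone(self) -> bool:
        return all(self.get_atom(n) is not None for n in BACKBONE_ATOMS)

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coords for a in self.atoms if a.element not in ("H", "D")]
        return np.array(coords, dtype=float).reshape(-1, 3)


@dataclass
class Chain:
    id: str
    role: Literal["receptor", "peptide"]
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)


@dataclass
class ComplexStructure:
    id: str
    receptor: Chain
    peptide: Chain
    release_date: datetime.date | None = None

    def __post_init__(self) -> None:
        if self.receptor.id == self.peptide.id:
            raise StructureError("receptor and peptide chain ids must differ")

    def chains(self) -> tuple[Chain, Chain]:
        return self.receptor, self.peptide


@dataclass
class AtomSelection:
    """Ordered coordinates plus bookkeeping of residues that could not contribute."""

    coords: np.ndarray             # (n, 3)
    residue_indices: list[int]     # seq_index of the residue behind each coordinate row
    skipped: list[int]             # seq_indices of residues missing required atoms

    def __len__(self) -> int:
        return len(self.coords)


def _is_amino_acid(name3: str) -> bool:
    info = gemmi.find_tabulated_residue(name3)
    if info is not None:
        return info.is_amino_acid()
    return name3 in THREE_TO_ONE


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties to first encountered."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [best[n] for n in order]


def _convert_chain(gchain: gemmi.Chain, chain_id: str, role: str) -> Chain:
    residues: list[Residue] = []
    for gres in gchain:
        if not _is_amino_acid(gres.name):
            continue
        atoms = [
            Atom(
                name=ga.name,
                element=ga.element.name.upper(),
                coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                occupancy=min(max(ga.occ, 0.0), 1.0),
                altloc=ga.altloc if ga.altloc != "\x00" else "",
            )
            for ga in gres
            if ga.element.name.upper() not in ("H", "D")
        ]
        if not atoms:
            continue
        icode = gres.seqid.icode.strip()
        residues.append(
            Residue(
                name3=gres.name,
                seq_index=len(residues),
                auth_number=f"{gres.seqid.num}{icode}",
                atoms=_resolve_altlocs(atoms),
            )
        )
    return Chain(id=chain_id, role=role, residues=residues)


def _release_date(st: gemmi.Structure) -> datetime.date | None:
    for key in (
        "_pdbx_database_status.recvd_initial_deposition_date",
        "_database_PDB_rev.date_original",
    ):
        raw = st.info[key] if key in st.info else ""
        if raw:
            try:
                return datetime.date.fromisoformat(raw)
            except ValueError:
                pass
    return None


def read_structure(
    path: str | Path,
    receptor_id: str,
    peptide_id: str,
    *,
    use_label_ids: bool = False,
    complex_id: str | None = None,
) -> ComplexStructure:
    """Read a two-chain complex from PDB or mmCIF.

    Chains are looked up by author ids (the PDB convention used in entry names
    like ``6A8N_AP``); pass ``use_label_ids=True`` to address mmCIF label ids
    instead. Only the first model is used. The release/deposition date is
    taken from the header when present.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    if use_label_ids:
        st.setup_entities()
    model = st[0]

    def find(cid: str) -> gemmi.Chain:
        for ch in model:
            if ch.name == cid:
                return ch
        if use_label_ids:
            for sub in model.subchains():
                if sub.subchain_id() == cid:
                    ch = gemmi.Chain(cid)
                    for r in sub:
                        ch.add_residue(r)
                    return ch
        raise StructureError(f"{path}: chain {cid!r} not found")

    receptor = _convert_chain(find(receptor_id), receptor_id, "receptor")
    peptide = _convert_chain(find(peptide_id), peptide_id, "peptide")
    for ch in (receptor, peptide):
        if not any(r.has_backbone() for r in ch.residues):
            raise StructureError(f"{path}: chain {ch.id} has no backbone-complete residues")
    cid = complex_id or f"{path.stem.upper()}_{receptor_id}{peptide_id}"
    return ComplexStructure(
        id=cid, receptor=receptor, peptide=peptide, release_date=_release_date(st)
    )


def write_pdb(complex_: ComplexStructure, path: str | Path) -> None:
    """Serialize a complex as fixed-column PDB (HEADER date preserved)."""
    lines: list[str] = []
    if complex_.release_date is not None:
        dep = complex_.release_date.strftime("%d-%b-%y").upper()
        code = (complex_.id.split("_")[0] + "    ")[:4]
        lines.append(f"HEADER    PROTEIN/PEPTIDE COMPLEX                 {dep}   {code}")
    serial = 1
    for chain in complex_.chains():
        for res in chain.residues:
            num = "".join(c for c in res.auth_number if c.isdigit() or c == "-") or "1"
            icode = res.auth_number[len(num):][:1] or " "
            for atom in res.atoms:
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3}"
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:>5} {name:<4} {res.name3:<3} {chain.id:>1}"
                    f"{int(num):>4}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2}"
                )
                serial += 1
        lines.append(f"TER   {serial:>5}      {chain.residues[-1].name3:<3} {chain.id:>1}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def select_atoms(chain: Chain, mode: SelectionMode) -> AtomSelection:
    """Extract ordered coordinates for a selection mode.

    ``backbone``: N, CA, C, O per residue; ``heavy``: all non-hydrogen atoms;
    ``CA``: alpha carbons; ``CB_proxy``: beta carbon, substituting the alpha
    carbon for glycine (the distogram representative-atom convention).
    Residues missing required atoms are skipped and reported in ``skipped``.
    """
    coords: list[np.ndarray] = []
    res_idx: list[int] = []
    skipped: list[int] = []
    for res in chain.residues:
        if mode == "backbone":
            picked = [res.get_atom(n) for n in BACKBONE_ATOMS]
            if any(a is None for a in picked):
                skipped.append(res.seq_index)
                continue
            for a in picked:
                coords.append(a.coords)
                res_idx.append(res.seq_index)
        elif mode == "heavy":
            heavy = [a for a in res.atoms if a.element not in ("H", "D")]
            if not heavy:
                skipped.append(res.seq_index)
                continue
            for a in heavy:
                coords.append(a.coords)
                res_idx.append(res.seq_index)
        elif mode == "CA":
            a = res.get_atom("CA")
            if a is None:
                skipped.append(res.seq_index)
                continue
            coords.append(a.coords)
            res_idx.append(res.seq_index)
        elif mode == "CB_proxy":
            a = res.get_atom("CB") or res.get_atom("CA")  # Gly has no CB
            if a is None:
                skipped.append(res.seq_index)
                continue
            coords.append(a.coords)
            res_idx.append(res.seq_index)
        else:
            raise ValueError(f"unknown selection mode {mode!r}")
    arr = np.array(coords, dtype=float).reshape(-1, 3)
    return AtomSelection(coords=arr, residue_indices=res_idx, skipped=skipped)


def chain_sequence(chain: Chain) -> str:
    """One-letter sequence; non-standard residues map to 'X'."""
    return "".join(res.code1 for res in chain.residues)


def peptide_length_ok(chain: Chain, max_len: int = 25, min_len: int = 3) -> bool:
    """Length-filter predicate for candidate peptide chains."""
    return min_len <= len(chain.residues) <= max_len
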