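"""Backbone-only structure models and coordinate-file I/O.

Parses PDB and mmCIF files into per-chain lists of backbone residues
(N, CA, C, O), together with the header metadata (title, resolution,
R-factor) used by the dataset quality filter.  Only residues with all
four backbone atoms present are kept; everything else (ligands, waters,
nucleic acids, incomplete residues) is dropped and counted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

__all__ = [
    "StructureMetadata",
    "BackboneResidue",
    "ChainModel",
    "ParseResult",
    "StructureParseError",
    "EmptyStructureError",
    "read_structure",
    "parse_metadata",
    "write_pdb",
]

#: C(i)->N(i+1) distances above this are flagged as chain breaks (Å).
#: The peptide bond is ~1.33 Å; 2.5 Å is a generous margin.
CHAIN_BREAK_CUTOFF = 2.5

#: Accepted intra-residue bond-length window for CA-N and CA-C (Å).
BOND_SANITY_RANGE = (1.2, 1.8)

_BACKBONE_ATOMS = ("N", "CA", "C", "O")


class StructureParseError(ValueError):
    """The coordinate file could not be parsed."""


class EmptyStructureError(StructureParseError):
    """The file contains no polypeptide chain with complete backbones."""


@dataclass(frozen=True)
class StructureMetadata:
    """Header metadata of one structure.

    ``resolution`` (Å) and ``r_factor`` are ``None`` when the header does
    not state them (e.g. NMR entries) — never 0.
    """

    structure_id: str
    title: str = ""
    resolution: Optional[float] = None
    r_factor: Optional[float] = None
    experiment_method: Optional[str] = None


@dataclass(frozen=True)
class BackboneResidue:
    """One residue's identity plus its four backbone-atom coordinates (Å)."""

    chain_id: str
    residue_number: int
    insertion_code: str
    aa_one_letter: str
    n_xyz: np.ndarray
    ca_xyz: np.ndarray
    c_xyz: np.ndarray
    o_xyz: np.ndarray


@dataclass
class ChainModel:
    """An ordered polypeptide chain of backbone residues.

    ``break_flags[i]`` is True when the peptide bond between residues
    ``i`` and ``i+1`` is broken (C->N distance above 2.5 Å).
    """

    chain_id: str
    residues: list[BackboneResidue] = field(default_factory=list)
    break_flags: list[bool] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def has_break_between(self, i: int, j: int) -> bool:
        """True if any peptide bond between residue indices i..j is broken."""
        lo, hi = (i, j) if i <= j else (j, i)
        return any(self.break_flags[lo:hi])


@dataclass
class ParseResult:
    metadata: StructureMetadata
    chains: list[ChainModel]
    n_dropped: int


def _residue_one_letter(name: str) -> Optional[str]:
    """One-letter code for an amino-acid residue name, or None if not AA.

    MSE (selenomethionine) maps to M; other non-standard amino acids with
    a complete backbone are kept as 'X' (assignment is geometry-only).
    """
    info = gemmi.find_tabulated_residue(name)
    if info is None or not info.is_amino_acid():
        return None
    if name == "MSE":
        return "M"
    if info.is_standard():
        return info.one_letter_code.upper()
    return "X"


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc identifier order
    return min(atoms, key=lambda a: (-a.occ, a.altloc))


def _load_gemmi(path: Path) -> gemmi.Structure:
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    return st


def read_structure(
    path, model_index: int = 0, altloc_policy: str = "occupancy"
) -> ParseResult:
    """Parse a PDB/mmCIF file into backbone chain models plus metadata.

    Residues missing any of N/CA/C/O, or with implausible CA-N / CA-C
    bond lengths, are dropped and counted in ``n_dropped``.  Hetero
    records are kept only for amino-acid residues (MSE continuations
    and similar).  Only one model is read (the first by default).
    """
    if altloc_policy != "occupancy":
        raise ValueError(f"unknown altloc policy: {altloc_policy!r}")
    path = Path(path)
    st = _load_gemmi(path)
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[model_index]

    chains: list[ChainModel] = []
    n_dropped = 0
    for ch in model:
        residues: list[BackboneResidue] = []
        for res in ch:
            one = _residue_one_letter(res.name)
            if one is None:
                continue
            coords = {}
            for atom_name in _BACKBONE_ATOMS:
                cands = [a for a in res if a.name == atom_name]
                if not cands:
                    break
                a = _pick_altloc(cands)
                coords[atom_name] = np.array(
                    [a.pos.x, a.pos.y, a.pos.z], dtype=float
                )
            if len(coords) < 4 or not all(
                np.all(np.isfinite(v)) for v in coords.values()
            ):
                n_dropped += 1
                continue
            d_n = float(np.linalg.norm(coords["CA"] - coords["N"]))
            d_c = float(np.linalg.norm(coords["CA"] - coords["C"]))
            lo, hi = BOND_SANITY_RANGE
            if not (lo < d_n < hi and lo < d_c < hi):
                n_dropped += 1
                continue
            residues.append(
                BackboneResidue(
                    chain_id=ch.name,
                    residue_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    aa_one_letter=one,
                    n_xyz=coords["N"],
                    ca_xyz=coords["CA"],
                    c_xyz=coords["C"],
                    o_xyz=coords["O"],
                )
            )
        if not residues:
            continue
        flags = [
            float(np.linalg.norm(residues[i + 1].n_xyz - residues[i].c_xyz))
            > CHAIN_BREAK_CUTOFF
            for i in range(len(residues) - 1)
        ]
        chains.append(ChainModel(ch.name, residues, flags))

    if not chains:
        raise EmptyStructureError(f"{path}: no polypeptide chain found")
    return ParseResult(_metadata_from(st, path), chains, n_dropped)


_R_FACTOR_PATTERNS = [
    re.compile(r"R VALUE\s+\(WORKING SET[^)]*\)\s*:\s*([0-9]*\.?[0-9]+)"),
    re.compile(r"R VALUE\s*(?:\(F[^)]*\))?\s*:\s*([0-9]*\.?[0-9]+)"),
]


def _r_factor_from_pdb_text(path: Path) -> Optional[float]:
    try:
        text = path.read_text(errors="replace")
    except OSError:
        return None
    for line in text.splitlines():
        if not line.startswith("REMARK   3"):
            continue
        for pat in _R_FACTOR_PATTERNS:
            m = pat.search(line)
            if m:
                try:
                    return float(m.group(1))
                except ValueError:
                    continue
    return None


def _r_factor_from_cif(path: Path) -> Optional[float]:
    try:
        doc = gemmi.cif.read(str(path))
    except (RuntimeError, ValueError):
        return None
    block = doc.sole_block()
    for tag in (
        "_refine.ls_R_factor_obs",
        "_refine.ls_R_factor_R_work",
        "_refine.ls_R_factor_all",
    ):
        val = block.find_value(tag)
        if val not in (None, "?", "."):
            try:
                return float(val)
            except ValueError:
                continue
    return None


def _metadata_from(st: gemmi.Structure, path: Path) -> StructureMetadata:
    def info(key: str) -> str:
        return st.info[key] if key in st.info else ""

    sid = info("_entry.id").strip() or (st.name or "").strip() or path.stem
    title = info("_struct.title").strip()
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    method = info("_exptl.method").strip() or None
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        r_factor = _r_factor_from_cif(path)
    else:
        r_factor = _r_factor_from_pdb_text(path)
    return StructureMetadata(
        structure_id=sid,
        title=title,
        resolution=resolution,
        r_factor=r_factor,
        experiment_method=method,
    )


def parse_metadata(path) -> StructureMetadata:
    """Extract header metadata only (resolution, R-factor, title).

    Missing header fields are legal and reported as ``None``.
    """
    path = Path(path)
    return _metadata_from(_load_gemmi(path), path)


_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


def write_pdb(chains: list[ChainModel], path, metadata: Optional[StructureMetadata] = None) -> None:
    """Write backbone chains as fixed-column PDB text (fixture output)."""
    lines: list[str] = []
    if metadata is not None:
        if metadata.title:
            lines.append(f"TITLE     {metadata.title[:60]}")
        if metadata.resolution is not None:
            lines.append(
                "REMARK   2 RESOLUTION.  "
                f"{metadata.resolution:5.2f} ANGSTROMS."
            )
    serial = 1
    for chain in chains:
        for res in chain.residues:
            res3 = _AA3.get(res.aa_one_letter, "UNK")
            for atom_name, xyz, element in (
                ("N", res.n_xyz, "N"),
                ("CA", res.ca_xyz, "C"),
                ("C", res.c_xyz, "C"),
                ("O", res.o_xyz, "O"),
            ):
                name_field = atom_name.center(4) if len(atom_name) == 4 else f" {atom_name:<3}"
                lines.append(
                    f"ATOM  {serial:5d} {name_field}{res3:>4} "
                    f"{chain.chain_id[:1]}{res.residue_number:4d}"
                    f"{res.insertion_code or ' ':1}   "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {element:>2}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
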