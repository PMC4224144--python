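"""Dataset filtering, summaries, normalization and export writers.

Everything downstream of assignment: the per-chain summary table
(id, title, length, resolution, PPII count/percent), the structure
quality filter (resolution < 3.0 Å, R-factor < 1.0), range queries over
summaries, FASTA export of assignment strings, Ramachandran record
export, and normalization of third-party assignment alphabets
(PROSS, SEGNO, XTLSSTR) to the four classes helix/strand/ppii/other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .dssp import SecondaryStructureString
from .geometry import DihedralTriple
from .ppii import ppii_content
from .structure import ChainModel, StructureMetadata

__all__ = [
    "ChainSummary",
    "RamachandranRecord",
    "METHOD_ALPHABETS",
    "quality_filter",
    "summarize_chain",
    "advanced_query",
    "write_assignment_fasta",
    "read_assignment_fasta",
    "export_ramachandran",
    "normalize_external_assignment",
    "class_statistics",
]

logger = logging.getLogger("polyproline")

#: dataset quality thresholds: X-ray structures better than 3.0 Å with
#: an R-factor below 1.0
MAX_RESOLUTION = 3.0
MAX_R_FACTOR = 1.0

CLASSES = ("helix", "strand", "ppii", "other")

#: per-method code -> class maps for the four assignment methods
METHOD_ALPHABETS: dict[str, dict[str, str]] = {
    "DSSP-PPII": {
        "H": "helix", "G": "helix", "I": "helix",
        "E": "strand", "B": "strand",
        "P": "ppii",
        "T": "other", "S": "other", "-": "other",
    },
    "PROSS": {
        "H": "helix", "E": "strand", "P": "ppii", "T": "other", "C": "other",
    },
    "XTLSSTR": {
        "H": "helix", "h": "helix", "G": "helix", "g": "helix",
        "E": "strand", "e": "strand",
        "P": "ppii", "p": "ppii",
        "T": "other", "N": "other",
    },
    "SEGNO": {
        "H": "helix", "G": "helix", "g": "helix", "I": "helix",
        "E": "strand", "e": "strand", "B": "strand", "b": "strand",
        "P": "ppii", "p": "ppii",
        "-": "other", "O": "other",
    },
}


@dataclass(frozen=True)
class ChainSummary:
    """One row of the per-chain summary table."""

    structure_id: str
    chain_id: str
    title: str
    length: int
    resolution: Optional[float]
    ppii_count: int
    ppii_percent: float


@dataclass(frozen=True)
class RamachandranRecord:
    """One (φ, ψ) point of a Ramachandran export."""

    residue_number: int
    aa_one_letter: str
    phi: float
    psi: float
    code: str


def quality_filter(
    metadata: StructureMetadata,
    max_resolution: float = MAX_RESOLUTION,
    max_rfactor: float = MAX_R_FACTOR,
) -> bool:
    """True iff resolution and R-factor are both present and below limits.

    Entries with a missing resolution or R-factor fail the filter with
    a logged warning (NMR entries, incomplete headers).
    """
    if metadata.resolution is None:
        logger.warning("%s: no resolution in header; fails quality filter",
                       metadata.structure_id)
        return False
    if metadata.r_factor is None:
        logger.warning("%s: no R-factor in header; fails quality filter",
                       metadata.structure_id)
        return False
    return metadata.resolution < max_resolution and metadata.r_factor < max_rfactor


def summarize_chain(
    metadata: StructureMetadata,
    chain: ChainModel,
    ss: SecondaryStructureString,
) -> ChainSummary:
    """Per-chain summary row; PPII percent to one decimal."""
    count = ss.codes.count("P")
    return ChainSummary(
        structure_id=metadata.structure_id,
        chain_id=chain.chain_id,
        title=metadata.title,
        length=len(chain),
        resolution=metadata.resolution,
        ppii_count=count,
        ppii_percent=round(ppii_content(ss), 1),
    )


_RANGE_FIELDS = ("resolution", "length", "ppii_count", "ppii_percent")


def advanced_query(
    summaries: Sequence[ChainSummary],
    *,
    resolution: Optional[tuple] = None,
    length: Optional[tuple] = None,
    ppii_count: Optional[tuple] = None,
    ppii_percent: Optional[tuple] = None,
    sort_by: Optional[str] = None,
    descending: bool = False,
) -> list[ChainSummary]:
    """Rows satisfying all provided inclusive (lo, hi) range criteria.

    ``None`` inside a bound leaves that side open; rows whose field is
    absent fail any criterion on it.  Order is stable unless
    ``sort_by`` names a column.
    """
    criteria = {
        "resolution": resolution,
        "length": length,
        "ppii_count": ppii_count,
        "ppii_percent": ppii_percent,
    }
    for name, rng in criteria.items():
        if rng is None:
            continue
        lo, hi = rng
        if lo is not None and hi is not None and lo > hi:
            raise ValueError(f"inverted range for {name}: [{lo}, {hi}]")

    def keep(row: ChainSummary) -> bool:
        for name, rng in criteria.items():
            if rng is None:
                continue
            value = getattr(row, name)
            if value is None:
                return False
            lo, hi = rng
            if lo is not None and value < lo:
                return False
            if hi is not None and value > hi:
                return False
        return True

    rows = [r for r in summaries if keep(r)]
    if sort_by is not None:
        if sort_by not in ChainSummary.__dataclass_fields__:
            raise ValueError(f"unknown column: {sort_by}")
        rows.sort(
            key=lambda r: (getattr(r, sort_by) is None, getattr(r, sort_by)),
            reverse=descending,
        )
    return rows


def write_assignment_fasta(
    entries: Iterable[tuple[str, str, str, str]], path
) -> None:
    """Write (id, chain, method_label, codes) records as FASTA.

    Header ``>{id}_{chain} method={label}``; code strings wrapped at 60
    columns, coil dashes written literally.
    """
    lines: list[str] = []
    for structure_id, chain_id, method_label, codes in entries:
        lines.append(f">{structure_id}_{chain_id} method={method_label}")
        for i in range(0, len(codes), 60):
            lines.append(codes[i : i + 60])
    Path(path).write_text("\n".join(lines) + "\n")


def read_assignment_fasta(path) -> list[tuple[str, str, str, str]]:
    """Inverse of :func:`write_assignment_fasta` (round-trips exactly)."""
    entries: list[tuple[str, str, str, str]] = []
    header: Optional[str] = None
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        name, _, rest = header.partition(" ")
        structure_id, _, chain_id = name.rpartition("_")
        label = rest.removeprefix("method=") if rest.startswith("method=") else rest
        entries.append((structure_id, chain_id, label, "".join(chunks)))

    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    flush()
    return entries


def export_ramachandran(
    chain: ChainModel,
    dihedrals: list[DihedralTriple],
    ss: SecondaryStructureString,
    only_code: Optional[str] = None,
) -> list[RamachandranRecord]:
    """(φ, ψ) records for residues with both angles defined.

    With ``only_code`` (e.g. ``"P"``) only residues carrying that code
    are exported — the PPII panel of a Ramachandran figure.
    """
    if not (len(chain) == len(dihedrals) == len(ss.codes)):
        raise ValueError("chain, dihedrals and assignment lengths disagree")
    records = []
    for res, d, code in zip(chain.residues, dihedrals, ss.codes):
        if d.phi is None or d.psi is None:
            continue
        if only_code is not None and code != only_code:
            continue
        records.append(
            RamachandranRecord(
                residue_number=res.residue_number,
                aa_one_letter=res.aa_one_letter,
                phi=d.phi,
                psi=d.psi,
                code=code,
            )
        )
    return records


def normalize_external_assignment(method_name: str, codes: str) -> list[str]:
    """Map a method-specific code string to helix/strand/ppii/other.

    Unknown codes within a known method normalize to "other" with a
    warning; an unknown method is an error.
    """
    try:
        alphabet = METHOD_ALPHABETS[method_name]
    except KeyError:
        raise ValueError(
            f"unknown method {method_name!r}; known: {sorted(METHOD_ALPHABETS)}"
        ) from None
    classes = []
    for c in codes:
        cls = alphabet.get(c)
        if cls is None:
            logger.warning("%s: unknown code %r normalized to 'other'", method_name, c)
            cls = "other"
        classes.append(cls)
    return classes


def class_statistics(class_strings: Iterable[Sequence[str]]) -> dict[str, float]:
    """Aggregate percentage of each class over normalized assignments."""
    counts = {c: 0 for c in CLASSES}
    total = 0
    for classes in class_strings:
        for c in classes:
            counts[c] += 1
            total += 1
    if total == 0:
        return {c: 0.0 for c in CLASSES}
    return {c: round(100.0 * counts[c] / total, 1) for c in CLASSES}
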