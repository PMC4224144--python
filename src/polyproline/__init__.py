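"""Polyproline-II aware secondary-structure assignment toolkit.

Assigns DSSP-style 8-state secondary structure from backbone
coordinates and extends it with the PPII code P (coil residues within
±29° of φ=−75°, ψ=+145°, in runs of at least two), plus ideal-backbone
construction, helix-parameter estimation, assignment pattern search
and per-chain reporting.
"""

from .structure import (
    StructureMetadata,
    BackboneResidue,
    ChainModel,
    ParseResult,
    read_structure,
    parse_metadata,
    write_pdb,
)
from .geometry import (
    DihedralTriple,
    HelixParams,
    dihedral,
    compute_dihedrals,
    build_ideal_backbone,
    helix_parameters,
)
from .dssp import HBond, SecondaryStructureString, assign_dssp, find_hbonds
from .ppii import (
    PPIIParameters,
    PPIISegment,
    residue_in_window,
    assign_ppii,
    ppii_segments,
    ppii_content,
)
from .patterns import PatternMatch, compile_pattern, search
from .report import (
    ChainSummary,
    RamachandranRecord,
    quality_filter,
    summarize_chain,
    advanced_query,
    write_assignment_fasta,
    read_assignment_fasta,
    export_ramachandran,
    normalize_external_assignment,
    class_statistics,
)

__version__ = "0.1.0"


def assign(chains, params=None):
    """Full pipeline: DSSP 8-state assignment plus PPII promotion.

    Returns one :class:`SecondaryStructureString` (method label
    "DSSP-PPII") per chain.
    """
    from .ppii import DEFAULT_PARAMS

    params = params or DEFAULT_PARAMS
    out = []
    for chain, ss in zip(chains, assign_dssp(chains)):
        out.append(assign_ppii(ss, compute_dihedrals(chain), params))
    return out
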