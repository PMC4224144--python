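"""Polyproline-II promotion rule and PPII statistics.

The rule extends an 8-state assignment with the code P: a residue is
promoted to PPII iff it currently carries a coil-region code, its
(φ, ψ) lie within ±ε of the canonical PPII centre (−75°, +145°), and
it belongs to a run of at least ``min_run`` consecutive residues that
all satisfy both conditions.  Defaults: ε = 29°, min_run = 2.  Regular
secondary structure (H, G, I, E, B) is never overwritten.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .dssp import SecondaryStructureString
from .geometry import DihedralTriple

__all__ = [
    "PPIIParameters",
    "PPIISegment",
    "residue_in_window",
    "assign_ppii",
    "ppii_segments",
    "ppii_content",
]

#: canonical PPII dihedral centre (degrees)
PPII_PHI0 = -75.0
PPII_PSI0 = 145.0
#: half-width of the acceptance window (degrees)
PPII_EPSILON = 29.0
#: minimum run of qualifying coil residues
PPII_MIN_RUN = 2


@dataclass(frozen=True)
class PPIIParameters:
    """Tunable parameters of the PPII promotion rule.

    ``eligible_codes`` defines the "coil region": by default the
    non-regular codes {'-', 'S', 'T'}; restrict to {'-'} for a stricter
    reading.
    """

    phi0: float = PPII_PHI0
    psi0: float = PPII_PSI0
    epsilon: float = PPII_EPSILON
    min_run: int = PPII_MIN_RUN
    eligible_codes: frozenset[str] = frozenset({"-", "S", "T"})

    def __post_init__(self):
        if not (0.0 < self.epsilon < 90.0):
            raise ValueError("epsilon must be in (0, 90) degrees")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


DEFAULT_PARAMS = PPIIParameters()


@dataclass(frozen=True)
class PPIISegment:
    """A maximal run of P codes (inclusive indices, 0-based)."""

    chain_id: str
    start_index: int
    end_index: int

    @property
    def length(self) -> int:
        return self.end_index - self.start_index + 1


def _circular_distance(a: float, b: float) -> float:
    """Smallest absolute angular difference in degrees (wraps at ±180)."""
    d = (a - b) % 360.0
    return min(d, 360.0 - d)


def residue_in_window(
    phi: Optional[float],
    psi: Optional[float],
    params: PPIIParameters = DEFAULT_PARAMS,
) -> bool:
    """True iff both angles lie within ±ε of the PPII centre.

    The comparison is circular and boundary-inclusive; residues with an
    undefined φ or ψ (termini, chain breaks) are never in the window.
    """
    if phi is None or psi is None:
        return False
    return (
        _circular_distance(phi, params.phi0) <= params.epsilon
        and _circular_distance(psi, params.psi0) <= params.epsilon
    )


def assign_ppii(
    ss: SecondaryStructureString,
    dihedrals: list[DihedralTriple],
    params: PPIIParameters = DEFAULT_PARAMS,
) -> SecondaryStructureString:
    """Promote qualifying coil runs to P; everything else is untouched.

    A residue becomes P iff its current code is eligible, its (φ, ψ)
    are in the window, and it sits in a maximal run of at least
    ``params.min_run`` consecutive residues satisfying both.
    """
    if len(ss.codes) != len(dihedrals):
        raise ValueError(
            f"assignment length {len(ss.codes)} != dihedral count {len(dihedrals)}"
        )
    qualifies = [
        code in params.eligible_codes and residue_in_window(d.phi, d.psi, params)
        for code, d in zip(ss.codes, dihedrals)
    ]
    codes = list(ss.codes)
    i = 0
    n = len(codes)
    while i < n:
        if not qualifies[i]:
            i += 1
            continue
        j = i
        while j < n and qualifies[j]:
            j += 1
        if j - i >= params.min_run:
            codes[i:j] = "P" * (j - i)
        i = j
    return replace(ss, codes="".join(codes), method_label="DSSP-PPII")


def ppii_segments(ss: SecondaryStructureString) -> list[PPIISegment]:
    """Maximal P-runs in chain order (empty list if none)."""
    segments: list[PPIISegment] = []
    start = None
    for i, c in enumerate(ss.codes):
        if c == "P" and start is None:
            start = i
        elif c != "P" and start is not None:
            segments.append(PPIISegment(ss.chain_id, start, i - 1))
            start = None
    if start is not None:
        segments.append(PPIISegment(ss.chain_id, start, len(ss.codes) - 1))
    return segments


def ppii_content(ss: SecondaryStructureString) -> float:
    """Percentage of residues assigned P (0–100)."""
    if not ss.codes:
        raise ValueError("empty assignment string")
    return 100.0 * ss.codes.count("P") / len(ss.codes)
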