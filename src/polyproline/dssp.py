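"""Hydrogen-bond detection and 8-state secondary-structure assignment.

The base layer that the polyproline-II rule extends.  Backbone amide
hydrogens are reconstructed from the previous residue's carbonyl
geometry, N-H···O=C bonds are scored with the Kabsch–Sander
electrostatic energy, and the classic turn/bridge grammar assigns the
codes H (α-helix), G (3₁₀), I (π), E (strand), B (isolated bridge),
T (turn), S (bend) and '-' (coil).

Residue indices used throughout are global 0-based positions over the
concatenated chains, so inter-chain bridges (β-sheets spanning chains)
are found naturally; turns and helices remain intra-chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import BackboneResidue, ChainModel

__all__ = [
    "HBond",
    "SecondaryStructureString",
    "place_amide_hydrogen",
    "hbond_energy",
    "find_hbonds",
    "assign_dssp",
]

#: Kabsch–Sander coupling constant q1*q2*332 (kcal/mol·Å)
KS_COUPLING = 0.084 * 332.0
#: a bond is recorded only below this energy (kcal/mol)
HBOND_CUTOFF = -0.5
#: energy clamp for near-contact geometries (kcal/mol)
ENERGY_FLOOR = -9.9
#: CA-CA pre-filter for the O(n²) bond scan (Å)
CA_CONTACT_CUTOFF = 9.0
#: bend threshold on the CA(i−2)->CA(i)->CA(i+2) direction change (degrees)
BEND_ANGLE_CUTOFF = 70.0

SS_ALPHABET = "HGIEBTSP-"


@dataclass(frozen=True)
class HBond:
    """Backbone hydrogen bond: donor NH(i) to acceptor C=O(j)."""

    donor_index: int
    acceptor_index: int
    energy: float


@dataclass(frozen=True)
class SecondaryStructureString:
    """Per-residue one-letter codes for one chain."""

    chain_id: str
    codes: str
    method_label: str = "DSSP"

    def __len__(self) -> int:
        return len(self.codes)

    def __post_init__(self):
        bad = set(self.codes) - set(SS_ALPHABET)
        if bad:
            raise ValueError(f"codes outside alphabet {SS_ALPHABET}: {sorted(bad)}")


def place_amide_hydrogen(residue: BackboneResidue, prev: BackboneResidue) -> np.ndarray:
    """Backbone amide H position: 1 Å from N along prev C->O reversed.

    H = N(i) + unit(C(i−1) − O(i−1)); the standard reconstruction used
    when coordinate files carry no hydrogens.
    """
    v = prev.c_xyz - prev.o_xyz
    return residue.n_xyz + v / np.linalg.norm(v)


def hbond_energy(
    h_xyz: np.ndarray,
    n_xyz: np.ndarray,
    c_xyz: np.ndarray,
    o_xyz: np.ndarray,
) -> float:
    """Kabsch–Sander electrostatic energy of one N-H···O=C contact.

    E = 0.084·332·(1/r(ON) + 1/r(CH) − 1/r(OH) − 1/r(CN)) kcal/mol,
    clamped at −9.9 for near-contact geometries.
    """
    r_on = float(np.linalg.norm(o_xyz - n_xyz))
    r_ch = float(np.linalg.norm(c_xyz - h_xyz))
    r_oh = float(np.linalg.norm(o_xyz - h_xyz))
    r_cn = float(np.linalg.norm(c_xyz - n_xyz))
    eps = 1e-6
    if min(r_on, r_ch, r_oh, r_cn) < eps:
        return ENERGY_FLOOR
    e = KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return max(e, ENERGY_FLOOR)


class _Topology:
    """Flat residue list over chains with chain/continuity bookkeeping."""

    def __init__(self, chains: list[ChainModel]):
        self.residues: list[BackboneResidue] = []
        self.chain_of: list[int] = []
        self.chain_lengths = [len(c) for c in chains]
        offset = 0
        self.offsets = []
        for ci, ch in enumerate(chains):
            self.offsets.append(offset)
            for r in ch.residues:
                self.residues.append(r)
                self.chain_of.append(ci)
            offset += len(ch)
        # bonded_to_next[i]: peptide bond i -> i+1 exists (same chain, no break)
        self.bonded_to_next = []
        for ci, ch in enumerate(chains):
            for i in range(len(ch)):
                if i < len(ch) - 1:
                    self.bonded_to_next.append(not ch.break_flags[i])
                else:
                    self.bonded_to_next.append(False)

    def __len__(self) -> int:
        return len(self.residues)

    def contiguous(self, i: int, j: int) -> bool:
        """True if residues i..j are peptide-bonded with no break."""
        return all(self.bonded_to_next[k] for k in range(i, j))


def _place_hydrogens(topo: _Topology) -> list[np.ndarray | None]:
    """Amide H per residue; None at chain starts, after breaks, and for Pro."""
    hs: list[np.ndarray | None] = []
    for i, res in enumerate(topo.residues):
        if res.aa_one_letter == "P":
            hs.append(None)  # proline has no amide hydrogen
            continue
        if i == 0 or not topo.bonded_to_next[i - 1]:
            hs.append(None)
            continue
        hs.append(place_amide_hydrogen(res, topo.residues[i - 1]))
    return hs


def find_hbonds(chains: list[ChainModel]) -> list[HBond]:
    """All backbone hydrogen bonds below the −0.5 kcal/mol cutoff.

    Bonds between sequence neighbours (|i−j| < 2 within a chain) are
    never recorded.  Inter-chain bonds are allowed.
    """
    topo = _Topology(chains)
    return _find_hbonds(topo)


def _find_hbonds(topo: _Topology) -> list[HBond]:
    n = len(topo)
    hs = _place_hydrogens(topo)
    cas = np.array([r.ca_xyz for r in topo.residues])
    bonds: list[HBond] = []
    for i in range(n):  # donor
        if hs[i] is None:
            continue
        close = np.flatnonzero(
            np.linalg.norm(cas - cas[i], axis=1) < CA_CONTACT_CUTOFF
        )
        for j in close:  # acceptor
            j = int(j)
            if topo.chain_of[i] == topo.chain_of[j] and abs(i - j) < 2:
                continue
            acc = topo.residues[j]
            e = hbond_energy(hs[i], topo.residues[i].n_xyz, acc.c_xyz, acc.o_xyz)
            if e < HBOND_CUTOFF:
                bonds.append(HBond(donor_index=i, acceptor_index=j, energy=e))
    bonds.sort(key=lambda b: (b.donor_index, b.acceptor_index))
    return bonds


def assign_dssp(chains: list[ChainModel]) -> list[SecondaryStructureString]:
    """8-state assignment (H, G, I, E, B, T, S, '-') per chain.

    An n-turn at i requires a bond NH(i+n)->CO(i) (n ∈ {3, 4, 5}); two
    consecutive n-turns seed a minimal helix (n=4 -> H, n=3 -> G,
    n=5 -> I), extended maximally.  Bridges follow the parallel /
    antiparallel bond patterns between non-overlapping triplets;
    ladders of connected bridges become E, isolated bridges B.
    Remaining turn residues get T, strong CA-trace bends S.  On
    overlap the priority is H > E > B > G > I > T > S > '-'.
    """
    topo = _Topology(chains)
    n = len(topo)
    bonds = _find_hbonds(topo)
    # bond(d, a): NH of d donates to C=O of a
    bond_set = {(b.donor_index, b.acceptor_index) for b in bonds}

    def hbond(acc: int, don: int) -> bool:
        return (don, acc) in bond_set

    same_chain = lambda i, j: topo.chain_of[i] == topo.chain_of[j]

    # --- n-turns (intra-chain, contiguous) -------------------------------
    turns: dict[int, set[int]] = {3: set(), 4: set(), 5: set()}
    for nt in (3, 4, 5):
        for i in range(n - nt):
            if not same_chain(i, i + nt) or not topo.contiguous(i, i + nt - 1):
                continue
            if hbond(i, i + nt):
                turns[nt].add(i)

    # --- helices from consecutive n-turns --------------------------------
    helix_members: dict[str, set[int]] = {"H": set(), "G": set(), "I": set()}
    for nt, code in ((4, "H"), (3, "G"), (5, "I")):
        for i in turns[nt]:
            if i - 1 in turns[nt]:
                helix_members[code].update(range(i, i + nt))

    # --- bridges ----------------------------------------------------------
    def valid_triplet(k: int) -> bool:
        return (
            0 < k < n - 1
            and same_chain(k - 1, k + 1)
            and topo.contiguous(k - 1, k)
        )

    bridges: dict[tuple[int, int], str] = {}  # (i, j) i<j -> 'P'|'A'
    for i in range(n):
        if not valid_triplet(i):
            continue
        for j in range(i + 1, n):
            if not valid_triplet(j):
                continue
            if same_chain(i, j) and j - i < 3:
                continue
            para = (hbond(i - 1, j) and hbond(j, i + 1)) or (
                hbond(j - 1, i) and hbond(i, j + 1)
            )
            anti = (hbond(i, j) and hbond(j, i)) or (
                hbond(i - 1, j + 1) and hbond(j - 1, i + 1)
            )
            if para:
                bridges[(i, j)] = "P"
            elif anti:
                bridges[(i, j)] = "A"

    strand_members: set[int] = set()
    bridge_members: set[int] = set()
    for (i, j), kind in bridges.items():
        step = 1 if kind == "P" else -1
        neighbours = ((i + 1, j + step), (i - 1, j - step))
        in_ladder = any(bridges.get(nb) == kind for nb in neighbours)
        target = strand_members if in_ladder else bridge_members
        target.add(i)
        target.add(j)
    bridge_members -= strand_members

    # --- turns and bends --------------------------------------------------
    turn_members: set[int] = set()
    for nt in (3, 4, 5):
        for i in turns[nt]:
            turn_members.update(range(i + 1, i + nt))

    bend_members: set[int] = set()
    for i in range(2, n - 2):
        if not same_chain(i - 2, i + 2) or not topo.contiguous(i - 2, i + 1):
            continue
        u = topo.residues[i].ca_xyz - topo.residues[i - 2].ca_xyz
        v = topo.residues[i + 2].ca_xyz - topo.residues[i].ca_xyz
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-9 or nv < 1e-9:
            continue
        cosang = np.clip(float(u @ v) / (nu * nv), -1.0, 1.0)
        if np.degrees(np.arccos(cosang)) > BEND_ANGLE_CUTOFF:
            bend_members.add(i)

    # --- final codes by priority -----------------------------------------
    codes = []
    for i in range(n):
        if i in helix_members["H"]:
            codes.append("H")
        elif i in strand_members:
            codes.append("E")
        elif i in bridge_members:
            codes.append("B")
        elif i in helix_members["G"]:
            codes.append("G")
        elif i in helix_members["I"]:
            codes.append("I")
        elif i in turn_members:
            codes.append("T")
        elif i in bend_members:
            codes.append("S")
        else:
            codes.append("-")

    out = []
    for ci, ch in enumerate(chains):
        start = topo.offsets[ci]
        out.append(
            SecondaryStructureString(
                chain_id=ch.chain_id,
                codes="".join(codes[start : start + len(ch)]),
                method_label="DSSP",
            )
        )
    return out
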