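import numpy as np
import pytest

from polyproline import build_ideal_backbone
from polyproline.structure import BackboneResidue, ChainModel

# canonical dihedral settings used across the suite
PPII_ANGLES = (-75.0, 145.0)
ALPHA_ANGLES = (-57.0, -47.0)
BETA_ANGLES = (-120.0, 120.0)


@pytest.fixture(scope="session")
def ppii_chain():
    return build_ideal_backbone(20, *PPII_ANGLES)


@pytest.fixture(scope="session")
def alpha_chain():
    return build_ideal_backbone(18, *ALPHA_ANGLES)


def transform_chain(chain, R, t, chain_id="B"):
    """Rigid copy of a chain (rotation R then translation t)."""
    residues = [
        BackboneResidue(
            chain_id, i + 1, "", r.aa_one_letter,
            R @ r.n_xyz + t, R @ r.ca_xyz + t, R @ r.c_xyz + t, R @ r.o_xyz + t,
        )
        for i, r in enumerate(chain.residues)
    ]
    return ChainModel(chain_id, residues, [False] * (len(residues) - 1))


@pytest.fixture(scope="session")
def antiparallel_sheet():
    """Two ideal strands paired antiparallel so that H-bond bridges form.

    The partner strand is the first rotated 180 deg about its own axis
    and shifted sideways; the offsets were chosen so the amide/carbonyl
    geometry supports inter-strand hydrogen bonds.
    """
    strand = build_ideal_backbone(8, -139.0, 135.0)
    cas = np.array([r.ca_xyz for r in strand.residues])
    axis = cas[-1] - cas[0]
    axis /= np.linalg.norm(axis)
    R = 2.0 * np.outer(axis, axis) - np.eye(3)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)
    t = 4.0 * perp - 0.25 * axis - 2.0 * np.array([0.0, 0.0, 1.0])
    return [strand, transform_chain(strand, R, t)]
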