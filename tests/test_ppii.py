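import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyproline import assign, build_ideal_backbone
from polyproline.dssp import SecondaryStructureString, assign_dssp
from polyproline.geometry import DihedralTriple
from polyproline.ppii import (
    PPIIParameters,
    assign_ppii,
    ppii_content,
    ppii_segments,
    residue_in_window,
)

from conftest import ALPHA_ANGLES, PPII_ANGLES

REGULAR = set("HGIEB")


def brute_force_ppii(codes, dihedrals, params):
    """Independent per-residue oracle: window check, then drop short runs."""
    marked = []
    for code, d in zip(codes, dihedrals):
        ok = code in params.eligible_codes
        if ok and (d.phi is None or d.psi is None):
            ok = False
        if ok:
            dphi = abs((d.phi - params.phi0 + 180.0) % 360.0 - 180.0)
            dpsi = abs((d.psi - params.psi0 + 180.0) % 360.0 - 180.0)
            ok = dphi <= params.epsilon and dpsi <= params.epsilon
        marked.append(ok)
    out = list(codes)
    i = 0
    while i < len(out):
        if marked[i]:
            j = i
            while j < len(out) and marked[j]:
                j += 1
            if j - i >= params.min_run:
                for k in range(i, j):
                    out[k] = "P"
            i = j
        else:
            i += 1
    return "".join(out)


def _triples(pairs):
    return [DihedralTriple(phi, psi, 180.0) for phi, psi in pairs]


def _ss(codes):
    return SecondaryStructureString("A", codes)


def random_fixture(rng):
    n = rng.integers(2, 40)
    codes = "".join(rng.choice(list("HGIEBTS-"), size=n))
    dihedrals = []
    for _ in range(n):
        if rng.random() < 0.1:
            dihedrals.append(DihedralTriple(None, None, None))
        elif rng.random() < 0.5:
            # concentrate near the PPII window to exercise boundaries
            dihedrals.append(DihedralTriple(
                float(rng.uniform(-110, -40)), float(rng.uniform(110, 180)), 180.0))
        else:
            dihedrals.append(DihedralTriple(
                float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180)), 180.0))
    return codes, dihedrals


class TestWindow:
    @pytest.mark.parametrize("phi,psi,expected", [
        (-75.0, 145.0, True),      # window centre
        (-104.0, 174.0, True),     # exactly on the +/-29 boundary (inclusive)
        (-104.1, 174.0, False),    # just outside in phi
        (-46.0, 116.0, True),      # other corner
        (-75.0, -145.0, False),    # psi far outside
    ])
    def test_window_membership(self, phi, psi, expected):
        assert residue_in_window(phi, psi) is expected

    def test_undefined_angles_are_never_in_window(self):
        assert residue_in_window(None, 145.0) is False
        assert residue_in_window(-75.0, None) is False

    def test_comparison_wraps_at_180(self):
        params = PPIIParameters(phi0=170.0, psi0=-170.0, epsilon=20.0)
        assert residue_in_window(-175.0, 175.0, params) is True

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PPIIParameters(epsilon=0.0)
        with pytest.raises(ValueError):
            PPIIParameters(min_run=0)


class TestAssignPPII:
    def test_all_coil_in_window_becomes_all_P(self):
        out = assign_ppii(_ss("----"), _triples([(-75, 145)] * 4))
        assert out.codes == "PPPP"
        assert out.method_label == "DSSP-PPII"

    def test_isolated_residue_is_never_P(self):
        out = assign_ppii(_ss("H-H"), _triples([(-57, -47), (-75, 145), (-57, -47)]))
        assert out.codes == "H-H"

    def test_trailing_coil_pair_promoted(self):
        out = assign_ppii(_ss("HH--"), _triples([(-57, -47)] * 2 + [(-75, 145)] * 2))
        assert out.codes == "HHPP"
        out = assign_ppii(_ss("EE--"), _triples([(-130, 125)] * 2 + [(-80, 150)] * 2))
        assert out.codes == "EEPP"

    def test_regular_structure_never_overridden(self):
        out = assign_ppii(_ss("HHHH"), _triples([(-75, 145)] * 4))
        assert out.codes == "HHHH"

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            assign_ppii(_ss("--"), _triples([(-75, 145)]))

    def test_oracle_equivalence_on_random_fixtures(self):
        rng = np.random.default_rng(20140621)
        params = PPIIParameters()
        for _ in range(300):
            codes, dihedrals = random_fixture(rng)
            got = assign_ppii(_ss(codes), dihedrals, params).codes
            assert got == brute_force_ppii(codes, dihedrals, params)

    def test_epsilon_monotonicity(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            codes, dihedrals = random_fixture(rng)
            small = assign_ppii(_ss(codes), dihedrals, PPIIParameters(epsilon=15.0))
            large = assign_ppii(_ss(codes), dihedrals, PPIIParameters(epsilon=29.0))
            p_small = {i for i, c in enumerate(small.codes) if c == "P"}
            p_large = {i for i, c in enumerate(large.codes) if c == "P"}
            assert p_small <= p_large

    @settings(max_examples=200, derandomize=True)
    @given(st.text(alphabet="HGIEBTS-", min_size=1, max_size=30), st.data())
    def test_conservative_extension(self, codes, data):
        dihedrals = [
            DihedralTriple(
                data.draw(st.floats(min_value=-180.0, max_value=180.0)),
                data.draw(st.floats(min_value=-180.0, max_value=180.0)),
                180.0,
            )
            for _ in codes
        ]
        out = assign_ppii(_ss(codes), dihedrals).codes
        # regular codes survive exactly; changes only go eligible -> P
        for before, after in zip(codes, out):
            if before in REGULAR:
                assert after == before
            else:
                assert after in (before, "P")
        # every maximal P-run respects the minimum length
        n = 0
        for c in out + "-":
            if c == "P":
                n += 1
            else:
                assert n == 0 or n >= 2
                n = 0


class TestPipeline:
    def test_ppii_fixture_interior_fully_promoted(self, ppii_chain):
        ss = assign([ppii_chain])[0]
        assert ss.codes == "-" + "P" * (len(ppii_chain) - 2) + "-"

    def test_alpha_fixture_never_P(self, alpha_chain):
        assert "P" not in assign([alpha_chain])[0].codes


class TestStatistics:
    @pytest.mark.parametrize("codes,expected", [
        ("PP-PPP", [(0, 1), (3, 5)]),
        ("------", []),
        ("P" * 13, [(0, 12)]),
        ("PPP", [(0, 2)]),
    ])
    def test_segments(self, codes, expected):
        segs = ppii_segments(_ss(codes))
        assert [(s.start_index, s.end_index) for s in segs] == expected
        for s in segs:
            assert s.length == s.end_index - s.start_index + 1

    @pytest.mark.parametrize("codes,expected", [
        ("PPPP", 100.0), ("PP--", 50.0), ("HHHHEEEE", 0.0),
    ])
    def test_content(self, codes, expected):
        assert ppii_content(_ss(codes)) == pytest.approx(expected)

    def test_content_of_empty_string_is_an_error(self):
        with pytest.raises(ValueError):
            ppii_content(_ss(""))
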