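# Methods

## Scope and model

The package assigns protein secondary structure from backbone
coordinates (N, CA, C, O) and extends the classic 8-state
hydrogen-bond assignment with the polyproline-II (PPII) state `P`.
Everything is computed from geometry; no sequence profiles, no side
chains, no energies beyond the hydrogen-bond term.

## Hydrogen-bond model and 8-state grammar

Amide hydrogens are reconstructed as
`H(i) = N(i) + unit(C(i−1) − O(i−1))` (1 Å bond); chain-start
residues, residues after a chain break, and prolines carry no donor.
A donor/acceptor pair is scored with the Kabsch–Sander electrostatic
energy `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol,
clamped at −9.9 for near-contact geometries; a bond exists below
−0.5 kcal/mol. Bonds between sequence neighbours (|i−j| < 2) are
discarded; inter-chain bonds are kept so β-sheets may span chains.

The grammar is the standard one: an n-turn at i is a bond
NH(i+n)→CO(i) for n ∈ {3, 4, 5}; two consecutive n-turns seed a
minimal helix (n=4 → `H`, n=3 → `G`, n=5 → `I`), extended maximally,
which gives the usual minimum lengths 4/3/5. Parallel and antiparallel
bridges follow the bond patterns between non-overlapping triplets
(|i−j| ≥ 3 within a chain); bridges connected through consecutive
residues form ladders (`E`), isolated bridges are `B`. Remaining
turn-span residues are `T`; a CA-trace direction change above 70°
(CA(i−2)→CA(i) vs CA(i)→CA(i+2)) is a bend `S`. On overlap the
priority is `H > E > B > G > I > T > S > '-'`. β-bulge stitching of
ladders is not implemented; on bulged sheets some `E` residues will
come out as `B`/`E` fragments.

## The PPII rule

A residue is promoted to `P` iff

* its current code is in the coil region — by default `{'-', 'S', 'T'}`,
  i.e. everything that is not a regular secondary structure; a stricter
  `{'-'}` is available via `PPIIParameters.eligible_codes`;
* its dihedrals satisfy |φ − (−75°)| ≤ ε and |ψ − (+145°)| ≤ ε with
  ε = 29° (circular comparison, boundary inclusive);
* it belongs to a run of ≥ 2 consecutive residues satisfying both.

Residues with undefined φ or ψ (termini, chain breaks) are never `P`.
The rule is a conservative extension: codes in `{H, G, I, E, B}` are
never modified. The choice of boundary-inclusive comparison and of the
default coil set are design decisions; both are parameters, and the
test suite pins their behaviour (including exact agreement with a
brute-force re-implementation over randomized inputs).

## Ideal-backbone builder

Fixtures are grown atom-by-atom from internal coordinates (NeRF-style
placement): bond lengths N–CA 1.458, CA–C 1.525, C–N 1.329, C=O
1.231 Å; angles N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°, CA–C–O
120.8°; carbonyl O placed in the peptide plane trans to the next N.
Torsions follow the IUPAC convention (cis = 0°, trans = 180°, range
(−180°, 180]), and recomputing dihedrals on a built chain returns the
requested (φ, ψ, ω) to ~1e-6°. These bond constants are conventional
ideal values; the measured pitches (9.23 Å/turn for PPII, 5.64 for α)
sit within ±0.3 Å of the canonical 9.3/5.4 figures, and small
differences in bond constants move them by a few hundredths of an Å.

## Helix parameters

Consecutive residues of a regular helix are related by a screw motion.
For each adjacent pair the rigid transform superposing the (N, CA, C)
frame of residue i onto i+1 is found by Kabsch superposition; the
rotation angle is the per-residue twist, the translation component
along the rotation axis the rise. The axis is oriented so the rise is
positive, making the twist sign the handedness (positive =
right-handed screw; PPII comes out negative, i.e. left-handed).
Values are averaged over the chain, and a per-step twist standard
deviation above 10° raises a not-helical error. The estimator is
invariant under rigid motions of the chain (tested to 1e-6), which is
why the acceptance script measures after a seeded random rotation and
translation.

## Pattern language

Patterns over the assignment alphabet compile to anchored regular
expressions inside a lookahead, so all overlapping occurrences are
found (one span per start position, greedy-longest at that start).
`*` and `X` both match exactly one code — the natural reading of
patterns like `HHH**PP*-` — and `{m,n}` bounds repetition of the
preceding token; an unbounded "any run" is unnecessary on fixed-length
strings and deliberately unsupported. Matching is case-insensitive
because third-party alphabets use lowercase sub-variants.

## Structure I/O and reporting

Parsing is backed by gemmi. Only residues with all four backbone atoms
and plausible CA–N / CA–C bond lengths (1.2–1.8 Å) are kept; the
count of dropped residues is reported. Altloc conformers are resolved
by highest occupancy (ties by identifier order); only the first model
of multi-model files is read; MSE maps to M and other non-standard
amino acids with complete backbones to X. A C(i)→N(i+1) distance above
2.5 Å flags a chain break. Resolution comes from the header, the
R-factor from `REMARK 3` (or `_refine` in mmCIF); absent values stay
absent and fail the strict quality filter (resolution < 3.0 Å and
R-factor < 1.0) with a warning. All inputs are local files; nothing is
fetched over the network.

## Synthetic fixtures: what they do and do not show

All tests run on backbones built by the internal-coordinate generator
(and rigid-body arrangements of them, e.g. the antiparallel two-strand
pairing used to exercise bridge detection). These fixtures have exact
dihedrals, ideal bond geometry, no thermal noise, no missing atoms and
no side chains. They demonstrate that the assignment rules, the
geometry and the statistics are implemented correctly; they do not
measure agreement with experimental structures, where distorted
geometry, β-bulges and borderline hydrogen bonds make assigners
differ. Problem sizes (20–30-residue fixtures, 1,000 randomized rule
fixtures, 10,000 randomized pattern trials) keep the full suite within
seconds while exercising every branch of the rules.

## Known limitations

* No β-bulge handling, no π-bulge special cases, no DSSP-4 extensions.
* The bend (`S`) threshold and the exact tie-breaking of the original
  DSSP implementations are not pinned to any reference executable;
  per-residue agreement with one is expected to be high but is not a
  release gate.
* PROSS/SEGNO/XTLSSTR are consumed as code strings only; their
  internal algorithms are out of scope.
* Redundancy culling of chain sets (sequence-identity clustering) is
  expected to be done upstream; the toolkit only consumes the
  resulting lists.
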