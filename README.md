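# polyproline

A toolkit for assigning the **polyproline-II helix (PPII)** — the third
most abundant regular protein secondary structure — on top of a
DSSP-style hydrogen-bond assignment, from backbone coordinates alone.

PPII is a left-handed, extremely extended helix centred at
φ = −75°, ψ = +145°, with ~3 residues per turn and a helical pitch of
~9.3 Å/turn (an α-helix, for comparison: 3.6 residues per turn,
5.4 Å/turn). Because PPII is stabilised by solvent rather than by
internal backbone hydrogen bonds, the classic hydrogen-bond assigners
leave it as coil. This package closes that gap:

1. **8-state assignment** (`H G I E B T S -`) from Kabsch–Sander
   hydrogen-bond energies,
   `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol with a
   bond below −0.5 kcal/mol, plus the standard turn/bridge grammar;
2. **PPII promotion**: a coil-region residue becomes `P` when its
   (φ, ψ) lie within ±ε of (−75°, +145°) with ε = 29° and it sits in a
   run of ≥ 2 such residues. Regular structure is never overwritten.

Around that core: a PDB/mmCIF reader (backbone only, header metadata),
an internal-coordinate builder for ideal poly-alanine backbones, a
screw-transform helix-parameter estimator, a pattern language for
searching assignment strings (`HHHH-PPEEE`, `HHH**PP*-`,
`PPPX{1,8}PP`), per-chain summaries with a structure-quality filter
(resolution < 3.0 Å, R-factor < 1.0), FASTA/TSV export, and
normalization of PROSS / SEGNO / XTLSSTR alphabets to
helix/strand/ppii/other classes.

## Worked example

```python
>>> import polyproline as pp
>>> chain = pp.build_ideal_backbone(20, phi=-75, psi=145)   # ideal PPII
>>> hp = pp.helix_parameters(pp.build_ideal_backbone(30, -75, 145))
>>> round(hp.pitch, 2), round(hp.residues_per_turn, 2), hp.is_left_handed
(9.23, 2.99, True)
>>> pp.find_hbonds([chain])        # PPII has no internal H-bonds
[]
>>> ss = pp.assign([chain])[0]     # DSSP 8-state + PPII promotion
>>> ss.codes
'-PPPPPPPPPPPPPPPPPP-'
>>> pp.ppii_content(ss)
90.0
>>> [s.length for s in pp.ppii_segments(ss)]
[18]
```

The termini stay coil because φ (first residue) and ψ (last residue)
are undefined there; every interior residue of the ideal PPII backbone
is promoted to `P`, i.e. 18/20 = 90% PPII content in one segment.

The same pipeline from the shell:

```sh
polyproline build-helix --n 20 --phi -75 --psi 145 -o ppii.pdb
polyproline assign ppii.pdb              # FASTA of assignment codes
polyproline stats ppii.pdb               # per-chain summary TSV
polyproline search --pattern "PPPX{1,8}PP" ppii.pdb
polyproline rama --code P ppii.pdb       # phi/psi of PPII residues
```

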