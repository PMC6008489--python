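# fragpanel

Profiling a fragment library against a kinase panel produces a small set of
interlocking quantities: single-point % inhibition matrices, selectivity
scores, IC50s from dose-response curves, assay-independent Ki values, and
size-normalised affinities. `fragpanel` implements that computational layer
as a tested, reusable pipeline for fragment-based kinase screening — the
setting where a low-molecular-weight library is screened at high
concentration (30–100 µM) against a panel representative of the kinome
(here 26 kinases anchored on the mitotic kinases MPS1, Aurora A and
Aurora B), hits are followed up with concentration-response curves, and
binding modes are checked against co-crystal structures.

## What it computes

**Selectivity scores.** For a compound screened at one concentration
against K kinases,

    S_compound(θ) = #{kinases inhibited > θ%} / #{kinases measured}

ranges from 0 (silent or perfectly selective) to 1 (hits everything);
S_kinase(θ) is the column-wise mirror image scoring how promiscuously a
kinase is hit by the library. The comparison is strict and missing cells
drop out of the denominator.

**Cheng-Prusoff conversion.** IC50s measured at different ATP
concentrations are placed on one scale via

    Ki = IC50 / (1 + [ATP]/Km,ATP)

**Ligand efficiency.** Binding free energy per heavy (non-hydrogen) atom,

    LE = 1.37 · pKi / HAC   (kcal·mol⁻¹ per heavy atom, 298 K)

with pKi = −log10(Ki in molar) and HAC derived from the molecular formula —
including formulas transcribed from HRMS `[M+H]+` lines (one H above
neutral).

**Dose-response fitting.** Four-parameter logistic curves
`y = bottom + (top − bottom)/(1 + (IC50/c)^hill)`, fitted by least squares
in log10(IC50) space with asymptotes fixed to the normalised 0–100% scale
by default, and censored "> c_max" reporting when the midpoint lies above
the tested range.

**Contact geometry.** Distance-based hydrogen-bond (ligand N/O to protein
N/O ≤ 3.5 Å) and hydrophobic (C–C ≤ 4.5 Å) contact detection in PDB
structures, with donor/acceptor role heuristics and pocket-residue
comparison between kinases (e.g. the MPS1 gatekeeper M602 vs L210 of
Aurora A).

**Synthetic screens.** A seeded generator produces complete panel screens
with known ground truth — promiscuous, selective and inactive compound
archetypes, Gaussian read noise, missing cells and replicated half-log
dilution curves — so every pipeline stage is testable end to end without
any external data.

## Worked example

```
$ fragpanel formula C9H11N4O --ion
neutral_formula: C9H10N4O
heavy_atoms: 14
monoisotopic_mz_MplusH: 191.0927
```

The ion formula from an HRMS line is reduced to the neutral molecule
(C9H10N4O, 14 heavy atoms) and its protonated monoisotopic m/z, 191.0927 Da,
matches the value such a report prints. With Ki = 94.7 µM against MPS1 this
compound's ligand efficiency is 1.37 × 4.024 / 14 = 0.39 kcal/mol per heavy
atom — fragment-hit territory.

A full synthetic round trip:

```
$ fragpanel simulate --seed 42 --out demo --n-compounds 8
wrote 6 files to demo
$ fragpanel profile --compounds demo/compounds.csv --panel demo/panel_profile.csv \
    --curves demo/dose_response.csv --conditions demo/assay_conditions.csv --out report
wrote fits.csv, potency.csv, selectivity.csv to report
$ head -4 report/potency.csv
compound_id,kinase_id,ic50_uM,ki_uM,pki,le,censored
S2,AURKA,29.2657,14.6328,4.83467,0.551958,False
S2,CK1D,76.882,38.441,4.41521,0.504069,False
S2,SRC,56.0228,28.0114,4.55267,0.519763,False
$ head -3 report/selectivity.csv
subject_type,subject_id,theta,hits,evaluated,score
compound,S1,50.0,0,26,0.0
compound,S2,50.0,3,25,0.12
```

Each fitted IC50 is halved to Ki (the simulated assays run at [ATP] = Km),
converted to pKi, and normalised by the compound's heavy-atom count;
compound S2 hits 3 of its 25 measured kinases above 50%, an S(50%) of 0.12
— a selective, ligand-efficient hit of the kind such a screen is run to
find. Identical inputs reproduce these files byte for byte.

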