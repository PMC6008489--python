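# Methods

## Formula arithmetic and masses

Formulas are parsed by an element-count grammar (symbol, optional integer,
repeated; repeated symbols accumulate) over a fixed table of twelve IUPAC
monoisotopic masses {H, B, C, N, O, F, Si, P, S, Cl, Br, I}. This covers
fragment-sized drug-like chemistry; any other symbol is a parse error,
which doubles as a typo guard on hand-transcribed tables. Parenthesised
groups, hydrates and isotope labels are out of scope.

`[M+H]+` m/z adds the proton mass (1.007276 Da) to the neutral monoisotopic
mass — i.e. the electron removed on protonation is accounted for. The
alternative convention (adding a neutral H atom, 1.007825 Da) differs by
0.0005 Da; published "calculated" values occasionally mix the two, and one
reference compound in our regression set (ion formula C17H14N3O2, printed
292.1086) follows the electron-ignoring convention. We apply the proton-mass
convention uniformly and verify printed values to ±0.0006 Da, a band that
absorbs the convention difference.

## Potency transforms

All concentrations are µM end to end; molar units appear only inside
pKi = −log10(Ki·10⁻⁶). The Cheng-Prusoff conversion
Ki = IC50/(1 + [ATP]/Km) assumes a purely ATP-competitive inhibitor and
classical (non-tight-binding) conditions; Morrison corrections and
mechanism inference are out of scope.

Ligand efficiency uses the fixed constant 1.37 kcal/mol per pKi unit
(2.303·R·T at 298 K). Against the 20 published (Ki, LE) table cells whose
heavy-atom counts follow from published ion formulas, this convention
reproduces 18 to within ±0.015; two cells (the methylpyrazole fragment and
the methoxy-bipyridine analogue, both vs Aurora A, printed 0.53 and 0.31
vs computed 0.50 and 0.34) are inconsistent with *any* single constant that
fits the rest and are treated as source inconsistencies rather than fitted
around.

Censored potencies (">100", ">1000") are first-class: the bound is stored
and Cheng-Prusoff scaled, but no pKi or LE is derived and reports render
them "> x (-)". The single-point model (% = 100/(1 + (IC50/c)^h)) and its
inverse are exact inverses on (0, 100)%; responses at or beyond the
endpoints return a censored bound at the screening concentration instead of
an extrapolation.

Printed values are rounded half-up (0.335 → 0.34) at presentation only —
2 dp for LE and scores, matching pharmacology-table convention; Python's
banker's rounding would disagree on exact halves.

## Selectivity scores

S(θ) uses a strict comparison (> θ): a cell at exactly the threshold does
not count. Missing cells are removed from the denominator rather than
imputed — a compound measured against 25 of 26 kinases is scored out of 25.
Scores are held as exact integer ratios (hits, evaluated) and rounded only
in reports, so re-reading a report and recomputing from the stored counts
reproduces the rounded values.

## Dose-response fitting

The 4PL is fitted by trust-region least squares over [log10(IC50), hill],
with bottom = 0 and top = 100 fixed by default (the normalised
%-inhibition readout); a flag frees the asymptotes. The log10(IC50)
parametrisation makes the fit equivariant under rescaling of the
concentration axis and keeps iterates positive. Initialisation: asymptotes
from the data extremes, IC50 at the tested concentration whose response is
nearest half-height, hill = 1 — robust for monotone data. Tolerances are
1e-12 on step/gradient/cost with at most 500 iterations per parameter;
noiseless synthetic curves are recovered to < 1e-6 relative error for hill
in [0.5, 2]. Failure modes return `converged=False`, never an exception;
flat response vectors are flagged unconverged/censored since they carry no
midpoint information. A fitted IC50 above the top tested concentration is
reported as a censored "> c_max" bound rather than an extrapolated value.
Hill slopes are bounded to [1e-3, 20]; outlier rejection and biphasic
models are out of scope.

## Synthetic screen generator

The generator emulates the statistical structure of a 26-kinase
fragment-panel screen, not any particular dataset. Defaults: 26 kinases, a
24-member library, 100 µM single-point screen, [ATP] = Km for every kinase
(Km normalised to 1 µM so `atp_over_km` is the one knob that matters),
additive Gaussian read noise of 5% (single point) and 2% (curves), 8-point
half-log dilutions from 100 µM in triplicate, 2% random cell dropout, and
values clipped to [−20, 120] — the range artefact-bearing normalised
readouts occupy in practice. Noise is additive Gaussian on the % scale, the
simplest model consistent with a normalised biochemical (mobility-shift
style) readout.

Compound archetypes: promiscuous (pKi ~ N(5.0, 0.5) iid across kinases),
selective (baseline N(3.0, 0.3) with 1–3 target kinases boosted +1.5 log
units) and inactive (N(2.5, 0.3)), mixed 20/40/40% by default — a
fragment screen is mostly quiet, with a few clean hits and the occasional
promiscuous scaffold. Under these settings the promiscuous archetype has an
analytic expected S(50%) of ≈ 0.92 (a cell clears 50% iff pKi > 4.30, and
P[N(5, 0.5) > 4.30] ≈ 0.92) and inactive compounds sit below 0.1; the
selective archetype spans the low-score range. The forward model is exactly
the inverse of the analysis (Ki = 10^(−pKi) µM, IC50 = Ki·(1+[ATP]/Km),
one-site response), so with noise switched off the analysis recovers the
truth identically — the basis of the round-trip tests.

What the generator does **not** emulate: pharmacophore-driven correlation
between related compounds or related kinases, plate/batch effects,
compound-concentration errors, partial inhibition, and solubility-driven
screen-concentration changes. Passing recovery tests therefore demonstrate
correctness of the computational pipeline under its stated assumptions, not
robustness to those real-data pathologies.

Dose-response follow-up covers the cells whose true IC50 lies inside the
tested dilution range, mirroring the practice of running curves only for
single-point actives; recovery statistics (median |ΔpKi| < 0.05, |bias| <
0.02 at default noise) are computed over converged, uncensored fits of 200
such pairs. All randomness derives from one integer seed through named
`numpy` generator streams; no global RNG state is touched, and identical
seeds give bit-identical files.

## Contact geometry

Hydrogen bonds are detected by a distance-only criterion: ligand N/O to
protein N/O within 3.5 Å. Crystal structures at the 2.5–3.0 Å resolutions
typical of kinase-ligand complexes carry no hydrogen positions, and the
distances quoted for such structures are bare donor–acceptor separations,
so an angular term would manufacture precision the data does not have.
Donor/acceptor roles are assigned from protein-atom chemistry (backbone and
side-chain carbonyl/carboxylate O accept; backbone N and saturated
side-chain N — including the lysine NZ that forms the catalytic-lysine
contact — donate); pairs whose protein atom is chemically ambiguous
(hydroxyls, histidine ring N) are labelled undetermined. Hydrophobic
contacts are C–C pairs within 4.5 Å grouped by protein residue.

Parsing is delegated to gemmi; hydrogens are dropped, waters excluded by
default, and alternate locations collapsed to the highest-occupancy
conformer (ties prefer altloc 'A'). Residue numbering is taken verbatim
from the file; pocket comparison between two structures uses a
user-supplied residue-number correspondence map — structural superposition
is explicitly out of scope, so the map encodes whatever alignment the user
trusts. Unmapped residues are reported with a null flag, not raised.

## Reporting

All CLI subcommands are deterministic: fixed row ordering (compound id,
then kinase id, lexicographic), half-up rounding at presentation only, and
a config echo in every output directory; identical inputs give
byte-identical outputs. Exit codes: 0 success, 2 input/validation error,
3 numerical failure.

## Problem sizes

The test suite exercises the statistical claims at the scales they are
stated for: 200 simulated curve fits for pipeline recovery, 1,000 random
matrices for the selectivity oracle, 100 Monte-Carlo replicates for noisy
fit accuracy, and 25–40 random synthetic complexes for contact-detection
equivalence. These sizes give stable medians while keeping the whole suite
in a few seconds.
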