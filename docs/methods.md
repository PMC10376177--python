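# Methods

## Mass arithmetic

Residue masses are the standard monoisotopic and average values for the 20
proteinogenic residues (hard-coded in `proteoforms`, glycine 57.02146 Da
monoisotopic, water 18.010565 Da); proton 1.007276 Da, hydrogen atom
1.007825 Da, isotope spacing 1.00335 Da. Peptide monoisotopic mass is the
residue sum plus water plus modification deltas; protein average mass uses
the abundance-weighted residue table and is reported in kDa to three
decimals. Against Biopython's independent tables the monoisotopic mass of a
723-residue chain agrees to ~1 mDa and the average mass to ~0.7 Da (the
residue tables are rounded to different precision); tests pin these at
0.005 Da and 0.002 kDa respectively.

Trypsin cleaves C-terminal to K/R except before P; protein termini are
peptide termini; default `max_missed = 2` (the common search default, and
enough to cover adduct-site peptides with awkward boundaries).
Carbamidomethyl (+57.02146, C) is fixed; oxidation (+15.99491, M) is
variable with at most 2 per peptide and at most 2 per crosslink candidate,
bounding the combinatorics.

The molar extinction coefficient at 280 nm is the chromophore sum
nW·5500 + nY·1490 + n_cystine·125 (Gill & von Hippel). All cysteines are
treated as reduced by default (`n_cystine = 0`), consistent with a
reduced/alkylated sample; the cystine count is a parameter.

Residue numbering always refers to the natural (untagged) chain; a
C-terminal affinity tag is carried as `tag_span` and excluded from mass and
extinction computations unless `include_tag=True`. This matches the
convention in which the distal tryptophan is "Trp90" in both a 723- and a
750-residue KatG.

## Crosslink candidates

An adduct is an ordered chain of sites; a covalent bond joins each adjacent
pair, and each bond forms with the loss of two hydrogen atoms, so
`M_corrected = M_naive − n_bonds × 2.01565 Da`. Candidates are emitted for
the full chain and every contiguous sub-chain (both the tri-peptide and
di-peptide species are observed in practice); non-contiguous pairs are
flag-enabled but off by default. A peptide covering several sites is
counted once, and the bond between two sites on one peptide still loses
2 H. Choices in which two *different* overlapping peptides would cover the
chain are skipped (they would double-count residues). Matching accepts a
candidate when the observed deconvoluted mass is within 0.05 Da (default,
Orbitrap-scale) of the corrected mass; the bond count is inferred
independently as `round(Δ_naive / 2.01565)`. Masses are also reported
rounded to integer daltons (half away from zero), the convention in which a
two-bond triple "differs by 4 Da" from its naive sum.

### A precursor-level isobaric degeneracy

Because water and an oxidation differ by exactly one bond loss
(18.010565 − 15.994915 = 2.015650 Da), a candidate consisting of a
missed-cleavage peptide that merges two adjacent components (one water
fewer) plus one Met oxidation is *exactly* isobaric with the fully cleaved
crosslinked chain with one more bond. A precursor-mass-only search cannot
distinguish these; the report therefore lists every accepted isobar, and
resolving them would need MS2 localisation, which is out of scope. This is
a property of the mass arithmetic itself, not of the implementation.

## Signal processing

Runs are centroided MS1 scans. XIC extraction sums centroid intensities
within a ppm window (default 10 ppm) per scan; a run-level index sorted by
m/z makes each extraction a binary search. Coelution requires, per
candidate, apexes in at least `min_charges = 2` charge-state XICs within
`rt_tol = 0.2` min of their median; an apex counts only if it exceeds 3× the
median nonzero intensity of its own trace (a simple robust noise floor — a
flat or noise-only trace never qualifies). Deconvolution reads, in the
single scan nearest the median apex RT, the most intense centroid within
tolerance of each supporting ion form, inverts each to a neutral mass and
takes the median; the maximum deviation from the median is reported as
dispersion. The "time window" for deconvolution is thus one scan — the
narrowest defensible choice, and exact on synthetic data.

The pipeline extracts XICs for the ion forms of *both* mass hypotheses per
candidate — bond-corrected first, then the naive sum — so that a species
lacking the crosslink is still detected and is then rejected on its
≈ +2 Da-per-bond mass delta rather than silently missed.

Charge inference from isotope spacing uses z = round(1.00335 / median
spacing), rejecting windows whose spacings deviate >20% from their median
(mixed species) or whose median is >5% away from 1.00335/z for the nearest
integer z (between two charge hypotheses). The default charge range for
crosslinked species (4.5–6.5 kDa) is z = 3..8.

Monoisotopic-vs-apex isotope misassignment correction (±1.00335/z) exists
behind a flag and is off by default: both the theory and the generator
target the monoisotopic peak.

## Synthetic data: what it emulates, and what it does not

`simulate_run` plants species on a regular RT grid (default 0.01 min over a
60-min gradient; tests use 0.05 min to stay fast) with averagine-Poisson
isotope envelopes (composition C4.9384 H7.7583 N1.3577 O1.4773 S0.0417 per
111.1254 Da; the Poisson rate is the expected number of heavy-isotope
substitutions), Gaussian elution profiles, per-peak ppm jitter and a
uniform-m/z, exponential-intensity noise floor. One integer seed drives all
randomness; identical seeds give byte-identical runs. Not emulated: peak
tailing, detector saturation, co-isolation artefacts, profile-mode data,
MS2. A green planted-recovery test therefore establishes the correctness of
the extraction/deconvolution arithmetic under realistic-but-idealised
signals, not robustness to every chromatographic pathology.

The synthetic protein generator (`synthetic_katg_protein`) draws residues
from average globular-protein frequencies, pins the adduct-site residues at
their published positions, keeps them strictly interior to tryptic peptides
and guarantees a cleavage site between consecutive adduct sites. It is a
labelled stand-in: it reproduces the length and site geometry of the real
proteins, not their sequences, so printed masses of the real proteins are
not reproduced by it (the real GenBank chains require a network fetch and
are supplied by the user as FASTA when available).

Kinetics traces are straight lines plus Gaussian noise; melt curves are
logistic in temperature on a 20–95 °C, 0.5 °C grid (a 1 °C/min ramp sampled
twice per degree), default baseline ratios 0.80 → 0.95 — typical nanoDSF
350/330 values — and steepness 2 °C.

## Kinetics and melting analysis

`fit_linear_rate` uses ordinary least squares; without an explicit window it
takes the longest initial window with R² ≥ 0.99 (initial-rate convention;
a constant trace counts as R² = 1 with slope 0). Specific activity:
`U/mg = |slope| / (ε[mM⁻¹cm⁻¹]·path[cm]) × volume[mL] / enzyme[mg]`, with
M⁻¹cm⁻¹ inputs converted by 10⁻³. A per-substrate stoichiometry divisor is
available but defaults to 1 (e.g. whether the 2 H₂O₂-per-turnover of the
catalatic reaction is folded into the unit is a reporting convention, not
applied by default).

`melt_analysis` smooths the ratio with a 9-point centered moving average,
takes the temperature of the extremum of its first derivative, and refines
it below the grid step with a parabola through the three derivative points
around the extremum. The 5-point window first tried was too noisy: at
2%-of-amplitude noise its median Tm error over 100 seeded curves was
0.52 °C, above the half-grid-step target, while the 9-point window with
parabolic refinement achieves 0.34 °C and remains narrow against a
transition several °C wide. Onset is the lowest temperature at which the
smoothed curve departs the pre-transition baseline by >2% of total
amplitude (the definition is operationalised here; "where the molecules
start to denaturate" has no standard formula), clipped to ≤ Tm. A curve
whose amplitude is under 4× the point-to-point noise estimate raises
"no transition detected".

## Pipeline and configuration

`PipelineConfig` is a flat dataclass, loadable from a TOML file (nested
tables are flattened); every report embeds the resolved configuration and a
hash of it. Reports are TSV (one row per candidate, exact and rounded
masses, deltas, accept/reject reason) plus a JSON summary. The `katglink`
CLI maps subcommands 1:1 onto library operations (`digest`, `candidates`,
`simulate`, `search`, `kinetics`, `melt`); `search` exits 0 iff at least one
candidate was accepted. Fixed config and inputs give byte-identical reports.

## Known limitations

- Precursor-level matching only: no MS2 crosslink localisation, no FDR over
  decoy crosslinks, and the isobaric degeneracy above is reported, not
  resolved.
- No retention-time alignment across runs and no profile-mode peak picking;
  mzML support is a deliberate MS1-centroid subset.
- Semi- and non-tryptic peptides are out of scope, as is translating
  nucleotide records: users supply protein FASTA.
- The absolute specific activities of the published enzymes depend on
  per-cuvette enzyme amounts that are not public; the package computes U/mg
  from user-supplied assay contexts and makes no claim about those values.
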