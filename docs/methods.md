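# Methods

## Scope and pipeline

`speccount` quantifies proteins from already-searched shotgun proteomics
data. The pipeline is: read a FASTA database and a tab-delimited PSM
table; keep PSMs with q-value ≤ 0.01 (inclusive, user-modifiable); strip
modification annotations from peptide strings; map each peptide to every
database protein containing it as an exact substring (no I/L
equivalence); classify peptides as unique (one protein) or degenerate
(two or more); tally spectral counts; score with one of Raw, NSAF, dNSAF,
emPAI or SI_N; optionally restrict to a parsimonious protein set; write a
tab-delimited table sorted by descending score (ties broken by ascending
identifier, values at 6 significant digits). Database searching, PSM
rescoring, and PepXML/mzIdentML/mzXML input are out of scope; the PSM
dialect supported is the tab-delimited one with columns
`file, scan, charge, sequence, q-value` (optional `protein id`, which is
ignored in favour of re-mapping against the FASTA so that counts and
lengths always refer to the same database).

A spectrum is identified by (source file stem, scan, charge), so the same
scan searched at two charge states is two PSMs. A PSM's spectrum counts
once for every protein its peptide maps to, not once per occurrence of
the peptide within a protein's sequence: s_N counts spectra, not matches.

## Scoring conventions

The normalising sums of NSAF, dNSAF, emPAI and SI_N run over the *scored*
proteins — those with at least one retained spectral count — not over the
whole database. For the count-based metrics the distinction is cosmetic
(zero-count proteins contribute zero terms); for emPAI it matters, since
the exponential form would otherwise assign mass to unobserved proteins.

Distribution factors: `d_{j,N} = s^u_N / Σ_{i∈S_j} s^u_i` with S_j the
set of proteins sharing degenerate peptide j. When no sharer has unique
evidence the formula is 0/0; the count is then split equally
(`d = 1/|S_j|`), which preserves Σ_N d_{j,N} = 1.

emPAI's "observable" peptides are the in-silico digestion products within
residue-length bounds 6–50 (defaults; configurable). Digestion uses
trypsin cleaving after K or R except before P, zero missed cleavages by
default. Observability is a proxy choice — a mass- or scan-range window
would be an alternative — but length bounds are transparent, standard in
emPAI practice, and exactly testable.

SI_N's denominator `Σ_j SI_j` uses the *raw* (non-length-normalised)
per-protein intensity sums. The equation admits a second reading in which
the denominator sums length-normalised indices; the raw-sum reading is
implemented because it keeps the denominator independent of the protein
under scoring and reduces to the intensity analogue of NSAF's
normalisation. Consequently SI_N scores do not sum to 1. Spectra shared
between proteins contribute their intensity to every sharing protein,
mirroring the counting convention.

Peptide-level scores are provided for Raw (PSM count per peptide) and the
SI_N analogue (summed intensity / peptide length / total). Peptide-level
emPAI and dNSAF are not defined: there is no observable/degenerate notion
at peptide level.

Numerical determinism: normalising sums are accumulated in sorted-key
order, so scores are bit-identical under permutation of the FASTA or the
PSM table.

## Parsimony

Greedy set cover over the post-filter observed peptides: repeatedly
select the protein covering the most uncovered peptides, ties broken by
ascending protein identifier (the greedy rule leaves ties unspecified;
determinism is required for reproducibility). Restriction to the
parsimonious set optionally renormalises NSAF/dNSAF/emPAI to sum to 1
again; Raw and SI_N are never rescaled. Full protein-grouping graphs and
FDR-aware inference are out of scope.

## Evaluation statistics

*Reproducibility*: for a pair of replicate runs scored with the same
metric, Spearman rank correlation over the proteins scored in both
(average ranks for ties; proteins seen in only one run are ignored).
Metrics are compared with two-sided Wilcoxon signed-rank tests on paired
correlation vectors — exact null distribution up to 25 non-zero
differences (zeros dropped), normal approximation beyond — at the
Bonferroni-corrected level α/(number of metric pairs); with four metrics,
0.05/6 ≈ 0.008333. A dominance edge A→B is emitted when A's net signed
ranks are positive and the p-value beats the threshold; edges can never
point both ways. Technical vs biological correlations are compared with a
two-sided Mann–Whitney rank-sum test, exact when both groups have ≤ 20
values and no ties, otherwise the tie-corrected normal approximation.

*Linearity*: for each spiked protein with a positive count in ≥ 3 runs
(configurable), ordinary least squares of count (response) on known
amount (predictor) over the runs where the protein is scored; runs with a
zero or absent count are excluded rather than imputed as zero, in the
spirit of the positive-count filter. Reported per protein: slope,
intercept, Pearson r, R² = r², and the mean percent error
`MPE = (100/m) Σ |fitted − observed| / observed` over the m fitted
points. MPE is taken in this standard reading since no alternative is
canonical. A flat response (constant counts) is reported with r = 0
rather than an undefined correlation; constant amounts make the fit
degenerate and the protein is listed as skipped. Fits are on the linear
scale throughout; no log transform is applied. Metric comparison on
linearity repeats the signed-rank machinery separately on per-protein r,
R² and MPE, with the edge direction reversed for MPE (lower is better).

## Synthetic data

The generator produces data with the statistical structure the metrics
are sensitive to, not realistic spectra (peak m/z values are
placeholders; retention time and instrument effects are not modelled).

*Proteome*: each protein is a concatenation of random tryptic peptides
(6–18 residues, interior residues excluding K/R/P, terminating in K or
R), giving ≥ 3 observable peptides per protein; lengths default to
150–400 residues. Shared-peptide structure is created by inserting
`n_shared_peptides` peptides (8–14 residues) verbatim into two proteins
each.

*Counts*: `total_psms` spectra are allocated to proteins by a multinomial
draw with probability ∝ abundance × length — the generative regime in
which NSAF's length normalisation recovers relative abundance — then
uniformly over each protein's in-bounds tryptic peptides. An `expected`
sampling mode replaces the draw with largest-remainder rounding of the
expected counts, modelling the noise-free limit used in the recovery
test. Default abundances are log-uniform over two decades, a deliberately
modest slice of a real proteome's dynamic range. True-positive q-values
are uniform below 0.01; a configurable decoy fraction adds rows with
q-values in (0.02, 0.5) and peptides absent from the database. Spectrum
total intensities are log-normal (heavy-tailed, exercising SI_N's
intensity weighting); written MGF peaks are a Dirichlet split of each
total.

*Replicates* redraw counts with abundances perturbed by i.i.d.
multiplicative log-normal noise of unit mean; the coefficient of
variation defaults to 0.30 for biological and 0.10 for technical
replicates, so technical pairs correlate better by construction.

*Dilution series*: spiked proteins follow amounts
`top_amount / fold^(step−1)` (defaults 870 fmol, fold 2, 8 standards);
background proteins keep a fixed abundance averaging 1000 fmol-equivalents
per protein. The background must dominate the total signal: the relative
metrics are compositional (they sum to 1), and if the spikes carried a
large share of the signal their scores would saturate at the top of the
curve regardless of amount, as in a real spike-in experiment without a
lysate background. All randomness derives from the single `SimSpec.seed`
through per-purpose child streams (labels hashed with CRC32, not
Python's randomised `hash`), so identical specs give byte-identical
output files.

What passing tests on these simulations do *not* show: robustness to
chromatographic drift, peak-intensity miscalibration, search-engine score
biases, or shared-peptide structure as dense as real paralog families.

## Testing strategy

Every metric is checked against an independent naive transcription of its
formula on hundreds of random instances (agreement to 1e-12); digestion
is checked against a separate hand-rolled cleaver; greedy covers are
compared with the exhaustive minimum cover on instances of ≤ 12 proteins;
the exact Wilcoxon tails are asserted against hand-enumerated null
probabilities (2/2¹⁰ for ten uniformly signed differences; 2/C(6,3) for
fully separated groups of three). Simulation-based tests pin seeds and
use problem sizes (depths 10⁴–10⁵, tens of proteins) chosen to keep the
whole suite fast while leaving comfortable statistical margins.
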