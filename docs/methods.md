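# Methods

## Data model and filtering

A search-result table holds one row per peptide-spectrum assignment:
`sample_id, spectrum_id, peptide, e_value, is_decoy, species` (semicolon
list), optional `proteins`. A spectrum with several equally likely peptides
(identical E-values, typically isobaric alternatives) occupies several rows
sharing its `spectrum_id`; a sample's spectrum count is the number of
*distinct* spectrum ids, never the number of rows. Species names are matched
case-insensitively after whitespace normalization. Modifications are written
inline as residue plus bracketed delta or name — `P[OH]` / `P[+15.9949]` for
hydroxyproline, the dominant collagen modification; the modification table is
extensible but deliberately small.

FDR is estimated per sample as (distinct decoy peptide sequences ≤ E) /
(distinct target peptide sequences ≤ E). Non-redundancy uses the exact
peptide string including modification annotations: a modified and an
unmodified form are distinct identifications. Candidate thresholds are the
observed target E-values plus the cap E = 0.01 itself, evaluated with ≤
comparisons; the filter keeps the largest candidate with FDR < 1%, and the
cap applies unconditionally because many bone samples produce no decoy hits
at all, which would otherwise leave the threshold unbounded. Decoy/target
ties at one E-value count the decoy as kept (conservative). Filtering is
idempotent, and equal-E alternatives of one spectrum survive or fail
together since they share one E-value.

## Tallies, ratios, winners

Three datatypes tally the same filtered sample:

* **peptide** — distinct peptide sequences per taxon / total distinct peptides;
* **psm** — all match rows per taxon / total rows (equal-E alternatives count);
* **spectra** — distinct spectra per taxon / total distinct spectra, a
  spectrum being attributed to the union of its peptides' species sets.

An item shared by k taxa increments all k counts while denominators stay
totals of distinct items, so per-taxon ratios are attribution fractions, not
a distribution — they may sum to more than 1. This is deliberate: the spectra
datatype neutralizes the multiplier effect of isobaric alternatives (only
one peptide per spectrum can be real) and counts redundant spectra as
evidence, which is why it separates correct from incorrect identifications
better than peptide counting. The winner is the arg-max taxon; exact ties
are broken lexicographically and always flagged. Order-level tallies map
species through a validated taxonomy (unmapped species are dropped with a
warning, never guessed); the human level is the binary collapse "species set
contains Homo sapiens".

## Substitution classification

A wrong-species peptide is compared against the closest equal-length
consensus peptide of the sample's true species (minimal Hamming distance on
modification-stripped sequences; no same-length candidate → excluded and
counted separately, since no alignment procedure is defined for collagen
tryptic peptides of different lengths). The call is **isobaric** when total
monoisotopic masses (modifications included) agree within 0.02 Da *and* a
mechanism is identifiable: positionwise equal-mass residue swap (I⇔L),
modification-compensated pair within a window of ≤ 3 residues (e.g.
hydroxyproline+Ala ⇔ Pro+Ser), or residue-multiset-preserving inversion
within the same window ("adjacent or near adjacent"). The 0.02 Da tolerance
enforces strict chemical isobarity: K vs Q (0.036 Da) is a sequence change,
not an isobaric pair, even though typical fragment tolerances (0.3 Da) could
not distinguish them. Everything else is **non-isobaric**, annotated with the
summed minimal nucleotide distance over changed positions (minimum Hamming
distance over codon pairs of the standard genetic code) — the biological
plausibility scale: single-nucleotide single-residue changes may be true
polymorphisms; multi-nucleotide and multi-residue variants are almost always
artifacts. The isobaric decision is symmetric in peptide and reference.

E-value stratification across the classes {correct, isobaric, non-isobaric
1 AA, non-isobaric >1 AA} runs a one-way ANOVA plus Tukey HSD at α = 0.01 on
log10(E), because E-values span many orders of magnitude; groups with n < 2
are summarized but excluded from testing. The package reproduces, as a demo
rather than a filtering feature, the finding that a median-E cutoff on the
worst class also removes a substantial share of correct spectra — which is
why no E-value filter beyond the FDR threshold is applied.

## Sample similarity

For samples X and Y, a spectrum of X is shared when any of its peptide
sequences occurs among Y's identified sequences (equal-E alternatives all
contribute; exact strings including modifications by default, with a
modification-stripped option). The similarity ratio
(x_shared + y_shared)/(X_T + Y_T) accommodates the large spread in spectral
depth (79–710 spectra per sample) without further normalization. Clustering
is agglomerative on distance 1 − similarity with average linkage (UPGMA) —
the natural choice for a similarity matrix without an embedding — with
deterministic child ordering; dendrograms serialize to Newick.

## Bayesian identification probability

Each model regresses label ∈ {0,1} (winner matches known truth) on a single
untransformed covariate: the winner ratio (species and order models) or the
human spectra ratio (human model). Samples of unknown species are excluded
from the species model only. Priors are Normal(0, 10²) on both α and β —
weak enough to be negligible at n ≈ 56, strong enough to keep the posterior
proper under complete separation, which is the expected regime for the order
and human models.

Sampling uses the affine-invariant ensemble MCMC sampler (emcee) with a
differential-evolution move mixture (80% DE, 20% DE-snooker), which mixes
far better than the default stretch move on this strongly correlated
two-parameter posterior. Defaults: 16 walkers × 2000 retained steps after
1000 warmup steps, seeded end to end; walkers are exposed to ArviZ as chains
for split-R̂ and ESS diagnostics (target R̂ < 1.01, warned otherwise). This
ensemble sampler was chosen over gradient-based MCMC as the package's own
design decision: the posterior is two-dimensional and cheap, so gradient
information buys nothing, while the ensemble is dependency-light and exactly
reproducible from one integer seed.

Datatype comparison uses PSIS-LOO on the deviance scale (−2 × expected log
predictive density) via ArviZ, with Pareto-k diagnostics surfaced and a
recommendation to fall back to exact LOO when any k > 0.7. Exact LOO refits
the model n times (per-refit seed = base seed + index), predicts each
held-out sample, and summarizes with the held-out posterior predictive mean,
a central 95% interval, and ROC/AUC over the means (trapezoidal; equals the
Mann–Whitney U statistic normalized by n₁n₀). Probability curves report the
central 95% interval of the per-draw p at each grid ratio (an interval of p
draws, not of the mean curve — the wider, more conservative reading).

A caveat worth knowing: exact-LOO AUC is *downward*-biased under the null at
small n, because removing a held-out positive lowers its own training base
rate; with no signal the held-out predictions anti-rank the labels. Chance
performance is therefore an upper reference, not a central one, for permuted
labels.

## Synthetic cohorts

The generator emulates the filtered search-result layer, not spectra or
search-engine physics. Default conditions (the study conditions): 58 samples
across 18 taxonomic groups (15 known species + bird/fish/frog of unknown
species + two ovicaprids generated from sheep with unknown true species);
spectra per sample uniform on [79, 710]; spectra per peptide sequence from a
shifted geometric with mean ≈ 5.7; 80% of spectra correct-species; wrong
identifications 36% isobaric / 64% non-isobaric, the latter 64% single-AA /
36% multi-AA; 92% of correct peptides shared with other species; equal-E
alternative peptides on 17% / 1.6% / 0.5% of spectra; Poisson decoys at
0.004 per spectrum (many samples draw none); and a 5% tail of junk targets
with E ∈ (0.01, 0.1) for the filter to remove.

Consensus peptide pools evolve from one ancestral pool of collagen-like
G-X-Y tryptic peptides along class → order → species branches (substitution
probabilities 0.5 / 0.25 / 0.10 per peptide), so related species share more
identical peptides. Database-representation skew is modelled at the
attribution level rather than by simulating a sequence database: a correct
peptide is attributed to its own species with probability
db_entries/(db_entries + 1000), with lost and shared attributions drawn from
other species weighted by database entries × 3 for same-order relatives.
Species with ~50–90 database entries (deer, bear, otter, squirrel,
woodchuck, opossum) therefore lose their winner slot to well-represented
neighbours — the documented failure mode of real low-representation taxa.
Per-class E-values are log-uniform on configurable ranges whose medians
order correct ≈ isobaric < 1-AA < multi-AA; the true per-class medians of
the original data are not published, so these ranges are free parameters
with the stated defaults.

What passing tests on this generator do *not* show: robustness to real
fragment-level ambiguity (the generator plants mechanisms, it does not
rescore spectra), to contaminated or multi-source samples, to taxonomies
with many unsequenced sister species, or to search engines whose E-value
calibration differs from the class-dependent ranges assumed here. Real
species-level AUC will be lower than the synthetic one because real
misidentified samples can carry high wrong-winner ratios.

## Numerical choices and edge cases

Identical seeds give bit-identical cohorts and identical posterior
summaries. Empty samples (nothing below the E cap) produce flagged empty
results and warnings, never exceptions; all-one-label model inputs fit under
the priors with a warning; ratios outside [0, 1] and non-positive E-values
are validation errors; AUC with one class absent is an error rather than a
convention. Test and acceptance runs use reduced sampler settings
(16 × 600–800 draws) and a reduced 7-species cohort where full defaults are
not needed; the acceptance script runs the full 58-sample conditions.
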