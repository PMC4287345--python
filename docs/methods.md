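# Methods

## Model and procedure

`edrug` tests whether the mutation status of a protein functional region
(PFR) predicts drug response across a panel of samples. The response
variable is the activity area (area above the dose–response curve,
unitless, non-negative; on CCLE-like panels roughly 0–8). The unit of
testing is a 1-based inclusive residue interval on one protein isoform,
tagged by annotation source (`pfam`, `predicted_domain`, `idr`). Regions
are never merged: overlapping regions — common, since domain annotation
and disorder prediction are independent — are tested independently, and
a mutation inside several regions counts for each of them. Per gene,
analyses conventionally use the largest isoform (ties broken by
lexicographically smallest isoform id, so selection is deterministic).

Only missense mutations are admitted. Truncating variants are rejected
at parse time (with a logged count) because a truncation in an upstream
domain also removes every downstream region, making region attribution
ambiguous; silent variants carry no protein change.

The screen applies three two-sided Wilcoxon rank-sum comparisons per
(region, drug) pair, in order, with the first failure recorded as the
pair's status:

| stage | groups | keep when | default level |
|---|---|---|---|
| minimum mutations | — | ≥ `min_mutated` mutated profiled samples | 2 |
| stage I | region-mutated vs comparison group | `p₁ < p_stage1` | 0.01 |
| gene level | gene-mutated vs gene-unmutated | `p_g ≥ p_gene` | 0.01 |
| stage II | region-mutated vs mutated-elsewhere-in-gene | `p₂ < p_stage2` | 0.05 |

The gene-level comparison is an *exclusion* filter: a pair whose signal
is just as visible gene-wide carries no region-specific information.
Stage II uses a looser level than stage I because both of its groups are
small (within-gene mutation counts) and far fewer pairs reach it. The
decision rule uses these raw staged thresholds; Benjamini–Hochberg
q-values over all stage-I-tested pairs are attached as an informational
column only, leaving the published-style decision rule unchanged.

Two conventions were genuinely open and are both implemented:

* **Stage-I comparison group.** Default `gene_unmutated` (samples with
  no missense anywhere in the gene), giving the cleanest contrast with
  stage II; `region_unmutated` (everyone not mutated in the region,
  which additionally pools other-region mutants) is selectable.
* **Stage-I level.** 0.01 by default; configurable, since a stricter
  0.001 variant of the same design is equally defensible.

A sample mutated both inside and outside a region belongs to the
region-mutated group only: the region perturbation is present, and the
sample must not be double-counted into the within-gene comparison group.
When every gene mutation lies inside the region, stage II has no
comparison group; its p-value is recorded as absent and the pair can
never be called significant (the conservative choice). Samples missing a
drug's activity value drop out of that drug's tests only; mutated
samples absent from the activity table entirely are flagged unprofiled
and never tested.

Effect direction is the sign of `delta_median` (median activity area of
region-mutated minus comparison samples): negative means region mutants
respond worse — a **resistance** association; positive, **sensitizing**;
zero, undetermined.

## Rank-sum p-values

The Wilcoxon/Mann–Whitney p-value is computed from the exact null
distribution of U whenever the smaller group has ≤ 8 members and the
pooled data are tie-free; otherwise from the normal approximation with
tie-corrected variance and a continuity correction (average ranks for
ties). The exact null is built as the coefficient sequence of the
Gaussian binomial coefficient [m+n, m]_q via iterated polynomial
multiplication/division and cached per (m, n); two-sided p is
2·min(P(U ≤ u), P(U ≥ u)), capped at 1. Counts are held in float64 —
exact integers up to 2⁵³, far beyond every regime where exact equality
is asserted.

Keying the exact/approximate switch to the *smaller* group matters. The
screen's typical stage-I contrast is a handful of mutated samples
against hundreds of unmutated ones, and there the normal approximation
is badly conservative (with 2 mutated samples its smallest achievable
two-sided p is ≈ 0.015, so such pairs could never reject at 0.01, and
measured null rejection at α = 0.01 fell near 0.005). With the
exact-by-smaller-group rule the measured stage-I rejection rate on
effect-free cohorts is statistically indistinguishable from α at both
0.01 and 0.05. The cost stays bounded: the distribution has m·n + 1
support points with m ≤ 8.

## Synthetic cohorts

The generator defines the conditions under which the method's properties
are demonstrated. Defaults, chosen once to emulate a CCLE-scale panel:

| parameter | default | meaning |
|---|---|---|
| baseline activity | 3.0 | Gaussian mean of activity area (0–8 scale) |
| noise sd | 0.5 | per-(sample, drug) Gaussian noise |
| mutation rate | 0.05 | per-sample per-gene missense probability |
| gene length | 200–800 aa | uniform per gene |
| regions per gene | 2 | disjoint, one per equal-width block |
| region length | 30–120 aa | capped by the block width |

Mutated positions are uniform over the gene; activity values are drawn
per (sample, drug), planted per-region shifts are added to region-
mutated samples, and values are clipped at 0 (preserving the activity
invariant). All draws flow from a single `numpy` generator seeded by the
truth's seed, so a truth object reproduces its cohort bit for bit.

`generate_opposing_effects_cohort` builds the cancellation design
directly: two disjoint regions per gene, exactly `n_mut_per_region`
mutated samples in each (disjoint sets), shifts −δ and +δ, and one
private drug column per gene. The balance makes the two shifts cancel in
the whole-gene mutated group, so the gene-level filter stays null while
both region contrasts carry full signal; the private drug column keeps
effects planted for one gene from contaminating another gene's
comparison groups when a sample happens to be mutated in both. Under the
default conditions (±1.0 shift = 2 noise sd, 15 mutated samples per
region, 200 samples), recovery of planted pairs is essentially complete
and the planted genes' gene-level p stays above 0.01 in every replicate.

What the generator does *not* emulate: mutational hotspots and
signatures (uniform placement only, with a hotspot option for stress
tests), copy-number and expression covariation, panel-wide drug
correlations, sample lineage structure, and missingness patterns of real
response matrices. Passing tests therefore demonstrate the statistical
machinery under clean Gaussian conditions, not robustness to every
artefact of consortium data.

## Disorder prediction

FoldIndex score per residue: FI = 2.785·⟨H⟩ − |⟨q⟩| − 1.151, with ⟨H⟩
the window mean of Kyte–Doolittle hydropathy rescaled by (h + 4.5)/9 and
⟨q⟩ the window mean of charge (K, R = +1; D, E = −1; others 0). Windows
are centred, default 51 residues, truncated at the termini. 'X' gets
neutral hydropathy (0.5 scaled) and zero charge; other non-standard
letters are rejected rather than guessed. Since hydropathies have one
decimal digit, window sums are accumulated as exact integer tenths, so
the profile is invariant under sequence reversal bit for bit. IDRs are
maximal runs of FI < −0.1 of length ≥ 10; the window size and minimum
run length are tool conventions (the published tool's default window,
and a floor that suppresses single-residue noise calls) and both are
exposed in the configuration. The score is bounded in [−2.151, +1.634]
for standard residues (poly-R and poly-I attain the bounds).

## Survival, chemistry, enrichment

Patients are stratified by resistance-direction regions only (the
direction with clinical exposure: patients are treated with the drug
their tumor resists), with precedence resistance-region >
other-region > unmutated, and patients lacking mutation data excluded
with a logged count. Kaplan–Meier uses the standard product-limit
conventions (right-continuous, drops at event times, events before
censorings at ties). The k-sample log-rank statistic is the quadratic
form of the observed−expected vector in its hypergeometric covariance
(pseudo-inverse for the k−1 reduction, df = k−1); for two groups the
group with more observed than expected events is reported as the worse
arm. For a three-group comparison the package reports the 3-sample test
and leaves pairwise contrasts to the caller, which can run any subset of
groups.

Fisher exact tests are computed by integer hypergeometric enumeration
(exact rational tails, correctly rounded to float; two-sided sums all
tables with point probability ≤ observed, the R `fisher.test`
convention). Tanimoto similarity is |a∧b|/|a∨b| on equal-length bit
vectors, declared 1.0 when both fingerprints are empty. Target expansion
unions the target sets (at the chosen interaction-score threshold) of
the drug and of every chemical with similarity strictly above the
cutoff. GO enrichment runs a one-sided Fisher test per term over the
background universe with BH q-values across tested terms; terms with no
annotated background member are skipped.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive throughout the API; the BED exporter
  is the only 0-based half-open surface.
* `run_edrug` output is ordered by (drug, region); with a fixed dataset
  and thresholds the result table is byte-identical across runs.
* Zero-variance expression or activity vectors make Pearson correlation
  undefined and raise, rather than returning NaN.
* Empty rank-sum groups raise; an all-tied pool returns p = 1.
* Gene-level p-values are cached per (gene, drug) within a run.

## Known limitations

* Genomic-to-protein coordinate mapping is out of scope: mutations enter
  at protein coordinates (MAF-subset TSV).
* Domain intervals are inputs; no Pfam/HMM scanning or de-novo domain
  prediction is performed. Disorder prediction is the only annotation
  computed in-package.
* The screen's raw-threshold decision rule inherits the multiplicity
  behaviour of its staged design; q-values are reported but deliberately
  not used for calling.
* Survival analysis is restricted to nonparametric stratification; no
  Cox or parametric models.
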