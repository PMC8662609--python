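# Methods

## The erosion model and what the simulator emulates

The generator treats hotspot erosion as a static property of an F1 hybrid
genome. Two PRDM9 alleles each activate their own hotspot set; hotspot
intensities ("heats") are log-normal, reflecting a spectrum of binding
affinities from strong to weak. With probability `erosion_prob`, a
hotspot's binding site is lost on the homolog carrying that allele's own
genetic background (allele 1 → B6 homolog, allele 2 → ALT homolog), which
multiplies its heat there by `erosion_factor` (default 0.05 — strong but
not total loss, so partially eroded sites exist). Non-eroded hotspots get
independent log-normal jitter (`homolog_jitter_sd`, default 0.2 on the log
scale) between homologs: binding on the two chromosomes is similar, never
identical. A de novo allele is a hotspot set with low erosion probability.

Reads are emitted pre-aligned: per hotspot and homolog the count is
Poisson(`read_depth` × heat); SSDS geometry places plus-strand reads at
`center − offset` and minus-strand reads at `center + offset` with offset ~
Normal(150, 50) bp, emulating resected DSB ends (H3K4me3 mode places reads
symmetrically). Uniform background reads are added at `background_per_kb`.
Sequences are copied from the homolog of origin — the ALT haplotype is the
reference with the simulated SNPs substituted — with per-base substitution
error ε (default 0.01, uniform over the three other bases). Reads are
single-end, 50 bp, constant Q40 base quality. Coordinates are 0-based
half-open internally; VCF is written 1-based, BED 0-based half-open.

What the simulator does **not** emulate: mapping bias and mappability
(reads are born aligned), indels and structural variation between strains,
repeat regions, fragment-length variation beyond the strand offset,
chromatin-driven background structure, PCR duplicates, and any
evolution-over-generations dynamics of erosion. Passing tests therefore
demonstrate correctness of the inference machinery under the stated
generative assumptions, not robustness to alignment artifacts in real
libraries.

SNP density defaults to 1 per 100 bp, the order observed between distant
mouse (sub)species; at 50 bp reads this makes roughly 40% of reads
informative. Local SNP density still varies (placement is uniform), so
per-hotspot informative-read capture varies substantially — which is why
truth summaries report both an all-reads weighting and an
"informative-capable" weighting (reads overlapping ≥1 SNP), the latter
being the estimand a homolog-assignment pipeline can actually measure.

## Homolog assignment and the misclassification rate

A read votes at each overlapped informative SNP: reference base → B6,
alternative base → ALT; any other base, a base under the quality threshold
(default Q20), or a deleted position abstains (abstentions still count as
readable sites, so `votes_B6 + votes_ALT ≤ n_informative`). The call is
the majority; ties with at least one readable site are *ambiguous*; reads
overlapping no site are *uninformative*. Duplicate/secondary/supplementary
alignments are excluded. Majority voting was chosen over
likelihood-weighted read calls to keep per-read labels interpretable; the
error correction happens downstream at the hotspot level.

For a single-SNP read with per-base error ε, an error lands on the other
allele's base one time in three (wrong call) and abstains two times in
three (ambiguous). Conditional on receiving a B6/ALT call, the per-read
misassignment rate is therefore (ε/3)/(1 − 2ε/3)
(`assign.effective_misassignment_rate`); reads spanning several SNPs are
misassigned less often, so using the single-SNP rate downstream is mildly
conservative. The pipeline derives its default symmetry ε this way from
the simulation's ε; for real data it is a configurable input (default
0.01).

## Fraction estimation and classification

Each informative read at a hotspot with true B6 fraction f is labelled B6
with probability p = ε + f(1 − 2ε). The binomial MLE of p is the sample
proportion, and since the map p → f is monotone for ε < 0.5, the MLE of f
is its clamped inverse (the closed form in the README); the 95% CI maps a
Clopper–Pearson interval through the same transform. Clopper–Pearson was
preferred over Wilson here to keep coverage conservative at the extreme
fractions eroded hotspots produce. Identifiability requires ε < 0.5,
enforced at validation.

Classification uses the B6-contribution band [0.25, 0.75]: inside
(inclusive) = matched, above = eroded toward B6, below = eroded toward
ALT; hotspots with fewer than `min_reads` (default 5) informative reads
are unresolved and excluded from aggregation. Band endpoints are inclusive
for "matched" because erosion is defined strictly as more than 75% of
reads from one homolog. Per-allele matched proportions are reported both
read-weighted (informative reads at matched peaks over informative reads
at all resolved peaks) and peak-weighted, since the appropriate weighting
is a judgment call; ambiguous and uninformative reads enter neither
numerator nor denominator.

## Peak calling

A window of 1 kb slides in 100 bp steps; the read-midpoint count in each
window is tested against Poisson(µ) with µ the larger of the local rate (a
10 kb window centered on the test window, test window excluded) and the
genome-wide rate, then Benjamini–Hochberg corrected across all windows.
Windows with q ≤ 0.01 and ≥ 5 reads are merged (gap ≤ 200 bp) into peaks.
SSDS centers are the midpoint between the mean plus-strand and mean
minus-strand read positions, exploiting the simulated strand offset;
H3K4me3 centers are the plain read-position mean. The caller requires
coordinate-sorted input and is deterministic given the read multiset. It
is a deliberately simple stand-in for production SSDS callers: adequate to
resolve kb-scale hotspots at ≥10× enrichment (recall ≥ 0.9, median center
error well under 250 bp in the acceptance checks), not tuned for
overlapping or sub-kb features.

## Attribution and dominance

Hybrid peaks are matched to single-allele reference maps by center
distance: attributed to allele k iff within `max_dist` (default 500 bp,
hotspot positions being point-like) of a center in map k and not within
`max_dist` of the other map; near both or neither → unattributed (a
conservative ambiguity rule). Dominance summaries report per-allele shares
of peaks and of informative reads; both partitions sum to one including
the unattributed class.

## Phenotypes and the cliff-edge fit

Cohorts draw synapsed nuclei as Binomial(nuclei_total, p_group) with at
least 50 nuclei scored per mouse (default 100); sperm counts follow a
near-zero Poisson law for groups below the synapsis threshold τ and a
log-normal law centered at 10^6 above it. The default 24-mouse cohort uses
six groups at p ∈ {0.2, 0.3, 0.4, 0.6, 0.7, 0.8}, four mice each —
spanning both sides of τ = 0.5 the way a panel of sterile hybrids,
engineered-allele hybrids and parental strains does, with no group sitting
on the threshold (realized synapsis at n = 100 nuclei has SD ≈ 0.05, so
groups at 0.45/0.55 would routinely cross sides and make τ
interval-identified only up to that noise).

The fit transforms sperm counts as log10(count), with zero counts first
replaced by a floor of 2 (the plotting convention for azoospermic mice);
the step model m_below·1[x < τ] + m_above·1[x ≥ τ] is fitted by exhaustive
search of τ over midpoints between sorted distinct synapsis values,
minimizing SSE (ties resolved toward the smallest τ). A fit is *valid*
when m_above ≥ m_below and *degenerate* when the response is flat (every
threshold fits equally). The CI is a percentile bootstrap over mice
(default 1000 resamples, seeded). Welch's unequal-variance t-test is used
for all group comparisons, two-sided; with zero variance in both groups
and equal means, p = 1 by convention.

## Determinism and numerical choices

One master seed spawns independent per-stage streams
(`numpy.random.SeedSequence` spawn keys), so identical configuration
yields byte-identical FASTA/VCF/SAM/TSV outputs and JSON report, and any
stage can be rerun in isolation. All thresholds actually used are echoed
in the report (`thresholds_used`) next to a hash of the configuration.
Degenerate inputs are handled as data, not crashes: empty read sets warn
and return empty tables, an empty peak list yields an empty summary,
undefined matched proportions (no resolved attributed peaks) return None
with a warning.

## Scales used in the automated checks

The test and acceptance runs use desk-scale problems chosen so that
statistical assertions have adequate power while the whole suite stays
fast: 0.2–1 Mb chromosomes for unit-level properties; two 2 Mb regime
configurations (40 hotspots per allele, depth 100 reads per unit heat,
5 kb minimum hotspot spacing — sparser than the generator default to avoid
composite peaks that conflate adjacent opposite-biased hotspots) whose
erosion probabilities 0.915 and 0.559 solve the erosion model's nominal
matched-read proportions of 0.15 (heavily eroded wild-type-like hybrid)
and 0.60 (de-novo-allele hybrid with residual asymmetry); 100 phenotype
cohorts of 24 mice for threshold-recovery rates. Realized truth
proportions vary around the nominal values run to run — the acceptance
comparison is always estimate versus the realized, per-dataset truth.

## Known limitations

* The attribution rule cannot resolve hotspots genuinely shared between
  allele maps; they stay unattributed.
* The ε correction assumes a single, read-independent misassignment rate;
  with highly variable per-read SNP counts it is conservative rather than
  exact.
* The peak caller's BH correction is across windows, not independent
  tests; q-values are approximate (overlapping windows are positively
  dependent, which BH tolerates but renders conservative).
* Paired-end data, indel-based assignment and X/Y-specific behavior are
  out of scope.
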