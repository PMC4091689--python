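# Methods

This note records the models, rules and numerical choices the toolkit
implements, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Read processing model

Reads are processed as a stream: FASTQ records flow through the quality
filter, the host filter and the aligners one at a time, so peak memory is
the reference k-mer index plus a constant per read. A read passes quality
control iff at least `qc_min_fraction` (default 0.8) of its bases have
Phred quality ≥ `qc_min_quality` (default 20); the comparison is done on
the pass-fraction (`n_pass / n ≥ p`) rather than on `n_pass ≥ p·n` to
avoid float-representation artefacts at exact boundaries such as 40/50
vs p = 0.8. The Phred offset defaults to 33 (offset 64 selectable);
quality bytes below the declared offset are an error, not a silent
re-interpretation.

Alignment is a contract (`read sequence → scored hits`), with two shipped
implementations. The k-mer-seed test aligner indexes every k-mer
(k = 21) of the references, probes three evenly spaced seed positions per
read, and verifies each candidate placement by counting matching bases; a
hit needs matches/length ≥ 0.9. It handles substitution errors only —
adequate because the bundled read simulator is substitution-only. The SAM
adapter turns the output of any external aligner into the same record
stream (score from the AS tag, falling back to MAPQ; flag 4 = unmapped),
so production alignments can enter the pipeline without re-implementing
an aligner.

Multi-mapping policy: each aligned read contributes exactly 1 to exactly
one reference — the best-scoring hit, score ties broken by a seeded
uniform choice ("best-unique"). An "all-best-fractional" mode (1/n to
each tied best hit, float counts) exists for sensitivity analyses.
Counts are 64-bit integers everywhere upstream of relative abundances.

## Count tables

Combining runs into samples and aggregating features into annotation
groups are exact integer sums; both conserve column totals, with
unannotated features pooled under the sentinel `unannotated`. Relative
abundances divide each column by its **annotated** total by default
(the unannotated pool is excluded from both numerator and denominator);
the choice is recorded on the table as `denominator_policy` and can be
flipped. A gene mapping to several KEGG orthologs contributes its full
count to each (documented double counting); a fractional mode splits the
count instead.

Rarefaction to depth d is a single seeded multivariate-hypergeometric
draw per sample — the sample's reads form an urn with one colour per
feature and d reads are drawn without replacement — so each rarefied
column sums to d exactly and stays integer. One draw (rather than an
average over draws) keeps presence calls and richness well-defined
integer quantities; samples with fewer than d reads are dropped and
reported. The conventional full-scale depth is 11,000,000 aligned reads;
desk-scale analyses in the tests use depths of 10²–10⁵ scaled to the
simulated read counts.

Differential relative abundance uses the two-sided Mann–Whitney rank-sum
test per feature with Benjamini–Hochberg adjustment; features constant
across both groups (including all-zero) are assigned p = 1 rather than
NaN. The test choice is a field convention, not a claim about any
particular published comparison.

## Presence, core and pan

Presence rules: a gene is present in a sample iff ≥ `gene_presence_min_reads`
(default 2) reads aligned to it, applied to rarefied counts; a species is
present iff its relative abundance is **strictly above**
`species_presence_min_abund` (default 10⁻⁴ — "above" is read as strict;
a `strict=False` switch exists). Repeat visits are removed first: the
visit-1 sample per subject is kept, or the lowest visit with a warning
when visit 1 is absent, so cores are defined per individual.

The core at fraction f contains features present in ≥ ⌈f·N⌉ of N
subjects; the ceiling is computed as `ceil(f·N − 1e-9)` so that binary
float representation cannot turn 0.9 × 10 into a threshold of 10.
Pan/core accumulation curves average over `n_orderings` (default 100)
seeded random subject orderings; at n = N every ordering gives the
order-invariant core/pan sizes exactly. Gene richness is the per-sample
column sum of the presence matrix at the same ≥ 2-read rule used for the
core (the rule is applied uniformly).

Venn analysis partitions gene clusters by the exact set of studies they
occur in (15 non-empty regions for 4 studies); per-sample read fractions
are attributed to regions, optionally normalised by region gene count
(per-gene abundance share) before rescaling to sum 1.

## Diversity

Shannon diversity uses the natural logarithm, H = −Σ pᵢ ln pᵢ over
features with pᵢ > 0; all-zero samples yield NaN and are flagged, not
silently zeroed. Heatmap sample clustering uses complete linkage on
1 − Spearman correlation between profiles restricted to the top
`n_top_features` (default 30) by mean relative abundance; a constant
profile has no rank variance, so its distances are defined as 1 with a
warning. Dendrograms export to Newick.

## Enterotyping

The protocol: (1) keep genera with cross-sample mean abundance strictly
above `min_mean` (default 10⁻⁴, i.e. 0.01 %) and renormalise; (2) replace
zeros with a pseudocount (default 10⁻⁶ — small enough that the
disjoint-support distance is within 10⁻³ of its √ln 2 limit at 10⁻⁹,
large enough to keep KL terms finite) and compute the root
Jensen–Shannon distance, a metric; (3) run PAM for each k in `k_range`
(default 2–10); (4) select k by the Calinski–Harabasz index; (5) report
silhouette widths and per-cluster driver genera (largest inside-vs-outside
mean-abundance excess).

**PAM.** Classic BUILD seeding (most central point first, then greedy
gain maximisation) followed by best-improvement SWAP until no single
medoid/non-medoid exchange lowers the total nearest-medoid distance.
Best-improvement SWAP from the BUILD start can stall in a sub-optimal
basin even at n = 8 (R's `cluster::pam` lands in the identical basin on
the same inputs), so `pam` additionally runs SWAP from `n_restarts = 6`
seeded random medoid sets and keeps the lowest-cost solution; with that
budget the exhaustive medoid-subset optimum was reached in every one of
600 randomized small-matrix trials exercised by the test suite. The seed
fully determines the result.

**Calinski–Harabasz from distances.** Only a distance matrix exists, so
CH is computed via the pairwise dispersion identity
(Σ‖xᵢ−x̄‖² = Σ_{i<j} d²ᵢⱼ/n for any embedded set): W = Σ_c Σ_{i<j∈c}
d²ᵢⱼ/n_c, B = T − W, CH = (B/(k−1))/(W/(n−k)) — the same device as the
PERMANOVA pseudo-F. A medoid-plug-in variant was evaluated and rejected:
it systematically understates between-cluster dispersion on root-JSD
matrices and prefers k = 2 even when PAM at the planted k = 3 recovers
the labels perfectly. k = 1 (or k = n) is undefined and flagged NaN.

Silhouette uses the standard s(i) = (b−a)/max(a,b) on the precomputed
distances (singletons score 0; a single cluster is flagged undefined).
Cluster-agreement between two labelings is the Hungarian-matched maximal
fraction of identically assigned samples.

## Gene catalogue construction

The pairwise kernel aligns the shorter sequence end-to-end against the
best-matching stretch of the longer (glocal/infix edit-distance
alignment). Identity = matching columns / aligned columns of the
shorter's span (gap columns count against identity); coverage = aligned
length of the shorter / its length. `N` never matches, not even another
`N` — enforced by remapping `N` to a distinct private letter on each
side before alignment. Thresholds default to identity ≥ 0.95 and
coverage ≥ 0.90 of the shorter sequence.

Greedy clustering processes sequences longest-first (ties by id); each
sequence joins the first existing cluster — in founding order — whose
**representative** it matches at both thresholds (representative-vs-member
acceptance; member-vs-member variants would merge more), else founds a
new cluster. A shared-k-mer prefilter (k = 8) restricts which
representatives are aligned; at ≥ 95 % identity over gene-length
sequences a shared 8-mer is guaranteed, and the tests verify the filter
reproduces the unfiltered reference result exactly. Per-study catalogues
are merged by re-clustering the pooled representatives at the same
thresholds, with ids namespaced by study; each global cluster's study
set is the union of its members' labels.

## Synthetic data: what it emulates, what it does not

The generators plant every quantity the pipeline is later asked to
recover, and every one is seed-deterministic.

* **References**: random uniform-base genomes, each the concatenation of
  its genes (optionally padded), so one read stream exercises both
  databases; species grouped into genera; a host sequence included.
* **Reads**: sources ∝ composition × contig length, uniform start,
  substitution errors at 0.5 % per base (no indels — which is what makes
  the exact-seed test aligner sufficient); host reads at a binomial
  fraction (default 0.00023, matching the low host contamination typical
  of gut metagenomes); two-state quality model (clean reads at Q38, a
  2 % fraction of degraded reads whose bases are Q8 with probability
  0.5), so roughly 98 % of reads pass the default QC rule.
* **Cohorts**: a planted always-present core of species with an
  abundance floor (2 %), plus variable species present in a minority of
  samples with a 0.5 % floor when present — margins that make read-level
  presence match composition-level presence deterministically at the
  tested depths.
* **Enterotype cohorts**: k Dirichlet components over 73 genera
  (concentration 0.3) with one distinct driver genus per component
  boosted to concentration 12 (driver mean share ≈ 36 %, comparable to
  the dominance of the classical gut enterotype drivers); balanced
  component assignment.
* **Multi-study gene sets**: core genes copied to all studies and
  pair-shared genes copied to two, each copy carrying exactly
  ⌊0.02·len⌋ substitutions so pairwise divergence is ≤ 4 % by
  construction — strictly inside the 5 % clustering radius; unique genes
  are independent random sequences.

Not emulated: indel and platform-specific error profiles, strain-level
variation, GC bias, abundance distributions fitted to real cohorts, and
real taxonomies. Passing tests therefore demonstrate algorithmic
correctness and recovery of planted structure, not concordance with any
real cohort's published values; quantities that depend on tens of
billions of real reads (catalogue sizes in the millions, study-scale
mapping rates) are out of reach at desk scale by design.

## Problem sizes and tolerances used in the tests

The acceptance suite runs, on one CPU: 1000 randomized conservation
fixtures; 10,000 seeded rarefaction draws on a 10-feature column checked
within 3σ of the hypergeometric mean; exhaustive-ordering pan/core
checks on ≤ 6 subjects; PAM vs exhaustive medoid subsets on 100 random
8-point matrices for k ∈ {2,3}; root-JSD metric checks on 1000 random
profiles and the √ln 2 limit within 10⁻³ at pseudocount 10⁻⁹; enterotype
recovery (k = 3 chosen, agreement ≥ 0.9) in ≥ 95 of 100 seeds at n = 60;
exact Venn-region recovery on planted multi-study gene sets; a full
20-sample × 10⁵-read pipeline run recovering genus compositions within
±2 percentage points absolute and planted core genes exactly at depth
60,000; and rank-sum type-I error 0.05 ± 0.02 over 1000 null features at
n = 10 vs 10. `scripts/acceptance.py` re-measures the same quantities at
10 samples × 3 × 10⁴ reads.

## Limitations

* The streaming counter treats paired-end files as independent
  single-end streams; no fragment-level deduplication.
* No compositional transforms (CLR/ALR) or zero-imputation models; no
  richness extrapolation estimators (Chao, ICE).
* The greedy catalogue clustering is order-dependent by specification
  (longest first); representative-vs-member acceptance means borderline
  pairs can split where member-vs-member tools would merge.
* The alignment identity cutoff for calling a read aligned is a contract
  parameter of the test aligner, not a validated production setting.
* `ch_index` treats distances as Euclidean-embeddable for the variance
  decomposition; root-JSD is a metric but not exactly Euclidean, so B is
  clamped at 0 in degenerate cases.
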