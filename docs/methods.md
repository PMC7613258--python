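# Methods

## Signal model

DamID resolves protein–DNA association at the level of GATC fragments: the
intervals between consecutive GATC motifs, since Dam methylates the adenine
of GATC and methylation-sensitive digestion releases whole fragments.
Fragment boundaries are placed at motif midpoints (`motif_start + 2`), the
symmetric choice, so each motif contributes two bases to each flanking
fragment.  The regions before the first and after the last motif of a
chromosome are kept as flagged *terminal* fragments so that the map tiles
the chromosome exactly; statistics can exclude them via the flag.

Each alignment is assigned to the single fragment containing its 5′-most
aligned base (start on the plus strand, `end − 1` on the minus strand),
because DamID reads begin at methylated GATC cut sites; midpoint assignment
is available as an option.  Duplicate alignments are kept — amplicon counts
are the DamID signal — with deduplication possible upstream via the MAPQ
filter and standard tools.

The per-fragment occupancy score for one fusion/control pair is

    score_f = log2((rpm_fusion_f + ψ) / (rpm_control_f + ψ)),

where `rpm = count / library_size × 10⁶` and ψ defaults to 0.5 RPM.  RPM
scaling makes scores invariant to sequencing depth; the symmetric
pseudocount keeps them finite and antisymmetric under swapping the roles.
Fragments with zero counts in both samples carry no information and are
masked invalid rather than scored 0, so that downstream exclusion rules are
well defined.  Zero is a meaningful log-ratio value and is never imputed.

**Background centering.**  Because the fusion library contains extra genic
reads, background fragments otherwise sit slightly below zero after RPM
scaling.  `center_profile` subtracts the mode of the score distribution,
estimated by a Gaussian kernel density (Silverman bandwidth) on a 512-point
grid spanning the observed range, restricted to fragments with at least
1 RPM in both samples (at least 100 such fragments are required).  The mode
— not the mean — is used so that the minority of genuinely occupied
fragments does not drag the background away from zero.  The operation is
idempotent to numerical precision.  Profiles from all fusion × control
replicate pairings (four for a 2 + 2 design) are averaged per fragment; a
fragment is valid in the average if valid in at least one pair.

## Gene calling

A feature's statistic is the unweighted mean score of the valid fragments
overlapping its longest-transcript extent by ≥ 1 bp (unweighted rather than
length-weighted, so genes rich in short fragments remain comparable).
Features with no valid overlapping fragment are unscored, a status rather
than an error.

Significance is assessed against an empirical null matched on fragment
count `n`: valid fragment scores are shuffled genome-wide and regrouped
into consecutive pseudo-features of `n` fragments; the one-sided empirical
p-value is `(1 + #{null mean ≥ observed}) / (1 + n_permutations)` (10,000
permutations by default).  Nulls are cached per distinct `n` and generated
in sorted-`n` order from a single seeded generator, making results
invariant to feature input order.  Benjamini–Hochberg correction is applied
across all scored features of a run — genome-wide, and separately for
protein-coding genes and miRNAs since they are called in separate runs —
and features with FDR < 0.05 are flagged expressed.  Only enrichment is
tested; depletion is not expression.

A contiguous-block null (`null_mode="block"`: a random valid fragment plus
its `n − 1` successors on the same chromosome) is also implemented.  It
preserves local signal autocorrelation and is maximally conservative, but
when an appreciable fraction of the genome is genuinely occupied the block
pool consists partly of intact signal blocks, and the power to call all but
the strongest genes collapses (on the standard synthetic experiment it
recovers 1% of truly expressed genes versus ~90% for the shuffle null,
at identical type-I control).  The shuffle null — the approach of the
established RNA-polymerase DamID gene-calling scripts — is therefore the
default.  Note that under either null the marginal pool includes occupied
fragments, which makes calls conservative for background genes; the
residual power cost falls on short, weakly expressed genes whose few
fragments cannot clear the marginal tail.  This mirrors the known
GATC-availability limitation of the method: a gene spanning only two GATC
sites needs both methylated to reach significance.

miRNAs (typically 21 bp, often within a single fragment) are called on
extents extended 500 bp up- and downstream, which raises the number of
overlapping fragments and hence the p-value resolution; the extension is
symmetric, so strand does not affect it.

## Metagene aggregation

Aggregation profiles anchor each feature's TSS and TES on the x-axis:
flanks (default 3 kb) are sampled at native per-base resolution from the
covering fragment's score, the gene body is pushed or stretched to a common
pseudo-length (default 3 kb) by linear interpolation of the per-base
series, and fixed-width bins (default 10 bp) average their bases, ignoring
missing values.  Rows of minus-strand features are reversed so upstream is
always left.  Linear interpolation (rather than fragment-level remapping)
is deterministic and resolution-preserving; a body already at the
pseudo-length reproduces its native bin averages exactly.  Flank bases
falling inside neighbouring genes are not excluded.  Per bin, the mean over
features is reported with a 95% confidence band (mean ± 1.96·sd/√n).  The
optional z-transform re-expresses the curve as deviations from the mean
signal across the plotted region, per track.  `isoform_end_density`
aggregates, with the same machinery, the per-base isoform coverage of each
gene (0/1 per isoform, averaged over isoforms), quantifying the 3′
positional preference of shorter isoforms.

## Comparative statistics

Sample similarity uses read counts binned per GATC fragment, per
fixed-width window (fragment counts assigned by fragment midpoint), or per
gene (summed counts, or mean occupancy for profiles).  For each compared
pair, bins that are zero in both members and bins jointly above the 99.9th
percentile are excluded before correlating — the joint-outlier rule removes
PCR-stack artefacts that would otherwise inflate correlations, while bins
extreme in only one sample (genuine signal differences) are retained.  The
threshold is configurable.  PCA operates on bin-centred values with
components ordered by decreasing explained variance.

`rank_bin_compare` sorts genes by descending occupancy score and reports
the mean of an external quantitative expression measure in consecutive
rank bins of 500 genes (the last bin may be short).

Overlap significance between gene sets uses the upper-tail hypergeometric
distribution against a fixed sampling pool (default 20,191, the number of
annotated coding genes; overridable).  For three or more sets, the null —
k uniform random subsets of the observed sizes — is sampled by the exact
sequential-hypergeometric chain: |A₁∩…∩Aⱼ| given the previous intersection
size is hypergeometric, so the chain is distribution-identical to
materialising the subsets while being vectorisable; p = (1 + hits)/(1 +
draws) with a seeded generator.  Both routes are validated against
exhaustive subset enumeration at small universe sizes in the test suite.

## Synthetic experiments

The generator emulates the observable structure of a TaDa experiment while
remaining minimal:

* **Genome** — iid uniform A/C/G/T, giving GATC motifs every ~256 bp in
  expectation, close to the density of a compact metazoan genome.  Default
  one chromosome of 2 Mb.
* **Annotation** — 400 non-overlapping genes with log-normal lengths
  (meanlog 7.6, sdlog 0.6, clamped to 0.3–20 kb; ~2 kb median), placed
  uniformly among feasible positions; 1–3 nested isoforms per gene, shorter
  isoforms 3′-anchored with probability 0.7; 30 intergenic 21-bp miRNAs.
* **Control channel** — per-fragment background accessibility
  `a_f ~ Gamma(shape 2, scale 1)`; spatially independent (no chromatin-
  domain autocorrelation is modelled).
* **Fusion channel** — `a_f` plus, for every expressed gene overlapping the
  fragment, `expression × w(pos)` with `w = (pos_frac·(1−ε)+ε)^β` evaluated
  at the fragment midpoint along the gene 5′→3′ (floor ε = 0.1, exponent
  β = 1 by default, β = 0 for uniform genic methylation).  The positional
  weight reproduces the TSS depletion / 3′ preference characteristic of
  RNA-polymerase TaDa signal.
* **Expression** — an exact 25% of genes drawn expressed, levels
  `LogNormal(meanlog 3.0, sdlog 0.75)` in units of the accessibility scale.
  This calibration was chosen by power analysis before any pipeline run:
  with mean accessibility 2, it yields per-gene log2 shifts of roughly 1–4,
  matching the −2 to 4 dynamic range typical of occupancy tracks, and
  detectable effects at the default depth.
* **Sampling** — per replicate, a Gamma noise factor of variance 0.02
  (mean 1) perturbs each fragment's propensity, then exactly `depth`
  (2×10⁶) reads are drawn multinomially, so per-sample depth is met
  exactly.  Each read is a 75-bp alignment anchored at its fragment's 5′
  boundary, emitted pre-aligned as SAM or BED on request; because reads are
  assigned back to the fragment containing their 5′ base, the multinomial
  fragment draws are identical to the counts obtained by writing and
  re-counting the alignments (verified in the tests).

All randomness derives from the config seed through per-stage seed
sequences, so every artifact is byte-identical across runs.  What the
generator does **not** model: sequence-level read errors and mapping
ambiguity, PCR duplicates, methylation carry-over between stages, chromatin
domain autocorrelation, GC or fragment-length amplification bias, and
overlapping/nested gene models.  Passing tests therefore demonstrate the
correctness and operating characteristics of the analysis under the stated
generative model, not performance on real libraries affected by those
artefacts.

## Numerical and interface choices

* Longest-transcript ties are broken by lexicographically smallest
  transcript id; gene extents convert GFF3 1-based inclusive coordinates to
  0-based half-open internally and back on write.
* `library_size` counts all input reads (assigned + unassigned), keeping
  RPM scaling invariant to how many reads fall on unplaced contigs.
* Permutation p-values carry the +1 correction, so p ≥ 1/(n_permutations+1)
  and the calls are slightly conservative; calls stabilise with more
  permutations.
* Whether the FDR is computed genome-wide or per chromosome is a genuine
  open choice; genome-wide is implemented.
* Profile serialisation keeps 6 decimal places (bedGraph and scored GFF3);
  truth tables round-trip at full float precision.
* The test suite's simulations are scaled to desk size (0.1–2 Mb genomes,
  tens to hundreds of genes) — sufficient for the statistical properties
  they check, chosen so the whole suite runs in seconds.

## Known limitations

* Power is bounded by GATC availability: genes with very few fragments
  cannot reach small empirical p-values, and the marginal null pool
  includes occupied fragments, further penalising weak short genes.
* The KDE mode estimate requires a dominant background population; profiles
  where most fragments are occupied would be mis-centred.
* The pipeline consumes alignments; mapping, adapter/linker trimming and
  paired-end handling are out of scope.
* No differential-occupancy statistic between two profiles is provided;
  conditions are compared at the level of called gene sets.
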