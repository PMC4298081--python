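# Methods

This note documents the models, parameter choices and numerical conventions
behind `cottonsnp`, and what the synthetic-data tests do and do not
establish.

## Filter cascade

Pileup records carry per-base counts with `depth` equal to their sum,
1-based inclusive coordinates throughout.  The cascade is:

1. drop indel-flagged records and records with depth < 3;
2. call a candidate where depth ≥ 10, the modal base differs from the
   assembly base, and the modal base holds ≥ 90% of the reads;
3. drop candidates within 50 bp (inclusive) of an intron–exon boundary;
4. drop positions in the homeo mask.

**Operationalising "homozygous".**  The purity threshold of 0.9 makes
"homozygous for a different base" concrete; it is configurable.  Sites where
two non-reference bases split the reads (neither reaching purity) are
rejected, not split into two candidates.  The reference genotype is taken
from the assembly base itself; the alternative — re-calling the reference
accession from its self-remap — was considered and not adopted, since the
self-remap is used for homeo masking only.

**Homeo mask.**  A site is masked when, in the reference accession's
self-remap, its second-most-frequent base reaches a fraction of ≥ 0.2 at
depth ≥ 3.  Collapsed homeologous copies put the true minor fraction near
0.5, so 0.2 at low depth trades a small false-positive rate for high
recall; both knobs are exposed and logged in the mask object.

The intron filter and the homeo mask commute (both are pure row filters on
disjoint predicates); the documented order is filter → call → intron → mask.

## Marker classes and redundancy

Classes are assigned per species from *all* candidates that survive the
cascade, before any redundancy removal or flank exclusion — classes depend
on the full polymorphism context of the contig, so they are always
recomputed, never cached.  "Within 50 bp" is inclusive (a 50-bp spacing is
Class III).  Markers closer than 50 bp to a contig end are excluded rather
than padded.

Marker identity is exact string equality on the canonical 101-mer (flanks
around the IUPAC code of the unordered allele pair).  No reverse-complement
matching: transcriptome strand is fixed by the assembly.  Within-species
duplicate keys move wholly to the overlap set (no representative is kept).
Cross-species duplicates keep the record in the highest-ranked species
(Gb > Gt > Gm > Ga > Gl), annotated with the count and identity of sharing
species.  Keys whose allele pair differs between species (same flanks,
different alternate) are triallelic: retained in every species set, flagged,
excluded from Venn tallies and from the shared-across-all-species analysis.
Ties anywhere are broken by hierarchy, then contig id, then position, which
makes the kept set independent of input order.

## Two-point RH model

Deletions are read from genotype shifts: heterozygote → 0, donor homozygote
→ 1, unscored → missing.  The opposite homozygote is biologically
unexpected in this cross and is treated as missing with a warning, not as a
deletion.  The deletion-indicating genotype is configurable because the
cross direction (irradiated donor pollen) could argue for the opposite
shift; the default follows the published scoring rule.

The equal-retention model with retention probability `r` and breakage
probability `θ` gives cell probabilities (1 = retained)

    P11 = (1−θ)r + θr²,  P10 = P01 = θr(1−r),  P00 = (1−θ)(1−r) + θ(1−r)²

The closed forms r̂ = (2n11+n10+n01)/2N and θ̂ = (n10+n01)/(2N·r̂(1−r̂))
(clipped to [0, 1]) are the joint maximum-likelihood estimates — verified in
the test suite against exhaustive grid maximisation (step 1e-3, refined
locally to 1e-5; the refinement exists because a raw 1e-3 grid argmax can
sit ~1.4e-3 from the continuous optimum along the likelihood ridge).
LOD compares the MLE against θ = 1 (unlinked) at the pooled r̂; distance is
−100·ln(1−θ̂) cR.  Counting is pairwise-complete; no imputation.  Links are
undefined when pooled retention is 0 or 1 (skipped with a log entry).

**Known limitation — spurious links.**  The pooled-retention null does not
model the margin asymmetry of chance tables, and at ~9 deletions per marker
over 131 hybrids an unlinked pair sharing 4–6 deleted hybrids by chance can
reach LOD ≥ 3 within 100 cR.  At 200 markers on 5 chromosomes this produces
a spurious cross-chromosome merge in roughly one panel in seven.  This is a
property of the model and thresholds, not of the implementation; panels with
many markers need a higher LOD threshold (or a margin-fitted null) if clean
chromosome separation is required.

**Bins and order.**  Bins partition a syntenic group into sets of markers
whose deletion values agree on every mutually scored hybrid; missing cells
are wildcards.  Wildcard compatibility is not transitive, so the partition
is built greedily over markers in sorted order, testing against all current
members of a bin — deterministic and order-independent, but markers with
identical underlying patterns can occasionally land in different bins when
missing cells hide a conflict with an earlier bin member; this is
data-inherent, not algorithmic.  In-group ordering (greedy nearest-neighbour
seed, window reversals, single-marker reinsertion, to a local optimum of the
obligate-break count) is explicitly advisory: a 131-hybrid panel at a 6.9%
deletion rate has too few informative breaks to fix marker order, which is
why bins are the primary output.

**Outliers.**  Deletion-count outliers use Tukey's rule with quartiles
defined as medians of the lower/upper halves, the overall median belonging
to neither half for odd n; the threshold is Q3 + 1.5·(Q3−Q1), flagging
strictly greater counts.  Fewer than 4 markers is refused (quartiles
unstable).

## Functional analysis

Shared loci are positions called in every analysed species; loci with two
distinct alternate alleles are triallelic and excluded from ratio
arithmetic.  Substitutions are classified by translating the codon
containing the SNP with the reference and the alternate base (standard
genetic code, strand-aware); a premature stop in the reference CDS, a
length not divisible by 3, or a position inside the frame offset yields
`untranslated`.  The headline statistic is the raw non-synonymous :
synonymous **count** ratio (reported to 4 dp), not a per-site normalised
rate — that is how the comparison it mirrors was computed.  The random
comparator samples n loci from n distinct contigs, uniformly, deterministic
under its seed.  A longest-ORF fallback (ATG-to-stop, ≥ 90 codons, both
strands) provides CDS annotations for annotation-free fixtures.

## Synthetic world

The generator's defaults state the emulated conditions:

| parameter | default | rationale |
|---|---|---|
| `rh_n_hybrids` | 131 | size of the real WWRH panel |
| `rh_deletion_freq` | 0.069 | observed per-marker deletion fraction (~8.9/131) |
| `mean_depth` | 30 | within the 20.9–48.5× span of the real per-species depths |
| `error_rate` | 0.01 | typical short-read platform miscall rate |
| `contig_length_mean` | 900 bp | near the source assembly's N50 (~1.1 kb) |
| `transition_bias` | 0.62 | reproduces the observed Ts/Tv ≈ 1.6 |
| `homeolog_site_rate` | 0.005 /bp | order of magnitude of A/D homeolog divergence in transcripts |
| `donor_divergence` | 0.003 /bp | interspecific allele-SNP density before filtering |
| `shared_site_rate` | 5e-4 /bp | yields a small all-species shared set, as observed |
| `rh_segment_scale` | 50 cR | free choice; no generative model was published, only the 6.9% rate |
| `missing_rate` | 0.02 | "questionable genotypes unscored" — a few percent in practice |
| `boundary_rate` | 1/400 bp | a handful of intron–exon boundaries per transcript |

Depth is Poisson around the mean (the source reports means only; a
`constant` mode exists for exact-arithmetic tests).  Sequencing errors
scatter uniformly over the three other bases.  Collapsed homeolog sites
split reads 50/50 in the self-remap *and* in donor pileups (donors share
the AD ancestry or map to one subgenome).  Planted allele-SNPs avoid
homeolog and shared-site positions so the ground truth stays unambiguous.
CDS intervals cover ~60% of each contig and are kept stop-free on the
coding strand by rewriting in-frame stops, so translation-based
classification is exercised rather than short-circuited.  RH deletion
segments arise from a Poisson break process along a per-chromosome cR axis;
each segment is deleted with probability equal to the target per-marker
rate, so the marginal deletion frequency is exact while nearby markers
co-delete.  All randomness descends from one seed through substreams keyed
by (stage, unit), making bundles byte-identical under a fixed config.

What the generator does **not** emulate: read-level artefacts (mapping
bias, base-quality structure, multi-mapper assignment), library
normalisation effects on depth, paralog families beyond the collapsed-
homeolog model, and real intron structure.  A green end-to-end test
establishes that the pipeline implements its stated rules exactly on data
satisfying its assumptions — not that those rules are sufficient for any
particular real library.

## Pipeline and scale

The orchestrated run enforces a conservation ledger at every stage (input
count = output + categorised removals) and writes a manifest whose hash is
reproducible under a fixed config and seed.  Test fixtures use 30–80
contigs of ~500–900 bp — large enough for hundreds of markers and
non-trivial redundancy/anchoring, small enough that the whole suite runs in
well under a minute; the statistical acceptance checks run at their stated
sizes (100 fixtures, 1,000 count tables, 50 panel seeds at 131 × 200).
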