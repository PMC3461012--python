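# Methods

## Data model and coordinate conventions

All coordinates are 0-based half-open; converters to 1-based inclusive
(genome-browser) tables exist at the I/O boundary. A PET is two 25 bp tags
(`tag5`, `tag3`) with chromosome, interval and strand each. The default
orientation convention is the SOLiD mate-pair one — both tags on the same
strand, the 5′ tag first in reading direction — selectable per library
(`concordant_orientation="fr"` covers Illumina paired-end runs). The PET
*span* is the outermost-coordinate distance between the two tags; an
inner-gap definition is available (`span_mode="inner"`) because the field
uses both, but outer-coordinate is the default and is what the span bounds
below refer to.

## Concordance classification

A PET is concordant iff same chromosome ∧ orientation pattern ∧ correct tag
order ∧ span within `[concordant_span_min, concordant_span_max]`, both bounds
inclusive. Presets: 1 kb library → max span 3,000 bp; 10 kb → 20,000 bp;
20 kb → 40,000 bp; `concordant_span_min` defaults to 0 (tight size selection
implies a practical minimum, so it is exposed). Classification is a total
partition: everything not concordant is discordant.

## Clustering

Two dPETs co-cluster iff they share the (chrom5, chrom3) and (strand5,
strand3) combination and both their 5′ tag starts and their 3′ tag starts lie
within a window of each other; clusters are the transitive closure
(single linkage) of that relation. The window defaults to
`concordant_span_max`: two fragments spanning one fusion point can differ by
at most one fragment length on each side. Single linkage was chosen over
clique finding because it is order-independent and matches how overlapping
tag stacks behave; the window is tunable (`--cluster-window`).

Anchors are the tight hulls of the member tags per side. Breakpoints are
predicted from the innermost member tag edge in reading direction: 5′ anchor
on `+` → maximum tag end, on `−` → minimum tag start; the 3′ anchor mirrors
this (on `+` → minimum start, on `−` → maximum end), since the fusion lies
*before* the 3′ tags in reading direction. With cluster count `n` and
fragment length `f` the expected prediction error is ≈ `f / n`, which is why
well-supported clusters localise breakpoints to ~100 bp even with 10 kb
inserts.

Clusters below `cluster_count_min` (default 3) are treated as
chimeric-ligation / mismapping noise and dropped.

## SV typing

Single-cluster patterns (one fusion point): deletion — same chromosome,
concordant orientation and order, span above the concordant bound (hence
deletions smaller than `span_max − fragment` are structurally undetectable
by that library); tandem duplication — 3′→5′ order; unpaired inversion —
opposite tag strands; isolated translocation — two chromosomes. A cluster
whose span is below `concordant_span_min` with otherwise concordant geometry
is returned untyped (`None`): it suggests novel inserted sequence, which this
package does not model. A cluster matching the concordant pattern outright
raises an error — it should never have been classified discordant.

Paired-cluster signatures are evaluated on an anchor abstraction: each anchor
contributes its predicted breakpoint and the direction it extends away from
it (a `+` 5′ anchor sits left of its breakpoint, etc.). Two anchors form a
*junction* when they extend outward around nearly coincident breakpoints and
are essentially disjoint (≤50 bp overlap slack; ≤1,000 bp breakpoint gap,
`RECIPROCAL_MAX_GAP`); two anchors delimit a *source segment* when the
right-extending anchor's breakpoint precedes the left-extending one's and the
anchors either overlap (segment shorter than two fragments) or the gap
clearly exceeds the junction tolerance. Then:

- **inversion**: two opposite-orientation clusters whose 5′ anchors share the
  left boundary junction and 3′ anchors the right one;
- **balanced translocation**: two reciprocal inter-chromosomal clusters with
  junctions on both chromosomes;
- **insertion**: one shared junction (the target point) plus a source
  segment; intra/inter-chromosomal and direct/inverted follow from
  chromosomes and strand patterns, forward/backward from the target's
  position relative to the source (not applicable across chromosomes, which
  is why the inter-chromosomal combinations collapse into sub-types 7–8,
  giving eight sub-types in total).

A consequence of `RECIPROCAL_MAX_GAP` is that an inter-chromosomal insertion
whose source is shorter than ~1 kb is indistinguishable from a balanced
translocation at this geometry level and will be typed balanced; known
limitation.

**Cut-and-paste evidence (sub-types 5–6).** A cut-and-paste source leaves no
donor sequence at its reference locus, but large fragments still span the
excision concordantly, so the *fragment-footprint* coverage there looks
normal. The loss is visible in the **concordant-tag density** track: when the
moved segment is shorter than the minimum fragment length, no concordant tag
can map inside it. The coverage track therefore carries both signals
(fragment footprint for segmentation/copy number, tag starts per bin for the
gap test), and a forward insertion is upgraded to sub-type 5/6 when the mean
interior tag depth of the source is ≤5% of the genome-wide median. Without a
coverage track the call stays sub-type 1/3 with the caveat flag
`source-coverage-unchecked`. Only forward cut-and-paste variants exist in the
taxonomy, so backward insertions are never upgraded.

**Pairing order.** Candidate pairings are ranked by ascending source-segment
length (zero for inversions / balanced translocations), then descending
combined count, then shared-point distance. Length-first matters: a
cut-and-paste rearrangement admits two equivalent two-cluster descriptions
(segment `[s1,s2]` moved to `t`, or segment `[s2,t]` moved backward to `s1`),
and ranking by count can pick the non-parsimonious one; the smallest moved
segment is the canonical description. Unpaired clusters fall back to
single-cluster typing.

## Superclusters and complexity

Each anchor extended by `concordant_span_max` on both sides forms a search
window; clusters join a supercluster when any windows overlap on the same
chromosome (closed-interval touch counts; either anchor may mediate, strand
ignored). SVs whose clusters all sit in superclusters of count ≤3 are
isolated; the rest complex. Superclustering partitions the cluster set and is
order-independent (connected components).

## Cross-library comparison and resolution

For each isolated SV of the larger-insert (reference) library, both anchors
are extended one-sided *toward* the breakpoint by the reference library's
maximum insert; a same-type SV of the other library whose corresponding
anchors overlap both windows is *common* (ties resolved by summed breakpoint
distance, one-to-one). The matching side may include low-confidence clusters
of size 2; these never become library-specific themselves. Unmatched
reference SVs need a cluster count ≥ `specific_cluster_count_min` (default 6)
to be called library-specific; unmatched calls below that form an explicit
third bucket (`ref_low_confidence`) so the three buckets partition the
reference set.

Resolution is `|predicted − truth|` per breakpoint side; the contingency
analysis counts breakpoints above/below a threshold (default 1,500 bp) per
class and attaches the exact two-sided association probability
(`scipy.stats.fisher_exact`); tests cross-check it against a full
margin-fixed enumeration in exact integer arithmetic.

## Copy number and amplicon graphs

Physical coverage depth is the per-bin (default 1 kb) count of concordant
fragment footprints; copy number = depth / genome-wide median × baseline
ploidy (2). The median is robust against focal amplification; there is no
GC or mappability correction (the simulator has no such biases). Contigs are
cut at predicted breakpoints and at boundaries of zero-depth runs of at least
one full bin (guarding against binning artifacts). Reference edges connect
reference-consecutive contigs when ≥1 concordant fragment strictly straddles
the junction; each cluster adds a dPET edge between the contigs containing
its predicted breakpoints (an `L`-extending anchor fuses at its contig's
right end, an `R` anchor at the left end), weighted by cluster count and
annotated with head/tail orientation for rendering.

Amplicon growth seeds from the highest-weight unused dPET edge (ties: lowest
contig coordinates, then cluster id); the two seed contigs join
unconditionally, then neighbours through both edge kinds join while their
copy number is strictly >2, to a fixpoint. All dPET edges internal to the
final node set are marked used (each edge belongs to at most one amplicon);
graphs with ≤2 contigs are discarded. Whether reference-edge traversal should
require additional cPET support beyond the edge's existence is left at
"existence suffices"; the seed contigs are exempt from the amplification
test. Because baseline contigs sit at copy number ≈2 with sampling noise, a
large unamplified contig can drift marginally above the threshold and join a
graph; this does not affect which graphs exist or their seeds.

## Simulator

The simulator works at mapped-tag coordinates — no nucleotide sequences or
read mapping (an optional donor-FASTA emitter exists for integration demos
but is untested against real mappers). The donor genome is an ordered list of
reference segments per donor chromosome; planting deletions, tandem
duplications, inversions, terminal (unpaired) inversions, insertions of all
eight sub-types and translocations rewrites the segment lists and records
every fusion point at base-pair precision, together with the calls a perfect
analysis would make. An audit tool (`donor_junctions`) re-derives fusion
points by walking the finished donor, independently of the bookkeeping.

Fragments are sampled uniformly along the donor (chromosomes weighted by
length × copy number) with truncated-normal lengths — presets
(mean, SD) = (1,000, 100), (10,000, 1,000), (20,000, 2,000) bp, truncated at
±4 SD, reflecting tight unimodal gel size selection. Tags are mapped back
through the segment map; tags crossing a donor junction are dropped (a 25 bp
split tag would not map uniquely). Masked reference intervals model
repeat-induced unmappability as total tag loss. Chimeric ligation joins the
3′ end of one fragment to another (`chimera_rate`, benchmark default 1%);
PCR duplicates re-emit existing coordinates under new read ids
(`duplicate_rate`, default 5%). Fragments are sampled from the donor forward
strand only, so each fusion yields exactly one cluster rather than a
strand-mirrored pair, keeping truth bookkeeping 1:1; classification and
typing themselves are strand-general.

What the simulator does *not* emulate: mapping errors and ambiguous
placements beyond binary masking, GC/coverage bias, sequencing errors,
segmental-duplication mismapping, heterozygosity (the donor is haploid), or
overlapping/nested rearrangements. Passing tests therefore demonstrate the
correctness of the geometry, clustering and graph logic under realistic
sampling noise — not robustness to alignment artifacts of real data.

## Benchmark study conditions

`petsv.benchmarks` fixes the evaluation conditions: a 50 Mb four-chromosome
genome with 30 planted SVs covering every base type and all eight insertion
sub-types; insertion sources of 4–5 kb (below the 10 kb library's minimum
fragment length, so cut-and-paste gaps are visible); three small deletions of
3.0/3.5/4.0 kb (below the 10 kb span-bound limit, visible to the 1 kb
library); one 50 kb deletion with 1.5 kb masked tracts hugging both
breakpoints (spannable by 10 kb fragments only); events ≥300 kb apart so
superclusters stay isolated. Libraries: 10 kb at 60× and 1 kb at 8× physical
coverage — comparable sequencing effort, an order of magnitude apart in
physical coverage.

Recall is conditioned on detectability: deletions need
`span > span_max − fragment_mean + 2·SD`, and every fusion point needs at
least one unmasked flank window within the maximum fragment length on both
sides. This keeps "missed by design" (the small deletions for the 10 kb run,
the masked-flank deletion for the 1 kb run) distinct from genuine misses; the
excluded events are reported separately and asserted on directly.

Two stochastic effects worth knowing: at 8× physical coverage a single
junction is spanned by Poisson(≈8) fragments, so any one small deletion can
drop below the count-3 cutoff (~2% of runs) — the small-deletion class is
planted in triplicate and the library contrast asserted on the class; and at
a 1% chimera rate, roughly one run in fourteen has a chimeric dPET merge
into a true cluster by single linkage and displace one predicted breakpoint
beyond the matching tolerance, costing one event of recall/precision —
within the ≥0.95 acceptance bounds.

The amplicon benchmark uses three 5 Mb chromosomes plus episomes: a ten-copy
[chrA 0.9–1.2 Mb + chrB 2.0–2.3 Mb] unit (dominant fusion, cluster weight
≈10× everything else) and two single-copy satellite episomes chaining
amplified segments of chrB→chrC and chrC→chrA, sequenced at 30× with the
10 kb preset.

## Degenerate inputs and tie-breaks (summary)

Empty libraries/tables propagate as empty results; a library with no
concordant PETs cannot yield span statistics or a coverage track (error);
zero genome-wide median depth is an error. Cluster ids are assigned after
sorting by genomic location; supercluster and amplicon ids likewise, so all
outputs are byte-reproducible for a fixed input and seed (the CLI manifest
records command, config, input checksum and stage counts). Equal-weight seed
edges are ordered by contig coordinates, then cluster id.
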