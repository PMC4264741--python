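# Methods

This note documents the models, default parameters and design choices
behind `svcall`, and what the simulation-based tests do and do not
demonstrate about real data.

## Insert-size model and discordancy

All coordinates are 0-based, half-open internally; 1-based only at the VCF
boundary (BED/BEDPE stay 0-based). The insert size of a pair is the
*outer* distance, `rightmost mate end − leftmost mate start`, recomputed
from the mate coordinates; SAM TLEN is never trusted because its sign and
anchor conventions vary between aligners.

From up to `max_sample` same-chromosome pairs the modal coordinate-order
orientation is taken as the library's expectation (FR for short-insert
paired-end, RF for circularised mate-pair libraries), the median insert
size is computed over the majority-orientation pairs, and the scale σ_IS
is estimated robustly as 1.4826 × MAD. The robust estimator is the
default because the sampled pairs include SV-spanning outliers whose
inflated inserts would otherwise widen σ and hide the very events being
sought; `robust=False` restores the plain standard deviation. σ_IS is
floored at 1 bp so degenerate (constant-insert) simulated libraries do not
produce zero-width cluster windows. Estimation requires ≥ 50 usable pairs,
otherwise it aborts with an explicit error.

A pair is discordant, with reasons accumulated rather than exclusive, when

* `insert > median + k·σ_IS` (*large_insert*) or
  `insert < max(0, median − k·σ_IS)` (*small_insert*), with `k = 3` by
  default (≈ 0.27% of a Gaussian library flagged by chance per side);
* its orientation differs from the expectation (*orientation*);
* its mates map to different chromosomes (*inter_chromosomal*).

`k` and the clustering window multiplier (fixed at 2σ_IS) are independent
knobs: the first controls which pairs enter clustering, the second how
tightly they must agree to co-cluster.

Only uniquely mapped pairs take part: the default `min_mapq = 20` excludes
mapq-0 (multi-placed) reads. Duplicate-flagged pairs (FLAG 0x400) are
dropped by default; disable this for PCR-free/amplicon protocols where
duplicates are genuine.

## Hard clustering (streaming)

Discordant pairs sorted by `(chrom1, alpha)` are scanned once. A pair
joins an open cluster when its α and β positions are within 2σ_IS of the
cluster's running means, its strand signature matches exactly, and (for
same-chromosome pairs) its insert is within 2σ_IS of the cluster's running
mean insert. Among all matching clusters it joins the one minimising the
Euclidean distance in the (α, β) plane, ties broken by creation order;
otherwise it seeds a new cluster. Running means update incrementally after
every addition (`freeze_means` pins them at the seed values instead).
Inter-chromosomal pairs cluster per (chrom1, chrom2, signature) bucket
with the same positional windows and no insert criterion.

Clusters whose `µ^α` has fallen more than 2σ_IS behind the scan position
are closed. This eviction is purely a memory bound: a closed cluster's
mean is, by construction, more than 2σ_IS below every future α, so no
future pair could have joined it anyway — the streaming result is
provably identical to a full-history clusterer on sorted input, and the
test suite asserts this equivalence against an independent brute-force
implementation on randomized instances.

Strand signature is a hard key: pairs of different orientation never
co-cluster, because orientation *is* the downstream type signature.
Complex rearrangements therefore surface as several single-signature
clusters rather than one merged object, which is intentional — they
require manual interpretation of the cluster pattern.

**Support cutoff.** Clusters need a minimum member count,
`max(floor, round(coverage/10))` with `floor = 2`. The coverage fed to
this rule by the pipeline is the *physical* (fragment) coverage
`n_pairs × median_is / genome_size`, not the base coverage: for a
long-insert library the number of fragments spanning any point — and
hence the expected support of a true junction cluster — scales with
fragment coverage (≈ 900× for a 3 kb library at 30× base coverage with
50 bp reads), while chance co-clusters of insert-tail pairs stay in the
single digits. The cutoff is config-exposed (`--min-support`) for
libraries where this heuristic is inappropriate.

**Cluster fragmentation.** Junction-spanning read starts spread over
roughly `insert − 2·read_len` (≈ 2.9 kb at default conditions), wider than
the 2σ_IS ≈ 600 bp window, so one junction is typically reported as a few
adjacent clusters. All of them sit on the same breakpoints and type
identically; no attempt is made to re-merge them.

## Breakpoint intervals

Each cluster yields one interval per side, guaranteed (up to the
insert-size model) to contain the junction. For a read group whose strand
points *towards* its mates (strand equal to the expected orientation's
first strand) the junction lies to the right:
`[max(pos) + read_len, max(pos) + median_is)`. For a group pointing away
it lies to the left: `[min(pos) − median_is + read_len, min(pos) + 1)` —
the `+1` because a fragment cut exactly at the junction places a read
start *on* it. This strand-aware rule is what makes the intervals correct
for everted (DUP) and same-strand (INV) clusters, whose junctions sit on
the opposite side of the read group compared to the deletion-like case.
If the construction degenerates (median_is ≤ read_len), a fallback window
of width 4σ_IS centred on the running mean (offset by the read length on
the junction-right side) is used. Reported VCF positions are interval
midpoints with the full interval in CIPOS/CIEND.

## Type signatures

With expected orientation e = (e₁, e₂) and cluster signature s:
inter-chromosomal → TRA; s₁ = s₂ → INV; s = e with mean insert above
`median + k·σ_IS` → DEL, below `median − k·σ_IS` → INS; s = reversed(e)
(everted) → tandem DUP; anything else → COMPLEX. The map mirrors
automatically for RF libraries, and the suite verifies FR/RF symmetry on
identical simulated SV sets. INS here means "insert smaller than
expected": insertions longer than the library insert do not produce this
signature and are split-read territory, out of scope. Dispersed
duplications present as TRA/COMPLEX and are left as such.

## Depth-of-coverage ratio analysis

Window size is `genome_size × target_reads_per_window /
min(total_sample, total_ref)` rounded up to 100 bp (default target: 100
reads/window; default step: window/2). A read is anchored by its 5′-most
mapped base, so with non-overlapping windows counts are conserved
exactly. Per window, with counts n_s, n_r and library totals N_s, N_r:

    log2_ratio = log2( (n_s/N_s) / (n_r/N_r) )

Under the no-change null, the log-ratio of two Poisson counts is
approximately Gaussian with variance `(1/n_s + 1/n_r) / ln(2)²` on the
log2 scale; the two-sided tail probability of `z = log2_ratio / sd` is the
window p-value. Windows with a zero count keep `log2_ratio` undefined
(flagged) and get a 0.5 continuity correction on both counts for an
always-defined corrected ratio and p-value — this is what lets a
homozygous deletion (zero sample reads) still form a loss segment.
Calibration is checked empirically: on null Poisson simulations the
fraction of windows with p < 0.05 is 0.050 ± 0.01.

Segmentation is deliberately simple (the package's own rule-based stand-in,
`ratio_model=gaussian_poisson`): maximal runs of ≥ `min_consecutive`
(default 3) consecutive windows with |z| > `z_threshold` (default 3) and a
consistent sign. Near the detection limit (per-window |z| ≈ threshold)
runs fragment; segment-level statements in the tests therefore use deep
windows, while regional copy number is recovered from window means. No
GC-content or mapability correction is applied — a matched reference
sample sequenced under the same protocol is assumed to absorb those
biases, and the TSV output header says so.

## Realignment rescue and track filters

A discordant pair is a candidate mapping artifact if one of its reads also
aligns where a *concordant* placement relative to its mate would put it.
For each mate the window on the side its anchor points to
(`median_is + search_margin` long, margin default 4σ_IS) is scanned with
affine-gap local alignment (match 1, mismatch −1, gap open −2, extend −1);
the hit must cover ≥ 90% of the read at ≥ `min_identity_frac` (default
0.9) identity **and be on the strand that restores the expected
orientation**. The strand requirement is essential: the mate sequence of a
genuine inversion-spanning pair really does occur near the anchor, but
reverse-complemented — an orientation-blind search would discard every
such pair (measured: 100% loss without the strand check, 0% with it).
Pairs without stored sequences pass through unexamined.

Annotation tracks (BED3+; overlapping intervals unioned on load) score
each call by the covered fraction of its span — for translocations, of
each breakpoint interval, tagging if either side exceeds the threshold
(default 0.5, per-track override). `annotate` mode (default) only tags;
`remove` drops tagged calls.

## Evidence integration

DEL/DUP cluster calls and sign-consistent DOC segments with reciprocal
overlap ≥ 0.5 merge greedily by decreasing overlap, each object used at
most once; merged calls carry `EVIDENCE=cluster,doc` and the segment's
mean log-ratio. A DEL/DUP cluster call overlapping only an opposite-sign
segment is tagged `discordant_evidence` and both calls are kept.
Unmatched segments become IMPRECISE DOC-only `<DEL>`/`<DUP>` calls with
SUPPORT=0. INV/TRA/INS are copy-neutral and never merge. Translocations
are written as paired BND records with bracket notation derived from the
cluster strands and MATEID/EVENT cross-references; output is
deterministic, so identical inputs give byte-identical VCFs.

## Simulator

The simulator is the package's ground-truth generator. A uniform-ACGT
reference is rearranged by splicing (DEL removes, DUP inserts extra
tandem copies, INV reverse-complements in place, INS inserts novel
sequence, TRA reciprocally exchanges arms), recorded as a block map from
donor to reference coordinates. Fragments are drawn uniformly from the
donor with insert ~ Normal(mean, sd) truncated at 2·read_len; reads sit at
the fragment ends in the requested chemistry (FR or RF) and are reported
at their exact reference mapping through the block map — no aligner runs,
which isolates the caller's logic from aligner behaviour. Pairs are
labelled spanning only when their mates straddle a *non-collinear* block
boundary (the flank→first-copy boundary of a tandem DUP is
reference-collinear and correctly yields concordant pairs). Reads that
would cross a junction within their own length, or fall in novel inserted
sequence, are dropped — a real aligner would soft-clip or fail to place
them, and split-read evidence is out of scope.

Default scenario (the standard study condition used by the acceptance
script): two 2 Mb chromosomes; 2 DEL (10 kb, 8 kb), 1 tandem DUP (10 kb),
1 INV (12 kb), 1 reciprocal TRA; 30× coverage as an RF mate-pair library
with 3000 ± 300 bp inserts, 50 bp reads, 0.5% substitution errors. These
sizes keep a full 20-replicate study under a few CPU-minutes while leaving
every per-junction statistic (≈ 900× physical coverage, hundreds of
spanning pairs) in the regime the method targets.

What the simulator does **not** model — and hence what passing tests do
not show about real data: indels and quality-dependent sequencing errors,
GC and mapability bias, chimeric library artifacts, repetitive reference
sequence (every simulated locus is unique, so mapping ambiguity never
occurs), heterozygosity (events are implanted homozygously), and aligner
behaviour at junctions. The realignment and track filters are exercised
on constructed artifacts and synthetic tracks, not on genuinely
misassembled mappings.

## Known limitations

* Events smaller than ~2σ_IS of insert spread, or insertions longer than
  the library insert, are invisible to the read-pair signal.
* One junction is reported as several adjacent clusters at default
  conditions (see *cluster fragmentation*); consumers should collapse
  calls whose confidence intervals overlap if a 1:1 event list is needed.
* The DOC segmenter is a rule-based stand-in, not a change-point method;
  low-amplitude events near the z-threshold fragment or drop out.
* `min_support` scales with fragment coverage by a /10 heuristic; for very
  shallow or very deep libraries it should be set explicitly.
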