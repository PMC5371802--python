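# Methods

## Filtering model

The unit of observation is an OTU count table: non-negative integer read
counts per OTU per PCR replicate, with a ranked lineage (possibly
truncated, possibly empty) attached to each OTU. A *phylotype* is defined
operationally as the most specific assigned (rank, label) pair of a
lineage; an empty lineage maps to the reserved "unknown" phylotype.
Homonymous labels at different ranks remain distinct because the pair is
the identity; identical labels reached through conflicting lineage paths
are merged into one phylotype and the conflict is logged rather than
resolved (reference-taxonomy reconciliation is out of scope).

Stringency levels are parameterised as `(min_count, min_replicates,
remove_singletons)` and generalise beyond three replicates; the named
presets are T0 = (1, 1, no), T1 = (1, 1, yes), T10 = (10, 1, no),
T10-R1 = (10, 2, no) and T10-R2 = (10, R, no).

Two semantics matter and are fixed here deliberately:

* **Singleton removal acts at OTU level, per replicate.** Every cell equal
  to exactly 1 is zeroed independently per replicate and the table is
  re-aggregated. This is the only reading under which OTU counts fall
  under T1 as well as phylotype counts; zeroing at phylotype level would
  leave OTU counts untouched.
* **Threshold levels are evaluated on raw phylotype counts**, not on
  post-T1 counts. For thresholds ≥ 10 the two are equivalent (a cell ≥ 10
  is never zeroed), which is also why the surviving sets nest:
  T10-R2 ⊆ T10-R1 ⊆ T10 ⊆ T1 ⊆ T0.

Whether the ≥10-copy levels are taken relative to T0 or applied
cumulatively after T1 changes nothing about the surviving sets (by the
nesting argument); reported OTU counts use the T0 baseline throughout and
retention percentages are always relative to T0.

Rounding follows reporting conventions: two decimals for per-level
retention, nearest whole percent for per-replicate means, both half away
from zero.

## Quality control

Reads are trimmed by a fixed head/tail cut (default 10 + 10 bases, the
low-quality ends of 100 bp HiSeq reads) *before* the quality rule is
evaluated. A read is kept iff strictly more than `min_fraction` (default
0.95) of its remaining positions have Phred quality ≥ `q_threshold`
(default 20): "more than 95%" is a strict inequality, so exactly 95% of
positions fails, and the boundary is pinned by a test. Quality encoding is
fixed to Phred+33 and other encodings are rejected rather than guessed; a
minimum post-trim length of 1 (configurable) routes over-trimmed reads to
a separate length-dropped tally.

## Clustering stand-in

The greedy centroid clusterer exists so synthetic end-to-end runs need no
external OTU tool; production tables from dedicated clustering tools are
imported through the table reader instead, and the module is not intended
to scale beyond thousands of sequences. Records are processed in
decreasing abundance (ties by id), each joining the first centroid — in
founding order — with identity ≥ the threshold (default 0.97). Identity is
computed from one optimal global alignment (match +1, mismatch −1, gap −1)
as identical columns divided by alignment length *including gap columns*,
with deterministic traceback tie-breaking (diagonal, then up, then left).
Both the denominator and the tie-break are conventions fixed here so an
exhaustive-enumeration oracle can reproduce them exactly.

## Annotation and comparison

Top-hit selection takes, per query, the hit with maximal bit-score, ties
broken by minimal e-value and then input order (a convention; upstream
parsers rarely document theirs). The e-value gate is strict
(`evalue < 1e-5` by default). Subjects missing from the supplied taxonomy
map are kept and flagged "unknown" — distinct from queries with no gated
hit, which are listed as unannotated. The same machinery serves a
SILVA-style 7-rank cellular order and an ICTV-style 6-rank viral order;
rank orders are configurable presets.

Cross-method and cross-fraction comparisons project lineages to a target
rank (genus by default) with fallback to the most specific assigned rank
when the target is unassigned. "Most specific" is the only sensible
reading of a genus-or-coarser fallback: the most general rank would
collapse everything to domain. Unassigned lineages are excluded from
presence–absence sets, since a shared "unknown" token would register as a
spurious common taxon. Shared percentages use the union denominator
`100·|A∩B|/|A∪B|` — the only denominator symmetric in the two sets —
reported to two decimals. The metagenome set is held at its unfiltered
annotation while the amplicon stringency varies, so amplicon-side Venn
regions are non-increasing in stringency.

## Synthetic data

The generator emulates the study conditions the pipeline assumes: three
PCR replicates, lognormal relative abundances (the standard
species-abundance assumption; location 0, scale 1.5 by default),
multinomial per-replicate sampling at a configurable depth, artefact OTUs
appended with count exactly 1 in one replicate, and terrestrial
contaminant lineages (chickpea, sesame, tobacco) spiked at count 1 by
default. Synthetic lineages share coarser ranks through a deterministic
genus→family→order→class→phylum mapping, and a configurable fraction of
taxa truncate above species level.

Problem sizes are chosen for desk-scale runs: default communities of
25–150 taxa at depths of 3 000–20 000 reads per replicate keep every suite
in seconds while leaving multinomial noise clearly visible. Two
constructions make key guarantees exact rather than statistical:

* artefacts are count-1-in-one-replicate *by construction* (a "messy" mode
  draws geometric counts ≥ 1 for stress tests where recovery is only
  statistical);
* with `ensure_detectable` (default on), any true taxon whose multinomial
  draw gives a maximum count ≤ 1 across replicates is raised to 2 in one
  replicate, so singleton removal can never delete a genuine community
  member. The adjustment touches only taxa with expected counts near
  zero and is negligible for the sampling-accuracy checks.

Under these defaults, singleton removal recovers the true phylotype set
*exactly* and removes every count-1 contaminant — the testable realisation
of replicate-aware denoising. What passing these tests does **not** show:
real amplicon artefacts are not all singletons (chimeras and systematic
PCR errors recur across replicates), abundances are compositional rather
than multinomial at fixed known depth, and real lineages carry annotation
errors; on real data T1 is a bias–variance trade-off, not an oracle.

The metagenome simulator emits a 12-column tabular hit file in which each
query's intended subject carries the top bit-score, with decoy subjects
below it, so top-hit selection recovers a configured superkingdom mixture
(default: heavily bacterial with an ~11% unknown slice, matching
contig-level annotation of marine metagenomes against a whole-organism
protein database). The viral slice uses a curated-style namespace of
tailed-phage and giant-virus families. `overlap_fraction` controls how
many cellular genera are drawn from the amplicon community (default 0.10,
a "very little overlap" regime).

The FASTQ simulator draws per-base qualities i.i.d. (Q ∈ [20, 40] with
probability `p_good_base`, else Q ∈ [2, 19]), making the kept fraction
under the strict >95% rule exactly a binomial tail P(X > 0.95·L) — the
closed form the QC suite checks against. Real quality profiles are
position- and cycle-dependent; this generator is a semantics check, not a
platform error model.

All generators use one `numpy` `default_rng` seeded per call; no global
state. Scripts deriving many seeds spawn them from a single master seed.

## Numerical and degenerate-input choices

* Percentages: half-away-from-zero rounding everywhere (two decimals for
  level retention and shared percentages, whole percents for replicate
  means).
* Empty tables round-trip; an empty T0 baseline is an error for retention
  reporting; an amplicon set emptied by filtering produces a warning and
  zeroed Venn regions rather than an error.
* BLAST coordinates stay 1-based inclusive end-to-end; no internal
  conversion.
* `passes_quality` on an empty read is a caller error: over-trimmed reads
  must be tallied as length-dropped, keeping the QC identity
  `reads_in = kept + dropped_quality + dropped_length` exact.
* Deterministic subsampling (library-size normalisation) preserves the
  original relative order of the selected items and returns everything
  unchanged when the request covers the input.

## Known limitations

Swarm-style single-linkage clustering, chimera detection, BIOM/SAM
formats, abundance rarefaction, compositional normalisation and
differential abundance are out of scope. The greedy clusterer is
quadratic in the number of distinct sequences. Lineage comparison is
string-based after whitespace normalisation; synonym resolution across
reference databases is the user's responsibility.
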