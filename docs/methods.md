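# Methods

`stygdiv` implements a distance-based analysis of species diversity in the
Stygiellidae, the family of anaerobic jakobid flagellates, from SSU rDNA
sequence data.  It covers four connected procedures: (1) uncorrected
p-distance computation over anchor-defined alignment windows, (2) species
delimitation from the barcoding gap between intra- and interspecific
distances, (3) assignment of short hypervariable-region environmental
fragments (pyrotags) to delimited species or environmental clades, and (4)
culture-vs-environment detection statistics.  A synthetic-community
generator provides inputs with the statistical structure the analysis
assumes.

## Distances

The p-distance between two aligned rows is `mismatches / comparable sites`,
where a site is comparable iff both rows carry an unambiguous base
(A/C/G/T).  Gaps, `N` and IUPAC ambiguity codes are excluded *pairwise*
(pairwise deletion), not by deleting any column with missing data
(complete deletion).  Pairwise deletion maximises the usable signal for
short fragments that cover only part of the alignment, and is the standard
convention for p-distances on partially overlapping data.  No
substitution-model correction (JC, K2P) is applied: the delimitation logic
operates on raw mismatch fractions, and the thresholds it uses were stated
on the same scale.

A comparison is *undefined* when fewer than `min_sites` comparable sites
remain: 100 sites for full-length comparisons, 80 for V9-sized fragments
(the V9 window is only 130 columns wide).  The guard prevents distances
computed on tiny overlaps from entering minima and maxima; both defaults
are configurable.  Distances are carried at full float precision and only
rounded (4 decimals) in TSV output.

## Coordinates and windows

Analysis windows are 1-based inclusive intervals on the *ungapped*
residues of a designated anchor row, mapped through alignment columns
before slicing.  The two built-in windows are positions 545–1544 (the
central SSU region used for delimitation) and 1645–1774 (the V9 region,
130 nt, used for fragment assignment) on the anchor.  Queries must already
be aligned into the reference coordinate system (or pre-sliced to a
window); the package does not align reads.

## Species delimitation

Intraspecific SSU rDNA distances in this family do not exceed 4.6% while
the minimum interspecific distance is 6.7%; the gap between these
envelopes licenses distance-based delimitation.  The package
operationalises it as single-linkage clustering with linkage threshold
`t_intra = 0.046`: flat single-linkage clusters at threshold t are exactly
the connected components of the graph with edges `d <= t`, which is how
they are computed (scipy connected components).  After clustering, every
cluster pair's minimum separation is checked against `t_inter = 0.067`;
any pair separated by a value strictly inside `(t_intra, t_inter)` is
recorded as a gap violation — the data then do not exhibit the clean gap
the method assumes, and the flag is the honest output.

Clusters containing at least one culture-sourced member take the (unique)
species label of their cultured members; a cluster mixing two cultured
species is an error, not a silent merge.  Culture-free clusters become
environmental clades labelled `EC I`, `EC II`, … by descending member
count, ties broken by ascending smallest member id.  The original EC
numbering convention of the source survey is not recoverable from its
text; this ordering is a documented convention chosen so that relabelling
or reordering the input never changes the result.

## OTU clustering

Pyrotag dereplication uses greedy uclust-style clustering at 97% identity:
sequences are processed by descending count (ties by ascending id); each
joins the first OTU whose *representative* is within `1 - cutoff`
p-distance, else founds a new OTU.  Only representative-vs-query identity
is used — no refinement rounds — so the procedure is deterministic and its
tie-breaks testable.  Representatives are consequently pairwise below the
cutoff.

## Fragment assignment

For a query q and species s, `d(q, s)` is the minimum p-distance from q to
the members of s over the shared window.  The closest species s* claims q
iff `d(q, s*) <= max_intra(s*) + slack`, where `max_intra` is the species'
own maximum intraspecific distance over that window (0 for singletons) and
`slack = 0.01` absolute — about one substitution on a 130-site V9
fragment, standing in for the unquantified "slightly higher than
intraspecific" margin the distance-envelope approach tolerates.  Two
species satisfying their envelopes at distances within 1e-9 of each other
make the call ambiguous (reported, never silently broken).  Queries with
fewer than `min_sites` comparable sites against every reference are
`unassigned_low_overlap`; queries no envelope admits enter the founder
pool.

Founder-pool fragments are OTU-clustered at 97%; an OTU becomes (part of)
a new environmental clade when its minimum distance to every existing
clade exceeds `t_inter` wherever an overlap of at least `min_sites` exists
to compute one.  OTUs that cannot be compared to some clade at all are
still founded but flagged `overlap-incomplete` (the situation of a clade
known only from a fragment that shares no columns with another clade's
sequences).  Founded OTUs mutually within `t_intra` merge into a single
clade — mirroring how several distinct V9 OTUs can constitute one new EC —
numbered after the existing ECs.

## Helix-27 signature

The diagnostic paired-site check reads two configured alignment columns
and reports `CG` (the Andalucina state), `AT` (other jakobids), or `other`
(gap, ambiguity, or any different pair, including the reversed
orientation G:C — the check is strict about orientation).  The column
indices are configuration, not computed: secondary-structure prediction is
out of scope.

## Survey statistics

`tally` sums (species, source, count) records into a species × method
matrix over the five detection methods (culture, clone library, and V4,
V9, V6–V8 pyrotags).  `recovery_fraction` is the fraction of a species
universe detected by at least one method of a subset; it is monotone in
the method set.  `relative_abundance` normalises each method column over
its cells with known counts.

The packaged fixture `stygiellidae_survey.tsv` encodes the published
incidence: 10 species in the universe (6 cultured, 4 environmental
clades), 21 cultured strains, 83 environmental clones, 629 pyrotags (V4=1,
V6–V8=56, V9=572), with EC V (known only from a 172-nt V9 fragment) and
the unresolved bin excluded from the universe.  Most per-species counts
were never published; those cells carry an `NP` marker — detected, count
unknown — and are excluded from any cell-level arithmetic, with column
totals carried in a `TOTAL` row.  On this fixture, culture-based recovery
is 6/10 = 60% and environmental recovery 8/10 = 80%.  The
`published_survey` preset of the generator re-emits this incidence pattern
as records, distributing each method's total across its detected lineages
(1 per unpublished cell, remainder to the first); those per-cell counts
are synthetic stand-ins — only incidence and totals are faithful.

## Synthetic communities

`generate_references` plants K = 10 species (6 cultured) of 2–6 strains
each on 1800-nt sequences.  A random ancestor spawns one mutated ancestor
per species; species ancestors are rejection-sampled until every pairwise
p-distance reaches `d_inter_min + d_intra_max` (= 0.113), each carrying
`ceil(0.65 * 0.113 * L)` substitutions — enough that the expected pairwise
separation (~0.137) clears the floor and rejection is rare.  Strains then
mutate their ancestor at up to `floor(d_intra_max/2 * L)` sites, so any
two strains of a species differ at most by `d_intra_max` and strains of
different species by at least `d_inter_min`.  Because mutation is
stochastic, the finished community is audited by brute-force distance
summary and redrawn wholesale on any breach (at most 1000 attempts; the
defaults essentially never redraw).

Fragments are cut from the V9-like window of a uniformly chosen strain,
with independent per-site substitution errors at rate 0.002 (a realistic
post-filtering amplicon error rate) and per-species Poisson counts around
a strongly skewed abundance profile, default expected counts
(250, 120, 100, 40, 15, 5, 3, 2, 1, 1): a few hyper-abundant lineages over
a long rare tail, as pyrotag surveys of anoxic habitats show.  Evolution
is substitution-only by default; an optional indel mode
(`indel_columns > 0`) inserts alignment columns carried by ~30% of
non-anchor rows, exercising pairwise deletion and gapped-anchor
coordinate mapping without altering window coordinates.

Everything derives from `SimConfig.seed`; each stage uses its own
sub-stream (`[seed, k]`), so regenerating fragments never perturbs the
references, and identical configurations give byte-identical FASTA/TSV.

### What the generator does and does not emulate

It reproduces the features the analysis logic depends on: the distance
envelope, cultured/uncultured structure, short noisy window fragments,
and abundance skew.  It does not model rate heterogeneity across sites,
realistic rRNA secondary structure, chimeras, or PCR/primer bias.
Passing recovery tests therefore demonstrates the *algorithmic*
correctness of delimitation and assignment under the stated envelope
assumptions — not robustness to every artefact of real amplicon data.

## Numerical and design choices

- Thresholds `t_intra = 0.046`, `t_inter = 0.067`, identity 0.97 and
  slack 0.01 are defaults, overridable everywhere, and echoed into run
  manifests.  The envelope values derive from the family's published
  distance tables, whose underlying supplementary sequence data are not
  shipped; they function here as constraints and defaults, not as
  recomputed quantities.
- Cluster merging uses `<=` at `t_intra`; gap violations use the open
  interval; envelope admission uses `<=` with absolute slack; ambiguity
  tolerance is 1e-9.
- Single-linkage components, EC numbering, and greedy OTU tie-breaks are
  all deterministic and order-invariant (tested under input permutation).
- Problem sizes in the test suite and acceptance script — 50 community
  seeds, 500 noisy fragments, enumeration oracles up to 8 sequences —
  were chosen as the smallest sizes at which the recovery and equivalence
  properties are meaningfully exercised; all complete in seconds.

## Known limitations

- Queries must arrive aligned to the reference coordinate system; there
  is no built-in aligner or phylogenetic placement.
- The assignment slack is a single absolute constant; a per-species or
  length-scaled margin might be preferable for very short fragments.
- `min_sites` interacts with fragment length: fragments shorter than the
  guard are unassignable by construction.
- Recovery fractions treat detection as binary; no rarefaction or
  diversity indices are computed.
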