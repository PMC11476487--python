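# Methods

## Scan-path encoding

A scan path is an identified, ordered sequence of AOI labels. Labels are
case-sensitive tokens without whitespace; single letters are the usual
convention, and multi-character tokens are supported with an explicit
delimiter (default `|`) in files and CLI arguments. Every ingested
sequence — whether read from a file, assembled from fixations, or simulated
— has runs of consecutive identical labels collapsed to a single label
before comparison, so a dwell of several fixations on one AOI counts as a
single visit. Collapsing is idempotent and applied uniformly: comparison
semantics should not depend on where a sequence came from. Empty scan paths
are rejected rather than given a similarity convention; the framework has
no meaningful value for them.

When scan paths are built from fixation tables, a fixation is mapped to the
first AOI (in definition order) whose rectangle contains it. Coordinates
are pixels, origin top-left, x rightward, y downward; containment is
half-open, `[min, max)`, so abutting AOIs never both claim a shared edge,
and first-defined-wins resolves genuine overlaps deterministically.
Fixations outside every AOI are excluded (counted in the log); a
participant with no in-AOI fixation is dropped with a warning.

## Similarity metrics

**Jaccard coefficient similarity** is computed on the distinct-AOI sets:
`J = |A ∩ B| / |A ∪ B|`. It is symmetric, lies in [0, 1], is invariant to
any permutation of a sequence, and equals 1 exactly when the two paths
visited the same AOIs.

**Normalized string-edit similarity** is `S = 1 − d/n`, with `d` the
minimal unit-cost Levenshtein distance between the label sequences and `n`
the length of the longer (collapsed) sequence. Unit costs — 1 per
insertion, deletion, or substitution, no transpositions — are used
throughout; only the minimal total matters, since the individual
(i, d, s) breakdown of an optimal edit script is not unique. Because the
distance between sequences of lengths `m ≤ n` is at most `n`, `S` also
lies in [0, 1], reaching 1 only for identical sequences.

Distances are computed by `edlib` (global alignment on the token
sequences); a two-row dynamic-programming fallback handles inputs edlib
cannot encode. The test suite checks the implementation against an
independent memoized-recursive definition of the distance, exhaustively on
short sequences and on large random samples, and verifies symmetry, range,
identity, and the triangle inequality.

## Classification

For a population of `n ≥ 2` scan paths the package builds both `n × n`
pairwise similarity matrices (symmetric, unit diagonal). Each path's
coordinate on a metric is its arithmetic mean similarity to the other
`n − 1` paths, self-similarity excluded — the only per-path aggregate
consistent with averaging over pairwise comparisons that yields one point
per path. The HIGH/LOW threshold per metric is the mean of that metric over
the `n(n−1)/2` unordered distinct pairs, so the thresholds come from the
data rather than a subjective cutoff. By symmetry the mean of the per-path
means equals the pair-average threshold exactly; the suite asserts this
identity per metric.

A path is HIGH on a metric iff its mean is **≥** the threshold (ties go to
HIGH — a deterministic, documented tie-break), and the two flags select one
of the four quadrants. With exactly two paths each path's single similarity
is also the threshold, so both land in HIGH/HIGH; the package accepts
`n = 2` but warns that the result is uninformative. Quadrant counts always
sum to `n`, and classification is invariant to input order.

No significance testing or multiple-comparison machinery is attached: the
framework is descriptive, and alternative thresholding schemes (expected
values under a task-structure null, permutation baselines) are out of
scope.

## Synthetic scan-path simulator

The simulator draws `n_draws` AOI labels independently from a categorical
distribution and collapses consecutive duplicates, so simulated paths can
be shorter than the draw count. The reference configuration is 10 AOIs
(A–J), 15 draws per path, and two regimes of four paths each:

| parameter | default | meaning |
|---|---|---|
| labels | A–J (10 AOIs) | the AOI inventory |
| n_draws | 15 | pre-collapse samples per path |
| uniform regime | p = 0.10 each | random search over all AOIs |
| focused regime | C .20, D .20, E .30, F .25, G .05, rest 0 | strategy concentrated on C–F |
| k_per_group | 4 | paths per regime |

Probabilities must be non-negative and sum to 1 (within 1e-9); labels must
be distinct. A single master seed is expanded into per-path substreams with
`numpy.random.SeedSequence.spawn`, making populations reproducible and
independent of generation order. Draws are i.i.d. — the simulator emulates
where gaze lands, not Markov transition structure, fixation durations, or
coordinates, so passing recovery tests show that the pipeline separates
content-focused from diffuse sampling regimes, not that it captures every
property of real gaze data.

`recovery_experiment` replicates simulate-then-classify over a range of
seeds and reports, per seed, how many focused paths were classified
HIGH/HIGH and how many uniform paths LOW/LOW, together with the modal joint
outcome (ties between equally frequent outcomes break toward larger
recovery counts). Replication across seeds is the appropriate summary
because any single draw of eight 15-sample paths is noisy. The margins are
asymmetric by construction: in 15 uniform draws a path visits about 8 of
the 10 AOIs, so uniform–uniform Jaccard similarity is substantial and the
uniform paths' Jaccard means sit only slightly below the pair-average
threshold. Perfect joint separation of all eight paths in a single run is
therefore far from guaranteed, even though HIGH/HIGH is the most frequent
classification for each focused path and LOW/LOW for each uniform path
individually; `recovery_experiment` quantifies exactly this.

## Numerical and interface choices

* Floating-point assertions in tests use absolute tolerance 1e-9; values
  printed to three decimals are matched after rounding.
* The CLI prints similarities with 10 decimals so output parses back to the
  library value within 1e-9.
* Report JSON field names (`n_paths`, `thresholds.string_edit_mean`,
  `thresholds.jaccard_mean`, `paths[].id/string_edit_mean/jaccard_mean/
  quadrant/quadrant_description`, `quadrant_counts`) are frozen for
  downstream parsing; quadrant descriptions are the four fixed phrases.
* Sequence files round-trip: writing uses the compact single-letter form
  when every token is one character, else delimiter-joined tokens.

## Known limitations

* Duration-weighted alignment (ScanMatch-style), vector/shape-based
  comparison (MultiMatch), and multi-dimensional alignment (FuncSim) are
  not implemented; the metrics here consider AOI membership and order only.
* Fixation/saccade event detection is upstream of this package: it consumes
  fixations or ready-made sequences, not raw gaze samples.
* Average-based thresholds are relative to the analyzed population: adding
  or removing one scan path moves the thresholds and can change other
  paths' quadrants. That is inherent to the self-referential design.
* Test-suite problem sizes: exhaustive oracle comparison runs over all
  collapsed sequence pairs up to length 4 on a 4-letter alphabet plus
  10,000 seeded random longer pairs; metric-law checks use 10,000 random
  pairs; recovery runs use 100-seed replications. These sizes make the
  checks exact-or-statistical at desk scale while keeping the suite fast.
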