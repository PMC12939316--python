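# Methods

## Model and rationale

`mirank` aggregates ordinal evidence. The unit of observation is a study's
claim "these were the N most abundant miRNAs in product X, in this order".
Because platforms (HiSeq generations, microarrays, SOLiD), normalisations and
reporting formats differ across the food-profiling literature, expression
values are not comparable; rank positions within a study are. The Borda score
`s(p) = N − p + 1` converts each ballot into points, summed with equal study
weights. The scheme deliberately rewards both *height* (being ranked first)
and *recurrence* (being listed at all by many studies): a miRNA listed 8th by
five studies (5 × 3 = 15) outranks one listed 1st by a single study (10),
which matches the goal of identifying *consistent* predominance rather than
one-off claims.

Assumptions worth stating:

- Studies are exchangeable (equal weights). A `weights` mapping exists for
  sensitivity analyses but the reproduction path never uses it.
- Only top-N membership is informative; positions beyond the window carry no
  signal and score 0. N defaults to 10 and is configurable (scaled tests use
  3).
- Ties ("ranked similarly") are scored as the arithmetic mean of the scores
  their block spans, with positions beyond N contributing 0 to the mean. The
  source tables mark ties but never score them; the mean policy was chosen
  because it conserves a ballot's total mass N(N+1)/2 and is symmetric in the
  tied members. A boundary tie at positions 10–11 of a top-10 list therefore
  scores 0.5 each.
- Consensus ties break by recurrence, then best observed position, then
  display name. Only the recurrence key is motivated by the aggregation
  scheme itself ("cumulative recurrence"); the rest is a deterministic
  convention, and the consensus records a per-pair trace of which key decided
  each adjacent ordering. Score comparisons use a 1e-9 tolerance (ties
  produce halves; exact rational arithmetic is unnecessary).

## Nomenclature

Cross-study set algebra needs a species-independent identity. `canonicalize`
strips species prefixes (`bta-`, `spu-`, …; unknown 3–4-letter prefixes are
stripped with a warning), normalises stem casing (`MiR` → `miR`,
`Let` → `let`), lowercases paralog letters, splits the mature arm
(`-5p`/`-3p`), and drops underscore variant suffixes (`_1`) and invertebrate
placeholder letters (`-x/-y/-z`). Two deliberate non-actions: armless names
are *not* assigned a guessed arm (that would silently change set counts;
arm-exact matching is used throughout the reproduction path, with a `lenient`
policy available), and lettered paralogs (miR-92a vs miR-92b) are never
collapsed (an optional `family_key` helper exists but is unused in the
reproduction path).

## Fixtures and the reproduction path

The packaged TSVs transcribe the curated summary tables of highly conserved
predominant miRNAs in raw (46 rows) and processed (26 rows) animal-source
foods, keeping each printed source label (e.g. "Offal (beef liver, rabbit
liver)") as cell provenance; a packaged label map assigns every label to one
of five food groups × {raw, processed}. Row counts (46/26/48) are checked at
load time. The per-product ten-most-abundant table that precedes them in the
source is *not* used for set analysis: it mixes non-conserved names
(miR-2478, miR-26c, miR-148d) and conflicts with the curated tables in one
case.

Partition definitions: a miRNA is **exclusive** to a group when every
documented occurrence (raw and processed pooled) falls in that group;
otherwise **shared**. Exclusives with ≥ 1 processed-state occurrence
**persist** after processing. Strict computation over the fixtures yields
exclusive sets of sizes 3 (lean meat), 3 (meat fat), 3 (meat offal), 6
(dairy) and 3 (seafood) — 18 in total — and a persistence set of four:
miR-133b, miR-23a-3p, miR-192-5p, miR-200c-3p.

Two table-vs-narrative discrepancies are reported as notes rather than
resolved: (1) the narrative names miR-92-5p among offal-selective miRNAs but
no such table row exists; the strict result is miR-192-5p, consistent with
the persistence list. (2) miR-30e-5p is tabulated in both beef heart (offal)
and pearl oyster (seafood), making the narrative's seafood count of 4 and
total of 19 unreachable by strict computation (3 and 18 here). The pipeline
emits the strict counts plus the notes.

## Enrichment and network analytics

These stages are generic re-implementations of what dedicated suites provide,
kept behind the package's own surface so the pipeline has no service
dependencies. The hypergeometric upper tail P(X ≥ x) is computed via
`scipy.stats.hypergeom.sf` (survival function; numerically stable, exact for
the universe sizes used here) and is cross-checked in the test suite against
exhaustive draw enumeration for all admissible configurations with M ≤ 12.
BH q-values come from `statsmodels` (`fdr_bh`) behind `bh_adjust`, applied
across *all* tested sets regardless of the reported overlap cut. The ORA
universe defaults to the target map's own gene space — the natural background
when queries arise from target prediction — and is overridable. The
most-targeted-gene selector exposes both parameterisations found in practice
(absolute cap of 100 with a ≥ 40-miRNA coverage threshold, or a top-fraction
such as 20%); defaults are cap + threshold. Networks are undirected simple
graphs on the STRING 0–1000 score scale (fractional input scores are
rescaled ×1000, duplicate pairs keep the max, self-loops drop); the default
confidence threshold is 700 ("high confidence", 0.7) and presentation
filters (min-degree 2, top-5 hubs) follow the conventions of published
degree tables. Printed target counts and node degrees in the source
literature depend on database versions and are treated as format references
only.

## Synthetic data generator

The generator emulates the study-level evidence the pipeline consumes, with
known ground truth. Per product, true abundance of the rank-r pool member is
r^(−s) with Zipf exponent s = 1.2 by default — heavy-tailed dominance chosen
to match reported top-10 fractions of roughly 43–97% of mapped reads. Each
of `studies_per_product` (default 8) studies observes
`true × exp(N(0, σ²))` with σ = 0.3 (log-scale multiplicative noise) and
reports its observed top-N. Serialized tables apply naming jitter — a random
species prefix with probability 0.5, arm dropped with probability 0.1 — to
exercise the canonicalizer on realistic dialect mixes.

Planted structure: for five groups the exclusive-set sizes default to
(3, 3, 3, 6, 4), mirroring the reproduction path. Each group's exclusives
occupy true ranks 1..e of its products; the rest of the top-N window and the
deeper pool are a globally shared miRNA series, so exclusivity of the planted
sets is identifiable from top-N membership alone, and `group_exclusive` on
the ground-truth presence structure returns the planted sets exactly.
Companion generators plant a gene covered by a configured number of target
sets, a gene set strictly containing a designated query (hence minimal ORA
p), and a star hub of known degree. All randomness flows from the config's
single seed; there is no global generator state.

What the generator does *not* emulate: sequencing reads, platform-specific
biases, extracellular-vesicle packaging, or correlated errors between studies
— noise acts directly on abundances. Passing recovery tests therefore show
the aggregation statistic behaves correctly under rank noise, not that real
cross-platform biases are harmless.

## Numerical and degenerate-input choices

- Ballot positions are 1-based; position 1 = most abundant. Rank gaps are
  kept as given with a warning; duplicate miRNAs within a ballot are fatal
  with both line numbers.
- Non-contiguous tie spans are rejected; a singleton "tie" scores as a plain
  position.
- Empty aggregation scopes, empty ORA queries/universes, empty conserved
  allow-lists and inconsistent hypergeometric counts are all fatal rather
  than silently empty.
- `top_k` at a boundary tie (records k and k+1 equal on every key but name)
  reports both members and sets a flag instead of cutting arbitrarily.

## Problem sizes and observed behaviour

The recovery experiment uses 8 studies/product, pool size 30, top-10 windows
and 20 replicates; the whole test suite and the acceptance script each run in
seconds. Under those conditions the measured mean top-10 recall is ≈ 0.96,
with misses concentrated at the rank-10/11 boundary where adjacent Zipf
abundances differ by ~11%. Exact recovery of the planted exclusive sets holds
deterministically on the ground-truth presence structure; when presence is
instead derived from noisy consensus top-10 lists, planted exclusives are
retained (containment) but low-recurrence tail miRNAs occasionally enter a
single product's top-10 and appear as spurious extras — the noiseless limit
restores exact equality, and the pipeline tests assert exactly that pair of
properties.

## Known limitations

- The aggregation cannot distinguish "absent" from "unreported": a miRNA
  missing from a study's top-N may still be abundant. Scores are therefore
  evidence of documented predominance, not of abundance differences.
- Borda totals are not comparable across scopes with different study counts;
  only within-scope order is meaningful.
- The conserved filter is list-based (arm-exact); no sequence-level homology
  is computed.
- Group-exclusivity is relative to the documented evidence base — sparsely
  profiled groups (seafood, processed products) are more likely to show
  exclusives by absence of counter-evidence.
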