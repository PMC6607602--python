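# Methods

## Model and procedure

`circtargets` treats a circRNA as a miRNA sponge and asks which genes its
bound miRNA set points at repeatedly. The pipeline has four stages.

**1. Binding-site prediction.** Sites are local alignments between the
reversed miRNA (3'→5') and the target (5'→3') under a complementarity
scoring scheme: Watson–Crick pair +5, G:U wobble +1, mismatch −3, affine
gaps −9 to open (first gapped position included) and −4 per extension.
Substitution scores at miRNA positions 2–8 (the seed, 1-based from the
5' end) are multiplied by 4, anchoring alignments on seed pairing. The
fill is a three-state Gotoh dynamic program (numba-jitted); sites are
extracted greedily — best cell first, ties by smaller target start —
with each accepted site's target interval masked before rescanning, so
retained sites never overlap. A site must reach score ≥ 140 (a perfect
seed alone contributes 7 × 5 × 4 = 140). Retained sites are then
filtered by a per-column duplex-energy proxy (G:C −3, A:U −2, G:U −1,
mismatch/gap +1 kcal·mol⁻¹; keep if ≤ 1.0) and, in strict mode (the
default), by contiguous all-Watson–Crick seed pairing: no wobble, no gap
anywhere in positions 2–8. Strict mode is the strictest defensible
reading of seed-requiring scanners; the window and all constants are
configurable (`ScannerParams`). The energy model is deliberately a
monotone per-column sum, not a nearest-neighbor fold — the contract only
needs a stability cutoff, and a thermodynamic fold would add a heavy
dependency for no testable gain here. Scaling applies to substitution
scores only, not gap penalties; gaps are already excluded from the seed
in strict mode.

**2. Junction handling.** The backsplice pseudo-sequence joins the
3'-terminal k nt in front of the 5'-terminal k nt (k = 30 by default, so
any site up to 30 nt crossing the splice point is fully contained);
circRNAs shorter than k are doubled instead, which preserves every
boundary-spanning context without padding. The splice point sits at
pseudo-sequence index min(k, L). Junction hits that do not span that
index duplicate body-scan hits and are discarded; spanning hits are
calibrated to circular coordinates by `((L − min(k, L)) + pos) mod L`.
A calibrated site stores `end = start + length`, so `end > L` flags a
wrapped site while `start` always lies in [0, L). After merging body and
junction hits, same-miRNA sites overlapping on the circle are resolved
greedily by descending score (ties by smaller start), which keeps the
per-miRNA binding-site count nbs well-defined.

**3. Common targeting time.** For each gene g targeted (per the
interaction table) by at least one bound miRNA,
CT_g = Σ nbs(m) over bound miRNAs m targeting g. Interaction rows are
collapsed to unique (miRNA, gene) pairs first; miRNAs without sites
contribute nothing. Ranking is by CT descending with lexicographic
tie-breaks — the total order is deliberate so reports are byte-stable.
Comparison lists rank miRNAs by best alignment score (descending) or
best duplex energy (ascending) per miRNA and take the top
ceil(fraction × count) (default 10%); "best" rather than "mean"
aggregation was chosen because the per-miRNA summary carries the
extremes, and a ceiling guarantees a non-empty selection. Site density
is reported per kilobase.

**4. Convergence testing.** The selected gene list is tested per pathway
with the one-sided hypergeometric upper tail (scipy), adjusted across
pathways by Benjamini–Hochberg (statsmodels); a pathway is enriched at
q ≤ 0.05. The universe defaults to the union of pathway members and can
be overridden. Whether the *count* of enriched pathways is surprising is
judged against a permutation null: `n_perm` lists of the same size drawn
uniformly without replacement from the deduplicated full target-gene
pool of the bound miRNAs, with the add-one estimator
p = (1 + #{null ≥ observed}) / (n_perm + 1), which is never zero and is
exact under exchangeability. Genes outside the universe are dropped with
a warning. Every draw descends from the run seed; identical
configurations reproduce identical outputs bit for bit.

## Tunable parameters

| parameter | default | unit / range | notes |
|---|---|---|---|
| score_threshold | 140 | alignment score | perfect seed = 140 |
| energy_threshold | 1.0 | kcal/mol, keep ≤ | per-column proxy |
| strict | true | — | all-WC contiguous seed |
| seed window | 2–8 | miRNA positions | configurable |
| seed_scale | 4.0 | multiplier | substitutions only |
| flank k | 30 | nt | junction flank |
| top_n | 100 | genes | CT list size |
| fraction | 0.10 | (0, 1] | score/energy lists |
| q_threshold | 0.05 | FDR | enrichment call |
| n_perm | 1000 | draws | permutation null |

## Synthetic data: what it emulates, what it does not

The fixture generator builds the complete input set with exactly known
ground truth. miRNAs are random 20–23-mers whose seed 7-mers are
mutually non-colliding (no miRNA's site contains another's seed match,
and each site contains its own exactly once). The standard circRNA
(L = 1500) embeds exact reverse complements of 8 of 20 miRNAs at 12
non-overlapping positions — one copy split across position 0 so the seed
match straddles the backsplice point — over a background that is
rejection-resampled until no stray seed match survives; with strict
scanning this makes planted nbs and coordinates exactly recoverable,
which is what the recovery tests assert. The interaction table contains
a dense co-target block (the 5 highest-nbs miRNAs × 20 genes) over
sparse background targeting (rate 0.12 per pair, giving a target pool of
roughly 200 of 300 genes — comfortably larger than the 50-gene selected
list). The pathway collection plants a co-regulated module spanning
three overlapping 15-gene pathways inside the block; a single planted
pathway cannot demonstrate convergence, because BH at q ≤ 0.05 lets
~5% of null draws reach one enriched pathway (the FDR floor), while
null counts of three are rare.

The generator does **not** emulate genomic base composition, paralogous
repeats, expression levels, interaction-evidence reliability, or
near-miss binding sites with biologically plausible mismatch patterns.
Passing tests therefore demonstrate algorithmic correctness — exact
recovery under clean ground truth, exact score agreement with an
exhaustive alignment oracle, calibrated statistics — not predictive
accuracy on real transcripts.

A separate calibration testbed checks the permutation machinery itself:
430 mutually disjoint 12-gene pathways in a 12 000-gene universe, 30
entirely inside the sampling pool (anchoring the BH threshold) and 400
with pool membership ramping from 3 to 10 members, so half-pool draws
enrich a widely varying number of pathways. Under that design the null
enriched-count spreads over tens of values (sd ≈ 14) and the permutation
p of a null draw is near-uniform; with overlapping pathways the count
distribution is lumpy and no calibration statement is possible.

## Numerical choices and degenerate inputs

- Traceback compares stored cell values exactly; every stored value
  equals one of its candidate expressions bit-for-bit, and with
  integer-valued scoring constants all sums are exactly representable,
  so site extraction is deterministic. Precedence: diagonal, then
  target-consuming gap, then miRNA-consuming gap; gap closure beats
  extension (shortest gaps win).
- Hypergeometric p-values are evaluated once per unique
  (overlap, set-size) pair and broadcast back — numerically identical to
  elementwise evaluation and much faster for large collections.
- Sequence normalization rejects characters outside {A,C,G,U,T} (N
  included) rather than skipping them: silently losing a window that
  might carry a site is worse than a loud error.
- Input coordinates are 0-based half-open internally; reports print
  1-based inclusive.
- circRNAs shorter than the flank are doubled for the junction scan;
  miRNAs shorter than 10 nt or than the seed window are rejected.
- An empty bound-miRNA set short-circuits the pipeline: reports are
  written with headers only and enrichment is skipped with a notice, as
  is the whole enrichment stage when no gene-set file is given.

## Problem sizes used in tests

The default suite runs the scanner oracle on 100 miRNA/target pairs
(targets ≤ 60 nt), planted-site recovery on 20 fixture seeds, rotation
invariance on 10 rotations, hypergeometric exactness on every
(N ≤ 25, K, n, k), permutation calibration on 200 repetitions of
n_perm = 200, and the CT-vs-random discrimination on 20 seeds. These
sizes keep the whole suite around a minute while leaving each check
statistically meaningful.

## Known limitations

- The scanner mirrors the classic seed-anchored aligner's documented
  defaults but does not promise numeric identity with any external
  binary; an optional pass-through backend exists for users who need
  parity, and the built-in scanner is the tested one.
- The duplex-energy proxy orders duplexes sensibly but is not a free
  energy; do not compare its values against folding programs.
- CT weights all interactions equally; evidence tiers can be filtered at
  read time but are not weighted.
- The permutation null conditions on the observed target pool; it tests
  convergence beyond pool composition, not the pool itself.
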