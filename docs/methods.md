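# Methods

## Data model

A transaction is one respondent's non-empty set of endorsed reason codes
(positive integers under a codebook; the canonical study codebook has the
five wife-beating justification items coded 1–5). Respondents endorsing no
condition are excluded by the survey design, so an empty row in an input
file is an error rather than a skip, and duplicate codes within a row
collapse silently (transactions are sets). Everywhere in the package an
itemset is represented as a sorted tuple of integer codes, which makes
dictionary keys deterministic and output ordering stable.

Datasets compress losslessly into a multiset of distinct response patterns
with multiplicities. For k items there are at most 2^k − 1 patterns (31 for
the five-item module), so the compressed table is tiny regardless of sample
size, and every support is a multiplicity-weighted superset count over it.
The complete husbands' dataset (6,243 respondents) ships embedded in this
compressed form; the wives' side is not reconstructable from published
counts, so wives-style comparisons accept transcribed percentage tables,
clearly labelled as transcribed rather than recomputed.

## The miner

Minsup is supplied as a fraction (or percent) of the dataset size n and
converted to an absolute count by round-half-up: `max(1, floor(f·n + 0.5))`.
An itemset is frequent iff its support count ≥ that absolute threshold.
This convention was checked against every row of the published husbands'
ladder; e.g. at 26% the threshold is 1623 and the pair {2,5} with support
1622 is correctly excluded.

Phase 1 tallies each item's cumulative support over the compressed keys and
keeps the items meeting the threshold. Phase 2 intersects each key with the
frequent items, drops empty intersections and merges identical results by
summing multiplicities; the dropped multiplicity still counts in n for
percentage purposes. Phase 3 enumerates every non-empty subset of every
trimmed key and accumulates the key's multiplicity onto each subset.

Two deliberate choices depart from a literal reading of the original
algorithm description, which removes a subset from its accumulator the
moment it crosses the threshold (freezing its count early):

- **Exact supports.** Reported supports are always the fully accumulated
  counts — the frequent/infrequent verdict is identical either way, but the
  task is defined as frequent itemsets *with their supports*, and the full
  tallies are what the published accumulation table reports.
- **Order invariance.** Because nothing is frozen early, the result cannot
  depend on the order keys are processed in; a property test permutes the
  key order and asserts identity.

No Apriori-style candidate pruning is added beyond the trimming itself:
powersets are generated per trimmed key, which is trivial at the k ≤ 6
scales this package targets and keeps the implementation faithful to the
three-phase design. The brute-force oracle miner shares no code path with
the main miner (it re-derives even the threshold arithmetic) and enumerates
all 2^|alphabet| − 1 candidates directly over raw rows; it refuses
alphabets larger than 20 items.

## Reports

Ladder and prose percentages use floor integer percent, `(100·sup) // n`:
the published shares (4425/6243 → 70%, 3032/6243 → 48%, 2385/6243 → 38%)
are floors, not roundings (rounding would give 71% for 70.88%). The
results-file column `support_pct` keeps two decimals instead, since a file
consumer can floor but cannot un-floor. "Co-occurring" means size ≥ 2:
the disparity report defaults to min_size = 2, ladders include singletons.
In the disparity table a percentage is drawn from each population's own
supports whenever available — including an itemset only frequent on the
other side, via the retained candidate supports — otherwise the cell is
marked absent and no delta is computed. Whether the published wives-side
table used exactly this percentage convention cannot be verified without
the wives' raw data; the convention is documented here rather than assumed
verified.

## Synthetic generator

The generator emulates the qualitative structure real attitude data
exhibits: positively associated endorsements and no empty responses. Each
respondent draws a standard-normal latent factor z; item j is endorsed
independently given z with probability sigmoid(base_logit_j + scale·z);
the pattern law is obtained by integrating z with Gauss–Hermite quadrature
(probabilists' convention, default 31 nodes — exact when scale = 0 and
accurate to well below the validation tolerance otherwise) and conditioning
on at least one endorsement. Parameters:

- `k` — number of items (study value 5);
- `base_logits` — per-item endorsement propensity on the logit scale
  (0.0 ⇒ marginal probability 0.5 before conditioning);
- `propensity_scale` — strength of the shared factor, ≥ 0. The `simulate`
  default is 1.5, which at k = 5 yields pairwise correlations ≈ 0.15,
  a realistic degree of positive association for attitude items.

A caution on the correlation structure: conditioning on ≥ 1 endorsement
induces *negative* association by itself (at k = 2 with p = 0.5 and
scale = 0 the pairwise correlation is exactly −1/2), so "scale > 0 implies
positive correlation" holds only once the shared factor dominates the
conditioning — comfortably true at the study's k = 5 for scale ≳ 0.5. The
positive-correlation test therefore pins k = 5, scale = 1.5.

Because expected supports are exact sums over the 2^k patterns, sampled
datasets admit quantitative checks: the empirical support of any itemset at
n = 10,000 should fall within four binomial standard errors of its
expectation, and does in ≥ 95 of 100 seeded replicates. Sampling is inverse
CDF over the sorted pattern list from a single integer seed, so identical
inputs give byte-identical datasets across platforms.

What the generator does *not* emulate: demographic covariates (age,
residence, education), item-specific dependence beyond a single shared
factor, and missing/refused responses. Tests passing on synthetic data
therefore certify the mining machinery, not any sociological conclusion
about real populations.

## Numerical and degenerate-input choices

- Pattern-law validation tolerates |Σp − 1| ≤ 1e-9 (quadrature and
  empirical laws agree to machine precision; the slack covers accumulated
  rounding at large k).
- A parameter setting whose non-empty-pattern mass is ≤ 1e-12 (all items
  effectively impossible) is an error: there is nothing to condition on.
- The absolute threshold never falls below 1, so a tiny minsup on a tiny
  dataset still requires at least one occurrence.
- An empty dataset cannot be mined (minsup is undefined at n = 0); an empty
  *file* is, however, a valid dataset of size 0 for I/O purposes.
- Compressed keys are processed in sorted order for reproducible logs, but
  correctness is order-independent (property-tested).

## Known limitations

- The miner targets survey-scale alphabets (a handful of items); powerset
  enumeration is exponential in the size of the largest trimmed transaction
  and no sparse-data engineering is attempted.
- Two-population contrasts are descriptive percentage differences; no
  statistical test or confidence interval is attached.
- Association-rule measures (confidence, lift) are out of scope; the
  analysis is support-only.

## Problem sizes in the test suite

The equivalence battery runs the miner against the brute-force oracle on
200 random datasets (k ≤ 6, n ≤ 200, random minsup); nesting and closure
properties use 20 random datasets and seeded hypothesis cases; support
recovery uses 100 seeds × 10,000 draws. These sizes give exhaustive
coverage of the 5-item study geometry — the embedded dataset itself is
desk-scale and every published tally is reproduced exactly.
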