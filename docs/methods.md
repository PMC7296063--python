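# Methods

## Architecture extraction

A protein's domain architecture is read from HMMER3 `--domtblout` rows.
Filtering uses the per-domain independent E-value (the `i-Evalue` column):
the statistic is per hit, and filtering here is per domain hit, not per
sequence. The default cutoff is 1e-37; lowering it yields fewer, more
confident domains and therefore sparser corpora.

Hits are ordered along the protein by ascending envelope start. HMMER's
`acc` (average posterior probability of the aligned residues) is *not* a
coordinate, so it cannot order domains; we use it to resolve conflicts
instead: two hits whose envelopes intersect by more than 50% of the
shorter envelope annotate the same region, and the higher-acc hit wins
(ties: lower E-value, then file order). Overlaps at or below 50% are kept
as distinct consecutive domains, since genuine Pfam hits often abut with
slightly overlapping envelopes. The 50% threshold is a convention, not a
fitted value; results are insensitive to it except for heavily nested
annotations.

## The transition model

Architectures are flanked by `X-start`/`X-end` and adjacent ordered pairs
counted over the whole corpus (window size 2, repeats within one protein
included). One integer count table backs both conditional views — the
successor-given-predecessor (F2B) and predecessor-given-successor (B2F)
matrices — which guarantees their consistency by construction. Counts are
raw: no pseudocounts or smoothing, so a pair never observed in training
has probability exactly 0 and the simulator can never emit it. Terminator
augmentation guarantees every domain has at least one successor and one
predecessor pair, so every conditional distribution is well defined.
Conditional probabilities are computed on demand from the counts rather
than stored, because the two CA rules normalize along different axes.

## The cellular automaton

The lattice has `2m+1` cells, `m` being the largest *domain* count over
training proteins (terminators excluded); the run lasts at most `m` steps.
The occupied region is always one contiguous block around the center, so
only the two frontier cells can change per step: the right frontier draws
a successor of the current rightmost symbol, the left frontier a
predecessor of the current leftmost symbol, each by roulette-wheel
selection over the raw counts. Extension beyond a terminator is impossible
because no pair follows `X-end` or precedes `X-start` in any count table —
no extra rule is needed. Termination requires *both* terminators present;
with a terminator ancestor, that terminator counts as present from t = 0,
so growth is one-sided. At t = m, missing terminators are appended during
read-off. A consequence of the construction is that the two directions are
independent Markov walks; the test suite exploits this for an exact
brute-force oracle.

Numerical conventions: one shared `numpy` Generator per corpus; each
roulette draw consumes exactly one uniform variate; per step the left
frontier draws before the right; roulette candidates are scanned in
lexicographic symbol order. Any fixed convention is statistically
equivalent — these choices pin down bit-reproducibility for a given seed.
A simulation that would yield zero domains (possible only with a
terminator ancestor, and excluded in practice because the pair
(`X-start`, `X-end`) never occurs in training) raises an error rather than
emitting an empty protein.

## Evaluation

Hit-Acc(DAWP) compares terminator-stripped whole sequences against the set
of training architecture types; duplicates among simulated proteins each
count, duplicates in training do not. Hit-Acc(TAPD/QAPD) take all
contiguous length-3/4 windows over *terminator-augmented* sequences, so a
single-domain protein still contributes the triplet
(`X-start`, D, `X-end`) and changes at protein termini are scored; the
numerator is the simulated occurrence total of window types shared with
training. A statistic with a zero denominator (e.g. QAPD on a corpus of
only single-domain proteins) is reported as undefined (`None`/`null`),
never coerced to 0 or 100. Frequency reports sort by count with
lexicographic tie-breaks so repeated runs produce identical CSVs. The
neighbor-degree report counts, per domain, the distinct domains occurring
adjacent to it in training (terminators excluded); in real corpora this
distribution is heavy-tailed — a few hub domains have many neighbors.

## The synthetic-data generator

`synthgen` replaces the downloaded, HMMER-annotated corpora with samples
from a fully specified first-order Markov chain: a start distribution over
domains, one successor distribution per domain (over domains plus
`X-end`), and a length cap `max_len = 10`, matching the most complex
architectures seen in real Pfam-annotated family corpora. Random ground
truths draw each row's termination probability in [0.3, 0.5], i.e. a mean
architecture length of 2–3 domains — the scale real corpora show (a few
thousand domain occurrences over ~1,600 proteins averages ~2.6 domains per
protein). This keeps the length cap essentially inactive, which matters:
forced truncation at `max_len` would otherwise inflate the apparent
(domain, `X-end`) transition rates and bias parameter recovery. Remaining
row mass is spread over a random subset of about `(1 − sparsity)·(g+1)`
successors; X-end is always admissible, and any domain left unreachable
from `X-start` by sparsification receives a floor start probability so the
chain's invariants hold by construction.

What the generator does *not* emulate: domain-content correlations beyond
first order, protein-family structure, annotation noise (missed or
spurious hits beyond the synthetic decoy rows in domtblout fixtures), and
E-value-dependent corpus composition. Passing tests therefore demonstrate
correctness of the machinery — counting, simulation, scoring — under a
known generating process, not that real corpora are first-order Markov.

## Design choices where the design was open

- The printed form of the front-to-back rule is ambiguous about which of
  the two symbols conditions the draw; we read it as: the successor `G` of
  the current frontier symbol `F` is drawn with probability proportional
  to `N(F, G)`. The opposite reading would sample predecessors from the
  successor matrix and contradict the matrices' stated direction.
- The two prior matrices are kept as views of one count table; building
  them independently would invite inconsistency and doubles memory for no
  benefit.
- `m` is defined from domain counts excluding terminators; including them
  would only enlarge the lattice without changing reachable architectures.

## Problem sizes and limitations

The acceptance script uses a ground truth of 8 domain classes at sparsity
0.4, a 3,000-protein training corpus, 20,000 simulated proteins per
ancestor and 50,000 samples for parameter recovery; the property tests use
100,000 CA runs for the distribution-equivalence check. These sizes give
3σ-stable statistics for all the quantities asserted.

Known limitations: the model is strictly pair-based (no triplet
conditioning), so long-range repeat structure is reproduced only insofar
as pairs imply it; simulated corpora can contain architectures absent from
training (that is the point), but never novel *pairs*; and extraction
assumes hmmscan column orientation (model name in column 1, query in
column 4).
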