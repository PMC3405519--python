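# Methods

## The ideal-observer cohort model

The package models a listener with error-free phone recognizers and full
knowledge of a pronunciation lexicon. After segments *s₁…sₜ* the cohort
is the set of entries whose transcription begins with that prefix; the
likelihood of the heard prefix is 1 for matching words and 0 otherwise,
so Bayesian combination with prior word probabilities reduces to
frequency normalization within the cohort:

    p(wordᵢ | speech) = f(wordᵢ) / Σⱼ∈cohort f(wordⱼ)

Frequencies are occurrences per million and are taken as given; no
smoothing is applied by default (`read_lexicon` exposes an optional
frequency floor, off by default, for corpora with zero counts).
Homophones are merged before any measure is computed — entries with
identical transcriptions are collapsed and their frequencies summed,
keeping the most frequent spelling purely as a label — because the
listener's evidence is phonological. An optional monomorphemic filter
restricts the lexicon to uninflected words, the usual scope for cohort
simulations; the flag defaults to true when the input file lacks a
morphology column. If every cohort member has frequency 0 (possible only
with a floor-less corpus containing zero counts) the conditional
distribution is taken as uniform over the members.

Two measures summarize each position:

* **Lexical entropy** −Σ p log₂ p in bits. The log base is fixed at 2;
  any base rescales all entropies by a constant and preserves every
  comparison, but bits make the equal-frequency two-candidate case
  exactly 1.
* **Segment prediction error** Σᵢ |obsᵢ − p(segᵢ|speech)| over predicted
  segments, observed probabilities being 1 for the heard segment and 0
  otherwise. For a normalized prediction this equals 2·(1 − p(heard)),
  a property-tested identity.

The next-segment distribution mixes each cohort member's deterministic
continuation weighted by its conditional probability; the normalizing
denominator is the total cohort probability mass, which reproduces the
worked two-word example (0.899/0.101) exactly.

### Timing conventions

Entropy is a *state* measure, evaluated on the cohort after each segment
is heard; prediction error is a *transition* measure, evaluated on each
arriving segment against the prediction formed from the preceding
cohort. Position indices are segment counts, 1-based, and include the
end-of-word marker `#`, which is appended automatically on read. The
marker makes word offset itself predictable, so a word that is a proper
prefix of another still reaches a uniqueness point (at its offset).

### Degenerate inputs

An empty cohort is valid and absorbing: once no word matches, entropy is
0, the prediction is empty, and each further segment contributes a
prediction error of 1 (the heard segment against zero predicted mass).
This keeps baseline nonwords' post-DP profiles identical across training
days — after the deviation point no lexical knowledge distinguishes
them. Probabilities are double precision with no renormalization;
normalization is asserted to 1e-12 in tests.

### Printed-precision arithmetic

The canonical worked example reports prediction error 0.202 for hearing
/n/ after /k@ptI/: that is the summed error evaluated on the cohort
probabilities at their printed 3-decimal precision (0.101 + 0.101). The
full-precision value is 2·8/79 ≈ 0.20253. The library always computes at
full precision; the acceptance script reproduces the printed arithmetic
when reporting the worked-example value, and the tests pin both numbers.

## Experiment simulation

Each item family is a triplet: an existing **source** word, a trained
**novel** form, an untrained **baseline** nonword, sharing a prefix up
to the deviation point (DP) where all three diverge pairwise. The source
word's uniqueness point (UP) must precede the DP, and is computed against
the base lexicon and held fixed across days (it is a property of the
pre-existing lexicon). Day 1 items are assumed consolidated overnight:
the day-1 lexicon adds that triplet's novel word at its source's
frequency. Day 2 items are trained but unconsolidated, so the day-2
lexicon is the unmodified base; any episodic-memory trace of day-2
training is deliberately not modeled.

Windows are defined in segment positions, the simulation-level analogue
of the latency windows used for neural data: pre-DP = 1..DP−1,
post-DP = DP..offset (the end marker is included by default;
`include_offset=False` excludes it), UP-locked = UP..DP−1. Averaging is
window-mean within a stimulus first, then unweighted across triplets,
mirroring per-item epoching followed by grand-averaging.

The two diagnostic post-DP interactions on mean prediction error are

    lexicality_by_day = (novel − source)_day2 − (novel − source)_day1
    novelty_by_day    = (baseline − novel)_day1 − (baseline − novel)_day2

Both are strictly positive whenever the design constraints hold: on day 2
the novel form is a nonword (error 2 at the DP, 1 per segment after)
while the source predicts perfectly post-UP; on day 1 the two candidates
split the prediction, moving error onto the source and off the novel
form, while the baseline keeps its nonword penalty on both days. No
statistical test is attached to the contrasts; they are deterministic
functions of the lexicon.

## Predictive-coding segment layer

Each segment of the inventory is one channel carrying a prediction unit
(P, top-down prior = the lexical next-segment distribution), a state
unit (S, bottom-up likelihood = unit mass on the heard segment) and a
prediction-error unit (PE = |P − S| per channel). Channels are ordered
by the inventory ordering; the optional Gaussian tuning kernel blurs
each density over channel-index distance with reflecting boundaries
(scipy's reflect-mode Gaussian filter), which conserves each density's
total mass to 1e-9. Index distance is the minimal assumption — no
segment-similarity space is imposed — and width 0 (delta tuning, the
default) makes the aggregate PE series equal the segment-prediction-error
timecourse exactly, so the unit layer is a strict refinement of the
scalar measure. Units are memoryless per position: no leaky integration,
hierarchical message passing or lexical updating from PE signals is
modeled, and no scaling to measured neural amplitudes is attempted.

## Synthetic materials

The generator stands in for a licensed pronunciation database. Words are
uniform random segment strings (no phonotactics) of 4–8 segments over a
20-symbol inventory; 1000 words approximate the scale at which cohort
dynamics are nontrivial while keeping the full 50-triplet simulation
under a second. Frequencies follow a rank-frequency power law scaled to
per-million units, f(r) = 10⁶·r^(−s)/H_n(s) with exponent s = 1 (the
classical Zipf value), so the rank-1:rank-10 ratio is exactly 10^s.
Triplets place the DP 1–3 segments before the end marker (as in
*formula*/*formubo*, which diverge at the penultimate segment), require
UP < DP, and substitute DP segments used by no cohort member, which
constructively guarantees novel and baseline forms are nonwords. All
sampling flows through one seeded generator, so generation is a pure
function of the config; tail completion retries are bounded (default
1000 per word) before erroring with the violated constraint.

What the synthetic data does *not* emulate: real phonotactics, syllable
structure or stress; the segment-inventory statistics of any language;
acoustic deviation points (coarticulation makes real DPs earlier than
symbolic ones); and real corpus frequency estimation noise. Passing
tests therefore show that the measures and the learning manipulation
behave as derived under the model's assumptions, not that a particular
natural lexicon yields particular effect sizes.

## Numerical and design choices

* Normalization tolerance 1e-12; comparisons against 3-d.p. printed
  figures are made after rounding to 3 d.p.
* CLI tabular output uses 6 significant digits for stable diffs; JSON
  output keeps full precision. Lexicon files round-trip frequencies via
  `repr` so write-then-read is exact.
* Ties and ordering: dictionaries preserve insertion order; profile and
  file outputs are emitted in a fixed condition order, making equal-seed
  runs byte-identical.
* The uniqueness point of a word in a single-word lexicon is 1; the
  degenerate DP = 1 triplet is representable but rejected by validation
  (UP ≥ 1 forces DP ≥ 2).

## Problem sizes

Default study conditions (1000 words, 50 triplets) were chosen as the
package's standard demonstration scale; the full test suite and the
acceptance script each complete in a few seconds on one core. Cohort
queries are linear scans over the lexicon — simple and exactly
auditable; at 10⁵-word scale a prefix trie would be the natural upgrade
and is a known limitation, not a correctness one.
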