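# lexicohort

Ideal-observer cohort computations for incremental spoken word
recognition, and a simulation of how learning new words reshapes them.

## The problem

Hearing the beginning of a word ("formu…") activates every lexical
candidate that matches it. Two families of theory disagree about what the
brain computes over that candidate set: **lexical competition** accounts
hold that candidates inhibit one another until one wins, so neural
activity should track the *uncertainty* of the candidate distribution;
**segment prediction** accounts hold that candidates are used to predict
the upcoming speech sound, so activity should track the *prediction
error* on each arriving segment. Teaching people a made-up neighbor of an
existing word (e.g. *formubo* alongside *formula*) pushes these accounts
apart: once the new word is lexicalized it raises lexical uncertainty
before the two forms diverge, but changes prediction error most sharply
*after* the divergence. This package implements both measures, the
word-learning experiment simulation that separates them, and a
predictive-coding unit layer that realizes the prediction-error account
neuron-style.

## The model

Given a pronunciation lexicon with per-million frequencies and an
error-free segment recognizer, the cohort after hearing prefix *s₁…sₜ* is
the set of words whose transcription starts with it, with

- word probability: p(wordᵢ | speech) = f(wordᵢ) / Σⱼ f(wordⱼ) over the cohort;
- **lexical entropy**: H = −Σᵢ p(wordᵢ|speech) · log₂ p(wordᵢ|speech) (bits);
- next-segment prediction: p(seg|speech) = Σⱼ p(seg|wordⱼ) · p(wordⱼ|speech),
  where the end-of-word marker `#` counts as a predictable segment;
- **segment prediction error**: SPE = Σᵢ |obsᵢ − p(segᵢ|speech)|, with
  observed probabilities 1/0 for heard/absent segments — algebraically
  2·(1 − p(heard)) for a normalized prediction.

Landmarks: the **uniqueness point** (UP) is the first position at which a
word is the sole cohort member; the **deviation point** (DP) is the first
position at which a source word, its trained novel form and an untrained
baseline nonword diverge (design constraint: UP < DP). Day-1-trained
novel words are treated as consolidated and hence in the lexicon (at
their source word's frequency); day-2-trained items are not.

The predictive-coding layer maps each segment to a channel of prediction
(P), state (S) and prediction-error (PE) units: P carries the lexical
next-segment distribution, S the heard segment, each optionally blurred
by a Gaussian tuning kernel over channels, and PE their channel-wise
absolute difference. At tuning width 0 the aggregate PE series equals the
SPE timecourse exactly.

## Worked example

```python
from lexicohort import (LexicalEntry, merge_homophones, cohort,
                        next_segment_distribution, segment_prediction_error)
from lexicohort.lexicon import parse_transcription

lex = merge_homophones([
    LexicalEntry("captain", parse_transcription("k@ptIn"), 71.0),
    LexicalEntry("captive", parse_transcription("k@ptIv"), 8.0),
])
prefix = tuple("k@ptI")
print({e.orthography: round(p, 3) for e, p in cohort(lex, prefix).members})
# {'captain': 0.899, 'captive': 0.101}
d = next_segment_distribution(lex, prefix)
print({s: round(p, 3) for s, p in d.items()})
# {'n': 0.899, 'v': 0.101}
print(round(segment_prediction_error({s: round(p, 3) for s, p in d.items()}, "n"), 3))
# 0.202
```

After /k@ptI/ only *captain* and *captive* survive; their frequencies
(71 and 8 per million) give cohort probabilities 0.899 and 0.101, which
are also the predicted probabilities of /n/ versus /v/. Hearing /n/
leaves a summed absolute error of 0.202 (on the 3-d.p. probabilities;
2·8/79 ≈ 0.2025 at full precision).

## Pipeline

The `analysis/` scripts run the full study on synthetic materials and
write their tables to `results/`:

1. `01_worked_example.py` — the captain/captive timecourse above;
2. `02_generate_stimuli.py` — a 1000-word Zipfian lexicon and 50
   source/novel/baseline triplets (seed 12345);
3. `03_simulate_experiment.py` — six-condition window profiles; it prints
   post-DP mean prediction errors (source day1 0.413 / day2 0.000, novel
   day1 0.413 / day2 1.413, baseline 1.413 on both days), the UP-locked
   entropy elevation on day 1 only (1.000 vs 0.000 bits), and the two
   positive interactions (lexicality-by-day 1.413, novelty-by-day 1.000);
4. `04_predictive_coding.py` — P/S/PE unit activities for the
   formula/formubo/formuty family (DP-position aggregate PE: 1.0, 1.0, 2.0).

The same stages are available as a CLI: `lexicohort synth | lexicon |
measure | simulate | pc` (see `--help`); every file-writing run leaves a
manifest with its config, seed and input digests.

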