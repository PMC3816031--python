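# phonotop

Per-phoneme HMM topology optimization for small-vocabulary recognition
of disordered (dysarthric) speech — with a synthetic feature-space
corpus generator so the whole pipeline runs without access-restricted
clinical recordings.

## Why

Dysarthria — a motor speech disorder caused by cerebral palsy, head
trauma or degenerative neurological disease — affects a speaker's
phonemes unevenly: some are prolonged, some imprecisely articulated,
some substituted.  Conventional speaker-dependent recognizers give every
phoneme the same HMM architecture (typically a 3-state left-to-right
"Bakis" model).  `phonotop` instead treats each phoneme's architecture
as a free parameter and optimizes the whole assignment:

* **topology** per phoneme: Bakis-1 (self-loop + advance), Bakis-2
  (plus skip-by-two arcs), or Ergodic (fully connected);
* **emitting states** per phoneme: 3–11;
* **Gaussian mixture components** per state (one global value): 1–16.

A candidate assignment is an integer chromosome of 2·P + 1 genes (81
for the standard 40-phoneme inventory).  A micro-genetic algorithm —
population 10, seeded with the three uniform baseline systems,
roulette-wheel selection with a negative-fitness shift, gene-wise
linear crossover `c_i = α·a_i + (1−α)·b_i`, a stepped mutation schedule
β ∈ {0, 0.10, 0.30, 0.40, 0.50} with α = 1 − β, elitist replacement,
T = 30 iterations — searches the space.  Fitness of a chromosome is the
word recognition accuracy

    WAcc = 100 · (N − D − S − I) / N

of the recognizer it encodes: phone HMMs flat-started and trained by
embedded Baum-Welch on the train split, mixtures grown by binary
splitting, sentences decoded by Viterbi against a small-vocabulary
grammar ("the X is Y the Z"), hypotheses aligned to references by
minimal edit distance.  See `docs/methods.md` for the full model
description and design choices.

Because the clinical corpora this method targets are restricted, the
`simulate` module generates corpora from known ground-truth phone HMMs
with controllable dysarthria-severity knobs (phoneme prolongation,
articulatory imprecision, phone substitutions), which also makes every
stage independently testable against the generator's truth.

## Worked example

`examples/` holds one short script per capability.  Training a uniform
Bakis-1 baseline on a synthetic mild-severity speaker and scoring its
test split (`python examples/02_train_and_decode.py`) prints:

```
Test split: 10 sentences, 60 reference words
Deletions 0, substitutions 5, insertions 0
WAcc = 100*(60 - 0 - 5 - 0)/60 = 91.67%
```

i.e. the recognizer got 55 of 60 test words right; the five errors are
word substitutions, and WAcc pools error counts over the split before
applying the formula (it is *not* the mean of per-sentence accuracies,
and it can go negative when insertions dominate).  The other examples
cover corpus synthesis (`01`), the micro-GA topology search with its
convergence trace and per-phoneme assignment table (`03`), and severity
effects plus the matched-pairs significance test (`04`).

A thin CLI wraps the same library calls:

```bash
phonotop simulate --seed 3 --out data/
phonotop optimize --config run.yaml --seed 7 --out results/
phonotop experiment --config cohort.yaml --seed 1 --out report/
```

## Library layout

| module | contents |
|---|---|
| `phonotop.topology` | topology specs and transition masks |
| `phonotop.hmm` | Gaussian-mixture phone HMMs, flat start, embedded Baum-Welch, mixture splitting, sampling |
| `phonotop.decoder` | lexicon/grammar network compilation, Viterbi decoding, edit alignment, WAcc |
| `phonotop.ga` | chromosome codec, selection/crossover/mutation, the micro-GA loop |
| `phonotop.simulate` | ground-truth models, toy lexicon, severity transforms, corpora, cohorts |
| `phonotop.training` | flat-start → EM → mixture-growth pipeline |
| `phonotop.experiment` | baseline-vs-optimized harness, matched-pairs test |
| `phonotop.io` | HTK parameter files, MLF label files, lexicons, model JSON, manifests |

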