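# Methods

## Problem and model

Dysarthria affects a speaker's phonemes unevenly: some sounds are
prolonged, some are imprecisely articulated, some are substituted.  A
recognizer that forces one HMM architecture onto every phoneme (the
usual 3-state left-to-right monophone) therefore leaves accuracy on the
table.  `phonotop` models each phoneme with its own hidden Markov model
whose *architecture* — topology type, emitting-state count — is a free
parameter, and searches the joint architecture space with a
micro-genetic algorithm to maximize word recognition accuracy on a
held-out fitness set.

Three topology families are supported, all with non-emitting entry and
exit states so phone models concatenate into sentence models:

* **Bakis-1** — strict left-to-right: self-loop plus advance-by-one arcs;
  entry to the first state, exit from the last.
* **Bakis-2** — Bakis-1 plus skip-by-two arcs (state *i* → *i* + 2).  The
  classic "additional transitions" augmentation; the exact arc set is a
  design choice of this package.
* **Ergodic** — every emitting state reachable from every other; entry
  uniform over all states and exit allowed from all states.

State emissions are diagonal-covariance Gaussian mixtures, the standard
choice for cepstral features.  State counts range over 3–11 and the
global mixture count over 1–16; with topology these are the integer
genes of the optimizer's chromosome (2·P + 1 genes for P phonemes; 81
for the standard 40-phoneme inventory with silence).

## Training

Supervised ("embedded") training concatenates each sentence's phone
models — silence at the sentence boundaries — into one composite HMM
and runs Baum-Welch over it, pooling state/mixture occupancies across
sentences and across all occurrences of a phoneme.  Details:

* **Initialization** is a flat start: every state's emission gets the
  global data mean/variance and transitions are uniform over the allowed
  arcs.
* **E-step numerics** use scaled linear-space forward-backward with
  per-frame normalization of the emission densities; the transition-count
  cross terms are accumulated with a single matrix product per sentence.
  If per-frame scaling under- or overflows, the sentence falls back to a
  log-space (log-sum-exp) pass.  Both paths agree to ~1e-10 and the
  log-space path is kept as the reference implementation in the tests.
* **Guarantee**: the total data log-likelihood is non-decreasing across
  iterations (tolerance 1e-6 in tests).  Variance flooring and the
  "keep old parameters when a state receives ~0 occupancy" rule could in
  principle break monotonicity, but the floor (1e-2 × global per-dimension
  variance, absolute minimum 1e-8) rarely binds after a flat start.
* **Schedules**: 20 EM iterations by default with early stop when the
  per-frame log-likelihood gain drops below 1e-4.  Mixtures grow by
  HTK-style binary splitting — heaviest components duplicated at
  ±0.2·stddev with weights halved, doubling until the target, overshoot
  trimmed — with 5 EM iterations after each split (defaults; reduced in
  the test suite, see *Problem sizes* below).
* **Degenerate inputs**: sentences with fewer frames than the shortest
  path through their composite model have zero probability under every
  parameterization; they are skipped with a logged warning rather than
  aborting training.  Infeasibility depends only on the (fixed) topology,
  so the training objective is constant across iterations.

## Decoding and scoring

The recognizer compiles the lexicon and grammar into a network of word
instances (each a phone-HMM concatenation), with silence models at the
sentence boundaries; a sentence-template grammar fully connects
consecutive slots, a word-loop grammar adds loop-back arcs.  Viterbi
search runs over the dense state graph; on score ties the earliest word
in lexicon order wins because states are laid out in lexicon order and
`argmax` takes the first maximum.  One known ambiguity: in a word loop
containing a single-phone Ergodic word, an internal arc and the
loop-back arc can connect the same state pair; the decoder keeps the
larger of the two probabilities and attributes the arc to whichever
dominates, which can miscount a word boundary in that contrived case.
Template grammars, the primary use, are unaffected.

Hypotheses are scored against references with a unit-cost minimal edit
alignment (deletions D, substitutions S, insertions I), and

    WAcc = 100 · (N − D − S − I) / N

pooled over a corpus by summing counts before applying the formula.
WAcc can be negative when insertions dominate — which is exactly why the
optimizer's selection step shifts negative fitnesses (below).  Unit
costs are a design choice; HTK's HResults historically used weighted
costs (7/7/10), which can shift the D/S/I decomposition but rarely the
total.  A failed decode (no admissible path) scores as deletion of all
reference words so the formula stays defined per sentence.

## The micro-GA

Population X = 10 (an intentionally small, "micro" population), budget
T = 30 iterations.  The first three individuals are seeded as the three
uniform baseline systems — Bakis-1 with 3 states, Bakis-2 with 4,
Ergodic with 3, all at the baseline mixture count (6, matching the
conventional "(3, 6)" speaker-dependent baseline); the rest are random.
Because the seeds *are* the baselines, elitist replacement guarantees
the optimized system never scores below the best baseline on the
fitness set.

Per iteration, with progress w = 100·(iteration)/T evaluated at the
start of the iteration:

1. **Selection** — roulette wheel on S(x) = F_x / ΣF.  If any fitness is
   negative, |min F| is added to all first, so the most negative
   individual gets probability exactly 0.  If every shifted fitness is 0
   the distribution degenerates to uniform (a design choice for an
   all-equal population).  X draws form X/2 couples.
2. **Crossover** — gene-wise linear blend c_i = α·a_i + (1 − α)·b_i and
   the mirror image, rounded half-away-from-zero and clamped to each
   gene's domain.  Arithmetic blending is applied uniformly to all
   genes, including the categorical topology codes — a deliberate
   carry-over of the uniform integer treatment; the midpoint of Bakis-1
   and Ergodic is Bakis-2.
3. **Mutation** — β of the schedule below; Y = round(β·X) parents drawn
   without replacement each have h = round(β·m) distinct genes resampled
   to a *different* in-domain value ("changed" means actually changed).
4. **Replacement** — elitist (μ+λ): parents and all offspring pooled,
   best X kept, incumbents preferred on ties.  Best-so-far fitness is
   therefore monotone non-decreasing.

The mutation probability follows a stepped schedule: β = 0 below 10 %
progress, then 0.10 / 0.30 / 0.40 / 0.50 as progress passes
10/30/50/70 %, with α = 1 − β throughout.  The continuous curve
β(w) = 0.2·ln(w) − 0.36 (natural log — the base-10 reading does not
reproduce the printed levels) lands on the same values at the
thresholds and is exposed as `beta_formula` for documentation; the
optimizer uses the step function.  Crossover and mutation offspring are
pooled within one generation.  Classic micro-GA restart-on-convergence
is not implemented.  Fitness is cached on the gene vector: the small
population revisits chromosomes constantly, and each cache miss costs a
full train-and-decode cycle.

Fitness of a chromosome = WAcc of the recognizer it encodes, trained on
the train split and decoded on the disjoint fitness split.  A failed
build scores −100.

## Synthetic corpus generator

Real dysarthric-speech corpora of this kind are access-restricted, so
the package ships a generator that emulates their structure in feature
space (no audio): a ~40-phoneme inventory with silence, a toy lexicon
whose six-slot sentence template "the X is Y the Z" draws monosyllabic
nouns for X/Z (2–4 phones here) and bisyllabic verbs for Y (4–6
phones), sentences built by drawing X ≠ Z and Y without replacement and
then duplicating each base sentence with X and Z swapped (so every
noun and verb is pronounced twice per round), and sentence-level
train/fitness/test splits re-drawn until the train split covers the
whole phoneme inventory.  The default feature dimension 39 mirrors a
12-MFCC + energy + Δ + ΔΔ front-end; tests run at dimension 2–4 for
speed, as the algorithms are dimension-agnostic.

Ground-truth models draw per-phoneme topologies from a configurable
distribution (default 0.4/0.3/0.3 over Bakis-1/Bakis-2/Ergodic, states
uniform on 3–6, silence fixed at Bakis-1/3) with self-loop-dominant
transitions (mean state dwell ≈ 2 frames).  The `separation` knob
scales phone-mean spread relative to the ≈ unit emission standard
deviation: base means are N(0, separation²/2 · I) per dimension.
Within-phone state offsets are controlled by the *independent*
`state_spread` knob (default 1.0σ, typical of cepstral trajectories) —
deliberately decoupled from `separation` so that confusable
inventories still carry the internal temporal structure that
multi-state topologies model.  At separation 5 phones are nearly
perfectly classifiable from sampled segments; the neutral default is
2.0; the cohort experiments below use 0.5, i.e. heavily overlapping
phone classes.

Severity acts on the generating models, qualitatively mirroring
dysarthric phenomena with no claim of clinical realism:

| profile  | self-loop boost | variance × | substitution rate |
|----------|-----------------|------------|-------------------|
| mild     | 1.1             | 1.5        | 0.05              |
| moderate | 1.4             | 2.5        | 0.10              |
| severe   | 1.8             | 4.0        | 0.20              |

Crucially, impairment is *phoneme-differential* — the premise of
per-phoneme architecture optimization.  The tabulated boost/inflation
values are cohort-level averages; each phoneme draws its own
multipliers uniformly from [1, 2·value − 1], so some phones are heavily
prolonged or smeared while others stay nearly intact.  The boost
multiplies self-loop probabilities (rows renormalized) — prolonged
phonemes; variance inflation emulates imprecise articulation;
substitutions swap the generating phone for its nearest neighbour (by
state-mean distance) while the transcription keeps the *intended*
words, as the errors are acoustic.  Substitution rates sit in the range
reported for dysarthric phoneme errors, and the profiles were fixed so
that uniform-baseline recognizers on the cohort conditions score in the
~75–90 WAcc band — the operating range where topology optimization is
meaningful — rather than at ceiling.

What the generator does **not** emulate: real cepstral dynamics
(frame-to-frame correlation within a state is zero here), coarticulation
across phone boundaries, speaker-specific spectral warping, channel
effects, and genuine word-level deletions/insertions by the speaker.
Passing tests therefore show the estimation and search machinery is
correct under the model's own assumptions, not that the approach's
clinical gains transfer to any particular speaker.

## Cohorts and the comparative experiment

A cohort shares one lexicon/grammar; each synthetic speaker gets the
shared truth architectures with per-speaker mean jitter
(sd = 0.25·separation) plus its severity transform.  The default
grouping mirrors a 4 mild / 3 moderate / 3 severe ten-speaker panel.
The experiment harness trains each uniform baseline under one of three
schemes — all speakers pooled, target speaker only, or pooled within
the severity group — scores the test split, runs the micro-GA, and
reports the comparison table, per-phoneme assignment tables,
convergence traces and a matched-pairs significance test.  The
matched-pairs test is implemented as a two-sided sentence-level
sign-flip permutation test on paired error counts (exact enumeration up
to 12 pairs, 10,000 resamples above; a warning below 6 pairs), a
standard surrogate for the classic matched-pairs recognizer comparison.

## Problem sizes in the shipped tests

The test suite keeps every simulation small enough for a single CPU:
unit fixtures use 5–6 phonemes at dimension 2–3 with ~16–24 sentences;
the parameter-recovery checks use 3 phone models at dimension 2 with up
to 320 sentences; the cohort comparison experiment uses five seeded
cohorts of one speaker each at 10 phonemes (silence included),
dimension 4, separation 0.5, severe severity, 96 sentences split
29/33/34 across train/fitness/test, a 10-word lexicon, population 6,
T = 10, and training schedules of 3 EM iterations (1 after each mixture
split).  These sizes are the package's own test-scale choices; the
library defaults remain the full-scale values (population 10, T = 30,
20 EM iterations, 39-dim features).

### What the cohort comparison does and does not show

Two properties are checked on those five cohorts.  The structural
guarantee — the optimizer's fitness-set WAcc never falls below the
seeded uniform Bakis-1(3, 6) baseline — holds in 100 % of runs, by
elitism over the seeded individuals.  The transfer property — the
optimized system strictly beating that baseline on the held-out test
split in ≥ 4 of 5 cohorts — does **not** hold at this scale, and the
analysis is instructive.  Oracle probes (training the truth-matched
Bakis-1 state counts directly) gain only about 0–4 WAcc points over the
uniform baseline here, truth architectures containing Ergodic phones
lose outright (an ergodic phone model accepts almost any segment, which
makes it a liability in *discriminative* decoding even when the data
was generated ergodically), and in some seeds the oracle loses on the
fitness split while winning on test — the fitness split cannot reliably
rank architectures whose true effect is one or two words.  A
~30-evaluation micro-GA selecting on such a split therefore propagates
winner's-curse noise rather than transferable gains.  The published
full-scale setting (39-dimensional real speech, larger corpora) puts
the architecture effect well above this noise floor; reproducing the
transfer property would need corpora large enough that a ~1-word
architecture effect is resolvable — far larger than the corpora the
shipped test suite chooses to simulate.

## Known limitations

* Arithmetic crossover on the categorical topology gene treats
  Bakis-2 as "between" Bakis-1 and Ergodic; a one-point or uniform
  crossover might respect the categorical structure better.
* The decoder has no beam pruning; dense Viterbi is fine at toy scale
  but quadratic in network states.
* Mixture growth assumes a uniform component count across states (a
  single global gene), as the chromosome design dictates.
* The synthetic generator's independence assumptions (above) make the
  recognition task easier per frame than real speech at the same
  nominal separation; severity knobs compensate only qualitatively.
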