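"""Synthetic dysarthric-speech corpus generation.

Every stage of the recognizer — flat start, embedded training, decoding,
topology optimization — is exercised on corpora generated from known
ground-truth phone HMMs, emulating the structure of the small-vocabulary
nonsense-sentence corpus the method targets: a ~40-phoneme inventory
(silence included), a six-word sentence template "the X is Y the Z" with
monosyllabic-noun X/Z slots and a bisyllabic-verb Y slot, sentences built
as noun/verb draws without replacement plus X/Z-swapped counterparts, and
train / fitness / test splits that each cover the phoneme inventory.

Dysarthria severity is emulated with three knobs acting on the generating
models: a multiplicative self-loop boost (phoneme prolongation), emission
variance inflation (imprecise articulation) and a phone substitution rate
(the transcription keeps the *intended* words — errors are acoustic).
Features are synthesized directly in feature space; no audio is involved.
The default dimension of 39 matches a 12-MFCC + energy + Δ + ΔΔ
front-end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import Corpus, Sentence
from .decoder import Grammar, Lexicon, SILENCE, expand_to_phones
from .hmm import GaussianMixtureEmission, ModelSet, PhoneHMM, sample_from_models
from .topology import (
    BAKIS1,
    BAKIS2,
    ERGODIC,
    TOPOLOGY_NAMES,
    TopologySpec,
    build_transition_mask,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthSpec:
    """Ground-truth generator settings.

    ``separation`` scales the spread of phone mean vectors relative to the
    (≈ unit) emission standard deviation: base phone means are drawn
    N(0, separation²·I/2), so the expected squared distance between two
    phone means is d·separation².  ``state_spread`` independently scales
    the within-phone state-to-state mean offsets — the spectral
    trajectory a multi-state model captures; about one standard
    deviation is typical of cepstral trajectories, and it is kept
    separate from ``separation`` so confusable inventories still carry
    internal temporal structure.
    """

    n_phones: int = 40          # inventory size, silence included
    feature_dim: int = 39
    topo_probs: tuple[float, float, float] = (0.4, 0.3, 0.3)
    state_range: tuple[int, int] = (3, 6)
    n_mixtures: int = 1
    separation: float = 2.0
    state_spread: float = 1.0

    def __post_init__(self) -> None:
        if self.n_phones < 3:
            raise ValueError("need at least 3 phonemes")
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        if abs(sum(self.topo_probs) - 1.0) > 1e-9:
            raise ValueError("topology probabilities must sum to 1")

    def inventory(self) -> list[str]:
        return [SILENCE] + [f"p{i:02d}" for i in range(1, self.n_phones)]


@dataclass(frozen=True)
class SeverityProfile:
    """Knobs emulating dysarthric phenomena during synthesis.

    Dysarthria affects a speaker's phonemes at *different* levels, which
    is the premise of per-phoneme architecture optimization.  The
    multipliers here are therefore cohort-level averages: each phoneme
    draws its own dilation/inflation uniformly from [1, 2·value − 1]
    (mean = value), so some phones are heavily prolonged or smeared
    while others are nearly intact."""

    duration_dilation: float = 1.0
    variance_inflation: float = 1.0
    substitution_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_dilation < 1 or self.variance_inflation < 1:
            raise ValueError("severity multipliers must be >= 1")
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ValueError("substitution rate must lie in [0, 1]")


NEUTRAL = SeverityProfile()

#: Graded profiles: prolongation, articulatory imprecision (variance) and
#: phone-substitution rate all increase with severity; substitution rates
#: sit in the range reported for dysarthric phoneme errors.
SEVERITY_PROFILES: dict[str, SeverityProfile] = {
    "none": NEUTRAL,
    "mild": SeverityProfile(1.1, 1.5, 0.05),
    "moderate": SeverityProfile(1.4, 2.5, 0.10),
    "severe": SeverityProfile(1.8, 4.0, 0.20),
}


# ---------------------------------------------------------------------------
# ground-truth models
# ---------------------------------------------------------------------------

def _random_transitions(
    spec: TopologySpec, rng: np.random.Generator
) -> np.ndarray:
    """Plausible phone transition matrix: dominant self-loops (dwell ≈ 2
    frames), forward mass split between advance and skip arcs."""
    mask = build_transition_mask(spec)
    n = spec.n_states
    trans = np.zeros_like(mask, dtype=float)
    trans[0, mask[0]] = 1.0 / mask[0].sum()
    for i in range(1, n + 1):
        allowed = np.where(mask[i])[0]
        self_p = rng.uniform(0.4, 0.6)
        weights = np.full(len(allowed), 0.0)
        for j, tgt in enumerate(allowed):
            if tgt == i:
                weights[j] = self_p
            else:
                weights[j] = (1 - self_p) * rng.uniform(0.5, 1.5)
        others = weights.sum() - self_p
        if others > 0:
            weights[allowed != i] *= (1 - self_p) / others
        trans[i, allowed] = weights / weights.sum()
    return trans


def make_truth_models(
    spec: TruthSpec, seed: int | np.random.Generator
) -> tuple[ModelSet, pd.DataFrame]:
    """Ground-truth phone HMM bank plus its topology assignment table.

    Silence is modelled as an ordinary phoneme with a fixed Bakis-1,
    3-state architecture; the other phones draw their topology from
    ``spec.topo_probs`` and their state count uniformly from
    ``spec.state_range``.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    inventory = spec.inventory()
    d = spec.feature_dim
    hmms: dict[str, PhoneHMM] = {}
    rows = []
    for label in inventory:
        if label == SILENCE:
            tspec = TopologySpec(BAKIS1, 3)
        else:
            topo = int(rng.choice(3, p=spec.topo_probs))
            n_states = int(
                rng.integers(spec.state_range[0], spec.state_range[1], endpoint=True)
            )
            tspec = TopologySpec(topo, n_states)
        base = rng.normal(0.0, spec.separation / np.sqrt(2.0), size=d)
        emissions = []
        for _ in range(tspec.n_states):
            center = base + rng.normal(0.0, spec.state_spread, size=d)
            m = spec.n_mixtures
            means = center[None, :] + rng.normal(0.0, 0.5, size=(m, d)) * (m > 1)
            variances = rng.uniform(0.5, 1.5, size=(m, d))
            weights = (
                rng.dirichlet(np.full(m, 5.0)) if m > 1 else np.ones(1)
            )
            emissions.append(GaussianMixtureEmission(weights, means, variances))
        hmms[label] = PhoneHMM(label, tspec, _random_transitions(tspec, rng), emissions)
        rows.append(
            {
                "phoneme": label,
                "topology": TOPOLOGY_NAMES[tspec.topo_type],
                "n_states": tspec.n_states,
            }
        )
    model_set = ModelSet(hmms=hmms, feature_dim=d, variance_floor=1e-8)
    return model_set, pd.DataFrame(rows)


def apply_severity(
    model_set: ModelSet,
    severity: SeverityProfile,
    rng: np.random.Generator | None = None,
) -> ModelSet:
    """Severity-transformed copy: self-loops boosted (rows renormalized)
    and emission variances inflated.

    With an ``rng``, each phoneme draws its own multipliers uniformly
    from [1, 2·value − 1] — phoneme-differential impairment, the
    phenomenon per-phoneme topology optimization targets.  Without one,
    the profile's multipliers apply uniformly (useful for controlled
    monotonicity checks)."""
    out = model_set.copy()
    if severity == NEUTRAL:
        return out
    for hmm in out.hmms.values():
        if rng is None:
            dilation = severity.duration_dilation
            inflation = severity.variance_inflation
        else:
            dilation = float(
                rng.uniform(1.0, 2.0 * severity.duration_dilation - 1.0)
            )
            inflation = float(
                rng.uniform(1.0, 2.0 * severity.variance_inflation - 1.0)
            )
        n = hmm.n_states
        for i in range(1, n + 1):
            row = hmm.trans[i].copy()
            row[i] *= dilation
            hmm.trans[i] = row / row.sum()
        for e in hmm.emissions:
            e.variances = e.variances * inflation
    return out


def confusable_map(model_set: ModelSet) -> dict[str, str]:
    """Nearest-neighbour phone map by average state-mean distance
    (silence excluded); used for severity-driven substitutions."""
    labels = [l for l in model_set.labels if l != SILENCE]
    centers = {
        l: np.mean(
            [e.means.mean(axis=0) for e in model_set.hmms[l].emissions], axis=0
        )
        for l in labels
    }
    out = {}
    for l in labels:
        dists = {
            o: float(np.linalg.norm(centers[l] - centers[o]))
            for o in labels
            if o != l
        }
        out[l] = min(dists, key=dists.get)
    return out


# ---------------------------------------------------------------------------
# lexicon and grammar
# ---------------------------------------------------------------------------

def build_toy_lexicon(
    inventory: list[str],
    n_nouns: int = 74,
    n_verbs: int = 37,
    seed: int | np.random.Generator = 0,
) -> tuple[Lexicon, Grammar]:
    """Random small-vocabulary lexicon and its six-slot sentence template.

    Function words "the" and "is" get 2-phone pronunciations; nouns 2–4
    phones (monosyllabic), verbs 4–6 (bisyllabic).  All pronunciations are
    distinct and jointly cover the full (non-silence) phone inventory.
    """
    if n_nouns < 2 or n_verbs < 1:
        raise ValueError("need at least 2 nouns and 1 verb")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    phones = [p for p in inventory if p != SILENCE]
    if len(phones) < 2:
        raise ValueError("phone inventory too small to build distinct words")

    # draw from a coverage pool first so every phone appears in some word
    pool = list(rng.permutation(phones))

    def draw() -> str:
        if pool:
            return pool.pop()
        return str(rng.choice(phones))

    used: set[tuple[str, ...]] = set()

    def make_pron(lo: int, hi: int) -> tuple[str, ...]:
        for _ in range(500):
            length = int(rng.integers(lo, hi, endpoint=True))
            pron = tuple(draw() for _ in range(length))
            if pron not in used:
                used.add(pron)
                return pron
        raise ValueError(
            "phone inventory too small to build distinct pronunciations"
        )

    entries: dict[str, tuple[str, ...]] = {}
    entries["the"] = make_pron(2, 2)
    entries["is"] = make_pron(2, 2)
    nouns = [f"noun{i:02d}" for i in range(1, n_nouns + 1)]
    verbs = [f"verb{i:02d}" for i in range(1, n_verbs + 1)]
    for w in nouns:
        entries[w] = make_pron(2, 4)
    for w in verbs:
        entries[w] = make_pron(4, 6)

    lexicon = Lexicon(entries)
    grammar = Grammar(
        kind="sentence_template",
        slots=[["the"], nouns, ["is"], verbs, ["the"], nouns],
    )
    return lexicon, grammar


# ---------------------------------------------------------------------------
# sentence synthesis
# ---------------------------------------------------------------------------

def _sentence_plan(
    grammar: Grammar, n: int, rng: np.random.Generator
) -> list[tuple[str, ...]]:
    """Word sequences per the template scheme: X and Z drawn without
    replacement (X ≠ Z), Y without replacement, then X/Z-swapped
    counterparts; wraps with fresh draws (logged) if ``n`` exceeds one
    round's capacity."""
    nouns, verbs = grammar.slots[1], grammar.slots[3]
    capacity = 2 * min(len(nouns) // 2, len(verbs))
    if n > capacity:
        logger.warning(
            "requested %d sentences > one-round capacity %d; repeating "
            "the draw with replacement across rounds",
            n,
            capacity,
        )
    plans: list[tuple[str, ...]] = []
    while len(plans) < n:
        ns = list(rng.permutation(nouns))
        vs = list(rng.permutation(verbs))
        k = min(len(ns) // 2, len(vs))
        base = [
            ("the", ns[2 * i], "is", vs[i], "the", ns[2 * i + 1])
            for i in range(k)
        ]
        swapped = [(w[0], w[5], w[2], w[3], w[4], w[1]) for w in base]
        plans.extend(base + swapped)
    return plans[:n]


def synthesize_sentences(
    truth: ModelSet,
    lexicon: Lexicon,
    grammar: Grammar,
    n: int,
    severity: SeverityProfile = NEUTRAL,
    seed: int | np.random.Generator = 0,
    inter_word_sil: bool = False,
) -> Corpus:
    """Sample ``n`` sentences from severity-transformed truth models.

    Phone substitutions (at ``severity.substitution_rate``) swap the
    *generating* phone for its nearest confusable while the transcription
    keeps the intended words, as in dysarthric productions.
    """
    if n < 1:
        raise ValueError("need at least one sentence")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    models = apply_severity(truth, severity, rng)
    confusables = (
        confusable_map(models) if severity.substitution_rate > 0 else {}
    )
    sentences = []
    for i, words in enumerate(_sentence_plan(grammar, n, rng)):
        phones = expand_to_phones(
            words, lexicon, boundary_sil=True, inter_word_sil=inter_word_sil
        )
        generating = [
            confusables[p]
            if p != SILENCE and rng.random() < severity.substitution_rate
            else p
            for p in phones
        ]
        features, _ = sample_from_models(
            [models.hmms[p] for p in generating], rng
        )
        sentences.append(
            Sentence(
                features=features,
                words=tuple(words),
                phones=phones,
                sent_id=f"s{i + 1:04d}",
            )
        )
    return Corpus(sentences)


# ---------------------------------------------------------------------------
# splits and cohorts
# ---------------------------------------------------------------------------

def make_splits(
    corpus: Corpus,
    fractions: tuple[float, float, float] = (0.5, 0.25, 0.25),
    seed: int | np.random.Generator = 0,
    inventory: list[str] | None = None,
    max_attempts: int = 100,
) -> Corpus:
    """Random sentence-level train/fitness/test tagging, re-drawn (up to
    ``max_attempts``) until the train split covers every phoneme."""
    if abs(sum(fractions) - 1.0) > 1e-9 or len(fractions) != 3:
        raise ValueError("fractions must be three values summing to 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = len(corpus)
    required = set(inventory) if inventory else corpus.phones_present()
    n_train = int(round(fractions[0] * n))
    n_fit = int(round(fractions[1] * n))
    n_train = max(1, min(n_train, n - 2))
    n_fit = max(1, min(n_fit, n - n_train - 1))
    tags_base = (
        ["train"] * n_train
        + ["fitness"] * n_fit
        + ["test"] * (n - n_train - n_fit)
    )
    for _ in range(max_attempts):
        perm = rng.permutation(n)
        tags = [""] * n
        for pos, tag in zip(perm, tags_base):
            tags[pos] = tag
        tagged = corpus.retagged(tags)
        covered = tagged.subset("train").phones_present()
        if required <= covered:
            return tagged
    raise ValueError(
        "could not cover all phonemes in the train split; "
        "use a larger corpus or a bigger train fraction"
    )


@dataclass
class Speaker:
    name: str
    severity: str
    truth: ModelSet
    truth_table: pd.DataFrame
    corpus: Corpus


@dataclass
class Cohort:
    speakers: list[Speaker]
    lexicon: Lexicon
    grammar: Grammar
    inventory: list[str]


def make_cohort(
    n_speakers: int,
    severity_levels: list[str] | None = None,
    seed: int = 0,
    spec: TruthSpec = TruthSpec(),
    n_nouns: int = 74,
    n_verbs: int = 37,
    n_sentences: int = 74,
    fractions: tuple[float, float, float] = (0.5, 0.25, 0.25),
) -> Cohort:
    """Per-speaker corpora sharing one lexicon/grammar.

    Each speaker gets its own truth models — the shared base models with
    per-speaker mean jitter, then the severity transform — emulating a
    group of mild/moderate/severe speakers (the default level list mirrors
    a 4/3/3 mild/moderate/severe grouping, truncated or cycled to
    ``n_speakers``).
    """
    if n_speakers < 1:
        raise ValueError("need at least one speaker")
    if severity_levels is None:
        base_levels = ["mild"] * 4 + ["moderate"] * 3 + ["severe"] * 3
        severity_levels = [
            base_levels[i % len(base_levels)] for i in range(n_speakers)
        ]
    if len(severity_levels) != n_speakers:
        raise ValueError("one severity level per speaker required")
    rng = np.random.default_rng(seed)
    base_truth, _ = make_truth_models(spec, rng)
    inventory = spec.inventory()
    lexicon, grammar = build_toy_lexicon(inventory, n_nouns, n_verbs, rng)

    speakers = []
    for i, level in enumerate(severity_levels):
        truth = base_truth.copy()
        jitter_sd = 0.25 * spec.separation
        for hmm in truth.hmms.values():
            for e in hmm.emissions:
                e.means = e.means + rng.normal(
                    0.0, jitter_sd, size=e.means.shape
                )
        table = pd.DataFrame(
            {
                "phoneme": inventory,
                "topology": [
                    TOPOLOGY_NAMES[truth.hmms[p].spec.topo_type]
                    for p in inventory
                ],
                "n_states": [truth.hmms[p].spec.n_states for p in inventory],
            }
        )
        corpus = synthesize_sentences(
            truth,
            lexicon,
            grammar,
            n_sentences,
            severity=SEVERITY_PROFILES[level],
            seed=rng,
        )
        corpus = make_splits(corpus, fractions, seed=rng, inventory=inventory)
        speakers.append(
            Speaker(
                name=f"SPK{i + 1:02d}",
                severity=level,
                truth=truth,
                truth_table=table,
                corpus=corpus,
            )
        )
    return Cohort(speakers, lexicon, grammar, inventory)
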