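"""Grammar compilation, Viterbi word recognition and word-accuracy scoring.

The recognizer decodes against a small-vocabulary network: either a fixed
sentence template in the style of the nonsense phrases "the X is Y the Z"
(each slot restricted to its word class) or an unconstrained word loop.
Hypotheses are scored against the reference transcription with a
unit-cost minimal edit alignment, and word recognition accuracy is

    WAcc = 100 · (N − D − S − I) / N

with N reference words and D/S/I the deleted, substituted and inserted
words of the alignment.  WAcc can be negative when insertions dominate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus
from .hmm import EmissionStack, ModelSet, PhoneHMM

SILENCE = "sil"


# ---------------------------------------------------------------------------
# lexicon and grammar
# ---------------------------------------------------------------------------

@dataclass
class Lexicon:
    """Pronunciation dictionary: word → phoneme sequence."""

    entries: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for word, phones in self.entries.items():
            if not phones:
                raise ValueError(f"word {word!r} has an empty pronunciation")
            self.entries[word] = tuple(phones)

    def phones(self, word: str) -> tuple[str, ...]:
        try:
            return self.entries[word]
        except KeyError:
            raise KeyError(f"word {word!r} not in lexicon") from None

    @property
    def words(self) -> list[str]:
        return list(self.entries)

    def phoneme_inventory(self) -> set[str]:
        out: set[str] = set()
        for phones in self.entries.values():
            out.update(phones)
        return out


@dataclass
class Grammar:
    """Either an ordered sentence template (one word set per slot) or a
    free word loop over a vocabulary."""

    kind: str  # "sentence_template" | "word_loop"
    slots: list[list[str]] = field(default_factory=list)
    loop_words: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind == "sentence_template":
            if not self.slots or any(not s for s in self.slots):
                raise ValueError("template slots must be non-empty")
        elif self.kind == "word_loop":
            if not self.loop_words:
                raise ValueError("word loop needs a vocabulary")
        else:
            raise ValueError(f"unknown grammar kind {self.kind!r}")

    def num_word_sequences(self, length: int | None = None) -> int:
        """Count of admissible word sequences (for a word loop, of the
        given length)."""
        if self.kind == "sentence_template":
            return int(np.prod([len(s) for s in self.slots], dtype=object))
        if length is None:
            raise ValueError("word loop needs an explicit sequence length")
        return len(self.loop_words) ** length


def expand_to_phones(
    words: tuple[str, ...] | list[str],
    lexicon: Lexicon,
    boundary_sil: bool = True,
    inter_word_sil: bool = False,
) -> tuple[str, ...]:
    """Expand a word sequence into its phone sequence, with silence at the
    sentence boundaries (and optionally between words)."""
    phones: list[str] = [SILENCE] if boundary_sil else []
    for i, w in enumerate(words):
        if i > 0 and inter_word_sil:
            phones.append(SILENCE)
        phones.extend(lexicon.phones(w))
    if boundary_sil:
        phones.append(SILENCE)
    return tuple(phones)


# ---------------------------------------------------------------------------
# decoding network
# ---------------------------------------------------------------------------

@dataclass
class DecodingNetwork:
    """Symbolic recognition network: layers of word alternatives.

    ``layers`` is an ordered list of word lists; consecutive layers are
    fully connected.  Layer entries of ``None`` stand for the silence model.
    ``loop`` marks a single word layer that may repeat (word-loop grammar).
    """

    lexicon: Lexicon
    layers: list[list[str | None]]
    loop_layer: int | None = None
    grammar: Grammar | None = None

    def word_layers(self) -> list[list[str]]:
        return [
            [w for w in layer if w is not None]
            for layer in self.layers
            if any(w is not None for w in layer)
        ]


def compile_network(lexicon: Lexicon, grammar: Grammar) -> DecodingNetwork:
    """Compile lexicon + grammar into a decoding network with silence
    models at the sentence boundaries."""
    vocab = (
        [w for slot in grammar.slots for w in slot]
        if grammar.kind == "sentence_template"
        else list(grammar.loop_words)
    )
    missing = [w for w in vocab if w not in lexicon.entries]
    if missing:
        raise ValueError(
            "grammar word(s) missing from lexicon: " + ", ".join(sorted(set(missing)))
        )
    layers: list[list[str | None]] = [[None]]
    loop_layer = None
    if grammar.kind == "sentence_template":
        for slot in grammar.slots:
            layers.append(list(slot))
    else:
        layers.append(list(grammar.loop_words))
        loop_layer = 1
    layers.append([None])
    return DecodingNetwork(lexicon, layers, loop_layer, grammar)


class _StateNetwork:
    """State-level expansion of a DecodingNetwork under a ModelSet.

    Word instances (one per layer entry) are phone-HMM concatenations;
    instance exit states connect to the entry states of every instance in
    the next layer (and back to the same layer for a word loop).
    """

    def __init__(self, network: DecodingNetwork, model_set: ModelSet):
        self.network = network
        lex = network.lexicon
        # expand word instances
        inst_words: list[str | None] = []
        inst_layer: list[int] = []
        inst_chains: list[list[PhoneHMM]] = []
        for li, layer in enumerate(network.layers):
            for w in layer:
                phones = (SILENCE,) if w is None else lex.phones(w)
                try:
                    chain = [model_set.hmms[p] for p in phones]
                except KeyError as exc:
                    raise ValueError(
                        f"phoneme {exc.args[0]!r} of word {w!r} has no model"
                    ) from None
                inst_words.append(w)
                inst_layer.append(li)
                inst_chains.append(chain)
        self.inst_words = inst_words

        sizes = [sum(h.n_states for h in c) for c in inst_chains]
        offsets = np.concatenate([[0], np.cumsum(sizes)])[:-1].astype(int)
        S = int(sum(sizes))
        self.n_states = S
        self.state_instance = np.zeros(S, dtype=int)

        pi = np.zeros(S)
        A = np.zeros((S, S))
        cross = np.zeros((S, S))  # arcs that start a new word instance
        exit_p = np.zeros(S)
        entry_vecs = []
        exit_vecs = []
        emissions = []
        for ii, chain in enumerate(inst_chains):
            o = offsets[ii]
            n_tot = sizes[ii]
            self.state_instance[o : o + n_tot] = ii
            entry = np.zeros(S)
            exitv = np.zeros(S)
            pos = o
            for k, h in enumerate(chain):
                n = h.n_states
                A[pos : pos + n, pos : pos + n] = h.internal
                if k == 0:
                    entry[pos : pos + n] = h.entry_probs
                if k + 1 < len(chain):
                    nxt = chain[k + 1]
                    A[pos : pos + n, pos + n : pos + n + nxt.n_states] = (
                        np.outer(h.exit_probs, nxt.entry_probs)
                    )
                else:
                    exitv[pos : pos + n] = h.exit_probs
                emissions.extend(h.emissions)
                pos += n
            entry_vecs.append(entry)
            exit_vecs.append(exitv)

        n_layers = len(network.layers)
        layer_insts: list[list[int]] = [[] for _ in range(n_layers)]
        for ii, li in enumerate(inst_layer):
            layer_insts[li].append(ii)

        for ii in layer_insts[0]:
            pi += entry_vecs[ii]
        for li in range(n_layers):
            succ_layers = [li + 1] if li + 1 < n_layers else []
            if network.loop_layer == li:
                succ_layers.append(li)
            succ_insts = [jj for lj in succ_layers for jj in layer_insts[lj]]
            if not succ_insts:
                continue
            for ii in layer_insts[li]:
                for jj in succ_insts:
                    # exit mass split evenly over successor word instances
                    arc = np.outer(exit_vecs[ii], entry_vecs[jj])
                    arc /= len(succ_insts)
                    cross = np.maximum(cross, arc)
                    A += arc
        for ii in layer_insts[n_layers - 1]:
            exit_p += exit_vecs[ii]

        with np.errstate(divide="ignore"):
            self.log_pi = np.log(pi)
            self.log_A = np.log(A)
            self.log_exit = np.log(exit_p)
        self.is_cross = cross > 0
        self.stack = EmissionStack(emissions)

    def viterbi(self, features: np.ndarray) -> tuple[list[str], float]:
        if features.shape[0] == 0:
            raise ValueError("empty feature sequence")
        log_b, _ = self.stack.emission_log_probs(features)
        T, S = log_b.shape
        psi = np.zeros((T, S), dtype=int)
        delta = self.log_pi + log_b[0]
        for t in range(1, T):
            scores = delta[:, None] + self.log_A
            psi[t] = np.argmax(scores, axis=0)
            delta = scores[psi[t], np.arange(S)] + log_b[t]
        final = delta + self.log_exit
        best = int(np.argmax(final))
        score = float(final[best])
        if not np.isfinite(score):
            return [], -np.inf
        # backtrace
        states = np.zeros(T, dtype=int)
        states[-1] = best
        for t in range(T - 1, 0, -1):
            states[t - 1] = psi[t, states[t]]
        words: list[str] = []
        for t, s in enumerate(states):
            boundary = t == 0 or self.is_cross[states[t - 1], s]
            if boundary:
                w = self.inst_words[self.state_instance[s]]
                if w is not None:
                    words.append(w)
        return words, score


def viterbi_decode(
    model_set: ModelSet,
    network: DecodingNetwork | _StateNetwork,
    features: np.ndarray,
) -> tuple[list[str], float]:
    """Best admissible word sequence and its Viterbi path log-score.

    If no admissible path exists (sequence shorter than the minimal path
    through the network) the hypothesis is empty with score −inf.
    """
    sn = (
        network
        if isinstance(network, _StateNetwork)
        else _StateNetwork(network, model_set)
    )
    return sn.viterbi(features)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass
class AlignmentResult:
    """Counts of a minimal-cost edit alignment between reference and
    hypothesis word sequences (unit costs for D, S, I)."""

    N: int
    D: int
    S: int
    I: int
    pairs: list[tuple[str | None, str | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.N, self.D, self.S, self.I) < 0:
            raise ValueError("negative alignment count")
        if self.D + self.S > self.N:
            raise ValueError("D + S cannot exceed reference length")

    @property
    def errors(self) -> int:
        return self.D + self.S + self.I


def align_transcripts(
    ref: list[str] | tuple[str, ...], hyp: list[str] | tuple[str, ...]
) -> AlignmentResult:
    """Minimal-cost edit alignment with unit deletion/substitution/insertion
    costs.  Traceback prefers match/substitution, then deletion, then
    insertion, making the reported decomposition deterministic."""
    nr, nh = len(ref), len(hyp)
    cost = np.zeros((nr + 1, nh + 1), dtype=int)
    cost[:, 0] = np.arange(nr + 1)
    cost[0, :] = np.arange(nh + 1)
    for i in range(1, nr + 1):
        for j in range(1, nh + 1):
            sub = cost[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1])
            cost[i, j] = min(sub, cost[i - 1, j] + 1, cost[i, j - 1] + 1)
    i, j = nr, nh
    D = S = I = 0
    pairs: list[tuple[str | None, str | None]] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and cost[i, j] == cost[i - 1, j - 1] + (
            ref[i - 1] != hyp[j - 1]
        ):
            S += ref[i - 1] != hyp[j - 1]
            pairs.append((ref[i - 1], hyp[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and cost[i, j] == cost[i - 1, j] + 1:
            D += 1
            pairs.append((ref[i - 1], None))
            i -= 1
        else:
            I += 1
            pairs.append((None, hyp[j - 1]))
            j -= 1
    pairs.reverse()
    return AlignmentResult(N=nr, D=D, S=S, I=I, pairs=pairs)


def word_accuracy(a: AlignmentResult) -> float:
    """Percent word recognition accuracy, 100·(N − D − S − I)/N."""
    if a.N < 1:
        raise ValueError("word accuracy undefined for an empty reference")
    return 100.0 * (a.N - a.D - a.S - a.I) / a.N


def pooled_accuracy(alignments: list[AlignmentResult]) -> float:
    """WAcc over pooled counts (sum N, D, S, I first, then the formula);
    this is not the mean of per-sentence accuracies in general."""
    n = sum(a.N for a in alignments)
    if n < 1:
        raise ValueError("pooled reference is empty")
    return 100.0 * (n - sum(a.errors for a in alignments)) / n


def score_corpus(
    model_set: ModelSet,
    corpus: Corpus,
    network: DecodingNetwork,
) -> tuple[float, list[AlignmentResult]]:
    """Decode every sentence and pool alignment counts over the corpus.

    A failed decode (no admissible path) counts as deletion of all
    reference words.  Returns the pooled WAcc and the per-sentence
    alignments (for paired significance testing)."""
    if len(corpus) == 0:
        raise ValueError("cannot score an empty corpus")
    sn = _StateNetwork(network, model_set)
    alignments: list[AlignmentResult] = []
    for sent in corpus:
        hyp, score = sn.viterbi(sent.features)
        if not np.isfinite(score):
            alignments.append(
                AlignmentResult(N=len(sent.words), D=len(sent.words), S=0, I=0)
            )
        else:
            alignments.append(align_transcripts(list(sent.words), hyp))
    return pooled_accuracy(alignments), alignments


def corpus_accuracy(
    model_set: ModelSet, corpus: Corpus, network: DecodingNetwork
) -> float:
    """Pooled word recognition accuracy over a corpus."""
    return score_corpus(model_set, corpus, network)[0]
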