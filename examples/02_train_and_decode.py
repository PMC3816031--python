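"""Train a uniform-topology baseline recognizer and score it.

Flat-starts a 3-state Bakis-1 model bank with 2-component Gaussian
mixtures, runs embedded Baum-Welch on the train split, then decodes the
test split against the sentence-template grammar and reports word
recognition accuracy WAcc = 100·(N − D − S − I)/N.
"""

import phonotop as pt

spec = pt.TruthSpec(n_phones=8, feature_dim=4, state_range=(3, 5), separation=1.2)
truth, _ = pt.make_truth_models(spec, seed=4)
lexicon, grammar = pt.build_toy_lexicon(spec.inventory(), n_nouns=6, n_verbs=3, seed=4)
corpus = pt.synthesize_sentences(
    truth, lexicon, grammar, 40, severity=pt.SEVERITY_PROFILES["mild"], seed=5
)
corpus = pt.make_splits(corpus, (0.5, 0.25, 0.25), seed=6, inventory=spec.inventory())

assignment = pt.uniform_assignment(spec.inventory(), pt.BAKIS1, 3)
models = pt.train_recognizer(
    assignment, 2, corpus.subset("train"), spec.feature_dim,
    pt.TrainConfig(em_iters=8, split_em_iters=3),
)

network = pt.compile_network(lexicon, grammar)
wacc, alignments = pt.score_corpus(models, corpus.subset("test"), network)
n = sum(a.N for a in alignments)
d = sum(a.D for a in alignments)
s = sum(a.S for a in alignments)
i = sum(a.I for a in alignments)
print(f"Test split: {len(alignments)} sentences, {n} reference words")
print(f"Deletions {d}, substitutions {s}, insertions {i}")
print(f"WAcc = 100*({n} - {d} - {s} - {i})/{n} = {wacc:.2f}%")
# WAcc pools error counts over the whole split before applying the
# formula, so it is not the average of per-sentence accuracies.
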