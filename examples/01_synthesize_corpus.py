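"""Generate a small synthetic dysarthric-speech corpus and inspect it.

Builds ground-truth phone HMMs for a 10-phoneme inventory, a toy
"the X is Y the Z" lexicon/grammar, and samples 50 sentences at moderate
severity.  Prints the corpus composition and the truth topology table.
"""

import phonotop as pt

spec = pt.TruthSpec(
    n_phones=10, feature_dim=4, state_range=(3, 6), separation=1.5
)
truth, table = pt.make_truth_models(spec, seed=1)
lexicon, grammar = pt.build_toy_lexicon(spec.inventory(), n_nouns=6, n_verbs=3, seed=1)

corpus = pt.synthesize_sentences(
    truth, lexicon, grammar, 50,
    severity=pt.SEVERITY_PROFILES["moderate"], seed=2,
)
corpus = pt.make_splits(corpus, (0.5, 0.25, 0.25), seed=3, inventory=spec.inventory())

print("Ground-truth architectures (what the optimizer must rediscover):")
print(table.to_string(index=False))
print(f"\nLexicon: {len(lexicon.entries)} words; "
      f"grammar admits {grammar.num_word_sequences()} word sequences")
print(f"Corpus: {len(corpus)} sentences, {corpus.total_frames()} frames total")
for split in ("train", "fitness", "test"):
    sub = corpus.subset(split)
    print(f"  {split:8s} {len(sub):3d} sentences")
s = corpus.sentences[0]
print(f"\nFirst sentence: {' '.join(s.words)}")
print(f"  phones: {' '.join(s.phones)}")
print(f"  features: {s.features.shape[0]} frames x {s.features.shape[1]} dims")
# The feature matrix is what a recognizer would see after an MFCC
# front-end; the word/phone tiers are its supervised transcriptions.
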