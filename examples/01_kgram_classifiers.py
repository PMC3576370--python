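"""Train the three generative sequence classifiers on a synthetic corpus.

Builds a two-class order-1 Markov corpus, fits the multinomial bag-of-letters
model, a bag-of-3-grams model, and the order-1 chain NB(2), and scores a
held-out sequence under each.
"""

from hubseq import binary_corpus, score_sequence, train_markov, train_nb_kgram, train_nb_multinomial

dataset, spec = binary_corpus(50, 300, seed=11, concentration=0.1, min_separation=0.3)
print(f"corpus: {len(dataset)} sequences, emitter separation {spec.separation:.2f}")

query = dataset.records[0]
train = dataset.subset(range(1, len(dataset)))

for name, model in [
    ("multinomial NB ", train_nb_multinomial(train)),
    ("NB 3-gram      ", train_nb_kgram(train, 3)),
    ("NB(2) chain    ", train_markov(train, 2)),
]:
    scored = score_sequence(model, query)
    print(
        f"{name} predicts {scored.label!r} for {query.id} "
        f"(log-score margin {scored.margin:.1f})"
    )
# The margin is the log-posterior gap between the best and second class:
# larger margins mean the class-conditional composition models disagree more
# strongly about the query.
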