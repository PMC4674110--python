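"""Generate a synthetic multi-bird song corpus and inspect its structure.

Builds a small corpus with the default grammar (two stereotyped chains and
four branch points per bird), prints one rendition's label string, and
summarises the ground-truth transition probabilities for one bird.
"""

import songgaps as sg

cfg = sg.default_config(n_birds=3, renditions_per_bird=10, seed=42)
corpus, truth = sg.generate_corpus(cfg)

rend = corpus.birds[0].renditions[0]
print("one rendition of", corpus.birds[0].bird_id + ":", "".join(rend.labels))
print(f"  {len(rend.labels)} syllables, first gaps (ms):",
      [round(float(g), 1) for g in rend.gaps_ms[:5]])

bird1 = truth.transitions.query("bird_id == 'bird01' and kind == 'branch'")
print("\nground-truth branch transitions for bird01:")
print(bird1[["from_label", "to_label", "p_true", "mu_log10_gap"]]
      .to_string(index=False))
print("\np_true is the termination-excluded transition probability;"
      "\nmu_log10_gap is the expected log10 gap (ms) inside that transition —"
      "\nhigher-probability transitions get shorter expected gaps.")
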