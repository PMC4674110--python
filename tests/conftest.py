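import numpy as np
import pandas as pd
import pytest

import songgaps as sg


@pytest.fixture(scope="session")
def small_corpus():
    """A 4-bird corpus at reduced size, shared by read-only tests."""
    cfg = sg.default_config(n_birds=4, renditions_per_bird=15, seed=7)
    corpus, truth = sg.generate_corpus(cfg)
    return corpus, truth


@pytest.fixture(scope="session")
def small_analysis(small_corpus):
    corpus, _ = small_corpus
    return sg.analyze_corpus(corpus)


def events_from_sequences(sequences, gap_ms=50.0):
    """Build an events frame from {bird: [label strings]} with constant gaps."""
    rows = []
    for bird, rends in sequences.items():
        for j, labels in enumerate(rends):
            n = len(labels)
            for i, lab in enumerate(labels):
                rows.append(
                    {
                        "bird_id": bird,
                        "condition": "A",
                        "rendition_id": f"r{j:04d}",
                        "position": i,
                        "label": lab,
                        "next_label": labels[i + 1] if i < n - 1 else None,
                        "gap_to_next_ms": gap_ms if i < n - 1 else np.nan,
                    }
                )
    return pd.DataFrame(rows)
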