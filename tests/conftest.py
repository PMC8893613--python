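import numpy as np
import pytest

from almostsig.corpus_io import ArticleRecord
from almostsig.phrase_match import PhraseDictionary


@pytest.fixture
def nested_dict():
    """Dictionary with nested phrases to exercise subsumption."""
    return PhraseDictionary(
        (
            "marginally significant",
            "only marginally significant",
            "a strong trend",
            "a nonsignificant trend",
            "failed to reach statistical significance",
        )
    )


def brute_force_hits(text: str, phrases) -> list[tuple[int, int, str]]:
    """Independent O(len(text) * len(phrases)) scan: check every offset."""
    out = []
    for phrase in phrases:
        k = len(phrase)
        for i in range(len(text) - k + 1):
            if text[i : i + k] == phrase:
                out.append((i, i + k, phrase))
    return sorted(out)


def make_random_corpus(rng: np.random.Generator, n_docs: int, phrases, year=2000):
    """Documents of random words salted with random phrase insertions."""
    vocab = ["alpha", "beta", "gamma", "delta", "sig", "trend", "marginally",
             "significant", "a", "strong", "only", "statistical", "reach"]
    records = []
    for i in range(n_docs):
        words = list(rng.choice(vocab, size=int(rng.integers(5, 40))))
        for phrase in phrases:
            if rng.random() < 0.3:
                pos = int(rng.integers(0, len(words) + 1))
                words.insert(pos, phrase)
        records.append(
            ArticleRecord(id=f"doc{i}", pub_year=year, text_raw=" ".join(words))
        )
    return records
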