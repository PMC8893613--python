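import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from almostsig.corpus_io import ArticleRecord
from almostsig.phrase_match import PhraseDictionary, scan_corpus
from almostsig.pvalue_extract import (
    categorize,
    extract_mentions,
    extract_window,
    format_pvalue,
    parse_pvalue,
    summarize_pvalues,
)
from almostsig.phrase_match import PhraseHit


def hit(end, doc_id="d", phrase="q"):
    return PhraseHit(doc_id, phrase, end - len(phrase), end)


class TestExtractWindow:
    def test_truncated_at_document_end(self):
        text = "x" * 50
        assert len(extract_window(text, hit(10), width=100)) == 40

    def test_empty_when_phrase_ends_document(self):
        text = "x" * 10
        assert extract_window(text, hit(10), width=100) == ""

    def test_full_width_when_available(self):
        text = "x" * 500
        assert len(extract_window(text, hit(10), width=100)) == 100


class TestParsePValue:
    @pytest.mark.parametrize(
        "window,value,comparator",
        [
            ("lower in group b (p = 0.052)", 0.052, "="),
            ("a trend (p < .06) was seen", 0.06, "<"),
            ("risk ratio 1.3, p = 1.2 × 10-3", 0.0012, "="),
            ("effect (p=0.07)", 0.07, "="),
            ("p ≤ 0.1 overall", 0.1, "<="),
            ("p >= 0.9 for interaction", 0.9, ">="),
            ("p-value = 0.061", 0.061, "="),
            ("p values < 0.10", 0.10, "<"),
            ("signal at p = 3e-4 here", 0.0003, "="),
            ("p = 1.5 x 10^-2", 0.015, "="),
        ],
    )
    def test_grammar(self, window, value, comparator):
        got = parse_pvalue(window)
        assert got is not None
        assert got[0] == pytest.approx(value)
        assert got[1] == comparator

    @pytest.mark.parametrize(
        "window",
        [
            "no p here at all",
            "group a vs group b",
            "bp = 0.03 mmhg",  # "p" embedded in a word is not a P value
            "p = 12.3",  # > 1: a ratio, not a probability
        ],
    )
    def test_rejections(self, window):
        assert parse_pvalue(window) is None

    def test_scan_continues_past_rejected_token(self):
        got = parse_pvalue("power p = 85 but also p = 0.06 later")
        assert got is not None and got[0] == 0.06

    def test_first_token_wins(self):
        got = parse_pvalue("first p = 0.08 then p = 0.001")
        assert got[0] == 0.08

    def test_distance_is_token_offset(self):
        window = "lower in group b (p = 0.052)"
        assert parse_pvalue(window)[3] == window.index("(p")


class TestCategorize:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.049, "below"),
            (0.05, "mid"),  # boundaries belong to the mid band
            (0.052, "mid"),
            (0.15, "mid"),
            (0.151, "above"),
            (0.0, "below"),
            (1.0, "above"),
        ],
    )
    def test_boundaries(self, value, expected):
        assert categorize(value) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize(1.5)


class TestSummarize:
    def test_median_and_proportions(self):
        import pandas as pd

        mentions = pd.DataFrame(
            {
                "value": [0.01, 0.06, 0.06, 0.2],
                "category": ["below", "mid", "mid", "above"],
            }
        )
        s = summarize_pvalues(mentions, n_windows=8)
        assert s["n"] == 4
        assert s["extraction_rate"] == 0.5
        assert s["median"] == 0.06
        props = {c: s["categories"][c]["proportion"] for c in ("below", "mid", "above")}
        assert props == {"below": 0.25, "mid": 0.5, "above": 0.25}
        assert sum(props.values()) == pytest.approx(1.0)

    def test_simple_median(self):
        import pandas as pd

        mentions = pd.DataFrame(
            {"value": [0.05, 0.06, 0.07], "category": ["mid"] * 3}
        )
        assert summarize_pvalues(mentions)["median"] == 0.06

    def test_empty_input_flagged(self):
        import pandas as pd

        s = summarize_pvalues(pd.DataFrame(columns=["value", "category"]))
        assert s["n"] == 0
        assert np.isnan(s["median"])

    def test_proportions_invariant_to_permutation(self):
        import pandas as pd

        rng = np.random.default_rng(3)
        values = rng.uniform(0.0, 0.3, 50)
        cats = [categorize(v) for v in values]
        frame = pd.DataFrame({"value": values, "category": cats})
        s1 = summarize_pvalues(frame)
        s2 = summarize_pvalues(frame.sample(frac=1.0, random_state=0))
        assert s1["categories"] == s2["categories"]
        assert s1["quantiles"] == s2["quantiles"]


class TestRoundTrip:
    @given(
        value=st.floats(min_value=1e-4, max_value=1.0, allow_nan=False),
        comparator=st.sampled_from(["=", "<", ">", "<=", ">="]),
        style=st.sampled_from(["paren", "bare", "naked_decimal", "sci"]),
        decimals=st.integers(min_value=2, max_value=4),
    )
    @settings(max_examples=500, deadline=None, derandomize=True)
    def test_format_then_parse_recovers_printed_value(
        self, value, comparator, style, decimals
    ):
        token = format_pvalue(value, comparator, decimals=decimals, style=style)
        if style == "sci":
            exp = int(np.floor(np.log10(value)))
            expected = round(value / 10.0**exp, decimals) * 10.0**exp
        else:
            expected = round(value, decimals)
        if expected > 1.0:  # mantissa rounding may push just past the cap
            return
        got = parse_pvalue(token)
        assert got is not None
        assert got[0] == pytest.approx(expected, rel=1e-9, abs=1e-12)
        assert got[1] == comparator


def test_extract_mentions_end_to_end():
    d = PhraseDictionary(("almost significant",))
    records = [
        ArticleRecord("a", 2000, "it was almost significant (p = 0.052) overall"),
        ArticleRecord("b", 2000, "almost significant but no value given"),
    ]
    hits, _ = scan_corpus(records, d)
    mentions = extract_mentions(records, hits)
    assert len(mentions) == 1
    row = mentions.iloc[0]
    assert row["article_id"] == "a"
    assert row["value"] == 0.052
    assert row["category"] == "mid"
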