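import math

import numpy as np
import pandas as pd
import pytest

from almostsig.prevalence_stats import (
    Z_95,
    assign_bin,
    bin_by_period,
    prevalence_table,
    proportion_ci,
)


def cc_wilson_reference(x, n, z=Z_95):
    """Independent transcription of Newcombe's continuity-corrected Wilson
    score formulas, evaluated in extended precision."""
    L = np.longdouble
    x, n, z = L(x), L(n), L(z)
    p = x / n
    q = 1 - p
    lo = (
        (2 * n * p + z * z - 1 - z * np.sqrt(z * z - 2 - 1 / n + 4 * p * (n * q + 1)))
        / (2 * (n + z * z))
    )
    hi = (
        (2 * n * p + z * z + 1 + z * np.sqrt(z * z + 2 - 1 / n + 4 * p * (n * q - 1)))
        / (2 * (n + z * z))
    )
    return float(max(lo, 0)), float(min(hi, 1))


class TestProportionCI:
    def test_study_scale_counts(self):
        p, lo, hi = proportion_ci(49134, 567758)
        assert (round(p, 4), round(lo, 4), round(hi, 4)) == (0.0865, 0.0858, 0.0873)

    def test_boundary_clipping(self):
        _, lo, _ = proportion_ci(0, 100)
        assert lo == 0.0
        _, _, hi = proportion_ci(100, 100)
        assert hi == 1.0

    def test_matches_independent_transcription_on_grid(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(1, 10**6))
            x = int(rng.integers(0, n + 1))
            _, lo, hi = proportion_ci(x, n)
            ref_lo, ref_hi = cc_wilson_reference(x, n)
            if x > 0:
                assert lo == pytest.approx(ref_lo, rel=1e-10)
            if x < n:
                assert hi == pytest.approx(ref_hi, rel=1e-10)

    def test_width_monotone_decreasing_in_n(self):
        widths = []
        for n in (100, 1_000, 10_000, 100_000):
            x = round(n * 0.0865)
            _, lo, hi = proportion_ci(x, n)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_ci(1, 0)
        with pytest.raises(ValueError):
            proportion_ci(5, 3)


class TestBinning:
    @pytest.mark.parametrize(
        "year,width,expected",
        [(1990, 3, 1990), (1992, 3, 1990), (1993, 3, 1993), (2019, 3, 2017),
         (2020, 3, 2020), (1990, 1, 1990), (2005, 1, 2005)],
    )
    def test_assign_bin(self, year, width, expected):
        assert assign_bin(year, width) == expected

    def _summary(self, years, positives=None):
        positives = positives or [False] * len(years)
        return pd.DataFrame(
            {
                "article_id": [f"d{i}" for i in range(len(years))],
                "pub_year": years,
                "phrase_positive": positives,
            }
        )

    def test_partition_conserves_counts(self):
        rng = np.random.default_rng(5)
        years = rng.integers(1990, 2021, size=500).tolist()
        for width in (1, 3):
            binned = bin_by_period(self._summary(years), width)
            assert int(binned["n_total"].sum()) == 500

    def test_yearly_bins_cover_window(self):
        years = list(range(1990, 2021))
        binned = bin_by_period(self._summary(years), 1)
        assert len(binned) == 31

    def test_three_year_bins_anchor_at_1990_with_partial_2020(self):
        years = list(range(1990, 2021))
        binned = bin_by_period(self._summary(years), 3)
        starts = binned["bin_start_year"].tolist()
        assert starts == list(range(1990, 2018, 3)) + [2020]
        assert binned.loc[binned["bin_start_year"] == 2020, "n_total"].item() == 1

    def test_out_of_window_year_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            bin_by_period(self._summary([1989]), 1)


class TestPrevalenceTable:
    def test_single_year_prevalence(self):
        summary = pd.DataFrame(
            {
                "article_id": [f"d{i}" for i in range(200)],
                "pub_year": [2005] * 200,
                "phrase_positive": [i < 20 for i in range(200)],
            }
        )
        hits = pd.DataFrame(columns=["article_id", "phrase", "start", "end", "subsumed_by"])
        table = prevalence_table(summary, hits)
        row = table[table["scope"] == "overall"].iloc[0]
        assert row["prevalence"] == pytest.approx(0.10)
        assert row["ci_low"] < 0.10 < row["ci_high"]

    def test_absent_phrase_all_zero(self):
        summary = pd.DataFrame(
            {
                "article_id": ["a", "b"],
                "pub_year": [2000, 2001],
                "phrase_positive": [False, False],
            }
        )
        hits = pd.DataFrame(columns=["article_id", "phrase", "start", "end", "subsumed_by"])
        table = prevalence_table(summary, hits, phrases=["a strong trend"])
        ph = table[table["scope"] == "phrase"]
        assert (ph["n_positive"] == 0).all()
        assert (ph["prevalence"] == 0.0).all()

    def test_overall_prevalence_matches_direct_fraction(self):
        rng = np.random.default_rng(9)
        n = 300
        summary = pd.DataFrame(
            {
                "article_id": [f"d{i}" for i in range(n)],
                "pub_year": rng.integers(1990, 2020, size=n),
                "phrase_positive": rng.random(n) < 0.0865,
            }
        )
        hits = pd.DataFrame(columns=["article_id", "phrase", "start", "end", "subsumed_by"])
        table = prevalence_table(summary, hits)
        overall = table[table["scope"] == "overall"]
        pooled = (overall["n_positive"].sum(), overall["n_total"].sum())
        assert pooled == (
            int(summary["phrase_positive"].sum()),
            n,
        )

    def test_yearly_estimates_track_constant_rate(self):
        # constant-rate simulation: each yearly estimate within 3 binomial SDs
        rng = np.random.default_rng(17)
        p_true, docs_per_year = 0.0865, 2000
        rows = []
        for year in range(1990, 2000):
            flags = rng.random(docs_per_year) < p_true
            rows += [
                {"article_id": f"{year}-{i}", "pub_year": year, "phrase_positive": bool(f)}
                for i, f in enumerate(flags)
            ]
        summary = pd.DataFrame(rows)
        hits = pd.DataFrame(columns=["article_id", "phrase", "start", "end", "subsumed_by"])
        table = prevalence_table(summary, hits)
        sd = math.sqrt(p_true * (1 - p_true) / docs_per_year)
        overall = table[table["scope"] == "overall"]
        assert ((overall["prevalence"] - p_true).abs() <= 3 * sd).all()
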