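"""Seeded synthetic corpora with the statistical structure the pipeline assumes.

Each document is filler prose (from a screened vocabulary that can never
form a dictionary phrase) into which target phrases are injected:

* phrase occurrence is Bernoulli per document with a logit-linear time
  trend: P(phrase | year t) = logistic(logit(π₀) + β (t − midpoint year));
* with probability ``q`` (default 0.41, the observed direct-referral rate)
  an injected phrase is followed, within the 100-character window, by a
  formatted P-value token;
* P values are drawn from a three-component mixture over the below / mid /
  above bands (default weights 0.25 / 0.68 / 0.07) whose shapes reproduce
  the observed quantile structure: median ≈ 0.06, quartiles ≈ [0.05, 0.08],
  5–95% interval ≈ [0.006, ~0.15].

Every insertion is recorded in a :class:`GroundTruth` table so recovery of
prevalences, trends and extraction rates can be checked exactly. Identical
seeds give byte-identical corpora.

A count-level view of the same occurrence model,
:func:`simulate_bin_counts`, draws per-bin binomial positives directly —
useful for large simulation studies where document text is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus_io import ArticleRecord
from .phrase_match import PhraseDictionary
from .pvalue_extract import format_pvalue

__all__ = [
    "PhraseSpec",
    "SyntheticConfig",
    "GroundTruth",
    "generate",
    "simulate_bin_counts",
    "ground_truth_report",
    "DEFAULT_P_WEIGHTS",
    "sample_pvalues",
]

#: below / mid / above mixture weights emulating the observed band shares
DEFAULT_P_WEIGHTS = (0.25, 0.68, 0.07)

# Band supports and Beta shapes. The mid band is a Beta scaled onto
# [0.05, 0.15] with CDF 0.368 at 0.06 and 0.735 at 0.08, which under the
# default weights puts the overall median at 0.06 and the 75th percentile
# at 0.08; the below band is skewed toward small values so the overall 5th
# percentile lands near 0.006.
_BAND_PARAMS = {
    "below": (0.001, 0.049, 0.705, 1.0),  # lo, span, alpha, beta
    "mid": (0.05, 0.10, 0.8038, 3.0592),
    "above": (0.15, 0.35, 0.8, 3.0),
}

# Filler vocabulary: common methods-section words chosen to share no word
# with any shipped dictionary phrase (so no phrase can arise by accident);
# the disjointness is re-checked at config validation, not assumed.
_FILLER_VOCAB = (
    "patients cohort enrolled baseline randomization allocation outcome "
    "outcomes measured followup visit week month dosage placebo intervention "
    "therapy treatment arm group mean median deviation interval analysis "
    "protocol criteria inclusion exclusion adverse events blinded assessor "
    "questionnaire score scale primary secondary endpoint hospital center "
    "recruitment consent ethics committee approved sample size power "
    "calculated using model adjusted covariates age sex duration severity "
    "reduction improvement change compared versus control received daily"
).split()


@dataclass(frozen=True)
class PhraseSpec:
    """One injected phrase: baseline prevalence at the midpoint year and a
    per-year log-odds slope."""

    phrase: str
    baseline_prevalence: float
    logodds_slope_per_year: float = 0.0

    def occurrence_prob(self, year: float, midpoint: float) -> float:
        logit0 = np.log(self.baseline_prevalence / (1.0 - self.baseline_prevalence))
        z = logit0 + self.logodds_slope_per_year * (year - midpoint)
        return float(1.0 / (1.0 + np.exp(-z)))


@dataclass(frozen=True)
class SyntheticConfig:
    year_start: int = 1990
    year_end: int = 2019
    docs_per_year: int = 200
    phrase_specs: tuple[PhraseSpec, ...] = ()
    direct_referral_prob: float = 0.41
    p_weights: tuple[float, float, float] = DEFAULT_P_WEIGHTS
    filler_words_per_doc: int = 60
    seed: int = 0
    screen_dictionary: PhraseDictionary | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.direct_referral_prob <= 1.0:
            raise ValueError("direct_referral_prob must be in [0, 1]")
        if abs(sum(self.p_weights) - 1.0) > 1e-9:
            raise ValueError("p_weights must sum to 1")
        if self.docs_per_year < 1:
            raise ValueError("docs_per_year must be >= 1")
        for spec in self.phrase_specs:
            if not 0.0 < spec.baseline_prevalence < 1.0:
                raise ValueError(f"baseline prevalence out of (0,1): {spec}")
        self._screen_filler()

    def _screen_filler(self) -> None:
        """Reject configs whose filler vocabulary could fabricate a phrase hit."""
        phrases = [s.phrase for s in self.phrase_specs]
        if self.screen_dictionary is not None:
            phrases = list(self.screen_dictionary.phrases) + phrases
        filler_set = set(_FILLER_VOCAB)
        for phrase in phrases:
            if set(phrase.split()) & filler_set:
                raise ValueError(
                    f"phrase {phrase!r} shares words with the filler vocabulary"
                )
        # belt and braces: scan one long filler-only text for any phrase
        probe = " ".join(_FILLER_VOCAB * 3)
        for phrase in phrases:
            if phrase in probe:
                raise ValueError(f"filler text can contain phrase {phrase!r}")

    @property
    def midpoint_year(self) -> float:
        return (self.year_start + self.year_end) / 2.0

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)


@dataclass
class GroundTruth:
    """What was actually inserted, and the generating probabilities."""

    insertions: pd.DataFrame  # article_id, year, phrase, p_inserted, p_value
    occurrence_probs: pd.DataFrame  # phrase, year, true_prob
    config: SyntheticConfig


def sample_pvalues(rng: np.random.Generator, n: int, weights=DEFAULT_P_WEIGHTS) -> tuple[np.ndarray, np.ndarray]:
    """Draw n P values from the band mixture; returns (values, band labels)."""
    bands = np.array(["below", "mid", "above"])
    idx = rng.choice(3, size=n, p=list(weights))
    values = np.empty(n)
    for k, band in enumerate(bands):
        lo, span, a, b = _BAND_PARAMS[band]
        m = int((idx == k).sum())
        values[idx == k] = lo + span * rng.beta(a, b, m)
    return values, bands[idx]


def _filler(rng: np.random.Generator, n_words: int) -> str:
    return " ".join(rng.choice(_FILLER_VOCAB, size=n_words))


def generate(config: SyntheticConfig) -> tuple[list[ArticleRecord], GroundTruth]:
    """Generate a corpus of article records plus its ground-truth table.

    Each phrase spec is inserted at most once per document. When a P token
    accompanies an insertion it is placed a few filler words after the
    phrase, always inside the 100-character extraction window. The text is
    emitted already lowercase so it is a fixed point of normalization.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ArticleRecord] = []
    ins_rows: list[dict] = []
    mid = config.midpoint_year

    probs = {
        spec.phrase: {y: spec.occurrence_prob(y, mid) for y in config.years}
        for spec in config.phrase_specs
    }

    for year in config.years:
        for j in range(config.docs_per_year):
            doc_id = f"syn-{year}-{j:05d}"
            chunks = [_filler(rng, 8)]
            for spec in config.phrase_specs:
                if rng.random() >= probs[spec.phrase][year]:
                    continue
                chunks.append(spec.phrase)
                p_inserted = rng.random() < config.direct_referral_prob
                p_value = np.nan
                if p_inserted:
                    value, _ = sample_pvalues(rng, 1, config.p_weights)
                    p_value = round(float(value[0]), 4)
                    gap = _filler(rng, int(rng.integers(1, 5)))
                    chunks.append(f"{gap} {format_pvalue(p_value, '=', 4)}")
                chunks.append(_filler(rng, int(rng.integers(4, 10))))
                ins_rows.append(
                    {
                        "article_id": doc_id,
                        "year": year,
                        "phrase": spec.phrase,
                        "p_inserted": p_inserted,
                        "p_value": p_value,
                    }
                )
            chunks.append(_filler(rng, max(config.filler_words_per_doc - 12, 4)))
            text = " ".join(chunks)
            records.append(ArticleRecord(id=doc_id, pub_year=year, text_raw=text))

    insertions = pd.DataFrame(
        ins_rows, columns=["article_id", "year", "phrase", "p_inserted", "p_value"]
    )
    occ = pd.DataFrame(
        [
            {"phrase": ph, "year": y, "true_prob": p}
            for ph, by_year in probs.items()
            for y, p in by_year.items()
        ],
        columns=["phrase", "year", "true_prob"],
    )
    return records, GroundTruth(insertions, occ, config)


def simulate_bin_counts(
    spec: PhraseSpec,
    years: range,
    docs_per_bin: int,
    bin_width: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-bin binomial draws from the same occurrence model as ``generate``.

    The bin probability is the mean of the yearly occurrence probabilities
    in the bin. Returns the per-phrase prevalence-table schema so the
    result feeds directly into trend fitting.
    """
    mid = (years.start + years.stop - 1) / 2.0
    rows = []
    for bin_start in range(years.start, years.stop, bin_width):
        bin_years = [y for y in range(bin_start, bin_start + bin_width) if y in years]
        p = float(np.mean([spec.occurrence_prob(y, mid) for y in bin_years]))
        k = int(rng.binomial(docs_per_bin, p))
        rows.append(
            {
                "phrase": spec.phrase,
                "bin_start_year": bin_start,
                "bin_width_years": bin_width,
                "n_total": docs_per_bin,
                "n_positive": k,
                "prevalence": k / docs_per_bin,
                "true_prob": p,
            }
        )
    return pd.DataFrame(rows)


def ground_truth_report(gt: GroundTruth, bin_width: int = 3) -> pd.DataFrame:
    """True per-phrase occurrence probabilities binned like the estimates.

    Returns columns ``phrase, bin_start_year, bin_width_years, true_prob,
    logodds_slope_per_year`` for side-by-side comparison with fitted
    trend results.
    """
    slopes = {s.phrase: s.logodds_slope_per_year for s in gt.config.phrase_specs}
    occ = gt.occurrence_probs.copy()
    occ["bin_start_year"] = gt.config.year_start + (
        (occ["year"] - gt.config.year_start) // bin_width
    ) * bin_width
    out = (
        occ.groupby(["phrase", "bin_start_year"])["true_prob"]
        .mean()
        .reset_index()
        .sort_values(["phrase", "bin_start_year"], kind="mergesort")
        .reset_index(drop=True)
    )
    out["bin_width_years"] = bin_width
    out["logodds_slope_per_year"] = out["phrase"].map(slopes)
    return out
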