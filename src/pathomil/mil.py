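"""Multi-instance aggregation of patch likelihoods into slide features.

Two complementary encodings turn a slide's bag of patch-level survival
likelihoods into a fixed-length vector:

* **PALHI** (patch likelihood histogram): the empirical distribution of
  likelihoods over 101 bins centered at 0.00, 0.01, ..., 1.00, plus the
  fractions of patches predicted class 0 / class 1 — 103 features.
* **BoW**: the same 101 bins act as vocabulary words; a slide is a
  document whose term frequencies are weighted by smoothed inverse
  document frequency, ``idf = ln((1+N)/(1+df)) + 1``, and L2-normalized;
  plus a one-hot majority-vote label pair — 103 features.

Early fusion concatenates both into the 206-dimensional slide vector.
Published signature formulas use slightly different feature spellings
(e.g. ``HistogramBoWProb_0.15``, ``BoWProb_008``); :func:`resolve_alias`
maps those onto the canonical names.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SlideLikelihoods

__all__ = [
    "N_BINS",
    "BIN_CENTERS",
    "PALHI_NAMES",
    "BOW_NAMES",
    "FUSED_NAMES",
    "BoWVocabulary",
    "palhi_encode",
    "fit_bow_vocabulary",
    "bow_encode",
    "fuse",
    "resolve_alias",
    "encode_cohort",
]

N_BINS = 101
#: Bin centers 0.00 .. 1.00; bin i covers [c-0.005, c+0.005), last closed.
BIN_CENTERS = np.round(np.arange(N_BINS) / 100.0, 2)

PALHI_NAMES = [f"HistogramProb_{c:.2f}" for c in BIN_CENTERS] + ["HistFracPred_0", "HistFracPred_1"]
BOW_NAMES = [f"BoWProb_{c:.2f}" for c in BIN_CENTERS] + ["BoWPred_0", "BoWPred_1"]
FUSED_NAMES = PALHI_NAMES + BOW_NAMES

# Published formulas strip trailing zeros and the decimal point from some
# feature names; this table records the canonical reading of each spelling.
_EXPLICIT_ALIASES = {
    "BoWProb_008": "BoWProb_0.08",
    "BoWProb_06": "BoWProb_0.60",
    "BoWProb_063": "BoWProb_0.63",
    "BoWProb_068": "BoWProb_0.68",
}


def resolve_alias(name: str) -> str:
    """Map a published feature spelling onto its canonical name."""
    if name in FUSED_NAMES:
        return name
    if name.startswith("HistogramBoWProb_"):
        return resolve_alias("HistogramProb_" + name.split("_", 1)[1])
    if name in _EXPLICIT_ALIASES:
        return _EXPLICIT_ALIASES[name]
    m = re.fullmatch(r"(HistogramProb|BoWProb)_0(\d+)", name)
    if m:  # digit-run spelling: 0DD... -> 0.DD
        cand = f"{m.group(1)}_{float('0.' + m.group(2)):.2f}"
        if cand in FUSED_NAMES:
            return cand
    m = re.fullmatch(r"(HistogramProb|BoWProb)_([01](?:\.\d+)?)", name)
    if m:  # trailing-zero-stripped decimal: 0.6 -> 0.60
        cand = f"{m.group(1)}_{float(m.group(2)):.2f}"
        if cand in FUSED_NAMES:
            return cand
    raise KeyError(f"unknown feature name: {name!r}")


def _bin_indices(probs: np.ndarray) -> np.ndarray:
    return np.clip(np.floor(probs * 100.0 + 0.5), 0, 100).astype(int)


def _bin_counts(bag: SlideLikelihoods) -> np.ndarray:
    return np.bincount(_bin_indices(bag.probabilities), minlength=N_BINS).astype(float)


def palhi_encode(bag: SlideLikelihoods) -> pd.Series:
    """Histogram encoding: 101 normalized bin masses + 2 label fractions."""
    if len(bag) == 0:
        raise ValueError("empty likelihood bag")
    hist = _bin_counts(bag) / len(bag)
    frac1 = float(bag.predicted_labels.mean())
    values = np.concatenate([hist, [1.0 - frac1, frac1]])
    return pd.Series(values, index=PALHI_NAMES, name=bag.slide_id)


@dataclass(frozen=True)
class BoWVocabulary:
    """Likelihood-bin vocabulary with smoothed IDF weights."""

    document_frequency: np.ndarray
    n_slides: int

    def __post_init__(self) -> None:
        df = np.asarray(self.document_frequency, dtype=float)
        if df.shape != (N_BINS,):
            raise ValueError(f"document_frequency must have shape ({N_BINS},)")
        if (df < 0).any() or (df > self.n_slides).any():
            raise ValueError("df must lie in [0, n_slides]")
        object.__setattr__(self, "document_frequency", df)

    @property
    def idf(self) -> np.ndarray:
        return np.log((1.0 + self.n_slides) / (1.0 + self.document_frequency)) + 1.0


def fit_bow_vocabulary(corpus: list[SlideLikelihoods]) -> BoWVocabulary:
    """Document frequency of each likelihood bin over a slide corpus."""
    if not corpus:
        raise ValueError("empty corpus")
    df = np.zeros(N_BINS)
    for bag in corpus:
        df += _bin_counts(bag) > 0
    return BoWVocabulary(document_frequency=df, n_slides=len(corpus))


def bow_encode(bag: SlideLikelihoods, vocab: BoWVocabulary) -> pd.Series:
    """TF-IDF encoding: L2-normalized tf*idf block + majority-vote one-hot.

    Majority ties go to class 0.
    """
    if len(bag) == 0:
        raise ValueError("empty likelihood bag")
    tf = _bin_counts(bag) / len(bag)
    tfidf = tf * vocab.idf
    norm = np.linalg.norm(tfidf)
    if norm > 0:
        tfidf = tfidf / norm
    majority = 1 if bag.predicted_labels.mean() > 0.5 else 0
    labels = np.array([1.0, 0.0]) if majority == 0 else np.array([0.0, 1.0])
    return pd.Series(np.concatenate([tfidf, labels]), index=BOW_NAMES, name=bag.slide_id)


def fuse(palhi: pd.Series, bow: pd.Series) -> pd.Series:
    """Early fusion: concatenate PALHI and BoW into the 206-dim slide vector."""
    if list(palhi.index) != PALHI_NAMES or list(bow.index) != BOW_NAMES:
        raise ValueError("inputs must be complete PALHI / BoW vectors in canonical order")
    fused = pd.concat([palhi, bow])
    if fused.index.duplicated().any():
        raise ValueError("duplicate feature names after fusion")
    fused.name = palhi.name
    return fused


def encode_cohort(bags: list[SlideLikelihoods], vocab: BoWVocabulary | None = None
                  ) -> tuple[pd.DataFrame, BoWVocabulary]:
    """Fused 206-feature matrix (slides x features) for a bag collection.

    Fits the BoW vocabulary on ``bags`` unless one is supplied (validation
    cohorts reuse the training vocabulary).
    """
    if vocab is None:
        vocab = fit_bow_vocabulary(bags)
    rows = [fuse(palhi_encode(b), bow_encode(b, vocab)) for b in bags]
    X = pd.DataFrame(rows)
    X.index.name = "slide_id"
    return X, vocab
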