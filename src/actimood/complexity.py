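"""Nonlinear complexity features: sample entropy and symbolic dynamics.

Sample entropy (SampEn) follows the Richman–Moorman convention: with
template length ``m`` and tolerance ``r`` (a fraction of the sample SD),
SampEn = -ln(A/B) where B counts ordered pairs of distinct length-``m``
templates whose Chebyshev distance is <= r, A the same for length ``m + 1``,
both over the n - m template start positions, self-matches excluded.  Higher
values mean more irregular minute-to-minute dynamics.

The symbolic-dynamics statistic coarse-grains the series into a 6-letter
alphabet (equal-width bins over the range after clipping to mean ± 3 SD,
which tames outliers), slides a 3-letter window along the string, and counts
the number of distinct words observed out of the 6^3 = 216 possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import ActivitySeries
from .variability import _as_values

__all__ = [
    "ComplexityConfig",
    "ComplexityFeatures",
    "sample_entropy",
    "symbolize",
    "symbolic_dynamics_count",
    "ComplexityExtractor",
]


@dataclass(frozen=True)
class ComplexityConfig:
    """Parameters of the two complexity estimators.

    m : SampEn template length (minutes).
    r_frac : SampEn tolerance as a fraction of the sample SD.
    n_symbols : alphabet size of the symbolic coarse-graining.
    word_length : symbols per overlapping word.
    clip_sd : clipping half-width in SDs before binning.
    """

    m: int = 2
    r_frac: float = 0.2
    n_symbols: int = 6
    word_length: int = 3
    clip_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_frac <= 0:
            raise ValueError("r_frac must be > 0")
        if self.n_symbols < 2:
            raise ValueError("n_symbols must be >= 2")
        if self.word_length < 1:
            raise ValueError("word_length must be >= 1")

    @property
    def pattern_space(self) -> int:
        """Number of possible words: n_symbols ** word_length (216 at defaults)."""
        return self.n_symbols**self.word_length


@dataclass(frozen=True)
class ComplexityFeatures:
    sample_entropy: float
    symbolic_count: int

    def as_dict(self) -> dict[str, float]:
        return {"sample_entropy": self.sample_entropy, "symbolic_count": self.symbolic_count}


def _template_distances(x: np.ndarray, m: int) -> np.ndarray:
    """Chebyshev distance matrix between all length-m templates of x."""
    n = len(x)
    d = np.abs(x[:, None] - x[None, :])
    nt = n - m + 1
    c = d[:nt, :nt].copy()
    for o in range(1, m):
        np.maximum(c, d[o : o + nt, o : o + nt], out=c)
    return c


def sample_entropy(
    series: ActivitySeries | Sequence[float], cfg: ComplexityConfig = ComplexityConfig()
) -> float:
    """Sample entropy of a fully observed series, in nats.

    Returns NaN (with a warning naming the cause) on degenerate inputs:
    zero-variance series (tolerance r = 0) or vanishing match counts.
    """
    x = _as_values(series)
    m = cfg.m
    if len(x) <= m + 1:
        raise ValueError(f"need length > m + 1 = {m + 1}, got {len(x)}")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("sample_entropy undefined: zero-variance series (r = 0)")
        return float("nan")
    r = cfg.r_frac * sd
    nt = len(x) - m  # template start positions shared by the m and m+1 counts
    cm = _template_distances(x, m)[:nt, :nt]
    cm1 = _template_distances(x, m + 1)
    b = int((cm <= r).sum() - nt)        # ordered pairs, self-matches removed
    a = int((cm1 <= r).sum() - nt)
    if b == 0 or a == 0:
        which = "B (length-m matches)" if b == 0 else "A (length-m+1 matches)"
        warnings.warn(f"sample_entropy undefined: {which} count is zero")
        return float("nan")
    return float(-np.log(a / b))


def symbolize(series: ActivitySeries | Sequence[float], cfg: ComplexityConfig = ComplexityConfig()) -> np.ndarray:
    """Map a series to symbols 1..n_symbols.

    Values are clipped to mean ± clip_sd·SD; the clipped range is split into
    n_symbols equal-width bins (left-closed, top bin right-closed).  A
    zero-width range degenerates to all symbols 1.
    """
    x = _as_values(series)
    mean, sd = x.mean(), x.std(ddof=1)
    xc = np.clip(x, mean - cfg.clip_sd * sd, mean + cfg.clip_sd * sd)
    lo, hi = xc.min(), xc.max()
    if hi == lo:
        return np.ones(len(x), dtype=np.int64)
    width = (hi - lo) / cfg.n_symbols
    sym = np.floor((xc - lo) / width).astype(np.int64)
    np.clip(sym, 0, cfg.n_symbols - 1, out=sym)  # right edge of the top bin
    return sym + 1


def symbolic_dynamics_count(
    series: ActivitySeries | Sequence[float], cfg: ComplexityConfig = ComplexityConfig()
) -> int:
    """Number of distinct overlapping words in the symbolized series."""
    sym = symbolize(series, cfg) - 1
    w = cfg.word_length
    if len(sym) < w:
        raise ValueError(f"need length >= word_length = {w}, got {len(sym)}")
    codes = np.zeros(len(sym) - w + 1, dtype=np.int64)
    for o in range(w):
        codes = codes * cfg.n_symbols + sym[o : o + len(codes)]
    return int(np.unique(codes).size)


def complexity_features(
    series: ActivitySeries | Sequence[float], cfg: ComplexityConfig = ComplexityConfig()
) -> ComplexityFeatures:
    return ComplexityFeatures(
        sample_entropy=sample_entropy(series, cfg),
        symbolic_count=symbolic_dynamics_count(series, cfg),
    )


class ComplexityExtractor(TransformerMixin, BaseEstimator):
    """Sample entropy + symbolic-dynamics count as an sklearn transformer."""

    def __init__(
        self,
        m: int = 2,
        r_frac: float = 0.2,
        n_symbols: int = 6,
        word_length: int = 3,
        clip_sd: float = 3.0,
    ):
        self.m = m
        self.r_frac = r_frac
        self.n_symbols = n_symbols
        self.word_length = word_length
        self.clip_sd = clip_sd

    def _config(self) -> ComplexityConfig:
        return ComplexityConfig(
            m=self.m,
            r_frac=self.r_frac,
            n_symbols=self.n_symbols,
            word_length=self.word_length,
            clip_sd=self.clip_sd,
        )

    def fit(self, X, y=None):
        self._config()  # validates
        return self

    def transform(self, X) -> pd.DataFrame:
        cfg = self._config()
        rows = [complexity_features(s, cfg).as_dict() for s in X]
        return pd.DataFrame(rows, columns=["sample_entropy", "symbolic_count"])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["sample_entropy", "symbolic_count"], dtype=object)
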