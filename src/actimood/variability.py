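"""Linear variability features of a per-minute activity epoch.

Activity-count series have unstable means, so dispersion is reported
relative to the mean: the coefficient of variation CV = 100·SD/mean and the
root mean square of successive differences RMSSD = 100·RMSSD_raw/mean, both
in percent.  Their raw ratio RMSSD/SD indexes how much of the dispersion is
minute-to-minute scatter rather than slow drift, and the lag-1
autocorrelation indexes short-range persistence.

Undefined quantities (zero mean, zero variance) propagate as NaN, never as
silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import ActivitySeries

__all__ = ["VariabilityFeatures", "variability_features", "VariabilityExtractor"]

FEATURE_NAMES = ("mean", "cv_percent", "rmssd_percent", "rmssd_sd_ratio", "autocorr_lag1")


@dataclass(frozen=True)
class VariabilityFeatures:
    mean: float
    cv_percent: float
    rmssd_percent: float
    rmssd_sd_ratio: float
    autocorr_lag1: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def _as_values(series) -> np.ndarray:
    if isinstance(series, ActivitySeries):
        return series.values
    return np.asarray(series, dtype=float)


def _kernel(x: np.ndarray) -> tuple[float, ...]:
    n = len(x)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    rmssd = float(np.sqrt(np.sum(np.diff(x) ** 2) / (n - 1)))
    cv = 100.0 * sd / mean if mean != 0 else np.nan
    rmssd_pct = 100.0 * rmssd / mean if mean != 0 else np.nan
    ratio = rmssd / sd if sd != 0 else np.nan
    if sd != 0:
        dev = x - mean
        ac1 = float(np.sum(dev[:-1] * dev[1:]) / np.sum(dev**2))
    else:
        ac1 = np.nan
    return mean, cv, rmssd_pct, ratio, ac1


def variability_features(series: ActivitySeries | Sequence[float]) -> VariabilityFeatures:
    """Compute mean, CV%, RMSSD%, RMSSD/SD and lag-1 autocorrelation.

    Requires a fully observed series of length >= 3.
    """
    x = _as_values(series)
    if len(x) < 3:
        raise ValueError(f"need at least 3 minutes, got {len(x)}")
    return VariabilityFeatures(*_kernel(x))


class VariabilityExtractor(TransformerMixin, BaseEstimator):
    """Per-series linear variability features as an sklearn transformer.

    ``transform`` accepts a sequence of 1-D series (arrays or
    :class:`ActivitySeries`) and returns a ``(n_series, 5)`` DataFrame.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        rows = [variability_features(s).as_dict() for s in X]
        return pd.DataFrame(rows, columns=list(FEATURE_NAMES))

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
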