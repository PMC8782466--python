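"""One-stop feature extraction: variability + complexity + graph metrics.

The full feature vector of one epoch holds the five linear variability
features, the two complexity features, and six graph metrics per
neighbourhood parameter k (columns ``mean_edges_k2`` ... ``triangles_k40``).
:func:`cohort_feature_table` applies the extraction to every recording of a
cohort over a per-recording epoch plan, yielding the tidy table the
statistics in :mod:`actimood.cohort` consume.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .complexity import ComplexityConfig, ComplexityExtractor, complexity_features
from .preprocess import ActivitySeries, EpochSpec, extract_epoch, impute_missing
from .simgraph import SimilarityGraphConfig, SimilarityGraphExtractor, metrics_for_ks
from .variability import VariabilityExtractor, variability_features

__all__ = [
    "ActigraphyFeatureExtractor",
    "extract_features",
    "epoch_plan",
    "cohort_feature_table",
    "DEFAULT_FULL_KS",
    "DEFAULT_SHORT_KS",
]

DEFAULT_FULL_KS = (2, 5, 40)
DEFAULT_SHORT_KS = (2, 5)


class ActigraphyFeatureExtractor(TransformerMixin, BaseEstimator):
    """All actigraphy features of each series, as an sklearn transformer.

    Composes the variability, complexity and similarity-graph extractors;
    ``transform`` maps a sequence of fully observed series to a DataFrame
    with ``5 + 2 + 6 * len(ks)`` columns.
    """

    def __init__(
        self,
        ks: Sequence[int] = DEFAULT_FULL_KS,
        m: int = 2,
        r_frac: float = 0.2,
        n_symbols: int = 6,
        word_length: int = 3,
        clip_sd: float = 3.0,
        ratio_threshold: float = 1.2,
        distance_comparator: str = "strict_less",
        zero_pair_rule: str = "both_zero_similar",
    ):
        self.ks = ks
        self.m = m
        self.r_frac = r_frac
        self.n_symbols = n_symbols
        self.word_length = word_length
        self.clip_sd = clip_sd
        self.ratio_threshold = ratio_threshold
        self.distance_comparator = distance_comparator
        self.zero_pair_rule = zero_pair_rule

    def _parts(self):
        return (
            VariabilityExtractor(),
            ComplexityExtractor(
                m=self.m, r_frac=self.r_frac, n_symbols=self.n_symbols,
                word_length=self.word_length, clip_sd=self.clip_sd,
            ),
            SimilarityGraphExtractor(
                ks=self.ks, ratio_threshold=self.ratio_threshold,
                distance_comparator=self.distance_comparator,
                zero_pair_rule=self.zero_pair_rule,
            ),
        )

    def fit(self, X, y=None):
        for part in self._parts():
            part.fit(X)
        return self

    def transform(self, X) -> pd.DataFrame:
        frames = [part.fit(X).transform(X) for part in self._parts()]
        return pd.concat(frames, axis=1)

    def get_feature_names_out(self, input_features=None):
        return np.concatenate([p.get_feature_names_out() for p in self._parts()])


def extract_features(
    series: ActivitySeries | Sequence[float],
    ks: Sequence[int] = DEFAULT_FULL_KS,
    complexity_cfg: ComplexityConfig = ComplexityConfig(),
    graph_cfg: SimilarityGraphConfig = SimilarityGraphConfig(),
) -> dict[str, float]:
    """Full feature dict of one fully observed epoch."""
    row: dict[str, float] = {}
    row.update(variability_features(series).as_dict())
    row.update(complexity_features(series, complexity_cfg).as_dict())
    for k, gm in metrics_for_ks(series, ks, graph_cfg).items():
        row.update(gm.as_dict(k=k))
    return row


def epoch_plan(
    series: ActivitySeries,
    full_minutes: int = 1190,
    short_minutes: int = 120,
    morning_start: int = 480,   # 08:00
    evening_start: int = 1200,  # 20:00
    full_ks: Sequence[int] = DEFAULT_FULL_KS,
    short_ks: Sequence[int] = DEFAULT_SHORT_KS,
) -> list[tuple[EpochSpec, tuple[int, ...]]]:
    """Standard epoch plan for one recording.

    The full epoch is the first ``full_minutes``; the morning and evening
    windows are placed at fixed clock times (defaults 08:00-10:00 and
    20:00-22:00) relative to the recording start.  Windows that do not fit
    inside the recording are skipped with a warning.
    """
    plan: list[tuple[EpochSpec, tuple[int, ...]]] = []
    n = len(series)
    if full_minutes <= n:
        plan.append((EpochSpec(0, full_minutes, f"full-{full_minutes}"), tuple(full_ks)))
    else:
        warnings.warn(f"recording shorter than {full_minutes} minutes; full epoch skipped")
    if series.start_time is None:
        return plan
    start_mod = series.start_time.hour * 60 + series.start_time.minute
    for clock, label in ((morning_start, "morning"), (evening_start, "evening")):
        offset = (clock - start_mod) % 1440
        if offset + short_minutes <= n:
            plan.append(
                (EpochSpec(offset, short_minutes, f"{label}-{short_minutes}"), tuple(short_ks))
            )
        else:
            warnings.warn(f"{label} window does not fit recording {series.subject_id}")
    return plan


def cohort_feature_table(
    recordings: Sequence[ActivitySeries],
    max_missing_frac: float = 0.05,
    complexity_cfg: ComplexityConfig = ComplexityConfig(),
    graph_cfg: SimilarityGraphConfig = SimilarityGraphConfig(),
    **plan_kwargs,
) -> pd.DataFrame:
    """Tidy feature table: one row per (subject, state, epoch).

    Each recording is mean-imputed (rejected above the missing-data
    threshold), the epoch plan is derived, and every epoch is fully
    featurised.  Rejections propagate as exceptions; callers batching over
    recordings decide whether to skip.
    """
    rows = []
    for rec in recordings:
        full = impute_missing(rec, max_missing_frac=max_missing_frac)
        for spec, ks in epoch_plan(full, **plan_kwargs):
            epoch = extract_epoch(full, spec)
            row = {"subject_id": rec.subject_id, "state": rec.state, "epoch": spec.label}
            row.update(extract_features(epoch, ks=ks, complexity_cfg=complexity_cfg,
                                        graph_cfg=graph_cfg))
            rows.append(row)
    return pd.DataFrame(rows)
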