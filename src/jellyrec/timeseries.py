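"""Daily aggregation of positive detections and truth-series agreement."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr


class TimeseriesError(ValueError):
    pass


def daily_positive_counts(detections: pd.DataFrame,
                          timestamp_col: str = "timestamp",
                          label_col: str = "prediction") -> pd.Series:
    """Per-day count of positive detections.

    Timestamps must be ISO-8601; unparseable rows raise an error listing
    their indices.
    """
    ts = pd.to_datetime(detections[timestamp_col], errors="coerce")
    bad = detections.index[ts.isna()].tolist()
    if bad:
        raise TimeseriesError(f"unparseable timestamps in rows {bad}")
    pos = detections[label_col].astype(int) == 1
    return pos.groupby(ts.dt.date).sum().astype(int)


def series_correlation(counts: pd.Series, truth: pd.Series) -> float | None:
    """Pearson correlation of two daily series on their shared days.

    Returns None (absent) when either series is constant, where the
    correlation is undefined.
    """
    joined = pd.concat([counts, truth], axis=1, join="inner").dropna()
    if len(joined) < 2:
        return None
    a, b = joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float)
    if a.std() == 0 or b.std() == 0:
        return None
    return float(pearsonr(a, b).statistic)
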