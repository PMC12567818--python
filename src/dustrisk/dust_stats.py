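"""Seasonal descriptive statistics, screening-value exceedance, and mean ratios.

Summarises total concentrations CT per metal (pooled and by season), screens
them against regulatory risk-screening values (e.g. GB 15618-2018, supplied
by the user — the standard's values depend on land use and soil pH, so none
are bundled), and computes pairwise ratios of pooled means between metals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .simulate import DustSample

logger = logging.getLogger(__name__)

__all__ = ["SeasonalSummary", "seasonal_summary", "exceedance", "mean_ratio_matrix"]


@dataclass
class SeasonalSummary:
    """Per-metal concentration summary, by season and pooled.

    ``per_season`` is indexed by (metal, season) with columns n/mean/min/max;
    ``pooled`` is indexed by metal.  Units: mg/kg.
    """

    per_season: pd.DataFrame
    pooled: pd.DataFrame

    @property
    def pooled_means(self) -> Dict[str, float]:
        return self.pooled["mean"].to_dict()


def _long_frame(samples: Sequence[DustSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        for metal, ct in s.ct.items():
            rows.append({"metal": metal, "season": s.season, "site": s.site, "ct": ct})
    return pd.DataFrame(rows)


def seasonal_summary(samples: Sequence[DustSample]) -> SeasonalSummary:
    """Counts, arithmetic means, minima and maxima per metal and season."""
    if not samples:
        raise ValueError("cannot summarise an empty sample set")
    df = _long_frame(samples)
    agg = {"n": ("ct", "size"), "mean": ("ct", "mean"),
           "min": ("ct", "min"), "max": ("ct", "max")}
    per_season = df.groupby(["metal", "season"], sort=False).agg(**agg)
    pooled = df.groupby("metal", sort=False).agg(**agg)
    return SeasonalSummary(per_season=per_season, pooled=pooled)


def exceedance(
    samples: Sequence[DustSample], screening: Mapping[str, float]
) -> pd.DataFrame:
    """Exceedance rate and maximum exceedance multiple vs screening values.

    rate = fraction of samples with CT strictly above the screening value;
    multiple = max(CT) / screening.  Metals without a screening value are
    skipped with a warning; non-positive screening values are rejected.
    """
    if not samples:
        raise ValueError("cannot screen an empty sample set")
    metals = list(samples[0].ct)
    rows = []
    for metal in metals:
        if metal not in screening:
            logger.warning("no screening value for %s; skipped", metal)
            continue
        sv = screening[metal]
        if sv <= 0:
            raise ValueError(f"screening value for {metal} must be positive, got {sv}")
        ct = np.array([s.ct[metal] for s in samples])
        rows.append(
            {
                "metal": metal,
                "screening": sv,
                "rate": float((ct > sv).mean()),
                "max_multiple": float(ct.max() / sv),
            }
        )
    return pd.DataFrame(rows).set_index("metal")


def mean_ratio_matrix(
    summary: Union[SeasonalSummary, Mapping[str, float]]
) -> pd.DataFrame:
    """Pairwise ratios of pooled means: entry (i, j) = mean_i / mean_j.

    Accepts a SeasonalSummary or a plain {metal: pooled mean} mapping.
    Ratios satisfy ratio_ij · ratio_ji = 1 and ratio_ii = 1.
    """
    means = summary.pooled_means if isinstance(summary, SeasonalSummary) else dict(summary)
    if not means:
        raise ValueError("no pooled means supplied")
    for metal, m in means.items():
        if m <= 0:
            raise ValueError(f"pooled mean for {metal} must be positive, got {m}")
    metals = list(means)
    vals = np.array([means[m] for m in metals])
    matrix = vals[:, None] / vals[None, :]
    return pd.DataFrame(matrix, index=metals, columns=metals)
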