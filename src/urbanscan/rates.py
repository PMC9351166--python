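"""Raw and empirical-Bayes smoothed area rates, and Jenks classification.

Small-area rates computed from few events over heterogeneous populations
are noisy: the variance of a raw rate scales with 1/population. Empirical
Bayes smoothing (global Marshall method-of-moments) shrinks each raw rate
toward the population-weighted prior mean, with shrinkage weight growing
as the area's population shrinks. Jenks natural breaks (exact Fisher
dynamic programming) supplies choropleth class limits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo_core import ConfigurationError, CountPanel, DataError

logger = logging.getLogger("urbanscan")

__all__ = ["RateTable", "raw_rates", "eb_smooth", "jenks_breaks", "jenks_labels"]


@dataclass
class RateTable:
    """Per-area raw and EB-smoothed rates (per ``per`` person-periods)."""

    area_id: np.ndarray
    raw_rate: np.ndarray
    eb_rate: np.ndarray
    weight: np.ndarray
    prior_mean: float  # on the output (per-``per``) scale
    per: float = 100_000.0
    class_label: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "area_id": self.area_id,
                "raw_rate": self.raw_rate,
                "eb_rate": self.eb_rate,
                "weight": self.weight,
            }
        )
        if self.class_label is not None:
            df["class"] = self.class_label
        return df


def raw_rates(panel: CountPanel, per: float = 100_000.0) -> np.ndarray:
    """Pooled-period raw rate per area: total count / population * per.

    Areas with zero population get NaN and are logged (they cannot carry a
    rate and are excluded downstream).
    """
    pop = panel.population
    tot = panel.area_totals().astype(float)
    out = np.full(panel.n_areas, np.nan)
    ok = pop > 0
    if not ok.all():
        logger.warning("raw_rates: %d zero-population areas excluded", int((~ok).sum()))
    out[ok] = tot[ok] / pop[ok] * per
    return out


def eb_smooth(
    counts: np.ndarray,
    population: np.ndarray,
    per: float = 100_000.0,
    area_id=None,
) -> RateTable:
    """Global (Marshall) method-of-moments empirical Bayes rate smoothing.

    With O_i events over n_i person-periods and raw rates r_i = O_i/n_i:

        m = sum(O) / sum(n)                              (prior mean)
        A = max(0, sum(n_i (r_i - m)^2)/sum(n) - m/(sum(n)/N))
        w_i = A / (A + m/n_i)
        eb_i = w_i r_i + (1 - w_i) m

    A is the method-of-moments between-area variance, floored at 0; when
    A = 0 every smoothed rate collapses to m. Rates are computed per
    person-period and rescaled to per-``per`` on output.
    """
    O = np.asarray(counts, dtype=float)
    n = np.asarray(population, dtype=float)
    if O.ndim != 1 or O.shape != n.shape:
        raise DataError("counts and population must be aligned 1-D arrays")
    keep = n > 0
    if keep.sum() < 2:
        raise DataError("need at least 2 areas with positive population")
    if n.sum() <= 0:
        raise DataError("total population is zero")
    O, n = O[keep], n[keep]
    N = len(n)
    r = O / n
    m = O.sum() / n.sum()
    A = np.sum(n * (r - m) ** 2) / n.sum() - m / (n.sum() / N)
    A = max(0.0, A)
    if A == 0.0:
        w = np.zeros(N)
    else:
        w = A / (A + m / n)
    eb = w * r + (1 - w) * m
    ids = np.asarray(area_id, dtype=object)[keep] if area_id is not None else np.arange(len(keep))[keep]
    return RateTable(
        area_id=ids,
        raw_rate=r * per,
        eb_rate=eb * per,
        weight=w,
        prior_mean=m * per,
        per=per,
    )


def jenks_breaks(values, k: int) -> np.ndarray:
    """Fisher–Jenks exact optimal 1-D classification into k classes.

    Dynamic programming over sorted values minimizing the total
    within-class sum of squared deviations. Returns the k-1 interior break
    points (upper bounds of classes 1..k-1, taken as the largest member of
    each class).
    """
    v = np.sort(np.asarray(values, dtype=float))
    nv = len(v)
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if len(np.unique(v)) < k:
        raise DataError(f"need at least {k} distinct values for {k} classes")
    # prefix sums for O(1) within-class SSD
    cs = np.concatenate([[0.0], np.cumsum(v)])
    cs2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def ssd(i: int, j: int) -> float:
        """Within-class SSD of v[i..j] inclusive."""
        s = cs[j + 1] - cs[i]
        s2 = cs2[j + 1] - cs2[i]
        cnt = j - i + 1
        return s2 - s * s / cnt

    cost = np.full((k, nv), np.inf)
    cut = np.zeros((k, nv), dtype=int)
    for j in range(nv):
        cost[0, j] = ssd(0, j)
    for c in range(1, k):
        for j in range(c, nv):
            best, arg = np.inf, c
            for i in range(c, j + 1):
                val = cost[c - 1, i - 1] + ssd(i, j)
                if val < best:
                    best, arg = val, i
            cost[c, j] = best
            cut[c, j] = arg
    # recover class boundaries
    breaks = []
    j = nv - 1
    for c in range(k - 1, 0, -1):
        i = cut[c, j]
        breaks.append(v[i - 1])
        j = i - 1
    return np.array(breaks[::-1])


def jenks_labels(values, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Class labels 1..k by ascending value from the optimal Jenks breaks."""
    values = np.asarray(values, dtype=float)
    breaks = jenks_breaks(values, k)
    labels = np.searchsorted(breaks, values, side="left") + 1
    return labels, breaks
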