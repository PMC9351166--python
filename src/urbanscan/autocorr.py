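"""Global and local (Anselin) Moran autocorrelation with permutation inference.

Global Moran's I is the cross-product statistic

    I = (n / S0) * (z' W z) / (z' z),        z = x - mean(x)

with expectation E[I] = -1/(n-1) under no autocorrelation. Inference is
either analytic under the randomization assumption (the usual z-score) or
by permutation. The local decomposition

    I_i = z_i / m2 * sum_j w_ij z_j,         m2 = (1/n) sum z^2

is tested by conditional permutation (hold z_i, permute the rest among
its neighbour slots) and each significant area is labelled HH/LL/HL/LH
from the signs of z_i and its spatial lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geo_core import DataError, SpatialWeights

__all__ = [
    "GlobalMoranResult",
    "LocalMoranResult",
    "global_moran",
    "local_moran",
    "residual_moran",
]


@dataclass
class GlobalMoranResult:
    I: float
    expected: float
    z: float
    p: float
    method: str
    n_perm: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "I": self.I,
            "expected": self.expected,
            "z": self.z,
            "p": self.p,
            "method": self.method,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


@dataclass
class LocalMoranResult:
    area_index: np.ndarray
    Ii: np.ndarray
    pseudo_p: np.ndarray
    quadrant: np.ndarray  # HH / LL / HL / LH / not-significant
    raw_quadrant: np.ndarray  # labels before the significance mask
    n_perm: int
    seed: int
    alpha: float
    fdr: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "area_index": self.area_index,
                "Ii": self.Ii,
                "pseudo_p": self.pseudo_p,
                "quadrant": self.quadrant,
            }
        )


def _moments(x: np.ndarray, W: SpatialWeights):
    z = x - x.mean()
    s2 = float(z @ z)
    if s2 == 0:
        raise DataError("constant input: Moran's I undefined (zero variance)")
    return z, s2


def _observed_I(z: np.ndarray, s2: float, W: SpatialWeights) -> float:
    n = len(z)
    return n / W.s0 * float(z @ W.lag(z)) / s2


def global_moran(
    x,
    W: SpatialWeights,
    inference: str = "analytic",
    n_perm: int = 999,
    seed: int = 0,
) -> GlobalMoranResult:
    """Global Moran's I with analytic-randomization or permutation inference.

    The permutation p-value is two-sided around E[I] = -1/(n-1):
    p = (1 + #{|I_perm - E| >= |I_obs - E|}) / (n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    n = W.n
    if len(x) != n:
        raise DataError("x length does not match weights")
    z, s2 = _moments(x, W)
    I_obs = _observed_I(z, s2, W)
    expected = -1.0 / (n - 1)
    if inference == "analytic":
        Wm = W.to_sparse()
        S0 = W.s0
        Wsym = Wm + Wm.T
        S1 = 0.5 * float((Wsym.multiply(Wsym)).sum())
        row = np.asarray(Wm.sum(axis=1)).ravel()
        col = np.asarray(Wm.sum(axis=0)).ravel()
        S2 = float(((row + col) ** 2).sum())
        m2 = s2 / n
        m4 = float((z**4).sum()) / n
        b2 = m4 / m2**2
        num = n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * S0**2) - b2 * (
            (n**2 - n) * S1 - 2 * n * S2 + 6 * S0**2
        )
        den = (n - 1) * (n - 2) * (n - 3) * S0**2
        var = num / den - expected**2
        zscore = (I_obs - expected) / np.sqrt(var)
        p = 2 * stats.norm.sf(abs(zscore))
        return GlobalMoranResult(I_obs, expected, float(zscore), float(p), "analytic-randomization")
    if inference == "permutation":
        rng = np.random.default_rng(seed)
        Wm = W.to_sparse()
        sims = np.empty(n_perm)
        zp = z.copy()
        for b in range(n_perm):
            rng.shuffle(zp)
            sims[b] = n / W.s0 * float(zp @ (Wm @ zp)) / s2
        extreme = int(np.sum(np.abs(sims - expected) >= abs(I_obs - expected)))
        p = (1 + extreme) / (n_perm + 1)
        zscore = (I_obs - sims.mean()) / sims.std(ddof=1)
        return GlobalMoranResult(
            I_obs, expected, float(zscore), float(p), "permutation", n_perm, seed
        )
    raise DataError(f"unknown inference method {inference!r}")


def local_moran(
    x,
    W: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    fdr: bool = False,
) -> LocalMoranResult:
    """Anselin local Moran's I with conditional permutation inference.

    For each area the observation is held fixed and the remaining n-1
    values are permuted into its neighbour slots; the pseudo p-value is
    two-sided (twice the smaller tail), floored at 2/(n_perm+1). Quadrant
    labels use the signs of (x_i - mean) and the spatial lag, masked to
    ``not-significant`` where pseudo_p > alpha (after optional
    Benjamini–Hochberg adjustment across areas).
    """
    x = np.asarray(x, dtype=float)
    n = W.n
    if len(x) != n:
        raise DataError("x length does not match weights")
    z, s2 = _moments(x, W)
    m2 = s2 / n
    lag = W.lag(z)
    Ii = z * lag / m2

    rng = np.random.default_rng(seed)
    card = np.array([len(nb) for nb in W.neighbours])
    kmax = int(card.max())
    # one pool of permuted other-indices per replicate, sliced per area
    ridx = np.empty((n_perm, kmax), dtype=int)
    base = np.arange(n - 1)
    for b in range(n_perm):
        ridx[b] = rng.permutation(base)[:kmax] if kmax <= n - 1 else np.resize(rng.permutation(base), kmax)
    pseudo_p = np.ones(n)
    for i in range(n):
        ki = card[i]
        if ki == 0:
            pseudo_p[i] = np.nan
            continue
        # map 0..n-2 onto indices excluding i
        oth = ridx[:, :ki].copy()
        oth[oth >= i] += 1
        sim_lag = (z[oth] * W.weights[i][None, :]).sum(axis=1)
        sim_Ii = z[i] * sim_lag / m2
        # two-sided permutation p: twice the smaller tail, so that the
        # rejection rate under spatial randomness matches the nominal level
        hi_tail = int(np.sum(sim_Ii >= Ii[i]))
        lo_tail = int(np.sum(sim_Ii <= Ii[i]))
        pseudo_p[i] = min(1.0, 2.0 * (1 + min(hi_tail, lo_tail)) / (n_perm + 1))

    quad_raw = np.empty(n, dtype=object)
    hi = z > 0
    lag_hi = lag > 0
    quad_raw[hi & lag_hi] = "HH"
    quad_raw[~hi & ~lag_hi] = "LL"
    quad_raw[hi & ~lag_hi] = "HL"
    quad_raw[~hi & lag_hi] = "LH"

    p_eff = pseudo_p.copy()
    if fdr:
        ok = ~np.isnan(pseudo_p)
        p_eff[ok] = _bh_adjust(pseudo_p[ok])
    quadrant = quad_raw.copy()
    notsig = np.isnan(p_eff) | (p_eff > alpha)
    quadrant[notsig] = "not-significant"
    return LocalMoranResult(
        area_index=np.arange(n),
        Ii=Ii,
        pseudo_p=pseudo_p,
        quadrant=quadrant,
        raw_quadrant=quad_raw,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
        fdr=fdr,
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def residual_moran(residuals, W: SpatialWeights, **kwargs) -> GlobalMoranResult:
    """Global Moran test applied to model residuals (OLS/GWR/MGWR diagnostics)."""
    return global_moran(residuals, W, **kwargs)
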