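"""The variable-selection funnel feeding the geographic regressions.

Candidate covariates pass through four gates, each recorded per variable
as a removal stage: (1) a Pearson correlation screen against the smoothed
rate; (2) iterative removal of collinear variables with VIF above a
threshold (largest first, recomputing after each drop); (3) an
exhaustive subset search keeping models whose coefficients are all
significant and all VIFs admissible, ranked by adjusted R² (ties by
AICc, then lexicographic variable order); (4) backward pruning of
non-significant terms in the final OLS. Areas with zero events over the
whole period are excluded beforehand as structural outliers.

All models are fit on z-standardized y and X.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geo_core import AreaTable, CountPanel, DataError

logger = logging.getLogger("urbanscan")

__all__ = [
    "ScreeningReport",
    "OLSResult",
    "pearson_screen",
    "vif",
    "exploratory_regression",
    "fit_ols",
    "run_funnel",
    "exclude_zero_count_areas",
]

STAGES = ("pearson", "collinearity", "subset-search", "ols", "retained")


@dataclass
class ScreeningReport:
    """Per-variable screening outcome (one removal stage each)."""

    table: pd.DataFrame  # columns: variable, pearson_r, pearson_p, stage

    def stage_of(self, name: str) -> str:
        return self.table.set_index("variable").loc[name, "stage"]

    @property
    def retained(self) -> list[str]:
        return self.table.loc[self.table.stage == "retained", "variable"].tolist()


@dataclass
class OLSResult:
    names: list
    coef: np.ndarray  # includes intercept first (standardized scale)
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r2: float
    adj_r2: float
    aicc: float
    aic: float
    residuals: np.ndarray
    vif: np.ndarray  # per covariate (excludes intercept)
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "terms": ["intercept"] + list(self.names),
            "coef": self.coef.tolist(),
            "se": self.se.tolist(),
            "t": self.t.tolist(),
            "p": self.p.tolist(),
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "aic": self.aic,
            "aicc": self.aicc,
            "vif": self.vif.tolist(),
            "n": self.n,
        }


def _zscore(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    sd = a.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - a.mean(axis=0)) / sd


def _ols_core(X: np.ndarray, y: np.ndarray):
    """Least squares with intercept; returns coef, se, t, p, r2, adj_r2, resid, aic, aicc."""
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < Z.shape[1]:
        raise DataError("singular design matrix (perfectly collinear columns)")
    resid = y - Z @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - rss / tss if tss > 0 else 0.0
    df = n - p - 1
    if df <= 0:
        raise DataError("not enough observations for the number of terms")
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(Z.T @ Z)
    se = np.sqrt(np.diag(cov))
    tvals = coef / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    adj_r2 = 1 - (1 - r2) * (n - 1) / df
    k = p + 1  # effective parameters (tr(S) of the projection, for parity with GWR)
    sigma_ml = np.sqrt(rss / n) if rss > 0 else 1e-150
    base = 2 * n * np.log(sigma_ml) + n * np.log(2 * np.pi) + n
    aic = base + 2 * (k + 1)
    aicc = base - n + n * (n + k) / (n - 2 - k)
    return coef, se, tvals, pvals, r2, adj_r2, resid, aic, aicc


def pearson_screen(X: pd.DataFrame, y, alpha: float = 0.05) -> pd.DataFrame:
    """Stage-1 screen: product-moment r and two-sided p per covariate.

    Variables with p > alpha (or zero variance) are marked for exclusion.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise DataError("need at least 3 observations for a correlation test")
    rows = []
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        if x.std() == 0:
            logger.warning("pearson_screen: %s has zero variance; excluded", name)
            rows.append({"variable": name, "pearson_r": np.nan, "pearson_p": np.nan, "pass": False})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"variable": name, "pearson_r": r, "pearson_p": p, "pass": p <= alpha})
    return pd.DataFrame(rows)


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_j = 1/(1 - R²_j), regressing j on the rest.

    Perfectly collinear columns report ``inf``.
    """
    cols = list(X.columns)
    out = {}
    Xv = X.to_numpy(dtype=float)
    n = Xv.shape[0]
    for j, name in enumerate(cols):
        if len(cols) == 1:
            out[name] = 1.0
            continue
        others = np.column_stack([np.ones(n), np.delete(Xv, j, axis=1)])
        yj = Xv[:, j]
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        tss = float(((yj - yj.mean()) ** 2).sum())
        rss = float(resid @ resid)
        r2 = 1 - rss / tss if tss > 0 else 1.0
        out[name] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def exploratory_regression(
    X: pd.DataFrame,
    y,
    vif_thresh: float = 7.5,
    max_size: int = 6,
    alpha: float = 0.05,
):
    """Two-pass exploratory regression.

    Pass A drops variables whose VIF in the current full model exceeds
    ``vif_thresh``, largest first, recomputing after each drop. Pass B
    enumerates all subsets of the survivors up to ``max_size``, keeping
    models where every slope is significant at ``alpha`` and every VIF is
    admissible, ranked by adjusted R² (ties by AICc then variable order).

    Returns (ranked model DataFrame, collinearity_dropped, best_variables).
    """
    y = _zscore(np.asarray(y, dtype=float))
    Xz = pd.DataFrame(_zscore(X.to_numpy(dtype=float)), columns=X.columns)

    dropped_collinear: list[str] = []
    current = list(Xz.columns)
    while len(current) > 1:
        v = vif(Xz[current])
        worst = v.idxmax()
        if v[worst] > vif_thresh:
            current.remove(worst)
            dropped_collinear.append(worst)
        else:
            break

    records = []
    for size in range(1, min(max_size, len(current)) + 1):
        for combo in itertools.combinations(sorted(current), size):
            sub = Xz[list(combo)]
            try:
                coef, se, t, p, r2, adj_r2, resid, aic, aicc = _ols_core(sub.to_numpy(), y)
            except DataError:
                continue
            slopes_ok = bool(np.all(p[1:] <= alpha))
            v = vif(sub)
            vif_ok = bool(np.all(v.to_numpy() <= vif_thresh))
            records.append(
                {
                    "variables": combo,
                    "size": size,
                    "adj_r2": adj_r2,
                    "aicc": aicc,
                    "all_significant": slopes_ok,
                    "vif_ok": vif_ok,
                    "admissible": slopes_ok and vif_ok,
                }
            )
    models = pd.DataFrame(records)
    best_vars: list[str] = []
    if len(models):
        adm = models[models.admissible]
        if len(adm):
            adm = adm.sort_values(
                by=["adj_r2", "aicc", "variables"],
                ascending=[False, True, True],
                kind="stable",
            )
            best_vars = list(adm.iloc[0]["variables"])
            models = pd.concat([adm, models[~models.admissible]], ignore_index=True)
        else:
            logger.warning("exploratory_regression: no admissible subset found")
    return models, dropped_collinear, best_vars


def fit_ols(X: pd.DataFrame, y, standardize: bool = True, alpha: float = 0.05,
            prune: bool = True) -> OLSResult:
    """OLS on (optionally z-standardized) data with backward p-value pruning.

    Terms with p > alpha are dropped one at a time (largest p first) and
    the model refit, yielding the final geographic-variable set.
    """
    y = np.asarray(y, dtype=float)
    if standardize:
        y = _zscore(y)
        X = pd.DataFrame(_zscore(X.to_numpy(dtype=float)), columns=X.columns, index=X.index)
    names = list(X.columns)
    while True:
        coef, se, t, p, r2, adj_r2, resid, aic, aicc = _ols_core(
            X[names].to_numpy(dtype=float), y
        )
        if not prune or len(names) == 0:
            break
        slope_p = p[1:]
        worst = int(np.argmax(slope_p))
        if slope_p[worst] <= alpha:
            break
        names.pop(worst)
    v = vif(X[names]) if names else pd.Series(dtype=float)
    return OLSResult(
        names=names,
        coef=coef,
        se=se,
        t=t,
        p=p,
        r2=r2,
        adj_r2=adj_r2,
        aicc=aicc,
        aic=aic,
        residuals=resid,
        vif=v.to_numpy(),
        n=len(y),
    )


def run_funnel(
    X: pd.DataFrame,
    y,
    alpha: float = 0.05,
    vif_thresh: float = 7.5,
    max_size: int = 6,
):
    """Full selection cascade; returns (ScreeningReport, final OLSResult).

    Every input variable ends in exactly one stage: ``pearson``,
    ``collinearity``, ``subset-search``, ``ols`` or ``retained``.
    """
    screen = pearson_screen(X, y, alpha=alpha)
    stage = {v: None for v in X.columns}
    for _, row in screen.iterrows():
        if not row["pass"]:
            stage[row["variable"]] = "pearson"
    keep1 = [v for v in X.columns if stage[v] is None]
    models, dropped_collinear, best_vars = exploratory_regression(
        X[keep1], y, vif_thresh=vif_thresh, max_size=max_size, alpha=alpha
    )
    if not best_vars and len(models):
        # no subset clears both gates; carry the best-fitting one forward so
        # the pipeline still produces a (flagged) model
        fallback = models.sort_values(
            by=["adj_r2", "aicc", "variables"], ascending=[False, True, True], kind="stable"
        ).iloc[0]
        best_vars = list(fallback["variables"])
        logger.warning("run_funnel: no admissible subset; falling back to %s", best_vars)
    for v in dropped_collinear:
        stage[v] = "collinearity"
    for v in keep1:
        if stage[v] is None and v not in best_vars:
            stage[v] = "subset-search"
    ols = fit_ols(X[best_vars], y, standardize=True, alpha=alpha) if best_vars else None
    final_vars = ols.names if ols is not None else []
    for v in best_vars:
        stage[v] = "retained" if v in final_vars else "ols"
    screen["stage"] = [stage[v] for v in screen["variable"]]
    return ScreeningReport(table=screen), ols


def exclude_zero_count_areas(areas: AreaTable, panel: CountPanel):
    """Drop areas with zero events over the whole period (reported, not silent).

    Returns (filtered AreaTable, filtered CountPanel, removed id list).
    """
    tot = panel.area_totals()
    if np.all(tot == 0):
        raise DataError("every area has zero events; nothing to model")
    keep = tot > 0
    removed = [str(a) for a in np.asarray(panel.area_id)[~keep]] if panel.area_id is not None else np.flatnonzero(~keep).tolist()
    if removed:
        logger.info("exclude_zero_count_areas: removed %d areas: %s", len(removed), removed)
    new_panel = CountPanel(
        counts=panel.counts[keep],
        population=panel.population[keep],
        years=panel.years,
        unassigned=panel.unassigned,
        area_id=panel.area_id[keep] if panel.area_id is not None else None,
    )
    return areas.subset(keep), new_panel, removed
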