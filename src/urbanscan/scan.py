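"""Kulldorff discrete-Poisson scan statistics: purely temporal and space-time.

A candidate window (a contiguous year interval, or a cylinder = circular
set of areas x year interval) with observed count c and expected count e
(indirect standardization on person-time, conditioned on the study total
C) scores

    LLR = c ln(c/e) + (C-c) ln((C-c)/(C-e))

when the direction condition holds (c > e for high-rate clusters, c < e
for low), else 0; 0*ln(0) = 0. Inference is by Monte-Carlo replication:
C events are redistributed multinomially with cell probabilities
proportional to the expectations, and the observed maximum LLR is ranked
among the replicate maxima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo_core import AreaTable, ConfigurationError, CountPanel, centroid_distances

__all__ = [
    "ScanCluster",
    "poisson_llr",
    "temporal_scan",
    "spacetime_scan",
    "cluster_report",
]


@dataclass
class ScanCluster:
    member_areas: tuple  # indices; empty for purely temporal clusters
    year_window: tuple  # (start, end) inclusive, in year labels
    O: float
    E: float
    LLR: float
    C: float
    p: float | None = None
    rank: int = 1

    @property
    def OE(self) -> float:
        return self.O / self.E

    @property
    def RR(self) -> float:
        """Relative risk inside vs outside: (O/E) / ((C-O)/(C-E))."""
        if self.C == self.O:
            return np.inf
        return (self.O / self.E) / ((self.C - self.O) / (self.C - self.E))


def poisson_llr(c, e, C, direction: str = "high"):
    """Log-likelihood ratio of a discrete-Poisson scan window.

    Vectorized over c/e. Windows failing the direction condition score 0.
    """
    c = np.asarray(c, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(e <= 0) or np.any(e >= C):
        raise ConfigurationError("expected count must lie strictly between 0 and C")
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(c > 0, c * np.log(np.where(c > 0, c, 1.0) / e), 0.0)
        rem = C - c
        t2 = np.where(rem > 0, rem * np.log(np.where(rem > 0, rem, 1.0) / (C - e)), 0.0)
    llr = t1 + t2
    if direction == "high":
        llr = np.where(c > e, llr, 0.0)
    elif direction == "low":
        llr = np.where(c < e, llr, 0.0)
    elif direction != "both":
        raise ConfigurationError(f"unknown direction {direction!r}")
    return llr if llr.ndim else float(llr)


def _year_windows(T: int, max_frac: float) -> list[tuple[int, int]]:
    """All contiguous [a, b] index windows of length <= max(1, floor(max_frac*T))."""
    max_len = max(1, int(np.floor(max_frac * T)))
    return [(a, b) for a in range(T) for b in range(a, min(T, a + max_len))]


def temporal_scan(
    panel: CountPanel,
    max_window_frac: float = 0.5,
    n_sim: int = 999,
    seed: int = 0,
    direction: str = "high",
) -> list[ScanCluster]:
    """Purely temporal Poisson scan over contiguous year windows (1-year cells).

    Expected counts are proportional to person-time: with constant
    population the expectation of a window is C * len / T. Secondary
    clusters are reported greedily among non-overlapping windows.
    """
    T = panel.n_years
    if T < 2:
        raise ConfigurationError("temporal scan needs at least 2 years")
    C = panel.total
    if C == 0:
        return []
    ct = panel.year_totals().astype(float)
    windows = _year_windows(T, max_window_frac)
    obs = np.array([ct[a : b + 1].sum() for a, b in windows])
    e = np.array([C * (b - a + 1) / T for a, b in windows])
    llr = poisson_llr(obs, e, C, direction)

    order = np.argsort(-llr, kind="stable")
    clusters: list[ScanCluster] = []
    used: set[int] = set()
    for idx in order:
        if llr[idx] <= 0:
            break
        a, b = windows[idx]
        span = set(range(a, b + 1))
        if span & used:
            continue
        used |= span
        clusters.append(
            ScanCluster(
                member_areas=(),
                year_window=(int(panel.years[a]), int(panel.years[b])),
                O=float(obs[idx]),
                E=float(e[idx]),
                LLR=float(llr[idx]),
                C=float(C),
                rank=len(clusters) + 1,
            )
        )
    if not clusters:
        return []
    if n_sim > 0:
        rng = np.random.default_rng(seed)
        probs = np.full(T, 1.0 / T)
        sims = rng.multinomial(C, probs, size=n_sim).astype(float)
        # window sums via prefix
        pref = np.concatenate([np.zeros((n_sim, 1)), np.cumsum(sims, axis=1)], axis=1)
        a_idx = np.array([a for a, b in windows])
        b_idx = np.array([b for a, b in windows])
        wsum = pref[:, b_idx + 1] - pref[:, a_idx]
        sim_llr = poisson_llr(wsum, np.broadcast_to(e, wsum.shape), C, direction)
        max_llr = sim_llr.max(axis=1)
        for cl in clusters:
            cl.p = float((1 + np.sum(max_llr >= cl.LLR)) / (n_sim + 1))
    return clusters


def _cylinder_candidates(panel: CountPanel, areas: AreaTable, max_pop_frac: float):
    """Per-centre sorted area orders and admissible prefix lengths."""
    pop = panel.population
    if areas.n == 1:
        return [np.array([0])], [1]
    D = centroid_distances(areas)
    cap = max_pop_frac * pop.sum()
    orders, nprefix = [], []
    for i in range(areas.n):
        order = np.argsort(D[i], kind="stable")
        cum = np.cumsum(pop[order])
        m = int(np.searchsorted(cum, cap, side="right"))
        orders.append(order)
        nprefix.append(max(1, m))
    return orders, nprefix


def spacetime_scan(
    panel: CountPanel,
    areas: AreaTable,
    max_pop_frac: float = 0.5,
    max_time_frac: float = 0.5,
    n_sim: int = 999,
    seed: int = 0,
    direction: str = "high",
) -> list[ScanCluster]:
    """Cylindrical space-time Poisson scan.

    Candidate cylinders are discs grown around each area centroid over
    nearest-centroid areas up to ``max_pop_frac`` of the total population,
    crossed with contiguous year windows up to ``max_time_frac`` of the
    period. Expectations are indirect person-time standardization
    conditioned on the study total. Secondary clusters share no areas with
    any better-ranked reported cluster.
    """
    if not (0 < max_pop_frac <= 1):
        raise ConfigurationError("max_pop_frac must be in (0, 1]")
    if not (0 < max_time_frac <= 1):
        raise ConfigurationError("max_time_frac must be in (0, 1]")
    n, T = panel.n_areas, panel.n_years
    C = panel.total
    if C == 0:
        return []
    pop = panel.population.astype(float)
    orders, nprefix = _cylinder_candidates(panel, areas, max_pop_frac)
    windows = _year_windows(T, max_time_frac)
    a_idx = np.array([a for a, b in windows])
    b_idx = np.array([b for a, b in windows])
    wlen = (b_idx - a_idx + 1).astype(float)
    total_pt = pop.sum() * T

    def scan_counts(counts: np.ndarray):
        """Return (best_llr, best_centre, best_prefix, best_window, llr arrays)."""
        best = (0.0, -1, 0, 0)
        per_centre = []
        for i in range(n):
            order, m = orders[i], nprefix[i]
            sub = counts[order[:m]]  # (m, T)
            cum_area = np.cumsum(sub, axis=0, dtype=float)  # prefix over areas
            pref = np.concatenate(
                [np.zeros((m, 1)), np.cumsum(cum_area, axis=1)], axis=1
            )
            obs = pref[:, b_idx + 1] - pref[:, a_idx]  # (m, n_windows)
            cpop = np.cumsum(pop[order[:m]])
            e = C * (cpop[:, None] * wlen[None, :]) / total_pt
            llr = poisson_llr(obs, e, C, direction)
            per_centre.append((llr, obs, e))
            j = int(np.argmax(llr))
            val = float(llr.ravel()[j])
            if val > best[0]:
                best = (val, i, j // len(windows), j % len(windows))
        return best, per_centre

    obs_best, per_centre = scan_counts(panel.counts)

    # rank all candidates, greedy non-overlap by area membership
    cand = []
    for i in range(n):
        llr, obs, e = per_centre[i]
        m = llr.shape[0]
        top = np.argsort(-llr, axis=None, kind="stable")[: 5 * (m + len(windows))]
        for j in top:
            if llr.ravel()[j] <= 0:
                break
            pi, wi = divmod(int(j), len(windows))
            cand.append(
                (
                    float(llr[pi, wi]),
                    frozenset(orders[i][: pi + 1].tolist()),
                    windows[wi],
                    float(obs[pi, wi]),
                    float(e[pi, wi]),
                )
            )
    cand.sort(key=lambda t: (-t[0], sorted(t[1]), t[2]))
    clusters: list[ScanCluster] = []
    used_areas: set[int] = set()
    seen: set = set()
    for llr_v, members, (a, b), o_v, e_v in cand:
        key = (members, (a, b))
        if key in seen:
            continue
        seen.add(key)
        if members & used_areas:
            continue
        used_areas |= members
        clusters.append(
            ScanCluster(
                member_areas=tuple(sorted(members)),
                year_window=(int(panel.years[a]), int(panel.years[b])),
                O=o_v,
                E=e_v,
                LLR=llr_v,
                C=float(C),
                rank=len(clusters) + 1,
            )
        )
        if len(clusters) >= 10:
            break
    if not clusters:
        return []

    if n_sim > 0:
        rng = np.random.default_rng(seed)
        cell_p = (pop[:, None] * np.ones(T)[None, :] / total_pt).ravel()
        max_llr = np.empty(n_sim)
        for s in range(n_sim):
            sim = rng.multinomial(C, cell_p).reshape(n, T)
            best, _ = _scan_max_only(sim, orders, nprefix, pop, a_idx, b_idx, wlen, C, total_pt, direction)
            max_llr[s] = best
        for cl in clusters:
            cl.p = float((1 + np.sum(max_llr >= cl.LLR)) / (n_sim + 1))
    return clusters


def _scan_max_only(counts, orders, nprefix, pop, a_idx, b_idx, wlen, C, total_pt, direction):
    """Maximum LLR over all cylinders for one (replicate) count matrix."""
    best = 0.0
    for i in range(len(orders)):
        order, m = orders[i], nprefix[i]
        sub = counts[order[:m]]
        cum_area = np.cumsum(sub, axis=0, dtype=float)
        pref = np.concatenate([np.zeros((m, 1)), np.cumsum(cum_area, axis=1)], axis=1)
        obs = pref[:, b_idx + 1] - pref[:, a_idx]
        cpop = np.cumsum(pop[order[:m]])
        e = C * (cpop[:, None] * wlen[None, :]) / total_pt
        llr = poisson_llr(obs, e, C, direction)
        v = float(llr.max())
        if v > best:
            best = v
    return best, None


def cluster_report(clusters: list[ScanCluster]) -> pd.DataFrame:
    """Tabulate clusters with the conventional reporting vocabulary."""
    rows = []
    for cl in clusters:
        rows.append(
            {
                "rank": cl.rank,
                "areas": ";".join(str(a) for a in cl.member_areas),
                "year_start": cl.year_window[0],
                "year_end": cl.year_window[1],
                "O": cl.O,
                "E": cl.E,
                "OE": cl.OE,
                "RR": cl.RR,
                "LLR": cl.LLR,
                "p": cl.p,
            }
        )
    return pd.DataFrame(rows)
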