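"""Config-driven orchestration of the full analysis.

A single YAML config drives the stage sequence: aggregate -> rates/Jenks
-> KDE -> global/local Moran -> temporal scan -> space-time scan ->
variable-selection funnel (with zero-count-area exclusion) -> residual
Moran -> GWR -> MGWR -> model comparison. Every stage writes a file
artifact and a machine-parseable ``key=value`` log line. One global seed
deterministically derives the per-stage seeds via
``numpy.random.SeedSequence(global_seed).spawn``, so a single integer
reproduces the entire run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping
from shapely.ops import unary_union

from . import autocorr, gwr, kde, rates, scan, screening, synth
from .geo_core import (
    ConfigurationError,
    aggregate_events,
    build_weights,
    read_areas,
    read_events,
    write_areas,
    write_events,
)

logger = logging.getLogger("urbanscan")

_DEFAULTS = {
    "paths": {"areas": None, "events": None, "output": "results"},
    "fields": {"id": "area_id", "population": "population", "year": "year"},
    "study_period": [2012, 2021],
    "rates": {"per": 100000, "ebs": True, "jenks_k": 5},
    "kde": {"cell_size": 250.0, "bandwidth": 3500.0, "kernel": "quartic", "scale": "count"},
    "weights": {"scheme": "queen", "row_standardize": True, "knn_k": 4},
    "lisa": {"n_perm": 999, "alpha": 0.05, "fdr": False},
    "scan": {"max_pop_frac": 0.5, "max_time_frac": 0.5, "n_sim": 199, "direction": "high"},
    "screening": {"alpha": 0.05, "vif_thresh": 7.5, "max_size": 6},
    "gwr": {"convergence_tol": 1.0e-5, "max_iter": 200, "mc_iters": 0},
    "seed": 0,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (flat sections, see ``_DEFAULTS``)."""

    data: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        data = {}
        for section, defaults in _DEFAULTS.items():
            if isinstance(defaults, dict):
                merged = dict(defaults)
                merged.update(raw.get(section, {}) or {})
                data[section] = merged
            else:
                data[section] = raw.get(section, defaults)
        cfg = cls(data=data)
        errors = cfg.validate()
        if errors:
            raise ConfigurationError("; ".join(errors))
        return cfg

    def validate(self) -> list[str]:
        """Collect every schema violation before any computation runs."""
        errors = []
        d = self.data
        for key in ("areas", "events"):
            p = d["paths"].get(key)
            if not p:
                errors.append(f"paths.{key} is required")
            elif not Path(p).exists():
                errors.append(f"paths.{key} does not exist: {p}")
        sp = d["study_period"]
        if not (isinstance(sp, (list, tuple)) and len(sp) == 2 and sp[0] <= sp[1]):
            errors.append("study_period must be [first_year, last_year]")
        if d["kde"]["bandwidth"] <= 0:
            errors.append("kde.bandwidth must be > 0")
        if not (0 < d["scan"]["max_pop_frac"] <= 1):
            errors.append("scan.max_pop_frac must be in (0, 1]")
        if not isinstance(d["seed"], int):
            errors.append("seed must be an integer")
        return errors

    def __getitem__(self, key):
        return self.data[key]


def _stage_seeds(global_seed: int, n: int = 12) -> list[int]:
    """Derive one 31-bit seed per stage from the global seed."""
    children = np.random.SeedSequence(global_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_pipeline(config: PipelineConfig, output_dir=None) -> dict:
    """Execute every stage; returns a dict of in-memory results.

    Each stage writes its artifact under the output directory and appends
    a structured log line. Any stage failure propagates after logging the
    failing stage name.
    """
    out = Path(output_dir or config["paths"]["output"])
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.txt"
    seeds = _stage_seeds(config["seed"])
    results: dict = {}

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                artefacts = fn()
            except Exception:
                with open(log_path, "a") as fh:
                    fh.write(f"ts={time.time():.0f} stage={name} status=failed\n")
                logger.exception("pipeline stage %r failed", name)
                raise
            dt = time.time() - t0
            with open(log_path, "a") as fh:
                fh.write(
                    f"ts={time.time():.0f} stage={name} status=ok wall_s={dt:.2f} "
                    f"artifacts={','.join(artefacts)}\n"
                )
        return wrap

    fields = config["fields"]
    period = tuple(config["study_period"])
    areas = read_areas(config["paths"]["areas"], fields["id"], fields["population"])
    events = read_events(config["paths"]["events"], fields["year"], study_period=period)
    years = range(period[0], period[1] + 1)

    @stage("aggregate")
    def _():
        panel = aggregate_events(events, areas, years)
        results["panel"] = panel
        df = pd.DataFrame(panel.counts, columns=[str(y) for y in panel.years])
        df.insert(0, "area_id", areas.area_id)
        df.to_csv(out / "counts.csv", index=False)
        return ["counts.csv"]

    panel = results["panel"]

    @stage("rates")
    def _():
        cfg = config["rates"]
        rt = rates.eb_smooth(
            panel.area_totals(), panel.population, per=cfg["per"], area_id=areas.area_id
        )
        x = rt.eb_rate if cfg["ebs"] else rt.raw_rate
        labels, breaks = rates.jenks_labels(x, cfg["jenks_k"])
        rt.class_label = labels
        results["rates"] = rt
        rt.to_frame().to_csv(out / "rates.csv", index=False)
        return ["rates.csv"]

    @stage("kde")
    def _():
        cfg = config["kde"]
        grid = kde.kde_surface(
            events, cfg["cell_size"], cfg["bandwidth"], cfg["kernel"], cfg["scale"]
        )
        results["kde"] = grid
        kde.write_ascii_grid(grid, out / "kde.asc")
        return ["kde.asc"]

    wcfg = config["weights"]
    W = build_weights(areas, wcfg["scheme"], wcfg["row_standardize"], wcfg["knn_k"])
    results["weights"] = W
    eb = results["rates"].eb_rate

    @stage("global_moran")
    def _():
        gm = autocorr.global_moran(eb, W)
        results["global_moran"] = gm
        with open(out / "moran_global.json", "w") as fh:
            json.dump(gm.to_dict(), fh, default=float)
        return ["moran_global.json"]

    @stage("local_moran")
    def _():
        cfg = config["lisa"]
        lm = autocorr.local_moran(
            eb, W, n_perm=cfg["n_perm"], seed=seeds[1], alpha=cfg["alpha"], fdr=cfg["fdr"]
        )
        results["local_moran"] = lm
        df = lm.to_frame()
        df.insert(0, "area_id", areas.area_id)
        df.to_csv(out / "lisa.csv", index=False)
        return ["lisa.csv"]

    scfg = config["scan"]

    @stage("temporal_scan")
    def _():
        clusters = scan.temporal_scan(
            panel,
            max_window_frac=scfg["max_time_frac"],
            n_sim=scfg["n_sim"],
            seed=seeds[2],
            direction=scfg["direction"],
        )
        results["temporal_clusters"] = clusters
        scan.cluster_report(clusters).to_csv(out / "scan_temporal.csv", index=False)
        return ["scan_temporal.csv"]

    @stage("spacetime_scan")
    def _():
        clusters = scan.spacetime_scan(
            panel,
            areas,
            max_pop_frac=scfg["max_pop_frac"],
            max_time_frac=scfg["max_time_frac"],
            n_sim=scfg["n_sim"],
            seed=seeds[3],
            direction=scfg["direction"],
        )
        results["spacetime_clusters"] = clusters
        scan.cluster_report(clusters).to_csv(out / "scan_spacetime.csv", index=False)
        feats = []
        for cl in clusters:
            union = unary_union([areas.geometry[i] for i in cl.member_areas])
            feats.append(
                {
                    "type": "Feature",
                    "geometry": mapping(union),
                    "properties": {
                        "rank": cl.rank,
                        "RR": cl.RR if np.isfinite(cl.RR) else None,
                        "LLR": cl.LLR,
                        "p": cl.p,
                    },
                }
            )
        with open(out / "clusters.geojson", "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh, default=float)
        return ["scan_spacetime.csv", "clusters.geojson"]

    # regression block operates on non-zero-count areas
    areas_nz, panel_nz, removed = screening.exclude_zero_count_areas(areas, panel)
    rt_nz = rates.eb_smooth(
        panel_nz.area_totals(), panel_nz.population,
        per=config["rates"]["per"], area_id=areas_nz.area_id,
    )
    y = rt_nz.eb_rate
    X = areas_nz.covariates.select_dtypes("number")
    rcfg = config["screening"]

    @stage("screening")
    def _():
        report, ols = screening.run_funnel(
            X, y, alpha=rcfg["alpha"], vif_thresh=rcfg["vif_thresh"], max_size=rcfg["max_size"]
        )
        if ols is None:
            raise ConfigurationError("variable-selection funnel retained no variables")
        results["screening"] = report
        results["ols"] = ols
        results["excluded_areas"] = removed
        report.table.to_csv(out / "screening.csv", index=False)
        with open(out / "ols.json", "w") as fh:
            json.dump({"excluded_zero_count_areas": removed, **ols.to_dict()}, fh, default=float)
        return ["screening.csv", "ols.json"]

    W_nz = build_weights(areas_nz, wcfg["scheme"], wcfg["row_standardize"], wcfg["knn_k"])

    @stage("residual_moran")
    def _():
        rm = autocorr.residual_moran(results["ols"].residuals, W_nz)
        results["residual_moran"] = rm
        with open(out / "residual_moran.json", "w") as fh:
            json.dump(rm.to_dict(), fh, default=float)
        return ["residual_moran.json"]

    gcfg = config["gwr"]
    final_vars = results["ols"].names
    Xf = X[final_vars].apply(lambda c: (c - c.mean()) / c.std(ddof=0))
    yz = (y - y.mean()) / y.std(ddof=0)
    coords = areas_nz.centroids

    @stage("gwr")
    def _():
        fit = gwr.fit_gwr(Xf, yz, coords, alpha=rcfg["alpha"])
        results["gwr"] = fit
        df = fit.to_frame()
        df.insert(0, "area_id", areas_nz.area_id)
        df.to_csv(out / "gwr.csv", index=False)
        with open(out / "gwr_diagnostics.json", "w") as fh:
            json.dump(fit.diagnostics(), fh, default=float)
        return ["gwr.csv", "gwr_diagnostics.json"]

    @stage("mgwr")
    def _():
        fit = gwr.fit_mgwr(
            Xf, yz, coords,
            convergence_tol=gcfg["convergence_tol"],
            max_iter=gcfg["max_iter"],
            alpha=rcfg["alpha"],
        )
        if gcfg["mc_iters"]:
            fit.mc_pseudo_p = gwr.monte_carlo_variability(
                fit, Xf, yz, coords, n_iter=gcfg["mc_iters"], seed=seeds[4]
            )
        results["mgwr"] = fit
        df = fit.to_frame()
        df.insert(0, "area_id", areas_nz.area_id)
        df.to_csv(out / "mgwr.csv", index=False)
        diag = fit.diagnostics()
        diag["monte_carlo_pseudo_p"] = fit.mc_pseudo_p
        with open(out / "mgwr_diagnostics.json", "w") as fh:
            json.dump(diag, fh, default=float)
        return ["mgwr.csv", "mgwr_diagnostics.json"]

    @stage("model_comparison")
    def _():
        cmp = gwr.model_comparison(results["ols"], results["gwr"], results["mgwr"])
        results["comparison"] = cmp
        cmp.to_csv(out / "model_comparison.csv", index=False)
        return ["model_comparison.csv"]

    return results


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def make_fixture(out_dir, preset: str = "paper-scale", seed: int = 0) -> dict:
    """Write a complete synthetic input set (areas.geojson, events.csv,
    config.yaml, truth.json).

    ``paper-scale``: 12x12 lattice (1 km cells), 10 years, ~700 events,
    25 candidate covariates of which 4 truly drive the rate, 2 implanted
    space-time cylinders. ``tiny``: 4x4 lattice, 3 years, for quick runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if preset == "paper-scale":
        # base_rate calibrated so the expected event total is ~700 (the
        # motivating study's scale: ~2.8M population, 10 years, ~2.4/100k/yr)
        spec = synth.SimulationSpec(nx=12, ny=12, years=10, seed=seed, base_rate=1.66e-5)
        n_noise = 21
        range_m = 4000.0
        clusters = [
            synth.ClusterSpec(centre=(303_500.0, 4_803_500.0), radius=1800.0,
                              year_start=2015, year_end=2019, rr=3.0),
            synth.ClusterSpec(centre=(309_500.0, 4_809_500.0), radius=1500.0,
                              year_start=2018, year_end=2021, rr=2.4),
        ]
    elif preset == "tiny":
        spec = synth.SimulationSpec(nx=4, ny=4, years=3, seed=seed,
                                    pop_range=(10_000, 30_000), base_rate=2.0e-4)
        n_noise = 4
        range_m = 1500.0
        clusters = []
    else:
        raise ConfigurationError(f"unknown preset {preset!r}")
    spec.clusters = clusters
    areas = synth.make_lattice(spec)
    active = {
        "population_density": synth.SurfaceSpec("constant", value=-0.25),
        "material_deprivation": synth.SurfaceSpec(
            "hotspot", centre=(float(areas.centroids[:, 0].min()), float(areas.centroids[:, 1].max())),
            range_m=5000.0, amplitude=0.45, base=0.05,
        ),
        "commercial_density": synth.SurfaceSpec("gradient", direction=0.6, low=-0.1, high=0.5),
        "large_buildings": synth.SurfaceSpec("constant", value=0.4),
    }
    names = list(active) + [f"noise_{i:02d}" for i in range(n_noise)]
    synth.simulate_covariates(areas, names, range_m=range_m, seed=seed + 10)
    spec.coef_surfaces = active
    panel = synth.simulate_counts(areas, spec)
    events = synth.scatter_points(panel, areas, seed=seed + 20)

    write_areas(areas, out / "areas.geojson")
    write_events(events, out / "events.csv")
    config = {
        "paths": {
            "areas": str(out / "areas.geojson"),
            "events": str(out / "events.csv"),
            "output": str(out / "results"),
        },
        "study_period": [spec.first_year, spec.first_year + spec.years - 1],
        "seed": seed,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh)
    truth = {
        "preset": preset,
        "seed": seed,
        "total_events": panel.total,
        "clusters": [
            {
                "areas": np.flatnonzero(c.member_mask(areas.centroids)).tolist(),
                "years": [c.year_start, c.year_end],
                "rr": c.rr,
            }
            for c in clusters
        ],
        "active_covariates": list(active),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh)
    return {"areas": areas, "panel": panel, "events": events, "truth": truth,
            "config": config, "spec": spec}
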