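"""End-to-end experiment driver.

Ties the modules into the full workflow — synthesize or load a cohort of
tumor sections, solve each to a stationary oxygenation map, quantify
hypoxia by area and by virtual electrode, run the variance analyses, and
evaluate radiation response — writing a reproducible bundle of CSV/JSON
outputs.  Identical configuration and master seed give byte-identical
outputs (CSV floats are rounded to 10 significant digits before writing).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .grid import GridGeometry, VascularDomain, load_domain_dir
from .synth import SynthParams, cohort_params, generate_domain
from .solver import SolverParams, solve_to_stationary_hypoxia, SolveResult
from .hypoxia import HypoxiaReport, hypoxic_area_fraction, hypoxic_mask, spatial_agreement
from .electrode import make_plan, sample, hp_from_readings
from .variance import variance_vs_tracks, strategy_method_variance

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "derive_seed"]

log = logging.getLogger("oxymap")


def derive_seed(master_seed: int, module: str, index: int = 0) -> int:
    """Deterministic per-module, per-tumor seed below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{module}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class ExperimentConfig:
    """Serializable description of one full experiment."""

    geometry: GridGeometry = field(default_factory=GridGeometry)
    solver: SolverParams = field(default_factory=SolverParams)
    synth_base: SynthParams = field(default_factory=SynthParams)
    input_dirs: list[str] | None = None  # load instead of synthesize
    n_tumors: int = 8
    thresholds: tuple[float, ...] = (2.5, 5.0, 10.0)
    strategies: tuple[str, ...] = ("uniform", "random", "half_radial", "full_radial")
    n_tracks: int = 6
    max_tracks: int = 8
    n_readings: int = 25
    replicates: int = 3
    doses: tuple[float, ...] = tuple(np.arange(0.0, 10.5, 0.5))
    master_seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        raw = json.loads(text)
        raw["geometry"] = GridGeometry(**raw["geometry"])
        raw["solver"] = SolverParams(**raw["solver"])
        raw["synth_base"] = SynthParams(**raw["synth_base"])
        for key in ("thresholds", "strategies", "doses"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ExperimentResult:
    domains: list[VascularDomain]
    solves: list[SolveResult]
    reports: list[HypoxiaReport]
    variance_tables: dict[str, pd.DataFrame]
    method_variance: dict[str, float]
    radiation: pd.DataFrame
    outdir: Path | None = None


def _round_sig(df: pd.DataFrame) -> pd.DataFrame:
    def r(v):
        if isinstance(v, float):
            return float(f"{v:.10g}")
        return v

    return df.map(r)


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    _round_sig(df).to_csv(path, index=index, float_format="%.10g")


def build_cohort(config: ExperimentConfig) -> list[VascularDomain]:
    if config.input_dirs:
        return [load_domain_dir(p) for p in config.input_dirs]
    params = cohort_params(
        config.n_tumors,
        seed=derive_seed(config.master_seed, "synth"),
        base=config.synth_base,
    )
    return [generate_domain(p, config.geometry) for p in params]


def run_experiment(config: ExperimentConfig, outdir: str | Path | None = None) -> ExperimentResult:
    """Run the full workflow and (optionally) write the output bundle."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    domains = build_cohort(config)
    log.info("cohort of %d tumors ready", len(domains))

    solves: list[SolveResult] = []
    for i, dom in enumerate(domains):
        res = solve_to_stationary_hypoxia(dom, config.solver)
        solves.append(res)
        log.info("tumor %d converged=%s steps=%d", i, res.converged, res.n_steps)
        if out is not None:
            _write_csv(res.trace, out / f"trace_tumor{i}.csv")

    primary = config.strategies[0] if config.strategies else None
    reports: list[HypoxiaReport] = []
    for i, (dom, res) in enumerate(zip(domains, solves)):
        K = res.K
        hp_area = {t: hypoxic_area_fraction(K, dom.tumor_mask, t) for t in config.thresholds}
        hp_elec = {}
        if primary is not None:
            plan = make_plan(
                primary, config.n_tracks, dom,
                seed=derive_seed(config.master_seed, "probe", i),
                n_readings=config.n_readings,
            )
            rs = sample(plan, K, dom.geometry, tumor_mask=dom.tumor_mask)
            hp_elec = dict(hp_from_readings(rs, float(K.max()), config.thresholds))
        agreement = {}
        if dom.hypoxia_reference_mask is not None:
            for t in config.thresholds:
                sim = hypoxic_mask(K, dom.tumor_mask, t)
                agreement[t] = spatial_agreement(sim, dom.hypoxia_reference_mask, dom.tumor_mask)
        report = HypoxiaReport(hp_area, hp_elec, agreement)
        reports.append(report)
        if out is not None:
            (out / f"hypoxia_tumor{i}.json").write_text(
                json.dumps(report.to_dict(), indent=2, sort_keys=True)
            )

    fields = [(dom, res.K) for dom, res in zip(domains, solves)]
    variance_tables: dict[str, pd.DataFrame] = {}
    method_variance: dict[str, float] = {}
    if config.strategies:
        for strat in config.strategies:
            tbl = variance_vs_tracks(
                fields, strat, config.max_tracks,
                n_readings=config.n_readings,
                replicates=config.replicates,
                seed=derive_seed(config.master_seed, "variance"),
            )
            variance_tables[strat] = tbl
            if out is not None:
                _write_csv(tbl, out / f"variance_{strat}.csv")
        method_variance = strategy_method_variance(
            fields, config.strategies,
            n_tracks=config.n_tracks, n_readings=config.n_readings,
            replicates=config.replicates,
            seed=derive_seed(config.master_seed, "methods"),
        )
        if out is not None:
            (out / "method_variance.json").write_text(
                json.dumps(method_variance, indent=2, sort_keys=True)
            )

    from .radiation import scenario_curves

    radiation = scenario_curves(solves[0].K, domains[0].tumor_mask, config.doses)
    if out is not None:
        _write_csv(radiation.reset_index(), out / "radiation.csv")
        manifest = {
            "oxymap_version": __version__,
            "master_seed": config.master_seed,
            "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
            "n_tumors": len(domains),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        (out / "config.json").write_text(config.to_json())

    return ExperimentResult(domains, solves, reports, variance_tables, method_variance,
                            radiation, out)
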