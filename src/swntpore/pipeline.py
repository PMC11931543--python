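"""End-to-end pipeline: simulate -> detect -> kinetics -> mobility -> report.

A :class:`RunConfig` (YAML on disk) declares the device geometry, trace
rendering parameters, analysis options, and a list of experimental
conditions, each an (ion, pH) pair with transport parameters and a voltage
list.  :func:`run_pipeline` produces one summary row per (ion, pH, V) and
per-condition mobility estimates, writing event TSVs, kinetics JSON, a
mobility TSV and the summary table.  Every stage is seeded from one root
seed, so re-running a config reproduces identical numeric output.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import detect as det
from . import io as pio
from . import kinetics as kin
from . import mobility as mob
from . import simulate as sim
from .core import (
    DeviceGeometry,
    GroundTruthEvent,
    SwntPoreError,
    TraceConfig,
    TransportParams,
)

__all__ = ["ConditionConfig", "RunConfig", "run_pipeline", "make_fixtures"]

logger = logging.getLogger("swntpore")


@dataclass(frozen=True)
class ConditionConfig:
    """One experimental condition: an ion at a pH, scanned over voltages."""

    ion: str
    ph: float
    mobility: float  # intrinsic mobility mu0, m^2/Vs
    voltages: tuple[float, ...]
    k_ads: float = 0.0
    k_des: float = 1.0
    threshold_voltage: float = 0.0
    entry_rate: float = 5.0
    pbc_per_volt: float = 30.0


@dataclass(frozen=True)
class RunConfig:
    """Fully seeded description of a pipeline run."""

    conditions: tuple[ConditionConfig, ...]
    geometry: DeviceGeometry = field(
        default_factory=lambda: DeviceGeometry(1.1e-3, 1.01e-9)
    )
    sampling_rate: float = 250_000.0
    duration: float = 10.0
    baseline_current: float = 1000.0
    noise_sd: float = 2.0
    filter_points: int = 99
    min_dwell_samples: int = 3
    n_boot: int = 500
    tail_factor: float = 4.0
    seed: int = 0
    output_dir: str = "swntpore_out"
    save_traces: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        geo = raw.get("geometry", {})
        trace = raw.get("trace", {})
        analysis = raw.get("analysis", {})
        conditions = tuple(
            ConditionConfig(
                ion=c["ion"],
                ph=float(c["ph"]),
                mobility=float(c["mobility_m2_per_vs"]),
                voltages=tuple(float(v) for v in c["voltages_v"]),
                k_ads=float(c.get("k_ads", 0.0)),
                k_des=float(c.get("k_des", 1.0)),
                threshold_voltage=float(c.get("threshold_v", 0.0)),
                entry_rate=float(c.get("entry_rate_hz", 5.0)),
                pbc_per_volt=float(c.get("pbc_pa_per_v", 30.0)),
            )
            for c in raw["conditions"]
        )
        return cls(
            conditions=conditions,
            geometry=DeviceGeometry(
                length=float(geo.get("length_m", 1.1e-3)),
                diameter=float(geo.get("diameter_m", 1.01e-9)),
            ),
            sampling_rate=float(trace.get("sampling_rate_hz", 250_000.0)),
            duration=float(trace.get("duration_s", 10.0)),
            baseline_current=float(trace.get("baseline_pa", 1000.0)),
            noise_sd=float(trace.get("noise_sd_pa", 2.0)),
            filter_points=int(analysis.get("filter_points", 99)),
            min_dwell_samples=int(analysis.get("min_dwell_samples", 3)),
            n_boot=int(analysis.get("n_boot", 500)),
            tail_factor=float(analysis.get("tail_factor", 4.0)),
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "swntpore_out")),
            save_traces=bool(raw.get("save_traces", False)),
        )


def _sub_seed(root: int, *key: int) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    return int(np.random.SeedSequence([root, *key]).generate_state(1)[0] % (2**31))


def _analyze_one_trace(config: RunConfig, cond: ConditionConfig, voltage: float,
                       seed: int):
    """Simulate and idealize one (condition, voltage) trace."""
    params = TransportParams(
        mobility_intrinsic=cond.mobility,
        voltage=voltage,
        k_ads=cond.k_ads,
        k_des=cond.k_des,
        threshold_voltage=cond.threshold_voltage,
        entry_rate=cond.entry_rate,
    )
    tcfg = TraceConfig(
        duration=config.duration,
        baseline_current=config.baseline_current,
        pbc_depth=sim.pbc_voltage_model(cond.pbc_per_volt, voltage)
        if voltage > 0
        else config.baseline_current * 0.03,
        sampling_rate=config.sampling_rate,
        noise_sd=config.noise_sd,
        seed=seed,
    )
    trace, truth = sim.simulate_trace(config.geometry, params, tcfg)
    trace.metadata.update({"ion": cond.ion, "ph": cond.ph})
    filtered = det.boxcar_filter(trace, config.filter_points)
    table = None
    levels = None
    if truth:
        hist = det.current_histogram(filtered)
        levels = det.find_two_states(hist)
        table = det.detect_events(
            filtered,
            levels,
            min_dwell_samples=config.min_dwell_samples,
            edge_margin=config.filter_points // 2,
            raw_trace=trace,
        )
    return trace, filtered, levels, table


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run every condition of a config; return the summary table.

    Stage failures are logged and recorded per row; remaining conditions
    still run.  Artifacts (event TSVs, kinetics JSON, mobility TSV,
    summary TSV) land under ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows: list[dict[str, Any]] = []
    mobility_rows: list[dict[str, Any]] = []
    kinetics_payload: dict[str, Any] = {}

    for ci, cond in enumerate(config.conditions):
        logger.info(
            "condition %s pH %.2f: voltages %s, mu0=%.3g, k_ads=%.3g, k_des=%.3g",
            cond.ion, cond.ph, cond.voltages, cond.mobility, cond.k_ads, cond.k_des,
        )
        scan_counts: dict[float, int] = {}
        volt_conditions: list[mob.VoltageCondition] = []
        for vi, voltage in enumerate(sorted(cond.voltages)):
            tag = f"{cond.ion}_ph{cond.ph:g}_v{voltage:g}"
            row: dict[str, Any] = {
                "ion": cond.ion, "ph": cond.ph, "voltage_v": voltage,
                "n_events": 0, "flag": "",
            }
            try:
                seed = _sub_seed(config.seed, ci, vi)
                trace, filtered, levels, table = _analyze_one_trace(
                    config, cond, voltage, seed
                )
                if config.save_traces:
                    pio.write_trace_npz(trace, outdir / f"trace_{tag}.npz")
                n_events = 0 if table is None else len(table)
                scan_counts[voltage] = n_events
                row["n_events"] = n_events
                if table is None or n_events == 0:
                    row["flag"] = "no-transport"
                    rows.append(row)
                    continue
                # purity on the raw record: smoothing ramps are filter
                # artifacts, not a third Coulter state
                qc = det.qc_condition(table, trace=trace, levels=levels)
                pio.write_events(table, outdir / f"events_{tag}.tsv")
                dwells = table.dwells
                row.update(
                    baseline_pa=table.baseline,
                    pbc_mean_pa=float(table.pbcs.mean()),
                    mean_dwell_s=float(dwells.mean()),
                    qc_min_events=qc.min_events_ok,
                    qc_purity=qc.purity,
                )
                if not qc.min_events_ok:
                    row["flag"] = "below-50-events"
                volt_conditions.append(
                    mob.VoltageCondition(
                        voltage=voltage,
                        mean_dwell=float(dwells.mean()),
                        sd_dwell=float(dwells.std(ddof=1)) if n_events > 1 else 0.0,
                        n=n_events,
                        pbc_mean=float(table.pbcs.mean()),
                        pbc_sd=float(table.pbcs.std(ddof=1)) if n_events > 1 else 0.0,
                    )
                )
                try:
                    est = kin.estimate_kinetics(
                        kin.DwellSample(dwells, {"ion": cond.ion, "ph": cond.ph}),
                        tail_factor=config.tail_factor,
                        n_boot=config.n_boot,
                        seed=_sub_seed(config.seed, ci, vi, 1),
                        allow_small=not qc.min_events_ok,
                    )
                    row.update(
                        t_peak_s=est.t_peak,
                        tail_start_s=est.tail_start,
                        tau_s=est.tau,
                        k_des_per_s=est.k_des.value,
                        k_des_ci_low=est.k_des.ci_low,
                        k_des_ci_high=est.k_des.ci_high,
                        k_ads_per_s=est.k_ads.value,
                        k_ads_ci_low=est.k_ads.ci_low,
                        k_ads_ci_high=est.k_ads.ci_high,
                    )
                    kinetics_payload[tag] = {
                        "ion": cond.ion, "ph": cond.ph, "voltage_v": voltage,
                        "n_events": n_events,
                        "t_peak_s": est.t_peak, "tail_start_s": est.tail_start,
                        "tau_s": est.tau,
                        "k_des_per_s": est.k_des.value,
                        "k_des_ci": [est.k_des.ci_low, est.k_des.ci_high],
                        "k_ads_per_s": est.k_ads.value,
                        "k_ads_ci": [est.k_ads.ci_low, est.k_ads.ci_high],
                    }
                except SwntPoreError as exc:
                    logger.warning("kinetics failed for %s: %s", tag, exc)
                    row["flag"] = (row["flag"] + ";kinetics-failed").lstrip(";")
            except SwntPoreError as exc:
                logger.error("stage failure for %s: %s", tag, exc)
                row["flag"] = f"error:{exc}"
            rows.append(row)

        # condition-level mobility and threshold voltage
        mobility_row: dict[str, Any] = {"ion": cond.ion, "ph": cond.ph}
        if len(scan_counts) >= 2:
            mobility_row["threshold_voltage_v"] = mob.threshold_voltage(scan_counts)
        try:
            if len(volt_conditions) >= 3:
                estimate = mob.mobility_from_regression(volt_conditions,
                                                        config.geometry)
            elif volt_conditions:
                vc = volt_conditions[-1]
                estimate = mob.mobility_single_point(
                    vc.voltage, vc.mean_dwell, config.geometry,
                    sd_dwell=vc.sd_dwell, n=vc.n,
                )
            else:
                estimate = None
                mobility_row["flag"] = "no-transport"
            if estimate is not None:
                mobility_row.update(
                    method=estimate.method,
                    mu_m2_per_vs=estimate.mu,
                    stderr=estimate.stderr,
                    intercept_per_s=estimate.intercept,
                )
        except SwntPoreError as exc:
            logger.error("mobility failed for %s pH %g: %s", cond.ion, cond.ph, exc)
            mobility_row["flag"] = f"error:{exc}"
        mobility_rows.append(mobility_row)

    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False,
                   float_format="%.9g")
    pd.DataFrame(mobility_rows).to_csv(
        outdir / "mobility.tsv", sep="\t", index=False, float_format="%.9g"
    )
    pio.write_json(kinetics_payload, outdir / "kinetics.json")
    logger.info("wrote %d summary rows to %s", len(summary), outdir)
    return summary


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def make_fixtures(seed: int, outdir: str | Path) -> dict[str, Any]:
    """Generate the standard test-fixture bundle and a checksum manifest.

    Fixtures: a noiseless single-event trace, a noisy two-state trace, a
    three-level "leak" trace (blockades at two distinct depths, mimicking
    elastomer-seal transport), and dwell-time samples over the kinetic
    parameter grid k_ads x k_des spanning the experimentally observed
    range.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geometry = DeviceGeometry(1.1e-3, 1.01e-9)
    files: list[Path] = []

    # 1. noiseless single 10 ms, 20 pA event
    cfg = TraceConfig(duration=0.1, baseline_current=1000.0, pbc_depth=20.0,
                      sampling_rate=25_000.0, noise_sd=0.0, seed=seed)
    event = GroundTruthEvent(start=0.04, end=0.05, dwell=0.01, depth=20.0,
                             n_adsorptions=0)
    trace = sim.render_trace([event], cfg, {"kind": "noiseless_single_event"})
    files.append(pio.write_trace(trace, outdir / "noiseless_single_event.csv"))

    # 2. noisy two-state trace
    params = TransportParams(mobility_intrinsic=2.76e-5, voltage=1.0,
                             k_ads=27.5, k_des=53.6, entry_rate=5.0)
    cfg2 = TraceConfig(duration=4.0, baseline_current=1000.0, pbc_depth=30.0,
                       sampling_rate=25_000.0, noise_sd=2.0,
                       seed=_sub_seed(seed, 2))
    trace2, _ = sim.simulate_trace(geometry, params, cfg2)
    trace2.metadata["kind"] = "two_state_noisy"
    files.append(pio.write_trace(trace2, outdir / "two_state_noisy.csv"))

    # 3. three-level leak trace: alternating blockade depths
    cfg3 = TraceConfig(duration=4.0, baseline_current=1000.0, pbc_depth=30.0,
                       sampling_rate=25_000.0, noise_sd=2.0,
                       seed=_sub_seed(seed, 3))
    rng = np.random.default_rng(_sub_seed(seed, 3, 1))
    events = []
    t = 0.05
    depth_cycle = [30.0, 60.0]
    i = 0
    while t + 0.06 < cfg3.duration:
        dwell = float(rng.uniform(0.01, 0.04))
        events.append(GroundTruthEvent(start=t, end=t + dwell, dwell=dwell,
                                       depth=depth_cycle[i % 2], n_adsorptions=0))
        t += dwell + float(rng.uniform(0.05, 0.15))
        i += 1
    trace3 = sim.render_trace(events, cfg3, {"kind": "leak_three_level"})
    files.append(pio.write_trace(trace3, outdir / "leak_three_level.csv"))

    # 4. dwell-time grid spanning the observed kinetic range
    grid = {"k_ads": [10.0, 50.0, 250.0], "k_des": [20.0, 100.0, 220.0]}
    t_drift = 0.010
    mu = geometry.length**2 / t_drift  # mobility giving 10 ms drift at 1 V
    for gi, k_ads in enumerate(grid["k_ads"]):
        for gj, k_des in enumerate(grid["k_des"]):
            p = TransportParams(mobility_intrinsic=mu, voltage=1.0,
                                k_ads=k_ads, k_des=k_des)
            dwells = sim.sample_dwell_times(
                geometry, p, 5000, _sub_seed(seed, 4, gi, gj)
            )
            path = outdir / f"dwells_kads{k_ads:g}_kdes{k_des:g}.tsv"
            pd.DataFrame({"dwell_s": dwells}).to_csv(
                path, sep="\t", index=False, float_format="%.9g"
            )
            files.append(path)

    manifest = {
        "seed": seed,
        "grid": grid,
        "t_drift_s": t_drift,
        "files": {f.name: _sha256(f) for f in files},
    }
    pio.write_json(manifest, outdir / "manifest.json")
    return manifest
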