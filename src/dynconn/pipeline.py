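"""End-to-end orchestration: simulate -> connect -> detect -> measure -> compare.

A run writes its artifacts into a run directory with a fixed layout and a
JSON manifest (config echo, seeds, per-stage wall times).  A master seed
fully determines every stochastic stage, so re-running the same config
reproduces every numeric output.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import aggregate_changes, codings_to_frame, transition_statistics
from .communities import MultilayerParams, repeat_detection
from .connectivity import (
    MONTAGE_1020,
    DEFAULT_BANDS,
    BandDefinition,
    ConnectivitySeries,
    connectivity_series,
    temporal_cov,
)
from .metrics import allegiance, ensemble_mean, flexibility, intermittence
from .stats import cov_comparison, flexibility_comparison, intermittence_curve
from .synth import simulate_cohort, simulate_questionnaires, write_cohort

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Pipeline settings.  Defaults reproduce the reference operating point
    (five bands, 10-s windows, gamma=1.1364/omega=0.5, 100-run ensembles,
    10,000-draw bootstraps, 1,000 x 30 CoV replicas); the simulation block is
    deliberately small so the default run finishes on one CPU."""

    # analysis
    bands: tuple = DEFAULT_BANDS
    window_seconds: float = 10.0
    gamma: float = 1.1364
    omega: float = 0.5
    n_iterations: int = 100
    bootstrap_n: int = 10_000
    cov_replicas: int = 1000
    cov_replica_size: int = 30
    threshold_step: float = 0.01
    min_pairs: int = 10
    seed: int = 0
    # simulation block
    n_subjects_per_group: int = 6
    n_nodes: int = 20
    n_layers: int = 20
    n_communities: int = 2
    rate: float = 128.0
    sim_window_seconds: float = 2.0
    sim_band: tuple = (8.0, 13.0)
    coupling: float = 0.9
    noise_sd: float = 0.5
    switch_rate_nc: float = 0.3
    switch_rate_c: float = 0.1
    switch_rate_in_person_scale: float = 0.5
    n_questionnaire_subjects: int = 132
    marginal_no_change_sm: int = 75
    marginal_no_change_ip: int = 97

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "bands" in raw:
            raw["bands"] = tuple(
                BandDefinition(b["name"], b["low"], b["high"]) for b in raw["bands"]
            )
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["bands"] = [
            {"name": b.name, "low": b.low, "high": b.high} for b in self.bands
        ]
        return d


def _analysis_band(config: RunConfig) -> BandDefinition:
    """Band used on simulated sessions: the configured planting band."""
    low, high = config.sim_band
    return BandDefinition("planted", float(low), float(high))


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run all stages on simulated cohorts and write the artifact tree."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_jsonable(),
        "stages": {},
    }
    timings = manifest["stages"]

    def _stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = {"seconds": round(time.perf_counter() - self.t0, 3)}
                if exc_type is not None:
                    timings[name]["failed"] = True
                    manifest["failed_stage"] = name
                    (outdir / "manifest.json").write_text(
                        json.dumps(manifest, indent=2)
                    )
                return False

        return _Timer()

    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0]) for name, s in zip(
        ("cohort_nc", "cohort_c", "questionnaire", "stats"), ss.spawn(4))}
    manifest["seeds"] = seeds

    # -- simulate ------------------------------------------------------------
    with _stage("simulate"):
        cohorts = {}
        for group, seed_key, rate_sm in (
            ("NC", "cohort_nc", config.switch_rate_nc),
            ("C", "cohort_c", config.switch_rate_c),
        ):
            cohorts[group] = simulate_cohort(
                group=group,
                n_subjects=config.n_subjects_per_group,
                switch_rate=rate_sm,
                switch_rate_by_context={
                    "social_media": rate_sm,
                    "in_person": rate_sm * config.switch_rate_in_person_scale,
                },
                n_nodes=config.n_nodes,
                n_layers=config.n_layers,
                n_communities=config.n_communities,
                rate=config.rate,
                window_seconds=config.sim_window_seconds,
                band=tuple(config.sim_band),
                coupling=config.coupling,
                noise_sd=config.noise_sd,
                seed=seeds[seed_key],
            )
            write_cohort(cohorts[group], outdir / "sessions",
                         params=config.to_jsonable())
        records = simulate_questionnaires(
            config.n_questionnaire_subjects,
            {
                "no_change_after_sm": config.marginal_no_change_sm,
                "no_change_after_inperson": config.marginal_no_change_ip,
            },
            seed=seeds["questionnaire"],
        )

    # -- behavior ------------------------------------------------------------
    with _stage("behavior"):
        codings = aggregate_changes(records)
        codings_to_frame(codings).to_csv(outdir / "change_codings.tsv",
                                         sep="\t", index=False)
        stats = transition_statistics(codings)
        (outdir / "transition_statistics.json").write_text(json.dumps(
            {k: v for k, v in stats.items() if not k.endswith("_exact")},
            indent=2,
        ))

    # -- connect -------------------------------------------------------------
    band = _analysis_band(config)
    with _stage("connect"):
        series: dict[tuple[str, str, int], ConnectivitySeries] = {}
        for group, cohort in cohorts.items():
            counters: dict[str, int] = {}
            for rec, sched, ctx in cohort.sessions:
                idx = counters.get(ctx, 0)
                counters[ctx] = idx + 1
                (cs,) = connectivity_series(rec, band, config.sim_window_seconds)
                series[(group, ctx, idx)] = cs

    # -- detect + metrics ----------------------------------------------------
    params = MultilayerParams(
        gamma=config.gamma, omega=config.omega,
        n_iterations=config.n_iterations, seed=seeds["stats"],
    )
    with _stage("detect_metrics"):
        flex_rows = []
        pair_rows = []
        cov_cells: dict[tuple[str, str], list[float]] = {}
        for (group, ctx, idx), cs in series.items():
            ensemble = repeat_detection(cs, params)
            flex = ensemble_mean([flexibility(m) for m in ensemble])
            alle = ensemble_mean([allegiance(m) for m in ensemble])
            inte = ensemble_mean([intermittence(m) for m in ensemble])
            labels = cs.labels or MONTAGE_1020[: cs.n_nodes]
            for s, lab in enumerate(labels):
                flex_rows.append({"group": group, "context": ctx,
                                  "subject": idx, "sensor": lab,
                                  "flexibility": flex.xi[s]})
            iu = np.triu_indices(cs.n_nodes, k=1)
            for a, b in zip(*iu):
                pair_rows.append({
                    "group": group, "context": ctx, "subject": idx,
                    "pair": f"{labels[a]}-{labels[b]}",
                    "allegiance": alle.values[a, b],
                    "intermittence": inte.values[a, b],
                })
            cov = temporal_cov(cs)
            cov_cells.setdefault((group, ctx), []).append(cov.session_mean)
        flex_df = pd.DataFrame(flex_rows)
        pair_df = pd.DataFrame(pair_rows)
        flex_df.to_csv(outdir / "flexibility.tsv", sep="\t", index=False)
        pair_df.to_csv(outdir / "pair_metrics.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"group": g, "context": c, "subject": i, "session_mean_cov": v}
             for (g, c), vals in cov_cells.items() for i, v in enumerate(vals)]
        ).to_csv(outdir / "session_cov.tsv", sep="\t", index=False)

    # -- compare -------------------------------------------------------------
    with _stage("compare"):
        ctx = "social_media"
        sub = flex_df[flex_df.context == ctx]
        piv_nc = sub[sub.group == "NC"].pivot(index="subject", columns="sensor",
                                              values="flexibility")
        piv_c = sub[sub.group == "C"].pivot(index="subject", columns="sensor",
                                            values="flexibility")
        piv_c = piv_c[piv_nc.columns]
        flex_cmp = flexibility_comparison(
            piv_nc.to_numpy(), piv_c.to_numpy(),
            sensor_labels=list(piv_nc.columns),
            n=config.bootstrap_n, seed=seeds["stats"],
        )
        flex_cmp.to_csv(outdir / "flexibility_comparison.tsv", sep="\t", index=False)

        psub = pair_df[pair_df.context == ctx]
        thresholds = np.round(
            np.arange(0.0, 1.0 + config.threshold_step / 2, config.threshold_step), 10
        )
        curve = intermittence_curve(
            psub[psub.group == "NC"].allegiance.to_numpy(),
            psub[psub.group == "NC"].intermittence.to_numpy(),
            psub[psub.group == "C"].allegiance.to_numpy(),
            psub[psub.group == "C"].intermittence.to_numpy(),
            thresholds=thresholds,
            n=config.bootstrap_n, seed=seeds["stats"] + 1,
            min_pairs=config.min_pairs,
        )
        pd.DataFrame({
            "threshold": curve.thresholds,
            "difference": curve.difference,
            "ci_low": curve.ci_low,
            "ci_high": curve.ci_high,
            "p_value": curve.p_values,
            "defined": curve.defined,
            "significant": curve.significant,
        }).to_csv(outdir / "intermittence_curve.tsv", sep="\t", index=False)

        cov_df = cov_comparison(
            {k: np.asarray(v) for k, v in cov_cells.items()},
            n_replicas=config.cov_replicas,
            replica_size=config.cov_replica_size,
            seed=seeds["stats"] + 2,
        )
        cov_df.to_csv(outdir / "cov_comparison.tsv", sep="\t", index=False)
        (outdir / "summary.json").write_text(json.dumps({
            "significant_fraction_pct": curve.significant_fraction,
            "n_sensors_flagged": int(flex_cmp.significant.sum()),
            "n_sensors_tested": int(len(flex_cmp)),
            "transition_statistics": {
                k: v for k, v in stats.items() if not k.endswith("_exact")
            },
        }, indent=2))

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def validate_inputs(paths) -> list[dict]:
    """Validate EDF headers and questionnaire tables.

    Returns a machine-readable issue list; entries carry ``severity``
    ("fatal" | "warning"), ``path`` and ``message``.  An empty list means
    everything checked out.
    """
    from .behavior import QUESTIONNAIRE_COLUMNS
    from .edf import read_edf_header

    issues: list[dict] = []
    for p in map(Path, paths):
        if not p.exists():
            issues.append({"severity": "fatal", "path": str(p),
                           "message": "file does not exist"})
            continue
        if p.suffix.lower() == ".edf":
            try:
                hdr = read_edf_header(p)
            except Exception as exc:  # unreadable header is fatal
                issues.append({"severity": "fatal", "path": str(p),
                               "message": f"unreadable EDF header: {exc}"})
                continue
            if hdr["rate"] <= 0:
                issues.append({"severity": "fatal", "path": str(p),
                               "message": "non-positive sampling rate in header"})
            unknown = [l for l in hdr["labels"] if l not in MONTAGE_1020]
            if unknown:
                issues.append({"severity": "warning", "path": str(p),
                               "message": f"labels not in 10-20 montage: {unknown}"})
            missing = [l for l in MONTAGE_1020 if l not in hdr["labels"]]
            if missing:
                issues.append({"severity": "warning", "path": str(p),
                               "message": f"montage sensors missing: {missing}"})
        elif p.suffix.lower() in (".csv", ".tsv"):
            sep = "," if p.suffix.lower() == ".csv" else "\t"
            try:
                frame = pd.read_csv(p, sep=sep, nrows=1)
            except Exception as exc:
                issues.append({"severity": "fatal", "path": str(p),
                               "message": f"unreadable table: {exc}"})
                continue
            missing_cols = set(QUESTIONNAIRE_COLUMNS) - set(frame.columns)
            if missing_cols:
                issues.append({
                    "severity": "warning", "path": str(p),
                    "message": f"missing questionnaire columns: {sorted(missing_cols)}",
                })
        else:
            issues.append({"severity": "warning", "path": str(p),
                           "message": "unrecognized input type"})
    return issues
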