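"""End-to-end orchestration: align -> agreement -> trending -> fluid -> summary.

A run produces a diff-able bundle directory:

    manifest.json             config echo + package version
    dataset.csv               the analysed dataset (when simulated)
    truth.csv                 ground truth (when simulated)
    agreement.csv             one row per (test method, calibration state)
    trending_summary.json     four-quadrant and polar statistics
    trending_points_*.csv     plot-ready per-delta tables
    fluid.csv                 per-subject fluid-challenge table
    fluid_summary.json        responder agreement + correlations
    table2.csv                per-timepoint descriptive summary with
                              baseline-contrast significance markers
    run.log                   structured record of every skip/exclusion

Results are pure functions of (input data, config): re-running with the
same config and seed reproduces every file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .agreement import bland_altman_repeated
from .core import DegenerateStatisticsError, align_pairs, read_measurements
from .fluid import PAIRING_MODES, fluid_analysis
from .simulate import SimulationConfig, export_ground_truth, simulate_study
from .summary import baseline_contrasts, describe
from .trending import (
    compute_deltas,
    four_quadrant_concordance,
    polar_points,
    polar_statistics,
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    input_path: str | None = None
    simulation: SimulationConfig | None = None
    ref_method: str = "td"
    test_methods: tuple[str, ...] = ("pR", "pF")
    calibration_states: tuple[str, ...] = ("precal", "postcal")
    variable: str = "CO"
    four_quadrant_zone: float = 0.75
    polar_zone: float = 0.5
    polar_limit: float = 30.0
    responder_threshold: float = 10.0
    fluid_pairing_modes: tuple[str, ...] = PAIRING_MODES
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.four_quadrant_zone < 0 or self.polar_zone < 0:
            raise ValueError("exclusion zones must be >= 0")
        if self.responder_threshold <= 0:
            raise ValueError("responder threshold must be > 0")


def _manifest(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return {"package": "cocompare", "version": __version__, "config": d}


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis for every (test method, state) combination.

    Returns the summary bundle as a dict and writes the bundle files to
    ``out_dir``. Any stage's degenerate-input error is surfaced with the
    stage name and the offending subset.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_records: list[str] = []
    handler = logging.Handler()
    handler.emit = lambda rec: log_records.append(f"{rec.name}: {rec.getMessage()}")
    pkg_logger = logging.getLogger("cocompare")
    pkg_logger.addHandler(handler)
    old_level = pkg_logger.level
    pkg_logger.setLevel(logging.INFO)

    try:
        if config.input_path is not None:
            dataset = read_measurements(config.input_path)
            simulated = False
        else:
            sim = config.simulation or SimulationConfig()
            if config.seed is not None:
                sim = dataclasses.replace(sim, seed=config.seed)
            dataset, truth = simulate_study(sim)
            dataset.to_csv(out / "dataset.csv")
            export_ground_truth(truth, out / "truth.csv")
            simulated = True

        missing = [m for m in (config.ref_method, *config.test_methods)
                   if m not in dataset.methods()]
        if missing:
            raise DegenerateStatisticsError(
                f"[stage input] method(s) {missing} absent from dataset "
                f"(present: {dataset.methods()})"
            )

        agreement_rows = []
        trending_summary: dict = {}
        for method in config.test_methods:
            for state in config.calibration_states:
                stage = f"{method}/{state}"
                try:
                    pairs = align_pairs(dataset, config.ref_method, method,
                                        config.variable, state)
                    ba = bland_altman_repeated(pairs)
                    agreement_rows.append({
                        "method": method, "calibration_state": state,
                        "n_pairs": ba.n_pairs, "n_subjects": ba.n_subjects,
                        "n_skipped": pairs.n_skipped,
                        "bias": ba.bias, "sd_diff": ba.sd_diff,
                        "loa_lower": ba.loa_lower, "loa_upper": ba.loa_upper,
                        "percentage_error": ba.percentage_error,
                        "within_subject_var": ba.within_subject_var,
                        "between_subject_var": ba.between_subject_var,
                        "simple_fallback": ba.simple_fallback,
                        "clamped_between": ba.clamped_between,
                    })

                    deltas = compute_deltas(pairs, dataset.schedule, state)
                    fq = four_quadrant_concordance(deltas, config.four_quadrant_zone)
                    pts, n_zero = polar_points(deltas)
                    pol = polar_statistics(pts, config.polar_zone, config.polar_limit)
                    trending_summary[f"{method}_{state}"] = {
                        "four_quadrant": dataclasses.asdict(fq),
                        "polar": dataclasses.asdict(pol),
                        "n_zero_change_dropped": n_zero,
                    }

                    rows = []
                    nonzero = [d for d in deltas
                               if not (d.delta_ref == 0 and d.delta_test == 0)]
                    pt_map = dict(zip(
                        (id(d) for d in nonzero), pts,
                    ))
                    for d in deltas:
                        p = pt_map.get(id(d))
                        rows.append({
                            "subject": d.subject_id,
                            "from_timepoint": d.interval[0],
                            "to_timepoint": d.interval[1],
                            "gap": d.gap,
                            "delta_ref": d.delta_ref,
                            "delta_test": d.delta_test,
                            "mean_abs_delta": (abs(d.delta_ref) + abs(d.delta_test)) / 2,
                            "angle": p.angle if p else "",
                            "radius": p.radius if p else "",
                            "reflected": p.reflected if p else "",
                        })
                    pd.DataFrame(rows).to_csv(
                        out / f"trending_points_{method}_{state}.csv", index=False
                    )
                except ValueError as exc:
                    raise type(exc)(f"[stage agreement/trending {stage}] {exc}") from exc

        fluid_rows = []
        fluid_summary: dict = {}
        for method in config.test_methods:
            for mode in config.fluid_pairing_modes:
                try:
                    fr = fluid_analysis(dataset, config.ref_method, method,
                                        config.responder_threshold, mode)
                except DegenerateStatisticsError as exc:
                    log_records.append(f"pipeline: fluid {method}/{mode} skipped: {exc}")
                    continue
                except ValueError as exc:
                    raise type(exc)(f"[stage fluid {method}/{mode}] {exc}") from exc
                fluid_summary[f"{method}_{mode}"] = {
                    "n_agree": fr.n_agree, "n_total": fr.n_total,
                    "n_responders_ref": int(sum(fr.responder_ref)),
                    "n_responders_test": int(sum(fr.responder_test)),
                    "spearman_rho": fr.spearman_rho, "spearman_p": fr.spearman_p,
                    "threshold": fr.threshold,
                }
                for i, subject in enumerate(fr.subjects):
                    fluid_rows.append({
                        "method": method, "pairing_mode": mode, "subject": subject,
                        "delta_sv_pct_ref": fr.delta_pct_ref[i],
                        "delta_sv_pct_test": fr.delta_pct_test[i],
                        "responder_ref": fr.responder_ref[i],
                        "responder_test": fr.responder_test[i],
                    })

        table_rows = []
        methods_states = [(config.ref_method, "na")] + [
            (m, s) for m in config.test_methods for s in config.calibration_states
        ]
        df = dataset.frame
        for method, state in methods_states:
            sel = df[(df["method"] == method) & (df["variable"] == config.variable)
                     & (df["calibration_state"] == state)]
            if sel.empty:
                continue
            try:
                contrasts = baseline_contrasts(dataset, config.variable, method, state)
                sig = {c.timepoint: c.significant for c in contrasts}
            except DegenerateStatisticsError:
                sig = {}
            row = {"method": method, "calibration_state": state}
            for tp in dataset.schedule:
                vals = sel.loc[sel["timepoint"] == tp, "value"]
                if vals.empty:
                    row[tp] = ""
                    continue
                desc = describe(vals.to_numpy())
                row[tp] = desc.formatted() + (" *" if sig.get(tp) else "")
            table_rows.append(row)

        pd.DataFrame(agreement_rows).to_csv(out / "agreement.csv", index=False)
        _json_dump(trending_summary, out / "trending_summary.json")
        pd.DataFrame(fluid_rows).to_csv(out / "fluid.csv", index=False)
        _json_dump(fluid_summary, out / "fluid_summary.json")
        pd.DataFrame(table_rows).to_csv(out / "table2.csv", index=False)
        manifest = _manifest(config)
        manifest["simulated"] = simulated
        _json_dump(manifest, out / "manifest.json")
        (out / "run.log").write_text("".join(line + "\n" for line in log_records))

        return {
            "manifest": manifest,
            "agreement": agreement_rows,
            "trending": trending_summary,
            "fluid": fluid_summary,
        }
    finally:
        pkg_logger.removeHandler(handler)
        pkg_logger.setLevel(old_level)
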