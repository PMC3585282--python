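"""CSV I/O, run configuration and the end-to-end pipeline.

File dialects (UTF-8, '.' decimal, header required; units carried in the
column names to prevent unit drift):

frequency scans
    electrode_id, role, phase_label, frequency_hz, z_real_ohm, z_imag_ohm
timecourses
    electrode_id, frequency_hz, time_s, z_real_ohm, z_imag_ohm

``run_pipeline`` drives the full workflow on a simulated condition:
simulate → fit every pre/post scan → aggregate electrodes per experiment →
paired statistics, writing every artifact with provenance metadata.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ParseError, PipelineError
from .fitting import FitOptions, fit_monolayer
from .model import CONVENTIONS, ComplexSpectrum, ElectrodeGeometry
from .simulate import ExperimentBundle, generate_experiment, preset
from .stats import aggregate_electrodes, anova_oneway, format_afp, ttest
from .timecourse import TimecourseTrace

__all__ = ["read_scan_csv", "write_scan_csv", "read_timecourse_csv",
           "write_timecourse_csv", "RunConfig", "fit_bundle", "run_pipeline"]

SCAN_COLUMNS = ["electrode_id", "role", "phase_label", "frequency_hz",
                "z_real_ohm", "z_imag_ohm"]
TRACE_COLUMNS = ["electrode_id", "frequency_hz", "time_s", "z_real_ohm", "z_imag_ohm"]
_FLOAT_FMT = "%.15g"  # round-trip lossless at 15 significant digits


def _read_table(path, required_columns) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as e:
        raise ParseError(f"{path}: {e}") from e
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    numeric = [c for c in required_columns if c.endswith(("_hz", "_ohm", "_s"))]
    for c in numeric:
        parsed = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[parsed.isna() & df[c].notna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise ParseError(f"{path}: non-numeric {c!r} at line(s) {[i + 2 for i in bad]}")
        if parsed.isna().any():
            raise ParseError(f"{path}: empty {c!r} at line(s) "
                             f"{[i + 2 for i in df.index[parsed.isna()]]}")
        df[c] = parsed
    return df


def read_scan_csv(path) -> list:
    """Read a frequency-scan CSV into a list of :class:`ComplexSpectrum`."""
    df = _read_table(path, SCAN_COLUMNS)
    df["phase_label"] = df["phase_label"].fillna("")
    spectra = []
    for (eid, role, phase), g in df.groupby(["electrode_id", "role", "phase_label"],
                                            sort=False):
        g = g.sort_index()
        try:
            spectra.append(ComplexSpectrum(str(eid), str(role), str(phase),
                                           g["frequency_hz"].to_numpy(),
                                           g["z_real_ohm"].to_numpy(),
                                           g["z_imag_ohm"].to_numpy()))
        except Exception as e:
            raise ParseError(f"{path}: electrode {eid!r} ({role}/{phase}): {e}") from e
    return spectra


def write_scan_csv(path, spectra) -> None:
    rows = []
    for s in spectra:
        for f, re, im in zip(s.frequencies_hz, s.z_real_ohm, s.z_imag_ohm):
            rows.append((s.electrode_id, s.role, s.phase_label, f, re, im))
    pd.DataFrame(rows, columns=SCAN_COLUMNS).to_csv(path, index=False,
                                                    float_format=_FLOAT_FMT)


def read_timecourse_csv(path, stimulus_time_s: float | None = None) -> list:
    """Read a timecourse CSV into a list of :class:`TimecourseTrace`."""
    df = _read_table(path, TRACE_COLUMNS)
    traces = []
    for (eid, fhz), g in df.groupby(["electrode_id", "frequency_hz"], sort=False):
        g = g.sort_values("time_s", kind="stable")
        try:
            traces.append(TimecourseTrace(str(eid), g["time_s"].to_numpy(),
                                          g["z_real_ohm"].to_numpy(),
                                          g["z_imag_ohm"].to_numpy(),
                                          float(fhz), stimulus_time_s))
        except Exception as e:
            raise ParseError(f"{path}: electrode {eid!r}: {e}") from e
    return traces


def write_timecourse_csv(path, traces) -> None:
    rows = []
    for tr in traces:
        for t, re, im in zip(tr.times_s, tr.z_real_ohm, tr.z_imag_ohm):
            rows.append((tr.electrode_id, tr.frequency_hz, t, re, im))
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False,
                                                     float_format=_FLOAT_FMT)


@dataclass
class RunConfig:
    """Configuration of one simulated end-to-end run."""

    scenario: str = "007AM"
    seed: int = 0
    output_dir: str = "ecisfit_run"
    geometry: ElectrodeGeometry = field(default_factory=ElectrodeGeometry)
    fit_options: FitOptions = field(default_factory=FitOptions)
    value_kind: str = "rb"  # which parameter the statistics summarize


def fit_bundle(bundle: ExperimentBundle,
               geometry: ElectrodeGeometry = ElectrodeGeometry(),
               options: FitOptions = FitOptions()) -> pd.DataFrame:
    """Fit every cell scan of a bundle against its experiment's reference."""
    rows = []
    for scan in bundle.cell_scans:
        exp_id = scan.electrode_id.split("_")[0]
        fit = fit_monolayer(scan, bundle.reference_scans[exp_id], geometry, options)
        rows.append(dict(experiment_id=exp_id, electrode_id=scan.electrode_id,
                         phase_label=scan.phase_label,
                         alpha=fit.params.alpha, rb=fit.params.rb, cm=fit.params.cm,
                         rms_relative_residual=fit.rms_relative_residual,
                         converged=fit.converged, qc=";".join(sorted(fit.qc))))
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a condition, fit it, aggregate and report.

    Writes scans, per-electrode fits, per-experiment aggregates, the
    statistics table and provenance metadata under ``config.output_dir``;
    returns the central results in memory.  Deterministic given the seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        scenario = preset(config.scenario, seed=config.seed)
        bundle = generate_experiment(scenario, config.geometry)
    except Exception as e:
        raise PipelineError(f"simulate: {e}") from e

    write_scan_csv(out / "scans.csv",
                   list(bundle.reference_scans.values()) + bundle.cell_scans)
    bundle.ground_truth.to_csv(out / "ground_truth.csv", index=False,
                               float_format=_FLOAT_FMT)

    try:
        fits = fit_bundle(bundle, config.geometry, config.fit_options)
    except Exception as e:
        raise PipelineError(f"fit: {e}") from e
    fits.to_csv(out / "fits.csv", index=False, float_format=_FLOAT_FMT)

    try:
        table = fits.rename(columns={config.value_kind: "value"})[
            ["experiment_id", "phase_label", "electrode_id", "value"]]
        table = table.rename(columns={"phase_label": "condition"})
        agg = aggregate_electrodes(table)
        pre = agg[agg["condition"] == "pre"].sort_values("experiment_id")["mean"].to_numpy()
        post = agg[agg["condition"] == "post"].sort_values("experiment_id")["mean"].to_numpy()
        f_stat, p_val = anova_oneway(pre, post)
        t_res = ttest(post, pre, mode="paired")
        stats = {
            "value_kind": config.value_kind,
            "n_experiments": int(len(pre)),
            "pre_mean": float(np.mean(pre)),
            "post_mean": float(np.mean(post)),
            "post_pre_ratio": float(np.mean(post) / np.mean(pre)),
            "anova": format_afp(f_stat, p_val),
            "anova_f": f_stat, "anova_p": p_val,
            "paired_t": t_res.t, "paired_p": t_res.p, "paired_df": t_res.df,
        }
    except Exception as e:
        raise PipelineError(f"aggregate/report: {e}") from e

    agg.to_csv(out / "aggregates.csv", index=False, float_format=_FLOAT_FMT)
    metadata = {
        "package": "ecisfit", "version": __version__,
        "scenario": config.scenario, "seed": config.seed,
        "window_hz": [config.fit_options.f_min_hz, config.fit_options.f_max_hz],
        "geometry": dataclasses.asdict(config.geometry),
        "conventions": dict(CONVENTIONS),
    }
    (out / "stats.json").write_text(json.dumps(stats, indent=2, sort_keys=True))
    (out / "metadata.json").write_text(json.dumps(metadata, indent=2, sort_keys=True))
    return {"fits": fits, "aggregates": agg, "stats": stats, "metadata": metadata,
            "output_dir": str(out)}
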