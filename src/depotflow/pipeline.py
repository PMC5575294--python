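"""Orchestration: simulate scenarios, analyze stacks, benchmark recovery.

Each entry point is a library function the CLI wraps thinly.  Reports are
tab-delimited tables with a one-line header; every analysis parameter used
is echoed to a run-metadata YAML for provenance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constants as C
from . import quantify, synthetic, transport
from .imaging import FlatFieldSet, ImageStack, average_gain, flat_field_correct, read_stack, register_drift, write_stack

__all__ = ["RunConfig", "run_simulate", "run_analysis", "run_recover"]

log = logging.getLogger("depotflow")


@dataclass
class RunConfig:
    """Analysis parameters for one pipeline run (all defaults documented)."""

    out_dir: Path
    scenario: str | Path | None = None  # preset name or scenario YAML path
    stack_path: Path | None = None
    seed: int | None = None
    n_baseline: int = 1
    window_mm: float = C.DEFAULT_ROI_SIZE_MM
    threshold_fraction: float = 0.1
    epsilon: float = C.DEFAULT_EPSILON
    youngs_modulus_kpa: float = C.DEFAULT_YOUNGS_MODULUS_KPA
    mu_abs_per_mm: float = C.DEFAULT_MU_ABS_PER_MM
    register: bool = True
    tissue_label: str = "subcutaneous"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _dump_metadata(cfg: RunConfig, out: Path, extra: dict | None = None) -> None:
    meta = {k: (str(v) if isinstance(v, Path) else v) for k, v in asdict(cfg).items()}
    if extra:
        meta.update(extra)
    (out / "run_metadata.yaml").write_text(yaml.safe_dump(meta))
    for k, v in meta.items():
        log.info("parameter %s = %r", k, v)


def _resolve_scenario(cfg: RunConfig) -> synthetic.ScenarioConfig:
    if cfg.scenario is None:
        raise ValueError("a scenario (preset name or YAML path) is required")
    if isinstance(cfg.scenario, (str, Path)) and Path(str(cfg.scenario)).exists():
        return synthetic.load_scenario(cfg.scenario, seed=cfg.seed)
    if cfg.seed is None:
        raise ValueError("a seed is required to simulate a preset scenario")
    return synthetic.preset_scenario(str(cfg.scenario), seed=cfg.seed)


def run_simulate(cfg: RunConfig) -> dict:
    """Generate a synthetic stack + flat fields + truth manifest on disk."""
    scen = _resolve_scenario(cfg)
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    stack, truth, manifest = synthetic.generate_stack(scen)
    _, _, flat = synthetic.render_flat_field(scen)
    write_stack(stack, out / "stack.tif")
    write_stack(
        ImageStack(
            frames=np.stack([flat.gain, flat.offset]),
            timestamps=np.array([0.0, 1.0]),
            pixel_size_um=scen.pixel_size_um,
        ),
        out / "flat.tif",
    )
    truth_df = pd.DataFrame(
        {
            "time_s": truth.times_s,
            "semi_axis_h_mm": truth.semi_axis_h_mm,
            "semi_axis_v_mm": truth.semi_axis_v_mm,
            "injected_volume_ul": truth.injected_volume_ul,
            "onset": truth.onset_flag.astype(int),
        }
    )
    _write_table(truth_df, out / "truth.tsv")
    (out / "truth_manifest.yaml").write_text(yaml.safe_dump(manifest))
    _dump_metadata(cfg, out, {"n_frames": len(stack)})
    log.info("simulated %d frames to %s", len(stack), out)
    return {"stack": out / "stack.tif", "truth": out / "truth.tsv", "manifest": manifest}


def _load_corrected(cfg: RunConfig) -> tuple[ImageStack, dict | None]:
    """Read raw stack + flats, flat-field correct, optionally deregister drift."""
    stack_path = cfg.stack_path or (cfg.out_dir / "stack.tif")
    raw = read_stack(stack_path)
    flat_path = Path(stack_path).parent / "flat.tif"
    if flat_path.exists():
        flats = read_stack(flat_path)
        flat = FlatFieldSet(gain=flats.frames[0], offset=flats.frames[1])
    else:
        warnings.warn("no flat-field images found; assuming unit gain / zero offset")
        flat = FlatFieldSet(gain=np.ones(raw.shape), offset=np.zeros(raw.shape))
    trans = np.stack([flat_field_correct(f, flat).filled(np.nan) for f in raw.frames])
    corrected = ImageStack(
        frames=trans,
        timestamps=raw.timestamps,
        pixel_size_um=raw.pixel_size_um,
        field_of_view_mm=raw.field_of_view_mm,
    )
    if cfg.register and len(corrected) >= 2:
        _, corrected = register_drift(corrected)
    manifest_path = Path(stack_path).parent / "truth_manifest.yaml"
    manifest = yaml.safe_load(manifest_path.read_text()) if manifest_path.exists() else None
    return corrected, manifest


def run_analysis(cfg: RunConfig) -> dict:
    """Full measurement chain on a corrected stack; writes all report tables."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    corrected, manifest = _load_corrected(cfg)
    if manifest is None:
        raise FileNotFoundError("analysis requires a truth/acquisition manifest for the protocol")
    proto = transport.InjectionProtocol(**{**manifest["protocol"], "needle_tip": tuple(manifest["protocol"]["needle_tip"])})
    tissue = transport.TissueParameters(**manifest["tissue"])

    trace = quantify.track_wf(
        corrected, proto, tissue,
        n_baseline=cfg.n_baseline,
        threshold_fraction=cfg.threshold_fraction,
    )
    _write_table(
        pd.DataFrame(
            {"time_s": trace.times_s, "wf_h_mm": trace.wf_h_mm, "wf_v_mm": trace.wf_v_mm, "region": trace.region}
        ),
        out / "wf_trace.tsv",
    )

    baseline = np.mean(corrected.frames[: cfg.n_baseline], axis=0)
    maps = [quantify.rcs_map(f, baseline, cfg.mu_abs_per_mm) for f in corrected.frames]
    profile_rows = []
    variation_rows = []
    for direction in ("horizontal", "vertical"):
        series = quantify.build_rcs_series(
            maps, corrected.timestamps, proto.needle_tip, direction, corrected.pixel_size_um, cfg.window_mm
        )
        for ti, t in enumerate(series.times_s):
            for d, v in zip(series.distances_mm, series.values[ti]):
                profile_rows.append((direction, t, d, v))
        for ti in range(1, len(series.times_s)):
            rate = quantify.rcs_temporal_variation(
                series.values[ti - 1], series.values[ti], series.times_s[ti - 1], series.times_s[ti]
            )
            for d, r in zip(series.distances_mm, rate):
                variation_rows.append((direction, series.times_s[ti], d, r))
    _write_table(
        pd.DataFrame(profile_rows, columns=["direction", "time_s", "distance_mm", "rcs_norm"]),
        out / "rcs_profiles.tsv",
    )
    _write_table(
        pd.DataFrame(variation_rows, columns=["direction", "time_s", "distance_mm", "rcs_rate_per_s"]),
        out / "rcs_variation.tsv",
    )

    # ROI coefficient of variation on the corrected frames
    rows = []
    try:
        rois = quantify.define_rois(proto.needle_tip, trace, corrected.pixel_size_um, corrected.shape, cfg.window_mm)
        for name, bounds in rois.items():
            stats = quantify.roi_cv(corrected, bounds, name)
            for t, m, s, c in zip(stats.times_s, stats.mean, stats.std, stats.cv):
                rows.append((name, t, m, s, c))
    except ValueError as exc:
        warnings.warn(f"ROI analysis skipped: {exc}")
    _write_table(pd.DataFrame(rows, columns=["roi", "time_s", "mean", "std", "cv"]), out / "roi_cv.tsv")

    # aspect ratios per region
    ar_rows = []
    for region in ("IR", "DR"):
        try:
            m, s = quantify.aspect_ratio(trace, region)
            ar_rows.append((region, m, s))
        except ValueError:
            pass
    _write_table(pd.DataFrame(ar_rows, columns=["region", "aspect_ratio", "std"]), out / "aspect_ratio.tsv")

    # cube-root fit over the post-onset injection region
    ir = trace.in_region("IR") & np.isfinite(trace.wf_h_mm) & (trace.wf_h_mm > 0)
    fit_rows = []
    onset_est = None
    central = np.array([float(np.ma.mean(m[max(proto.needle_tip[0] - 2, 0) : proto.needle_tip[0] + 3,
                                           max(proto.needle_tip[1] - 2, 0) : proto.needle_tip[1] + 3])) for m in maps])
    if central.size >= 6:
        onset_est = quantify.onset_time(corrected.timestamps, central, n_baseline=max(cfg.n_baseline, 3))
    if ir.sum() >= 3:
        # fit against time since onset so the lag does not bias the growth law
        t0 = onset_est or float(trace.times_s[ir][0])
        tt = trace.times_s[ir] - t0 + np.diff(trace.times_s).mean()
        keep = tt > 0
        if keep.sum() >= 3:
            fit = transport.fit_normalized_wf(tt[keep], trace.wf_h_mm[ir][keep] * 1e-3, proto)
            fit_rows.append(("horizontal", fit.wf_max_m, fit.r_squared, int(fit.degenerate)))
    _write_table(pd.DataFrame(fit_rows, columns=["direction", "wf_max_m", "r_squared", "degenerate"]), out / "fit.tsv")

    # onset + quasi-saturation
    qs_rows = []
    try:
        qs = quantify.quasi_saturation_time(trace.times_s, trace.wf_h_mm)
    except ValueError:
        qs = None
    qs_rows.append(("onset_s", onset_est if onset_est is not None else float("nan")))
    qs_rows.append(("quasi_saturation_s", qs if qs is not None else float("nan")))
    _write_table(pd.DataFrame(qs_rows, columns=["quantity", "value"]), out / "timing.tsv")

    # permeability mirroring the reported table schema
    perm_rows = []
    fin = np.isfinite(trace.wf_h_mm) & np.isfinite(trace.wf_v_mm)
    if np.any(fin & trace.in_region("IR")):
        last = int(np.nonzero(fin & trace.in_region("IR"))[0][-1])
        est = transport.estimate_permeability(
            proto.flow_rate_ul_min,
            trace.wf_h_mm[last] * 1e-3,
            trace.wf_v_mm[last] * 1e-3,
        )
        perm_rows.append(
            (cfg.tissue_label, proto.flow_rate_ul_min / 1000.0, est.k_horizontal, est.k_vertical)
        )
    _write_table(
        pd.DataFrame(perm_rows, columns=["tissue", "flow_rate_ml_min", "k_horizontal", "k_vertical"]),
        out / "permeability.tsv",
    )

    _dump_metadata(cfg, out, {"n_frames": len(corrected)})
    return {"trace": trace, "out_dir": out}


def run_recover(cfg: RunConfig, tolerances: dict | None = None) -> pd.DataFrame:
    """Compare analysis estimates against the generator truth manifest.

    Writes recovery.tsv with per-quantity relative errors and pass/fail at
    the given tolerances (defaults: semi-axes 2 px or 5%, anisotropy 0.05
    absolute, onset one frame interval, permeability-equivalent 10%).
    """
    out = cfg.out_dir
    stack_dir = Path(cfg.stack_path).parent if cfg.stack_path else out
    manifest_path = stack_dir / "truth_manifest.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError("truth manifest required for recovery benchmarking")
    manifest = yaml.safe_load(manifest_path.read_text())
    for key in ("final_semi_axis_h_mm", "final_semi_axis_v_mm", "anisotropy", "onset_time_s"):
        if key not in manifest:
            raise ValueError(f"truth manifest is missing {key!r}")
    res = run_analysis(cfg)
    trace: quantify.WFTrace = res["trace"]
    px_mm = manifest["pixel_size_um"] * 1e-3
    proto = manifest["protocol"]
    noiseless = bool(manifest.get("noiseless", False))
    tol = {
        "semi_axis_rel": 0.0 if noiseless else 0.05,
        "semi_axis_px": 2.0,
        "anisotropy_abs": 0.05,
        "onset_frames": 1.0,
        "k_rel": 0.10,
    }
    tol.update(tolerances or {})

    fin = np.isfinite(trace.wf_h_mm) & np.isfinite(trace.wf_v_mm) & trace.in_region("IR")
    if not np.any(fin):
        raise ValueError("no usable injection-region samples recovered")
    last = int(np.nonzero(fin)[0][-1])
    rows = []

    def add(name, truth_v, est_v, abs_tol, rel_tol):
        err = abs(est_v - truth_v)
        rel = err / abs(truth_v) if truth_v else np.inf
        ok = err <= abs_tol or rel <= rel_tol
        rows.append((name, truth_v, est_v, rel, bool(ok)))

    add("semi_axis_h_mm", manifest["final_semi_axis_h_mm"], trace.wf_h_mm[last],
        tol["semi_axis_px"] * px_mm, tol["semi_axis_rel"])
    add("semi_axis_v_mm", manifest["final_semi_axis_v_mm"], trace.wf_v_mm[last],
        tol["semi_axis_px"] * px_mm, tol["semi_axis_rel"])
    ratios = trace.wf_v_mm[fin] / trace.wf_h_mm[fin]
    add("anisotropy", manifest["anisotropy"], float(np.mean(ratios[-max(3, fin.sum() // 3):])),
        tol["anisotropy_abs"], 0.0)

    timing = pd.read_csv(out / "timing.tsv", sep="\t")
    onset_est = float(timing.loc[timing.quantity == "onset_s", "value"].iloc[0])
    frame_dt = float(np.diff(trace.times_s).mean())
    add("onset_time_s", manifest["onset_time_s"], onset_est, tol["onset_frames"] * frame_dt, 0.0)

    perm = pd.read_csv(out / "permeability.tsv", sep="\t")
    if len(perm):
        q = proto["flow_rate_ul_min"]
        k_truth = transport.permeability_darcy(
            q, manifest["final_semi_axis_h_mm"] * 1e-3, transport.injection_pressure(q / 60.0)
        )
        add("k_horizontal", k_truth, float(perm.k_horizontal.iloc[0]), 0.0, tol["k_rel"])

    df = pd.DataFrame(rows, columns=["quantity", "truth", "estimate", "rel_error", "passed"])
    _write_table(df, out / "recovery.tsv")
    if not df.passed.all():
        log.warning("recovery failures:\n%s", df[~df.passed])
    return df
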