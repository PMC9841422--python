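"""End-to-end orchestration: movie (or trajectory CSV) to fitted kinetics.

One call — :func:`run_pipeline` — executes extract -> fit -> filter ->
synchronise -> kinetics for the chosen enzyme mode and writes a
reproducible result bundle: per-molecule fit CSV, ensemble CSV, kinetics
JSON, survival CSV (displacement mode) and a manifest with the full
configuration, seeds and per-reason discard counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from . import imageproc, kinetics, sync, trajfit

logger = logging.getLogger(__name__)

MODES = ("exo", "phi29", "uvrd-unwind", "uvrd-displace")


@dataclass
class AnalysisConfig:
    """Every knob of the pipeline, with defaults from the assay protocol."""

    mode: str = "exo"
    frame_interval: float = 0.2           # s (5 fps; RPA experiments use 2.0)
    template_bp: int = trajfit.TEMPLATE_BP
    pixel_size: float = imageproc.DEFAULT_PIXEL_SIZE_UM
    # detection
    k_sigma: float = 5.0
    min_area: int = 4
    max_area: int = 200
    roi_radius: float = 4.0
    bg_annulus: tuple[float, float] = (6.0, 9.0)
    smoothing_sigma: float = 25.0
    drift_reference: str = "first_frame"
    detect_frames: int = 10               # temporal-mean window for detection
    # filtering
    r2_min: float = 0.7
    drop_min_score: float = 0.5
    # kinetics windows and constants
    synthesis_window_max: float = -10.0   # s
    binding_window_min: float = -20.0     # s
    fpt_x0: float = kinetics.DEFAULT_X0_S # s
    rpa_conc: float = kinetics.DEFAULT_RPA_CONC_NM  # nM
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not (0.0 <= self.r2_min <= 1.0):
            raise ConfigurationError("r2_min must lie in [0, 1]")
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be positive")
        if self.template_bp <= 0:
            raise ConfigurationError("template_bp must be positive")

    @classmethod
    def from_dict(cls, payload: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "bg_annulus" in payload:
            payload = {**payload, "bg_annulus": tuple(payload["bg_annulus"])}
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def extract_stage(
    config: AnalysisConfig,
    movie_path: str | Path,
    movie2_path: str | Path | None = None,
) -> tuple[list[imageproc.Trajectory], dict]:
    """Movie -> flat-field -> drift correction -> detection -> trajectories."""
    movie = imageproc.Movie.load(movie_path, config.frame_interval,
                                 config.pixel_size, channel="dna")
    profile = imageproc.estimate_illumination(movie, config.smoothing_sigma)
    movie = profile.correct(movie)
    shifts, movie = imageproc.correct_drift(movie, config.drift_reference)
    mean_frame = movie.stack[: config.detect_frames].mean(axis=0)
    spots = imageproc.detect_spots(mean_frame, config.k_sigma,
                                   config.min_area, config.max_area)
    second = None
    if movie2_path is not None:
        second = imageproc.Movie.load(movie2_path, config.frame_interval,
                                      config.pixel_size, channel="rpa")
        second = imageproc.estimate_illumination(
            second, config.smoothing_sigma).correct(second)
        reg = np.empty_like(second.stack)
        reg[0] = second.stack[0]
        from scipy import ndimage
        for f in range(1, second.n_frames):
            reg[f] = ndimage.shift(second.stack[f], -shifts[f], order=1,
                                   mode="nearest")
        second = imageproc.Movie(stack=reg, frame_interval=config.frame_interval,
                                 pixel_size=config.pixel_size, channel="rpa")
    trajs = imageproc.extract_trajectories(
        movie, spots, config.roi_radius, config.bg_annulus, second)
    info = {"n_spots": len(spots), "n_trajectories": len(trajs),
            "max_drift_px": float(np.abs(shifts).max()) if len(shifts) else 0.0}
    return trajs, info


def fit_processive(
    trajs: list[imageproc.Trajectory],
    config: AnalysisConfig,
    channel: str = "dna",
    direction: str = "decreasing",
):
    """Fit -> calibrate -> refit on the calibrated scale, per molecule.

    Returns (cal_fits, cal_trajs, statuses) aligned with ``trajs``; failed
    molecules carry None fits and a reason string.
    """
    cal_fits, cal_trajs, statuses = [], [], []
    for tr in trajs:
        y = tr.channels[channel]
        try:
            raw_fit = trajfit.fit_piecewise_linear(tr.times, y)
            cal = trajfit.calibrate(tr.times, y, raw_fit, direction,
                                    config.template_bp, tr.molecule_id)
            cal_fit = trajfit.fit_piecewise_linear(cal.times, cal.i_cal)
        except Exception as exc:
            cal_fits.append(None)
            cal_trajs.append(None)
            statuses.append(f"fit failed: {type(exc).__name__}")
            continue
        cal_fits.append(cal_fit)
        cal_trajs.append(cal)
        statuses.append("ok")
    return cal_fits, cal_trajs, statuses


def run_pipeline(
    config: AnalysisConfig,
    outdir: str | Path,
    movie: str | Path | None = None,
    movie2: str | Path | None = None,
    traj_csv: str | Path | None = None,
    trajs: list[imageproc.Trajectory] | None = None,
) -> dict:
    """Run the full analysis for one experiment and write the result bundle.

    Inputs are either movie TIFF path(s), a long-format trajectory CSV, or
    in-memory trajectories.  Returns the manifest dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "config_digest": config.digest(),
                      "version": __version__, "stages": {}}

    if trajs is None:
        if movie is not None:
            trajs, info = extract_stage(config, movie, movie2)
            manifest["stages"]["extract"] = info
            imageproc.write_trajectories(trajs, outdir / "trajectories.csv")
        elif traj_csv is not None:
            trajs = imageproc.read_trajectories(traj_csv)
            manifest["stages"]["extract"] = {"source": str(traj_csv),
                                             "n_trajectories": len(trajs)}
        else:
            raise ConfigurationError("need a movie, a trajectory CSV or trajectories")
    if not trajs:
        raise ConfigurationError("no molecules to analyse")

    duration = float(trajs[0].times[-1])
    n_frames = np.array([tr.times.size for tr in trajs])

    if config.mode in ("exo", "uvrd-unwind"):
        manifest["stages"].update(_run_processive(trajs, config, outdir, n_frames))
    elif config.mode == "phi29":
        manifest["stages"].update(_run_phi29(trajs, config, outdir, n_frames))
    else:  # uvrd-displace
        manifest["stages"].update(_run_displacement(trajs, config, outdir, duration))

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _molecule_table(trajs, fits, statuses, kept, reasons, config) -> pd.DataFrame:
    reason_by_idx = dict(reasons)
    rows = []
    for i, (tr, f, status) in enumerate(zip(trajs, fits, statuses)):
        rec = {"molecule_id": tr.molecule_id, "m": np.nan, "t": np.nan,
               "a": np.nan, "b": np.nan, "r2": np.nan, "rate_nt_s": np.nan,
               "kept": i in kept,
               "reason": "kept" if i in kept else reason_by_idx.get(i, status)}
        if f is not None:
            rec.update(m=f.m, t=f.t, a=f.a, b=f.b, r2=f.r2,
                       rate_nt_s=abs(f.m) * config.template_bp)
        rows.append(rec)
    return pd.DataFrame(rows).sort_values("molecule_id")


def _write_ensemble(ens: sync.SynchronisedEnsemble, path: Path) -> None:
    rows = []
    for label in ens.mean:
        rows.append(pd.DataFrame({
            "rel_time_s": ens.rel_times, "channel": label,
            "mean": ens.mean[label], "sem": ens.sem[label],
            "n": ens.n_contributing,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def _run_processive(trajs, config, outdir, n_frames) -> dict:
    cal_fits, cal_trajs, statuses = fit_processive(trajs, config)
    ok = [i for i, f in enumerate(cal_fits) if f is not None]
    fits_ok = [cal_fits[i] for i in ok]
    kept_rel, reasons_rel = trajfit.filter_trajectories(
        fits_ok, n_frames[ok], config.frame_interval, config.r2_min)
    kept = [ok[i] for i in kept_rel]
    reasons = [(ok[i], r) for i, r in reasons_rel]
    reasons += [(i, statuses[i]) for i in range(len(trajs)) if cal_fits[i] is None]

    dist = trajfit.compute_rates([cal_fits[i] for i in kept], config.template_bp)
    table = _molecule_table(trajs, cal_fits, statuses, set(kept), reasons, config)
    table.to_csv(outdir / "molecules.csv", index=False)

    rates_payload = {"n": dist.n, "mean_nt_s": dist.mean, "std_nt_s": dist.std,
                     "median_nt_s": dist.median,
                     "rates_nt_s": [float(r) for r in dist.rates]}
    (outdir / "rates.json").write_text(json.dumps(rates_payload, indent=1))

    stage: dict = {"fit": _discard_counts(len(trajs), kept, reasons)}
    if len(kept) >= 2:
        ens = sync.synchronise([cal_trajs[i] for i in kept],
                               [cal_fits[i].b for i in kept])
        _write_ensemble(ens, outdir / "ensemble.csv")
        stage["sync"] = {"n_molecules": ens.n_molecules,
                         "n_excluded": len(ens.excluded)}
    return stage


def _run_phi29(trajs, config, outdir, n_frames) -> dict:
    # dissociation drop on the DNA channel confirms completed replication
    drops = [trajfit.detect_drop(tr.times, tr.channels["dna"],
                                 config.drop_min_score) for tr in trajs]
    cal_fits, cal_trajs, statuses = fit_processive(
        trajs, config, channel="rpa", direction="increasing")
    ok = [i for i, f in enumerate(cal_fits) if f is not None]
    kept_rel, reasons_rel = trajfit.filter_trajectories(
        [cal_fits[i] for i in ok], n_frames[ok], config.frame_interval,
        config.r2_min, require_drop=True, drops=[drops[i] for i in ok])
    kept = [ok[i] for i in kept_rel]
    reasons = [(ok[i], r) for i, r in reasons_rel]
    reasons += [(i, statuses[i]) for i in range(len(trajs)) if cal_fits[i] is None]

    table = _molecule_table(trajs, cal_fits, statuses, set(kept), reasons, config)
    table.to_csv(outdir / "molecules.csv", index=False)
    stage: dict = {"fit": _discard_counts(len(trajs), kept, reasons)}

    if len(kept) >= 2:
        ens = sync.synchronise([cal_trajs[i] for i in kept],
                               [drops[i].t_drop for i in kept])
        _write_ensemble(ens, outdir / "ensemble.csv")
        fits_payload = {}
        try:
            efit = kinetics.fit_exponential_synthesis(
                ens.rel_times, ens.mean["cal"], config.template_bp,
                config.synthesis_window_max)
            fits_payload["exponential_synthesis"] = {
                "k_per_s": efit.k, "x0_s": efit.x0,
                "rate_bp_s": efit.rate_bp_s, "window_max_s": efit.fit_window_max}
        except Exception as exc:
            fits_payload["exponential_synthesis"] = {"error": str(exc)}
        try:
            bfit = kinetics.fit_rpa_binding(
                ens.rel_times, ens.mean["cal"] * config.template_bp,
                x0=0.0, rpa_conc=config.rpa_conc,
                template_nt=config.template_bp,
                window_min=config.binding_window_min)
            fits_payload["rpa_binding"] = {
                "k_exp_per_s": bfit.k_exp, "ssDNA_free_0_nt": bfit.ssDNA_free_0,
                "x0_s": bfit.x0, "k_on_nt_per_nM_s": bfit.k_on_reported,
                "convention": bfit.convention}
        except Exception as exc:
            fits_payload["rpa_binding"] = {"error": str(exc)}
        (outdir / "kinetics.json").write_text(json.dumps(fits_payload, indent=1))
        stage["sync"] = {"n_molecules": ens.n_molecules}
    return stage


def _run_displacement(trajs, config, outdir, duration) -> dict:
    fpts = kinetics.extract_fpts(trajs, movie_end=duration,
                                 min_score=config.drop_min_score,
                                 t_reagent_arrival=config.fpt_x0)
    curve = kinetics.survival_curve(fpts)
    pd.DataFrame({"time_s": curve.times,
                  "fraction_bound": curve.fraction_bound}).to_csv(
        outdir / "survival.csv", index=False)
    pd.DataFrame({"molecule_id": [tr.molecule_id for tr in trajs],
                  "event_time_s": fpts.event_times,
                  "censored": fpts.censored}).to_csv(
        outdir / "fpts.csv", index=False)
    payload: dict = {"n_total": fpts.n_total, "n_censored": fpts.n_censored,
                     "x0_s": config.fpt_x0}
    try:
        gfit = kinetics.fit_gamma_fpt(fpts, x0=config.fpt_x0)
        payload["gamma_fit"] = {"shape_n": gfit.n, "rate_k_per_s": gfit.k,
                                "log_likelihood": gfit.log_likelihood,
                                "n_events": gfit.n_events,
                                "n_dropped": gfit.n_dropped}
    except Exception as exc:
        payload["gamma_fit"] = {"error": str(exc)}
    (outdir / "kinetics.json").write_text(json.dumps(payload, indent=1))
    return {"fpt": {"n_total": fpts.n_total, "n_censored": fpts.n_censored}}


def _discard_counts(n_total, kept, reasons) -> dict:
    counts: dict[str, int] = {}
    for _, r in reasons:
        counts[r] = counts.get(r, 0) + 1
    return {"n_total": n_total, "n_kept": len(kept),
            "n_discarded": n_total - len(kept), "discard_reasons": counts}
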