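"""Forward simulation of the single-molecule assay.

Generates per-molecule intensity trajectories, first-passage-time sets and
full two-channel TIRF movies with ground-truth sidecars, so that every
downstream stage (image processing, piecewise fitting, synchronisation,
kinetic inference) can be exercised and validated without experimental
data.

The observable is the calibrated intensity of a surface-tethered DNA
template: 1 = full double-stranded template, 0 = none.  Four kinetic
programs are modelled:

* ``digestion`` / ``unwinding`` — processive conversion of dsDNA to ssDNA:
  plateau at 1, linear decay of slope -rate/template_bp between activity
  start ``a`` and end ``b``, plateau at 0.
* ``strand_displacement`` — the DNA-stain channel stays at 1 until the
  newly synthesised strand dissociates in a single frame; a second (RPA)
  channel rises with pseudo-first-order binding kinetics saturating at 1.
* ``displacement_event`` — tether rupture: intensity 1 until the
  first-passage time, 0 after.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from .errors import ConfigurationError, ParameterError
from .imageproc import Movie, Trajectory, DEFAULT_PIXEL_SIZE_UM
from .kinetics import FPTSet
from .trajfit import PiecewiseFit, TEMPLATE_BP

PROCESSIVE_KINDS = ("digestion", "unwinding")
KINDS = PROCESSIVE_KINDS + ("strand_displacement", "displacement_event")


@dataclass
class KineticProgram:
    """Ground-truth kinetic behaviour of one molecule."""

    kind: str
    rate: float | None = None          # nt/s, processive kinds
    start_time: float = 0.0            # s
    end_time: float | None = None      # s; derived from rate for processive kinds
    fpt: float | None = None           # s, displacement_event only
    rpa_rate: float | None = None      # 1/s, pseudo-first-order RPA binding
    rpa_start: float | None = None     # s, onset of ssDNA exposure (default start_time)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ParameterError(f"unknown kinetic program kind {self.kind!r}")
        if self.start_time < 0:
            raise ParameterError("start_time must be >= 0")
        if self.kind in PROCESSIVE_KINDS and (self.rate is None or self.rate <= 0):
            raise ParameterError("processive programs need rate > 0")
        if self.kind == "displacement_event" and (self.fpt is None or self.fpt < 0):
            raise ParameterError("displacement_event needs fpt >= 0")
        if self.end_time is not None and self.kind != "displacement_event" \
                and self.end_time <= self.start_time:
            raise ParameterError("end_time must exceed start_time")

    def resolved_end(self, template_bp: int = TEMPLATE_BP) -> float:
        """Reaction end time, deriving start + template/rate when needed."""
        if self.kind in PROCESSIVE_KINDS:
            derived = self.start_time + template_bp / self.rate
            if self.end_time is not None and not math.isclose(
                    self.end_time, derived, rel_tol=1e-6, abs_tol=1e-9):
                raise ParameterError(
                    "end_time inconsistent with start_time + template_bp/rate")
            return derived
        if self.kind == "displacement_event":
            return self.fpt
        if self.end_time is None:
            raise ParameterError("strand_displacement needs an explicit end_time")
        return self.end_time


# ---------------------------------------------------------------------------
# rate heterogeneity

def _truncnorm_location(mean: float, std: float) -> float:
    """Parent-normal location whose zero-truncated mean equals ``mean``."""

    from scipy.special import log_ndtr

    def trunc_mean(mu):
        alpha = mu / std
        # Mills ratio in log space: stable for strongly negative alpha
        log_ratio = stats.norm.logpdf(alpha) - log_ndtr(alpha)
        return mu + std * math.exp(log_ratio)

    # trunc_mean is increasing in mu and always exceeds mu
    lo = mean - 50.0 * std
    return optimize.brentq(lambda mu: trunc_mean(mu) - mean, lo, mean, xtol=1e-12)


def sample_rates(mean: float, std: float, n: int, seed: int) -> np.ndarray:
    """Draw per-molecule rates from a normal truncated at zero.

    The parent normal keeps scale ``std`` and its location is solved so the
    truncated distribution's mean equals ``mean`` — the sample mean
    converges to the requested mean regardless of how much mass the parent
    would place below zero.
    """
    if mean <= 0:
        raise ParameterError("mean rate must be positive")
    if std < 0:
        raise ParameterError("std must be non-negative")
    if n < 1:
        raise ParameterError("n must be >= 1")
    if std == 0:
        return np.full(n, float(mean))
    mu = _truncnorm_location(mean, std)
    rng = np.random.default_rng(seed)
    a = (0.0 - mu) / std
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=std, size=n, random_state=rng)


def sample_rates_lognormal(median: float, std: float, n: int, seed: int) -> np.ndarray:
    """Rates from a lognormal parameterised by median and standard deviation.

    Suited to heavy-tailed rate distributions reported as median +/- STD
    (e.g. helicase unwinding).  The log-scale sigma solves
    (std/median)^2 = u(u-1) with u = exp(sigma^2).
    """
    if median <= 0 or std < 0 or n < 1:
        raise ParameterError("median must be > 0, std >= 0, n >= 1")
    if std == 0:
        return np.full(n, float(median))
    r2 = (std / median) ** 2
    u = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * r2))
    sigma = math.sqrt(math.log(u))
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=math.log(median), sigma=sigma, size=n)


# ---------------------------------------------------------------------------
# trajectories

def _program_values(
    program: KineticProgram,
    template_bp: int,
    times: np.ndarray,
) -> dict[str, np.ndarray]:
    """Noiseless calibrated intensity per channel at the given times."""
    t = np.asarray(times, float)
    if program.kind in PROCESSIVE_KINDS:
        a = program.start_time
        b = program.resolved_end(template_bp)
        m = -program.rate / template_bp
        tt = 1.0 - m * a
        return {"dna": m * np.clip(t, a, b) + tt}
    if program.kind == "strand_displacement":
        drop = program.resolved_end(template_bp)
        dna = np.where(t < drop, 1.0, 0.0)
        channels = {"dna": dna}
        if program.rpa_rate is not None:
            start = program.rpa_start if program.rpa_start is not None \
                else program.start_time
            rpa = 1.0 - np.exp(-program.rpa_rate * np.clip(t - start, 0.0, None))
            rpa[t < start] = 0.0
            channels["rpa"] = rpa
        return channels
    # displacement_event
    return {"dna": np.where(t < program.fpt, 1.0, 0.0)}


def true_piecewise(program: KineticProgram,
                   template_bp: int = TEMPLATE_BP) -> PiecewiseFit | None:
    """Ground-truth (m, t, a, b) for processive programs, else None."""
    if program.kind not in PROCESSIVE_KINDS:
        return None
    a = program.start_time
    b = program.resolved_end(template_bp)
    m = -program.rate / template_bp
    return PiecewiseFit(m=m, t=1.0 - m * a, a=a, b=b, r2=1.0,
                        n_points=0, sse=0.0)


def simulate_trajectory(
    program: KineticProgram,
    template_bp: int = TEMPLATE_BP,
    frame_interval: float = 0.2,
    n_frames: int | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    molecule_id: int = 0,
    tail_s: float = 60.0,
) -> tuple[Trajectory, PiecewiseFit | None]:
    """Simulate one molecule's calibrated intensity trajectory.

    ``n_frames`` defaults to covering the full program plus ``tail_s``
    seconds of post-reaction plateau.
    Additive Gaussian noise of ``noise_sigma`` is applied independently to
    every channel.  Returns the trajectory and, for processive programs,
    the generating piecewise-linear parameters.
    """
    if noise_sigma < 0:
        raise ParameterError("noise_sigma must be >= 0")
    end = program.resolved_end(template_bp)
    if n_frames is None:
        n_frames = int(math.ceil((end + tail_s) / frame_interval)) + 1
    elif (n_frames - 1) * frame_interval < end:
        raise ParameterError("n_frames too short to contain the kinetic program")
    times = np.arange(n_frames) * frame_interval
    channels = _program_values(program, template_bp, times)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        channels = {k: v + rng.normal(0.0, noise_sigma, v.size)
                    for k, v in channels.items()}
    traj = Trajectory(molecule_id=molecule_id, times=times, channels=channels)
    return traj, true_piecewise(program, template_bp)


def simulate_fpt_set(
    n_mol: int,
    shape: float,
    rate: float,
    x0: float = 20.0,
    seed: int = 0,
) -> FPTSet:
    """First-passage times distributed as x0 + Gamma(shape, rate)."""
    if n_mol < 1 or shape <= 0 or rate <= 0 or x0 < 0:
        raise ParameterError("need n_mol >= 1, shape > 0, rate > 0, x0 >= 0")
    rng = np.random.default_rng(seed)
    events = x0 + rng.gamma(shape, 1.0 / rate, size=n_mol)
    return FPTSet(event_times=events, censored=np.zeros(n_mol, bool),
                  t_reagent_arrival=x0)


# ---------------------------------------------------------------------------
# movies

@dataclass
class SceneConfig:
    """Imaging conditions for a simulated TIRF movie."""

    field_size: tuple[int, int] = (64, 64)     # rows, cols (px)
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM  # um / px
    spot_density: float = 0.5                  # molecules / um^2
    frame_interval: float = 0.2                # s
    n_frames: int = 100
    psf_sigma: float = 1.0                     # px
    photon_scale: float = 200.0                # ADU per unit calibrated intensity
    background: float = 10.0                   # ADU per px before beam profile
    read_noise_sigma: float = 2.0              # ADU
    shot_noise: bool = True
    drift_per_frame: tuple[float, float] = (0.0, 0.0)  # (dy, dx) px / frame
    beam_profile_sigma: float = 0.0            # px; 0 disables the profile
    edge_margin: float = 10.0                  # px kept free of spot centres
    min_separation: float = 6.0                # px between spot centres; the
    # effective separation is max(min_separation, 4*psf_sigma) — overlapping
    # spots merge under connected-component detection, so overlap must be
    # requested explicitly by lowering this
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.spot_density <= 2.0):
            raise ConfigurationError("spot_density must be in (0, 2]")
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        for name in ("photon_scale", "background", "read_noise_sigma",
                     "psf_sigma", "beam_profile_sigma"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def area_um2(self) -> float:
        r, c = self.field_size
        return r * c * self.pixel_size ** 2


@dataclass
class MoleculeTruth:
    molecule_id: int
    y: float
    x: float
    program: KineticProgram
    piecewise: PiecewiseFit | None


@dataclass
class GroundTruth:
    """Sidecar record of everything the simulator knows."""

    scene: SceneConfig
    molecules: list[MoleculeTruth]
    template_bp: int = TEMPLATE_BP

    @property
    def cumulative_drift(self) -> np.ndarray:
        dy, dx = self.scene.drift_per_frame
        f = np.arange(self.scene.n_frames)[:, None]
        return f * np.array([dy, dx])

    def to_json(self, path: str | Path) -> None:
        def clean(d):
            return {k: v for k, v in d.items() if v is not None}

        payload = {
            "template_bp": self.template_bp,
            "scene": asdict(self.scene),
            "molecules": [
                {
                    "molecule_id": m.molecule_id, "y": m.y, "x": m.x,
                    "program": clean(asdict(m.program)),
                    "piecewise": None if m.piecewise is None else {
                        "m": m.piecewise.m, "t": m.piecewise.t,
                        "a": m.piecewise.a, "b": m.piecewise.b,
                    },
                }
                for m in self.molecules
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        scene_kw = dict(payload["scene"])
        scene_kw["field_size"] = tuple(scene_kw["field_size"])
        scene_kw["drift_per_frame"] = tuple(scene_kw["drift_per_frame"])
        scene = SceneConfig(**scene_kw)
        mols = []
        for rec in payload["molecules"]:
            program = KineticProgram(**rec["program"])
            pw = rec["piecewise"]
            piecewise = None if pw is None else PiecewiseFit(
                m=pw["m"], t=pw["t"], a=pw["a"], b=pw["b"], r2=1.0, n_points=0)
            mols.append(MoleculeTruth(molecule_id=rec["molecule_id"],
                                      y=rec["y"], x=rec["x"],
                                      program=program, piecewise=piecewise))
        return cls(scene=scene, molecules=mols,
                   template_bp=payload["template_bp"])


def _place_spots(scene: SceneConfig, n: int, rng: np.random.Generator,
                 min_sep: float) -> np.ndarray:
    """Random sequential placement with a minimum pairwise separation."""
    rows, cols = scene.field_size
    m = scene.edge_margin
    if rows - 2 * m <= 0 or cols - 2 * m <= 0:
        raise ConfigurationError("field too small for requested density")
    placed = np.empty((0, 2))
    attempts = 0
    while placed.shape[0] < n:
        attempts += 1
        if attempts > 2000 * n:
            raise ConfigurationError("field too small for requested density")
        cand = np.array([rng.uniform(m, rows - m), rng.uniform(m, cols - m)])
        if placed.size and np.min(np.hypot(*(placed - cand).T)) < min_sep:
            continue
        placed = np.vstack([placed, cand])
    return placed


def _render_spot(img: np.ndarray, y: float, x: float, amp: float, sigma: float):
    """Add a 2-D Gaussian of peak ``amp`` at sub-pixel centre (y, x)."""
    if amp == 0.0:
        return
    r = int(math.ceil(5.0 * sigma))
    rows, cols = img.shape
    y0, y1 = max(0, int(math.floor(y)) - r), min(rows, int(math.floor(y)) + r + 1)
    x0, x1 = max(0, int(math.floor(x)) - r), min(cols, int(math.floor(x)) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1)[:, None] - y
    xx = np.arange(x0, x1)[None, :] - x
    img[y0:y1, x0:x1] += amp * np.exp(-(yy * yy + xx * xx) / (2.0 * sigma ** 2))


def psf_normalisation(psf_sigma: float) -> float:
    """Integrated intensity of a unit-peak Gaussian spot (2*pi*sigma^2)."""
    return 2.0 * math.pi * psf_sigma ** 2


def simulate_movie(
    scene: SceneConfig,
    programs: list[KineticProgram],
    template_bp: int = TEMPLATE_BP,
    allow_density_mismatch: bool = False,
) -> tuple[dict[str, Movie], GroundTruth]:
    """Render a full movie (per-channel stacks) plus its ground truth.

    Spots are placed with minimum separation 4*psf_sigma; each frame renders
    every molecule as a 2-D Gaussian whose peak amplitude is
    photon_scale * (that molecule's calibrated trajectory value), shifted by
    the cumulative stage drift; the whole frame (including the flat
    background) is modulated by a centred Gaussian beam profile, then Poisson
    shot noise and Gaussian read noise are applied.
    """
    n = len(programs)
    expected = scene.spot_density * scene.area_um2
    if not allow_density_mismatch and not (0.8 * expected <= n <= 1.2 * expected):
        raise ConfigurationError(
            f"{n} programs inconsistent with spot_density x area "
            f"(expected {expected:.1f} +/- 20%)")
    rng = np.random.default_rng(scene.seed)
    min_sep = max(4.0 * scene.psf_sigma, scene.min_separation)
    positions = _place_spots(scene, n, rng, min_sep)

    times = np.arange(scene.n_frames) * scene.frame_interval
    per_mol = [_program_values(p, template_bp, times) for p in programs]
    channels = ["dna"] + (["rpa"] if any("rpa" in v for v in per_mol) else [])

    rows, cols = scene.field_size
    if scene.beam_profile_sigma > 0:
        yy = np.arange(rows)[:, None] - (rows - 1) / 2.0
        xx = np.arange(cols)[None, :] - (cols - 1) / 2.0
        beam = np.exp(-(yy * yy + xx * xx) / (2.0 * scene.beam_profile_sigma ** 2))
    else:
        beam = np.ones((rows, cols))

    dy, dx = scene.drift_per_frame
    movies = {}
    for label in channels:
        stack = np.empty((scene.n_frames, rows, cols))
        for f in range(scene.n_frames):
            img = np.full((rows, cols), float(scene.background))
            oy, ox = f * dy, f * dx
            for (py, px), vals in zip(positions, per_mol):
                if label not in vals:
                    continue
                _render_spot(img, py + oy, px + ox,
                             scene.photon_scale * vals[label][f], scene.psf_sigma)
            img *= beam
            if scene.shot_noise:
                img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
            if scene.read_noise_sigma > 0:
                img = img + rng.normal(0.0, scene.read_noise_sigma, img.shape)
            stack[f] = img
        movies[label] = Movie(stack=stack, frame_interval=scene.frame_interval,
                              pixel_size=scene.pixel_size, channel=label)

    truth = GroundTruth(
        scene=scene,
        molecules=[
            MoleculeTruth(molecule_id=i, y=float(p[0]), x=float(p[1]),
                          program=prog, piecewise=true_piecewise(prog, template_bp))
            for i, (p, prog) in enumerate(zip(positions, programs))
        ],
        template_bp=template_bp,
    )
    return movies, truth


def write_movie(movies: dict[str, Movie], truth: GroundTruth,
                outdir: str | Path) -> None:
    """One TIFF per channel plus a JSON ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for label, movie in movies.items():
        movie.save(outdir / f"{label}.tif")
    truth.to_json(outdir / "ground_truth.json")
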