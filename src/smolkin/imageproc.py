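"""From raw movies to per-molecule intensity trajectories.

Pipeline order: flat-field (beam-profile) correction -> drift correction ->
threshold spot detection on an early-frame temporal mean -> ROI intensity
integration with local-annulus background subtraction.  Molecules are
surface-tethered and immobile after drift correction, so a single spot set
detected at the start of the movie is reused for every frame; there is no
particle tracking.

Coordinates are 0-based with the pixel-centre convention; times are
frame_index * frame_interval with frame 0 at t = 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import measure
from skimage.registration import phase_cross_correlation

from .errors import DegenerateInputError, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE_UM = 0.16  # typical for a 100x objective on a 16-um EMCCD chip


@dataclass
class Movie:
    """A single-channel image stack with acquisition metadata."""

    stack: np.ndarray               # frames x rows x cols, ADU
    frame_interval: float           # s
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM  # um / px
    channel: str = "dna"

    def __post_init__(self):
        self.stack = np.asarray(self.stack)
        if self.stack.ndim != 3:
            raise ParameterError("movie stack must be frames x rows x cols")
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.stack.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def save(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.stack.astype(np.float32))

    @classmethod
    def load(cls, path: str | Path, frame_interval: float,
             pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
             channel: str = "dna") -> "Movie":
        stack = tifffile.imread(str(path))
        if stack.ndim == 2:
            stack = stack[None]
        return cls(stack=np.asarray(stack, float), frame_interval=frame_interval,
                   pixel_size=pixel_size, channel=channel)


@dataclass
class IlluminationProfile:
    """Multiplicative flat-field correction factors (unit mean)."""

    field: np.ndarray

    def correct(self, movie: Movie) -> Movie:
        return Movie(stack=movie.stack / self.field, frame_interval=movie.frame_interval,
                     pixel_size=movie.pixel_size, channel=movie.channel)


@dataclass
class SpotSet:
    """Detected diffraction-limited spots (intensity-weighted centroids)."""

    y: np.ndarray            # row centroid, px
    x: np.ndarray            # col centroid, px
    area: np.ndarray         # px^2
    peak: np.ndarray         # ADU

    def __len__(self) -> int:
        return self.y.size


@dataclass
class Trajectory:
    """Per-molecule background-subtracted intensity over time.

    ``channels`` maps channel label -> intensity series; all series share
    ``times``.  The first channel is the DNA stain by convention.
    """

    molecule_id: int
    times: np.ndarray
    channels: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    def channel(self, label: str) -> np.ndarray:
        return self.channels[label]

    @property
    def primary(self) -> np.ndarray:
        return next(iter(self.channels.values()))


def estimate_illumination(movie: Movie, smoothing_sigma: float = 25.0) -> IlluminationProfile:
    """Estimate the excitation-beam profile from the temporal mean frame.

    A Gaussian blur with sigma much larger than the spot radius averages the
    diffraction-limited spots out, leaving the smooth illumination envelope,
    which is normalised to unit mean.
    """
    mean_frame = movie.stack.mean(axis=0)
    if not np.any(mean_frame > 0):
        raise DegenerateInputError("all-zero movie: cannot estimate illumination")
    smooth = ndimage.gaussian_filter(mean_frame, smoothing_sigma, mode="nearest")
    smooth = np.clip(smooth, np.finfo(float).tiny, None)
    profile = smooth / smooth.mean()
    return IlluminationProfile(field=profile)


def correct_drift(
    movie: Movie,
    reference: str = "first_frame",
    upsample_factor: int = 50,
) -> tuple[np.ndarray, Movie]:
    """Estimate and undo rigid stage drift by phase cross-correlation.

    Each frame is registered against the first frame (default) or chained
    against its predecessor (for slow drifts that accumulate beyond the
    correlation peak).  Shifts are sub-pixel; frames are resampled with
    linear interpolation by the negated estimates.

    Returns (shifts, registered movie); ``shifts[f]`` is the estimated
    (dy, dx) displacement of frame f relative to frame 0.
    """
    if movie.n_frames < 2:
        raise ParameterError("drift correction needs at least 2 frames")
    if reference not in ("first_frame", "previous_frame"):
        raise ParameterError(f"unknown reference {reference!r}")
    stack = movie.stack
    if float(stack.std()) == 0.0:
        logger.warning("featureless movie: applying zero drift correction")
        return np.zeros((movie.n_frames, 2)), movie

    shifts = np.zeros((movie.n_frames, 2))
    ref = stack[0]
    for f in range(1, movie.n_frames):
        target = stack[f - 1] if reference == "previous_frame" else ref
        shift, _, _ = phase_cross_correlation(
            target, stack[f], upsample_factor=upsample_factor, normalization=None
        )
        # phase_cross_correlation returns the shift that maps frame -> target
        delta = -np.asarray(shift, float)
        shifts[f] = shifts[f - 1] + delta if reference == "previous_frame" else delta

    registered = np.empty_like(stack, dtype=float)
    registered[0] = stack[0]
    for f in range(1, movie.n_frames):
        registered[f] = ndimage.shift(
            np.asarray(stack[f], float), -shifts[f], order=1, mode="nearest"
        )
    return shifts, Movie(stack=registered, frame_interval=movie.frame_interval,
                         pixel_size=movie.pixel_size, channel=movie.channel)


def detect_spots(
    image: np.ndarray,
    k_sigma: float = 5.0,
    min_area: int = 4,
    max_area: int = 200,
) -> SpotSet:
    """Threshold spot detection on a flat-fielded frame.

    Threshold = median + k_sigma * sigma_MAD, with sigma_MAD the
    1.4826-scaled median absolute deviation (robust to the bright spots
    themselves).  8-connected components with area inside
    [min_area, max_area] become spots; centroids are intensity-weighted
    after local median subtraction.  Two spots closer than the connectivity
    scale merge into one component — a documented consequence of the method.
    """
    img = np.asarray(image, float)
    med = float(np.median(img))
    sigma = 1.4826 * float(np.median(np.abs(img - med)))
    mask = img > med + k_sigma * sigma
    labels = measure.label(mask, connectivity=2)
    ys, xs, areas, peaks = [], [], [], []
    for region in measure.regionprops(labels, intensity_image=img - med):
        if not (min_area <= region.area <= max_area):
            continue
        cy, cx = region.centroid_weighted
        ys.append(cy)
        xs.append(cx)
        areas.append(region.area)
        peaks.append(region.intensity_max + med)
    return SpotSet(y=np.array(ys), x=np.array(xs),
                   area=np.array(areas), peak=np.array(peaks))


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    inside = dy * dy + dx * dx <= radius * radius
    return dy[inside], dx[inside]


def _annulus_offsets(inner: float, outer: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(outer))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = dy * dy + dx * dx
    ring = (d2 > inner * inner) & (d2 <= outer * outer)
    return dy[ring], dx[ring]


def extract_trajectories(
    movie: Movie,
    spots: SpotSet,
    roi_radius: float = 4.0,
    bg_annulus: tuple[float, float] = (6.0, 9.0),
    second_channel: Movie | None = None,
) -> list[Trajectory]:
    """Integrate each spot's intensity over time with background subtraction.

    Per frame, I = sum over the disc of radius ``roi_radius`` around the
    spot centre minus the annulus background median times the ROI pixel
    count.  Spots whose annulus exceeds the field are dropped (the count is
    logged).  When a second registered channel is given, the identical ROI
    is applied to it.  Overlapping ROIs are both kept and flagged.
    """
    if bg_annulus[0] < roi_radius or bg_annulus[1] <= bg_annulus[0]:
        raise ParameterError("background annulus must lie outside the ROI")
    rows, cols = movie.shape
    dyr, dxr = _disk_offsets(roi_radius)
    dya, dxa = _annulus_offsets(*bg_annulus)
    margin = int(np.ceil(bg_annulus[1]))

    centres = [(int(round(y)), int(round(x))) for y, x in zip(spots.y, spots.x)]
    in_bounds = [
        margin <= cy < rows - margin and margin <= cx < cols - margin
        for cy, cx in centres
    ]
    n_dropped = len(centres) - sum(in_bounds)
    if n_dropped:
        logger.info("dropped %d edge spot(s) with out-of-bounds ROI", n_dropped)

    # flag ROI overlaps (centre distance below two ROI radii)
    yy = spots.y[:, None] - spots.y[None, :]
    xx = spots.x[:, None] - spots.x[None, :]
    d2 = yy * yy + xx * xx
    np.fill_diagonal(d2, np.inf)
    overlapping = d2.min(axis=1) < (2 * roi_radius) ** 2 if len(spots) > 1 else \
        np.zeros(len(spots), bool)

    movies = {movie.channel: movie}
    if second_channel is not None:
        movies[second_channel.channel] = second_channel

    trajs: list[Trajectory] = []
    times = movie.times
    for mol_id, ((cy, cx), ok) in enumerate(zip(centres, in_bounds)):
        if not ok:
            continue
        channels = {}
        for label, mv in movies.items():
            roi = mv.stack[:, cy + dyr, cx + dxr]          # frames x roi px
            ann = mv.stack[:, cy + dya, cx + dxa]
            bg = np.median(ann, axis=1)
            channels[label] = roi.sum(axis=1) - bg * dyr.size
        trajs.append(Trajectory(
            molecule_id=mol_id, times=times, channels=channels,
            meta={"y": float(spots.y[mol_id]), "x": float(spots.x[mol_id]),
                  "overlapping_roi": bool(overlapping[mol_id])},
        ))
    return trajs


# ---------------------------------------------------------------------------
# trajectory CSV interchange (long format)

def trajectories_to_frame(trajs: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for tr in trajs:
        for label, intensity in tr.channels.items():
            rows.append(pd.DataFrame({
                "molecule_id": tr.molecule_id,
                "channel": label,
                "frame": np.arange(tr.times.size),
                "time_s": tr.times,
                "intensity": intensity,
            }))
    if not rows:
        return pd.DataFrame(
            columns=["molecule_id", "channel", "frame", "time_s", "intensity"])
    return pd.concat(rows, ignore_index=True)


def write_trajectories(trajs: list[Trajectory], path: str | Path) -> None:
    # %.17g keeps float64 round-trip exact through the CSV interchange
    trajectories_to_frame(trajs).to_csv(path, index=False, float_format="%.17g")


def read_trajectories(path: str | Path) -> list[Trajectory]:
    df = pd.read_csv(path, float_precision="round_trip")
    trajs = []
    for mol_id, group in df.groupby("molecule_id", sort=True):
        channels = {}
        times = None
        for label, sub in group.groupby("channel", sort=True):
            sub = sub.sort_values("frame")
            channels[label] = sub["intensity"].to_numpy(float)
            times = sub["time_s"].to_numpy(float)
        # DNA channel first when present
        if "dna" in channels:
            channels = {"dna": channels.pop("dna"), **channels}
        trajs.append(Trajectory(molecule_id=int(mol_id), times=times, channels=channels))
    return trajs
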