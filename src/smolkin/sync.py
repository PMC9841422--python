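"""Post-reaction synchronisation of single-molecule trajectories.

Each molecule's time axis is shifted so a well-defined end-of-reaction
event (the fitted activity end ``b``, or the detected dissociation drop)
sits at relative time zero, then the ensemble mean and SEM are computed on
the common frame grid.  Averaging after synchronisation preserves kinetic
shape that plain ensemble averaging washes out when molecules start and
finish at different times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class SynchronisedEnsemble:
    """Mean +/- SEM intensity on a grid anchored at the reaction end."""

    rel_times: np.ndarray                     # s; 0 = reaction end
    mean: dict[str, np.ndarray]               # per channel
    sem: dict[str, np.ndarray]
    n_contributing: np.ndarray
    n_molecules: int
    frame_interval: float
    excluded: list[int] = field(default_factory=list)

    def channel_mean(self, label: str) -> np.ndarray:
        return self.mean[label]

    def masked(self, min_n: int = 5) -> np.ndarray:
        """Boolean selector of grid points with enough contributing molecules."""
        return self.n_contributing >= min_n


def synchronise(
    trajs: list,
    anchors: list[float],
    min_n: int = 1,
) -> SynchronisedEnsemble:
    """Anchor every trajectory at its reaction end and average.

    ``trajs`` may be Trajectory objects (multi-channel) or
    CalibratedTrajectory objects (single calibrated series).  Each anchor is
    snapped to the nearest frame — drop detection is frame-quantised, so no
    sub-frame interpolation is attempted.  Molecules whose anchor lies
    outside their time range are excluded and logged.  Grid points with
    fewer than ``min_n`` contributors are trimmed from the ends.
    """
    if len(trajs) != len(anchors):
        raise ParameterError("one anchor per trajectory required")
    if not trajs:
        raise ParameterError("no trajectories to synchronise")

    def channels_of(tr) -> dict[str, np.ndarray]:
        if hasattr(tr, "channels"):
            return tr.channels
        return {"cal": tr.i_cal}   # CalibratedTrajectory

    dts = [float(tr.times[1] - tr.times[0]) for tr in trajs]
    dt = dts[0]
    if not np.allclose(dts, dt, rtol=1e-6):
        raise ParameterError("trajectories must share one frame interval")

    usable, offsets, excluded = [], [], []
    for i, (tr, anchor) in enumerate(zip(trajs, anchors)):
        if not (tr.times[0] <= anchor <= tr.times[-1]) or not np.isfinite(anchor):
            excluded.append(i)
            logger.info("molecule %d excluded: anchor %.3g s outside range", i, anchor)
            continue
        usable.append(tr)
        offsets.append(int(round((anchor - tr.times[0]) / dt)))
    if not usable:
        raise ParameterError("all anchors outside their trajectories")

    lo = min(-k for k in offsets)
    hi = max(tr.times.size - 1 - k for tr, k in zip(usable, offsets))
    grid = np.arange(lo, hi + 1)
    labels = list(channels_of(usable[0]).keys())

    sums = {c: np.zeros(grid.size) for c in labels}
    sqs = {c: np.zeros(grid.size) for c in labels}
    counts = np.zeros(grid.size, int)
    for tr, k in zip(usable, offsets):
        idx = np.arange(tr.times.size) - k - lo
        counts[idx] += 1
        for c, y in channels_of(tr).items():
            sums[c][idx] += y
            sqs[c][idx] += y * y

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = {c: np.where(counts > 0, sums[c] / np.maximum(counts, 1), np.nan)
                for c in labels}
        sem = {}
        for c in labels:
            var = (sqs[c] - counts * mean[c] ** 2) / np.maximum(counts - 1, 1)
            var = np.clip(var, 0.0, None)
            sem[c] = np.where(counts > 1, np.sqrt(var / np.maximum(counts, 1)), 0.0)

    keep = counts >= min_n
    first, last = np.argmax(keep), len(keep) - np.argmax(keep[::-1]) - 1
    sl = slice(first, last + 1)
    return SynchronisedEnsemble(
        rel_times=grid[sl] * dt,
        mean={c: mean[c][sl] for c in labels},
        sem={c: sem[c][sl] for c in labels},
        n_contributing=counts[sl],
        n_molecules=len(usable),
        frame_interval=dt,
        excluded=excluded,
    )
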