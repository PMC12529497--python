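"""Single-cell migration analysis: tracking, mean speed, MSD, PRW fits.

Nuclei time-lapse frames are segmented into centroids, linked into
trajectories by mutual-nearest-neighbor assignment, and summarized by the
two standard motility statistics:

* mean speed — average Euclidean step length per unit time over
  consecutive frames;
* mean squared displacement (MSD) — time-averaged
  ``MSD(tau) = < |r(t + tau) - r(t)|^2 >_t`` per cell, pooled over cells.

For a persistent random walk (Ornstein-Uhlenbeck velocity with stationary
2-D rms speed ``S`` and persistence time ``P``) the ensemble MSD follows
the Fuerth formula

    MSD(tau) = 2 S^2 P [ tau - P (1 - exp(-tau / P)) ]

which :class:`PRWModel` fits by weighted least squares to recover
``(S, P)``.  Units: micrometres and minutes throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import cdist
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

__all__ = [
    "Trajectory", "CentroidFrame", "MigrationStats",
    "detect_nuclei", "link_trajectories", "mean_speed", "msd",
    "ensemble_stats", "furth_msd", "PRWModel", "PRWResults", "fit_prw",
]


@dataclass(frozen=True)
class Trajectory:
    """One cell's time-stamped positions (um, min)."""

    cell_id: int
    frames: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "frames", np.asarray(self.frames, dtype=int))
        for name in ("t", "x", "y"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        n = len(self.frames)
        if not (len(self.t) == len(self.x) == len(self.y) == n) or n < 2:
            raise ValueError("frames, t, x, y must share length >= 2")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        dts = np.diff(self.t)
        if np.any(dts <= 0):
            raise ValueError("duplicate or decreasing time stamps")

    def __len__(self):
        return len(self.frames)

    @property
    def dt(self) -> float:
        return float(np.diff(self.t)[0])

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        dts = np.diff(self.t)
        return bool(np.allclose(dts, dts[0], rtol=rtol))


@dataclass(frozen=True)
class CentroidFrame:
    """Detected nucleus centroids of one frame (um)."""

    frame: int
    t: float                      # min
    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    area: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self):
        return len(self.x)


@dataclass(frozen=True)
class MigrationStats:
    """Pooled per-cell migration statistics of one condition."""

    speeds: np.ndarray            # per-cell mean speed (um/min)
    lags: np.ndarray              # min, starting at 0
    msd_mean: np.ndarray          # um^2, ensemble mean over cells per lag
    msd_sd: np.ndarray            # um^2
    msd_n: np.ndarray             # cells contributing per lag
    per_cell_msd: list            # list of (lags, msd) tuples

    @property
    def n_cells(self) -> int:
        return len(self.speeds)

    @property
    def speed_mean(self) -> float:
        return float(np.mean(self.speeds))

    @property
    def speed_sd(self) -> float:
        return float(np.std(self.speeds, ddof=1)) if len(self.speeds) > 1 else 0.0


# ---------------------------------------------------------------------------
# detection and linking


def detect_nuclei(image: np.ndarray, pixel_size: float,
                  min_area: float = 30.0, max_area: float | None = None,
                  frame: int = 0, t: float = 0.0) -> CentroidFrame:
    """Segment nuclei by Otsu two-class thresholding and return
    intensity-weighted centroids in micrometres.

    ``min_area``/``max_area`` are in um^2; components outside the window
    are discarded (``max_area`` rejects merged/clumped nuclei, whose
    centroid would fall between the true cells).  A uniform image yields
    an empty frame.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if image.max() == image.min():
        e = np.empty(0)
        return CentroidFrame(frame, t, e.copy(), e.copy(), e.copy(), e.copy())
    thr = threshold_otsu(image, nbins=256)
    labels = sk_label(image > thr, connectivity=2)
    min_px = min_area / pixel_size**2
    max_px = np.inf if max_area is None else max_area / pixel_size**2
    xs, ys, inten, areas = [], [], [], []
    for p in regionprops(labels, intensity_image=image):
        if not min_px <= p.area <= max_px:
            continue
        cy, cx = p.centroid_weighted
        xs.append(cx * pixel_size)
        ys.append(cy * pixel_size)
        inten.append(p.intensity_mean * p.area)
        areas.append(p.area * pixel_size**2)
    return CentroidFrame(frame, t, np.asarray(xs), np.asarray(ys),
                         np.asarray(inten), np.asarray(areas))


def link_trajectories(frames: Sequence[CentroidFrame],
                      max_step: float,
                      min_length: int = 3) -> list[Trajectory]:
    """Greedy mutual-nearest-neighbor linking of centroid frames.

    Per consecutive frame pair, a track end and a detection are linked iff
    each is the other's nearest neighbor and their distance is below
    ``max_step`` (um).  Unmatched detections open new tracks; unmatched
    track ends terminate (no gap closing).  Tracks shorter than
    ``min_length`` points are discarded.
    """
    frames = sorted(frames, key=lambda f: f.frame)
    open_tracks: list[dict] = []
    done: list[dict] = []
    next_id = 0

    def new_track(f: CentroidFrame, i: int):
        nonlocal next_id
        tr = {"id": next_id, "frames": [f.frame], "t": [f.t],
              "x": [f.x[i]], "y": [f.y[i]]}
        next_id += 1
        return tr

    for fi, f in enumerate(frames):
        if fi == 0:
            open_tracks = [new_track(f, i) for i in range(len(f))]
            continue
        linked_dets = set()
        still_open = []
        if open_tracks and len(f):
            ends = np.array([[tr["x"][-1], tr["y"][-1]] for tr in open_tracks])
            dets = np.column_stack([f.x, f.y])
            D = cdist(ends, dets)
            nn_det = D.argmin(axis=1)
            nn_trk = D.argmin(axis=0)
            for ti, tr in enumerate(open_tracks):
                j = nn_det[ti]
                if nn_trk[j] == ti and D[ti, j] <= max_step:
                    tr["frames"].append(f.frame)
                    tr["t"].append(f.t)
                    tr["x"].append(f.x[j])
                    tr["y"].append(f.y[j])
                    linked_dets.add(int(j))
                    still_open.append(tr)
                else:
                    done.append(tr)
        else:
            done.extend(open_tracks)
        open_tracks = still_open
        for j in range(len(f)):
            if j not in linked_dets:
                open_tracks.append(new_track(f, j))
    done.extend(open_tracks)

    out = []
    for tr in done:
        if len(tr["frames"]) >= min_length:
            out.append(Trajectory(tr["id"], tr["frames"], tr["t"],
                                  tr["x"], tr["y"]))
    return out


# ---------------------------------------------------------------------------
# statistics


def mean_speed(traj: Trajectory) -> float:
    """Mean speed (um/min): average step length / step duration over
    consecutive frame pairs."""
    dts = np.diff(traj.t)
    steps = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return float(np.mean(steps / dts))


def msd(traj: Trajectory, max_lag_fraction: float = 0.25,
        anchored: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """MSD curve of one trajectory: (lags in min, MSD in um^2), lag 0
    included as 0.

    Time-averaged over all overlapping pairs by default; ``anchored=True``
    instead measures squared displacement from the first point (a single
    pair per lag — the origin-anchored reading, higher variance).
    Lags run up to ``max_lag_fraction`` of the track length
    (``anchored`` uses every lag).
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 points for an MSD curve")
    if not traj.is_uniform():
        raise ValueError("non-uniform sampling: MSD requires a fixed dt")
    n = len(traj)
    dt = traj.dt
    if anchored:
        ks = np.arange(0, n)
        vals = (traj.x - traj.x[0])**2 + (traj.y - traj.y[0])**2
        return ks * dt, vals
    kmax = max(int(np.floor(max_lag_fraction * (n - 1))), 1)
    lags = np.arange(0, kmax + 1) * dt
    out = np.zeros(kmax + 1)
    for k in range(1, kmax + 1):
        dx = traj.x[k:] - traj.x[:-k]
        dy = traj.y[k:] - traj.y[:-k]
        out[k] = np.mean(dx**2 + dy**2)
    return lags, out


def ensemble_stats(trajs: Sequence[Trajectory],
                   max_lag_fraction: float = 0.25) -> MigrationStats:
    """Pool per-cell speeds and MSD curves into condition-level statistics.

    The ensemble mean and SD at each lag are taken over the cells whose
    tracks are long enough to contribute that lag.
    """
    trajs = [t for t in trajs]
    if len(trajs) == 0:
        raise ValueError("no trajectories supplied")
    speeds = np.array([mean_speed(t) for t in trajs])
    curves = [msd(t, max_lag_fraction=max_lag_fraction) for t in trajs
              if len(t) >= 3]
    if not curves:
        raise ValueError("no trajectory long enough for an MSD curve")
    dt = curves[0][0][1] - curves[0][0][0] if len(curves[0][0]) > 1 else 1.0
    kmax = max(len(lags) - 1 for lags, _ in curves)
    lags = np.arange(0, kmax + 1) * dt
    mean = np.zeros(kmax + 1)
    sd = np.zeros(kmax + 1)
    n = np.zeros(kmax + 1, dtype=int)
    for k in range(kmax + 1):
        vals = np.array([m[k] for lg, m in curves if len(m) > k])
        n[k] = len(vals)
        mean[k] = vals.mean()
        sd[k] = vals.std(ddof=1) if len(vals) > 1 else 0.0
    return MigrationStats(speeds=speeds, lags=lags, msd_mean=mean,
                          msd_sd=sd, msd_n=n, per_cell_msd=curves)


# ---------------------------------------------------------------------------
# PRW model


def furth_msd(tau, S: float, P: float):
    """2-D Fuerth MSD: ``2 S^2 P [tau - P (1 - exp(-tau/P))]``."""
    tau = np.asarray(tau, dtype=float)
    return 2.0 * S**2 * P * (tau - P * (1.0 - np.exp(-tau / P)))


class PRWModel:
    """Persistent-random-walk model fitted to an ensemble MSD curve.

    Weighted least squares of the Fuerth form on the mean MSD; for fixed
    persistence time ``P`` the squared speed enters linearly, so the fit
    reduces to a deterministic 1-D profile search over a log-spaced ``P``
    grid followed by bounded local refinement.

    Weights default to ``1 / lag`` (longer lags average fewer independent
    pairs); lag 0 is excluded.
    """

    #: persistence values beyond this multiple of the longest lag are not
    #: identifiable from the curve; estimates there are flagged at_bound
    P_BOUND_FACTOR = 10.0

    def __init__(self, lags: np.ndarray, msd_mean: np.ndarray,
                 weights: np.ndarray | None = None):
        lags = np.asarray(lags, dtype=float)
        m = np.asarray(msd_mean, dtype=float)
        keep = lags > 0
        self.lags = lags[keep]
        self.msd = m[keep]
        if len(self.lags) < 4:
            raise ValueError("need at least 4 nonzero lags to fit a PRW")
        self.weights = (1.0 / self.lags if weights is None
                        else np.asarray(weights, dtype=float)[keep])

    @classmethod
    def from_stats(cls, stats: MigrationStats,
                   min_support: float = 0.25, **kw) -> "PRWModel":
        """Build from ensemble statistics, fitting only well-supported lags.

        Lags contributed by fewer than ``min_support`` of the tracks are
        dropped: in tracked (fragmented) data the long-lag tail averages a
        self-selected subset of surviving tracks, whose mobility is not
        representative of the ensemble.
        """
        keep = stats.msd_n >= min_support * stats.msd_n.max()
        return cls(stats.lags[keep], stats.msd_mean[keep], **kw)

    def _profile(self, P: float) -> tuple[float, float]:
        """Best S^2 and weighted SSE at fixed P."""
        f = 2.0 * P * (self.lags - P * (1.0 - np.exp(-self.lags / P)))
        w = self.weights
        denom = float(w @ (f * f))
        if denom <= 0:
            return 0.0, float(w @ (self.msd**2))
        s2 = max(float(w @ (f * self.msd)) / denom, 0.0)
        r = self.msd - s2 * f
        return s2, float(w @ (r * r))

    def fit(self, n_grid: int = 80) -> "PRWResults":
        tmax = self.lags[-1]
        upper = self.P_BOUND_FACTOR * tmax * 10.0
        grid = np.logspace(np.log10(self.lags[0] / 10.0),
                           np.log10(upper), n_grid)
        sses = np.array([self._profile(P)[1] for P in grid])
        i = int(np.argmin(sses))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, n_grid - 1)]
        if hi > lo:
            res = minimize_scalar(lambda lp: self._profile(np.exp(lp))[1],
                                  bounds=(np.log(lo), np.log(hi)),
                                  method="bounded",
                                  options={"xatol": 1e-10})
            if not res.success:
                raise RuntimeError(
                    f"PRW fit did not converge; best grid point "
                    f"P = {grid[i]:.4g} min")
            P_hat = float(np.exp(res.x))
        else:
            P_hat = float(grid[i])
        s2, sse = self._profile(P_hat)
        S_hat = float(np.sqrt(s2))
        at_bound = P_hat > self.P_BOUND_FACTOR * tmax
        return PRWResults(self, S_hat, P_hat, sse, at_bound)


class PRWResults:
    """PRW fit: speed scale ``S`` (um/min), persistence ``P`` (min)."""

    def __init__(self, model: PRWModel, S: float, P: float, sse: float,
                 at_bound: bool):
        self.model = model
        self.S = S
        self.P = P
        self.sse = sse
        self.at_bound = at_bound

    @property
    def params(self) -> np.ndarray:
        return np.array([self.S, self.P])

    def predict(self, lags=None) -> np.ndarray:
        tau = self.model.lags if lags is None else lags
        return furth_msd(tau, self.S, self.P)

    def summary(self) -> str:
        lines = [
            "Persistent-random-walk (Fuerth) MSD fit",
            "=======================================",
            f"lags fitted          {len(self.model.lags)} "
            f"({self.model.lags[0]:.0f} - {self.model.lags[-1]:.0f} min)",
            f"speed scale S        {self.S:.4g} um/min",
            f"persistence time P   {self.P:.4g} min"
            + ("  [at identifiability bound]" if self.at_bound else ""),
            f"weighted SSE         {self.sse:.4g}",
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (f"<PRWResults S={self.S:.3g} um/min, P={self.P:.3g} min"
                f"{', at_bound' if self.at_bound else ''}>")


def fit_prw(stats: MigrationStats, **kw) -> PRWResults:
    """Fit the Fuerth MSD form to ensemble statistics; returns results
    carrying ``(S, P)`` estimates and an identifiability flag."""
    return PRWModel.from_stats(stats, **kw).fit()
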