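"""Seeded forward-model simulators with known ground truth.

Every downstream measurement stage has a generator here that produces its
input together with the true parameters, so parameter recovery can be
tested end to end:

* :func:`gen_indentation_curve` — Hertzian loading curves at the
  experimental geometry (R = 0.5 mm sphere, depths up to 200 um) plus
  Gaussian force noise.
* :func:`gen_traction_scene` — a traction field of Gaussian patches on a
  polyacrylamide-like gel, the exact elastic surface displacement it
  produces, and a fluorescent-bead image pair (reference / deformed)
  rendered with an isotropic Gaussian PSF.
* :func:`gen_prw_trajectories` — persistent random walks from the exact
  discrete-time Ornstein-Uhlenbeck velocity process, sampled at the
  10-min frame interval of overnight (16 h) live imaging.
* :func:`gen_fa_scene` — a three-channel morphometry scene: elliptical
  focal-adhesion spots inside a cell mask, with analytic per-object
  eccentricity in the ground truth.

Each generator is a pure function of its spec (seed included): identical
specs reproduce bit-identical outputs.  Sub-streams separate geometry
from noise, so changing a noise level does not reshuffle positions.
Noise is additive Gaussian throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .indentation import ForceDepthCurve, hertz_force
from .migration import Trajectory
from .tfm import DisplacementField, TractionField, forward_displacement

__all__ = [
    "SyntheticIndentationSpec", "TractionPatch", "SyntheticTractionSpec",
    "SyntheticPRWSpec", "EllipseMask", "SyntheticFASceneSpec",
    "SyntheticGroundTruth",
    "gen_indentation_curve", "gen_traction_scene", "gen_prw_trajectories",
    "gen_fa_scene", "render_nuclei_frames",
]


# ---------------------------------------------------------------------------
# ground truth container


def _encode(v):
    if isinstance(v, np.ndarray):
        return {"__ndarray__": v.tolist(), "dtype": str(v.dtype)}
    if isinstance(v, pd.DataFrame):
        return {"__dataframe__": v.to_dict(orient="list")}
    if isinstance(v, dict):
        return {k: _encode(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_encode(x) for x in v]
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def _decode(v):
    if isinstance(v, dict):
        if "__ndarray__" in v:
            return np.asarray(v["__ndarray__"], dtype=v["dtype"])
        if "__dataframe__" in v:
            return pd.DataFrame(v["__dataframe__"])
        return {k: _decode(x) for k, x in v.items()}
    if isinstance(v, list):
        return [_decode(x) for x in v]
    return v


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """True parameters attached to a generated scene.

    ``params`` holds the scenario-specific truth (modulus, traction field
    arrays, per-cell motility parameters, FA ellipse table...).  The
    to_dict/from_dict pair is a lossless YAML/JSON-safe round trip.
    """

    scenario: str
    params: dict

    def to_dict(self) -> dict:
        return {"scenario": self.scenario, "params": _encode(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticGroundTruth":
        return cls(scenario=d["scenario"], params=_decode(d["params"]))


# ---------------------------------------------------------------------------
# indentation


class SyntheticIndentationSpec(BaseModel):
    """Hertzian loading-curve generator parameters (SI units)."""

    model_config = ConfigDict(frozen=True)

    E_true: float = Field(9300.0, gt=0, description="Young's modulus (Pa)")
    R: float = Field(5e-4, gt=0, description="indenter radius (m)")
    poisson: float = Field(0.5, ge=0, le=0.5)
    depth_max: float = Field(200e-6, gt=0, description="max depth (m)")
    n_samples: int = Field(200, ge=2)
    noise_sd: float = Field(0.0, ge=0, description="force noise SD (N)")
    indentation_speed: float = Field(15e-6, gt=0,
                                     description="m/s (metadata only)")
    seed: int = 0


def gen_indentation_curve(spec: SyntheticIndentationSpec
                          ) -> tuple[ForceDepthCurve, SyntheticGroundTruth]:
    """Forward Hertz model plus Gaussian force noise.

    Depths are equally spaced on [0, depth_max]; with ``noise_sd = 0``
    every sample satisfies the closed form exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    depth = np.linspace(0.0, spec.depth_max, spec.n_samples)
    force = hertz_force(spec.E_true, spec.R, spec.poisson, depth)
    force = np.asarray(force) + rng.normal(0.0, spec.noise_sd, spec.n_samples) \
        if spec.noise_sd > 0 else np.asarray(force)
    curve = ForceDepthCurve(depth=depth, force=force, R=spec.R,
                            poisson=spec.poisson,
                            indentation_speed=spec.indentation_speed)
    gt = SyntheticGroundTruth("indentation",
                              {"E_true": spec.E_true,
                               "spec": spec.model_dump()})
    return curve, gt


# ---------------------------------------------------------------------------
# traction scene


class TractionPatch(BaseModel):
    """One Gaussian traction patch.

    ``direction=None`` makes the patch radially contractile (stress points
    inward, peaking at radius ``width``) — a force-balanced single-cell
    pattern.  A unit ``direction`` gives a directed Gaussian patch, which
    carries net force; combine such patches in balanced pairs.
    """

    model_config = ConfigDict(frozen=True)

    center_x: float               # um
    center_y: float               # um
    peak: float = Field(ge=0, description="peak stress (Pa)")
    width: float = Field(gt=0, description="Gaussian width sigma (um)")
    direction: Optional[tuple[float, float]] = None


class SyntheticTractionSpec(BaseModel):
    """Bead-image-pair generator driven by the elastic forward model."""

    model_config = ConfigDict(frozen=True)

    grid_shape: tuple[int, int] = (256, 256)      # (rows, cols)
    pixel_size: float = Field(0.4, gt=0)          # um / px
    E_gel: float = Field(30000.0, gt=0)           # Pa
    poisson: float = Field(0.5, ge=0, le=0.5)
    patches: tuple[TractionPatch, ...] = ()
    bead_density: float = Field(0.02, gt=0)       # beads / px^2
    bead_sigma: float = Field(0.8, gt=0)          # PSF sigma (um)
    bead_amplitude: float = Field(400.0, gt=0)    # intensity units
    background: float = Field(100.0, ge=0)
    noise_sd: float = Field(5.0, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        for p in self.patches:
            if p.width < 2 * self.pixel_size:
                raise ValueError(
                    "patch width must be >= 2 x pixel_size to be "
                    "representable on the grid")
        return self

    def default_cell_patch(self) -> "SyntheticTractionSpec":
        """The default scene: one contractile 300-Pa patch at the field
        center with 15-um width — a single adherent cell's footprint."""
        ny, nx = self.grid_shape
        patch = TractionPatch(center_x=nx * self.pixel_size / 2,
                              center_y=ny * self.pixel_size / 2,
                              peak=300.0, width=15.0, direction=None)
        return self.model_copy(update={"patches": (patch,)})


def build_patch_traction(spec: SyntheticTractionSpec) -> TractionField:
    """Evaluate the summed patch traction field on the pixel grid."""
    ny, nx = spec.grid_shape
    gx = np.arange(nx) * spec.pixel_size
    gy = np.arange(ny) * spec.pixel_size
    X, Y = np.meshgrid(gx, gy)
    tx = np.zeros((ny, nx))
    ty = np.zeros((ny, nx))
    for p in spec.patches:
        dx, dy = X - p.center_x, Y - p.center_y
        r2 = dx**2 + dy**2
        if p.direction is None:
            # contractile ring profile, max |t| = peak at r = width,
            # zero net force by symmetry
            r = np.sqrt(r2)
            mag = p.peak * (r / p.width) * np.exp(0.5 * (1 - r2 / p.width**2))
            with np.errstate(invalid="ignore", divide="ignore"):
                ux = np.where(r > 0, -dx / r, 0.0)
                uy = np.where(r > 0, -dy / r, 0.0)
            tx += mag * ux
            ty += mag * uy
        else:
            d = np.asarray(p.direction, dtype=float)
            d = d / np.linalg.norm(d)
            mag = p.peak * np.exp(-r2 / (2 * p.width**2))
            tx += mag * d[0]
            ty += mag * d[1]
    return TractionField(grid_x=gx, grid_y=gy, t_x=tx, t_y=ty,
                         E_gel=spec.E_gel, poisson=spec.poisson)


def _render_beads(shape: tuple[int, int], pos_px: np.ndarray,
                  sigma_px: float, amplitude: float) -> np.ndarray:
    """Sum of Gaussian spots stamped on local patches (x, y in px)."""
    img = np.zeros(shape)
    half = max(int(np.ceil(4 * sigma_px)), 2)
    ny, nx = shape
    for x, y in pos_px:
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(cx - half, 0), min(cx + half + 1, nx)
        y0, y1 = max(cy - half, 0), min(cy + half + 1, ny)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)[:, None]
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -((xs - x)**2 + (ys - y)**2) / (2 * sigma_px**2))
    return img


def gen_traction_scene(spec: SyntheticTractionSpec):
    """Forward traction scene: true fields plus a rendered bead-image pair.

    Returns ``(reference, deformed, true_traction, true_displacement,
    ground_truth)``.  Beads are placed uniformly at random; in the deformed
    image each bead moves by the true displacement interpolated bilinearly
    at its (continuous) position, so PIV error is measurable against an
    off-grid truth.
    """
    if len(spec.patches) == 0:
        spec = spec.default_cell_patch()
    traction = build_patch_traction(spec)
    disp = forward_displacement(traction)
    ny, nx = spec.grid_shape
    extent = min(nx, ny) * spec.pixel_size
    max_u = float(np.max(disp.magnitude))
    if max_u > 0.1 * extent:
        raise ValueError(
            f"peak displacement {max_u:.3g} um exceeds 10% of the field "
            "extent; use a stiffer E_gel or smaller patch stress")

    ss = np.random.SeedSequence(spec.seed)
    rng_pos, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]
    n_beads = int(round(spec.bead_density * nx * ny))
    pos = rng_pos.uniform([0, 0], [nx - 1, ny - 1], size=(n_beads, 2))  # px

    sigma_px = spec.bead_sigma / spec.pixel_size
    ref = _render_beads((ny, nx), pos, sigma_px, spec.bead_amplitude)

    from scipy.ndimage import map_coordinates
    coords = np.vstack([pos[:, 1], pos[:, 0]])       # (row, col)
    u_at = map_coordinates(disp.u, coords, order=1, mode="nearest")
    v_at = map_coordinates(disp.v, coords, order=1, mode="nearest")
    pos_def = pos + np.column_stack([u_at, v_at]) / spec.pixel_size
    deformed = _render_beads((ny, nx), pos_def, sigma_px, spec.bead_amplitude)

    for img in (ref, deformed):
        img += spec.background
        if spec.noise_sd > 0:
            img += rng_noise.normal(0.0, spec.noise_sd, img.shape)

    gt = SyntheticGroundTruth("traction", {
        "t_x": traction.t_x, "t_y": traction.t_y,
        "u": disp.u, "v": disp.v,
        "bead_positions_px": pos,
        "spec": spec.model_dump()})
    return ref, deformed, traction, disp, gt


# ---------------------------------------------------------------------------
# persistent random walks


class SyntheticPRWSpec(BaseModel):
    """PRW trajectory generator parameters (um, min)."""

    model_config = ConfigDict(frozen=True)

    n_cells: int = Field(300, ge=1)
    speed_scale: float = Field(0.4, gt=0, description="stationary rms "
                               "speed S (um/min)")
    persistence_time: float = Field(20.0, gt=0, description="min")
    dt: float = Field(10.0, gt=0, description="frame interval (min)")
    duration: float = Field(960.0, description="total time (min)")
    arena: Optional[tuple[float, float]] = None  # (width, height) um

    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.duration < 2 * self.dt:
            raise ValueError("duration must be >= 2 * dt")
        return self


def gen_prw_trajectories(spec: SyntheticPRWSpec
                         ) -> tuple[list[Trajectory], SyntheticGroundTruth]:
    """Exact discrete-time Ornstein-Uhlenbeck persistent random walks.

    The 2-D velocity process has relaxation time ``persistence_time`` and
    stationary rms speed ``speed_scale``; velocity and its time integral
    are sampled jointly from their exact Gaussian transition law, so the
    frame interval is not a convergence parameter.  Initial velocities are
    stationary; initial positions are uniform in ``arena`` (origin if no
    arena).  All trajectories have ``duration/dt + 1`` points.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    P, dt, S = spec.persistence_time, spec.dt, spec.speed_scale
    n_steps = int(round(spec.duration / dt))
    n = spec.n_cells
    sigma_v = S / np.sqrt(2.0)            # per-component stationary SD
    a = np.exp(-dt / P)
    var_v = sigma_v**2 * (1 - a**2)
    var_x = sigma_v**2 * P**2 * (2 * dt / P - 3 + 4 * a - a**2)
    cov_xv = sigma_v**2 * P * (1 - a)**2
    # conditional decomposition: eta_x | eta_v
    beta = cov_xv / var_v if var_v > 0 else 0.0
    var_x_c = max(var_x - cov_xv**2 / var_v, 0.0) if var_v > 0 else var_x

    if spec.arena is not None:
        w, h = spec.arena
        x = rng.uniform([0, 0], [w, h], size=(n, 2))
    else:
        x = np.zeros((n, 2))
    v = rng.normal(0.0, sigma_v, size=(n, 2))

    t = np.arange(n_steps + 1) * dt
    pos = np.empty((n_steps + 1, n, 2))
    vel = np.empty((n_steps + 1, n, 2))
    pos[0], vel[0] = x, v
    for k in range(1, n_steps + 1):
        n1 = rng.standard_normal((n, 2))
        n2 = rng.standard_normal((n, 2))
        eta_v = np.sqrt(var_v) * n1
        eta_x = beta * eta_v + np.sqrt(var_x_c) * n2
        x = x + v * P * (1 - a) + eta_x
        v = a * v + eta_v
        pos[k], vel[k] = x, v

    trajs = [Trajectory(cell_id=i, frames=np.arange(n_steps + 1), t=t,
                        x=pos[:, i, 0], y=pos[:, i, 1]) for i in range(n)]
    gt = SyntheticGroundTruth("prw", {
        "speed_scale": S, "persistence_time": P,
        "velocities": vel.reshape(n_steps + 1, -1),
        "spec": spec.model_dump()})
    return trajs, gt


def render_nuclei_frames(trajs: list[Trajectory], pixel_size: float,
                         shape: tuple[int, int], seed: int = 0,
                         origin: tuple[float, float] = (0.0, 0.0),
                         nucleus_sigma: float = 3.0,
                         amplitude: float = 1000.0,
                         background: float = 100.0,
                         noise_sd: float = 10.0):
    """Render trajectories as a nuclei time-lapse (one Gaussian blob per
    cell per frame).  Yields ``(frame_index, t_min, image)``.

    ``origin`` is the physical (x, y) position (um) of pixel (0, 0);
    choose it so the field of view extends beyond the seeded region, as an
    imaging field would, otherwise wanderers clip at the frame edge.
    Positions outside the frame are simply out of view.
    """
    n_frames = len(trajs[0].t)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    ox, oy = origin
    for k in range(n_frames):
        pos = np.array([[(tr.x[k] - ox) / pixel_size,
                         (tr.y[k] - oy) / pixel_size]
                        for tr in trajs if len(tr) > k])
        img = _render_beads(shape, pos, nucleus_sigma, amplitude)
        img += background
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd, img.shape)
        yield k, float(trajs[0].t[k]), img


# ---------------------------------------------------------------------------
# FA morphometry scene


class EllipseMask(BaseModel):
    """Axis-aligned-to-rotated ellipse footprint in pixel coordinates."""

    model_config = ConfigDict(frozen=True)

    center_x: float
    center_y: float
    semi_major: float = Field(gt=0)
    semi_minor: float = Field(gt=0)
    angle: float = 0.0            # rad, CCW from +x

    def contains(self, x, y, margin: float = 0.0):
        dx, dy = np.asarray(x) - self.center_x, np.asarray(y) - self.center_y
        c, s = np.cos(self.angle), np.sin(self.angle)
        xr = c * dx + s * dy
        yr = -s * dx + c * dy
        a = max(self.semi_major - margin, 1e-9)
        b = max(self.semi_minor - margin, 1e-9)
        return (xr / a)**2 + (yr / b)**2 <= 1.0


class SyntheticFASceneSpec(BaseModel):
    """Three-channel morphometry scene generator parameters."""

    model_config = ConfigDict(frozen=True)

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = Field(0.2, gt=0)          # um / px
    cell_mask: Optional[EllipseMask] = None       # default: centered ellipse
    n_fa: int = Field(40, ge=0)
    fa_major_axis: tuple[float, float] = (14.0, 3.0)   # full length px: mean, sd
    fa_minor_axis: tuple[float, float] = (6.0, 1.5)
    fa_intensity: float = Field(600.0, gt=0)
    background: float = Field(100.0, ge=0)
    noise_sd: float = Field(10.0, ge=0)
    seed: int = 0

    def resolved_cell_mask(self) -> EllipseMask:
        if self.cell_mask is not None:
            return self.cell_mask
        ny, nx = self.image_shape
        return EllipseMask(center_x=nx / 2, center_y=ny / 2,
                           semi_major=0.4 * nx, semi_minor=0.3 * ny)


def _ellipse_coverage(shape, cx, cy, a, b, angle, supersample: int = 3):
    """Anti-aliased ellipse: per-pixel coverage fraction on a local patch.

    Returns (slice_y, slice_x, coverage array).
    """
    r = int(np.ceil(max(a, b))) + 2
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, shape[1])
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, shape[0])
    ss = supersample
    off = (np.arange(ss) + 0.5) / ss - 0.5
    xs = (np.arange(x0, x1)[:, None] + off).ravel()
    ys = (np.arange(y0, y1)[:, None] + off).ravel()
    X, Y = np.meshgrid(xs, ys)
    c, s = np.cos(angle), np.sin(angle)
    dx, dy = X - cx, Y - cy
    xr = c * dx + s * dy
    yr = -s * dx + c * dy
    inside = ((xr / a)**2 + (yr / b)**2 <= 1.0).astype(float)
    cov = inside.reshape(y1 - y0, ss, x1 - x0, ss).mean(axis=(1, 3))
    return slice(y0, y1), slice(x0, x1), cov


def gen_fa_scene(spec: SyntheticFASceneSpec):
    """FA morphometry scene: (fa_image, nuclei_image, cell_image, truth).

    Elliptical FA spots with anti-aliased edges are placed without overlap
    inside the cell mask; the ground-truth table carries each ellipse's
    center, axes, orientation and analytic eccentricity
    ``sqrt(1 - (b/a)^2)``.
    """
    ny, nx = spec.image_shape
    cell = spec.resolved_cell_mask()
    ss = np.random.SeedSequence(spec.seed)
    rng_geom, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]

    placed: list[dict] = []
    max_tries = 200
    for i in range(spec.n_fa):
        ok = False
        for _ in range(max_tries):
            major = max(rng_geom.normal(*spec.fa_major_axis), 4.0)
            minor = float(np.clip(rng_geom.normal(*spec.fa_minor_axis),
                                  2.0, major))
            angle = rng_geom.uniform(0, np.pi)
            a, b = major / 2.0, minor / 2.0
            x = rng_geom.uniform(0, nx)
            y = rng_geom.uniform(0, ny)
            if not cell.contains(x, y, margin=a + 1):
                continue
            clear = True
            for q in placed:
                dmin = a + q["major_px"] / 2.0 + 3.0
                if (x - q["center_x_px"])**2 + (y - q["center_y_px"])**2 < dmin**2:
                    clear = False
                    break
            if clear:
                placed.append({
                    "center_x_px": x, "center_y_px": y,
                    "major_px": major, "minor_px": minor,
                    "orientation_rad": angle,
                    "eccentricity": float(np.sqrt(1 - (minor / major)**2)),
                })
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place FA {i + 1}/{spec.n_fa} without overlap "
                f"after {max_tries} tries; reduce n_fa or FA size")

    fa_img = np.zeros((ny, nx))
    for q in placed:
        sy, sx, cov = _ellipse_coverage(
            (ny, nx), q["center_x_px"], q["center_y_px"],
            q["major_px"] / 2.0, q["minor_px"] / 2.0, q["orientation_rad"])
        fa_img[sy, sx] += spec.fa_intensity * cov

    X, Y = np.meshgrid(np.arange(nx), np.arange(ny))
    cell_fg = cell.contains(X, Y)
    cell_img = np.where(cell_fg, 400.0, 0.0)
    nucleus = EllipseMask(center_x=cell.center_x, center_y=cell.center_y,
                          semi_major=min(30.0, cell.semi_major / 3),
                          semi_minor=min(25.0, cell.semi_minor / 3),
                          angle=cell.angle)
    nuc_img = np.where(nucleus.contains(X, Y), 800.0, 0.0)

    for img in (fa_img, nuc_img, cell_img):
        img += spec.background
        if spec.noise_sd > 0:
            img += rng_noise.normal(0.0, spec.noise_sd, img.shape)

    table = pd.DataFrame(placed) if placed else pd.DataFrame(
        columns=["center_x_px", "center_y_px", "major_px", "minor_px",
                 "orientation_rad", "eccentricity"])
    gt = SyntheticGroundTruth("fa_scene", {
        "fa_table": table,
        "cell_mask": cell.model_dump(),
        "spec": spec.model_dump()})
    return fa_img, nuc_img, cell_img, gt
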