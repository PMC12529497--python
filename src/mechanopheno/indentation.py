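"""Young's modulus estimation from spherical-indenter loading curves.

A rigid sphere of radius ``R`` pressed a depth ``d`` into an elastic
half-space of Young's modulus ``E`` and Poisson's ratio ``nu`` carries the
Hertz contact force

    F(d) = (4 sqrt(R) / 3) * E / (1 - nu^2) * d^(3/2)

Hydrogels are treated as incompressible (``nu = 0.5``).  Because the model
is linear in ``E`` once ``d^(3/2)`` is known, the least-squares estimator
has a closed form and needs no iterative optimisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ForceDepthCurve",
    "ElasticModulusEstimate",
    "HertzModel",
    "HertzResults",
    "hertz_force",
    "fit_hertz",
    "summarize_samples",
]


def hertz_force(E: float, R: float, poisson: float, d) -> np.ndarray | float:
    """Hertz contact force (N) of a spherical indenter at depth ``d`` (m).

    Parameters
    ----------
    E : Young's modulus (Pa), > 0.
    R : indenter radius of curvature (m), > 0.
    poisson : Poisson's ratio, in [0, 1).
    d : indentation depth (m), scalar or array, >= 0.
    """
    if E <= 0:
        raise ValueError(f"E must be positive, got {E}")
    if R <= 0:
        raise ValueError(f"R must be positive, got {R}")
    if not 0 <= poisson < 1:
        raise ValueError(f"poisson must be in [0, 1), got {poisson}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("indentation depth d must be non-negative")
    out = (4.0 * np.sqrt(R) / 3.0) * E / (1.0 - poisson**2) * d**1.5
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ForceDepthCurve:
    """One loading curve: matched depth (m) and force (N) samples.

    ``depth`` must be non-decreasing with at least two samples; the contact
    point is assumed to sit at ``depth = 0`` (curves are pre-zeroed).
    """

    depth: np.ndarray
    force: np.ndarray
    R: float
    poisson: float = 0.5
    sample_id: str = ""
    thickness: float | None = None
    indentation_speed: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "depth", np.asarray(self.depth, dtype=float))
        object.__setattr__(self, "force", np.asarray(self.force, dtype=float))
        if self.depth.ndim != 1 or self.depth.shape != self.force.shape:
            raise ValueError("depth and force must be matching 1-D arrays")
        if len(self.depth) < 2:
            raise ValueError("need at least 2 samples")
        if np.any(np.diff(self.depth) < 0):
            raise ValueError("depth must be non-decreasing")
        if np.any(self.depth < 0):
            raise ValueError("depth must be non-negative")
        if self.R <= 0:
            raise ValueError(f"R must be positive, got {self.R}")
        if not 0 <= self.poisson <= 0.5:
            raise ValueError(f"poisson must be in [0, 0.5], got {self.poisson}")


@dataclass(frozen=True)
class ElasticModulusEstimate:
    """Point estimate of the Young's modulus from one loading curve."""

    E: float                      # Pa
    stderr: float                 # Pa
    rmse: float                   # N, residual RMS of the fit
    n_points: int
    depth_range_used: tuple[float, float]  # m
    sample_id: str = ""


class HertzModel:
    """Hertz spherical-indentation model bound to one loading curve.

    The force is linear in ``E`` given ``d^(3/2)``, so ``fit`` uses the
    exact weighted-projection estimator rather than an iterative solver.

    Parameters
    ----------
    curve : ForceDepthCurve
    depth_fraction : optional (lo, hi) fractions of the maximal depth
        delimiting the fit window; default uses the full curve.
    """

    def __init__(self, curve: ForceDepthCurve,
                 depth_fraction: tuple[float, float] | None = None):
        self.curve = curve
        self.depth_fraction = depth_fraction

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, R: float, poisson: float = 0.5,
                       depth_col: str = "depth_m", force_col: str = "force_n",
                       **kwargs) -> "HertzModel":
        curve = ForceDepthCurve(df[depth_col].to_numpy(),
                                df[force_col].to_numpy(), R=R, poisson=poisson)
        return cls(curve, **kwargs)

    def _window(self) -> np.ndarray:
        d = self.curve.depth
        if self.depth_fraction is None:
            return np.ones_like(d, dtype=bool)
        lo, hi = self.depth_fraction
        dmax = d.max()
        return (d >= lo * dmax) & (d <= hi * dmax)

    def fit(self) -> "HertzResults":
        c = self.curve
        keep = self._window()
        d, f = c.depth[keep], c.force[keep]
        if len(d) < 5:
            raise ValueError("need at least 5 points in the fit window")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(f))):
            raise ValueError("non-finite values in the fit window")
        x = (4.0 * np.sqrt(c.R) / 3.0) / (1.0 - c.poisson**2) * d**1.5
        sxx = float(x @ x)
        if sxx == 0.0:
            raise ValueError("degenerate curve: all depths zero in window")
        E_hat = float(x @ f) / sxx
        if E_hat <= 0:
            raise ValueError(f"non-physical fit: E = {E_hat:.3g} Pa <= 0")
        resid = f - E_hat * x
        dof = max(len(d) - 1, 1)
        sigma2 = float(resid @ resid) / dof
        stderr = float(np.sqrt(sigma2 / sxx))
        rmse = float(np.sqrt(np.mean(resid**2)))
        return HertzResults(self, E_hat, stderr, rmse, len(d),
                            (float(d.min()), float(d.max())))


class HertzResults:
    """Fit results: ``E`` (Pa), its standard error, and fit diagnostics."""

    def __init__(self, model: HertzModel, E: float, stderr: float,
                 rmse: float, n_points: int,
                 depth_range: tuple[float, float]):
        self.model = model
        self.E = E
        self.stderr = stderr
        self.rmse = rmse
        self.n_points = n_points
        self.depth_range_used = depth_range

    @property
    def params(self) -> np.ndarray:
        return np.array([self.E])

    @property
    def bse(self) -> np.ndarray:
        return np.array([self.stderr])

    def predict(self, depth=None) -> np.ndarray:
        d = self.model.curve.depth if depth is None else depth
        c = self.model.curve
        return hertz_force(self.E, c.R, c.poisson, d)

    def as_estimate(self) -> ElasticModulusEstimate:
        return ElasticModulusEstimate(
            E=self.E, stderr=self.stderr, rmse=self.rmse,
            n_points=self.n_points, depth_range_used=self.depth_range_used,
            sample_id=self.model.curve.sample_id)

    def summary(self) -> str:
        c = self.model.curve
        lines = [
            "Hertz spherical-indentation fit",
            "===============================",
            f"samples used       {self.n_points}",
            f"depth range (um)   {self.depth_range_used[0]*1e6:.2f} - "
            f"{self.depth_range_used[1]*1e6:.2f}",
            f"R (mm)             {c.R*1e3:.3f}",
            f"Poisson ratio      {c.poisson:.2f}",
            f"E (Pa)             {self.E:.6g} +/- {self.stderr:.3g}",
            f"residual RMS (N)   {self.rmse:.3g}",
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (f"<HertzResults E={self.E:.4g} Pa "
                f"(+/- {self.stderr:.2g}), n={self.n_points}>")


def fit_hertz(curve: ForceDepthCurve,
              depth_fraction: tuple[float, float] | None = None
              ) -> ElasticModulusEstimate:
    """Least-squares Young's modulus from a loading curve (closed form)."""
    return HertzModel(curve, depth_fraction=depth_fraction).fit().as_estimate()


def summarize_samples(estimates: Sequence[ElasticModulusEstimate],
                      grouping: Sequence[str] | None = None) -> pd.DataFrame:
    """Two-level aggregation: per-sample means first, then across-sample
    mean +/- SD per group.

    ``grouping`` assigns each estimate to a condition group; defaults to a
    single group.  Within a group, repeats of the same ``sample_id`` are
    averaged before the across-sample statistics, mirroring the
    repeated-measurements-per-sample experimental design.
    """
    if len(estimates) == 0:
        raise ValueError("no estimates supplied")
    if grouping is None:
        grouping = ["all"] * len(estimates)
    if len(grouping) != len(estimates):
        raise ValueError("grouping must match estimates in length")
    df = pd.DataFrame({
        "group": list(grouping),
        "sample_id": [e.sample_id for e in estimates],
        "E": [e.E for e in estimates],
    })
    per_sample = df.groupby(["group", "sample_id"], sort=True)["E"].mean()
    out = per_sample.groupby("group").agg(
        E_mean="mean", E_sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
        n_samples="count")
    return out.reset_index()
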