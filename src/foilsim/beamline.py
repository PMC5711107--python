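"""Dual-foil beamline geometry and secondary-foil parameterization.

The axial coordinate z is zero at the top of the primary foil; the top
of the secondary foil sits at z1 and the calculation plane at z2 (depth
d past isocenter).  The vacuum exit window sits upstream of the primary
foil at negative z.

A secondary foil is an axisymmetric stack of annular segments of
piecewise-constant thickness.  Gaussian foil designs are segmented the
way such foils are machined: equally spaced annuli whose steps cross
the true Gaussian at the midpoint of each descending edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .materials import Material, get_material


@dataclass(frozen=True)
class BeamlineGeometry:
    """Distances defining the dual-foil system (all cm).

    ``z1`` is the top of the secondary foil, ``z_iso`` the isocenter and
    ``z2`` the calculation plane, all measured from the top of the
    primary foil.  ``SAD`` is the nominal source-to-axis distance used
    by the inverse-square factors of the X-ray model; the transport
    itself uses the explicit distances.
    """

    d_window_primary: float
    d_primary_secondary: float
    d_secondary_iso: float
    SAD: float = 100.0
    calc_depth: float = 2.0

    def __post_init__(self) -> None:
        for attr in ("d_window_primary", "d_primary_secondary", "d_secondary_iso", "SAD"):
            if getattr(self, attr) <= 0.0:
                raise ValueError(f"{attr} must be > 0")
        if self.calc_depth < 0.0:
            raise ValueError("calc_depth must be >= 0")

    @property
    def z_window(self) -> float:
        return -self.d_window_primary

    @property
    def z1(self) -> float:
        return self.d_primary_secondary

    @property
    def z_iso(self) -> float:
        return self.d_primary_secondary + self.d_secondary_iso

    @property
    def z2(self) -> float:
        return self.z_iso + self.calc_depth


@dataclass(frozen=True)
class GaussianFoilSpec:
    """Gaussian secondary-foil design: t(r) = t0 exp(-r^2 / 2 sigma^2)."""

    material: Material
    t0: float
    sigma: float
    n_segments: int
    r_max: float = 3.65

    def __post_init__(self) -> None:
        if self.t0 <= 0.0:
            raise ValueError("t0 must be > 0")
        if self.sigma <= 0.0:
            raise ValueError("sigma must be > 0")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.r_max <= 0.0:
            raise ValueError("r_max must be > 0")


@dataclass(frozen=True)
class SegmentedFoil:
    """Piecewise-constant axisymmetric foil.

    ``boundaries[k]`` is the outer radius of annulus k, which has
    thickness ``thicknesses[k]``; annuli are half-open ``[r_k, r_{k+1})``
    and the thickness is zero beyond the last boundary.
    """

    boundaries: np.ndarray
    thicknesses: np.ndarray
    material: Material

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        t = np.asarray(self.thicknesses, dtype=float)
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "thicknesses", t)
        if b.ndim != 1 or b.shape != t.shape or b.size == 0:
            raise ValueError("boundaries and thicknesses must be equal-length 1-D arrays")
        if b[0] <= 0.0 or np.any(np.diff(b) <= 0.0):
            raise ValueError("boundaries must be strictly increasing and positive")
        if np.any(t < 0.0):
            raise ValueError("thicknesses must be >= 0")

    @property
    def r_max(self) -> float:
        return float(self.boundaries[-1])

    @property
    def max_thickness(self) -> float:
        return float(self.thicknesses.max())

    @property
    def min_positive_thickness(self) -> float:
        pos = self.thicknesses[self.thicknesses > 0.0]
        return float(pos.min()) if pos.size else 0.0

    def local_thickness(self, r):
        """Thickness at radius r (cm); boundary radii belong to the inner annulus."""
        rq = np.abs(np.asarray(r, dtype=float))
        # side="left": r exactly on boundary k maps to annulus k (inner side)
        idx = np.searchsorted(self.boundaries, rq, side="left")
        t = np.where(idx < self.thicknesses.size,
                     self.thicknesses[np.minimum(idx, self.thicknesses.size - 1)], 0.0)
        return t if t.ndim else float(t)


def gaussian_thickness(r, spec: GaussianFoilSpec):
    """Thickness of the ideal Gaussian foil at radius r."""
    r = np.asarray(r, dtype=float)
    t = spec.t0 * np.exp(-(r * r) / (2.0 * spec.sigma**2))
    return t if t.ndim else float(t)


def segment_gaussian_foil(spec: GaussianFoilSpec) -> SegmentedFoil:
    """Stair-step approximation of a Gaussian foil.

    Annuli are equally spaced on [0, r_max].  The innermost thickness is
    anchored to the mean of the true Gaussian over the central annulus;
    each internal step is then placed so that the midpoint of its
    descending edge lies on the true Gaussian:
    ``(t_k + t_{k+1})/2 = t_gauss(r_k)``, clamped at zero.
    """
    n = spec.n_segments
    edges = np.linspace(0.0, spec.r_max, n + 1)
    boundaries = edges[1:]
    t = np.empty(n)
    if n == 1:
        t[0] = spec.t0
    else:
        # area-weighted mean of the Gaussian over the central annulus:
        # (2/r1^2) * int_0^r1 r t(r) dr
        r1 = boundaries[0]
        s2 = 2.0 * spec.sigma**2
        t[0] = (s2 / (r1 * r1)) * spec.t0 * (1.0 - math.exp(-(r1 * r1) / s2))
        for k in range(1, n):
            t[k] = max(0.0, 2.0 * gaussian_thickness(boundaries[k - 1], spec) - t[k - 1])
    return SegmentedFoil(boundaries=boundaries, thicknesses=t, material=spec.material)


def load_secondary_foil_file(path) -> SegmentedFoil:
    """Read a secondary-foil CSV (``# material=<name>`` header line, then
    ``r_outer_cm,thickness_cm`` rows)."""
    material: Material | None = None
    rs: list[float] = []
    ts: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            if text.startswith("#"):
                body = text.lstrip("#").strip()
                if body.lower().startswith("material"):
                    material = get_material(body.split("=", 1)[1].strip())
                continue
            if text.lower().startswith("r_outer_cm"):
                continue
            parts = text.replace(",", " ").split()
            try:
                r, t = float(parts[0]), float(parts[1])
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}: line {lineno}: expected 'r_outer_cm,thickness_cm', got {text!r}"
                ) from exc
            if rs and r <= rs[-1]:
                raise ValueError(
                    f"{path}: line {lineno}: radii must be strictly increasing "
                    f"({r:g} <= {rs[-1]:g})"
                )
            rs.append(r)
            ts.append(t)
    if material is None:
        raise ValueError(f"{path}: missing '# material=<name>' line")
    if not rs:
        raise ValueError(f"{path}: no segment rows")
    return SegmentedFoil(np.asarray(rs), np.asarray(ts), material)


def write_secondary_foil_file(foil: SegmentedFoil, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# material={foil.material.name}\n")
        fh.write("r_outer_cm,thickness_cm\n")
        for r, t in zip(foil.boundaries, foil.thicknesses):
            fh.write(f"{r:.17g},{t:.17g}\n")
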