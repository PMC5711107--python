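"""Radial profile container and two-column profile file I/O.

A :class:`Profile` holds relative values on a radial grid.  Profiles may
be stored on a non-negative half-grid (axially symmetric quantities are
computed that way and mirrored for display) or on a full symmetric
grid.  The ``normalization`` tag records the convention:

- ``cax_100``: central-axis value is 100 (percent scale),
- ``cax_1``: central-axis value is 1,
- ``absolute_per_electron``: per-incident-electron planar fluence, 1/cm^2,
- ``percent_of_dmax``: percent of the central-axis dose maximum (the
  X-ray contamination scale; the value at r = 0 is the central-axis
  X-ray percent dose, not 100).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

NORMALIZATIONS = ("cax_100", "cax_1", "absolute_per_electron", "percent_of_dmax")


@dataclass(frozen=True)
class Profile:
    r: np.ndarray
    v: np.ndarray
    normalization: str = "cax_1"

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "v", v)
        if r.ndim != 1 or r.shape != v.shape:
            raise ValueError("r and v must be 1-D arrays of equal length")
        if not np.all(np.diff(r) > 0):
            raise ValueError("radial grid must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("profile values must be finite")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "cax_100" and abs(self.at(0.0) - 100.0) > 1e-9:
            raise ValueError("cax_100 profile must have v(0) == 100")

    @property
    def is_half_grid(self) -> bool:
        return self.r[0] >= 0.0

    def at(self, r, extrapolate: bool = False):
        """Linearly interpolate the profile at radius ``r`` (mirrors a half-grid)."""
        rq = np.abs(np.asarray(r, dtype=float)) if self.is_half_grid else np.asarray(r, dtype=float)
        if not extrapolate:
            lo, hi = self.r[0], self.r[-1]
            if np.any(rq < lo - 1e-12) or np.any(rq > hi + 1e-12):
                raise ValueError(
                    f"radius outside profile support [{lo:g}, {hi:g}] cm"
                )
        return np.interp(rq, self.r, self.v)

    def mirrored(self) -> "Profile":
        """Full symmetric grid version of a half-grid profile."""
        if not self.is_half_grid:
            return self
        if self.r[0] == 0.0:
            r = np.concatenate([-self.r[:0:-1], self.r])
            v = np.concatenate([self.v[:0:-1], self.v])
        else:
            r = np.concatenate([-self.r[::-1], self.r])
            v = np.concatenate([self.v[::-1], self.v])
        return Profile(r, v, self.normalization)

    def rescaled(self, normalization: str) -> "Profile":
        """Convert between the two central-axis normalization conventions."""
        if normalization == self.normalization:
            return self
        v0 = self.at(0.0)
        if v0 == 0.0:
            raise ValueError("cannot renormalize a profile with zero CAX value")
        target = {"cax_1": 1.0, "cax_100": 100.0}
        if normalization not in target:
            raise ValueError(f"cannot rescale to {normalization!r}")
        return Profile(self.r, self.v * (target[normalization] / v0), normalization)


def read_profile_file(path) -> Profile:
    """Read a two-column (position_cm, relative_dose) text profile.

    Columns may be separated by whitespace or commas; lines starting
    with ``#`` are comments.  Malformed rows raise with a line number.
    """
    rs: list[float] = []
    vs: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.replace(",", " ").split()
            try:
                r, v = float(parts[0]), float(parts[1])
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}: line {lineno}: expected two numeric columns, got {text!r}"
                ) from exc
            rs.append(r)
            vs.append(v)
    if not rs:
        raise ValueError(f"{path}: no data rows")
    order = np.argsort(rs)
    return Profile(np.asarray(rs)[order], np.asarray(vs)[order], "cax_1")


def write_profile_file(profile: Profile, path, header: Iterable[str] = ()) -> None:
    """Write a profile as two-column text, lossless at 9 significant digits."""
    full = profile.mirrored()
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("# position_cm  relative_dose\n")
        for r, v in zip(full.r, full.v):
            fh.write(f"{r:.9g}  {v:.9g}\n")
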