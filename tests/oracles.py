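"""Independent numerical oracles used by the test suite.

These deliberately avoid the production code paths they check: the
random walk samples explicit Gaussian scattering kicks slab by slab,
and the Cartesian convolution integrates the pencil-beam kernel on a
dense rectangular grid instead of the polar quadrature.
"""

import math

import numpy as np

from foilsim.transport import pencil_kernel_variance


def random_walk(elements, z_plane, n_particles, rng, n_sub=50):
    """Propagate particles through thin/extended Gaussian scatterers.

    ``elements`` are TransportElement-like (T, thickness, z_top,
    extended); per-axis kick variance over a path dz is T dz / 2.
    Returns (x, y, tx, ty) at ``z_plane``.
    """
    x = np.zeros(n_particles)
    y = np.zeros(n_particles)
    tx = np.zeros(n_particles)
    ty = np.zeros(n_particles)
    z = None
    for el in sorted(elements, key=lambda e: e.z_top):
        if el.extended:
            dz_slab = el.thickness / n_sub
            for i in range(n_sub):
                z_mid = el.z_top + (i + 0.5) * dz_slab
                if z is None:
                    z = z_mid
                else:
                    x += tx * (z_mid - z)
                    y += ty * (z_mid - z)
                    z = z_mid
                s = math.sqrt(el.T * dz_slab / 2.0)
                tx += rng.normal(0.0, s, n_particles)
                ty += rng.normal(0.0, s, n_particles)
        else:
            z_mid = el.z_top + 0.5 * el.thickness
            if z is None:
                z = z_mid
            else:
                x += tx * (z_mid - z)
                y += ty * (z_mid - z)
                z = z_mid
            s = math.sqrt(el.T * el.thickness / 2.0)
            tx += rng.normal(0.0, s, n_particles)
            ty += rng.normal(0.0, s, n_particles)
    x += tx * (z_plane - z)
    y += ty * (z_plane - z)
    return x, y, tx, ty


def cartesian_convolution(
    r_out, moments_z1, foil, geometry, E_sec, T_air, n=1501, kernel="conditional"
):
    """Dense rectangular-grid evaluation of the pencil-beam convolution.

    Shares the physics inputs (z1 fluence, kernel variances) with the
    production path but replaces the polar quadrature with a Cartesian
    Riemann sum over the source disc.
    """
    rmax = foil.r_max
    xs = np.linspace(-rmax, rmax, n)
    h = xs[1] - xs[0]
    X, Y = np.meshgrid(xs, xs)
    rho = np.hypot(X, Y)
    disc = rho <= rmax
    A2 = moments_z1.A2
    phi = np.where(disc, np.exp(-(rho**2) / A2) / (math.pi * A2), 0.0)

    # kernel variance per annulus (piecewise constant in rho)
    edges = np.concatenate([[0.0], foil.boundaries])
    reps = 0.5 * (edges[:-1] + edges[1:])
    var_by_annulus = np.array(
        [
            pencil_kernel_variance(
                float(r), foil, geometry, moments_z1, E_sec, T_air, kernel
            )
            for r in reps
        ]
    )
    idx = np.searchsorted(foil.boundaries, rho, side="left")
    idx = np.minimum(idx, len(var_by_annulus) - 1)
    sig2 = var_by_annulus[idx]

    proj = geometry.z2 / geometry.z1
    out = np.empty(len(r_out))
    w = phi * h * h
    px, py = proj * X, proj * Y
    for i, r in enumerate(r_out):
        d2 = (r - px) ** 2 + py**2
        out[i] = float(np.sum(w * np.exp(-d2 / sig2) / (math.pi * sig2)))
    return out


def e1_series(x: float) -> float:
    """E1 by power series (x <= 1): -gamma - ln x + sum (-1)^(k+1) x^k/(k k!)."""
    gamma = 0.5772156649015329
    total = -gamma - math.log(x)
    term = 1.0
    for k in range(1, 60):
        term *= -x / k
        total -= term / k
    return total


def e1_continued_fraction(x: float) -> float:
    """E1 by modified Lentz continued fraction (x > 1)."""
    tiny = 1e-300
    b = x + 1.0
    c = 1.0 / tiny
    d = 1.0 / b
    f = d
    for i in range(1, 200):
        a = -(i * i)
        b += 2.0
        d = 1.0 / (a * d + b)
        c = b + a / c
        delta = c * d
        f *= delta
        if abs(delta - 1.0) < 1e-16:
            break
    return f * math.exp(-x)


def e1_oracle(x: float) -> float:
    return e1_series(x) if x <= 1.0 else e1_continued_fraction(x)
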