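"""Synthetic phantoms and noisy low-dose sinogram simulation.

The phantoms are additive compositions of ellipses, which gives both a
deterministic rasterization on any grid and closed-form fan-beam line
integrals (quadratic ray–ellipse intersection), so the simulator doubles
as an independent oracle for the discrete projector.

The noise model is Poisson transmission counts: a ray with clean line
integral ``y`` detects ``N ~ Poisson(I0 * exp(-y))`` photons, floored at
a small electronic count to keep the log transform finite.  The per-ray
variance of the log-transformed measurement follows the delta method,
``sigma^2 = exp(y) / I0``, which is what the weighted least-squares data
term uses as the diagonal of Σ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import AttenuationImage, ImageGrid, ScanGeometry, Sinogram

__all__ = [
    "Ellipse",
    "EllipsePhantom",
    "NoiseModel",
    "StatisticalWeights",
    "make_head_phantom",
    "analytic_sinogram",
    "add_transmission_noise",
    "identity_weights",
    "PHANTOM_PRESETS",
]

VARIANCE_FLOOR = 1e-12  # keeps Σ⁻¹ bounded


@dataclass(frozen=True)
class Ellipse:
    """One additive ellipse: centre/semi-axes in mm, rotation in degrees,
    ``delta_mu`` the attenuation increment (mm⁻¹) inside the ellipse."""

    center_x: float
    center_y: float
    semi_axis_a: float
    semi_axis_b: float
    rotation: float
    delta_mu: float

    def __post_init__(self) -> None:
        if self.semi_axis_a <= 0 or self.semi_axis_b <= 0:
            raise ValueError("ellipse semi-axes must be > 0")


@dataclass(frozen=True)
class EllipsePhantom:
    """Additive collection of ellipses describing a piecewise-constant
    attenuation map."""

    ellipses: tuple[Ellipse, ...]

    def rasterize(self, grid: ImageGrid, supersample: int = 4) -> AttenuationImage:
        """Deterministic anti-aliased rasterization onto ``grid``.

        Each pixel is sampled on a ``supersample x supersample`` sub-grid
        and the ellipse indicator averaged, which keeps edge pixels
        consistent with the analytic line integrals to sub-pixel accuracy.
        """
        if supersample < 1:
            raise ValueError("supersample must be >= 1")
        n_rows, n_cols, p = grid.n_rows, grid.n_cols, grid.pixel_size
        offs = ((np.arange(supersample) + 0.5) / supersample - 0.5) * p
        x0, y0 = grid.pixel_centers()
        values = np.zeros((n_rows, n_cols))
        for oy in offs:
            for ox in offs:
                x = x0 + ox
                y = y0 + oy
                for e in self.ellipses:
                    phi = math.radians(e.rotation)
                    c, s = math.cos(phi), math.sin(phi)
                    xr = (x - e.center_x) * c + (y - e.center_y) * s
                    yr = -(x - e.center_x) * s + (y - e.center_y) * c
                    inside = (xr / e.semi_axis_a) ** 2 \
                        + (yr / e.semi_axis_b) ** 2 <= 1.0
                    values += np.where(inside, e.delta_mu, 0.0)
        values /= supersample * supersample
        return AttenuationImage(grid=grid, values=values)


@dataclass(frozen=True)
class NoiseModel:
    """Poisson transmission noise parameters.

    ``incident_photons`` is the unattenuated photon count per ray (I0);
    ``electronic_floor`` the minimum registered count, which prevents a
    logarithm of zero on heavily attenuated rays.
    """

    incident_photons: float
    electronic_floor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.incident_photons <= 0:
            raise ValueError("incident_photons must be > 0")
        if self.electronic_floor < 1:
            raise ValueError("electronic_floor must be >= 1")


@dataclass
class StatisticalWeights:
    """Per-ray variance estimates — the diagonal of Σ in the PWLS model."""

    variances: np.ndarray

    def __post_init__(self) -> None:
        self.variances = np.asarray(self.variances, dtype=np.float64)
        if not np.all(np.isfinite(self.variances)):
            raise ValueError("variances must be finite")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive")


# ---------------------------------------------------------------------------
# Phantom presets
# ---------------------------------------------------------------------------

# Skull-like head sections.  Geometry is expressed in fractions of the
# grid half-width so the same anatomy renders on any field of view; the
# attenuation deltas are absolute (mm⁻¹) and keep the composite within
# roughly [0, 0.02] mm⁻¹ — soft tissue near 0.01, bone shell near 0.019.
PHANTOM_PRESETS: dict[str, tuple[tuple[float, ...], ...]] = {
    # (cx, cy, a, b, rotation_deg, delta_mu) in fractional units
    "head": (
        (0.00, 0.00, 0.72, 0.92, 0.0, 0.019),     # skull shell
        (0.00, 0.00, 0.65, 0.85, 0.0, -0.0085),   # brain interior
        (-0.14, 0.14, 0.08, 0.22, 15.0, -0.002),  # left ventricle
        (0.14, 0.14, 0.08, 0.22, -15.0, -0.002),  # right ventricle
        (0.18, -0.30, 0.06, 0.06, 0.0, 0.0015),   # small dense inset
        (-0.05, -0.45, 0.04, 0.04, 0.0, 0.001),   # low-contrast dot
        (0.00, 0.38, 0.11, 0.06, 0.0, -0.001),    # frontal low-contrast inset
        (0.25, 0.20, 0.025, 0.025, 0.0, 0.002),   # tiny calcification
    ),
    # Mirror-asymmetric variant used for limited-angle studies, where a
    # symmetric object would hide the missing-wedge anisotropy.
    "asymmetric": (
        (0.02, -0.03, 0.78, 0.88, 20.0, 0.019),
        (0.02, -0.03, 0.70, 0.80, 20.0, -0.0085),
        (-0.20, 0.10, 0.07, 0.24, 35.0, -0.002),
        (0.16, -0.22, 0.10, 0.05, -30.0, 0.0018),
        (0.30, 0.18, 0.05, 0.05, 0.0, 0.002),
        (-0.12, -0.38, 0.04, 0.08, 60.0, 0.0012),
        (-0.30, -0.10, 0.05, 0.03, 10.0, -0.0015),
    ),
    "empty": (),
}


def make_head_phantom(grid: ImageGrid, preset: str = "head",
                      supersample: int = 4,
                      ) -> tuple[AttenuationImage, EllipsePhantom]:
    """Skull-like ellipse phantom rasterized onto ``grid``.

    Returns both the image and the analytic ellipse description (in mm,
    scaled to 95% of the grid half-width) for use with
    :func:`analytic_sinogram`.
    """
    if grid.n_rows < 32 or grid.n_cols < 32:
        raise ValueError("grid too small for the head phantom (< 32x32)")
    if preset not in PHANTOM_PRESETS:
        raise ValueError(
            f"unknown phantom preset {preset!r}; "
            f"choose from {sorted(PHANTOM_PRESETS)}"
        )
    scale = 0.95 * min(grid.width, grid.height) / 2.0
    ellipses = tuple(
        Ellipse(cx * scale, cy * scale, a * scale, b * scale, rot, dmu)
        for (cx, cy, a, b, rot, dmu) in PHANTOM_PRESETS[preset]
    )
    phantom = EllipsePhantom(ellipses=ellipses)
    return phantom.rasterize(grid, supersample=supersample), phantom


# ---------------------------------------------------------------------------
# Analytic fan-beam line integrals
# ---------------------------------------------------------------------------

def analytic_sinogram(phantom: EllipsePhantom,
                      geometry: ScanGeometry) -> Sinogram:
    """Closed-form fan-beam sinogram of an ellipse phantom.

    For each ray and each ellipse the chord length follows from the
    quadratic ray–ellipse intersection; the ray value is the sum of
    ``delta_mu * chord`` over ellipses.  Exact up to floating point, so
    this serves as the noise-free ground truth and projector oracle.
    """
    beta = np.deg2rad(geometry.view_angles)[:, None]
    gamma = geometry.bin_fan_angles[None, :]
    r_s = geometry.source_to_center

    sx = r_s * np.cos(beta) + 0.0 * gamma
    sy = r_s * np.sin(beta) + 0.0 * gamma
    # central ray (-cos b, -sin b) rotated CCW by gamma
    dx = -np.cos(beta + gamma)
    dy = -np.sin(beta + gamma)

    values = np.zeros((geometry.n_views, geometry.n_bins))
    for e in phantom.ellipses:
        phi = math.radians(e.rotation)
        c, s = math.cos(phi), math.sin(phi)
        ex = (sx - e.center_x) * c + (sy - e.center_y) * s
        ey = -(sx - e.center_x) * s + (sy - e.center_y) * c
        fx = dx * c + dy * s
        fy = -dx * s + dy * c
        a2 = e.semi_axis_a ** 2
        b2 = e.semi_axis_b ** 2
        qa = fx * fx / a2 + fy * fy / b2
        qb = 2.0 * (ex * fx / a2 + ey * fy / b2)
        qc = ex * ex / a2 + ey * ey / b2 - 1.0
        disc = qb * qb - 4.0 * qa * qc
        chord = np.where(disc > 0.0, np.sqrt(np.maximum(disc, 0.0)) / qa, 0.0)
        values += e.delta_mu * chord
    return Sinogram(geometry=geometry, values=values)


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

def add_transmission_noise(clean: Sinogram, model: NoiseModel,
                           ) -> tuple[Sinogram, StatisticalWeights]:
    """Add Poisson transmission noise and estimate per-ray variances.

    Counts ``N ~ Poisson(I0 * exp(-y))`` are floored at the electronic
    count; the noisy line integral is ``ln(I0 / N)`` and the variance
    estimate ``exp(y_noisy) / I0`` (delta method), floored at
    ``VARIANCE_FLOOR``.  Reproducible: driven by a counter-based Philox
    generator seeded from the model.
    """
    y = clean.values
    if np.any(y < 0):
        raise ValueError("clean sinogram must be non-negative")
    i0 = model.incident_photons
    rng = np.random.Generator(np.random.Philox(model.seed))
    expected = i0 * np.exp(-y)
    counts = rng.poisson(expected).astype(np.float64)
    counts = np.maximum(counts, model.electronic_floor)
    noisy = np.log(i0 / counts)
    variances = np.maximum(np.exp(noisy) / i0, VARIANCE_FLOOR)
    return (Sinogram(geometry=clean.geometry, values=noisy),
            StatisticalWeights(variances=variances))


def identity_weights(geometry: ScanGeometry) -> StatisticalWeights:
    """Unit variances (Σ = I): PWLS reduces to ordinary least squares."""
    return StatisticalWeights(
        variances=np.ones((geometry.n_views, geometry.n_bins)))
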