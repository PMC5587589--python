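"""Fan-beam scan geometry and image-grid descriptions.

The geometry convention used throughout the package:

* 0-based array indices; pixel ``(0, 0)`` is the top-left corner of the
  image, the rotation axis sits at the grid centre.
* Physical coordinates are in mm with ``+x`` to the right and ``+y`` up;
  view angle 0 places the source on the ``+x`` axis and angles increase
  counter-clockwise.
* The detector is curved (equiangular bins on an arc centred on the
  source) by default; a flat equispaced detector is available via
  ``detector_shape="flat-equispaced"``.
* View angles are ``start + k * angular_range / n_views`` so that a full
  360° orbit never duplicates its first view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ScanGeometry",
    "ImageGrid",
    "AttenuationImage",
    "Sinogram",
    "make_geometry",
    "default_grid",
    "GEOMETRY_PRESETS",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Fan-beam acquisition description.

    Parameters
    ----------
    n_views : int
        Number of projection views.
    angular_range : float
        Total angular span of the orbit in degrees, in ``(0, 360]``.
    n_bins : int
        Number of detector bins per view.
    source_to_detector : float
        Distance from the X-ray source to the detector, mm.
    center_to_detector : float
        Distance from the rotation centre to the detector, mm.
    detector_extent : float
        Total detector length in mm.  For the curved detector this is arc
        length measured on the detector arc (radius ``source_to_detector``
        around the source); for the flat detector it is a straight length.
    detector_shape : str
        ``"curved-equiangular"`` (default) or ``"flat-equispaced"``.
    start_angle : float
        Angle of the first view in degrees (default 0).
    """

    n_views: int
    angular_range: float
    n_bins: int
    source_to_detector: float
    center_to_detector: float
    detector_extent: float
    detector_shape: str = "curved-equiangular"
    start_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise ValueError(f"n_views must be >= 1, got {self.n_views}")
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")
        if not (0.0 < self.angular_range <= 360.0):
            raise ValueError(
                f"angular_range must lie in (0, 360], got {self.angular_range}"
            )
        for name in ("source_to_detector", "center_to_detector", "detector_extent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.source_to_detector <= self.center_to_detector:
            raise ValueError(
                "source_to_detector must exceed center_to_detector "
                "(the source lies outside the object)"
            )
        if self.detector_shape not in ("curved-equiangular", "flat-equispaced"):
            raise ValueError(f"unknown detector_shape {self.detector_shape!r}")

    # -- derived quantities -------------------------------------------------

    @property
    def source_to_center(self) -> float:
        """Source-to-rotation-centre distance, mm."""
        return self.source_to_detector - self.center_to_detector

    @property
    def fan_angle(self) -> float:
        """Full fan opening angle in radians."""
        if self.detector_shape == "curved-equiangular":
            return self.detector_extent / self.source_to_detector
        return 2.0 * math.atan(
            0.5 * self.detector_extent / self.source_to_detector
        )

    @property
    def fov_radius(self) -> float:
        """Radius (mm) of the circular field of view inscribed in the fan."""
        return self.source_to_center * math.sin(0.5 * self.fan_angle)

    @property
    def view_angles(self) -> np.ndarray:
        """View angles in degrees, uniformly spaced over the orbit."""
        step = self.angular_range / self.n_views
        return self.start_angle + step * np.arange(self.n_views)

    @property
    def bin_fan_angles(self) -> np.ndarray:
        """Signed fan angle (radians) of each detector bin's ray.

        Measured counter-clockwise from the central ray.  For the flat
        detector these are derived from the equispaced bin positions.
        """
        centers = (np.arange(self.n_bins) - (self.n_bins - 1) / 2.0)
        if self.detector_shape == "curved-equiangular":
            dgamma = self.fan_angle / self.n_bins
            return centers * dgamma
        du = self.detector_extent / self.n_bins
        return np.arctan(centers * du / self.source_to_detector)

    # -- serialization ------------------------------------------------------

    _FIELDS = (
        "n_views",
        "angular_range",
        "n_bins",
        "source_to_detector",
        "center_to_detector",
        "detector_extent",
        "detector_shape",
        "start_angle",
    )

    def to_config_text(self) -> str:
        """Serialize to a plain-text ``key: value`` block."""
        lines = []
        for name in self._FIELDS:
            lines.append(f"{name}: {getattr(self, name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config_text(cls, text: str) -> "ScanGeometry":
        """Parse a ``key: value`` block written by :meth:`to_config_text`."""
        kwargs: dict = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition(":")
            key = key.strip()
            value = value.strip()
            if key not in cls._FIELDS:
                raise ValueError(f"unknown geometry field {key!r}")
            if key in ("n_views", "n_bins"):
                kwargs[key] = int(value)
            elif key == "detector_shape":
                kwargs[key] = value
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)

    def to_attrs(self) -> dict:
        """Flat dict of fields, suitable for HDF5 attributes."""
        return {name: getattr(self, name) for name in self._FIELDS}

    @classmethod
    def from_attrs(cls, attrs) -> "ScanGeometry":
        kwargs = {}
        for name in cls._FIELDS:
            value = attrs[name]
            if isinstance(value, bytes):
                value = value.decode()
            if name in ("n_views", "n_bins"):
                value = int(value)
            elif name != "detector_shape":
                value = float(value)
            else:
                value = str(value)
            kwargs[name] = value
        return cls(**kwargs)


@dataclass(frozen=True)
class ImageGrid:
    """Square-pixel reconstruction grid centred on the rotation axis."""

    n_rows: int
    n_cols: int
    pixel_size: float  # mm

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def width(self) -> float:
        """Physical width (mm) of the grid."""
        return self.n_cols * self.pixel_size

    @property
    def height(self) -> float:
        """Physical height (mm) of the grid."""
        return self.n_rows * self.pixel_size

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """``(x, y)`` physical coordinates (mm) of every pixel centre.

        Both arrays have shape ``(n_rows, n_cols)``; row 0 is the top of
        the image (largest ``y``).
        """
        cols = (np.arange(self.n_cols) - (self.n_cols - 1) / 2.0) * self.pixel_size
        rows = ((self.n_rows - 1) / 2.0 - np.arange(self.n_rows)) * self.pixel_size
        x, y = np.meshgrid(cols, rows)
        return x, y


@dataclass
class AttenuationImage:
    """2-D map of linear attenuation coefficients (mm⁻¹) on a grid."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"image shape {self.values.shape} does not match grid "
                f"{self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attenuation image contains non-finite values")


@dataclass
class Sinogram:
    """Line-integral data (dimensionless), ``n_views x n_bins``."""

    geometry: ScanGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (self.geometry.n_views, self.geometry.n_bins)
        if self.values.shape != expected:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"{expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

# Sparse-view head protocol: 120 views over a full circle, 672 bins,
# source-to-detector 1040 mm, centre-to-detector 570 mm.  The detector
# extent is chosen so the fan inscribes a 500 mm diameter field of view
# (a standard body FOV; the protocol itself does not fix the extent):
# extent = 2*asin(250/470) * 1040.
_XCAT_EXTENT = 2.0 * math.asin(250.0 / 470.0) * 1040.0

# Micro-CT protocol: 4000 equiangular bins spanning 50.12 mm of arc;
# object-to-source 121 mm, object-to-detector 165 mm.
_MICRO = dict(
    n_bins=4000,
    source_to_detector=121.0 + 165.0,
    center_to_detector=165.0,
    detector_extent=50.12,
)

GEOMETRY_PRESETS: dict[str, dict] = {
    "xcat_sparse": dict(
        n_views=120,
        angular_range=360.0,
        n_bins=672,
        source_to_detector=1040.0,
        center_to_detector=570.0,
        detector_extent=_XCAT_EXTENT,
    ),
    # dense reference orbit used as the "ideal" fully sampled baseline
    "xcat_dense": dict(
        n_views=1160,
        angular_range=360.0,
        n_bins=672,
        source_to_detector=1040.0,
        center_to_detector=570.0,
        detector_extent=_XCAT_EXTENT,
    ),
    "micro_sparse": dict(n_views=225, angular_range=360.0, **_MICRO),
    "micro_dense": dict(n_views=450, angular_range=360.0, **_MICRO),
    "micro_limited": dict(n_views=291, angular_range=197.88, **_MICRO),
}


def make_geometry(preset: str | None = None, **overrides) -> ScanGeometry:
    """Build a validated :class:`ScanGeometry` from a preset or parameters.

    Parameters
    ----------
    preset : str, optional
        One of ``xcat_sparse``, ``xcat_dense``, ``micro_sparse``,
        ``micro_dense``, ``micro_limited``.  Keyword overrides are applied
        on top of the preset; with no preset the full parameter set must
        be supplied.
    """
    if preset is not None:
        if preset not in GEOMETRY_PRESETS:
            raise ValueError(
                f"unknown geometry preset {preset!r}; "
                f"choose from {sorted(GEOMETRY_PRESETS)}"
            )
        params = dict(GEOMETRY_PRESETS[preset])
        params.update(overrides)
        return ScanGeometry(**params)
    return ScanGeometry(**overrides)


def default_grid(geometry: ScanGeometry, n: int | None = None) -> ImageGrid:
    """Reconstruction grid whose field of view inscribes the fan beam.

    ``n`` defaults to 256 for the head protocols and 512 for the micro-CT
    protocols (chosen by detector bin count).
    """
    if n is None:
        n = 512 if geometry.n_bins >= 2000 else 256
    pixel = 2.0 * geometry.fov_radius / n
    return ImageGrid(n_rows=n, n_cols=n, pixel_size=pixel)
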