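"""File formats: TIFF images, HDF5 sinograms, YAML run configuration.

Images are written as 32-bit float TIFF with the pixel size recorded in
the resolution tags.  Sinograms live in HDF5 together with the scan
geometry (as attributes), the statistical weights and the simulation
seed, so a reconstruction can be re-run from the file alone.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .fbp import FbpFilterSpec
from .feature_refinement import FrConfig
from .geometry import AttenuationImage, ImageGrid, ScanGeometry, Sinogram
from .pipeline import ReconConfig
from .pwls_tv import TvConfig
from .simulate import StatisticalWeights

__all__ = [
    "save_image_tiff",
    "load_image_tiff",
    "save_sinogram_h5",
    "load_sinogram_h5",
    "save_config",
    "load_config",
]


def save_image_tiff(path, image: AttenuationImage) -> None:
    """Write an attenuation image as 32-bit float TIFF (values in mm⁻¹)."""
    pixels_per_cm = 10.0 / image.grid.pixel_size
    tifffile.imwrite(
        path,
        image.values.astype(np.float32),
        resolution=(pixels_per_cm, pixels_per_cm),
        resolutionunit="CENTIMETER",
        metadata={"pixel_size_mm": image.grid.pixel_size},
    )


def load_image_tiff(path, pixel_size: float | None = None) -> AttenuationImage:
    """Read an image written by :func:`save_image_tiff`.

    The pixel size is recovered from the resolution tags unless given.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(np.float64)
        if pixel_size is None:
            try:
                xres = page.tags["XResolution"].value
                pixel_size = 10.0 * xres[1] / xres[0]
            except (KeyError, ZeroDivisionError):
                pixel_size = 1.0
    grid = ImageGrid(n_rows=values.shape[0], n_cols=values.shape[1],
                     pixel_size=float(pixel_size))
    return AttenuationImage(grid=grid, values=values)


def save_sinogram_h5(path, sino: Sinogram,
                     weights: StatisticalWeights | None = None,
                     seed: int | None = None,
                     truth: AttenuationImage | None = None) -> None:
    """Write sinogram (+ optional weights, seed, ground truth) to HDF5."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("sinogram", data=sino.values)
        for key, value in sino.geometry.to_attrs().items():
            ds.attrs[key] = value
        if weights is not None:
            fh.create_dataset("variances", data=weights.variances)
        if seed is not None:
            fh.attrs["seed"] = int(seed)
        if truth is not None:
            t = fh.create_dataset("mu_true", data=truth.values)
            t.attrs["pixel_size_mm"] = truth.grid.pixel_size


def load_sinogram_h5(path) -> tuple[Sinogram, StatisticalWeights | None,
                                    AttenuationImage | None]:
    """Read back what :func:`save_sinogram_h5` wrote."""
    with h5py.File(path, "r") as fh:
        ds = fh["sinogram"]
        geometry = ScanGeometry.from_attrs(ds.attrs)
        sino = Sinogram(geometry=geometry, values=ds[()])
        weights = None
        if "variances" in fh:
            weights = StatisticalWeights(variances=fh["variances"][()])
        truth = None
        if "mu_true" in fh:
            t = fh["mu_true"]
            values = t[()]
            grid = ImageGrid(values.shape[0], values.shape[1],
                             float(t.attrs["pixel_size_mm"]))
            truth = AttenuationImage(grid=grid, values=values)
    return sino, weights, truth


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def config_to_dict(config: ReconConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(data: dict) -> ReconConfig:
    data = dict(data)
    if "tv" in data and isinstance(data["tv"], dict):
        data["tv"] = TvConfig(**data["tv"])
    if "fr" in data and isinstance(data["fr"], dict):
        data["fr"] = FrConfig(**data["fr"])
    if "fbp_filter" in data and isinstance(data["fbp_filter"], dict):
        data["fbp_filter"] = FbpFilterSpec(**data["fbp_filter"])
    return ReconConfig(**data)


def save_config(path, config: ReconConfig,
                geometry: ScanGeometry | None = None,
                grid: ImageGrid | None = None) -> None:
    """Write the fully resolved run configuration as YAML."""
    doc: dict = {"reconstruction": config_to_dict(config)}
    if geometry is not None:
        doc["geometry"] = geometry.to_attrs()
    if grid is not None:
        doc["grid"] = dataclasses.asdict(grid)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path) -> tuple[ReconConfig, ScanGeometry | None,
                               ImageGrid | None]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    config = config_from_dict(doc["reconstruction"])
    geometry = None
    if "geometry" in doc:
        geometry = ScanGeometry(**doc["geometry"])
    grid = None
    if "grid" in doc:
        grid = ImageGrid(**doc["grid"])
    return config, geometry, grid
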