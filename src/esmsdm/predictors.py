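"""Remote-sensing predictor derivation, standardization and screening.

Spectral indices (EVI2, NDWI1, BSI), the PALSAR HV/HH polarization ratio
and the annulus-neighborhood topographic position index (TPI) are the
standard predictor set for boreal vegetation mapping at 30 m. All index
operations are elementwise and mask-propagating; standardization fixes
the population-sd convention; the correlation filter screens predictor
pairs at |Pearson r| > 0.7 over a background-point sample, keeping the
higher-priority member of each offending pair.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidArgumentError
from .raster import Raster, RasterStack

__all__ = [
    "evi2",
    "ndwi1",
    "bsi",
    "palsar_hvhh",
    "tpi",
    "standardize",
    "standardize_stack",
    "correlation_filter",
    "derive_predictors",
]

log = logging.getLogger(__name__)

#: Default retention priority when a correlated pair must be broken.
#: NDWI1 precedes BSI: moisture sensitivity is the ecologically preferred
#: signal for poikilohydric vegetation.
DEFAULT_KEEP_PRIORITY = ("TPI", "EVI2", "NDWI1", "VCF", "PALSAR_HVHH", "BSI")


def _check_aligned(*layers: Raster) -> None:
    shapes = {l.shape for l in layers}
    if len(shapes) != 1:
        raise InvalidArgumentError("layers are not grid-aligned")


def evi2(nir: Raster, red: Raster) -> Raster:
    """Two-band enhanced vegetation index: 2.5*(NIR-RED)/(NIR+2.4*RED+1)."""
    _check_aligned(nir, red)
    out = 2.5 * (nir.data - red.data) / (nir.data + 2.4 * red.data + 1.0)
    return nir.copy_with(out)


def ndwi1(nir: Raster, swir1: Raster) -> Raster:
    """Normalized difference water index: (NIR-SWIR1)/(NIR+SWIR1), in [-1, 1].

    Cells with a zero denominator are masked in the output and logged.
    """
    _check_aligned(nir, swir1)
    denom = nir.data + swir1.data
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (nir.data - swir1.data) / denom
    bad = (denom == 0) & nir.mask & swir1.mask
    if bad.any():
        log.warning("ndwi1: %d zero-denominator cells masked", int(bad.sum()))
        out[bad] = np.nan
    return nir.copy_with(out)


def bsi(swir1: Raster, red: Raster, nir: Raster, blue: Raster) -> Raster:
    """Bare soil index in normalized-difference form.

    ((SWIR1+RED) - (NIR+BLUE)) / ((SWIR1+RED) + (NIR+BLUE)), in [-1, 1].
    """
    _check_aligned(swir1, red, nir, blue)
    top = (swir1.data + red.data) - (nir.data + blue.data)
    denom = (swir1.data + red.data) + (nir.data + blue.data)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = top / denom
    bad = (denom == 0) & swir1.mask & red.mask & nir.mask & blue.mask
    if bad.any():
        log.warning("bsi: %d zero-denominator cells masked", int(bad.sum()))
        out[bad] = np.nan
    return swir1.copy_with(out)


def palsar_hvhh(hv: Raster, hh: Raster) -> Raster:
    """Ratio of HV-polarized to HH-polarized L-band backscatter."""
    _check_aligned(hv, hh)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = hv.data / hh.data
    bad = (hh.data == 0) & hv.mask & hh.mask
    if bad.any():
        log.warning("palsar_hvhh: %d zero-HH cells masked", int(bad.sum()))
        out[bad] = np.nan
    return hv.copy_with(out)


def _annulus_kernel(inner: float, outer: float) -> np.ndarray:
    """Boolean annulus membership kernel, center-to-center Euclidean distance
    in pixel units, inclusive bounds; the focal cell is never a member."""
    r = int(np.ceil(outer))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d = np.hypot(yy, xx)
    kernel = (d >= inner) & (d <= outer)
    kernel[r, r] = False
    return kernel


def tpi(dem: Raster, inner_radius: float = 15, outer_radius: float = 20) -> Raster:
    """Topographic position index over an annulus neighborhood.

    Per cell: elevation minus the mean elevation of cells whose center
    distance d (pixels) satisfies inner_radius <= d <= outer_radius.
    Near the raster edge the partial annulus mean (cells inside the
    raster) is used; cells whose annulus lies entirely outside, and
    masked DEM cells, are nodata. Defaults (15, 20 pixels) follow the
    standard GIS annulus configuration for 30 m grids.
    """
    if inner_radius >= outer_radius:
        raise InvalidArgumentError("inner_radius must be < outer_radius")
    kernel = _annulus_kernel(inner_radius, outer_radius).astype(float)
    valid = dem.mask.astype(float)
    filled = np.where(dem.mask, dem.data, 0.0)
    # constant-0 padding outside the raster: sums simply omit outside cells
    sums = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
    out = dem.data - mean
    out[counts < 0.5] = np.nan
    return dem.copy_with(out)


def standardize(layer: Raster) -> Raster:
    """Z-score over unmasked cells using the population (n) standard deviation."""
    vals = layer.data[layer.mask]
    if vals.size < 2:
        raise InvalidArgumentError("need at least 2 unmasked cells")
    sd = vals.std()
    if sd == 0:
        raise InvalidArgumentError("zero variance; cannot standardize")
    return layer.copy_with((layer.data - vals.mean()) / sd)


def standardize_stack(stack: RasterStack) -> RasterStack:
    return RasterStack({n: standardize(stack[n]) for n in stack.names})


def correlation_filter(
    stack: RasterStack,
    background_xy: np.ndarray,
    threshold: float = 0.7,
    keep_priority: Sequence[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop the lower-priority member of every predictor pair with
    |Pearson r| > threshold at the background points.

    Returns (retained names in stack order, full correlation matrix for
    logging). ``keep_priority`` is an ordering over predictor names;
    names absent from it rank below all listed names, in stack order.
    """
    background_xy = np.atleast_2d(np.asarray(background_xy, dtype=float))
    if len(background_xy) < 2:
        raise InvalidArgumentError("need at least 2 background points")
    priority = list(keep_priority) if keep_priority is not None else list(
        DEFAULT_KEEP_PRIORITY
    )

    def rank(name: str) -> tuple[int, int]:
        if name in priority:
            return (0, priority.index(name))
        return (1, stack.names.index(name))

    values = {n: stack[n].values_at(background_xy) for n in stack.names}
    df = pd.DataFrame(values)
    corr = df.corr(method="pearson")
    dropped: set[str] = set()
    for a, b in itertools.combinations(stack.names, 2):
        if a in dropped or b in dropped:
            continue
        if abs(corr.loc[a, b]) > threshold:
            loser = a if rank(a) > rank(b) else b
            dropped.add(loser)
            log.info(
                "correlation_filter: |r(%s, %s)| = %.3f > %.2f; dropping %s",
                a, b, abs(corr.loc[a, b]), threshold, loser,
            )
    retained = [n for n in stack.names if n not in dropped]
    return retained, corr


def derive_predictors(
    bands: dict[str, Raster],
    inner_radius: float = 15,
    outer_radius: float = 20,
) -> RasterStack:
    """Compute the predictor set available from a band collection.

    Recognized band keys: BLUE, RED, NIR, SWIR1 (reflectance), HV, HH
    (backscatter), DEM (elevation, m), VCF (carried through as-is).
    Produces every predictor whose inputs are present, standardized.
    """
    layers: dict[str, Raster] = {}
    if "DEM" in bands:
        layers["TPI"] = tpi(bands["DEM"], inner_radius, outer_radius)
    if {"NIR", "RED"} <= bands.keys():
        layers["EVI2"] = evi2(bands["NIR"], bands["RED"])
    if {"NIR", "SWIR1"} <= bands.keys():
        layers["NDWI1"] = ndwi1(bands["NIR"], bands["SWIR1"])
    if "VCF" in bands:
        layers["VCF"] = bands["VCF"]
    if {"HV", "HH"} <= bands.keys():
        layers["PALSAR_HVHH"] = palsar_hvhh(bands["HV"], bands["HH"])
    if {"SWIR1", "RED", "NIR", "BLUE"} <= bands.keys():
        layers["BSI"] = bsi(bands["SWIR1"], bands["RED"], bands["NIR"], bands["BLUE"])
    if not layers:
        raise InvalidArgumentError("no recognized bands supplied")
    return standardize_stack(RasterStack(layers))
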