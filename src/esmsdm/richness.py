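"""Stacked-SDM richness surfaces.

Richness is the per-cell count of species predicted present, obtained by
summing binary distribution maps — overall and per guild (mosses,
liverworts, sphagna). Nodata cells in an individual species map count as
absences by default, so a localized data gap in one predictor does not
punch holes in the community surface.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np

from .errors import InvalidArgumentError
from .raster import Raster
from .synthetic import GUILDS

__all__ = ["stack_richness", "guild_richness"]

log = logging.getLogger(__name__)


def stack_richness(
    binary_maps: Mapping[str, Raster], na_as_absence: bool = True
) -> Raster:
    """Cellwise sum of per-species presence maps.

    With ``na_as_absence`` (default) a nodata cell in any single map
    contributes 0; otherwise nodata propagates to the richness surface.
    """
    maps = dict(binary_maps)
    if not maps:
        raise InvalidArgumentError("no binary maps supplied")
    shapes = {r.shape for r in maps.values()}
    if len(shapes) != 1:
        raise InvalidArgumentError("binary maps must share one grid")
    first = next(iter(maps.values()))
    total = np.zeros(first.shape)
    any_nodata = np.zeros(first.shape, dtype=bool)
    for r in maps.values():
        total += np.where(r.mask, r.data, 0.0)
        any_nodata |= ~r.mask
    if not na_as_absence:
        total[any_nodata] = np.nan
    out = first.copy_with(total)
    return out


def guild_richness(
    binary_maps: Mapping[str, Raster],
    guild_assignments: Mapping[str, str],
    na_as_absence: bool = True,
) -> dict[str, Raster]:
    """One richness map per guild plus the overall surface.

    Returns ``{"all": ..., "moss": ..., "liverwort": ..., "sphagna": ...}``;
    the overall map equals the cellwise sum of the three guild maps. An
    empty guild yields an all-zero map.
    """
    maps = dict(binary_maps)
    if not maps:
        raise InvalidArgumentError("no binary maps supplied")
    for sp in maps:
        g = guild_assignments.get(sp)
        if g not in GUILDS:
            raise InvalidArgumentError(f"species {sp!r} has unknown guild {g!r}")
    first = next(iter(maps.values()))
    out: dict[str, Raster] = {}
    for guild in GUILDS:
        members = {sp: r for sp, r in maps.items() if guild_assignments[sp] == guild}
        if members:
            out[guild] = stack_richness(members, na_as_absence)
        else:
            out[guild] = first.copy_with(np.zeros(first.shape))
    out["all"] = stack_richness(maps, na_as_absence)
    return out
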