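"""Reference-free geolocation: select origin-informative ASVs, resolve them
to taxa by the largest-percent-identity (LPI) rule, and build unified
distribution maps.

A *unified point map* pools the occurrence records of every species in a
country's group onto one binned lon/lat lattice (hexagonal by default,
square available) and counts observations per bin, so areas where the
group's species co-occur accumulate high counts.  A *unified region map*
superimposes per-species botanical-region presences: each region's value is
the number of group species recorded there.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diff_abund import DAResult
from .tables_io import (
    BlastHitTable,
    CountTable,
    OccurrenceSet,
    RegionPresenceTable,
    SampleSheet,
)

__all__ = [
    "TaxonAssignment",
    "UnifiedPointMap",
    "UnifiedRegionMap",
    "select_overabundant_asvs",
    "resolve_lpi",
    "genus_fallback",
    "unified_point_map",
    "unified_region_map",
]


@dataclass
class TaxonAssignment:
    """ASV -> taxon resolution under the LPI rule."""

    asv_id: str
    resolution: str  # single_species | species_set | genus | unassigned
    taxa: list[str] = field(default_factory=list)
    lpi: float | None = None

    def __post_init__(self) -> None:
        if self.resolution == "single_species" and len(self.taxa) != 1:
            raise ValueError("single_species requires exactly one taxon")
        if self.resolution == "species_set" and len(self.taxa) < 2:
            raise ValueError("species_set requires >= 2 taxa")
        if self.resolution == "unassigned" and self.taxa:
            raise ValueError("unassigned carries no taxa")


@dataclass
class UnifiedPointMap:
    """Binned pooled occurrence counts; ``bins`` columns depend on geometry
    (hex: q, r, center_lon, center_lat, count; square: ix, iy, ...)."""

    bins: pd.DataFrame
    geometry: str  # 'hex' | 'square'
    bin_width: float

    @property
    def total(self) -> int:
        return int(self.bins["count"].sum())

    def max_bin(self) -> pd.Series:
        return self.bins.loc[self.bins["count"].idxmax()]


@dataclass
class UnifiedRegionMap:
    counts: pd.Series  # region code -> number of group species present
    species_group: list[str]


# ---------------------------------------------------------------------------
# selection of origin-informative ASVs
# ---------------------------------------------------------------------------


def select_overabundant_asvs(
    da: DAResult,
    counts: CountTable,
    sheet: SampleSheet,
    min_samples: int = 2,
    exclude_groups: tuple[str, ...] = (),
) -> dict[str, list[str]]:
    """Per-country sets of overabundant, country-exclusive ASVs.

    For country A the set contains ASVs flagged overabundant in A that have
    nonzero counts in at least ``min_samples`` country-A tablet samples and
    zero counts in every country-B tablet sample ("only occurred" in A);
    symmetric for B.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if len(da.table) == 0:
        warnings.warn("empty differential-abundance result; returning empty sets",
                      stacklevel=2)
        return {"A": [], "B": []}
    meta = sheet.data
    tablets = meta[(meta["sample_type"] == "tablet") & ~meta["group_label"].isin(exclude_groups)]
    tablets = tablets[tablets.index.isin(counts.sample_ids)]
    out: dict[str, list[str]] = {}
    for country, other in (("A", "B"), ("B", "A")):
        own = list(tablets.index[tablets["country"] == country])
        opp = list(tablets.index[tablets["country"] == other])
        flagged = [a for a in da.overabundant(country) if a in counts.counts.index]
        sel = []
        for asv in flagged:
            row = counts.counts.loc[asv]
            if (row[own] > 0).sum() >= min_samples and (row[opp] == 0).all():
                sel.append(asv)
        out[country] = sel
    return out


# ---------------------------------------------------------------------------
# LPI taxon resolution
# ---------------------------------------------------------------------------


def _norm_name(name: str) -> str:
    return " ".join(str(name).split())


def resolve_lpi(hits: BlastHitTable, asv: str, rank: str = "species") -> TaxonAssignment:
    """Resolve one ASV to taxa by the largest-percent-identity rule.

    Among the ASV's hits at the requested rank, only those at the maximum
    percent identity are kept: one distinct taxon -> ``single_species``
    (or ``genus`` when resolving at genus rank); several distinct taxa ->
    ``species_set``; no hits at that rank -> ``unassigned``.
    """
    sub = hits.hits_for(asv)
    sub = sub[sub["srank"] == rank]
    if len(sub) == 0:
        return TaxonAssignment(asv_id=asv, resolution="unassigned")
    lpi = float(sub["pident"].max())
    top = sub[sub["pident"] == lpi]
    taxa = sorted({_norm_name(t) for t in top["staxon"]})
    if len(taxa) == 1:
        resolution = "single_species" if rank == "species" else "genus"
        return TaxonAssignment(asv_id=asv, resolution=resolution, taxa=taxa, lpi=lpi)
    resolution = "species_set" if rank == "species" else "genus"
    return TaxonAssignment(asv_id=asv, resolution=resolution, taxa=taxa, lpi=lpi)


def genus_fallback(
    hits: BlastHitTable, country_asvs: list[str]
) -> tuple[list[TaxonAssignment], str]:
    """Resolve a country's ASV set, falling back to genus rank as a whole.

    Species-level LPI resolution is attempted for every ASV; if at least one
    succeeds, the species-level assignments are returned (rank='species').
    Only when none resolves to species does the whole set fall back to
    genus-rank resolution (rank='genus'); if that fails too the result is
    empty with rank='none'.
    """
    species_level = [resolve_lpi(hits, a, rank="species") for a in country_asvs]
    resolved = [t for t in species_level if t.resolution != "unassigned"]
    if resolved:
        return resolved, "species"
    genus_level = [resolve_lpi(hits, a, rank="genus") for a in country_asvs]
    resolved = [t for t in genus_level if t.resolution != "unassigned"]
    if resolved:
        return resolved, "genus"
    return [], "none"


# ---------------------------------------------------------------------------
# unified maps
# ---------------------------------------------------------------------------


def _hex_bin(lon: np.ndarray, lat: np.ndarray, width: float):
    """Assign points to a pointy-top hexagonal lattice anchored at
    (-180, -90); ``width`` is the hexagon width in degrees of longitude."""
    size = width / math.sqrt(3.0)
    x = lon + 180.0
    y = lat + 90.0
    qf = (math.sqrt(3.0) / 3.0 * x - y / 3.0) / size
    rf = (2.0 / 3.0 * y) / size
    # cube rounding
    xf, zf = qf, rf
    yf = -xf - zf
    rx, ry, rz = np.round(xf), np.round(yf), np.round(zf)
    dx, dy, dz = np.abs(rx - xf), np.abs(ry - yf), np.abs(rz - zf)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)
    q = rx.astype(int)
    r = rz.astype(int)
    cx = size * (math.sqrt(3.0) * q + math.sqrt(3.0) / 2.0 * r)
    cy = size * 1.5 * r
    return q, r, cx - 180.0, cy - 90.0


def unified_point_map(
    occ: OccurrenceSet,
    species_group,
    bin_width: float = 5.0,
    geometry: str = "hex",
) -> UnifiedPointMap:
    """Pool all occurrence records of the group's species and bin them.

    Every record counts (duplicated coordinates included); the bin lattice
    is fixed and anchored at (-180, -90) so maps of different groups are
    comparable.  Species without any record trigger a warning.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    group = [_norm_name(s) for s in species_group]
    present = set(occ.data["species"].map(_norm_name)) if len(occ.data) else set()
    missing = [s for s in group if s not in present]
    if missing:
        warnings.warn(f"species with zero occurrence records: {missing}", stacklevel=2)
    norm = occ.data.assign(species=occ.data["species"].map(_norm_name))
    sub = norm[norm["species"].isin(set(group))]
    lon = sub["lon"].to_numpy(float)
    lat = sub["lat"].to_numpy(float)
    if geometry == "hex":
        q, r, cx, cy = _hex_bin(lon, lat, bin_width)
        df = pd.DataFrame({"q": q, "r": r, "center_lon": cx, "center_lat": cy})
        keys = ["q", "r"]
    elif geometry == "square":
        ix = np.floor((lon + 180.0) / bin_width).astype(int)
        iy = np.floor((lat + 90.0) / bin_width).astype(int)
        df = pd.DataFrame(
            {
                "ix": ix,
                "iy": iy,
                "center_lon": (ix + 0.5) * bin_width - 180.0,
                "center_lat": (iy + 0.5) * bin_width - 90.0,
            }
        )
        keys = ["ix", "iy"]
    else:
        raise ValueError("geometry must be 'hex' or 'square'")
    if len(df) == 0:
        bins = pd.DataFrame(columns=[*keys, "center_lon", "center_lat", "count"])
    else:
        bins = (
            df.groupby(keys, as_index=False)
            .agg(center_lon=("center_lon", "first"), center_lat=("center_lat", "first"))
            .merge(df.groupby(keys).size().rename("count").reset_index(), on=keys)
        )
    return UnifiedPointMap(bins=bins, geometry=geometry, bin_width=bin_width)


def unified_region_map(
    regions: RegionPresenceTable, species_group
) -> UnifiedRegionMap:
    """Superimpose per-species botanical-region presences for a group.

    Each region's count is the number of group species present there;
    species missing from the table count as all-absent rows (warned)."""
    group = [_norm_name(s) for s in species_group]
    idx_norm = {_norm_name(s): s for s in regions.data.index}
    missing = [s for s in group if s not in idx_norm]
    if missing:
        warnings.warn(f"species absent from region table (counted as 0): {missing}",
                      stacklevel=2)
    total = pd.Series(0, index=regions.data.columns, dtype=int)
    for s in group:
        if s in idx_norm:
            total = total + regions.data.loc[idx_norm[s]].astype(int)
    total.name = "n_species"
    return UnifiedRegionMap(counts=total, species_group=group)
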