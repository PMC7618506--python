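"""Domain containers and readers/writers for every external format the pipeline touches.

All on-disk formats are plain text (TSV/CSV, UTF-8, "." decimal point):

* count tables   — TSV, first column ``asv_id``, remaining columns sample ids
* sample sheets  — TSV with the required metadata columns
* BLAST hits     — TSV, columns ``qseqid staxon srank pident qcov`` (outfmt-6-like)
* occurrences    — CSV ``species,lon,lat``
* region tables  — CSV wide 0/1 matrix, header ``species,<region code>,...``
* peak lists     — CSV ``measurement_id,tablet_id,group,mz,intensity``, one peak per row
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MARKERS",
    "SAMPLE_TYPES",
    "COUNTRIES",
    "MANUFACTURING",
    "WATER_SOURCES",
    "MZ_RANGE",
    "CountTable",
    "SampleSheet",
    "BlastHitTable",
    "OccurrenceSet",
    "RegionPresenceTable",
    "SpectrumSet",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_blast_hits",
    "write_blast_hits",
    "read_occurrences",
    "write_occurrences",
    "read_regions",
    "write_regions",
    "read_peaks",
    "write_peaks",
]

MARKERS = frozenset({"16S", "18S", "trnL"})
SAMPLE_TYPES = frozenset({"tablet", "excipient", "dust", "water", "neg_control"})
COUNTRIES = frozenset({"A", "B", "unknown"})
MANUFACTURING = frozenset({"direct_compression", "wet_granulation"})
WATER_SOURCES = frozenset({"none", "local", "foreign"})

#: DART acquisition window in Daltons; peaks outside are flagged, never dropped.
MZ_RANGE = (50.0, 800.0)


class FormatError(ValueError):
    """Raised when an input file violates its documented schema."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """ASV-by-sample matrix of non-negative integer read counts.

    ``counts`` is indexed by ASV id with one column per sample; ``marker``
    records which amplicon (16S bacterial, 18S eukaryotic or trnL plant) the
    table profiles.
    """

    counts: pd.DataFrame
    marker: str

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}; expected one of {sorted(MARKERS)}")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise FormatError(f"duplicate ASV ids: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError("counts must be integers")
        if (arr < 0).any():
            raise FormatError("counts must be non-negative")

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, samples: Sequence[str]) -> "CountTable":
        missing = [s for s in samples if s not in self.counts.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return CountTable(self.counts.loc[:, list(samples)].copy(), self.marker)

    def drop_asvs(self, asvs: Iterable[str]) -> "CountTable":
        drop = [a for a in asvs if a in self.counts.index]
        return CountTable(self.counts.drop(index=drop), self.marker)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class SampleSheet:
    """Per-sample metadata: role, production country, manufacturing method,
    water source, and the experimental group label (e.g. ``E-5``)."""

    data: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("sample_type", "country", "manufacturing", "water_source", "group_label")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"sample sheet missing required column(s): {missing}")
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample ids in sample sheet")
        if len(self.data) == 0:
            raise FormatError("empty sample sheet")
        for col, allowed in (
            ("sample_type", SAMPLE_TYPES),
            ("country", COUNTRIES),
            ("manufacturing", MANUFACTURING),
            ("water_source", WATER_SOURCES),
        ):
            bad = sorted(set(self.data[col]) - allowed)
            if bad:
                raise FormatError(f"invalid {col} value(s) {bad}; allowed: {sorted(allowed)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def samples_of_type(self, sample_type: str) -> list[str]:
        return list(self.data.index[self.data["sample_type"] == sample_type])

    def samples_of_group(self, group_label: str) -> list[str]:
        return list(self.data.index[self.data["group_label"] == group_label])

    def country_of(self, samples: Sequence[str]) -> pd.Series:
        return self.data.loc[list(samples), "country"]

    def resolve(self, count_table: CountTable) -> None:
        """Check that every sample of a count table has exactly one metadata row."""
        missing = [s for s in count_table.sample_ids if s not in self.data.index]
        if missing:
            raise FormatError(f"samples without metadata: {missing}")


@dataclass
class BlastHitTable:
    """Tabular BLAST hits: query ASV, subject taxon, rank, percent identity
    (0-100) and query coverage (0-1)."""

    data: pd.DataFrame

    COLUMNS = ("qseqid", "staxon", "srank", "pident", "qcov")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"BLAST hit table missing column(s): {missing}")
        if len(self.data):
            pid = self.data["pident"].to_numpy(float)
            if ((pid < 0) | (pid > 100)).any():
                raise FormatError("percent identity outside [0, 100]")
            cov = self.data["qcov"].to_numpy(float)
            if ((cov < 0) | (cov > 1)).any():
                raise FormatError("query coverage outside [0, 1]")
            bad = sorted(set(self.data["srank"]) - {"species", "genus", "higher"})
            if bad:
                raise FormatError(f"unknown taxon rank(s): {bad}")

    def hits_for(self, asv: str) -> pd.DataFrame:
        return self.data[self.data["qseqid"] == asv]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class OccurrenceSet:
    """Point occurrence records (species, longitude, latitude) in degrees."""

    data: pd.DataFrame  # columns species, lon, lat

    def __post_init__(self) -> None:
        missing = [c for c in ("species", "lon", "lat") if c not in self.data.columns]
        if missing:
            raise FormatError(f"occurrence table missing column(s): {missing}")
        if len(self.data):
            if self.data["species"].astype(str).str.strip().eq("").any():
                raise FormatError("empty species name in occurrence set")
            lon = self.data["lon"].to_numpy(float)
            lat = self.data["lat"].to_numpy(float)
            if ((lon < -180) | (lon > 180)).any():
                raise FormatError("longitude outside [-180, 180]")
            if ((lat < -90) | (lat > 90)).any():
                raise FormatError("latitude outside [-90, 90]")

    def for_species(self, names: Iterable[str]) -> pd.DataFrame:
        names = set(names)
        return self.data[self.data["species"].isin(names)]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class RegionPresenceTable:
    """Species x botanical-region 0/1 presence matrix (WGSRPD level-3 codes)."""

    data: pd.DataFrame  # indexed by species, columns region codes

    def __post_init__(self) -> None:
        arr = self.data.to_numpy()
        if len(self.data) and not np.isin(arr, (0, 1)).all():
            raise FormatError("region presence entries must be 0 or 1")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def regions(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SpectrumSet:
    """Centroided DART-MS peak lists, one row per peak.

    ``peaks`` columns: measurement_id, tablet_id, group, mz, intensity, blank,
    out_of_range.  Within a measurement m/z is strictly increasing; peaks
    outside the 50-800 Da acquisition window are kept but flagged.
    """

    peaks: pd.DataFrame

    COLUMNS = ("measurement_id", "tablet_id", "group", "mz", "intensity")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.peaks.columns]
        if missing:
            raise FormatError(f"peak table missing column(s): {missing}")
        df = self.peaks
        if "blank" not in df.columns:
            df = df.assign(blank=False)
        if "out_of_range" not in df.columns:
            oor = (df["mz"] < MZ_RANGE[0]) | (df["mz"] > MZ_RANGE[1])
            df = df.assign(out_of_range=oor.to_numpy())
        if len(df):
            if (df["intensity"].to_numpy(float) < 0).any():
                raise FormatError("negative peak intensity")
            df = df.sort_values(["measurement_id", "mz"], kind="stable").reset_index(drop=True)
            for mid, grp in df.groupby("measurement_id", sort=False):
                mz = grp["mz"].to_numpy(float)
                if (np.diff(mz) <= 0).any():
                    raise FormatError(f"duplicate m/z within measurement {mid!r}")
        self.peaks = df.reset_index(drop=True)

    @property
    def measurement_ids(self) -> list[str]:
        return list(dict.fromkeys(self.peaks["measurement_id"]))

    def measurement(self, mid: str) -> pd.DataFrame:
        return self.peaks[self.peaks["measurement_id"] == mid]

    def split_blanks(self) -> tuple["SpectrumSet", "SpectrumSet"]:
        """Return (samples, blanks)."""
        mask = self.peaks["blank"].astype(bool)
        return (
            SpectrumSet(self.peaks[~mask].reset_index(drop=True)),
            SpectrumSet(self.peaks[mask].reset_index(drop=True)),
        )

    def __len__(self) -> int:
        return len(self.peaks)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_count_table(path: str | Path, marker: str) -> CountTable:
    """Read a TSV count table (first column ``asv_id``, one column per sample)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: count table needs an asv_id column plus sample columns")
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "asv_id"
    parsed = {}
    for col in df.columns:
        try:
            parsed[col] = pd.to_numeric(df[col], downcast=None).astype("int64")
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(f"{path}: non-integer cell at row {row!r}, column {col!r}") from exc
        if (pd.to_numeric(df[col]) % 1 != 0).any():
            bad = df[col][pd.to_numeric(df[col]) % 1 != 0]
            raise FormatError(
                f"{path}: non-integer cell at row {bad.index[0]!r}, column {col!r}"
            )
    out = pd.DataFrame(parsed, index=df.index)
    return CountTable(out, marker)


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.index.name = "asv_id"
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if len(df) == 0:
        raise FormatError(f"{path}: empty sample sheet")
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: sample sheet missing required column(s): ['sample_id']")
    return SampleSheet(df.set_index("sample_id"))


def write_metadata(sheet: SampleSheet, path: str | Path) -> None:
    df = sheet.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_blast_hits(
    path: str | Path, min_coverage: float = 0.0, min_identity: float = 0.0
) -> BlastHitTable:
    """Read an outfmt-6-like hit table, dropping rows below the coverage or
    identity thresholds (both inclusive: a hit exactly at the threshold is
    kept, matching QIIME's ``--p-query-cov`` / ``--p-perc-identity`` semantics)."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=list(BlastHitTable.COLUMNS),
        header=None,
        dtype={"qseqid": str, "staxon": str, "srank": str},
        comment="#",
    )
    if len(df) == 0:
        return BlastHitTable(pd.DataFrame(columns=list(BlastHitTable.COLUMNS)))
    table = BlastHitTable(df)  # validates bounds before filtering
    keep = (df["pident"] >= min_identity) & (df["qcov"] >= min_coverage)
    return BlastHitTable(table.data[keep].reset_index(drop=True))


def write_blast_hits(hits: BlastHitTable, path: str | Path) -> None:
    hits.data.to_csv(path, sep="\t", header=False, index=False)


def read_occurrences(path: str | Path) -> OccurrenceSet:
    df = pd.read_csv(path)
    expected = ["species", "lon", "lat"]
    if list(df.columns[:3]) != expected:
        raise FormatError(f"{path}: expected header 'species,lon,lat'")
    return OccurrenceSet(df[expected])


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    occ.data.to_csv(path, index=False)


def read_regions(path: str | Path) -> RegionPresenceTable:
    df = pd.read_csv(path)
    if df.columns[0] != "species":
        raise FormatError(f"{path}: expected first header column 'species'")
    df = df.set_index("species")
    return RegionPresenceTable(df.astype(int))


def write_regions(regions: RegionPresenceTable, path: str | Path) -> None:
    df = regions.data.copy()
    df.index.name = "species"
    df.to_csv(path)


def read_peaks(path: str | Path) -> SpectrumSet:
    """Read a long-format centroided peak list.

    An optional ``blank`` column (0/1) marks background strip measurements.
    Peaks outside the acquisition window raise a warning but are retained
    with ``out_of_range=True``.
    """
    df = pd.read_csv(path, dtype={"measurement_id": str, "tablet_id": str, "group": str})
    missing = [c for c in SpectrumSet.COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: peak list missing column(s): {missing}")
    if "blank" in df.columns:
        df["blank"] = df["blank"].astype(bool)
    oor = (df["mz"] < MZ_RANGE[0]) | (df["mz"] > MZ_RANGE[1])
    if oor.any():
        warnings.warn(
            f"{path}: {int(oor.sum())} peak(s) outside the {MZ_RANGE[0]}-{MZ_RANGE[1]} m/z "
            "acquisition window; kept but flagged",
            stacklevel=2,
        )
    return SpectrumSet(df)


def write_peaks(spectra: SpectrumSet, path: str | Path) -> None:
    cols = list(SpectrumSet.COLUMNS) + ["blank"]
    df = spectra.peaks[cols].copy()
    df["blank"] = df["blank"].astype(int)
    df.to_csv(path, index=False)
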