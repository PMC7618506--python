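"""Synthetic study generator: every input the pipeline consumes, with known
ground truth.

The default count-table configuration emulates the study design: two
production sites (country A and country B) sharing one excipient-derived
ASV pool but differing in site-specific surface-dust and tap-water pools;
eight tablet groups of three tablets each (direct compression with windows
closed / open, wet granulation, a no-water wet-granulation formulation, and
the cross-over group ``E-5`` made at site A with site-B water, dust:water
signal 3:1); pure-excipient, dust, water and negative-control samples; and
per-sample read depths drawn from the observed 16S range.  Counts follow a
Dirichlet-multinomial so replicate tablets are overdispersed relative to a
plain multinomial.

A calibration layout (``da_calibration_config``) replaces the pool
structure with a single shared pool in which a known subset of ASVs carries
a planted log2-fold change between countries, for error-rate studies of the
differential-abundance stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tables_io import (
    BlastHitTable,
    CountTable,
    OccurrenceSet,
    RegionPresenceTable,
    SampleSheet,
    SpectrumSet,
)

__all__ = [
    "StudyTruth",
    "GroupSpec",
    "CountSimConfig",
    "SpectraSimConfig",
    "BiogeoSimConfig",
    "da_calibration_config",
    "simulate_counts",
    "simulate_spectra",
    "simulate_biogeography",
]


@dataclass
class StudyTruth:
    """Ground truth of a simulated study; each generator fills its part."""

    asv: pd.DataFrame | None = None  # index asv_id: pool, planted_lfc
    spectral: pd.DataFrame | None = None  # index feature id: true_mz, kind, shift
    species: pd.DataFrame | None = None  # index species: kind, center_lon/lat, radius
    asv_species: pd.Series | None = None  # asv_id -> species


@dataclass(frozen=True)
class GroupSpec:
    """Composition of one tablet group."""

    country: str
    manufacturing: str
    water_source: str
    dust_frac: float
    water_frac: float
    dust_site: str
    water_site: str | None = None
    prediction_only: bool = False


def _default_groups() -> dict[str, GroupSpec]:
    return {
        "E-1": GroupSpec("A", "direct_compression", "none", 0.02, 0.0, "A"),
        "E-2": GroupSpec("A", "direct_compression", "none", 0.08, 0.0, "A"),
        "E-3": GroupSpec("A", "wet_granulation", "local", 0.24, 0.08, "A", "A"),
        "E-4": GroupSpec("A", "wet_granulation", "none", 0.15, 0.0, "A"),
        "E-5": GroupSpec("A", "wet_granulation", "foreign", 0.24, 0.08, "A", "B",
                         prediction_only=True),
        "T-1": GroupSpec("B", "direct_compression", "none", 0.02, 0.0, "B"),
        "T-2": GroupSpec("B", "direct_compression", "none", 0.08, 0.0, "B"),
        "T-3": GroupSpec("B", "wet_granulation", "local", 0.24, 0.08, "B", "B"),
    }


@dataclass
class CountSimConfig:
    n_excipient_asvs: int = 120
    n_dust_asvs: int = 60  # per site
    n_water_asvs: int = 30  # per site
    n_contam_asvs: int = 12
    n_shared_asvs: int = 0  # shared environmental pool (calibration layouts)
    n_planted: int = 0  # planted-lfc ASVs within the shared pool
    planted_lfc: float = 0.0  # |log2 fold| planted between countries
    tablets_per_group: int = 3
    n_excipient_samples: int = 2
    n_dust_samples_per_site: int = 1
    n_water_samples_per_site: int = 1
    n_neg_controls: int = 2
    depth_range: tuple[int, int] = (5264, 329354)  # observed 16S per-sample range
    control_depth_range: tuple[int, int] = (200, 2000)
    # total Dirichlet concentration across the composition; 5000 gives a
    # replicate-to-replicate CV of ~30% for a mid-abundance ASV, in line with
    # technical replicates of a controlled tablet formulation
    concentration: float = 5000.0
    contam_frac: float = 0.003
    marker: str = "16S"
    groups: Mapping[str, GroupSpec] = field(default_factory=_default_groups)


def da_calibration_config(
    n_asvs: int = 500, n_planted: int = 50, planted_lfc: float = 3.0
) -> CountSimConfig:
    """Layout for differential-abundance error-rate studies: one shared pool,
    ``n_planted`` ASVs with a planted |lfc| split evenly between countries,
    no site pools so every unplanted ASV is a true null."""
    return CountSimConfig(
        n_excipient_asvs=0,
        n_dust_asvs=0,
        n_water_asvs=0,
        n_contam_asvs=0,
        n_shared_asvs=n_asvs,
        n_planted=n_planted,
        planted_lfc=planted_lfc,
        contam_frac=0.0,
        depth_range=(20000, 100000),
    )


def _lognormal_profile(rng: np.random.Generator, n: int, sigma: float = 1.0) -> np.ndarray:
    if n == 0:
        return np.zeros(0)
    w = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return w / w.sum()


def _dirichlet_multinomial(
    rng: np.random.Generator, probs: np.ndarray, depth: int, concentration: float
) -> np.ndarray:
    mask = probs > 0
    alpha = probs[mask] * concentration
    p = rng.dirichlet(alpha)
    out = np.zeros(len(probs), dtype=np.int64)
    out[mask] = rng.multinomial(depth, p)
    return out


def simulate_counts(
    config: CountSimConfig | None = None, seed: int | None = None
) -> tuple[CountTable, SampleSheet, StudyTruth]:
    """Simulate an ASV count table, sample sheet and truth record.

    Tablet composition is excipient pool plus a scenario-dependent admixture
    of the site's dust pool and (for wet granulation) the water pool, with
    dust dominating; negative controls carry sparse contamination ASVs that
    also seep faintly into tablets.
    """
    config = config or CountSimConfig()
    rng = np.random.default_rng(seed)

    pools: list[tuple[str, int]] = [
        ("excipient", config.n_excipient_asvs),
        ("dust_A", config.n_dust_asvs),
        ("dust_B", config.n_dust_asvs),
        ("water_A", config.n_water_asvs),
        ("water_B", config.n_water_asvs),
        ("control_contam", config.n_contam_asvs),
        ("shared", config.n_shared_asvs),
    ]
    asv_ids, pool_of = [], []
    for pool, n in pools:
        for i in range(n):
            asv_ids.append(f"ASV_{pool}_{i + 1:03d}")
            pool_of.append(pool)
    if not asv_ids:
        raise ValueError("no ASVs configured")
    pool_of = np.array(pool_of)
    idx = {pool: np.where(pool_of == pool)[0] for pool, _ in pools}

    base = {pool: _lognormal_profile(rng, len(idx[pool])) for pool, _ in pools}
    planted_lfc = np.zeros(len(asv_ids))
    if config.n_planted:
        if config.n_planted > config.n_shared_asvs:
            raise ValueError("n_planted exceeds n_shared_asvs")
        planted = rng.choice(idx["shared"], size=config.n_planted, replace=False)
        half = config.n_planted // 2
        planted_lfc[planted[:half]] = config.planted_lfc  # overabundant in A
        planted_lfc[planted[half:]] = -config.planted_lfc  # overabundant in B

    def tablet_probs(spec: GroupSpec) -> np.ndarray:
        frac_env = spec.dust_frac + spec.water_frac + config.contam_frac
        if frac_env > 1.0:
            raise ValueError(
                f"admixture fractions exceed 1 (dust {spec.dust_frac} + water "
                f"{spec.water_frac} + contamination {config.contam_frac})"
            )
        p = np.zeros(len(asv_ids))
        shared_frac = 0.0
        if config.n_shared_asvs:
            # the shared pool takes the excipient role in calibration layouts
            shared_frac = 1.0 - frac_env if config.n_excipient_asvs == 0 else 0.3
        exc_frac = 1.0 - frac_env - shared_frac
        if exc_frac < -1e-12:
            raise ValueError("admixture fractions exceed 1")
        if config.n_excipient_asvs:
            p[idx["excipient"]] += exc_frac * base["excipient"]
        if config.n_shared_asvs:
            w = base["shared"] * np.exp2(
                np.where(spec.country == "A", 0.5, -0.5) * planted_lfc[idx["shared"]]
            )
            p[idx["shared"]] += shared_frac * w / w.sum()
        if spec.dust_frac:
            p[idx[f"dust_{spec.dust_site}"]] += spec.dust_frac * base[f"dust_{spec.dust_site}"]
        if spec.water_frac and spec.water_site:
            pool = f"water_{spec.water_site}"
            p[idx[pool]] += spec.water_frac * base[pool]
        if config.contam_frac and config.n_contam_asvs:
            p[idx["control_contam"]] += config.contam_frac * base["control_contam"]
        return p / p.sum()

    columns: dict[str, np.ndarray] = {}
    meta_rows: dict[str, dict] = {}
    lo, hi = config.depth_range

    for label, spec in config.groups.items():
        probs = tablet_probs(spec)
        for t in range(config.tablets_per_group):
            sid = f"{label}-t{t + 1}"
            depth = int(rng.integers(lo, hi + 1))
            columns[sid] = _dirichlet_multinomial(rng, probs, depth, config.concentration)
            meta_rows[sid] = {
                "sample_type": "tablet",
                "country": spec.country,
                "manufacturing": spec.manufacturing,
                "water_source": spec.water_source,
                "group_label": label,
            }

    def env_sample(sid: str, pool: str, country: str, stype: str) -> None:
        p = np.zeros(len(asv_ids))
        p[idx[pool]] = base[pool]
        if p.sum() == 0:
            return
        depth = int(rng.integers(lo, hi + 1))
        columns[sid] = _dirichlet_multinomial(rng, p, depth, config.concentration)
        meta_rows[sid] = {
            "sample_type": stype,
            "country": country,
            "manufacturing": "direct_compression",
            "water_source": "none",
            "group_label": sid.rsplit("-", 1)[0],
        }

    if config.n_excipient_asvs:
        for i in range(config.n_excipient_samples):
            env_sample(f"EXC-{i + 1}", "excipient", "unknown", "excipient")
    if config.n_dust_asvs:
        for site in ("A", "B"):
            for i in range(config.n_dust_samples_per_site):
                env_sample(f"DUST-{site}-{i + 1}", f"dust_{site}", site, "dust")
    if config.n_water_asvs:
        for site in ("A", "B"):
            for i in range(config.n_water_samples_per_site):
                env_sample(f"WTR-{site}-{i + 1}", f"water_{site}", site, "water")
    if config.n_contam_asvs:
        clo, chi = config.control_depth_range
        for i in range(config.n_neg_controls):
            sid = f"NEG-{i + 1}"
            p = np.zeros(len(asv_ids))
            p[idx["control_contam"]] = base["control_contam"]
            depth = int(rng.integers(clo, chi + 1))
            columns[sid] = _dirichlet_multinomial(rng, p, depth, config.concentration)
            meta_rows[sid] = {
                "sample_type": "neg_control",
                "country": "unknown",
                "manufacturing": "direct_compression",
                "water_source": "none",
                "group_label": "NEG",
            }

    counts = pd.DataFrame(columns, index=asv_ids)
    table = CountTable(counts, config.marker)
    sheet = SampleSheet(pd.DataFrame.from_dict(meta_rows, orient="index"))
    truth = StudyTruth(
        asv=pd.DataFrame({"pool": pool_of, "planted_lfc": planted_lfc}, index=asv_ids)
    )
    return table, sheet, truth


# ---------------------------------------------------------------------------
# DART-MS spectra
# ---------------------------------------------------------------------------


@dataclass
class SpectraSimConfig:
    n_shared_peaks: int = 120
    n_site_peaks: int = 20  # per site
    n_background_peaks: int = 30
    tablets_per_group: int = 4
    replicates: int = 3  # technical replicates per tablet
    n_blanks: int = 3
    noise_sd: float = 5.0  # additive intensity noise (arbitrary units)
    site_shift: float = 50.0  # planted own-site intensity surplus
    base_off_site: float = 10.0
    mz_jitter_sd: float = 0.004  # per-measurement centroid wobble (Da)
    e5_water_fraction: float = 0.25  # how much of the B signature E-5 carries
    groups: tuple[str, ...] = ("E-1", "E-2", "E-3", "E-4", "T-1", "T-2", "T-3")
    query_groups: tuple[str, ...] = ("E-5",)


def _spaced_mz(rng: np.random.Generator, n: int, lo=55.0, hi=795.0, min_gap=2.5) -> np.ndarray:
    """Random m/z values with a minimum mutual gap (so aggregation at 1 Da
    never merges distinct true features)."""
    span = (hi - lo) - (n - 1) * min_gap
    if span <= 0:
        raise ValueError("mass range too small for the requested peak count and spacing")
    u = np.sort(rng.uniform(0.0, span, size=n))
    return lo + u + min_gap * np.arange(n)


def simulate_spectra(
    config: SpectraSimConfig | None = None, seed: int | None = None
) -> tuple[SpectrumSet, StudyTruth]:
    """Simulate centroided DART-MS peak lists with site-shifted intensities.

    Shared peaks have a common intensity in every tablet; each site owns a
    set of peaks elevated by ``site_shift`` in its own tablets.  Background
    peaks appear in every measurement and in the blank strips.  The
    cross-over group ``E-5`` carries the site-A signature plus a
    ``e5_water_fraction`` echo of the site-B signature.
    """
    config = config or SpectraSimConfig()
    rng = np.random.default_rng(seed)
    n_total = (
        config.n_shared_peaks + 2 * config.n_site_peaks + config.n_background_peaks
    )
    mz = _spaced_mz(rng, n_total)
    rng.shuffle(mz)
    pos = 0
    shared_mz = mz[pos : pos + config.n_shared_peaks]; pos += config.n_shared_peaks
    site_a_mz = mz[pos : pos + config.n_site_peaks]; pos += config.n_site_peaks
    site_b_mz = mz[pos : pos + config.n_site_peaks]; pos += config.n_site_peaks
    bg_mz = mz[pos:]

    shared_base = rng.uniform(15.0, 100.0, size=config.n_shared_peaks)
    bg_base = rng.uniform(5.0, 40.0, size=config.n_background_peaks)

    def site_weight(group: str, site: str) -> float:
        country = "A" if group.startswith("E") else "B"
        if group in config.query_groups:  # E-5: site-A chemistry + faint B echo
            return 1.0 if site == "A" else config.e5_water_fraction
        return 1.0 if country == site else 0.0

    rows = []

    def emit(mid, tid, group, true_mz, mean_int, blank=False):
        inten = mean_int + rng.normal(0.0, config.noise_sd, size=len(true_mz))
        keep = inten > 0.5
        obs_mz = true_mz[keep] + rng.normal(0.0, config.mz_jitter_sd, size=keep.sum())
        for m, i in zip(obs_mz, inten[keep]):
            rows.append(
                {
                    "measurement_id": mid,
                    "tablet_id": tid,
                    "group": group,
                    "mz": float(m),
                    "intensity": float(i),
                    "blank": blank,
                }
            )

    all_groups = tuple(config.groups) + tuple(config.query_groups)
    for group in all_groups:
        for t in range(config.tablets_per_group):
            tid = f"{group}-tab{t + 1}"
            for r in range(config.replicates):
                mid = f"{tid}-m{r + 1}"
                wa, wb = site_weight(group, "A"), site_weight(group, "B")
                true_mz = np.concatenate([shared_mz, site_a_mz, site_b_mz, bg_mz])
                mean_int = np.concatenate(
                    [
                        shared_base,
                        config.base_off_site + wa * config.site_shift
                        + np.zeros(config.n_site_peaks),
                        config.base_off_site + wb * config.site_shift
                        + np.zeros(config.n_site_peaks),
                        bg_base,
                    ]
                )
                emit(mid, tid, group, true_mz, mean_int)
    for b in range(config.n_blanks):
        emit(f"BLANK-m{b + 1}", "BLANK", "BLANK", bg_mz, bg_base, blank=True)

    spectra = SpectrumSet(pd.DataFrame(rows))
    truth_rows = []
    for arr, kind, shift in (
        (shared_mz, "shared", 0.0),
        (site_a_mz, "site_A", config.site_shift),
        (site_b_mz, "site_B", config.site_shift),
        (bg_mz, "background", 0.0),
    ):
        for m in arr:
            truth_rows.append({"true_mz": float(m), "kind": kind, "shift": shift})
    truth = StudyTruth(spectral=pd.DataFrame(truth_rows))
    return spectra, truth


# ---------------------------------------------------------------------------
# biogeography
# ---------------------------------------------------------------------------


@dataclass
class BiogeoSimConfig:
    species_per_site: int = 6
    n_cosmopolitan: int = 4
    records_per_species: int = 40
    range_radius: float = 10.0  # degrees
    ambiguity_rate: float = 0.0  # fraction of ASVs with tied top hits
    region_size: float = 30.0  # synthetic botanical-region grid cell (degrees)
    # default site centers: the two production laboratories (lon, lat)
    site_centers: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"A": (-1.77759, 53.64307), "B": (100.53383, 13.76638)}
    )


def simulate_biogeography(
    config: BiogeoSimConfig | None = None,
    seed: int | None = None,
    site_asvs: Mapping[str, list[str]] | None = None,
) -> tuple[BlastHitTable, OccurrenceSet, RegionPresenceTable, StudyTruth]:
    """Simulate BLAST hits, occurrence records and a region-presence table.

    Site-pool species draw records from a truncated Gaussian around their
    site's coordinates; cosmopolitan species are spread worldwide.  BLAST
    hits link ASVs to species (with optional tied top hits) plus genus-rank
    rows; the region table intersects each species' circular range with a
    rectangular region grid.
    """
    config = config or BiogeoSimConfig()
    if config.range_radius <= 0:
        raise ValueError("range_radius must be > 0")
    rng = np.random.default_rng(seed)

    species_rows = {}
    for site, (clon, clat) in config.site_centers.items():
        for i in range(config.species_per_site):
            name = f"Gen{site}{i // 2 + 1} sp{i + 1}"
            species_rows[name] = {
                "kind": f"site_{site}",
                "center_lon": clon,
                "center_lat": clat,
                "radius": config.range_radius,
            }
    for i in range(config.n_cosmopolitan):
        species_rows[f"Cosmo{i + 1} ubique"] = {
            "kind": "cosmopolitan",
            "center_lon": np.nan,
            "center_lat": np.nan,
            "radius": np.nan,
        }
    species_df = pd.DataFrame.from_dict(species_rows, orient="index")

    # occurrences
    occ_rows = []
    for name, row in species_df.iterrows():
        if row["kind"] == "cosmopolitan":
            lon = rng.uniform(-180.0, 180.0, size=config.records_per_species)
            lat = rng.uniform(-60.0, 75.0, size=config.records_per_species)
        else:
            pts = []
            while len(pts) < config.records_per_species:
                cand = rng.normal(
                    loc=(row["center_lon"], row["center_lat"]),
                    scale=config.range_radius / 2.0,
                    size=(4 * config.records_per_species, 2),
                )
                d = np.hypot(cand[:, 0] - row["center_lon"], cand[:, 1] - row["center_lat"])
                ok = (
                    (d <= config.range_radius)
                    & (np.abs(cand[:, 0]) <= 180)
                    & (np.abs(cand[:, 1]) <= 90)
                )
                pts.extend(cand[ok].tolist())
            arr = np.array(pts[: config.records_per_species])
            lon, lat = arr[:, 0], arr[:, 1]
        for x, y in zip(lon, lat):
            occ_rows.append({"species": name, "lon": float(x), "lat": float(y)})
    occ = OccurrenceSet(pd.DataFrame(occ_rows))

    # region grid: presence where the species range circle meets the cell
    nx = int(math.ceil(360.0 / config.region_size))
    ny = int(math.ceil(180.0 / config.region_size))
    region_codes = [f"R{ix}_{iy}" for ix in range(nx) for iy in range(ny)]
    presence = pd.DataFrame(0, index=species_df.index, columns=region_codes, dtype=int)
    for name, row in species_df.iterrows():
        if row["kind"] == "cosmopolitan":
            presence.loc[name] = 1
            continue
        for ix in range(nx):
            for iy in range(ny):
                x0 = -180.0 + ix * config.region_size
                y0 = -90.0 + iy * config.region_size
                nearest_x = min(max(row["center_lon"], x0), x0 + config.region_size)
                nearest_y = min(max(row["center_lat"], y0), y0 + config.region_size)
                d = math.hypot(nearest_x - row["center_lon"], nearest_y - row["center_lat"])
                if d <= config.range_radius:
                    presence.loc[name, f"R{ix}_{iy}"] = 1
    regions = RegionPresenceTable(presence)

    # BLAST hits: one ASV per species by default, or the caller's ASV ids
    hit_rows = []
    asv_species = {}
    for site in config.site_centers:
        site_species = [n for n, r in species_df.iterrows() if r["kind"] == f"site_{site}"]
        if site_asvs and site in site_asvs:
            ids = list(site_asvs[site])
        else:
            ids = [f"ASV_geo_{site}_{i + 1:03d}" for i in range(len(site_species))]
        for j, asv in enumerate(ids):
            sp = site_species[j % len(site_species)]
            asv_species[asv] = sp
            lpi = round(float(rng.uniform(97.5, 100.0)), 1)
            hit_rows.append(
                {"qseqid": asv, "staxon": sp, "srank": "species", "pident": lpi, "qcov": 0.98}
            )
            if rng.random() < config.ambiguity_rate:
                others = [s for s in site_species if s != sp] or list(species_df.index)
                alt = others[int(rng.integers(len(others)))]
                hit_rows.append(
                    {"qseqid": asv, "staxon": alt, "srank": "species", "pident": lpi,
                     "qcov": 0.98}
                )
            # a weaker secondary hit and a genus-rank row
            hit_rows.append(
                {
                    "qseqid": asv,
                    "staxon": species_df.index[int(rng.integers(len(species_df)))],
                    "srank": "species",
                    "pident": round(lpi - float(rng.uniform(0.5, 2.0)), 1),
                    "qcov": 0.97,
                }
            )
            hit_rows.append(
                {"qseqid": asv, "staxon": sp.split()[0], "srank": "genus", "pident": lpi,
                 "qcov": 0.98}
            )
    hits = BlastHitTable(pd.DataFrame(hit_rows))
    truth = StudyTruth(species=species_df, asv_species=pd.Series(asv_species))
    return hits, occ, regions, truth
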