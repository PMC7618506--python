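"""Orchestration of the two headline analyses with provenance manifests.

``run_origin_analysis`` chains decontamination -> abundance filtering ->
differential abundance -> iterative rarefaction -> DAPC with LOOCV ->
held-out membership prediction for the cross-over group.
``run_geomap_analysis`` chains decontamination -> differential abundance ->
overabundant-ASV selection -> LPI taxon resolution (with genus fallback) ->
unified point and region maps per country.

Both return a results bundle plus a :class:`RunManifest` recording the
configuration hash, seeds, per-stage record counts, output checksums and
every warning emitted, so a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import pandas as pd

from . import classify, community, decontam, diff_abund, geomap, synthetic_data
from .tables_io import CountTable, SampleSheet

__all__ = ["RunManifest", "run_origin_analysis", "run_geomap_analysis", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "control_threshold": 10,
    "min_total": 1000,
    "q": 0.05,
    "rarefaction_depth": 5000,
    "rarefaction_iters": 100,
    "var_target": 0.90,
    "predict_group": "E-5",
    "min_samples": 2,
    "bin_width": 5.0,
    "exclude_taxon": None,  # e.g. "Zea:90"
}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    checksums: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, **info})

    def checksum(self, name: str, obj) -> None:
        if isinstance(obj, pd.DataFrame):
            payload = obj.to_csv(float_format="%.10g")
        elif isinstance(obj, pd.Series):
            payload = obj.to_csv(float_format="%.10g")
        else:
            payload = json.dumps(obj, sort_keys=True, default=str)
        self.checksums[name] = hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "stages": self.stages,
                "checksums": self.checksums,
                "warnings": self.warnings,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _merged(config: dict | None) -> dict:
    out = dict(DEFAULT_CONFIG)
    out.update(config or {})
    return out


def _obtain_inputs(config: dict, manifest: RunManifest):
    """Load the count table and sample sheet from paths, or simulate them."""
    from . import tables_io

    if "counts_path" in config:
        table = tables_io.read_count_table(config["counts_path"], config.get("marker", "16S"))
        sheet = tables_io.read_metadata(config["metadata_path"])
        truth = None
        manifest.record("load", counts=str(config["counts_path"]), n_asvs=table.shape[0])
    else:
        sim_conf = config.get("sim_config") or synthetic_data.CountSimConfig()
        table, sheet, truth = synthetic_data.simulate_counts(sim_conf, seed=config["seed"])
        manifest.record("simulate", n_asvs=table.shape[0], n_samples=table.shape[1])
    sheet.resolve(table)
    return table, sheet, truth


def _decontaminate(table: CountTable, sheet: SampleSheet, config: dict,
                   manifest: RunManifest) -> tuple[CountTable, CountTable]:
    """Apply the exclusion rules; returns (control-filtered table,
    fully filtered table).  The control-filtered table keeps excipient-derived
    ASVs and is the basis for rarefaction; the fully filtered one feeds the
    differential-abundance stage."""
    controls = [s for s in sheet.samples_of_type("neg_control") if s in table.sample_ids]
    if controls:
        table, rep = decontam.remove_control_asvs(
            table, controls, threshold=config["control_threshold"]
        )
        manifest.record("filter_controls", **rep.to_dict())
    control_filtered = table
    excipients = [s for s in sheet.samples_of_type("excipient") if s in table.sample_ids]
    if excipients:
        table, rep = decontam.remove_excipient_asvs(table, excipients)
        manifest.record("filter_excipients", **rep.to_dict())
    if config.get("exclude_taxon") and config.get("hits") is not None:
        name, _, ident = str(config["exclude_taxon"]).partition(":")
        table, rep = decontam.remove_taxon_asvs(
            table, config["hits"], name, float(ident or 90)
        )
        manifest.record("filter_taxon", **rep.to_dict())
    return control_filtered, table


def run_origin_analysis(config: dict | None = None) -> dict:
    """Reference-based origin prediction: filters -> differential abundance ->
    rarefaction -> DAPC LOOCV -> held-out group prediction."""
    config = _merged(config)
    manifest = RunManifest(config_hash=_config_hash(
        {k: v for k, v in config.items() if isinstance(v, (int, float, str, type(None)))}
    ), seed=config["seed"])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        table, sheet, truth = _obtain_inputs(config, manifest)
        control_filtered, table = _decontaminate(table, sheet, config, manifest)
        filtered = diff_abund.abundance_filter(table, min_total=config["min_total"])
        manifest.record("abundance_filter", n_asvs=filtered.shape[0],
                        min_total=config["min_total"])

        predict_group = config["predict_group"]
        da = diff_abund.wald_da_test(
            filtered, sheet, q=config["q"], exclude_groups=(predict_group,)
        )
        da_asvs = list(da.table.index[da.table["overabundant_in"] != "none"])
        manifest.record("differential_abundance", n_da_asvs=len(da_asvs), q=config["q"])

        # rarefy the control-filtered counts (full sequencing depth per
        # sample) and take the discriminant ASVs' rarefied rows afterwards
        meta = sheet.data
        tablet_ids = [s for s in control_filtered.sample_ids
                      if meta.loc[s, "sample_type"] == "tablet"]
        tablets = control_filtered.subset_samples(tablet_ids)
        rarefied = community.rarefy_iterative(
            tablets,
            depth=config["rarefaction_depth"],
            n_iter=config["rarefaction_iters"],
            seed=config["seed"] + 1,
        )
        manifest.record("rarefaction", depth=config["rarefaction_depth"],
                        n_samples=rarefied.shape[1])

        if not da_asvs:
            manifest.record("dapc", skipped="no differentially abundant ASVs")
            bundle = {"da": da.table, "loocv_accuracy": None, "no_signal": True,
                      "manifest": manifest, "truth": truth}
            manifest.warnings.extend(str(w.message) for w in caught)
            return bundle

        feats = rarefied.counts.loc[[a for a in da_asvs if a in rarefied.counts.index]].T
        train_ids = [s for s in feats.index if meta.loc[s, "group_label"] != predict_group]
        query_ids = [s for s in feats.index if meta.loc[s, "group_label"] == predict_group]
        labels = meta.loc[train_ids, "country"].to_numpy()

        def fitter(x, y):
            return classify.fit_dapc(x, y, var_target=config["var_target"])

        cv_table, accuracy = classify.loocv(fitter, feats.loc[train_ids], labels)
        manifest.record("dapc_loocv", accuracy=accuracy, n_pcs_target=config["var_target"])

        prediction = None
        if query_ids:
            model = fitter(feats.loc[train_ids], labels)
            prediction = classify.predict_membership(model, feats.loc[query_ids])
            manifest.record(
                "predict_heldout",
                group=predict_group,
                assigned=prediction.assigned.to_dict(),
            )
        manifest.checksum("da_table", da.table)
        manifest.checksum("loocv", cv_table)
        if prediction is not None:
            manifest.checksum("heldout_posteriors", prediction.posteriors)
        manifest.warnings.extend(str(w.message) for w in caught)
    return {
        "da": da.table,
        "da_asvs": da_asvs,
        "loocv": cv_table,
        "loocv_accuracy": accuracy,
        "heldout_prediction": prediction,
        "manifest": manifest,
        "truth": truth,
        "no_signal": False,
    }


def run_geomap_analysis(config: dict | None = None) -> dict:
    """Reference-free geolocation: filters -> differential abundance ->
    overabundant-ASV selection -> LPI resolution -> unified maps."""
    config = _merged(config)
    manifest = RunManifest(config_hash=_config_hash(
        {k: v for k, v in config.items() if isinstance(v, (int, float, str, type(None)))}
    ), seed=config["seed"])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        table, sheet, truth = _obtain_inputs(config, manifest)

        if "hits" in config:
            hits, occ, regions = config["hits"], config["occurrences"], config["regions"]
            geo_truth = None
        else:
            dust_asvs = None
            if truth is not None:
                dust_asvs = {
                    site: list(truth.asv.index[truth.asv["pool"] == f"dust_{site}"])
                    for site in ("A", "B")
                }
            hits, occ, regions, geo_truth = synthetic_data.simulate_biogeography(
                config.get("biogeo_config"), seed=config["seed"] + 7, site_asvs=dust_asvs
            )
            manifest.record("simulate_biogeography", n_hits=len(hits), n_records=len(occ))

        config_with_hits = dict(config)
        config_with_hits["hits"] = hits
        _, table = _decontaminate(table, sheet, config_with_hits, manifest)
        filtered = diff_abund.abundance_filter(table, min_total=config["min_total"])
        manifest.record("abundance_filter", n_asvs=filtered.shape[0])

        da = diff_abund.wald_da_test(
            filtered, sheet, q=config["q"], exclude_groups=(config["predict_group"],)
        )
        sets = geomap.select_overabundant_asvs(
            da, filtered, sheet,
            min_samples=config["min_samples"],
            exclude_groups=(config["predict_group"],),
        )
        manifest.record("select_overabundant",
                        n_A=len(sets["A"]), n_B=len(sets["B"]))

        bundle: dict = {"da": da.table, "sets": sets, "assignments": {}, "maps": {},
                        "manifest": manifest, "truth": truth, "geo_truth": geo_truth}
        no_signal = all(len(v) == 0 for v in sets.values())
        bundle["no_signal"] = no_signal
        for country, asvs in sets.items():
            assignments, rank = geomap.genus_fallback(hits, asvs)
            species = sorted({t for a in assignments for t in a.taxa})
            manifest.record(f"resolve_{country}", rank=rank, n_assigned=len(assignments),
                            n_taxa=len(species))
            bundle["assignments"][country] = {"rank": rank, "assignments": assignments,
                                              "species": species}
            if species:
                pmap = geomap.unified_point_map(occ, species, bin_width=config["bin_width"])
                rmap = geomap.unified_region_map(regions, species)
                bundle["maps"][country] = {"point": pmap, "region": rmap}
                manifest.checksum(f"point_map_{country}", pmap.bins)
                manifest.checksum(f"region_map_{country}", rmap.counts)
        manifest.checksum("da_table", da.table)
        manifest.warnings.extend(str(w.message) for w in caught)
    return bundle
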