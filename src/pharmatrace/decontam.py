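"""Contamination and excipient exclusion rules applied to count tables.

Three rules, applied in the order controls -> excipients -> taxon when
chained:

* **control rule** — an ASV with strictly more than ``threshold`` reads in
  any single negative control (DNA-extraction or PCR blank) is removed
  everywhere; the control columns themselves are dropped from the output.
* **excipient rule** — any ASV present (>= 1 read) in any pure-excipient
  sample is removed, so that downstream contrasts reflect the production
  environment rather than imported raw materials.
* **taxon rule** — ASVs whose BLAST hits match a named taxon at or above a
  percent-identity floor are removed (e.g. *Zea*, attributed to corn-starch
  excipients rather than the production environment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .tables_io import BlastHitTable, CountTable

__all__ = ["FilterReport", "remove_control_asvs", "remove_excipient_asvs", "remove_taxon_asvs"]


@dataclass
class FilterReport:
    """Audit trail of an exclusion rule: which ASVs each rule removed."""

    rule: str
    removed: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "n_removed": self.n_removed,
            "removed": list(self.removed),
            "params": dict(self.params),
        }


def _check_samples(table: CountTable, samples, what: str) -> list[str]:
    samples = list(samples)
    if not samples:
        raise ValueError(f"{what} sample set is empty; pass at least one {what} sample")
    missing = [s for s in samples if s not in table.counts.columns]
    if missing:
        raise KeyError(f"{what} sample(s) not in table: {missing}")
    return samples


def remove_control_asvs(
    counts: CountTable, control_samples, threshold: int = 10
) -> tuple[CountTable, FilterReport]:
    """Drop ASVs exceeding ``threshold`` reads in any negative control.

    The rule is strict (``> threshold``): an ASV with exactly ``threshold``
    reads in a control is retained.  Each control is considered on its own;
    reads are not summed across controls.  Control columns are removed from
    the returned table.
    """
    controls = _check_samples(counts, control_samples, "control")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ctrl = counts.counts[controls]
    removed = list(counts.counts.index[(ctrl > threshold).any(axis=1)])
    kept = counts.counts.drop(index=removed).drop(columns=controls)
    report = FilterReport(
        rule="controls", removed=removed, params={"threshold": threshold, "controls": controls}
    )
    return CountTable(kept, counts.marker), report


def remove_excipient_asvs(
    counts: CountTable, excipient_samples
) -> tuple[CountTable, FilterReport]:
    """Drop every ASV present (any nonzero count) in any pure-excipient sample.

    Presence-based with no read threshold; excipient columns are retained in
    the output so they can still be inspected downstream.
    """
    excipients = _check_samples(counts, excipient_samples, "excipient")
    exc = counts.counts[excipients]
    removed = list(counts.counts.index[(exc > 0).any(axis=1)])
    kept = counts.counts.drop(index=removed)
    report = FilterReport(rule="excipients", removed=removed, params={"excipients": excipients})
    return CountTable(kept, counts.marker), report


def remove_taxon_asvs(
    counts: CountTable, hits: BlastHitTable, taxon_name: str, min_identity: float = 90.0
) -> tuple[CountTable, FilterReport]:
    """Drop ASVs with any BLAST hit to ``taxon_name`` at >= ``min_identity``.

    Matching is by taxon-name prefix so that genus-level exclusion (e.g.
    ``Zea``) also catches species-level hits (``Zea mays``).
    """
    if not taxon_name or not taxon_name.strip():
        raise ValueError("taxon_name must be non-empty")
    if not 0 <= min_identity <= 100:
        raise ValueError("min_identity must be within [0, 100]")
    df = hits.data
    if len(df):
        name = taxon_name.strip()
        match = df["staxon"].astype(str).str.strip().str.startswith(name) & (
            df["pident"] >= min_identity
        )
        flagged = set(df.loc[match, "qseqid"])
    else:
        flagged = set()
    removed = [a for a in counts.counts.index if a in flagged]
    kept = counts.counts.drop(index=removed)
    report = FilterReport(
        rule="taxon", removed=removed, params={"taxon": taxon_name, "min_identity": min_identity}
    )
    return CountTable(kept, counts.marker), report
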