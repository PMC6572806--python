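"""Community statistics on OTU tables: rarefaction, richness, functional-group
relative abundance, total-sum scaling, and the surface-community reappearance
statistic at redox transition zones.

The central ecological observation these tools target: OTU richness in
energy-starved sediments decays with depth, but surface taxa that become
undetectable mid-column can reappear in the oxic-anoxic transition zone where
renewed energy supply allows in-situ growth of the buried seed bank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ZONE_LABELS = ("surface", "oxic", "OATZ", "anoxic", "AOTZ", "basal")

#: Default taxon → functional group assignment (names matched at any rank).
DEFAULT_FUNCTIONAL_GROUPS: dict[str, tuple[str, ...]] = {
    "AOA": ("Nitrosopumilales",),
    "AOB": ("Nitrosospira", "Nitrosomonas", "Nitrosococcus"),
    "NOB": ("Nitrospira", "Nitrospina"),
    "denitrifiers": ("Pseudomonas", "Arcobacter", "Aeromonas", "Woeseiaceae"),
}


@dataclass
class OtuTable:
    """Integer counts per (OTU, sample) with per-sample depth/zone metadata and
    a rank-delimited taxonomy string per OTU.

    ``counts``: DataFrame indexed by OTU id, one column per sample.
    ``metadata``: DataFrame indexed by sample id with at least ``depth_m`` and
    optionally ``site`` and ``zone`` columns.
    ``taxonomy``: Series indexed by OTU id of semicolon-delimited rank strings.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("OTU counts must be nonnegative")
        if not np.issubdtype(np.asarray(self.counts.values).dtype, np.integer):
            vals = self.counts.values
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("OTU counts must be integers")
            self.counts = self.counts.astype(np.int64)
        missing = [s for s in self.counts.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        if "depth_m" not in self.metadata.columns:
            raise ValueError("metadata must carry a depth_m column")

    def samples_in_zone(self, zone: str) -> list[str]:
        meta = self.metadata.loc[list(self.counts.columns)]
        return list(meta.index[meta["zone"] == zone])

    def restrict_taxa(self, names: tuple[str, ...] | list[str]) -> "OtuTable":
        keep = self.taxonomy.index[
            [taxonomy_matches(t, names) for t in self.taxonomy]
        ]
        return OtuTable(self.counts.loc[keep], self.metadata, self.taxonomy.loc[keep])


def taxonomy_matches(taxonomy: str, names: tuple[str, ...] | list[str]) -> bool:
    """Exact name match at any rank of a rank-delimited taxonomy string."""
    ranks = {r.strip() for r in str(taxonomy).replace("|", ";").split(";")}
    return any(n in ranks for n in names)


def rarefy_counts(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample one sample's counts to exactly ``depth`` reads without
    replacement (multivariate hypergeometric draw)."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    if total < depth:
        raise ValueError(f"sample has {total} reads < rarefaction depth {depth}")
    if total == depth:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts, depth)


def rarefy(table: OtuTable, depth: int = 1000, seed: int | None = 0) -> OtuTable:
    """Rarefy every sample to ``depth`` reads; samples with fewer reads are
    excluded with a log note.  Reproducible under a fixed seed."""
    rng = np.random.default_rng(seed)
    out = {}
    for sample in table.counts.columns:
        col = table.counts[sample].to_numpy()
        if col.sum() < depth:
            log.info("excluding sample %s: %d reads < depth %d", sample, col.sum(), depth)
            continue
        out[sample] = rarefy_counts(col, depth, rng)
    if not out:
        raise ValueError("no sample reaches the rarefaction depth")
    counts = pd.DataFrame(out, index=table.counts.index)
    return OtuTable(counts, table.metadata, table.taxonomy)


def richness(sample_counts: np.ndarray | pd.Series) -> int:
    """Number of OTUs with at least one read."""
    return int(np.count_nonzero(np.asarray(sample_counts) > 0))


def richness_profile(table: OtuTable) -> pd.DataFrame:
    """Per-sample observed richness with depth metadata, sorted by depth."""
    rows = [
        {"sample": s, "depth_m": float(table.metadata.loc[s, "depth_m"]),
         "richness": richness(table.counts[s])}
        for s in table.counts.columns
    ]
    return pd.DataFrame(rows).sort_values("depth_m", ignore_index=True)


def expected_rarefied_richness(counts: np.ndarray, depth: int) -> float:
    """Exact hypergeometric expectation of rarefied richness,
    Σᵢ (1 − C(N−nᵢ, d)/C(N, d)) — the classic rarefaction formula."""
    from scipy.special import gammaln

    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    n_total = int(counts.sum())
    if depth > n_total:
        raise ValueError("depth exceeds sample total")

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    terms = np.where(
        n_total - counts >= depth,
        np.exp(log_comb(n_total - counts, depth) - log_comb(n_total, depth)),
        0.0,
    )
    return float(np.sum(1.0 - terms))


def assign_functional_groups(
    table: OtuTable,
    groups: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Per-sample relative abundance (% of total reads) of each functional
    group; unmatched OTUs pool into ``other``.  The group map must be disjoint
    by taxon — an OTU matching two groups is an error."""
    groups = groups or DEFAULT_FUNCTIONAL_GROUPS
    assignment = {}
    for otu, tax in table.taxonomy.items():
        hits = [g for g, names in groups.items() if taxonomy_matches(tax, names)]
        if len(hits) > 1:
            raise ValueError(f"OTU {otu} matches multiple groups: {hits}")
        assignment[otu] = hits[0] if hits else "other"
    assignment = pd.Series(assignment).reindex(table.counts.index)
    rows = {}
    for sample in table.counts.columns:
        total = table.counts[sample].sum()
        if total == 0:
            log.info("sample %s has zero reads; omitted", sample)
            continue
        by_group = table.counts[sample].groupby(assignment).sum()
        rows[sample] = 100.0 * by_group / total
    out = pd.DataFrame(rows).T.reindex(columns=list(groups) + ["other"]).fillna(0.0)
    out.index.name = "sample"
    return out


def total_sum_scale(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundances summing to 1; zero-total samples are
    flagged in the log and omitted."""
    out = {}
    for sample in counts.columns:
        total = counts[sample].sum()
        if total == 0:
            log.info("sample %s has zero total within restriction; omitted", sample)
            continue
        out[sample] = counts[sample] / total
    return pd.DataFrame(out, index=counts.index)


@dataclass
class ReappearanceResult:
    fraction: float
    n_surface: int          # surface-detected OTUs that vanished through the gap
    n_reappearing: int
    surface_otus: list = field(default_factory=list)
    reappearing_otus: list = field(default_factory=list)


def reappearance_fraction(
    table: OtuTable,
    taxon_filter: tuple[str, ...] | None = None,
    surface_zone: str = "surface",
    gap_zones: tuple[str, ...] = ("oxic", "anoxic"),
    target_zone: str = "OATZ",
    rarefy_depth: int | None = None,
    seed: int | None = 0,
    detection_threshold: int = 1,
) -> ReappearanceResult:
    """Fraction of surface OTUs, undetectable through the gap zones, that are
    detected again in the target zone.

    Detection is ≥ ``detection_threshold`` reads (after optional rarefaction)
    in at least one sample of the zone.  The denominator is the set of OTUs
    detected in the surface zone AND undetected in every gap-zone sample.
    """
    if taxon_filter is not None:
        table = table.restrict_taxa(taxon_filter)
    if rarefy_depth is not None:
        table = rarefy(table, depth=rarefy_depth, seed=seed)

    def detected_in(zone: str) -> pd.Series:
        samples = table.samples_in_zone(zone)
        if not samples:
            return pd.Series(False, index=table.counts.index)
        return (table.counts[samples] >= detection_threshold).any(axis=1)

    surface = detected_in(surface_zone)
    if not surface.any():
        raise ValueError(f"no OTUs detected in zone {surface_zone!r}")
    gap = pd.Series(False, index=table.counts.index)
    for z in gap_zones:
        gap |= detected_in(z)
    target = detected_in(target_zone)
    candidates = surface & ~gap
    n_surface = int(candidates.sum())
    if n_surface == 0:
        return ReappearanceResult(float("nan"), 0, 0)
    reappearing = candidates & target
    return ReappearanceResult(
        float(reappearing.sum() / n_surface),
        n_surface,
        int(reappearing.sum()),
        list(candidates.index[candidates]),
        list(reappearing.index[reappearing]),
    )
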