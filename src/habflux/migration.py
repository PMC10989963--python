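"""Migrant calling across habitat pairs.

Three-step procedure per unordered habitat pair:

1. screen taxa present in more than half of the samples on each side
   (shared, prevalent taxa that can plausibly live in both habitats);
2. check that the niche breadth of those shared taxa differs between the
   two habitats (Wilcoxon signed-rank, paired by taxon) - the premise that
   environments select differently, so abundances should normally differ;
3. call a screened taxon a potential migrant when its relative abundance
   does NOT differ significantly between the two sides (two-sided Wilcoxon
   rank-sum): similar abundance despite differing niches is read as recent
   exchange of individuals.

Note the inversion: non-significance declares migration, so raising alpha
makes the rule stricter and multiple-testing correction would *inflate*
migrant calls. No correction is applied by default; effect sizes are
reported alongside p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import FeatureTable, GuildRecord, SampleMetadata, TaxonomyRecord
from .diversity import levins_breadth

logger = logging.getLogger(__name__)

EXACT_MAX_N = 25
MIN_SHARED_TAXA = 6


@dataclass(frozen=True)
class HabitatPair:
    """An unordered habitat pair (a < b lexically) with its sample lists."""

    habitat_a: str
    habitat_b: str
    samples_a: tuple[str, ...]
    samples_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.habitat_a == self.habitat_b:
            raise ValueError("a habitat pair needs two distinct habitats")
        if self.habitat_a > self.habitat_b:
            raise ValueError("habitats must be ordered: habitat_a < habitat_b")

    @property
    def label(self) -> str:
        return f"{self.habitat_a}-{self.habitat_b}"


@dataclass
class MigrationCall:
    """Per-taxon migrant decision for one habitat pair."""

    pair: str
    taxon_id: str
    p_value: float
    mean_rel_a: float
    mean_rel_b: float
    migrant: bool
    breadth_shift_p: float = np.nan

    @property
    def log2_fold(self) -> float:
        """Effect size: log2 ratio of side means (inf-safe via tiny floor)."""
        eps = 1e-12
        return float(np.log2((self.mean_rel_a + eps) / (self.mean_rel_b + eps)))

    @property
    def mean_rel(self) -> float:
        return 0.5 * (self.mean_rel_a + self.mean_rel_b)


def habitat_pairs(metadata: SampleMetadata) -> list[HabitatPair]:
    """All C(H, 2) unordered habitat pairs of the design (10 for 5 habitats)."""
    pairs = []
    for a, b in combinations(sorted(metadata.habitats), 2):
        pairs.append(HabitatPair(
            a, b,
            tuple(metadata.samples_in_habitat(a)),
            tuple(metadata.samples_in_habitat(b)),
        ))
    return pairs


def shared_prevalent_taxa(
    table: FeatureTable,
    metadata: SampleMetadata,
    pair: HabitatPair,
    prevalence: float = 0.5,
    mode: str = "per_side",
) -> list[str]:
    """Taxa present in strictly more than ``prevalence`` of the samples.

    ``mode="per_side"`` (default, the stricter reading) requires the
    threshold within EACH habitat of the pair; ``mode="pooled"`` applies it
    to the pooled samples of both habitats.
    """
    if len(pair.samples_a) < 2 or len(pair.samples_b) < 2:
        raise ValueError("each side of the pair needs >= 2 samples")
    pres_a = table.select_samples(list(pair.samples_a)).counts > 0
    pres_b = table.select_samples(list(pair.samples_b)).counts > 0
    if mode == "per_side":
        keep = (pres_a.mean(axis=1) > prevalence) & (pres_b.mean(axis=1) > prevalence)
    elif mode == "pooled":
        pooled = np.hstack([pres_a, pres_b])
        keep = pooled.mean(axis=1) > prevalence
    else:
        raise ValueError(f"unknown prevalence mode {mode!r}")
    taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    if not taxa:
        warnings.warn(f"no shared prevalent taxa for pair {pair.label}", stacklevel=2)
    return taxa


def breadth_shift_test(
    table: FeatureTable,
    pair: HabitatPair,
    taxa: list[str],
) -> tuple[float, pd.DataFrame]:
    """Wilcoxon signed-rank test of per-taxon Levins B between the two sides.

    Each shared taxon contributes one paired observation (its B in habitat a
    vs habitat b). Returns the pair-level p and the per-taxon B table.
    """
    if len(taxa) < MIN_SHARED_TAXA:
        logger.warning("pair %s: only %d shared taxa (< %d power floor)",
                       pair.label, len(taxa), MIN_SHARED_TAXA)
    sub = table.select_taxa(taxa)
    b_a = levins_breadth(sub, list(pair.samples_a)).reindex(taxa)
    b_b = levins_breadth(sub, list(pair.samples_b)).reindex(taxa)
    frame = pd.DataFrame({"B_a": b_a, "B_b": b_b})
    frame.index.name = "taxon_id"
    diffs = (frame["B_a"] - frame["B_b"]).dropna()
    if len(diffs) == 0 or np.allclose(diffs, 0):
        warnings.warn(f"pair {pair.label}: all niche-breadth differences zero",
                      stacklevel=2)
        return 1.0, frame
    res = stats.wilcoxon(diffs, alternative="two-sided", zero_method="wilcox")
    return float(res.pvalue), frame


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact for small tie-free samples,
    otherwise normal approximation with continuity correction (mid-ranks)."""
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (not has_ties and max(a.size, b.size) <= EXACT_MAX_N) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def call_migrants(
    table: FeatureTable,
    pair: HabitatPair,
    taxa: list[str],
    alpha: float = 0.05,
    correction: str = "none",
    breadth_shift_p: float = np.nan,
) -> list[MigrationCall]:
    """Per-taxon migrant decision: migrant iff abundance p-value >= alpha.

    Relative abundances of each screened taxon are compared across the two
    sides with a two-sided Wilcoxon rank-sum test. ``correction`` is "none"
    (default) or "bh" (Benjamini-Hochberg; note the inversion hazard - a
    correction raises p-values and therefore *adds* migrant calls).
    """
    if len(pair.samples_a) < 2 or len(pair.samples_b) < 2:
        raise ValueError("each side of the pair needs >= 2 samples")
    rel = pd.DataFrame(table.relative_abundance(),
                       index=table.taxon_ids, columns=table.sample_ids)
    p_values = np.empty(len(taxa))
    means_a = np.empty(len(taxa))
    means_b = np.empty(len(taxa))
    for i, taxon in enumerate(taxa):
        a = rel.loc[taxon, list(pair.samples_a)].to_numpy()
        b = rel.loc[taxon, list(pair.samples_b)].to_numpy()
        p_values[i] = _rank_sum_p(a, b)
        means_a[i], means_b[i] = a.mean(), b.mean()
    if correction == "bh":
        adjusted = _benjamini_hochberg(p_values)
    elif correction == "none":
        adjusted = p_values
    else:
        raise ValueError(f"unknown correction {correction!r}")
    calls = []
    for i, taxon in enumerate(taxa):
        calls.append(MigrationCall(
            pair=pair.label, taxon_id=taxon, p_value=float(adjusted[i]),
            mean_rel_a=float(means_a[i]), mean_rel_b=float(means_b[i]),
            migrant=bool(adjusted[i] >= alpha), breadth_shift_p=breadth_shift_p,
        ))
    return calls


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def summarize_migrants_by_supergroup(
    calls: list[MigrationCall],
    taxonomy: dict[str, TaxonomyRecord],
) -> pd.DataFrame:
    """Migrant counts and summed mean relative abundance per supergroup, per pair.

    Taxa without a taxonomy record are binned as "unassigned".
    """
    rows = []
    for call in calls:
        if not call.migrant:
            continue
        record = taxonomy.get(call.taxon_id)
        supergroup = record.supergroup if record is not None else "unassigned"
        rows.append({"pair": call.pair, "supergroup": supergroup,
                     "mean_rel": call.mean_rel})
    if not rows:
        return pd.DataFrame(columns=["pair", "supergroup", "n_taxa", "summed_mean_rel"])
    frame = pd.DataFrame(rows)
    out = (frame.groupby(["pair", "supergroup"])
           .agg(n_taxa=("mean_rel", "size"), summed_mean_rel=("mean_rel", "sum"))
           .reset_index())
    return out


def summarize_migrant_guilds(
    calls: list[MigrationCall],
    taxonomy: dict[str, TaxonomyRecord],
    guild_db: dict[str, GuildRecord],
) -> pd.DataFrame:
    """Summed mean relative abundance of migrant fungi per trophic mode, per pair.

    Fungal migrants are identified by lineage (Opisthokonta;Fungi); the guild
    lookup uses the lowest assigned rank. Fungi absent from the guild table
    are binned "unassigned", never dropped.
    """
    if not guild_db:
        raise ValueError("guild database is empty")
    rows = []
    for call in calls:
        if not call.migrant:
            continue
        record = taxonomy.get(call.taxon_id)
        if record is None or not record.is_fungus:
            continue
        guild = guild_db.get(record.lowest_assigned)
        mode = guild.trophic_mode if guild is not None else "unassigned"
        rows.append({"pair": call.pair, "trophic_mode": mode, "mean_rel": call.mean_rel})
    if not rows:
        return pd.DataFrame(columns=["pair", "trophic_mode", "summed_mean_rel"])
    frame = pd.DataFrame(rows)
    return (frame.groupby(["pair", "trophic_mode"])
            .agg(summed_mean_rel=("mean_rel", "sum"))
            .reset_index())
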