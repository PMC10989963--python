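"""Synthetic multi-habitat metacommunities with known ground truth.

The generator emulates the survey design the package targets: six parks x
five habitats x three replicates (90 samples per amplicon region), habitat-
structured taxon pools with partial overlap, a common rarefied depth, known
source-mixing proportions, and planted migrants - so that every pipeline
stage has an oracle.

Pools are log-normal rank-abundance curves (sigma 1.5 by default, the skewed
shape amplicon tables show). The park effect is a multiplicative log-normal
perturbation (sigma 0.3 by default), deliberately the smallest variance
component of the design. Neutral dynamics are available per habitat through
the Sloan marginal (independent per-taxon Beta draws).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .core_io import (
    HABITATS,
    SUPERGROUPS,
    FeatureTable,
    GuildRecord,
    PhyloTree,
    SampleMetadata,
    TaxonomyRecord,
)
from .migration import HabitatPair
from .source_tracking import PSEUDOCOUNT, SourceProfile

UNKNOWN = "unknown"


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic metacommunity scenario."""

    n_habitats: int = 5
    n_parks: int = 6
    n_replicates: int = 3
    n_taxa: int = 2000
    depth: int = 86_235
    habitat_overlap: float = 0.3
    mixing_matrix: dict[str, dict[str, float]] | None = None
    n_planted_migrants: int = 0
    effect_fold: float = 1.0
    neutral: bool = False
    neutral_N: int = 1000
    neutral_m: float = 0.1
    pool_sigma: float = 1.5
    park_sigma: float = 0.3
    block_weights: dict[str, float] | None = None
    region: str = "V4"
    fungal_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.habitat_overlap <= 1.0:
            raise ValueError("habitat_overlap must be in [0, 1]")
        if self.n_habitats < 1 or self.n_habitats > len(HABITATS):
            raise ValueError(f"n_habitats must be in [1, {len(HABITATS)}]")
        if self.mixing_matrix is not None:
            habitats = set(self.habitats)
            for row_hab, row in self.mixing_matrix.items():
                if row_hab not in habitats:
                    raise ValueError(f"mixing row for unknown habitat {row_hab!r}")
                bad = set(row) - habitats - {UNKNOWN}
                if bad:
                    raise ValueError(f"mixing row {row_hab!r} references unknown habitat(s) {bad}")
                if not np.isclose(sum(row.values()), 1.0, atol=1e-9):
                    raise ValueError(f"mixing row {row_hab!r} must sum to 1")

    @property
    def habitats(self) -> list[str]:
        return sorted(HABITATS[: self.n_habitats])

    def full_mixing(self) -> pd.DataFrame:
        """Mixing matrix as a dense frame (identity rows where unspecified)."""
        habitats = self.habitats
        cols = habitats + [UNKNOWN]
        rows = {}
        for h in habitats:
            row = {c: 0.0 for c in cols}
            if self.mixing_matrix and h in self.mixing_matrix:
                row.update(self.mixing_matrix[h])
            else:
                row[h] = 1.0
            rows[h] = row
        return pd.DataFrame(rows).T[cols]


@dataclass
class GroundTruth:
    """What the generator actually did, for use as a test oracle."""

    mixing_matrix: pd.DataFrame
    pool_members: dict[str, list[str]]
    unknown_pool: list[str]
    planted_migrants: dict[str, list[str]] = field(default_factory=dict)
    supergroup_of: dict[str, str] = field(default_factory=dict)
    guild_of: dict[str, str] = field(default_factory=dict)


def _lognormal_pool(rng, members: np.ndarray, n_taxa: int, sigma: float) -> np.ndarray:
    pool = np.zeros(n_taxa)
    pool[members] = rng.lognormal(0.0, sigma, size=members.size)
    return pool / pool.sum()


def _assign_pools(config: ScenarioConfig, rng) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Split taxa into a shared core plus one unique block per habitat
    (and one for the hidden 'unknown' pool when the mixing matrix uses it)."""
    habitats = config.habitats
    uses_unknown = float(config.full_mixing()[UNKNOWN].sum()) > 0
    n_blocks = len(habitats) + (1 if uses_unknown else 0)
    n_core = int(round(config.n_taxa * config.habitat_overlap))
    rest = config.n_taxa - n_core
    weights = np.array([
        (config.block_weights or {}).get(h, 1.0) for h in habitats
    ] + ([1.0] if uses_unknown else []))
    sizes = np.floor(rest * weights / weights.sum()).astype(int)
    sizes[-1] += rest - sizes.sum()
    order = rng.permutation(config.n_taxa)
    core = order[:n_core]
    members = {}
    start = n_core
    for h, size in zip(habitats, sizes[: len(habitats)]):
        members[h] = np.sort(np.concatenate([core, order[start: start + size]]))
        start += size
    unknown_members = (np.sort(np.concatenate([core, order[start:]]))
                       if uses_unknown else np.array([], dtype=int))
    return members, unknown_members


def _random_tree(taxon_ids: list[str], rng) -> PhyloTree:
    """Random bifurcating tree over the taxa, exponential branch lengths."""
    nodes = []
    for t in taxon_ids:
        node = skbio.TreeNode(name=t)
        node.length = float(rng.exponential(1.0))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        parent = skbio.TreeNode(children=[nodes[i], nodes[j]])
        parent.length = float(rng.exponential(1.0))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return PhyloTree(root)


def _make_taxonomy(taxon_ids: list[str], fungal_fraction: float, rng):
    """Synthetic PR2-style lineages; about half Opisthokonta, a configurable
    fraction of which are fungi with genus-level names."""
    taxonomy: dict[str, TaxonomyRecord] = {}
    guilds: dict[str, GuildRecord] = {}
    modes = ("pathotroph", "saprotroph", "symbiotroph")
    sg_weights = np.array([0.5] + [0.5 / (len(SUPERGROUPS) - 1)] * (len(SUPERGROUPS) - 1))
    for i, taxon in enumerate(taxon_ids):
        supergroup = rng.choice(SUPERGROUPS, p=sg_weights)
        if supergroup == "Opisthokonta" and rng.random() < fungal_fraction:
            genus = f"FungalGenus_{i}"
            lineage = ("Opisthokonta", "Fungi", "Dikarya", f"Phylum_{i % 7}",
                       f"Class_{i % 11}", f"Order_{i % 13}", f"Family_{i % 17}", genus)
            mode = modes[int(rng.integers(0, len(modes)))]
            guilds[genus] = GuildRecord(genus, mode)
        else:
            genus = f"Genus_{i}"
            lineage = (str(supergroup), f"Division_{i % 5}", f"Subdivision_{i % 7}",
                       f"Phylum_{i % 7}", f"Class_{i % 11}", f"Order_{i % 13}",
                       f"Family_{i % 17}", genus)
        taxonomy[taxon] = TaxonomyRecord(taxon, lineage)
    return taxonomy, guilds


def generate_metacommunity(config: ScenarioConfig):
    """Generate one scenario.

    Returns (FeatureTable, SampleMetadata, taxonomy, guild_db, PhyloTree,
    GroundTruth). Fully determined by ``config.seed``: every sample's counts
    are one multinomial draw at ``depth`` from its habitat's mixed pool after
    a park-level log-normal perturbation.
    """
    rng = np.random.default_rng(config.seed)
    habitats = config.habitats
    taxon_ids = [f"zOTU_{i + 1}" for i in range(config.n_taxa)]
    members, unknown_members = _assign_pools(config, rng)
    pools = {h: _lognormal_pool(rng, members[h], config.n_taxa, config.pool_sigma)
             for h in habitats}
    unknown_pool = (_lognormal_pool(rng, unknown_members, config.n_taxa, config.pool_sigma)
                    if unknown_members.size else np.zeros(config.n_taxa))
    mixing = config.full_mixing()

    parks = [f"P{i + 1}" for i in range(config.n_parks)]
    park_factor = {p: rng.lognormal(0.0, config.park_sigma, size=config.n_taxa)
                   for p in parks}

    sample_ids, meta_rows, columns = [], [], []
    for park in parks:
        for habitat in habitats:
            comp = np.zeros(config.n_taxa)
            for src in habitats:
                comp += mixing.loc[habitat, src] * pools[src]
            comp += mixing.loc[habitat, UNKNOWN] * unknown_pool
            comp = comp * park_factor[park]
            comp /= comp.sum()
            for rep in range(1, config.n_replicates + 1):
                sample = f"{park}_{habitat}_{rep}"
                if config.neutral:
                    a = config.neutral_N * config.neutral_m * comp
                    b = np.maximum(config.neutral_N * config.neutral_m * (1 - comp), 1e-12)
                    props = np.where(comp > 0, rng.beta(np.maximum(a, 1e-12), b), 0.0)
                    total = props.sum()
                    props = props / total if total > 0 else comp
                    counts = rng.multinomial(config.depth, props)
                else:
                    counts = rng.multinomial(config.depth, comp)
                sample_ids.append(sample)
                columns.append(counts)
                meta_rows.append({"sample_id": sample, "habitat": habitat,
                                  "park": park, "replicate": rep,
                                  "region": config.region})

    table = FeatureTable(taxon_ids, sample_ids, np.column_stack(columns))
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    taxonomy, guild_db = _make_taxonomy(taxon_ids, config.fungal_fraction, rng)
    tree = _random_tree(taxon_ids, rng)
    truth = GroundTruth(
        mixing_matrix=mixing,
        pool_members={h: [taxon_ids[i] for i in members[h]] for h in habitats},
        unknown_pool=[taxon_ids[i] for i in unknown_members],
        supergroup_of={t: r.supergroup for t, r in taxonomy.items()},
        guild_of={k: g.trophic_mode for k, g in guild_db.items()},
    )

    if config.n_planted_migrants > 0 and len(habitats) >= 2:
        for pair in _all_pairs(metadata):
            table, truth = plant_migrants(
                table, truth, pair, config.n_planted_migrants,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
    return table, metadata, taxonomy, guild_db, tree, truth


def _all_pairs(metadata: SampleMetadata) -> list[HabitatPair]:
    from .migration import habitat_pairs

    return habitat_pairs(metadata)


def plant_migrants(
    table: FeatureTable,
    truth: GroundTruth,
    pair: HabitatPair,
    n: int,
    seed: int = 0,
) -> tuple[FeatureTable, GroundTruth]:
    """Equalize the expected relative abundance of ``n`` shared taxa across a pair.

    Candidate taxa belong to both habitats' pools. For every sample of the
    pair, the selected taxa's proportions are set to the pooled pair mean,
    the rest rescaled, and the column redrawn at its original depth. The
    selected ids are recorded in the ground truth.
    """
    if n == 0:
        return table, truth
    rng = np.random.default_rng(seed)
    shared = sorted(set(truth.pool_members[pair.habitat_a])
                    & set(truth.pool_members[pair.habitat_b]))
    if n > len(shared):
        raise ValueError(f"requested {n} migrants but only {len(shared)} shared taxa")
    chosen = sorted(rng.choice(shared, size=n, replace=False).tolist())
    idx = np.array([table.taxon_ids.index(t) for t in chosen])
    pair_samples = list(pair.samples_a) + list(pair.samples_b)
    cols = [table.sample_ids.index(s) for s in pair_samples]
    counts = table.counts.copy()
    rel = counts[:, cols] / counts[:, cols].sum(axis=0, keepdims=True)
    target = rel[idx].mean(axis=1)  # pooled mean proportion of each planted taxon
    for c in cols:
        depth = counts[:, c].sum()
        comp = counts[:, c] / depth
        other_mass = 1.0 - comp[idx].sum()
        new_comp = comp.copy()
        scale = (1.0 - target.sum()) / other_mass if other_mass > 0 else 0.0
        new_comp *= scale
        new_comp[idx] = target
        new_comp = np.maximum(new_comp, 0)
        new_comp /= new_comp.sum()
        counts[:, c] = rng.multinomial(depth, new_comp)
    new_table = FeatureTable(list(table.taxon_ids), list(table.sample_ids), counts)
    planted = dict(truth.planted_migrants)
    planted[pair.label] = chosen
    new_truth = GroundTruth(
        mixing_matrix=truth.mixing_matrix,
        pool_members=truth.pool_members,
        unknown_pool=truth.unknown_pool,
        planted_migrants=planted,
        supergroup_of=truth.supergroup_of,
        guild_of=truth.guild_of,
    )
    return new_table, new_truth


def simulate_sloan(
    N: int,
    m: float,
    source_abundances: np.ndarray,
    n_samples: int,
    seed: int = 0,
) -> FeatureTable:
    """Sample communities from the Sloan neutral stationary distribution.

    Each sample draws per-taxon proportions from Beta(N*m*p, N*m*(1-p)),
    normalizes across taxa, and takes one multinomial of N reads.
    """
    if N <= 0 or m <= 0:
        raise ValueError("N and m must be positive")
    p = np.asarray(source_abundances, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9) or np.all(p == 0):
        raise ValueError("source_abundances must be a simplex")
    rng = np.random.default_rng(seed)
    a = N * m * p
    b = np.maximum(N * m * (1.0 - p), 1e-12)
    cols = []
    for _ in range(n_samples):
        props = np.where(p > 0, rng.beta(np.maximum(a, 1e-300), b), 0.0)
        total = props.sum()
        props = props / total if total > 0 else p
        cols.append(rng.multinomial(N, props))
    taxa = [f"zOTU_{i + 1}" for i in range(p.size)]
    samples = [f"S{i + 1}" for i in range(n_samples)]
    return FeatureTable(taxa, samples, np.column_stack(cols))


def logseries_abundances(n_taxa: int, seed: int = 0, theta: float = 0.999) -> np.ndarray:
    """A log-series relative-abundance vector (classic neutral metacommunity shape)."""
    rng = np.random.default_rng(seed)
    k = rng.logseries(theta, size=n_taxa).astype(float)
    return k / k.sum()


def simulate_sink_mixture(
    n_taxa: int = 500,
    depth: int = 50_000,
    mixing: tuple[float, ...] = (0.45, 0.25, 0.20, 0.10),
    overlap: float = 0.3,
    sigma: float = 1.5,
    seed: int = 0,
):
    """One sink drawn from known habitat sources plus a hidden unknown source.

    ``mixing`` lists the true proportions; the last entry belongs to a hidden
    pool whose profile is never exposed. Pools follow the habitat-structured
    design: a shared core (``overlap`` fraction of taxa) plus one unique
    block per source. Returns (sink_counts, profiles, true_mixing_series).
    """
    if not np.isclose(sum(mixing), 1.0, atol=1e-9):
        raise ValueError("mixing must sum to 1")
    rng = np.random.default_rng(seed)
    n_sources = len(mixing)  # last one hidden
    n_core = int(round(n_taxa * overlap))
    rest = n_taxa - n_core
    block = rest // n_sources
    pools = []
    for k in range(n_sources):
        extra = rest - block * n_sources if k == n_sources - 1 else 0
        own = np.arange(n_core + k * block, n_core + (k + 1) * block + extra)
        memb = np.concatenate([np.arange(n_core), own])
        pools.append(_lognormal_pool(rng, memb, n_taxa, sigma))
    comp = sum(w * pool for w, pool in zip(mixing, pools))
    sink = rng.multinomial(depth, comp)
    profiles = []
    for k in range(n_sources - 1):
        g = pools[k] + PSEUDOCOUNT
        profiles.append(SourceProfile(f"source_{k + 1}", g / g.sum()))
    names = [p.habitat for p in profiles] + [UNKNOWN]
    return sink, profiles, pd.Series(mixing, index=names)


def simulate_migration_pair(
    n_migrants: int = 50,
    n_shifted: int = 450,
    fold: float = 4.0,
    n_per_side: int = 18,
    depth: int = 20_000,
    sigma: float = 1.5,
    seed: int = 0,
):
    """A two-habitat table with planted migrants and fold-shifted taxa.

    ``n_migrants`` taxa have identical expected relative abundance on both
    sides; ``n_shifted`` taxa differ by ``fold`` (half up, half down, with
    the shifted block's total mass preserved so the migrants stay equal-mean
    after normalization). Returns (table, metadata, pair, migrant_ids,
    shifted_ids).
    """
    rng = np.random.default_rng(seed)
    n_taxa = n_migrants + n_shifted
    base = rng.lognormal(0.0, sigma, size=n_taxa)
    base /= base.sum()
    comp_a = base
    comp_b = base.copy()
    mig_idx = np.arange(n_migrants)
    shift_idx = np.arange(n_migrants, n_taxa)
    if n_shifted:
        factors = np.where(rng.random(n_shifted) < 0.5, fold, 1.0 / fold)
        shifted = base[shift_idx] * factors
        shifted *= base[shift_idx].sum() / shifted.sum()  # preserve block mass
        comp_b[shift_idx] = shifted
    comp_b /= comp_b.sum()
    taxa = [f"zOTU_{i + 1}" for i in range(n_taxa)]
    sample_ids, cols, rows = [], [], []
    for side, comp, habitat in (("a", comp_a, "soil"), ("b", comp_b, "water")):
        for i in range(n_per_side):
            sample = f"{habitat}_{i + 1}"
            sample_ids.append(sample)
            cols.append(rng.multinomial(depth, comp))
            rows.append({"sample_id": sample, "habitat": habitat,
                         "park": f"P{i % 6 + 1}", "replicate": i % 3 + 1,
                         "region": "V4"})
    table = FeatureTable(taxa, sample_ids, np.column_stack(cols))
    metadata = SampleMetadata(pd.DataFrame(rows))
    pair = HabitatPair("soil", "water",
                       tuple(metadata.samples_in_habitat("soil")),
                       tuple(metadata.samples_in_habitat("water")))
    migrant_ids = [taxa[i] for i in mig_idx]
    shifted_ids = [taxa[i] for i in shift_idx]
    return table, metadata, pair, migrant_ids, shifted_ids
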