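"""Table-level preprocessing: low-count taxon removal and rarefaction.

Order of operations matters: taxa are filtered on the raw table first, then
samples are rarefied to a common depth. Reversing the order changes results
because rarefaction can push borderline taxa below the filter threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .core_io import FeatureTable

#: Minimum total reads for a taxon to be retained (rare zOTUs below this are
#: treated as likely sequencing errors).
DEFAULT_MIN_TOTAL = 10

#: Common per-sample depth the survey normalizes to.
DEFAULT_DEPTH = 86_235


@dataclass
class PreprocessReport:
    """What preprocessing did: taxon counts, target depth, dropped samples."""

    n_taxa_in: int
    n_taxa_out: int
    depth_target: int
    dropped_samples: list[str]
    seed: int

    def __post_init__(self) -> None:
        if self.n_taxa_out > self.n_taxa_in:
            raise ValueError("n_taxa_out cannot exceed n_taxa_in")
        if self.depth_target <= 0:
            raise ValueError("depth_target must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def filter_low_count_taxa(table: FeatureTable, min_total: int = DEFAULT_MIN_TOTAL) -> FeatureTable:
    """Drop taxa whose total count across all samples is below ``min_total``.

    The sample set is unchanged. An empty result is a warning, not an error.
    """
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    totals = table.taxon_totals()
    keep = totals >= min_total
    if not keep.any():
        warnings.warn("no taxa pass the low-count filter", stacklevel=2)
    kept = [t for t, k in zip(table.taxon_ids, keep) if k]
    return FeatureTable(kept, list(table.sample_ids), table.counts[keep, :])


def rarefy(
    table: FeatureTable,
    depth: int = DEFAULT_DEPTH,
    seed: int = 0,
) -> tuple[FeatureTable, PreprocessReport]:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    One multivariate-hypergeometric draw per sample, deterministic given
    ``seed``. Samples with fewer than ``depth`` reads are dropped and listed
    in the report. Taxa that end up all-zero are retained for dimensional
    stability (richness ignores them by construction).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.sample_totals()
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"all samples have fewer than {depth} reads")
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    rng = np.random.default_rng(seed)
    cols = []
    kept_samples = []
    for j, (sample, ok) in enumerate(zip(table.sample_ids, keep)):
        if not ok:
            continue
        col = table.counts[:, j]
        if col.sum() == depth:
            cols.append(col)
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
        kept_samples.append(sample)
    out = FeatureTable(list(table.taxon_ids), kept_samples, np.column_stack(cols))
    report = PreprocessReport(
        n_taxa_in=len(table.taxon_ids),
        n_taxa_out=len(out.taxon_ids),
        depth_target=depth,
        dropped_samples=dropped,
        seed=seed,
    )
    return out, report
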