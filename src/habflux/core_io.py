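"""Domain types and tab-separated / newick readers and writers.

Feature tables are strictly taxa-as-rows (the amplicon convention); a
transposed table is not auto-detected. All text I/O is UTF-8.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger(__name__)

#: The five habitats of the urban-park sampling design. Extensible per call
#: for synthetic scenarios via the ``habitats`` argument of read_metadata.
HABITATS = ("moss", "soil", "tree_hole", "water", "sediment")

#: 18S rRNA hypervariable regions used by the survey design.
REGIONS = ("V4", "V9")

#: PR2-style taxonomy depth: 8 ranks from supergroup down to genus.
N_RANKS = 8

SUPERGROUPS = (
    "Opisthokonta", "Alveolata", "Stramenopiles", "Rhizaria", "Amoebozoa",
    "Archaeplastida", "Excavata", "Hacrobia",
)

TROPHIC_MODES = ("pathotroph", "saprotroph", "symbiotroph", "mixed", "unassigned")


class FormatError(ValueError):
    """Raised when an input file violates a format contract."""


def normalize_habitat(token: str) -> str:
    """Normalize a habitat label: case-insensitive, spaces/dashes -> underscore."""
    return "_".join(str(token).strip().lower().replace("-", " ").split())


@dataclass
class FeatureTable:
    """Integer count matrix, taxa (rows) x samples (columns).

    The universal currency of every analysis stage. Invariants: unique ids,
    non-negative integral counts, dimensions matching the id lists.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise FormatError("duplicate taxon ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if counts.dtype.kind == "f":
            if not np.all(np.isfinite(counts)) or np.any(counts != np.round(counts)):
                raise FormatError("counts must be integral")
            counts = counts.astype(np.int64)
        elif counts.dtype.kind not in "iu":
            raise FormatError("counts must be an integer array")
        if np.any(counts < 0):
            raise FormatError("counts must be non-negative")
        self.counts = counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def taxon_index(self, taxon_id: str) -> int:
        return self.taxon_ids.index(taxon_id)

    def sample_totals(self) -> np.ndarray:
        """Per-sample read totals (column sums)."""
        return self.counts.sum(axis=0)

    def taxon_totals(self) -> np.ndarray:
        """Per-taxon read totals (row sums)."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Column-normalized float matrix; all-zero columns stay zero."""
        totals = self.counts.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts / totals
        return np.where(totals > 0, rel, 0.0)

    def select_samples(self, sample_ids: list[str]) -> "FeatureTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return FeatureTable(list(self.taxon_ids), list(sample_ids), self.counts[:, idx])

    def select_taxa(self, taxon_ids: list[str]) -> "FeatureTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return FeatureTable(list(taxon_ids), list(self.sample_ids), self.counts[idx, :])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)


@dataclass
class SampleMetadata:
    """Per-sample design factors: habitat, park, replicate, amplicon region."""

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "habitat", "park", "replicate", "region")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        if self.frame["sample_id"].duplicated().any():
            dups = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise FormatError(f"duplicate sample ids in metadata: {sorted(set(dups))}")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def habitats(self) -> list[str]:
        return sorted(self.frame["habitat"].unique())

    def samples_in_habitat(self, habitat: str) -> list[str]:
        habitat = normalize_habitat(habitat)
        sel = self.frame["habitat"] == habitat
        return list(self.frame.loc[sel, "sample_id"])

    def subset(self, sample_ids: list[str]) -> "SampleMetadata":
        keep = self.frame["sample_id"].isin(sample_ids)
        return SampleMetadata(self.frame.loc[keep].copy())


@dataclass
class TaxonomyRecord:
    """A PR2-style 8-rank lineage for one taxon, supergroup first.

    Slots below the assigned depth are empty strings. The supergroup slot is
    either a known supergroup or the literal token "unassigned".
    """

    taxon_id: str
    lineage: tuple[str, ...]

    def __post_init__(self) -> None:
        ranks = tuple(str(r).strip() for r in self.lineage)
        if len(ranks) > N_RANKS:
            raise FormatError(
                f"{self.taxon_id}: lineage has {len(ranks)} ranks (max {N_RANKS})"
            )
        ranks = ranks + ("",) * (N_RANKS - len(ranks))
        if ranks[0] not in SUPERGROUPS and ranks[0] != "unassigned":
            raise FormatError(
                f"{self.taxon_id}: unknown supergroup {ranks[0]!r}; "
                f"expected one of {SUPERGROUPS} or 'unassigned'"
            )
        self.lineage = ranks

    @property
    def supergroup(self) -> str:
        return self.lineage[0]

    @property
    def is_fungus(self) -> bool:
        return self.lineage[0] == "Opisthokonta" and self.lineage[1] == "Fungi"

    @property
    def lowest_assigned(self) -> str:
        for rank in reversed(self.lineage):
            if rank:
                return rank
        return "unassigned"


@dataclass
class GuildRecord:
    """FUNGuild-style trophic mode for one taxon key (genus or lowest rank)."""

    taxon_key: str
    trophic_mode: str

    def __post_init__(self) -> None:
        mode = str(self.trophic_mode).strip().lower()
        if mode not in TROPHIC_MODES:
            raise FormatError(
                f"{self.taxon_key}: unknown trophic mode {mode!r}; "
                f"expected one of {TROPHIC_MODES}"
            )
        self.trophic_mode = mode


@dataclass
class PhyloTree:
    """A rooted tree with unique tip labels and non-negative branch lengths."""

    tree: skbio.TreeNode
    tip_names: set[str] = field(init=False)

    def __post_init__(self) -> None:
        names = [t.name for t in self.tree.tips()]
        if len(set(names)) != len(names):
            raise FormatError("duplicate tip labels in tree")
        n_missing = 0
        for node in self.tree.traverse(include_self=True):
            if node.length is None:
                node.length = 0.0
                if not node.is_root():
                    n_missing += 1
            elif node.length < 0:
                raise FormatError(f"negative branch length at {node.name!r}")
        if n_missing:
            logger.warning("%d missing branch lengths defaulted to 0", n_missing)
        self.tip_names = set(names)

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.tree.traverse(include_self=False))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_feature_table(path) -> FeatureTable:
    """Read a tab-separated count table: first column taxon ids, header samples."""
    # pandas mangles duplicate header names (s1, s1.1), so check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if len(set(header)) != len(header) or df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate taxon or sample ids")
    try:
        counts = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    if np.any(counts != np.round(counts)) or np.any(counts < 0):
        raise FormatError(f"{path}: cells must be non-negative integers")
    return FeatureTable(list(df.index), list(df.columns), counts.astype(np.int64))


def write_feature_table(table: FeatureTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path, habitats=HABITATS, regions=REGIONS) -> SampleMetadata:
    """Read the sample metadata TSV and validate closed vocabularies.

    Habitat strings are normalized (case- and space-insensitive) before
    validation, so "Tree hole" and "tree_hole" are the same habitat.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    return _validate_metadata(df, habitats, regions)


def _validate_metadata(df: pd.DataFrame, habitats=HABITATS, regions=REGIONS) -> SampleMetadata:
    df = df.copy()
    missing = [c for c in SampleMetadata.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing columns: {missing}")
    allowed = {normalize_habitat(h) for h in habitats}
    df["habitat"] = df["habitat"].map(normalize_habitat)
    bad = sorted(set(df["habitat"]) - allowed)
    if bad:
        raise FormatError(f"unknown habitat token(s): {bad}; allowed: {sorted(allowed)}")
    bad_region = sorted(set(df["region"].astype(str)) - set(regions))
    if bad_region:
        raise FormatError(f"unknown region token(s): {bad_region}; allowed: {list(regions)}")
    df["replicate"] = df["replicate"].astype(int)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.frame.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> dict[str, TaxonomyRecord]:
    """Read a two-column TSV (taxon_id, semicolon-delimited lineage)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected columns taxon_id, lineage")
    records: dict[str, TaxonomyRecord] = {}
    for taxon_id, lineage in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if taxon_id in records:
            raise FormatError(f"{path}: duplicate taxon id {taxon_id!r}")
        records[taxon_id] = TaxonomyRecord(taxon_id, tuple(lineage.split(";")))
    return records


def write_taxonomy(records: dict[str, TaxonomyRecord], path) -> None:
    rows = [
        {"taxon_id": r.taxon_id, "lineage": ";".join(r.lineage).rstrip(";")}
        for r in records.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_guild_db(path) -> dict[str, GuildRecord]:
    """Read a two-column TSV (taxon_key, trophic_mode)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected columns taxon_key, trophic_mode")
    records: dict[str, GuildRecord] = {}
    for key, mode in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if key in records:
            raise FormatError(f"{path}: duplicate taxon key {key!r}")
        records[key] = GuildRecord(key, mode)
    return records


def write_guild_db(records: dict[str, GuildRecord], path) -> None:
    rows = [{"taxon_key": r.taxon_key, "trophic_mode": r.trophic_mode} for r in records.values()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_newick(path) -> PhyloTree:
    """Read a standard newick tree; parse errors carry the character offset."""
    try:
        tree = skbio.read(str(path), format="newick", into=skbio.TreeNode)
    except Exception as exc:
        offset = _newick_error_offset(path)
        raise FormatError(f"{path}: unparseable newick near character {offset}: {exc}") from exc
    return PhyloTree(tree)


def _newick_error_offset(path) -> int:
    """Best-effort character offset of the first structural newick error."""
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return i
        elif ch == ";":
            if depth != 0:
                return i
    return len(text)


def write_newick(tree: PhyloTree, path) -> None:
    tree.tree.write(str(path), format="newick")


def check_consistency(table: FeatureTable, metadata: SampleMetadata) -> list[str]:
    """Require metadata for every table sample; flag metadata-only samples.

    Returns the (possibly empty) list of metadata samples absent from the
    table, after raising if any table sample lacks metadata.
    """
    meta_ids = set(metadata.sample_ids)
    orphans = [s for s in table.sample_ids if s not in meta_ids]
    if orphans:
        raise FormatError(f"samples missing from metadata: {orphans}")
    table_ids = set(table.sample_ids)
    extra = [s for s in metadata.sample_ids if s not in table_ids]
    if extra:
        warnings.warn(f"metadata samples absent from table: {extra}", stacklevel=2)
    return extra
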