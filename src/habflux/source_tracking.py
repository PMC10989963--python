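"""FEAST-style expectation-maximization microbial source tracking.

Each sink sample is modeled as a multinomial draw from a mixture of source
habitat profiles plus an unknown source:

    x ~ Multinomial(n, sum_k m_k * gamma_k + m_u * gamma_u)

E-step: r_jk = m_k gamma_kj / sum_k' m_k' gamma_k'j
M-step: m_k = sum_j x_j r_jk / sum_j x_j ; gamma_uj propto x_j r_j,unknown

The EM log-likelihood is non-decreasing every iteration. With a free unknown
profile the likelihood has a flat ridge (any down-scaling of the known
weights can be absorbed by the unknown), so by default the final mixing
proportions are resolved by a minimal-unknown convention: a non-negative
least-squares projection of the sink composition onto the known profiles,
with the unknown taking only the remainder. Set resolve_unknown="em" for
the raw EM point. See docs/methods.md for the identifiability discussion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .core_io import FeatureTable, SampleMetadata

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 1e-10
UNKNOWN = "unknown"


@dataclass
class SourceProfile:
    """A source habitat's relative-abundance profile over the taxon space."""

    habitat: str
    gamma: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        if np.any(g < 0):
            raise ValueError("profile entries must be >= 0")
        total = g.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"profile must sum to 1, got {total}")
        if np.any(g == 0):
            raise ValueError("profile must be strictly positive (apply pseudocount)")
        self.gamma = g


@dataclass
class SourceMixture:
    """Estimated mixing proportions of one sink over named sources + unknown."""

    sink_sample: str
    proportions: pd.Series  # index: source habitats (+ "unknown"); sums to 1
    ll_trace: list[float] = field(repr=False)
    n_iter: int = 0
    converged: bool = True
    em_proportions: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        p = self.proportions
        if np.any(p.to_numpy() < -1e-12):
            raise ValueError("proportions must be >= 0")
        if not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError(f"proportions must sum to 1, got {p.sum()}")
        diffs = np.diff(self.ll_trace)
        if diffs.size and np.any(diffs < -1e-9 * np.abs(np.array(self.ll_trace[:-1]))):
            raise ValueError("EM log-likelihood trace must be non-decreasing")


def build_source_profiles(
    table: FeatureTable,
    metadata: SampleMetadata,
    sink_sample: str,
    scope: list[str] | None = None,
) -> list[SourceProfile]:
    """Pool source-habitat samples into per-habitat profiles for one sink.

    ``scope`` lists candidate source habitats (default: all habitats except
    the sink's own). The sink sample is always excluded from pooling, so a
    habitat in scope that equals the sink's own habitat contributes only its
    other samples (no self-tracking leakage).
    """
    meta = metadata.frame.set_index("sample_id")
    if sink_sample not in meta.index:
        raise ValueError(f"sink sample {sink_sample!r} not in metadata")
    sink_habitat = meta.loc[sink_sample, "habitat"]
    if scope is None:
        scope = [h for h in metadata.habitats if h != sink_habitat]
    profiles = []
    for habitat in scope:
        samples = [s for s in metadata.samples_in_habitat(habitat) if s != sink_sample]
        if not samples:
            raise ValueError(f"source habitat {habitat!r} has no samples")
        pooled = table.select_samples(samples).counts.sum(axis=1).astype(float)
        pooled += PSEUDOCOUNT
        profiles.append(SourceProfile(habitat, pooled / pooled.sum()))
    return profiles


def _run_em(x, G, with_unknown, tol, max_iter, rng):
    K_known = G.shape[0]
    J = G.shape[1]
    if with_unknown:
        G = np.vstack([G, np.full(J, 1.0 / J)])
    K = G.shape[0]
    m = np.full(K, 1.0 / K) + rng.uniform(0, 1e-12, size=K)
    m /= m.sum()
    xs = x.sum()
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mix = np.maximum(m @ G, 1e-300)
        ll = float(x @ np.log(mix))
        r = (m[:, None] * G) / mix
        m_new = (r * x).sum(axis=1) / xs
        if with_unknown:
            gu = r[-1] * x
            s = gu.sum()
            if s > 0:
                G[-1] = gu / s
        m = m_new
        if trace and (ll - trace[-1]) < tol * abs(trace[-1]):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
    gamma_u = G[-1].copy() if with_unknown else None
    return m, gamma_u, trace, n_iter, converged


def _project_minimal_unknown(x: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Non-negative least-squares attribution of the sink to known profiles."""
    p = x / x.sum()
    res = lsq_linear(G.T, p, bounds=(0.0, 1.0))
    m = np.clip(res.x, 0.0, 1.0)
    total = m.sum()
    if total > 1.0:
        m /= total
    return m


def em_mixture(
    sink_counts: np.ndarray,
    profiles: list[SourceProfile],
    with_unknown: bool = True,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    seed: int = 0,
    sink_sample: str = "sink",
    resolve_unknown: str = "projection",
) -> SourceMixture:
    """Estimate mixing proportions of one sink over the given sources.

    ``resolve_unknown`` chooses how the known/unknown split is reported when
    ``with_unknown``: "projection" (default, minimal-unknown convention) or
    "em" (raw EM point; the unknown absorbs any mass shared with the knowns).
    The EM log-likelihood trace is returned either way and is non-decreasing.
    """
    x = np.asarray(sink_counts, dtype=float)
    if np.any(x < 0) or x.sum() <= 0:
        raise ValueError("sink counts must be non-negative with positive total")
    G = np.vstack([p.gamma for p in profiles])
    if G.shape[1] != x.size:
        raise ValueError("profiles and sink counts live on different taxon spaces")
    names = [p.habitat for p in profiles]
    rng = np.random.default_rng(seed)
    m, gamma_u, trace, n_iter, converged = _run_em(x, G.copy(), with_unknown, tol, max_iter, rng)
    if not converged:
        warnings.warn(f"EM did not converge within {max_iter} iterations", stacklevel=2)
    if with_unknown:
        em_props = pd.Series(m, index=names + [UNKNOWN])
        if resolve_unknown == "projection":
            mk = _project_minimal_unknown(x, G)
            props = pd.Series(np.append(mk, 1.0 - mk.sum()), index=names + [UNKNOWN])
        elif resolve_unknown == "em":
            props = em_props
        else:
            raise ValueError(f"unknown resolve_unknown mode {resolve_unknown!r}")
    else:
        props = pd.Series(m, index=names)
        em_props = props
    props = props.clip(lower=0.0)
    props /= props.sum()
    return SourceMixture(sink_sample, props, trace, n_iter, converged, em_props)


def track_all_sinks(
    table: FeatureTable,
    metadata: SampleMetadata,
    with_unknown: bool = True,
    seed: int = 0,
    **em_kwargs,
) -> dict[str, SourceMixture]:
    """Run source tracking for every sample against the other habitats."""
    root = np.random.default_rng(seed)
    mixtures = {}
    for j, sample in enumerate(table.sample_ids):
        profiles = build_source_profiles(table, metadata, sample)
        sub_seed = int(root.integers(0, 2**31 - 1))
        mixtures[sample] = em_mixture(
            table.counts[:, j], profiles, with_unknown=with_unknown,
            seed=sub_seed, sink_sample=sample, **em_kwargs,
        )
    return mixtures


def habitat_contribution_summary(
    mixtures: dict[str, SourceMixture],
    metadata: SampleMetadata,
) -> pd.DataFrame:
    """Mean source contributions per sink habitat.

    Rows are sink habitats, columns are all habitats plus "unknown"; a
    habitat's own column is 0 (habitats are traced against the other four).
    Rows sum to 1.
    """
    habitats = metadata.habitats
    cols = habitats + [UNKNOWN]
    meta = metadata.frame.set_index("sample_id")
    rows = {}
    for habitat in habitats:
        samples = metadata.samples_in_habitat(habitat)
        missing = [s for s in samples if s not in mixtures]
        if missing:
            raise ValueError(f"missing mixtures for sink samples: {missing}")
        block = pd.DataFrame([mixtures[s].proportions for s in samples])
        rows[habitat] = block.mean(axis=0).reindex(cols).fillna(0.0)
    out = pd.DataFrame(rows).T
    out.index.name = "sink_habitat"
    return out
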