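"""Sloan neutral community model (NCM) fitting.

The NCM predicts a taxon's occurrence frequency across samples from its mean
relative abundance p: under neutral drift with immigration, the stationary
proportion of a taxon follows Beta(N*m*p, N*m*(1-p)), where N is the local
community size (reads per rarefied sample) and m the immigration rate. The
predicted frequency of detection above a limit d (default one read, 1/N) is

    f_pred = 1 - BetaCDF(d; N*m*p, N*m*(1-p))

m is fitted by least squares of observed vs predicted occurrence frequency;
R^2 of that fit measures how neutral the community looks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import betainc

from .core_io import FeatureTable, SampleMetadata

logger = logging.getLogger(__name__)

_LOG_M_BOUNDS = (-6.0, 1.0)  # m in [1e-6, 10], fitted on log10 scale
MIN_TAXA = 10


@dataclass
class NCMFit:
    """A fitted Sloan model: m, Nm, R^2 and the per-taxon frequency table."""

    m: float
    N: int
    r2: float
    d: float
    per_taxon: pd.DataFrame  # columns: p, f_obs, f_pred, wilson_low, wilson_high
    m_ci: tuple[float, float] | None = None
    label: str = ""
    sse: float = field(default=np.nan, repr=False)

    @property
    def Nm(self) -> float:
        return self.N * self.m


def _predict(p: np.ndarray, N: float, m: float, d: float) -> np.ndarray:
    a = N * m * p
    b = np.maximum(N * m * (1.0 - p), 1e-12)
    return 1.0 - betainc(a, b, min(d, 1.0))


def _fit_m(p: np.ndarray, f_obs: np.ndarray, N: float, d: float) -> tuple[float, float]:
    def sse(log_m: float) -> float:
        resid = f_obs - _predict(p, N, 10.0**log_m, d)
        return float((resid**2).sum())

    res = minimize_scalar(sse, bounds=_LOG_M_BOUNDS, method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"NCM optimizer failed: {res.message}")
    return 10.0**res.x, res.fun


def _wilson(f: np.ndarray, n: int, z: float = 1.959963984540054) -> tuple[np.ndarray, np.ndarray]:
    denom = 1 + z**2 / n
    center = (f + z**2 / (2 * n)) / denom
    half = z * np.sqrt(f * (1 - f) / n + z**2 / (4 * n**2)) / denom
    return np.clip(center - half, 0, 1), np.clip(center + half, 0, 1)


def fit_sloan_ncm(
    table: FeatureTable,
    samples: list[str] | None = None,
    d: float | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    label: str = "",
) -> NCMFit:
    """Fit the Sloan NCM to a (rarefied) count table.

    ``samples`` restricts the fit to a subset (default: all). All retained
    samples must share one depth N. ``d`` defaults to one read (1/N).
    A seeded bootstrap over taxa (``n_boot`` resamples; 0 disables) gives a
    95% interval for m. R^2 is undefined (NaN) when observed frequencies are
    constant; this is flagged with a warning.
    """
    sub = table.select_samples(samples) if samples is not None else table
    depths = np.unique(sub.sample_totals())
    if depths.size != 1:
        raise ValueError(f"samples must be rarefied to one common depth, got {depths}")
    N = int(depths[0])
    if d is None:
        d = 1.0 / N
    totals = sub.taxon_totals()
    keep = totals > 0
    if keep.sum() < MIN_TAXA:
        raise ValueError(f"need >= {MIN_TAXA} taxa with nonzero total, have {int(keep.sum())}")
    taxa = [t for t, k in zip(sub.taxon_ids, keep) if k]
    rel = sub.counts[keep] / N
    p = rel.mean(axis=1)
    f_obs = (sub.counts[keep] > 0).mean(axis=1)

    m_hat, sse = _fit_m(p, f_obs, N, d)
    f_pred = _predict(p, N, m_hat, d)
    sst = float(((f_obs - f_obs.mean()) ** 2).sum())
    if sst == 0:
        logger.warning("constant observed occurrence frequency: R^2 undefined")
        r2 = np.nan
    else:
        r2 = 1.0 - sse / sst

    m_ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        J = p.size
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, J, size=J)
            boots[b], _ = _fit_m(p[idx], f_obs[idx], N, d)
        m_ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    lo, hi = _wilson(f_pred, len(sub.sample_ids))
    per_taxon = pd.DataFrame(
        {"p": p, "f_obs": f_obs, "f_pred": f_pred, "wilson_low": lo, "wilson_high": hi},
        index=pd.Index(taxa, name="taxon_id"),
    )
    return NCMFit(m=float(m_hat), N=N, r2=float(r2), d=float(d),
                  per_taxon=per_taxon, m_ci=m_ci, label=label, sse=sse)


def ncm_r2_by_habitat_count(
    table: FeatureTable,
    metadata: SampleMetadata,
    subsets: list[tuple[str, ...]] | None = None,
    n_boot: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, float]:
    """Fit one NCM per habitat combination and test the R^2-vs-size trend.

    ``subsets`` defaults to every non-empty combination of the metadata's
    habitats (2^H - 1 of them). Combinations with too few taxa are skipped
    and logged. Returns (per-combination table, Spearman rho of R^2 against
    combination size, p-value).
    """
    habitats = metadata.habitats
    if subsets is None:
        subsets = [c for r in range(1, len(habitats) + 1)
                   for c in combinations(habitats, r)]
    rows = []
    for combo in subsets:
        if len(set(combo)) != len(combo):
            raise ValueError(f"duplicate habitat in combination {combo}")
        samples = [s for h in combo for s in metadata.samples_in_habitat(h)]
        label = "+".join(combo)
        try:
            fit = fit_sloan_ncm(table, samples, n_boot=n_boot, seed=seed, label=label)
        except ValueError as exc:
            logger.info("skipping combination %s: %s", label, exc)
            continue
        rows.append({"combination": label, "size": len(combo),
                     "m": fit.m, "Nm": fit.Nm, "r2": fit.r2})
    frame = pd.DataFrame(rows)
    if frame["size"].nunique() > 1 and frame["r2"].notna().sum() > 2:
        res = stats.spearmanr(frame["size"], frame["r2"])
        rho, p = float(res.statistic), float(res.pvalue)
    else:
        rho, p = np.nan, np.nan
    return frame, rho, p
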