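"""Sitewise topology contrasts and the SH test.

The per-site difference of log-likelihoods between two candidate topologies
(``delta_sls``, sign convention mt − nuc: positive favors the mt-topology)
is classified into strongly supporting sites (strictly beyond ±threshold),
aggregated into per-group sums (ΔCLS) and per-site means (average ΔCLS),
and compared tree-against-tree by the Shimodaira–Hasegawa test with RELL
resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihood import SiteScoreTable


class EmptyInputError(ValueError):
    pass


def delta_sls(scores: SiteScoreTable, label_mt: str = "mt",
              label_nuc: str = "nuc") -> np.ndarray:
    """Per-site ΔSLS = LL(mt-topology) − LL(nuc-topology)."""
    for label in (label_mt, label_nuc):
        if label not in scores.scores:
            raise KeyError(f"no score vector labeled {label!r}")
    a = scores.scores[label_mt]
    b = scores.scores[label_nuc]
    if a.shape != b.shape:
        raise ValueError("score vectors have mismatched shapes")
    return a - b


@dataclass(frozen=True)
class SiteClassification:
    n_strong_mt: int
    n_strong_nuc: int
    n_weak: int
    pct_strong_mt: float
    pct_strong_nuc: float
    threshold: float

    @property
    def n_sites(self):
        return self.n_strong_mt + self.n_strong_nuc + self.n_weak


def classify_sites(dsls: np.ndarray, threshold: float = 0.5) -> SiteClassification:
    """Count sites strictly beyond ±threshold (strong support either way)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    dsls = np.asarray(dsls, dtype=float)
    if dsls.size == 0:
        raise EmptyInputError("empty ΔSLS vector")
    n_mt = int((dsls > threshold).sum())
    n_nuc = int((dsls < -threshold).sum())
    n = dsls.size
    return SiteClassification(
        n_strong_mt=n_mt, n_strong_nuc=n_nuc, n_weak=n - n_mt - n_nuc,
        pct_strong_mt=100.0 * n_mt / n, pct_strong_nuc=100.0 * n_nuc / n,
        threshold=threshold)


def complex_scores(
    dsls: np.ndarray,
    site_partition: np.ndarray,
    partition_group: dict[str, str] | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Aggregate ΔSLS by group: ΔCLS, average ΔCLS, strong-site percentages.

    ``site_partition`` assigns each site a partition name; ``partition_group``
    maps partitions to groups (e.g. OXPHOS complexes).  With no map, each
    partition is its own group.  Groups with zero sites are dropped with a
    warning.
    """
    dsls = np.asarray(dsls, dtype=float)
    site_partition = np.asarray(site_partition, dtype=object)
    if dsls.shape != site_partition.shape:
        raise ValueError("ΔSLS and site-partition vectors differ in length")
    if partition_group is None:
        groups = site_partition
    else:
        missing = sorted({p for p in np.unique(site_partition)
                          if p not in partition_group})
        if missing:
            raise KeyError(f"partitions without a group: {missing}")
        groups = np.array([partition_group[p] for p in site_partition],
                          dtype=object)
    rows = []
    seen = set()
    ordered = [g for g in groups if not (g in seen or seen.add(g))]
    if partition_group is not None:
        for g in partition_group.values():
            if g not in seen:
                warnings.warn(f"group {g!r} has zero sites; excluded")
    for g in ordered:
        d = dsls[groups == g]
        cls = classify_sites(d, threshold)
        rows.append({
            "group": g,
            "delta_cls": float(d.sum()),
            "avg_delta_cls": float(d.mean()),
            "pct_strong_mt": cls.pct_strong_mt,
            "pct_strong_nuc": cls.pct_strong_nuc,
            "n_sites": int(d.size),
        })
    return pd.DataFrame(rows)


def sh_test(scores: dict[str, np.ndarray], n_resamples: int = 1000,
            seed: int | None = None) -> pd.DataFrame:
    """Shimodaira–Hasegawa test by RELL resampling of sitewise LLs.

    For each tree the observed deficit to the best tree is compared with the
    distribution of centered resampled deficits (one-sided); the best tree
    gets p = 1 by construction.
    """
    labels = list(scores)
    if len(labels) < 2:
        raise ValueError("SH test needs at least two trees")
    vectors = [np.asarray(scores[l], dtype=float) for l in labels]
    if len({v.shape for v in vectors}) > 1 or vectors[0].ndim != 1:
        raise ValueError("sitewise LL vectors must share one length")
    mat = np.stack(vectors)
    k, n = mat.shape
    totals = mat.sum(axis=1)
    observed = totals.max() - totals                   # deficit per tree
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_resamples, n))
    resampled = mat[:, idx].sum(axis=2)                # (k, B)
    centered = resampled - resampled.mean(axis=1, keepdims=True)
    deficits = centered.max(axis=0)[None, :] - centered  # (k, B)
    pvals = (deficits >= observed[:, None]).mean(axis=1)
    return pd.DataFrame({
        "tree": labels,
        "log_likelihood": totals,
        "deficit": observed,
        "p_value": pvals,
    })
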