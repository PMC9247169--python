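"""Rank-based group comparisons and the two-sample t test.

Kruskal–Wallis (tie-corrected, chi-square approximation), Dunn's pairwise
post-hoc z tests with Bonferroni correction, and Student's pooled-variance
t test (Welch optional) — the inferential machinery for comparing
composition statistics across clades and concordance between marker groups.
Implemented directly from the rank/moment formulas; p-values come from the
chi-square, normal and t reference distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata
from scipy.stats import t as t_dist


class InvalidComparisonError(ValueError):
    pass


def _as_groups(groups) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[~np.isnan(a)] for a in arrays]
    if len(arrays) < 2:
        raise InvalidComparisonError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise InvalidComparisonError("every group must be non-empty")
    return arrays


def _tie_term(pooled_ranks_source: np.ndarray) -> float:
    """Sum of t^3 - t over tied-value run lengths t."""
    _, counts = np.unique(pooled_ranks_source, return_counts=True)
    return float(((counts ** 3) - counts).sum())


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    H = 12/(N(N+1)) * sum R_g^2/n_g - 3(N+1), divided by the tie correction
    1 - sum(t^3 - t)/(N^3 - N); p from chi-square with k-1 df.  When every
    value is identical, H = 0 and p = 1.
    """
    arrays = _as_groups(groups)
    pooled = np.concatenate(arrays)
    n = pooled.size
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start:start + a.size]
        h += r.sum() ** 2 / a.size
        start += a.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n ** 3 - n)
    h /= correction
    p = float(chi2.sf(h, df=len(arrays) - 1))
    return float(h), p


@dataclass
class PairwiseTestGrid:
    """Dunn post-hoc results: per-pair z, raw and Bonferroni-adjusted p."""

    labels: list[str]
    h_statistic: float
    h_p_value: float
    pairs: pd.DataFrame          # group1, group2, z, p_raw, p_adjusted
    low_power: list[str] = field(default_factory=list)

    def adjusted_p(self, a: str, b: str) -> float:
        m = self.pairs[((self.pairs.group1 == a) & (self.pairs.group2 == b)) |
                       ((self.pairs.group1 == b) & (self.pairs.group2 == a))]
        if m.empty:
            raise KeyError(f"no pair ({a}, {b})")
        return float(m.p_adjusted.iloc[0])


def dunn_bonferroni(groups, labels=None) -> PairwiseTestGrid:
    """Dunn's z tests on pooled mean ranks, Bonferroni over all pairs.

    z_ij = (Rbar_i - Rbar_j) / sqrt(V (1/n_i + 1/n_j)) with tie-corrected
    variance V = (N(N+1) - sum(t^3 - t)/(N-1)) / 12; two-sided p, adjusted
    p = min(1, p * k(k-1)/2).  Singleton groups are computed but flagged.
    """
    arrays = _as_groups(groups)
    k = len(arrays)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    labels = list(labels)
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start:start + a.size].mean())
        sizes.append(a.size)
        start += a.size
    variance = (n * (n + 1) - _tie_term(pooled) / (n - 1)) / 12.0
    n_pairs = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            denom = np.sqrt(variance * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
            p_raw = float(2.0 * norm.sf(abs(z)))
            rows.append({
                "group1": labels[i], "group2": labels[j],
                "z": float(z), "p_raw": p_raw,
                "p_adjusted": min(1.0, p_raw * n_pairs),
            })
    h, hp = kruskal_wallis(arrays)
    low_power = [labels[i] for i, s in enumerate(sizes) if s == 1]
    return PairwiseTestGrid(labels, h, hp, pd.DataFrame(rows), low_power)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float
    variant: str


def two_sample_t(x, y, variant: str = "pooled") -> TTestResult:
    """Two-sided two-sample t test; pooled-variance Student by default.

    With zero variance in both samples and equal means, t = 0 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidComparisonError("each sample needs at least 2 values")
    n1, n2 = x.size, y.size
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if variant == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif variant == "welch":
        se2_1, se2_2 = v1 / n1, v2 / n2
        se = np.sqrt(se2_1 + se2_2)
        if se == 0:
            df = n1 + n2 - 2
        else:
            df = (se2_1 + se2_2) ** 2 / (
                se2_1 ** 2 / (n1 - 1) + se2_2 ** 2 / (n2 - 1))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if se == 0:
        if diff == 0:
            return TTestResult(0.0, float(df), 1.0, variant)
        return TTestResult(float(np.sign(diff) * np.inf), float(df), 0.0, variant)
    t = diff / se
    p = float(2.0 * t_dist.sf(abs(t), df))
    return TTestResult(float(t), float(df), p, variant)


@dataclass
class ContactComparison:
    """Contact vs non-contact marker concordance comparison (with summaries)."""

    test: TTestResult
    summary: pd.DataFrame           # per group: n, mean, median
    n_missing: int
    plurality_threshold: float

    @property
    def contact_mean(self) -> float:
        return float(self.summary.loc["contact", "mean"])

    @property
    def non_contact_mean(self) -> float:
        return float(self.summary.loc["non-contact", "mean"])


def compare_contact_groups(marker_scf: dict[str, float | None],
                           marker_contact: dict[str, str],
                           variant: str = "pooled") -> ContactComparison:
    """Two-sample t on focal-branch sCF of contact vs non-contact markers.

    ``marker_scf`` maps marker -> sCF (``None`` = missing, dropped);
    ``marker_contact`` labels each marker ``contact`` or ``non-contact``
    (other labels, e.g. organellar markers, are ignored).
    """
    groups: dict[str, list[float]] = {"contact": [], "non-contact": []}
    n_missing = 0
    for marker, value in marker_scf.items():
        label = marker_contact.get(marker)
        if label not in groups:
            continue
        if value is None or (isinstance(value, float) and np.isnan(value)):
            n_missing += 1
            continue
        groups[label].append(float(value))
    for label, vals in groups.items():
        if not vals:
            raise InvalidComparisonError(
                f"group {label!r} has no usable sCF values")
    test = two_sample_t(groups["contact"], groups["non-contact"], variant)
    summary = pd.DataFrame({
        "n": {g: len(v) for g, v in groups.items()},
        "mean": {g: float(np.mean(v)) for g, v in groups.items()},
        "median": {g: float(np.median(v)) for g, v in groups.items()},
    })
    from .concordance import SCF_PLURALITY_THRESHOLD
    return ContactComparison(test, summary, n_missing, SCF_PLURALITY_THRESHOLD)
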