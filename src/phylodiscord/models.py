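"""Reversible substitution models with discrete-gamma rate heterogeneity.

A model couples a symmetric exchangeability matrix ``S`` with equilibrium
frequencies ``pi``; the rate matrix is ``Q = S @ diag(pi)`` with the diagonal
set so rows sum to zero, rescaled so that one unit of branch length equals
one expected substitution per site (``sum_i pi_i * -Q_ii == 1``).

Rate heterogeneity across sites follows the discrete-gamma convention:
``n_categories`` equal-probability categories, each represented by its mean
rate, with the gamma shape ``alpha`` shared between the shape and rate
parameter so the mean rate is one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from ._empirical import AA_ORDER, LG_FREQS, LG_RATES, WAG_FREQS, WAG_RATES

NT_ORDER = "ACGT"

#: IUPAC ambiguity codes -> compatible nucleotide sets
NT_AMBIGUITY = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    "X": "ACGT", "-": "ACGT", "?": "ACGT", ".": "ACGT",
}

AA_AMBIGUITY = {
    "B": "DN", "Z": "EQ", "J": "IL", "X": AA_ORDER,
    "-": AA_ORDER, "?": AA_ORDER, ".": AA_ORDER, "*": AA_ORDER,
}


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean rates of ``n_categories`` equal-probability gamma categories.

    Shape and rate are both ``alpha`` so the continuous distribution has
    mean 1; the category means are renormalized to average exactly 1.
    """
    if n_categories == 1:
        return np.ones(1)
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    k = n_categories
    cut = _gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    # mean of X on (lo, hi) for Gamma(alpha, alpha): uses the alpha+1 CDF
    upper = np.concatenate([cut, [np.inf]])
    lower = np.concatenate([[0.0], cut])
    mass_hi = gammainc(alpha + 1, alpha * np.where(np.isinf(upper), 1e12, upper))
    mass_lo = gammainc(alpha + 1, alpha * lower)
    means = (mass_hi - mass_lo) * k
    return means / means.mean()


def _expand_lower_triangle(values, n: int) -> np.ndarray:
    s = np.zeros((n, n))
    it = iter(values)
    for i in range(1, n):
        for j in range(i):
            s[i, j] = s[j, i] = next(it)
    return s


@dataclass(frozen=True)
class SubstitutionModel:
    """A time-reversible substitution model on a fixed alphabet."""

    alphabet: str                      # "aa" or "nt"
    states: str                        # state order, e.g. "ACGT"
    exchangeabilities: np.ndarray      # symmetric, zero diagonal
    frequencies: np.ndarray            # equilibrium distribution pi
    alpha: float | None = None         # gamma shape; None = rate homogeneity
    n_categories: int = 4
    name: str = "custom"
    _eig: tuple = field(default=None, repr=False, compare=False)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def rate_matrix(self) -> np.ndarray:
        """Normalized generator Q (one expected substitution per unit length)."""
        q = self.exchangeabilities * self.frequencies[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(self.frequencies * np.diag(q)).sum()
        return q / scale

    @property
    def category_rates(self) -> np.ndarray:
        if self.alpha is None or self.n_categories == 1:
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.n_categories)

    def _eigendecomposition(self):
        """Symmetric eigendecomposition of Q for fast matrix exponentials."""
        if self._eig is not None:
            return self._eig
        pi = self.frequencies
        sq = np.sqrt(pi)
        b = (sq[:, None] / sq[None, :]) * self.rate_matrix  # symmetric
        b = (b + b.T) / 2.0
        lam, u = np.linalg.eigh(b)
        left = u.T * sq[None, :]            # rows: u^T diag(sqrt pi)
        right = (u / sq[:, None])           # diag(1/sqrt pi) u
        object.__setattr__(self, "_eig", (lam, right, left))
        return self._eig

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q t rate); rows sum to 1, detailed balance holds."""
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        if rate <= 0:
            raise ValueError("rate multiplier must be positive")
        if t == 0.0:
            return np.eye(self.n_states)
        lam, right, left = self._eigendecomposition()
        p = (right * np.exp(lam * t * rate)[None, :]) @ left
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=1, keepdims=True)

    def with_frequencies(self, frequencies: np.ndarray) -> "SubstitutionModel":
        frequencies = np.asarray(frequencies, dtype=float)
        _check_frequencies(frequencies, self.n_states)
        return replace(self, frequencies=frequencies / frequencies.sum(),
                       _eig=None)

    def state_index(self, symbol: str) -> np.ndarray:
        """Partial-likelihood row for one observed symbol (handles ambiguity)."""
        symbol = symbol.upper()
        ambiguity = NT_AMBIGUITY if self.alphabet == "nt" else AA_AMBIGUITY
        if symbol in self.states:
            row = np.zeros(self.n_states)
            row[self.states.index(symbol)] = 1.0
            return row
        allowed = ambiguity.get(symbol)
        if allowed is None:
            raise ValueError(f"unknown state symbol {symbol!r}")
        row = np.zeros(self.n_states)
        for s in allowed:
            row[self.states.index(s)] = 1.0
        return row


def _check_frequencies(pi: np.ndarray, n: int) -> None:
    if pi.shape != (n,):
        raise ValueError(f"expected {n} frequencies, got {pi.shape}")
    if np.any(pi < 0):
        raise ValueError("frequencies must be nonnegative")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("frequencies must sum to 1 within 1e-8")


_AA_EMPIRICAL = {
    "wag": (WAG_RATES, WAG_FREQS),
    "lg": (LG_RATES, LG_FREQS),
}


def build_model(
    name: str,
    frequencies=None,
    alpha: float | None = None,
    n_categories: int = 4,
    alphabet: str | None = None,
) -> SubstitutionModel:
    """Construct a named reversible model.

    Parameters
    ----------
    name
        ``poisson`` (equal-rate amino acid), ``wag``, ``lg`` or ``gtr-like``
        (nucleotide model; symmetric exchangeabilities default to 1, i.e. an
        F81-style model unless custom exchangeabilities are wired in through
        a custom :class:`SubstitutionModel`).
    frequencies
        Explicit equilibrium frequencies, or ``None`` for the matrix's own
        (``wag``/``lg``) or uniform frequencies.
    alpha, n_categories
        Discrete-gamma shape and category count; ``alpha=None`` disables
        rate heterogeneity.
    """
    name = name.lower()
    if name == "poisson":
        states, n = AA_ORDER, 20
        s = np.ones((n, n))
        default_pi = np.full(n, 1.0 / n)
        alphabet = alphabet or "aa"
    elif name in _AA_EMPIRICAL:
        rates, freqs = _AA_EMPIRICAL[name]
        states, n = AA_ORDER, 20
        s = _expand_lower_triangle(rates, n)
        default_pi = np.asarray(freqs)
        default_pi = default_pi / default_pi.sum()
        alphabet = alphabet or "aa"
    elif name in ("gtr-like", "gtr", "f81"):
        states, n = NT_ORDER, 4
        s = np.ones((n, n))
        default_pi = np.full(n, 0.25)
        alphabet = alphabet or "nt"
    else:
        raise ValueError(f"unknown model name {name!r}")
    np.fill_diagonal(s, 0.0)
    if frequencies is None:
        pi = default_pi
    else:
        pi = np.asarray(frequencies, dtype=float)
        _check_frequencies(pi, n)
        pi = pi / pi.sum()
    return SubstitutionModel(
        alphabet=alphabet, states=states, exchangeabilities=s,
        frequencies=pi, alpha=alpha, n_categories=n_categories, name=name,
    )


def empirical_frequencies(model: SubstitutionModel, sequences) -> np.ndarray:
    """Observed state frequencies over an iterable of sequences.

    Ambiguity codes and gaps are ignored.  A pseudocount keeps unseen states
    strictly positive so the model remains ergodic.
    """
    counts = np.zeros(model.n_states)
    index = {s: i for i, s in enumerate(model.states)}
    for seq in sequences:
        for ch in str(seq).upper():
            i = index.get(ch)
            if i is not None:
                counts[i] += 1
    counts += 0.5
    return counts / counts.sum()
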