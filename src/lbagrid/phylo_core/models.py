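"""Amino-acid substitution models.

A model is a general time-reversible 20-state chain: a symmetric
exchangeability matrix S, a stationary frequency vector pi, and the
derived rate matrix Q with Q_ij = S_ij * pi_j (i != j), normalized so
the expected number of substitutions per unit branch length is one
(-sum_i pi_i Q_ii = 1).  Among-site rate heterogeneity uses the
standard discrete-gamma approximation: k equal-weight categories whose
rates are the means of the gamma distribution over its k quantile
intervals.

The empirical LG, WAG and JTT tables are bundled as PAML-layout text
files (lower-triangle exchangeabilities followed by frequencies), as
published by Le & Gascuel (2008), Whelan & Goldman (2001) and Jones,
Taylor & Thornton (1992).  The equal-rates Poisson model is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_STATES = 20

#: characters treated as fully ambiguous (partial likelihood 1 everywhere)
AMBIGUOUS = set("-X?*BZJUO.")


def encode_sequence(seq: str) -> np.ndarray:
    """Integer codes for an amino-acid string; ambiguity becomes -1."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        if ch in AA_INDEX:
            out[i] = AA_INDEX[ch]
        elif ch in AMBIGUOUS:
            out[i] = -1
        else:
            raise ValueError(f"unknown residue {ch!r} at column {i + 1}")
    return out


def build_rate_matrix(exchangeabilities: np.ndarray, frequencies: np.ndarray) -> np.ndarray:
    """Normalized GTR-form rate matrix Q from S and pi."""
    S = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(frequencies, dtype=float)
    if S.shape != (N_STATES, N_STATES):
        raise ValueError("exchangeability matrix must be 20x20")
    if not np.allclose(S, S.T):
        raise ValueError("exchangeability matrix must be symmetric")
    if np.any(S < 0):
        raise ValueError("exchangeabilities must be non-negative")
    if pi.shape != (N_STATES,) or np.any(pi <= 0):
        raise ValueError("frequencies must be 20 positive values")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("frequencies must sum to 1")
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -np.dot(pi, np.diag(Q))
    return Q / mean_rate


def discrete_gamma(alpha: float, k: int) -> np.ndarray:
    """Mean rates of the k equal-probability gamma categories (mean 1)."""
    if not (alpha > 0):
        raise ValueError("gamma shape must be positive")
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ValueError("number of categories must be an integer >= 1")
    if k == 1:
        return np.array([1.0])
    # boundaries of the equal-probability intervals for Gamma(alpha, rate=alpha)
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], bounds * alpha, [np.inf]])
    # E[X | interval] * k, using the regularized incomplete gamma of shape a+1
    upper = np.where(np.isinf(edges[1:]), 1.0, gammainc(alpha + 1.0, edges[1:]))
    lower = gammainc(alpha + 1.0, edges[:-1])
    rates = (upper - lower) * k
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """GTR-form amino-acid model with optional discrete-gamma rates."""

    name: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    gamma_shape: float | None = None
    n_categories: int = 4
    rate_matrix: np.ndarray = field(init=False, repr=False)
    _eig: tuple = field(init=False, repr=False)

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.frequencies = self.frequencies / self.frequencies.sum()
        self.rate_matrix = build_rate_matrix(self.exchangeabilities, self.frequencies)
        # symmetric eigendecomposition: B = D^1/2 Q D^-1/2 is symmetric
        sq = np.sqrt(self.frequencies)
        B = (self.rate_matrix * sq[:, None]) / sq[None, :]
        vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
        self._eig = (vals, vecs, sq)

    @property
    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.array([1.0])
        return discrete_gamma(self.gamma_shape, self.n_categories)

    @property
    def n_rate_parameters(self) -> int:
        """Free rate-heterogeneity parameters (for information criteria)."""
        return 0 if self.gamma_shape is None else 1

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), entries clipped to [0, 1]."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        if t == 0:
            return np.eye(N_STATES)
        vals, vecs, sq = self._eig
        inner = (vecs * np.exp(vals * t)) @ vecs.T
        P = inner * (sq[None, :] / sq[:, None])
        return np.clip(P, 0.0, 1.0)

    def with_gamma(self, alpha: float | None, k: int = 4) -> "SubstitutionModel":
        suffix = "" if alpha is None else f"+G{k}"
        base = self.name.split("+")[0]
        return SubstitutionModel(
            name=base + suffix,
            exchangeabilities=self.exchangeabilities,
            frequencies=self.frequencies,
            gamma_shape=alpha,
            n_categories=k,
        )


def load_paml_dat(text: str, name: str) -> SubstitutionModel:
    """Parse the common PAML layout: 19 lower-triangle rows, then
    a line of 20 stationary frequencies."""
    rows = [
        [float(x) for x in line.split()]
        for line in text.strip().splitlines()
        if line.strip()
    ]
    tri, freqs = rows[:19], rows[19]
    if [len(r) for r in tri] != list(range(1, 20)) or len(freqs) != 20:
        raise ValueError(f"malformed model file for {name}")
    S = np.zeros((N_STATES, N_STATES))
    for i, row in enumerate(tri, start=1):
        S[i, : len(row)] = row
    S = S + S.T
    return SubstitutionModel(name=name, exchangeabilities=S, frequencies=np.array(freqs))


def _load_bundled(stem: str, name: str) -> SubstitutionModel:
    text = (
        resources.files("lbagrid.phylo_core").joinpath(f"data/{stem}.dat").read_text()
    )
    return load_paml_dat(text, name)


def lg() -> SubstitutionModel:
    return _load_bundled("lg", "LG")


def wag() -> SubstitutionModel:
    return _load_bundled("wag", "WAG")


def jtt() -> SubstitutionModel:
    return _load_bundled("jtt", "JTT")


def poisson() -> SubstitutionModel:
    """Equal exchangeabilities, equal frequencies (the 20-state analog
    of Jukes-Cantor)."""
    S = np.ones((N_STATES, N_STATES))
    np.fill_diagonal(S, 0.0)
    return SubstitutionModel(
        name="Poisson",
        exchangeabilities=S,
        frequencies=np.full(N_STATES, 1.0 / N_STATES),
    )


def default_candidates(n_categories: int = 4) -> list[SubstitutionModel]:
    """The LG/WAG/JTT x {uniform, +G} candidate set for BIC selection.

    The gamma shape of the +G candidates is optimized implicitly only
    through the fixed default alpha = 0.5 starting value; callers that
    need a fitted alpha refit via :func:`select_model`.
    """
    out = []
    for base in (lg(), wag(), jtt()):
        out.append(base)
        out.append(base.with_gamma(0.5, n_categories))
    return out
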