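"""Per-cell inclusion-count laws used by the synthetic-field generator.

Every law here is the *conditional* count distribution of an inclusion-bearing
cell, i.e. its support starts at 1.  Whether a cell bears any inclusion at all
is decided separately by a prevalence Bernoulli draw (see
:mod:`ibscreen.simulate`).  Each law exposes its probability mass function so
that planted class shares (one / two / three-plus inclusions) and moments can
be computed analytically and used as oracles for pipeline recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CountLaw",
    "CategoricalCounts",
    "ShiftedNegBinomCounts",
    "TruncatedPoissonCounts",
    "count_law_from_dict",
]


class CountLaw:
    """Abstract per-cell inclusion-count distribution with support on {1, 2, ...}."""

    #: inclusive upper bound of the support
    max_count: int

    def pmf(self, k: np.ndarray | int) -> np.ndarray | float:
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        raise NotImplementedError

    # ---- analytic summaries -------------------------------------------------

    def support(self) -> np.ndarray:
        return np.arange(1, self.max_count + 1)

    def mean(self) -> float:
        k = self.support()
        return float(np.sum(k * self.pmf(k)))

    def sd(self) -> float:
        k = self.support()
        p = self.pmf(k)
        m = np.sum(k * p)
        return float(np.sqrt(np.sum((k - m) ** 2 * p)))

    def class_shares(self) -> dict[str, float]:
        """Analytic Class 1/2/3 shares among inclusion-bearing cells."""
        p1 = float(self.pmf(1))
        p2 = float(self.pmf(2))
        return {"CLASS1": p1, "CLASS2": p2, "CLASS3": max(0.0, 1.0 - p1 - p2)}


@dataclass(frozen=True)
class CategoricalCounts(CountLaw):
    """Explicit finite law: ``probs[k]`` is the probability of count ``k``."""

    probs: dict[int, float]

    def __post_init__(self) -> None:
        if not self.probs:
            raise ValueError("empty count law")
        ks = np.array(sorted(self.probs))
        ps = np.array([self.probs[int(k)] for k in ks], dtype=float)
        if ks.min() < 1:
            raise ValueError("count support must start at 1")
        if np.any(ps < 0) or not np.isclose(ps.sum(), 1.0, atol=1e-9):
            raise ValueError("probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "_ks", ks)
        object.__setattr__(self, "_ps", ps)
        object.__setattr__(self, "max_count", int(ks.max()))

    def pmf(self, k):
        k = np.asarray(k)
        out = np.zeros(k.shape, dtype=float)
        for kk, pp in zip(self._ks, self._ps):
            out = np.where(k == kk, pp, out)
        return out if out.ndim else float(out)

    def sample(self, rng, size):
        return rng.choice(self._ks, size=size, p=self._ps)


@dataclass(frozen=True)
class ShiftedNegBinomCounts(CountLaw):
    """1 + NegBinom(r, p), parameterized by target mean and SD, truncated above.

    Used for the young/old aging presets, whose per-cell counts are printed as
    mean ± SD; r and p are solved from those two moments of the shifted law.
    The upper truncation (resampling) keeps planted counts physically placeable
    inside a cell; its effect on the moments is folded into ``pmf``.
    """

    target_mean: float
    target_sd: float
    max_count: int = 30

    def __post_init__(self) -> None:
        m = self.target_mean - 1.0
        v = self.target_sd**2
        if m <= 0 or v <= m:
            raise ValueError("need mean > 1 and variance > mean - 1 (overdispersed)")
        p = m / v
        r = m**2 / (v - m)
        object.__setattr__(self, "_r", r)
        object.__setattr__(self, "_p", p)
        base = stats.nbinom.pmf(np.arange(0, self.max_count), r, p)
        object.__setattr__(self, "_pmf_vec", base / base.sum())

    def pmf(self, k):
        k = np.asarray(k)
        out = np.zeros(k.shape, dtype=float)
        valid = (k >= 1) & (k <= self.max_count)
        out[valid] = self._pmf_vec[k[valid].astype(int) - 1]
        return out if out.ndim else float(out)

    def sample(self, rng, size):
        draws = 1 + rng.negative_binomial(self._r, self._p, size=size)
        while np.any(draws > self.max_count):
            bad = draws > self.max_count
            draws[bad] = 1 + rng.negative_binomial(self._r, self._p, size=int(bad.sum()))
        return draws


@dataclass(frozen=True)
class TruncatedPoissonCounts(CountLaw):
    """Poisson(lam) conditioned on being >= 1."""

    lam: float
    max_count: int = field(default=40)

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")

    def pmf(self, k):
        k = np.asarray(k)
        norm = 1.0 - np.exp(-self.lam)
        out = np.where(k >= 1, stats.poisson.pmf(k, self.lam) / norm, 0.0)
        return out if out.ndim else float(out)

    def mean(self) -> float:
        # closed form: lambda / (1 - e^-lambda)
        return self.lam / (1.0 - np.exp(-self.lam))

    def sample(self, rng, size):
        draws = rng.poisson(self.lam, size=size)
        while np.any(draws == 0):
            zero = draws == 0
            draws[zero] = rng.poisson(self.lam, size=int(zero.sum()))
        return np.minimum(draws, self.max_count)


def count_law_from_dict(d: dict) -> CountLaw:
    """Build a count law from a config mapping, e.g. parsed from YAML."""
    kind = d.get("kind")
    if kind == "categorical":
        return CategoricalCounts({int(k): float(v) for k, v in d["probs"].items()})
    if kind == "shifted_negative_binomial":
        return ShiftedNegBinomCounts(float(d["mean"]), float(d["sd"]),
                                     int(d.get("max_count", 30)))
    if kind == "truncated_poisson":
        return TruncatedPoissonCounts(float(d["lam"]))
    raise ValueError(f"unknown count law kind: {kind!r}")
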