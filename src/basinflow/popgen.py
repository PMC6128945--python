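"""Per-population diversity statistics and Weir–Cockerham differentiation.

Statistics follow the conventions of RAD-seq population pipelines:
per-site allele frequencies from non-missing calls only, Nei's unbiased
small-sample correction on expected heterozygosity, and the Weir &
Cockerham (1984) theta estimator for pairwise F_ST as a multi-locus
ratio of sums of variance components. Negative multi-locus estimates
are reported as computed; no clamping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass(eq=False)
class PairMatrix:
    """Symmetric pairwise-statistic matrix (F_ST, resistance distance...)."""

    labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def reorder(self, labels) -> "PairMatrix":
        idx = [self.labels.index(l) for l in labels]
        return PairMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "PairMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))


def _pop_site_arrays(G: GenotypeMatrix, idx: np.ndarray):
    """Per-site (n_called_diploids, alt_count, het_count) for one population."""
    sub = G.calls[idx]
    called = sub != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    het = ((sub == 1) & called).sum(axis=0)
    return n, alt, het


def pop_stats(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-population P, pi, H_O, H_E, F_IS over the variable sites supplied.

    P is the mean major-allele frequency; H_E uses Nei's unbiased
    correction 2n/(2n-1) per site (n = called diploids); pi is the mean
    per-site unbiased expected heterozygosity; F_IS = 1 - sum(H_O)/sum(H_E)
    (ratio of sums; NaN when all sites are monomorphic in the population).
    Sites with no call in a population are excluded for that population.
    """
    records = []
    for pop, idx in G.pop_indices().items():
        n, alt, het = _pop_site_arrays(G, idx)
        analyzed = n >= 1
        if not analyzed.any():
            raise ValueError(f"population {pop!r} has no called genotypes at any site")
        n_a = n[analyzed].astype(float)
        p_alt = alt[analyzed] / (2.0 * n_a)
        p_major = np.maximum(p_alt, 1.0 - p_alt)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = 2.0 * n_a / (2.0 * n_a - 1.0)
        he = 2.0 * p_alt * (1.0 - p_alt) * corr
        ho = het[analyzed] / n_a
        sum_he = he.sum()
        fis = 1.0 - ho.sum() / sum_he if sum_he > 0 else np.nan
        records.append(
            {
                "population": pop,
                "P": float(p_major.mean()),
                "pi": float(he.mean()),
                "Ho": float(ho.mean()),
                "He": float(he.mean()),
                "Fis": float(fis) if np.isfinite(fis) else np.nan,
                "n_sites": int(analyzed.sum()),
            }
        )
    return pd.DataFrame(records).set_index("population")


def _wc_components(n1, p1, h1, n2, p2, h2):
    """Weir–Cockerham (1984) variance components for two populations.

    All arguments are per-locus vectors: called diploid counts, alternate
    allele frequencies, and observed heterozygote fractions. Returns
    (a, b, c, usable) where `usable` marks loci entering the ratio of sums
    (both populations called, nbar > 1, polymorphic across the pair).
    """
    n1 = n1.astype(float)
    n2 = n2.astype(float)
    r = 2.0
    nbar = (n1 + n2) / r
    usable = (n1 >= 1) & (n2 >= 1) & (nbar > 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
    c = hbar / 2.0
    usable &= np.isfinite(pbar) & (pbar > 0) & (pbar < 1)
    return a, b, c, usable


def _fst_pair(G: GenotypeMatrix, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    n1, alt1, het1 = _pop_site_arrays(G, idx_a)
    n2, alt2, het2 = _pop_site_arrays(G, idx_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, alt1 / (2.0 * np.maximum(n1, 1)), np.nan)
        p2 = np.where(n2 > 0, alt2 / (2.0 * np.maximum(n2, 1)), np.nan)
        h1 = np.where(n1 > 0, het1 / np.maximum(n1, 1), np.nan)
        h2 = np.where(n2 > 0, het2 / np.maximum(n2, 1), np.nan)
    a, b, c, usable = _wc_components(n1, p1, h1, n2, p2, h2)
    if not usable.any():
        return np.nan
    denom = (a + b + c)[usable].sum()
    if denom == 0:
        return np.nan
    return float(a[usable].sum() / denom)


def pairwise_fst(G: GenotypeMatrix) -> PairMatrix:
    """Multi-locus Weir–Cockerham theta between all population pairs.

    Loci monomorphic across a pair are skipped for that pair. Raises if a
    pair shares no usable locus.
    """
    pops = G.pop_labels
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    idx = G.pop_indices()
    vals = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            f = _fst_pair(G, idx[pops[i]], idx[pops[j]])
            if np.isnan(f):
                raise ValueError(
                    f"populations {pops[i]!r} and {pops[j]!r} share no usable loci"
                )
            vals[i, j] = vals[j, i] = f
    return PairMatrix(list(pops), vals)


def fst_permutation_test(
    G: GenotypeMatrix, pop_a: str, pop_b: str, n_perm: int, seed: int
) -> float:
    """Permutation p-value for F_ST between two populations.

    Individuals are shuffled between the two populations (group sizes
    preserved) and theta recomputed each time;
    p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    if n_perm <= 0:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    idx = G.pop_indices()
    for p in (pop_a, pop_b):
        if p not in idx:
            raise ValueError(f"unknown population {p!r}")
    ia, ib = idx[pop_a], idx[pop_b]
    observed = _fst_pair(G, ia, ib)
    pool = np.concatenate([ia, ib])
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        f = _fst_pair(G, perm[: len(ia)], perm[len(ia):])
        if f >= observed:
            n_ge += 1
    return (1 + n_ge) / (n_perm + 1)
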