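"""Two-locus linkage disequilibrium from unphased diploid genotypes.

Haplotype frequencies are estimated by expectation-maximization over the
double-heterozygote phase ambiguity (the only genotype class whose gamete
content is not determined), then summarized as D, D' and r^2:

    D   = p_AB - p_A p_B
    D'  = |D| / D_max
    r^2 = D^2 / (p_A p_a p_B p_b)

where A/a are the two alleles at the first locus and B/b at the second.
This mirrors what Haploview computes for its pairwise LD display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, HET, HOM_A, HOM_B, NOCALL

HAPLOTYPES = ("AB", "Ab", "aB", "ab")


@dataclass(frozen=True)
class TwoLocusGenotypes:
    """3x3 genotype counts indexed (locus 1, locus 2), each axis
    homRef / het / homAlt; individuals with a no-call at either locus are
    excluded, so the grid sums to ``n``."""

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (3, 3) or (counts < 0).any():
            raise ValueError("counts must be a non-negative 3x3 grid")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_matrix(
        cls, m: GenotypeMatrix, snp_i: int | str, snp_j: int | str
    ) -> "TwoLocusGenotypes":
        """Tally a SNP pair from a genotype matrix, dropping individuals
        with a no-call at either locus (pairwise-complete)."""
        i = m.snp_map.index_of(snp_i) if isinstance(snp_i, str) else snp_i
        j = m.snp_map.index_of(snp_j) if isinstance(snp_j, str) else snp_j
        g1, g2 = m.calls[:, i], m.calls[:, j]
        ok = (g1 != NOCALL) & (g2 != NOCALL)
        counts = np.zeros((3, 3), dtype=np.int64)
        np.add.at(counts, (g1[ok], g2[ok]), 1)
        return cls(counts)


@dataclass(frozen=True)
class HaplotypeFreqs:
    """EM-estimated two-locus haplotype frequencies (sum to 1)."""

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    log_likelihood: float
    iterations: int
    converged: bool

    def as_array(self) -> np.ndarray:
        return np.array([self.p_AB, self.p_Ab, self.p_aB, self.p_ab])


def _log_likelihood(counts: np.ndarray, p: np.ndarray) -> float:
    pAB, pAb, paB, pab = p
    cell_probs = np.array(
        [
            [pAB**2, 2 * pAB * pAb, pAb**2],
            [2 * pAB * paB, 2 * (pAB * pab + pAb * paB), 2 * pAb * pab],
            [paB**2, 2 * paB * pab, pab**2],
        ]
    )
    mask = counts > 0
    with np.errstate(divide="ignore"):
        logs = np.log(cell_probs, where=mask, out=np.full((3, 3), -np.inf))
    return float((counts[mask] * logs[mask]).sum())


def em_haplotypes(
    g: TwoLocusGenotypes, tol: float = 1e-8, max_iter: int = 1000
) -> HaplotypeFreqs:
    """Maximum-likelihood haplotype frequencies by EM.

    Every genotype cell except the double heterozygote contributes gametes
    deterministically; the double heterozygote splits between the AB/ab and
    Ab/aB phases in proportion to their current probability.  Initialization
    is at linkage equilibrium (products of observed allele frequencies), so
    the estimate is deterministic.  Convergence: max frequency change < tol.
    """
    c = g.counts
    n = g.n
    if n == 0:
        raise ValueError("no individuals with calls at both loci")
    n_hap = 2 * n
    # fixed gamete counts from the eight unambiguous cells
    base = np.array(
        [
            2 * c[0, 0] + c[0, 1] + c[1, 0],          # AB
            2 * c[0, 2] + c[0, 1] + c[1, 2],          # Ab
            2 * c[2, 0] + c[1, 0] + c[2, 1],          # aB
            2 * c[2, 2] + c[2, 1] + c[1, 2],          # ab
        ],
        dtype=float,
    )
    dh = float(c[1, 1])  # double heterozygotes: 2*dh gametes of unknown phase
    # allele freqs are fixed by the data (each double het carries one of each)
    p_A = (2 * c[0, :].sum() + c[1, :].sum()) / n_hap
    p_B = (2 * c[:, 0].sum() + c[:, 1].sum()) / n_hap
    p = np.array(
        [p_A * p_B, p_A * (1 - p_B), (1 - p_A) * p_B, (1 - p_A) * (1 - p_B)]
    )
    iterations = 0
    converged = True if dh == 0 else False
    for iterations in range(1, max_iter + 1):
        cis = p[0] * p[3]
        trans = p[1] * p[2]
        w = 0.5 if cis + trans == 0 else cis / (cis + trans)
        counts = base + dh * np.array([w, 1 - w, 1 - w, w])
        new_p = counts / n_hap
        delta = float(np.abs(new_p - p).max())
        p = new_p
        if delta < tol:
            converged = True
            break
        if dh == 0:
            converged = True
            break
    return HaplotypeFreqs(
        p_AB=float(p[0]),
        p_Ab=float(p[1]),
        p_aB=float(p[2]),
        p_ab=float(p[3]),
        log_likelihood=_log_likelihood(c, p),
        iterations=iterations,
        converged=converged,
    )


@dataclass(frozen=True)
class LdStats:
    """Pairwise LD summary; ``defined`` is False (and the statistics NaN)
    when either locus is monomorphic, where LD is undefined rather than 0."""

    D: float
    D_prime: float
    r2: float
    defined: bool = True


def ld_stats(h: HaplotypeFreqs) -> LdStats:
    p = h.as_array()
    p_A = p[0] + p[1]
    p_B = p[0] + p[2]
    p_a, p_b = 1 - p_A, 1 - p_B
    if min(p_A, p_a, p_B, p_b) <= 0:
        return LdStats(math.nan, math.nan, math.nan, defined=False)
    D = p[0] - p_A * p_B
    d_max = min(p_A * p_b, p_a * p_B) if D >= 0 else min(p_A * p_B, p_a * p_b)
    d_prime = abs(D) / d_max if d_max > 0 else 0.0
    r2 = D * D / (p_A * p_a * p_B * p_b)
    return LdStats(D=float(D), D_prime=float(min(d_prime, 1.0)), r2=float(min(r2, 1.0)))


@dataclass(frozen=True)
class LdMatrix:
    """Symmetric pairwise LD grids over a SNP subset."""

    snp_names: tuple[str, ...]
    r2: np.ndarray
    d_prime: np.ndarray
    d: np.ndarray
    n: np.ndarray

    def pair(self, a: str, b: str) -> LdStats:
        i = self.snp_names.index(a)
        j = self.snp_names.index(b)
        defined = not math.isnan(self.r2[i, j])
        return LdStats(
            float(self.d[i, j]), float(self.d_prime[i, j]), float(self.r2[i, j]),
            defined=defined,
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table (snp_i, snp_j, n, D, Dprime, r2), upper triangle."""
        rows = []
        k = len(self.snp_names)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "snp_i": self.snp_names[i],
                        "snp_j": self.snp_names[j],
                        "n": int(self.n[i, j]),
                        "D": round(float(self.d[i, j]), 4),
                        "Dprime": round(float(self.d_prime[i, j]), 2),
                        "r2": round(float(self.r2[i, j]), 2),
                    }
                )
        return pd.DataFrame(rows)


def ld_matrix(m: GenotypeMatrix, snp_subset) -> LdMatrix:
    """Pairwise EM haplotype frequencies and LD statistics over a SNP set.

    Individuals missing either member of a pair are dropped pairwise.  The
    diagonal r^2 is 1 for polymorphic loci (NaN for monomorphic ones); the
    grids are symmetric by construction.
    """
    names = [str(s) for s in snp_subset]
    if len(names) < 2:
        raise ValueError("need at least 2 SNPs for pairwise LD")
    indices = [m.snp_map.index_of(name) for name in names]
    k = len(names)
    r2 = np.full((k, k), np.nan)
    d_prime = np.full((k, k), np.nan)
    d = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        col = m.calls[:, indices[i]]
        called = col[col != NOCALL]
        poly = len(called) > 0 and (called != called[0]).any()
        r2[i, i] = 1.0 if poly else np.nan
        d_prime[i, i] = 1.0 if poly else np.nan
        d[i, i] = np.nan
        n[i, i] = len(called)
    for i in range(k):
        for j in range(i + 1, k):
            g = TwoLocusGenotypes.from_matrix(m, indices[i], indices[j])
            stats = ld_stats(em_haplotypes(g))
            for grid, value in ((r2, stats.r2), (d_prime, stats.D_prime), (d, stats.D)):
                grid[i, j] = grid[j, i] = value
            n[i, j] = n[j, i] = g.n
    return LdMatrix(tuple(names), r2, d_prime, d, n)
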