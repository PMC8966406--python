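"""Genome map construction, meiosis, and recurrent mutation.

The genome is a set of autosomes with loci addressed purely by genetic
position (centimorgans); there are no base-pair coordinates.  Each locus is
biallelic (alleles 0/1) and plays one of two roles: neutral marker or causal
QTL.  Haplotypes are dense ``uint8`` arrays in map order, and every consumer
of genotypes (relationship matrices, file writers, trait models) relies on
that single locus ordering.

Recombination follows a stationary gamma renewal (chiasma interference)
process: inter-crossover distances on a chromosome are i.i.d.
Gamma(shape=nu, scale=1/nu) in Morgans, so the expected crossover count
equals the map length in Morgans for every ``nu``, and ``nu = 1`` reduces to
a Poisson (no-interference) process.  Larger ``nu`` gives more regularly
spaced crossovers, i.e. positive interference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "GenomeMap",
    "build_genome_map",
    "sample_gamete",
    "sample_gametes",
    "apply_mutation",
    "expected_heterozygosity",
]

MARKER = 0
QTL = 1


@dataclass(frozen=True)
class GenomeMap:
    """Ordered biallelic loci on a multi-chromosome genetic map.

    Parameters
    ----------
    chrom_lengths : ndarray of float
        Length of each chromosome in centimorgans.
    chrom : ndarray of int
        0-based chromosome index of each locus, non-decreasing.
    pos_cM : ndarray of float
        Genetic position of each locus, strictly increasing within a
        chromosome and contained in ``[0, length)``.
    is_qtl : ndarray of bool
        Role flag per locus (True = QTL, False = marker).
    """

    chrom_lengths: np.ndarray
    chrom: np.ndarray
    pos_cM: np.ndarray
    is_qtl: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.chrom_lengths, dtype=float)
        chrom = np.asarray(self.chrom, dtype=np.int32)
        pos = np.asarray(self.pos_cM, dtype=float)
        is_qtl = np.asarray(self.is_qtl, dtype=bool)
        if lengths.ndim != 1 or np.any(lengths <= 0):
            raise ValueError("chromosome lengths must be positive")
        if not (chrom.shape == pos.shape == is_qtl.shape):
            raise ValueError("locus arrays must have identical shape")
        if chrom.size:
            if chrom.min() < 0 or chrom.max() >= lengths.size:
                raise ValueError("locus chromosome index out of range")
            order = np.lexsort((pos, chrom))
            if not np.array_equal(order, np.arange(chrom.size)):
                raise ValueError("loci must be sorted by (chromosome, position)")
            for c in np.unique(chrom):
                p = pos[chrom == c]
                if np.any(np.diff(p) <= 0):
                    raise ValueError("positions must be strictly increasing")
                if p[0] < 0 or p[-1] >= lengths[c]:
                    raise ValueError("locus position outside [0, chrom length)")
        object.__setattr__(self, "chrom_lengths", lengths)
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos_cM", pos)
        object.__setattr__(self, "is_qtl", is_qtl)

    # -- derived views ---------------------------------------------------
    @property
    def n_loci(self) -> int:
        return self.pos_cM.size

    @property
    def n_chrom(self) -> int:
        return self.chrom_lengths.size

    @property
    def total_length_cM(self) -> float:
        return float(self.chrom_lengths.sum())

    @property
    def n_markers(self) -> int:
        return int((~self.is_qtl).sum())

    @property
    def n_qtl(self) -> int:
        return int(self.is_qtl.sum())

    @property
    def marker_index(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    @property
    def qtl_index(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    def locus_ids(self) -> np.ndarray:
        """Stable locus identifiers: M<i> for markers, Q<i> for QTLs."""
        ids = np.empty(self.n_loci, dtype=object)
        ids[self.marker_index] = [f"M{i + 1}" for i in range(self.n_markers)]
        ids[self.qtl_index] = [f"Q{i + 1}" for i in range(self.n_qtl)]
        return ids

    def chrom_slices(self) -> list[slice]:
        """Contiguous locus slice for every chromosome (may be empty)."""
        bounds = np.searchsorted(self.chrom, np.arange(self.n_chrom + 1))
        return [slice(bounds[c], bounds[c + 1]) for c in range(self.n_chrom)]

    def subset(self, locus_idx: np.ndarray) -> "GenomeMap":
        """New map keeping the given (sorted) locus indices."""
        locus_idx = np.sort(np.asarray(locus_idx, dtype=np.int64))
        return GenomeMap(
            chrom_lengths=self.chrom_lengths,
            chrom=self.chrom[locus_idx],
            pos_cM=self.pos_cM[locus_idx],
            is_qtl=self.is_qtl[locus_idx],
        )


def build_genome_map(
    chrom_lengths_cM,
    n_markers: int,
    n_qtl: int,
    rng: np.random.Generator,
) -> GenomeMap:
    """Place markers and QTLs uniformly at random on a multi-chromosome map.

    Each locus lands uniformly over the total map length, so a chromosome
    receives loci with probability proportional to its length.  Roles are
    interleaved at random: exactly ``n_qtl`` of the placed loci become QTLs.
    """
    lengths = np.asarray(chrom_lengths_cM, dtype=float)
    if lengths.ndim != 1 or lengths.size == 0 or np.any(lengths <= 0):
        raise ValueError("chromosome lengths must be a non-empty positive list")
    if n_markers < 0 or n_qtl < 0:
        raise ValueError("marker and QTL counts must be non-negative")
    n = n_markers + n_qtl
    edges = np.concatenate([[0.0], np.cumsum(lengths)])
    total = edges[-1]
    # rejection loop guarantees strictly distinct positions
    u = rng.uniform(0.0, total, size=n)
    while np.unique(u).size < n:
        u = np.unique(u)
        u = np.concatenate([u, rng.uniform(0.0, total, size=n - u.size)])
    u.sort()
    chrom = np.searchsorted(edges, u, side="right") - 1
    chrom = np.clip(chrom, 0, lengths.size - 1).astype(np.int32)
    pos = u - edges[chrom]
    is_qtl = np.zeros(n, dtype=bool)
    if n_qtl:
        is_qtl[rng.choice(n, size=n_qtl, replace=False)] = True
    return GenomeMap(lengths, chrom, pos, is_qtl)


def _crossover_points(
    n_gametes: int,
    n_chrom: int,
    max_length_M: float,
    nu: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary gamma renewal points per (gamete, chromosome), sorted.

    Unit crossover rate in Morgans: the first point is a forward recurrence
    time sampled as U * Gamma(nu + 1, 1/nu), subsequent gaps Gamma(nu, 1/nu).
    Enough points are drawn that the last one passes ``max_length_M``.
    """
    k = int(np.ceil(max_length_M + 6.0 * np.sqrt((max_length_M + 1.0) / min(nu, 1.0)) + 6.0))
    gaps = rng.gamma(nu, 1.0 / nu, size=(n_gametes, n_chrom, k))
    gaps[:, :, 0] = rng.random((n_gametes, n_chrom)) * rng.gamma(
        nu + 1.0, 1.0 / nu, size=(n_gametes, n_chrom))
    points = np.cumsum(gaps, axis=2)
    while np.any(points[:, :, -1] <= max_length_M):  # pragma: no cover - rare tail
        extra = np.cumsum(
            rng.gamma(nu, 1.0 / nu, size=(n_gametes, n_chrom, 4)), axis=2)
        points = np.concatenate([points, points[:, :, -1:] + extra], axis=2)
    return points


@njit(cache=True)
def _meiosis_kernel(haps, parent_idx, bounds, pos_M, pts, init,
                    out):  # pragma: no cover - numba kernel
    B = parent_idx.size
    C = bounds.size - 1
    k = pts.shape[2]
    for g in range(B):
        p = parent_idx[g]
        for c in range(C):
            strand = init[g, c]
            ptr = 0
            for l in range(bounds[c], bounds[c + 1]):
                x = pos_M[l]
                while ptr < k and pts[g, c, ptr] <= x:
                    ptr += 1
                    strand ^= 1
                out[g, l] = haps[p, strand, l]


def sample_gametes(
    haplotypes: np.ndarray,
    parent_idx: np.ndarray,
    gmap: GenomeMap,
    interference: float,
    rng: np.random.Generator,
    chunk: int = 4096,
) -> np.ndarray:
    """Vectorised meiosis: one gamete per entry of ``parent_idx``.

    Crossovers on every chromosome follow the stationary gamma renewal
    process; the starting strand is chosen with probability 1/2 per
    chromosome.  Renewal points and initial strands are drawn from ``rng``
    in bulk; a compiled two-pointer sweep assembles the gametes.

    Parameters
    ----------
    haplotypes : ndarray, shape (n_individuals, 2, n_loci)
    parent_idx : ndarray of int, shape (B,)
        Which individual each gamete comes from (repeats allowed).
    interference : float
        Gamma renewal shape; must be > 0.

    Returns
    -------
    ndarray of uint8, shape (B, n_loci)
    """
    if interference <= 0:
        raise ValueError("interference must be > 0")
    parent_idx = np.asarray(parent_idx, dtype=np.int64)
    B = parent_idx.size
    L = gmap.n_loci
    out = np.empty((B, L), dtype=np.uint8)
    if L == 0 or B == 0:
        return out
    C = gmap.n_chrom
    pos_M = gmap.pos_cM / 100.0
    bounds = np.searchsorted(gmap.chrom, np.arange(C + 1)).astype(np.int64)
    max_len = float(gmap.chrom_lengths.max()) / 100.0
    for start in range(0, B, chunk):
        sel = parent_idx[start : start + chunk]
        b = sel.size
        pts = _crossover_points(b, C, max_len, interference, rng)
        init = rng.integers(0, 2, size=(b, C)).astype(np.int64)
        _meiosis_kernel(haplotypes, sel, bounds, pos_M, pts, init,
                        out[start : start + b])
    return out


def sample_gamete(
    parent: np.ndarray,
    gmap: GenomeMap,
    interference: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single meiosis from one parent's ``(2, n_loci)`` haplotype pair."""
    parent = np.asarray(parent, dtype=np.uint8)
    if parent.shape != (2, gmap.n_loci):
        raise ValueError("parent haplotypes do not match the map")
    return sample_gametes(parent[None, :, :], np.zeros(1, dtype=np.int64), gmap, interference, rng)[0]


def apply_mutation(
    haplotypes: np.ndarray,
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Recurrent two-allele mutation: flip each site independently.

    Works in place on any array of 0/1 alleles (a single haplotype, a gamete
    batch, or a whole population block) and also returns it.  The flip set is
    sampled exactly: a Binomial draw for the number of flips, then a uniform
    subset of sites — the conditional law of independent per-site flips.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must be in [0, 1]")
    n = haplotypes.size
    if rate == 0.0 or n == 0:
        return haplotypes
    n_flip = int(rng.binomial(n, rate))
    if n_flip:
        flat = haplotypes.reshape(-1)
        if n_flip > n // 4:
            idx = rng.permutation(n)[:n_flip]
        else:
            # rejection sampling of a uniform n_flip-subset (n_flip << n)
            idx = np.unique(rng.integers(0, n, size=n_flip))
            while idx.size < n_flip:
                extra = rng.integers(0, n, size=2 * (n_flip - idx.size))
                idx = np.unique(np.concatenate([idx, extra]))
            if idx.size > n_flip:
                idx = rng.choice(idx, size=n_flip, replace=False)
        flat[idx] ^= 1
    return haplotypes


def expected_heterozygosity(haplotypes: np.ndarray) -> float:
    """Mean 2pq across loci for a population haplotype block (n, 2, L)."""
    p = haplotypes.mean(axis=(0, 1))
    return float(np.mean(2.0 * p * (1.0 - p)))
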