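"""NK fitness landscapes with brute-force oracles for small instances.

The NK model defines a tunably rugged fitness function over length-``N``
sequences drawn from an alphabet of size ``A``.  Each site ``i`` contributes
a fitness component that depends on its own symbol and the symbols at ``K``
epistatic neighbor sites; total fitness is the mean of the ``N`` components.
``K = 0`` gives a separable (single-peaked) landscape, ``K = N - 1`` the
maximally rugged house-of-cards limit, whose expected number of local optima
for a binary alphabet is ``2^N / (N + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NKLandscape",
    "make_landscape",
    "gene_fitness",
    "cell_fitness",
    "enumerate_optimum",
    "count_local_optima",
]

_MAX_ENUM = 2**20


@dataclass(frozen=True)
class NKLandscape:
    """A seeded NK landscape: neighborhoods plus per-site component tables.

    ``neighbors[i]`` lists the K other sites whose symbols the component at
    site i depends on; ``tables[i]`` has ``A**(K+1)`` i.i.d. Uniform(0,1)
    entries indexed by the (K+1)-tuple (own symbol first) encoded in base A.
    The whole object regenerates identically from ``(N, K, A, seed)``.
    """

    N: int
    K: int
    A: int
    seed: int
    neighbors: np.ndarray = field(repr=False)  # (N, K) int
    tables: np.ndarray = field(repr=False)  # (N, A**(K+1)) float in [0,1]
    adjacent: bool = False


def make_landscape(N: int, K: int, A: int = 2, seed: int = 0, *, adjacent: bool = False) -> NKLandscape:
    """Draw a seeded NK landscape.

    Neighborhoods are drawn uniformly without replacement per site (the
    general random-neighborhood form); ``adjacent=True`` instead uses the K
    sites following i cyclically.  Table entries are i.i.d. Uniform(0,1).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= K <= N - 1:
        raise ValueError(f"K must satisfy 0 <= K <= N-1, got K={K}, N={N}")
    if A < 2:
        raise ValueError("alphabet size A must be >= 2")
    rng = np.random.default_rng(seed)
    if adjacent:
        neighbors = (np.arange(N)[:, None] + np.arange(1, K + 1)[None, :]) % N
        neighbors = neighbors.reshape(N, K)
    else:
        neighbors = np.empty((N, K), dtype=np.int64)
        for i in range(N):
            others = np.delete(np.arange(N), i)
            neighbors[i] = rng.choice(others, size=K, replace=False)
    tables = rng.uniform(0.0, 1.0, size=(N, A ** (K + 1)))
    return NKLandscape(N=N, K=K, A=A, seed=seed, neighbors=neighbors.astype(np.int64),
                       tables=tables, adjacent=adjacent)


def _component_indices(land: NKLandscape, genes: np.ndarray) -> np.ndarray:
    """Base-A encode each site's (own, neighbors...) tuple, own-site first.

    ``genes``: (..., N) integer array; returns (..., N) indices into tables.
    """
    A = land.A
    # own symbol carries the highest place value, then neighbors in order
    idx = genes.astype(np.int64) * A**land.K
    if land.K > 0:
        nb = genes[..., land.neighbors]  # (..., N, K)
        weights = A ** np.arange(land.K - 1, -1, -1, dtype=np.int64)
        idx = idx + (nb * weights).sum(axis=-1)
    return idx


def gene_fitness(land: NKLandscape, genes: np.ndarray) -> np.ndarray | float:
    """Mean of the N fitness components of one genotype (or a stack of them).

    ``genes`` may be a single length-N vector or any (..., N) stack; the
    result has shape (...,).  Values lie in [0, 1].
    """
    genes = np.asarray(genes)
    if genes.shape[-1] != land.N:
        raise ValueError(f"genotype length {genes.shape[-1]} != N={land.N}")
    if genes.min() < 0 or genes.max() >= land.A:
        raise ValueError("genotype symbol outside alphabet [0, A)")
    idx = _component_indices(land, genes)
    comps = np.take_along_axis(
        np.broadcast_to(land.tables, idx.shape[:-1] + land.tables.shape),
        idx[..., None], axis=-1,
    )[..., 0] if idx.ndim > 1 else land.tables[np.arange(land.N), idx]
    f = comps.mean(axis=-1)
    return float(f) if f.ndim == 0 else f


def cell_fitness(land: NKLandscape, genes: np.ndarray) -> np.ndarray | float:
    """Fitness of a multi-gene cell: arithmetic mean of its genes' fitnesses.

    ``genes``: (..., G, N) stack; returns (...,).  With G = 1 this equals
    ``gene_fitness`` and it is invariant to gene order.
    """
    genes = np.asarray(genes)
    if genes.ndim < 2:
        raise ValueError("cell genotypes need shape (..., G, N)")
    return np.asarray(gene_fitness(land, genes)).mean(axis=-1)


def _all_genotypes(land: NKLandscape) -> np.ndarray:
    """All A**N genotypes as an (A**N, N) array, row r = base-A digits of r."""
    size = land.A**land.N
    if size > _MAX_ENUM:
        raise ValueError(f"instance too large to enumerate: A^N = {size} > {_MAX_ENUM}")
    r = np.arange(size, dtype=np.int64)
    place = land.A ** np.arange(land.N - 1, -1, -1, dtype=np.int64)
    return (r[:, None] // place) % land.A


def enumerate_optimum(land: NKLandscape) -> tuple[np.ndarray, float]:
    """Exhaustive global optimum ``(genotype, fitness)``; requires A^N <= 2^20."""
    genos = _all_genotypes(land)
    fit = gene_fitness(land, genos)
    best = int(np.argmax(fit))
    return genos[best].copy(), float(fit[best])


def count_local_optima(land: NKLandscape) -> int:
    """Number of genotypes no single-site substitution of which increases fitness."""
    genos = _all_genotypes(land)
    fit = gene_fitness(land, genos)
    size = genos.shape[0]
    place = land.A ** np.arange(land.N - 1, -1, -1, dtype=np.int64)
    is_opt = np.ones(size, dtype=bool)
    base = np.arange(size, dtype=np.int64)
    for i in range(land.N):
        cur = genos[:, i]
        for s in range(land.A):
            mut = base + (s - cur) * place[i]
            # s == cur gives mut == base; a self-comparison never disqualifies
            is_opt &= fit[mut] <= fit
    return int(is_opt.sum())
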