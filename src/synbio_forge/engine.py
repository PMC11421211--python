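"""Reproducible randomness and batched execution shared by all simulators.

Every stochastic operation in this package takes an explicit :class:`RngKey`;
there is no hidden global RNG state.  Keys are *splittable*: a child stream is
a deterministic function of the parent key and a child index (a counter-based
discipline), so replicate ``i`` of a batch draws the same numbers whether the
batch has 4 or 4000 members, and a whole run is reproducible from one root
seed.

The key words are mixed with the splitmix64 finalizer, whose 64-bit output is
a bijection of its input: children of one parent are pairwise distinct by
construction.  Draws come from numpy's counter-based Philox bit generator
keyed on the 128-bit key value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

__all__ = ["RngKey", "split_key", "batch_map"]

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)


def _splitmix64(x: np.ndarray | np.uint64) -> np.ndarray | np.uint64:
    """splitmix64 finalizer; bijective on uint64 (scalar or array)."""
    z = np.asarray(x, dtype=np.uint64) + _GOLDEN
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    z = z ^ (z >> np.uint64(31))
    return z if isinstance(x, np.ndarray) else np.uint64(z)


def _child_words(w0: np.uint64, w1: np.uint64, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized child-key derivation for child indices ``idx`` (uint64 array).

    The first word is splitmix64(w0 ^ splitmix64(w1 + i)); both inner maps are
    injective in i for fixed (w0, w1), so children are pairwise distinct.
    """
    idx = idx.astype(np.uint64)
    with np.errstate(over="ignore"):
        h = _splitmix64(w1 + idx)
        c0 = _splitmix64(w0 ^ h)
        c1 = _splitmix64(w1 ^ _splitmix64(w0 + idx) ^ _GOLDEN)
    return c0, c1


@dataclass(frozen=True)
class RngKey:
    """A splittable random key identified by its seed path.

    Parameters
    ----------
    word0, word1
        128 bits of key material (two uint64 words).
    seed_path
        The ordered sequence of child indices (root seed first) that produced
        this key.  Two keys with the same seed path are identical.
    """

    word0: int
    word1: int
    seed_path: tuple[int, ...] = field(default=())

    @classmethod
    def from_seed(cls, seed: int) -> "RngKey":
        if seed < 0:
            raise ValueError("seed must be non-negative")
        s = np.uint64(seed & 0xFFFFFFFFFFFFFFFF)
        with np.errstate(over="ignore"):
            w0 = _splitmix64(s)
            w1 = _splitmix64(s ^ _GOLDEN)
        return cls(int(w0), int(w1), (int(seed),))

    @property
    def value(self) -> int:
        """128-bit key value used to key the Philox counter-based generator."""
        return (int(self.word1) << 64) | int(self.word0)

    def generator(self) -> np.random.Generator:
        """A fresh numpy Generator for this key's stream."""
        return np.random.Generator(np.random.Philox(key=self.value))

    def split(self, n: int) -> list["RngKey"]:
        return split_key(self, n)

    def child(self, i: int) -> "RngKey":
        """Single child key; ``key.child(i) == split_key(key, n)[i]`` for i < n."""
        c0, c1 = _child_words(np.uint64(self.word0), np.uint64(self.word1), np.asarray([i]))
        return RngKey(int(c0[0]), int(c1[0]), self.seed_path + (int(i),))


def split_key(key: RngKey, n: int) -> list[RngKey]:
    """Split ``key`` into ``n`` pairwise-distinct child keys.

    Deterministic in ``key``; ``n`` is not part of the derivation, so child
    ``i`` is the same for every ``n`` (replicate streams are prefix-stable
    across batch sizes).
    """
    if n < 1:
        raise ValueError(f"cannot split a key into n={n} children (need n >= 1)")
    c0, c1 = _child_words(np.uint64(key.word0), np.uint64(key.word1), np.arange(n, dtype=np.uint64))
    return [
        RngKey(int(c0[i]), int(c1[i]), key.seed_path + (i,))
        for i in range(n)
    ]


def _leading_size(x: Any) -> int:
    if isinstance(x, np.ndarray):
        if x.ndim == 0:
            raise ValueError("batched inputs must have a leading batch axis")
        return x.shape[0]
    return len(x)


def batch_map(op: Callable[..., Any], *inputs: Any) -> Any:
    """Apply a pure operation element-wise along a shared leading batch axis.

    Output row ``i`` equals ``op(inputs row i)``; by construction batched
    evaluation equals the loop of scalar calls (the batch-equals-loop
    contract).  Array outputs are stacked; other outputs are returned as a
    list.  Ragged leading sizes raise a shape error.
    """
    if not inputs:
        raise ValueError("batch_map needs at least one batched input")
    sizes = [_leading_size(x) for x in inputs]
    if len(set(sizes)) != 1:
        raise ValueError(f"ragged batch: inconsistent leading sizes {sizes}")
    out = [op(*(x[i] for x in inputs)) for i in range(sizes[0])]
    if out and all(isinstance(o, np.ndarray) for o in out):
        return np.stack(out)
    if out and all(np.isscalar(o) or isinstance(o, (int, float, np.generic)) for o in out):
        return np.asarray(out)
    return out
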