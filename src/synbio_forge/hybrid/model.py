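"""Hybrid stochastic/deterministic model definitions.

A :class:`HybridModel` partitions its species into a *stochastic* set
(discrete molecule counts advanced by tau-leaping) and a *deterministic* set
(continuous levels advanced by forward Euler).  Reactions change only
stochastic species; their propensities — and the deterministic drift — may
read the full state, which is how the two partitions couple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = ["Reaction", "HybridModel", "HybridState", "ModelDefinitionError"]


class ModelDefinitionError(ValueError):
    """A reaction produced a negative or non-finite propensity."""


@dataclass(frozen=True)
class Reaction:
    """One reaction channel: a stoichiometric change plus a propensity rule.

    ``stoich`` maps stochastic species names to integer count changes;
    ``propensity(full_state, params)`` must broadcast over a leading batch
    axis of ``full_state`` (shape ``(..., D)``) and return a rate in 1/time,
    non-negative for every valid state and zero whenever a consumed species
    is exhausted.
    """

    name: str
    stoich: Mapping[str, int]
    propensity: Callable[[np.ndarray, Mapping[str, float]], np.ndarray]


@dataclass(frozen=True)
class HybridModel:
    species_names: tuple[str, ...]
    stoch_idx: np.ndarray
    det_idx: np.ndarray
    reactions: tuple[Reaction, ...]
    drift: Callable[[np.ndarray, Mapping[str, float]], np.ndarray]
    params: Mapping[str, float]
    propensity_fn: Callable[[np.ndarray, Mapping[str, float]], np.ndarray] | None = None
    stoich_matrix: np.ndarray = field(init=False, repr=False)  # (R, n_stoch)

    def __post_init__(self):
        stoch = np.asarray(self.stoch_idx, dtype=np.int64)
        det = np.asarray(self.det_idx, dtype=np.int64)
        D = len(self.species_names)
        if set(stoch) & set(det):
            raise ValueError("stoch_idx and det_idx must be disjoint")
        if sorted(set(stoch) | set(det)) != list(range(D)):
            raise ValueError("stoch_idx ∪ det_idx must cover all species exactly once")
        name_to_stoch_col = {self.species_names[s]: c for c, s in enumerate(stoch)}
        S = np.zeros((len(self.reactions), len(stoch)), dtype=np.int64)
        for r, rxn in enumerate(self.reactions):
            for sp, change in rxn.stoich.items():
                if sp not in name_to_stoch_col:
                    raise ValueError(
                        f"reaction {rxn.name!r} touches non-stochastic species {sp!r}"
                    )
                S[r, name_to_stoch_col[sp]] = change
        object.__setattr__(self, "stoch_idx", stoch)
        object.__setattr__(self, "det_idx", det)
        object.__setattr__(self, "stoich_matrix", S)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def propensities(self, full_state: np.ndarray) -> np.ndarray:
        """All reaction propensities at ``full_state``; shape ``(..., R)``.

        Uses the model's fused ``propensity_fn`` when provided (it must equal
        the per-reaction rules stacked in definition order), else stacks the
        per-reaction callables.
        """
        if not self.reactions:
            return np.zeros(full_state.shape[:-1] + (0,))
        if self.propensity_fn is not None:
            return np.asarray(self.propensity_fn(full_state, self.params))
        rates = [np.broadcast_to(np.asarray(r.propensity(full_state, self.params), dtype=float),
                                 full_state.shape[:-1])
                 for r in self.reactions]
        return np.stack(rates, axis=-1)

    def validate_propensities(self, a: np.ndarray, t: float) -> None:
        bad = ~np.isfinite(a) | (a < 0)
        if bad.any():
            r = int(np.argwhere(bad)[0][-1])
            raise ModelDefinitionError(
                f"reaction {self.reactions[r].name!r} has invalid propensity at t={t:g}"
            )


@dataclass
class HybridState:
    """Counts over the stochastic partition, levels over the deterministic one."""

    counts: np.ndarray  # (n_stoch,) non-negative
    levels: np.ndarray  # (n_det,) finite
    t: float = 0.0

    def full(self, model: HybridModel) -> np.ndarray:
        x = np.zeros(model.n_species)
        x[model.stoch_idx] = self.counts
        x[model.det_idx] = self.levels
        return x

    @classmethod
    def from_full(cls, model: HybridModel, full: np.ndarray, t: float) -> "HybridState":
        return cls(counts=full[model.stoch_idx].copy(), levels=full[model.det_idx].copy(), t=t)
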