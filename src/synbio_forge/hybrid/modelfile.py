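"""YAML dialect for user-defined hybrid models, with a schema check.

Example::

    species:
      - {name: M, kind: stochastic}
      - {name: R, kind: deterministic}
    params: {k_tx: 40.0, d_m: 0.5}
    reactions:
      - name: transcription
        stoich: {M: +1}
        rate: {law: constant, k: k_tx}
      - name: decay
        stoich: {M: -1}
        rate: {law: mass_action, k: d_m, reactants: {M: 1}}
    drift:
      R:
        - {law: constant, k: 0.05}
        - {law: linear, k: -0.1, species: R}

Rate laws: ``constant`` (k), ``mass_action`` (k·Π falling products, e.g.
x(x−1)/2 for order 2), ``hill_activation`` / ``hill_repression``
(k·x^n/(K^n+x^n) and k·K^n/(K^n+x^n)).  ``k``/``K``/``n`` may be numbers or
names from the top-level ``params`` map.  Drift entries are summed per
deterministic species; ``linear`` is k·x of the named species.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .model import HybridModel, HybridState, Reaction

__all__ = ["load_model", "ModelFileError"]


class ModelFileError(ValueError):
    """The model file violates the documented schema."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ModelFileError(msg)


def _resolve(value: Any, params: Mapping[str, float], ctx: str) -> float:
    if isinstance(value, str):
        _require(value in params, f"{ctx}: unknown parameter name {value!r}")
        return float(params[value])
    _require(isinstance(value, (int, float)), f"{ctx}: expected number or parameter name")
    return float(value)


def _falling(x: np.ndarray, order: int) -> np.ndarray:
    """x(x−1)…(x−order+1)/order!: combinatorial mass-action factor."""
    out = np.ones_like(x)
    for i in range(order):
        out = out * np.maximum(x - i, 0.0)
    return out / _fact(order)


def _fact(n: int) -> float:
    f = 1.0
    for i in range(2, n + 1):
        f *= i
    return f


def _make_rate(spec: Mapping, params: Mapping[str, float], index: Mapping[str, int], ctx: str):
    _require(isinstance(spec, Mapping) and "law" in spec, f"{ctx}: rate needs a 'law' key")
    law = spec["law"]
    if law == "constant":
        k = _resolve(spec.get("k", 1.0), params, ctx)
        return lambda x, p: np.broadcast_to(k, x.shape[:-1]).astype(float)
    if law == "mass_action":
        k = _resolve(spec.get("k", 1.0), params, ctx)
        reactants = spec.get("reactants", {})
        _require(isinstance(reactants, Mapping) and reactants,
                 f"{ctx}: mass_action needs a non-empty 'reactants' map")
        pairs = []
        for sp, order in reactants.items():
            _require(sp in index, f"{ctx}: unknown species {sp!r}")
            _require(isinstance(order, int) and order >= 1, f"{ctx}: order must be int >= 1")
            pairs.append((index[sp], int(order)))

        def rate(x, p, pairs=tuple(pairs), k=k):
            out = np.full(x.shape[:-1], k)
            for col, order in pairs:
                out = out * _falling(x[..., col], order)
            return out

        return rate
    if law in ("hill_activation", "hill_repression"):
        k = _resolve(spec.get("k", 1.0), params, ctx)
        K = _resolve(spec.get("K", 1.0), params, ctx)
        n = _resolve(spec.get("n", 1.0), params, ctx)
        sp = spec.get("species")
        _require(sp in index, f"{ctx}: unknown species {sp!r}")
        col = index[sp]
        act = law == "hill_activation"

        def rate(x, p, col=col, k=k, K=K, n=n, act=act):
            xv = np.maximum(x[..., col], 0.0)
            a = xv**n / (K**n + xv**n)
            return k * (a if act else 1.0 - a)

        return rate
    raise ModelFileError(f"{ctx}: unknown rate law {law!r}")


def _make_drift_term(spec: Mapping, params, index, ctx: str):
    law = spec.get("law")
    if law == "constant":
        k = _resolve(spec.get("k", 0.0), params, ctx)
        return lambda x, p: np.broadcast_to(k, x.shape[:-1]).astype(float)
    if law == "linear":
        k = _resolve(spec.get("k", 0.0), params, ctx)
        sp = spec.get("species")
        _require(sp in index, f"{ctx}: unknown species {sp!r}")
        col = index[sp]
        return lambda x, p, col=col, k=k: k * x[..., col]
    if law in ("hill_activation", "hill_repression", "mass_action"):
        return _make_rate(spec, params, index, ctx)
    raise ModelFileError(f"{ctx}: unknown drift law {law!r}")


def load_model(path: str | Path) -> tuple[HybridModel, HybridState]:
    """Parse and validate a hybrid-model file.

    Returns the model plus its initial state (species missing from the
    optional ``initial`` map start at zero).
    """
    raw = yaml.safe_load(Path(path).read_text())
    _require(isinstance(raw, Mapping), "model file must be a mapping")
    unknown = set(raw) - {"species", "params", "reactions", "drift", "initial"}
    _require(not unknown, f"unknown top-level key(s): {sorted(unknown)}")
    species = raw.get("species")
    _require(isinstance(species, list) and species, "'species' must be a non-empty list")
    names, kinds = [], []
    for i, sp in enumerate(species):
        _require(isinstance(sp, Mapping) and "name" in sp and "kind" in sp,
                 f"species[{i}] needs 'name' and 'kind'")
        _require(sp["kind"] in ("stochastic", "deterministic"),
                 f"species[{i}]: kind must be 'stochastic' or 'deterministic'")
        names.append(str(sp["name"]))
        kinds.append(sp["kind"])
    _require(len(set(names)) == len(names), "duplicate species names")
    index = {n: i for i, n in enumerate(names)}
    params = raw.get("params", {}) or {}
    _require(isinstance(params, Mapping), "'params' must be a mapping")
    params = {str(k): float(v) for k, v in params.items()}

    stoch_names = {n for n, k in zip(names, kinds) if k == "stochastic"}
    reactions = []
    for i, r in enumerate(raw.get("reactions", []) or []):
        ctx = f"reactions[{i}]"
        _require(isinstance(r, Mapping) and "stoich" in r and "rate" in r,
                 f"{ctx}: needs 'stoich' and 'rate'")
        name = str(r.get("name", f"r{i}"))
        stoich = r["stoich"]
        _require(isinstance(stoich, Mapping) and stoich, f"{ctx}: empty stoich")
        for sp in stoich:
            _require(sp in index, f"{ctx}: unknown species {sp!r}")
            _require(sp in stoch_names, f"{ctx}: stoichiometry touches deterministic species {sp!r}")
        reactions.append(Reaction(name, {str(k): int(v) for k, v in stoich.items()},
                                  _make_rate(r["rate"], params, index, ctx)))

    drift_spec = raw.get("drift", {}) or {}
    _require(isinstance(drift_spec, Mapping), "'drift' must be a mapping")
    det_names = [n for n, k in zip(names, kinds) if k == "deterministic"]
    for sp in drift_spec:
        _require(sp in det_names, f"drift: {sp!r} is not a deterministic species")
    terms_per_det = []
    for n in det_names:
        terms = drift_spec.get(n, []) or []
        _require(isinstance(terms, list), f"drift[{n}] must be a list of terms")
        terms_per_det.append([
            _make_drift_term(t, params, index, f"drift[{n}][{j}]")
            for j, t in enumerate(terms)
        ])

    def drift(x, p):
        cols = []
        for terms in terms_per_det:
            acc = np.zeros(x.shape[:-1])
            for term in terms:
                acc = acc + term(x, p)
            cols.append(acc)
        if not cols:
            return np.zeros(x.shape[:-1] + (0,))
        return np.stack(cols, axis=-1)

    model = HybridModel(
        species_names=tuple(names),
        stoch_idx=np.array([i for i, k in enumerate(kinds) if k == "stochastic"], dtype=np.int64),
        det_idx=np.array([i for i, k in enumerate(kinds) if k == "deterministic"], dtype=np.int64),
        reactions=tuple(reactions),
        drift=drift,
        params=params,
    )
    initial = raw.get("initial", {}) or {}
    _require(isinstance(initial, Mapping), "'initial' must be a mapping")
    full = np.zeros(len(names))
    for sp, v in initial.items():
        _require(sp in index, f"initial: unknown species {sp!r}")
        full[index[sp]] = float(v)
    x0 = HybridState.from_full(model, full, t=0.0)
    return model, x0
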