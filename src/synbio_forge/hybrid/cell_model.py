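"""Bundled resource-aware coarse-grained cell model.

A host cell expresses three native gene classes — metabolic, ribosomal and
housekeeping — alongside two synthetic circuit genes.  All five compete for
the same ribosome pool, energy supply and charged tRNA, so circuit load feeds
back on host physiology (the growth-law coupling).  External conditions are
the nutrient density of the medium and an optional antibiotic that
inactivates ribosomes.

Partition (17 species):

* 11 stochastic (discrete counts, tau-leaped): the five mRNAs, the five
  proteins, and uncharged tRNA — low-copy species whose fluctuations matter.
* 6 deterministic (Euler): charged tRNA, cellular energy, internal nutrient,
  the growth-rate variable, external nutrient density, and intracellular
  antibiotic — fast or high-copy quantities whose fluctuations average out.

Rate laws are schematic Hill/mass-action forms: transcription is activated
by energy; translation of gene *g* is proportional to ribosome count times
gene *g*'s share of the mRNA pool (the competition term m_g/(K_R + Σm)),
modulated by energy, charged-tRNA and antibiotic Hill factors; tRNA charging
is Michaelis–Menten in the internal nutrient; antibiotic binds ribosomes by
mass action; proteins dilute at the growth rate.  Units: molecule counts and
minutes; deterministic variables are dimensionless pools except the
growth-rate variable (1/min).
"""

from __future__ import annotations

import numpy as np

from .model import HybridModel, HybridState, Reaction

__all__ = ["bundled_cell_model", "bundled_initial_state", "GENES",
           "STOCH_SPECIES", "DET_SPECIES"]

GENES = ("met", "rib", "hk", "c1", "c2")

STOCH_SPECIES = tuple(f"m_{g}" for g in GENES) + tuple(f"p_{g}" for g in GENES) + ("trna_u",)
DET_SPECIES = ("trna_c", "energy", "nutrient_int", "growth_rate", "nutrient_ext", "antibiotic")

_SP = {name: i for i, name in enumerate(STOCH_SPECIES + DET_SPECIES)}

DEFAULT_PARAMS: dict[str, float] = {
    # transcription (mRNA/min at full activation) and mRNA decay (1/min)
    "k_tx_met": 80.0, "k_tx_rib": 60.0, "k_tx_hk": 100.0, "k_tx_c1": 30.0, "k_tx_c2": 30.0,
    "K_e_tx": 1.0,   # energy half-activation of transcription
    "d_m": 0.7,
    # translation: per-ribosome max rate, mRNA competition scale, Hill factors
    "k_tl": 0.3, "K_R": 300.0, "K_e_tl": 0.5, "K_tc": 100.0, "K_ab": 1.0,
    # tRNA charging (Michaelis-Menten in internal nutrient)
    "k_ch": 0.2, "K_s": 0.5, "c_tc": 0.9,
    # energy production/consumption
    "k_e": 0.0005, "c_e": 0.008,
    # nutrient import and metabolism
    "k_imp": 1e-3, "K_x": 0.5, "k_met": 8e-4,
    # growth-rate relaxation toward its translation-set target
    "lam_max": 0.04, "K_lam": 50.0, "tau_lam": 2.0,
    # medium depletion (effectively constant medium over ~1 h) and antibiotic
    "rho_x": 1e-6, "k_ab_in": 0.5, "ab_ext": 0.0, "k_ab_bind": 0.02,
}


def _translation_rates(x: np.ndarray, p) -> np.ndarray:
    """Per-gene translation propensities, shape (..., 5)."""
    m = x[..., 0:5]
    p_rib = x[..., _SP["p_rib"]]
    e = np.maximum(x[..., _SP["energy"]], 0.0)
    tc = np.maximum(x[..., _SP["trna_c"]], 0.0)
    ab = np.maximum(x[..., _SP["antibiotic"]], 0.0)
    m_tot = m.sum(axis=-1)
    gate = (
        p["k_tl"] * p_rib / (p["K_R"] + m_tot)
        * (e / (p["K_e_tl"] + e))
        * (tc / (p["K_tc"] + tc))
        * (p["K_ab"] / (p["K_ab"] + ab))
    )
    return m * gate[..., None]


def _charging_rate(x: np.ndarray, p) -> np.ndarray:
    s_i = np.maximum(x[..., _SP["nutrient_int"]], 0.0)
    return p["k_ch"] * x[..., _SP["trna_u"]] * s_i / (p["K_s"] + s_i)


def _propensities(x: np.ndarray, p) -> np.ndarray:
    """Fused propensity vector; definition order must match the Reaction list."""
    e = np.maximum(x[..., _SP["energy"]], 0.0)
    ab = np.maximum(x[..., _SP["antibiotic"]], 0.0)
    lam = np.maximum(x[..., _SP["growth_rate"]], 0.0)
    tx_act = e**2 / (p["K_e_tx"] ** 2 + e**2)
    k_tx = np.stack([np.broadcast_to(p[f"k_tx_{g}"], x.shape[:-1]) for g in GENES], axis=-1)
    tx = k_tx * tx_act[..., None]
    m_deg = p["d_m"] * x[..., 0:5]
    tl = _translation_rates(x, p)
    p_dil = lam[..., None] * x[..., 5:10]
    charge = _charging_rate(x, p)[..., None]
    rib_hit = (p["k_ab_bind"] * ab * x[..., _SP["p_rib"]])[..., None]
    return np.concatenate([tx, m_deg, tl, p_dil, charge, rib_hit], axis=-1)


def _drift(x: np.ndarray, p) -> np.ndarray:
    """Derivatives of the six deterministic species, shape (..., 6)."""
    p_met = x[..., _SP["p_met"]]
    tc = x[..., _SP["trna_c"]]
    e = x[..., _SP["energy"]]
    s_i = np.maximum(x[..., _SP["nutrient_int"]], 0.0)
    lam = x[..., _SP["growth_rate"]]
    s_x = np.maximum(x[..., _SP["nutrient_ext"]], 0.0)
    ab = x[..., _SP["antibiotic"]]
    tl_tot = _translation_rates(x, p).sum(axis=-1)
    charge = _charging_rate(x, p)
    mm_s = s_i / (p["K_s"] + s_i)
    imp = p["k_imp"] * p_met * s_x / (p["K_x"] + s_x)
    d_tc = charge - p["c_tc"] * tl_tot - lam * tc
    d_e = p["k_e"] * p_met * mm_s - p["c_e"] * tl_tot - lam * e
    d_si = imp - p["k_met"] * p_met * mm_s - lam * s_i
    lam_target = p["lam_max"] * tl_tot / (p["K_lam"] + tl_tot)
    d_lam = (lam_target - lam) / p["tau_lam"]
    d_sx = -p["rho_x"] * imp
    d_ab = p["k_ab_in"] * (p["ab_ext"] - ab) - lam * ab
    return np.stack([d_tc, d_e, d_si, d_lam, d_sx, d_ab], axis=-1)


def bundled_cell_model(**param_overrides: float) -> HybridModel:
    """The bundled 11-stochastic / 6-deterministic resource-aware cell model.

    Keyword arguments override entries of the documented default parameter
    set (e.g. ``bundled_cell_model(k_tx_c1=60.0)`` doubles circuit gene 1's
    transcription rate, or ``ab_ext=2.0`` adds antibiotic to the medium).
    """
    params = dict(DEFAULT_PARAMS)
    unknown = set(param_overrides) - set(params)
    if unknown:
        raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
    params.update(param_overrides)

    reactions: list[Reaction] = []
    for g in GENES:
        reactions.append(Reaction(
            f"tx_{g}", {f"m_{g}": +1},
            lambda x, p, g=g: p[f"k_tx_{g}"]
            * np.maximum(x[..., _SP["energy"]], 0.0) ** 2
            / (p["K_e_tx"] ** 2 + np.maximum(x[..., _SP["energy"]], 0.0) ** 2),
        ))
    for g in GENES:
        reactions.append(Reaction(
            f"deg_m_{g}", {f"m_{g}": -1},
            lambda x, p, g=g: p["d_m"] * x[..., _SP[f"m_{g}"]],
        ))
    for gi, g in enumerate(GENES):
        reactions.append(Reaction(
            f"tl_{g}", {f"p_{g}": +1, "trna_u": +1},
            lambda x, p, gi=gi: _translation_rates(x, p)[..., gi],
        ))
    for g in GENES:
        reactions.append(Reaction(
            f"dil_p_{g}", {f"p_{g}": -1},
            lambda x, p, g=g: np.maximum(x[..., _SP["growth_rate"]], 0.0)
            * x[..., _SP[f"p_{g}"]],
        ))
    reactions.append(Reaction("trna_charging", {"trna_u": -1}, _charging_rate))
    reactions.append(Reaction(
        "rib_antibiotic", {"p_rib": -1},
        lambda x, p: p["k_ab_bind"] * np.maximum(x[..., _SP["antibiotic"]], 0.0)
        * x[..., _SP["p_rib"]],
    ))

    return HybridModel(
        species_names=STOCH_SPECIES + DET_SPECIES,
        stoch_idx=np.arange(len(STOCH_SPECIES)),
        det_idx=np.arange(len(STOCH_SPECIES), len(STOCH_SPECIES) + len(DET_SPECIES)),
        reactions=tuple(reactions),
        drift=_drift,
        params=params,
        propensity_fn=_propensities,
    )


def bundled_initial_state() -> HybridState:
    """A near-steady starting state for the default parameters (abundant
    nutrient, no antibiotic); counts were read off a long relaxed run."""
    counts = np.array([
        64, 47, 80, 24, 24,        # mRNAs
        543, 383, 652, 193, 196,   # proteins
        165,                       # uncharged tRNA
    ], dtype=float)
    levels = np.array([
        239.0,   # charged tRNA
        1.12,    # energy
        1.77,    # internal nutrient
        0.0132,  # growth-rate variable (1/min)
        1.0,     # external nutrient density
        0.0,     # intracellular antibiotic
    ])
    return HybridState(counts=counts, levels=levels, t=0.0)
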