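"""Leaf-level allometric machinery.

Eelgrass leaf dry weight scales with leaf length as ``w = alpha * l**beta``.
Everything in this module follows algebraically from that law: the biomass
of a leaf, the biomass gained over an interval, the dimensionless growth
fractions ``delta`` and ``lambda``, and the split of a biomass increment
into new tissue versus maturation of pre-existing tissue.

All functions are pure and accept scalars or numpy arrays.
"""

from __future__ import annotations

import numpy as np

from .exceptions import AllometryDomainError
from .types import AllometricParams, LeafObservation

__all__ = [
    "leaf_biomass",
    "delta_factor",
    "lambda_ratio",
    "biomass_increment_allometric",
    "growth_decomposition",
]


def leaf_biomass(length, params: AllometricParams):
    """Dry weight (g) of a leaf of the given length (mm): ``alpha * l**beta``.

    Strictly increasing in length; zero at zero length.
    """
    length = np.asarray(length, dtype=float)
    if np.any(length < 0):
        raise AllometryDomainError("leaf length must be >= 0")
    out = params.alpha * np.power(length, params.beta)
    return out.item() if out.ndim == 0 else out


def _check_increment(increment, length_end):
    increment = np.asarray(increment, dtype=float)
    length_end = np.asarray(length_end, dtype=float)
    if np.any(increment < 0):
        raise AllometryDomainError("increment must be >= 0")
    if np.any(length_end < 0):
        raise AllometryDomainError("length_end must be >= 0")
    if np.any(increment > length_end * (1 + 1e-12) + 1e-12):
        raise AllometryDomainError("increment must not exceed length_end")
    return increment, length_end


def delta_factor(increment, length_end, beta: float):
    """Fraction ``1 - (1 - dl/l_end)**beta`` of the final allometric leaf
    biomass gained over the interval.

    Lies in [0, 1]: 0 for no growth, 1 when the whole leaf is new.  An
    empty leaf (``length_end == 0`` with zero increment) returns 0 by
    convention.
    """
    increment, length_end = _check_increment(increment, length_end)
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(length_end > 0, increment / np.where(length_end > 0, length_end, 1.0), 0.0)
    out = 1.0 - np.power(np.clip(1.0 - lam, 0.0, 1.0), beta)
    out = np.asarray(out, dtype=float)
    return out.item() if out.ndim == 0 else out


def lambda_ratio(increment, length_end):
    """Length-growth fraction ``dl / l_end``, in [0, 1].

    Empty leaves (zero final length, zero increment) return 0.
    """
    increment, length_end = _check_increment(increment, length_end)
    out = np.where(length_end > 0, increment / np.where(length_end > 0, length_end, 1.0), 0.0)
    out = np.asarray(out, dtype=float)
    return out.item() if out.ndim == 0 else out


def biomass_increment_allometric(leaf: LeafObservation, params: AllometricParams) -> float:
    """Allometric projection of the biomass gained by one leaf (g):
    ``alpha * l_end**beta * delta``.

    Algebraically identical to ``leaf_biomass(l_end) - leaf_biomass(l_start)``.
    """
    delta = delta_factor(leaf.increment, leaf.length_end, params.beta)
    return float(params.alpha * leaf.length_end ** params.beta * delta)


def growth_decomposition(
    leaf: LeafObservation, params: AllometricParams
) -> tuple[float, float]:
    """Split the allometric biomass increment of a leaf into
    ``(new_tissue, maturation)``.

    ``new_tissue = alpha * dl**beta`` is the allometric biomass of the
    length increment itself — the contribution of newly produced leaf
    material.  ``maturation = alpha * l_end**beta * (delta - lambda**beta)``
    is the remainder attributable to the pre-existing tissue; it is
    nonnegative for ``beta >= 1`` and vanishes identically at ``beta = 1``.
    The two parts sum exactly to :func:`biomass_increment_allometric`.
    """
    alpha, beta = params.alpha, params.beta
    new_tissue = float(alpha * float(leaf.increment) ** beta)
    delta = delta_factor(leaf.increment, leaf.length_end, beta)
    lam = lambda_ratio(leaf.increment, leaf.length_end)
    maturation = float(alpha * leaf.length_end ** beta * (delta - lam ** beta))
    return new_tissue, maturation
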