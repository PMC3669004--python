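"""Domain types for eelgrass shoot-marking campaigns.

Conventions used throughout the package:

* lengths in millimetres, dry weights in grams, time in days;
* leaf rank 1 is the youngest (innermost) leaf on a shoot, so "the third
  leaf" of the plastochrone method is rank 3 counted from the centre;
* an interval runs from the marking time ``t`` to the retrieval time
  ``t + delta_t``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import AllometryDomainError, ValidationError

#: absolute slack (mm / g) allowed when checking derived-quantity identities
_TOL = 1e-9


@dataclass(frozen=True)
class AllometricParams:
    """Parameters of the allometric law ``w = alpha * l**beta``.

    ``alpha`` is the normalization constant (grams per mm**beta) and
    ``beta`` the dimensionless scaling exponent; both must be positive.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise AllometryDomainError(f"alpha must be > 0, got {self.alpha}")
        if not (self.beta > 0):
            raise AllometryDomainError(f"beta must be > 0, got {self.beta}")


@dataclass(frozen=True)
class LeafObservation:
    """One leaf on one retrieved shoot.

    ``increment`` defaults to ``length_end - length_start`` and
    ``increment_above_mark`` defaults to the full increment; field data
    with within-sheath growth supplies a smaller above-mark value.
    ``dry_weight_start`` is optional — it is known only for simulated
    data, since field dry weights are destructive at retrieval.
    """

    rank: int
    length_start: float
    length_end: float
    dry_weight_end: float
    increment: Optional[float] = None
    increment_above_mark: Optional[float] = None
    dry_weight_start: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValidationError(f"leaf rank must be >= 1, got {self.rank}")
        if self.length_start < 0 or self.length_end < 0:
            raise ValidationError("leaf lengths must be >= 0")
        if self.dry_weight_end < 0:
            raise ValidationError("dry_weight_end must be >= 0")
        if self.dry_weight_start is not None and self.dry_weight_start < 0:
            raise ValidationError("dry_weight_start must be >= 0")
        inc = self.increment
        if inc is None:
            inc = self.length_end - self.length_start
            object.__setattr__(self, "increment", inc)
        elif abs(inc - (self.length_end - self.length_start)) > _TOL:
            raise ValidationError(
                f"increment {inc} != length_end - length_start "
                f"({self.length_end - self.length_start})"
            )
        if inc < -_TOL or inc > self.length_end + _TOL:
            raise ValidationError(
                f"increment {inc} outside [0, length_end={self.length_end}]"
            )
        above = self.increment_above_mark
        if above is None:
            object.__setattr__(self, "increment_above_mark", inc)
        elif above < -_TOL or above > inc + _TOL:
            raise ValidationError(
                f"increment_above_mark {above} outside [0, increment={inc}]"
            )


@dataclass(frozen=True)
class ShootSample:
    """The ``n(s)`` leaves of one retrieved shoot."""

    shoot_id: str
    leaves: tuple[LeafObservation, ...]

    def __post_init__(self) -> None:
        if isinstance(self.leaves, list):
            object.__setattr__(self, "leaves", tuple(self.leaves))
        if len(self.leaves) < 1:
            raise ValidationError(f"shoot {self.shoot_id}: needs >= 1 leaf")
        ranks = sorted(leaf.rank for leaf in self.leaves)
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValidationError(
                f"shoot {self.shoot_id}: ranks {ranks} are not contiguous from 1"
            )

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def leaf(self, rank: int) -> Optional[LeafObservation]:
        """Return the leaf with the given rank, or None if absent."""
        for lf in self.leaves:
            if lf.rank == rank:
                return lf
        return None

    @property
    def has_start_weights(self) -> bool:
        return all(lf.dry_weight_start is not None for lf in self.leaves)


@dataclass(frozen=True)
class Campaign:
    """All shoots retrieved on one date, plus the marking bookkeeping
    needed for the plastochrone interval.

    ``p`` is the plastochrone interval in days; when ``None`` it is
    estimated from ``n_marked``/``new_leaves`` on demand.
    """

    date: _dt.date
    delta_t: float
    shoots: tuple[ShootSample, ...]
    n_marked: int
    new_leaves: int
    p: Optional[float] = None

    def __post_init__(self) -> None:
        if isinstance(self.date, str):
            object.__setattr__(self, "date", _dt.date.fromisoformat(self.date))
        if isinstance(self.shoots, list):
            object.__setattr__(self, "shoots", tuple(self.shoots))
        if not self.delta_t > 0:
            raise ValidationError(f"delta_t must be > 0, got {self.delta_t}")
        if self.n_marked < len(self.shoots):
            raise ValidationError(
                f"campaign {self.date}: retrieved {len(self.shoots)} shoots "
                f"exceeds n_marked={self.n_marked}"
            )
        if self.new_leaves < 0:
            raise ValidationError("new_leaves must be >= 0")
        if self.p is not None and not self.p > 0:
            raise ValidationError(f"p must be > 0 when set, got {self.p}")

    @property
    def n_retrieved(self) -> int:
        return len(self.shoots)


@dataclass(frozen=True)
class CampaignRates:
    """Per-shoot rate vectors and their campaign means (g/day) for the
    four estimators.  NaN marks a shoot excluded from a method (e.g. no
    rank-3 leaf for the plastochrone method); means average over the
    contributing shoots only.  ``lg``/``lg_s`` are None when dry weights
    at marking are unavailable (field data)."""

    delta_t: float
    p: float
    lg_s: Optional[np.ndarray]
    lga_s: np.ndarray
    lgm_s: np.ndarray
    lgp_s: np.ndarray
    lgm_formal_s: np.ndarray
    lgp_allometric_s: np.ndarray
    lg: Optional[float]
    lga: float
    lgm: float
    lgp: float
    marking_mode: str = "field"
    n_plastochrone_excluded: int = 0


@dataclass(frozen=True)
class ShootDecomposition:
    """Per-shoot terms of the plastochrone/marking bias algebra:
    ``csap`` (dimensionless factor multiplying the shoot plastochrone
    rate), ``rsap`` (growth of the non-third leaves, g/day), ``rsma``
    (maturation remainder, g/day) and ``rsmp = rsap - rsma``."""

    shoot_id: str
    csap: float
    rsap: float
    rsma: float
    rsmp: float
    lgp_allometric: float


@dataclass(frozen=True)
class CampaignBias:
    """Campaign-level biases of the three proxies relative to the in situ
    rate, the weighted factor ``cap``, the remainder means, and the
    bounds on the plastochrone bias."""

    cap: float
    bap: float
    bmp: float
    bp: Optional[float]
    ba: Optional[float]
    bm: Optional[float]
    blap: float
    bp_upper: float
    bp_allometric: float
    rswa: Optional[float] = None  # mean |Lg_s - Lga_s| estimation residual


@dataclass(frozen=True)
class FitResult:
    """Result of fitting the allometric law to length/weight pairs."""

    params: AllometricParams
    r_squared: float
    r_squared_log: float
    n: int
    residual_sd: float


@dataclass(frozen=True)
class MethodAgreement:
    """Agreement of one proxy series with the observed series."""

    method: str
    rmse: float
    ccc: float
    ccc_ci: tuple[float, float]
    slope: float
    intercept: Optional[float]
    r_squared: float
    through_origin: bool


@dataclass(frozen=True)
class AgreementReport:
    """Table-style summary across proxies plus the bias ordering."""

    methods: tuple[MethodAgreement, ...]
    bias_ordering_fraction: float
    n_campaigns: int

    def by_method(self, name: str) -> MethodAgreement:
        for m in self.methods:
            if m.method == name:
                return m
        raise KeyError(name)


def as_date(value) -> _dt.date:
    """Coerce ISO strings / datetimes to a date."""
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))
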