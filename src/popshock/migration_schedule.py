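"""Rogers-Castro model migration age schedules.

Net migration inputs are yearly totals with no age or sex detail, so the
totals are spread over single years of age with a parametric model
schedule. The "family" variant used here has three components: a
pre-labor-force exponential decay, a double-exponential labor-force peak,
and a constant floor — no retirement peak:

    w(x) = a1 * exp(-alpha1 * x)
         + a2 * exp(-alpha2 * (x - mu2) - exp(-lambda2 * (x - mu2)))
         + c

The default parameters are a documented, replaceable choice that places
most migration mass in young and working ages.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .schedules_io import AGES, AGE_MAX, FEMALE, MALE


@dataclasses.dataclass(frozen=True)
class RogersCastroParams:
    """Parameters of the family-model migration age schedule.

    a1/alpha1: pre-labor-force intensity and decay rate; a2/alpha2/mu2/
    lambda2: labor-force intensity, descent rate, peak age and ascent
    rate; c: constant baseline level.
    """

    a1: float
    alpha1: float
    a2: float
    alpha2: float
    mu2: float
    lambda2: float
    c: float

    def validate(self) -> "RogersCastroParams":
        if min(self.a1, self.a2, self.c) < 0:
            raise ValueError("a1, a2 and c must be non-negative")
        if min(self.alpha1, self.alpha2, self.lambda2) <= 0:
            raise ValueError("alpha1, alpha2 and lambda2 must be positive")
        if not 0 <= self.mu2 <= AGE_MAX:
            raise ValueError(f"mu2 must lie in [0, {AGE_MAX}]")
        return self


#: Default family profile for both sexes (migration concentrated in young
#: and working ages). A documented choice, not an estimate.
DEFAULT_FAMILY_PARAMS = RogersCastroParams(
    a1=0.02, alpha1=0.1, a2=0.06, alpha2=0.1, mu2=25.0, lambda2=0.4, c=0.003
)


def rogers_castro_density(params: RogersCastroParams, ages=AGES) -> np.ndarray:
    """Unnormalized schedule weights w(x) >= 0 at each age."""
    params.validate()
    x = np.asarray(ages, dtype=np.float64)
    pre = params.a1 * np.exp(-params.alpha1 * x)
    z = x - params.mu2
    labor = params.a2 * np.exp(-params.alpha2 * z - np.exp(-params.lambda2 * z))
    w = pre + labor + params.c
    if not np.isfinite(w).all() or (w < 0).any():
        raise ValueError("parameters produce non-finite or negative weights")
    return w


@dataclasses.dataclass
class MigrationProfile:
    """Per-sex age proportions plus the female share of the yearly total.

    ``proportions`` has shape (101, 2) and sums to 1 within each sex;
    ``sex_split`` is the fraction of total net migration allocated to
    females.
    """

    proportions: np.ndarray
    sex_split: float = 0.5

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=np.float64)
        if self.proportions.shape != (AGE_MAX + 1, 2):
            raise ValueError(f"proportions shape {self.proportions.shape} != ({AGE_MAX + 1}, 2)")

    def validate(self) -> "MigrationProfile":
        if (self.proportions < 0).any() or not np.isfinite(self.proportions).all():
            raise ValueError("proportions must be finite and non-negative")
        sums = self.proportions.sum(axis=0)
        if np.abs(sums - 1.0).max() > 1e-12:
            raise ValueError(f"per-sex proportions must sum to 1 (got {sums})")
        if not 0.0 <= self.sex_split <= 1.0:
            raise ValueError("sex_split must lie in [0, 1]")
        return self


def build_profile(
    params_f: RogersCastroParams = DEFAULT_FAMILY_PARAMS,
    params_m: RogersCastroParams = DEFAULT_FAMILY_PARAMS,
    sex_split: float = 0.5,
) -> MigrationProfile:
    """Normalize per-sex schedule weights into a MigrationProfile."""
    props = np.empty((AGE_MAX + 1, 2))
    for sex_i, params in ((FEMALE, params_f), (MALE, params_m)):
        w = rogers_castro_density(params)
        total = w.sum()
        if total <= 0:
            raise ValueError("all-zero schedule weights cannot be normalized")
        props[:, sex_i] = w / total
    return MigrationProfile(props, sex_split).validate()


def distribute_migration(total: float, profile: MigrationProfile) -> np.ndarray:
    """Spread one year's net migration total over (age, sex) cells.

    count(age, sex) = total * sexshare(sex) * proportion(age, sex); the
    cell counts sum to ``total`` up to floating point, and a negative
    total yields the mirrored negative counts.
    """
    profile.validate()
    shares = np.array([profile.sex_split, 1.0 - profile.sex_split])
    return total * profile.proportions * shares[np.newaxis, :]


def largest_remainder_round(values: np.ndarray) -> np.ndarray:
    """Deterministic integerization preserving the (rounded) total.

    Floors every cell, then hands the remaining units to the cells with
    the largest fractional parts. Works on non-negative arrays; used to
    integerize initial populations for stochastic projection.
    """
    values = np.asarray(values, dtype=np.float64)
    if (values < 0).any():
        raise ValueError("largest_remainder_round expects non-negative values")
    flat = values.ravel()
    floors = np.floor(flat)
    target = int(np.rint(flat.sum()))
    short = target - int(floors.sum())
    out = floors.copy()
    if short > 0:
        order = np.argsort(-(flat - floors), kind="stable")
        out[order[:short]] += 1
    return out.reshape(values.shape)


def stochastic_round(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unbiased random integerization preserving the yearly total.

    Cells are floored and the leftover mass is allocated as whole units by
    a multinomial draw with probabilities proportional to the fractional
    parts, so E[rounded cell] equals the fractional cell exactly and the
    array total stays within one unit of the input total (equal to it when
    the input total is integral). Sign-aware: a shared negative sign is
    factored out first.
    """
    values = np.asarray(values, dtype=np.float64)
    out = np.zeros_like(values)
    for sign in (1.0, -1.0):
        part = np.where(sign * values > 0, sign * values, 0.0)
        if part.sum() == 0:
            continue
        flat = part.ravel()
        floors = np.floor(flat)
        rem = flat - floors
        mass = rem.sum()
        units = int(np.floor(mass))
        if rng.random() < mass - units:
            units += 1
        alloc = floors
        if units > 0 and mass > 0:
            alloc = floors + rng.multinomial(units, rem / mass)
        out += sign * alloc.reshape(values.shape)
    return out
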