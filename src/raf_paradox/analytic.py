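"""Closed-form steady-state solutions and paradoxical-activation conditions.

All expressions are functions of the dimensionless groups (RAF_rel, d_rel,
s_rel, S_rel) and the autoinhibition constant K_A, re-derived from the
mass-action scheme in :mod:`raf_paradox.oracle` and validated against it.

Two algebraic families cover every variant:

* baseline (no drug):  ``(√(1+E) − 1)² / E`` with
  ``E = 8·RAF_rel·(1+s_rel) / (1 + K_A·(1+S_rel))²`` (14-3-3 terms dropped
  per variant — the four table abbreviations E3, E5, E7, E10);
* dosed:  ``(√(E² + F) − E)² / (F·(1+d_rel))`` with
  ``E = 1 + K_A·(1+S_rel) + d_rel`` and
  ``F = 8·RAF_rel·(1+d_rel)²·(1+s_rel)`` (abbreviations E1/E4/E9 and
  E2/E6/E8).

The PA conditions follow from requiring a positive initial slope of the
dosed expression at d_rel = 0 with free 14-3-3 clamped. The CAS coupling
enters as an effective autoinhibition constant K_A·(1+S_rel) and the DS
coupling as an effective RAF abundance RAF_rel·(1+s_rel), so the base-model
bound RAF_rel < (1+3K_A)(K_A−1)/8 generalizes directly.

The 14-3-3 concentration entering S_rel and s_rel is free 14-3-3 by
default; under the excess assumption (unbound 14-3-3 ≫ unbound RAF) free
and total coincide, and :func:`effective_s_free` exposes both conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import (
    DimensionlessGroups,
    ModelVariant,
    Parameters,
    ValidationError,
    dimensionless,
)


def effective_s_free(
    params: Parameters, s_free: float | None, convention: str = "free"
) -> float:
    """Resolve the 14-3-3 concentration the closed forms should use.

    ``convention="free"`` uses the supplied free concentration (defaulting
    to S_total when None, i.e. the excess assumption); ``"total"`` always
    uses S_total.
    """
    if convention == "total":
        return params.S_total
    if convention != "free":
        raise ValidationError(f"unknown 14-3-3 convention {convention!r}")
    return params.S_total if s_free is None else s_free


def table_abbreviations(
    params: Parameters, d_free: float, s_free: float
) -> dict[str, float]:
    """The ten dimensionless abbreviations E1…E10 of the solution table."""
    g = dimensionless(params, d_free, s_free)
    KA = params.K_A
    E1 = 1.0 + KA + g.d_rel
    E2 = 8.0 * g.RAF_rel * (1.0 + g.d_rel) ** 2
    E3 = 8.0 * g.RAF_rel / (1.0 + KA) ** 2
    E4 = E1 + KA * g.S_rel
    E5 = 8.0 * g.RAF_rel / (1.0 + KA + KA * g.S_rel) ** 2
    E6 = E2 * (1.0 + g.s_rel)
    E7 = E3 * (1.0 + g.s_rel)
    E10 = 8.0 * g.RAF_rel * (1.0 + g.s_rel) / (1.0 + KA + KA * g.S_rel) ** 2
    return {
        "E1": E1, "E2": E2, "E3": E3, "E4": E4, "E5": E5,
        "E6": E6, "E7": E7, "E8": E6, "E9": E4, "E10": E10,
    }


def _variant_groups(
    variant: ModelVariant, params: Parameters, d_free: float, s_free: float
) -> tuple[float, float, DimensionlessGroups]:
    """(E, F) of the dosed family with disabled couplings zeroed out."""
    g = dimensionless(params, d_free, s_free)
    S_rel = g.S_rel if variant.cas_enabled else 0.0
    s_rel = g.s_rel if variant.ds_enabled else 0.0
    E = 1.0 + params.K_A * (1.0 + S_rel) + g.d_rel
    F = 8.0 * g.RAF_rel * (1.0 + g.d_rel) ** 2 * (1.0 + s_rel)
    return E, F, g


def baseline_active_fraction(
    variant: ModelVariant, params: Parameters, s_free: float = 0.0
) -> float:
    """Active-RAF fraction at zero drug from the closed form.

    Evaluates (√(1+E) − 1)²/E in the stable form E/(√(1+E) + 1)², with E the
    variant's baseline abbreviation (E3, E5, E7 or E10).
    """
    E, F, _ = _variant_groups(variant, params, 0.0, s_free)
    e = F / (E * E)  # the E3/E5/E7/E10 abbreviation
    if e == 0.0:
        return 0.0
    return e / (math.sqrt(1.0 + e) + 1.0) ** 2


def active_fraction(
    variant: ModelVariant,
    params: Parameters,
    d_free: float,
    s_free: float = 0.0,
) -> float:
    """Active-RAF fraction at clamped free drug and free 14-3-3.

    Evaluates (√(E²+F) − E)²/(F·(1+d_rel)) in the stable form
    F/((√(E²+F) + E)²·(1+d_rel)).
    """
    E, F, g = _variant_groups(variant, params, d_free, s_free)
    if F == 0.0:
        return 0.0
    return F / ((math.sqrt(E * E + F) + E) ** 2 * (1.0 + g.d_rel))


def dimer_fraction(active: float, d_rel: float) -> float:
    """Dimer complexes per total RAF protomer: (1 + d_rel)/2 × active."""
    if not 0.0 <= active <= 1.0:
        raise ValidationError(f"active fraction must lie in [0, 1] (got {active!r})")
    if d_rel < 0:
        raise ValidationError(f"d_rel must be >= 0 (got {d_rel!r})")
    return 0.5 * (1.0 + d_rel) * active


@dataclass(frozen=True)
class PAConditionResult:
    """Outcome of a variant's paradoxical-activation inequality.

    ``margin`` is a signed dimensionless distance between the two sides of
    the inequality, oriented so that a positive margin always predicts PA:
    (bound − RAF_rel) for the RAF_rel-bounded variants, (K_A − bound) for
    the CAS+DS form. ``limit_note`` names the limit the condition assumes.
    """

    holds: bool
    margin: float
    bound: float
    limit_note: str | None


def pa_condition(
    variant: ModelVariant, params: Parameters, s_free: float = 0.0
) -> PAConditionResult:
    """Evaluate the variant's PA inequality at clamped free 14-3-3.

    CA:     RAF_rel < (1 + 3K_A)(K_A − 1)/8
    CAS:    RAF_rel < (K_A·S_rel + K_A − 1)(3K_A·S_rel + 3K_A + 1)/8
    DS:     RAF_rel < (1 + 3K_A)(K_A − 1)/(8(1 + s_rel))
    CAS+DS: K_A > K_Smon/(3(K_Smon + s)) · (1 + 2√(1 + 6·RAF_rel·(K_Sdim + s)/K_Sdim))
    """
    g = dimensionless(params, 0.0, s_free)
    KA = params.K_A
    if variant is ModelVariant.CA:
        bound = (1.0 + 3.0 * KA) * (KA - 1.0) / 8.0
        margin = bound - g.RAF_rel
        note = None
    elif variant is ModelVariant.CAS:
        bound = (
            (KA * g.S_rel + KA - 1.0) * (3.0 * KA * g.S_rel + 3.0 * KA + 1.0) / 8.0
        )
        margin = bound - g.RAF_rel
        note = "limit: 14-3-3 available to bind RAF in excess of RAF"
    elif variant is ModelVariant.DS:
        bound = (1.0 + 3.0 * KA) * (KA - 1.0) / (8.0 * (1.0 + g.s_rel))
        margin = bound - g.RAF_rel
        note = "limit: free 14-3-3 unchanged by drug (ds/dd_rel -> 0)"
    else:  # CAS_DS: bound on K_A rather than on RAF_rel
        bound = (
            params.K_Smon
            / (3.0 * (params.K_Smon + s_free))
            * (1.0 + 2.0 * math.sqrt(1.0 + 6.0 * g.RAF_rel * (1.0 + g.s_rel)))
        )
        margin = KA - bound
        note = "limit: total 14-3-3 in excess of total RAF"
    return PAConditionResult(holds=margin > 0.0, margin=margin, bound=bound, limit_note=note)
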