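"""Brute-force mass-action equilibrium solver for the full species network.

This module is the ground truth the closed-form expressions are validated
against. It builds every molecular species from the pairwise equilibrium
relations (detailed balance) and enforces conservation of total RAF, total
drug and total 14-3-3 by bracketed one-dimensional root-finding, making no
use of the dimensionless closed forms.

Species (concentrations in µM):

====== =======================================================
M      open, unbound monomer
A      autoinhibited monomer (cannot dimerize or bind drug)
AS     autoinhibited monomer · 14-3-3 dimer (CAS variants)
Md     drug-bound open monomer
D00    dimer, no drug bound
D01    dimer, one protomer drug-bound (both orientations)
D11    dimer, both protomers drug-bound
DxyS   the corresponding 14-3-3-clamped dimers (DS variants)
====== =======================================================

Equilibrium relations: A = K_A·M, AS = A·s/K_Smon, Md = M·d/K_d,
D00 = M²/K_dim, D01 = 2·M·Md/K_dim (statistical factor 2 for the two
orientations), D11 = Md²/K_dim, DxyS = Dxy·s/K_Sdim. Drug binding in the
dimer uses the same K_d as the monomer (no cooperativity); a drug-bound
protomer cannot be autoinhibited, and 14-3-3 engagement is all-or-none
(unbound or doubly bound counted as one unit).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from scipy.optimize import brentq

from .parameters import ModelVariant, Parameters, ValidationError

# residual floor used when a conserved total is zero
_ABS_FLOOR = 1e-12
_REL_TOL = 1e-10
_BRENTQ_KW = dict(xtol=1e-25, rtol=9e-16, maxiter=200)


class ConvergenceError(RuntimeError):
    """Conservation solve failed to reach tolerance (implementation defect)."""


@dataclass(frozen=True)
class SpeciesState:
    """Solved equilibrium concentrations of every species (µM)."""

    M: float
    A: float
    AS: float
    Md: float
    D00: float
    D01: float
    D11: float
    D00S: float
    D01S: float
    D11S: float
    d_free: float
    s_free: float
    r_total: float

    def replace(self, **changes: float) -> "SpeciesState":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @property
    def monomer_sum(self) -> float:
        return self.M + self.A + self.AS + self.Md

    @property
    def dimer_sum(self) -> float:
        return self.D00 + self.D01 + self.D11 + self.D00S + self.D01S + self.D11S


@dataclass(frozen=True)
class ConservationResiduals:
    """Signed residuals (µM) of the three conservation equations."""

    r_RAF: float
    r_drug: float
    r_S: float

    def within(self, params: Parameters, rel_tol: float = _REL_TOL) -> bool:
        for r, total in (
            (self.r_RAF, params.R_total),
            (self.r_drug, params.D_total),
            (self.r_S, params.S_total),
        ):
            if abs(r) > max(rel_tol * total, _ABS_FLOOR):
                return False
        return True


def solve_free_clamped(
    variant: ModelVariant, params: Parameters, d_free: float, s_free: float
) -> SpeciesState:
    """Equilibrium state at clamped free drug and free 14-3-3.

    RAF conservation reads
    ``R_total = M·(1 + K_A·(1 + s/K_Smon) + d/K_d)
    + 2·(M²/K_dim)·(1 + d/K_d)²·(1 + s/K_Sdim)``
    with the 14-3-3 terms dropped for variants that disable them; M is the
    positive root of this quadratic, evaluated in the numerically stable
    form M = 2·R_total / (c₁ + √(c₁² + 4·c₂·R_total)).
    """
    if d_free < 0 or s_free < 0:
        raise ValidationError("free concentrations must be >= 0")
    s_mon = s_free / params.K_Smon if variant.cas_enabled else 0.0
    s_dim = s_free / params.K_Sdim if variant.ds_enabled else 0.0
    dr = d_free / params.K_d

    c1 = 1.0 + params.K_A * (1.0 + s_mon) + dr
    c2 = 2.0 * (1.0 + dr) ** 2 * (1.0 + s_dim) / params.K_dim
    R = params.R_total
    if R == 0.0:
        M = 0.0
    else:
        M = 2.0 * R / (c1 + (c1 * c1 + 4.0 * c2 * R) ** 0.5)
    return _build_state(variant, params, M, d_free, s_free)


def _build_state(
    variant: ModelVariant,
    params: Parameters,
    M: float,
    d_free: float,
    s_free: float,
) -> SpeciesState:
    s_mon = s_free / params.K_Smon if variant.cas_enabled else 0.0
    s_dim = s_free / params.K_Sdim if variant.ds_enabled else 0.0
    dr = d_free / params.K_d
    A = params.K_A * M
    AS = A * s_mon
    Md = M * dr
    D00 = M * M / params.K_dim
    D01 = 2.0 * M * Md / params.K_dim
    D11 = Md * Md / params.K_dim
    return SpeciesState(
        M=M,
        A=A,
        AS=AS,
        Md=Md,
        D00=D00,
        D01=D01,
        D11=D11,
        D00S=D00 * s_dim,
        D01S=D01 * s_dim,
        D11S=D11 * s_dim,
        d_free=d_free,
        s_free=s_free,
        r_total=params.R_total,
    )


def _bound_s(state: SpeciesState) -> float:
    return state.AS + state.D00S + state.D01S + state.D11S


def _bound_d(state: SpeciesState) -> float:
    return state.Md + state.D01 + 2.0 * state.D11 + state.D01S + 2.0 * state.D11S


def conservation_residuals(
    state: SpeciesState, params: Parameters
) -> ConservationResiduals:
    """Signed residuals of RAF, drug and 14-3-3 conservation for a state."""
    return ConservationResiduals(
        r_RAF=state.monomer_sum + 2.0 * state.dimer_sum - params.R_total,
        r_drug=state.d_free + _bound_d(state) - params.D_total,
        r_S=state.s_free + _bound_s(state) - params.S_total,
    )


def solve_totals(variant: ModelVariant, params: Parameters) -> SpeciesState:
    """Equilibrium state satisfying all three conservation laws.

    Solved by nested bracketed root-finding: the outer variable is free drug
    on [0, D_total], the inner is free 14-3-3 on [0, S_total], and the
    innermost monomer concentration comes from the closed-form RAF
    conservation of :func:`solve_free_clamped`. Each bracket is valid because
    the residual is negative at 0 and non-negative at the total.
    """

    def solve_s(d: float) -> float:
        if params.S_total == 0.0 or not (variant.cas_enabled or variant.ds_enabled):
            return params.S_total if not (variant.cas_enabled or variant.ds_enabled) else 0.0
        S = params.S_total

        def resid(s: float) -> float:
            st = solve_free_clamped(variant, params, d, s)
            return s + _bound_s(st) - S

        if resid(S) <= 0.0:  # nothing binds (e.g. R_total = 0)
            return S
        return brentq(resid, 0.0, S, **_BRENTQ_KW)

    def resid_d(d: float) -> float:
        s = solve_s(d)
        st = solve_free_clamped(variant, params, d, s)
        return d + _bound_d(st) - params.D_total

    if params.D_total == 0.0:
        d_free = 0.0
    elif resid_d(params.D_total) <= 0.0:  # nothing binds drug
        d_free = params.D_total
    else:
        d_free = brentq(resid_d, 0.0, params.D_total, **_BRENTQ_KW)

    s_free = solve_s(d_free)
    state = solve_free_clamped(variant, params, d_free, s_free)
    res = conservation_residuals(state, params)
    if not res.within(params):
        raise ConvergenceError(
            f"conservation solve did not converge: residuals {res} for "
            f"{variant} with {params}"
        )
    return state


def active_raf(state: SpeciesState) -> float:
    """Fraction of total RAF protomers that are active.

    Active RAF is every protomer that sits inside a dimer and is not bound
    to drug, whether or not the dimer is clamped by 14-3-3:
    (2·D00 + D01 + 2·D00S + D01S)/R_total.
    """
    if state.r_total == 0.0:
        return 0.0
    return (
        2.0 * state.D00 + state.D01 + 2.0 * state.D00S + state.D01S
    ) / state.r_total


def dimer_count(state: SpeciesState) -> float:
    """Dimer complexes as a fraction of total RAF protomers.

    Analytically equal to (1 + d_rel)/2 × :func:`active_raf`.
    """
    if state.r_total == 0.0:
        return 0.0
    return state.dimer_sum / state.r_total


@dataclass(frozen=True)
class CycleProduct:
    """One thermodynamic cycle and its equilibrium-constant product."""

    name: str
    product: float


def cycle_products(
    state: SpeciesState, variant: ModelVariant, params: Parameters
) -> list[CycleProduct]:
    """Products around independent thermodynamic cycles; all equal 1.

    Every complex can be assembled from free species by more than one
    reaction order (e.g. bind drug then dimerize vs dimerize then bind
    drug); detailed balance demands the composite association constant be
    path-independent. Each cycle product is the constant measured from the
    state for one path divided by the value the parameter constants require
    along the other, so it equals 1 exactly at a consistent equilibrium and
    deviates when any relation in the loop is broken. Requires strictly
    positive free monomer and free drug (plus free 14-3-3 for the 14-3-3
    cycles).
    """
    M, d, s = state.M, state.d_free, state.s_free
    Kd, Kdim = params.K_d, params.K_dim
    out = [
        CycleProduct(
            "D01: M+d->Md, Md+M->D01 vs M+M->D00, D00+d->D01",
            (state.D01 / (M * M * d)) * (Kd * Kdim / 2.0),
        ),
        CycleProduct(
            "D11: M+d->Md twice, Md+Md->D11 vs D01+d->D11",
            (state.D11 / (M * M * d * d)) * (Kd * Kd * Kdim),
        ),
    ]
    if variant.ds_enabled:
        KSdim = params.K_Sdim
        out += [
            CycleProduct(
                "D00S: dimerize then bind 14-3-3 vs bind 14-3-3 then dimerize",
                (state.D00S / (M * M * s)) * (Kdim * KSdim),
            ),
            CycleProduct(
                "D01S: D00S+d->D01S vs D01+s->D01S",
                (state.D01S / (M * M * d * s)) * (Kd * Kdim * KSdim / 2.0),
            ),
            CycleProduct(
                "D11S: D01S+d->D11S vs D11+s->D11S",
                (state.D11S / (M * M * d * d * s)) * (Kd * Kd * Kdim * KSdim),
            ),
        ]
    if variant.cas_enabled and params.K_A > 0:
        out.append(
            CycleProduct(
                "AS: M->A then A+s->AS vs required K_A/K_Smon",
                (state.AS / (M * s)) * (params.K_Smon / params.K_A),
            )
        )
    return out


def check_detailed_balance(
    variant: ModelVariant,
    params: Parameters,
    d_free: float | None = None,
    s_free: float | None = None,
) -> list[CycleProduct]:
    """Enumerate thermodynamic cycles at a reference state; all products = 1.

    A product different from 1 indicates a broken equilibrium relation in
    the species construction (implementation defect), never a property of
    the parameters.
    """
    d = params.K_d if d_free is None else d_free
    s = params.K_Sdim if s_free is None else s_free
    state = solve_free_clamped(variant, params, d, s)
    return cycle_products(state, variant, params)
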