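"""Parameter containers, model variants and dimensionless groups.

The equilibrium model describes a RAF protomer that interconverts between an
open (dimerization- and drug-competent) monomer and a conformationally
autoinhibited monomer, dimerizes, binds an ATP-pocket inhibitor, and engages
dimeric 14-3-3 in two distinct roles:

* **CAS** (conformational autoinhibition stabilization): a 14-3-3 dimer binds
  the autoinhibited monomer, locking it out of the signaling pool.
* **DS** (dimer stabilization): a 14-3-3 dimer clamps across a RAF dimer,
  stabilizing the signaling assembly.

All concentrations are in µM throughout; 14-3-3 is counted in *dimer* units
(one 14-3-3 dimer engaging two phosphoserines is one binding unit).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
import pathlib
from dataclasses import dataclass
from typing import Mapping


class ValidationError(ValueError):
    """Raised when a parameter value violates its physical constraints."""


class ModelVariant(enum.Enum):
    """Which of the two 14-3-3 roles are enabled.

    ``CA`` is the base conformational-autoinhibition model with no 14-3-3
    coupling; ``CAS`` enables only the 14-3-3/autoinhibited-monomer
    interaction; ``DS`` only the 14-3-3/RAF-dimer interaction; ``CAS_DS``
    both.
    """

    CA = "CA"
    CAS = "CAS"
    DS = "DS"
    CAS_DS = "CAS_DS"

    @property
    def cas_enabled(self) -> bool:
        """True when 14-3-3 binds the autoinhibited monomer."""
        return self in (ModelVariant.CAS, ModelVariant.CAS_DS)

    @property
    def ds_enabled(self) -> bool:
        """True when 14-3-3 binds the RAF dimer."""
        return self in (ModelVariant.DS, ModelVariant.CAS_DS)


_POSITIVE_FIELDS = ("K_d", "K_dim", "K_Smon", "K_Sdim")
_NONNEGATIVE_FIELDS = ("K_A", "R_total", "S_total", "D_total")


@dataclass(frozen=True)
class Parameters:
    """One model instance: equilibrium constants and total concentrations.

    Attributes
    ----------
    K_A : float
        Dimensionless autoinhibition equilibrium constant, defined as
        [autoinhibited]/[open] for the monomer; larger values mean stronger
        autoinhibition.
    K_d : float
        Drug–protomer dissociation constant (µM); the same constant applies
        to the open monomer and to each dimer protomer (no cooperativity).
    K_dim : float
        RAF dimerization dissociation constant (µM).
    K_Smon : float
        Dissociation constant of the 14-3-3 dimer from the autoinhibited
        monomer (µM) — the CAS interaction.
    K_Sdim : float
        Dissociation constant of the 14-3-3 dimer from the RAF dimer (µM) —
        the DS interaction.
    R_total : float
        Total RAF protomer concentration (µM).
    S_total : float
        Total 14-3-3 concentration in dimer units (µM).
    D_total : float
        Total drug concentration (µM).
    """

    K_A: float
    K_d: float
    K_dim: float
    K_Smon: float
    K_Sdim: float
    R_total: float
    S_total: float = 0.0
    D_total: float = 0.0

    def __post_init__(self) -> None:
        for name in _POSITIVE_FIELDS:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(
                    f"{name} must be a finite, strictly positive dissociation "
                    f"constant (got {v!r})"
                )
        for name in _NONNEGATIVE_FIELDS:
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(
                    f"{name} must be finite and non-negative (got {v!r})"
                )

    def replace(self, **changes: float) -> "Parameters":
        """Return a validated copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def defaults(cls) -> "Parameters":
        """The reference parameter set used for all descriptive simulations.

        K_A = 10, K_d = 0.1 µM, K_dim = 0.1 µM, K_Smon = 0.2 µM,
        K_Sdim = 0.02 µM, total RAF 0.04 µM, total 14-3-3 (dimers) 1.0 µM,
        no drug.
        """
        return cls(
            K_A=10.0,
            K_d=0.1,
            K_dim=0.1,
            K_Smon=0.2,
            K_Sdim=0.02,
            R_total=0.04,
            S_total=1.0,
            D_total=0.0,
        )


def make_parameters(values: Mapping[str, float]) -> Parameters:
    """Build validated :class:`Parameters` from a flat name→value mapping.

    Raises
    ------
    ValidationError
        If a required field is missing, an unknown field is supplied, or a
        value violates its constraint (non-positive dissociation constant,
        negative total or K_A).
    """
    known = {f.name for f in dataclasses.fields(Parameters)}
    unknown = set(values) - known
    if unknown:
        raise ValidationError(f"unknown parameter field(s): {sorted(unknown)}")
    required = {
        f.name
        for f in dataclasses.fields(Parameters)
        if f.default is dataclasses.MISSING
    }
    missing = required - set(values)
    if missing:
        raise ValidationError(f"missing required parameter field(s): {sorted(missing)}")
    try:
        numeric = {k: float(v) for k, v in values.items()}
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric parameter value: {exc}") from exc
    return Parameters(**numeric)


def read_parameters(path: str | pathlib.Path) -> Parameters:
    """Read :class:`Parameters` from a flat JSON or YAML key-value file."""
    path = pathlib.Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        import yaml

        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValidationError(
            f"{path}: expected a flat mapping of parameter names to numbers"
        )
    return make_parameters(data)


@dataclass(frozen=True)
class DimensionlessGroups:
    """The four dimensionless ratios the closed forms are written in.

    ``RAF_rel`` = R_total/K_dim, ``d_rel`` = free drug/K_d,
    ``s_rel`` = free 14-3-3/K_Sdim (DS coupling),
    ``S_rel`` = 14-3-3/K_Smon (CAS coupling).
    """

    RAF_rel: float
    d_rel: float
    s_rel: float
    S_rel: float


def dimensionless(
    params: Parameters, d_free: float, s_free: float
) -> DimensionlessGroups:
    """Compute the dimensionless groups at given free drug and free 14-3-3.

    Parameters
    ----------
    params : Parameters
    d_free : float
        Unbound drug concentration (µM), ≥ 0.
    s_free : float
        Unbound 14-3-3 dimer concentration (µM), ≥ 0.
    """
    if d_free < 0:
        raise ValidationError(f"d_free must be >= 0 (got {d_free!r})")
    if s_free < 0:
        raise ValidationError(f"s_free must be >= 0 (got {s_free!r})")
    return DimensionlessGroups(
        RAF_rel=params.R_total / params.K_dim,
        d_rel=d_free / params.K_d,
        s_rel=s_free / params.K_Sdim,
        S_rel=s_free / params.K_Smon,
    )


@dataclass(frozen=True)
class AlphaSpec:
    """Meta-parameter trading DS strength against CAS strength.

    Applying ``alpha`` maps K_Sdim → alpha·K_Sdim (weakening the dimer
    interaction) and K_Smon → K_Smon/alpha (strengthening the monomer
    interaction). Small alpha therefore favors strong DS; large alpha favors
    strong CAS; alpha = 1 is the identity.
    """

    alpha: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and self.alpha > 0):
            raise ValidationError(f"alpha must be finite and > 0 (got {self.alpha!r})")


def apply_alpha(params: Parameters, spec: AlphaSpec | float) -> Parameters:
    """Return a copy of ``params`` with the alpha rescaling applied."""
    if not isinstance(spec, AlphaSpec):
        spec = AlphaSpec(float(spec))
    return params.replace(
        K_Sdim=params.K_Sdim * spec.alpha,
        K_Smon=params.K_Smon / spec.alpha,
    )
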