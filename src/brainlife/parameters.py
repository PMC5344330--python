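"""Model parameter space: definition, validation, and flat TOML (de)serialization.

The model is parameterized by 22 quantities measured in kg, MJ (megajoules),
years, and an arbitrary "skill unit":

* newborn tissue masses ``x_b0, x_r0, x_s0`` (brain, reproductive, somatic);
* tissue metabolism: the scaling constant ``K`` and exponent ``beta`` of the
  maximal resting metabolic rate, plus mass-specific maintenance rates
  ``B_b, B_r, B_s`` and synthesis heats ``E_b, E_r, E_s``;
* demography: fecundity constant ``f0``, mortality rate ``mu``, and terminal
  reproductive age ``T``;
* skill: newborn skill ``x_k0``, the brain metabolic fraction ``s_k`` spent on
  skills, the per-skill maintenance (memory) rate ``B_k`` and learning heat
  ``E_k``;
* maternal care: facilitation at birth ``phi0`` and its decay rate ``phi_r``;
* energy extraction: environmental difficulty ``alpha`` and skill
  effectiveness ``gamma``.

Two bookkeeping fields complete the set: ``competence_form`` selects a power
or exponential competence function, and ``C`` is the density-dependence
proportionality constant (it rescales R0 but never moves the optimum).

No unit conversion is performed anywhere: values are used exactly as given.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Union

__all__ = [
    "ParameterSet",
    "ConfigurationError",
    "ValidationError",
    "load_parameters",
    "save_parameters",
    "benchmark_parameters",
    "REQUIRED_KEYS",
    "OPTIONAL_KEYS",
]


class ConfigurationError(ValueError):
    """A parameter file is missing a required key or cannot be parsed."""


class ValidationError(ValueError):
    """A parameter value violates its documented bound."""


COMPETENCE_FORMS = ("power", "exponential")

#: The 22 model parameters; every parameter file must define all of them.
REQUIRED_KEYS = (
    "x_b0", "x_r0", "x_s0",
    "K", "beta", "B_b", "B_r", "B_s", "E_b", "E_r", "E_s",
    "f0", "mu", "T",
    "x_k0",
    "s_k", "B_k", "E_k",
    "phi0", "phi_r",
    "alpha", "gamma",
)

#: Optional keys with defaults: C = 1, competence_form = "power".
OPTIONAL_KEYS = ("C", "competence_form")

# fields that must be strictly positive; the rest of the numerics are >= 0
_STRICTLY_POSITIVE = (
    "x_b0", "x_r0", "x_s0",
    "K", "beta", "B_b", "B_r", "B_s", "E_b", "E_r", "E_s",
    "f0", "T", "B_k", "E_k", "phi_r", "C",
)
_NON_NEGATIVE = ("alpha", "gamma", "x_k0", "phi0", "mu")


@dataclass(frozen=True)
class ParameterSet:
    """All model parameters, validated on construction.

    Units: masses kg, heats MJ, time years, skill in "skill units";
    ``K`` is MJ·year⁻¹·kg⁻ᵝ, ``B_i`` MJ·year⁻¹·kg⁻¹, ``E_i`` MJ·kg⁻¹,
    ``f0`` offspring·year⁻¹·kg⁻¹, ``mu`` and ``phi_r`` year⁻¹,
    ``B_k`` MJ·year⁻¹·skill⁻¹, ``E_k`` MJ·skill⁻¹; all else dimensionless.
    """

    # (P1) newborn tissue masses
    x_b0: float
    x_r0: float
    x_s0: float
    # (P2) tissue metabolism
    K: float
    beta: float
    B_b: float
    B_r: float
    B_s: float
    E_b: float
    E_r: float
    E_s: float
    # (P3) demography
    f0: float
    mu: float
    T: float
    # (P4) newborn skill
    x_k0: float
    # (P5) skill metabolism
    s_k: float
    B_k: float
    E_k: float
    # (P6) maternal care
    phi0: float
    phi_r: float
    # (P7) energy extraction
    alpha: float
    gamma: float
    # bookkeeping
    competence_form: str = "power"
    C: float = 1.0

    def __post_init__(self) -> None:
        for name in _STRICTLY_POSITIVE:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be strictly positive and finite, got {v!r}")
        for name in _NON_NEGATIVE:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0):
                raise ValidationError(f"{name} must be >= 0 and finite, got {v!r}")
        if not 0.0 <= self.s_k <= 1.0:
            raise ValidationError(f"s_k must lie in [0, 1], got {self.s_k!r}")
        if not 0.0 <= self.phi0 < 1.0:
            raise ValidationError(f"phi0 must lie in [0, 1), got {self.phi0!r}")
        if self.competence_form not in COMPETENCE_FORMS:
            raise ValidationError(
                f"competence_form must be one of {COMPETENCE_FORMS}, got {self.competence_form!r}"
            )
        # With power competence, zero newborn skill and gamma > 0 pins
        # extraction efficiency at 0 forever: the dynamics collapse.
        if self.competence_form == "power" and self.gamma > 0 and self.x_k0 <= 0:
            raise ValidationError(
                "x_k0 must be > 0 with power competence and gamma > 0 "
                "(otherwise extraction efficiency is identically zero at birth)"
            )

    # -- convenience -------------------------------------------------------
    @property
    def newborn_body_mass(self) -> float:
        """Total newborn body mass x_b0 + x_r0 + x_s0, kg."""
        return self.x_b0 + self.x_r0 + self.x_s0

    def replace(self, **changes) -> "ParameterSet":
        """Return a copy with some fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_parameters(path: Union[str, Path]) -> ParameterSet:
    """Read a flat TOML parameter file into a validated :class:`ParameterSet`.

    The file must define every one of the 22 required keys by name; ``C``
    (default 1) and ``competence_form`` (default ``"power"``) are optional.
    Unknown keys raise a :class:`ConfigurationError`, which catches typos.
    """
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except FileNotFoundError:
        raise ConfigurationError(f"parameter file not found: {path}") from None
    except tomllib.TOMLDecodeError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from None

    missing = [k for k in REQUIRED_KEYS if k not in raw]
    if missing:
        raise ConfigurationError(f"missing required parameter key(s): {', '.join(missing)}")
    unknown = [k for k in raw if k not in REQUIRED_KEYS and k not in OPTIONAL_KEYS]
    if unknown:
        raise ConfigurationError(f"unknown parameter key(s): {', '.join(unknown)}")

    kwargs = {}
    for k, v in raw.items():
        if k == "competence_form":
            kwargs[k] = str(v)
        else:
            kwargs[k] = float(v)
    return ParameterSet(**kwargs)


def save_parameters(p: ParameterSet, path: Union[str, Path]) -> Path:
    """Write ``p`` to a flat TOML file; round-trips at full float precision."""
    path = Path(path)
    lines = ["# brainlife parameter file (kg / MJ / year / skill-unit)"]
    for field in dataclasses.fields(p):
        v = getattr(p, field.name)
        if isinstance(v, str):
            lines.append(f'{field.name} = "{v}"')
        else:
            lines.append(f"{field.name} = {float(v)!r}")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write parameter file {path}: {exc}") from exc
    return path


def benchmark_parameters(competence_form: str = "power") -> ParameterSet:
    """Return the packaged benchmark parameter set for the given competence form.

    These are *synthetic reconstructions*: the physiological constants are
    assembled from published human-female physiology (newborn tissue masses,
    ontogenetic resting-metabolic-rate scaling, tissue-specific maintenance
    and synthesis costs) and the skill/environment parameters were calibrated
    by trial and error so that the optimized strategy roughly matches observed
    human-female ontogenetic body and brain mass.  See ``docs/methods.md``.
    """
    if competence_form not in COMPETENCE_FORMS:
        raise ValidationError(
            f"competence_form must be one of {COMPETENCE_FORMS}, got {competence_form!r}"
        )
    from importlib.resources import files

    name = f"benchmark_{competence_form}_synthetic.toml"
    resource = files("brainlife.data").joinpath(name)
    return load_parameters(Path(str(resource)))
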