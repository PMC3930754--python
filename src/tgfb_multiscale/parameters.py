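"""Model parameters and initial conditions.

Every rate constant, capacity, exponent and delay of the multi-scale
TGF-beta model lives in :class:`ParameterSet`; the corresponding initial
conditions live in :class:`InitialState`.  Both carry the published default
values and can be overridden from a sectioned YAML configuration
(``cellular`` / ``tissue`` / ``bone`` sections, symbol names as keys).

Units are carried as metadata strings (see :data:`UNITS`); no automatic
unit conversion is performed because the bone niche uses effective
reference volumes/surfaces (``V_osteon``, ``V_frac``, ``S_frac``).

Sign conventions
----------------
Phenotype-indexed vectors are ordered from healthy (index 0) to the
malignant phenotype ``Phi``.  The healthy entry of the proliferation-rate
vector ``r_p`` is *negative* by default: healthy epithelium in the duct
model carries a net negative proliferation rate (slow net decline), which
is what calibrates the malignant take-over to roughly two years.  All
other per-phenotype vectors have positive entries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import logging
from dataclasses import dataclass, field
from typing import Any

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterSet",
    "InitialState",
    "ValidationError",
    "ConfigError",
    "default_parameters",
    "default_initial_state",
    "load_parameters",
    "load_initial_state",
    "serialize_parameters",
    "serialize_initial_state",
    "parameters_hash",
]


class ValidationError(ValueError):
    """A parameter or state value violates a model invariant."""


class ConfigError(ValueError):
    """A configuration document could not be parsed or contains unknown keys."""


#: unit strings, keyed by symbol
UNITS: dict[str, str] = {
    "beta_sM": "nmol",
    "R_sM": "nmol",
    "r_syn": "1/s",
    "r_sgn": "1/s",
    "r_pc": "1/s",
    "r_b": "1/(nmol s)",
    "r_u": "1/s",
    "Phi": "-",
    "r_p": "1/s",
    "r_a": "1/s",
    "r_d": "1/s",
    "r_m": "1/s",
    "g_p": "-",
    "g_a": "-",
    "p_Phi": "-",
    "C": "1/V_neigh",
    "alpha": "1/s",
    "gamma": "1/nmol",
    "f_Ocy": "S_frac/(V_osteon day)",
    "a_Ocy": "1/(V_osteon day)",
    "r_Oc": "V_frac/(nmol^2 day)",
    "a_Oc": "1/day",
    "p_Lng": "um/(nmol day)",
    "m_Lng": "um/(nmol day)",
    "a_Lng": "1/day",
    "a_Ob": "1/day",
    "p_RKL": "nmol V_osteon/(V_frac day)",
    "r_RKL": "nmol S_frac/(V_frac day)",
    "d_RKL": "1/day",
    "p_BMP": "nmol V_osteon/(V_frac day)",
    "d_BMP": "1/day",
    "p_CSF": "nmol V_osteon/(V_frac day)",
    "d_CSF": "1/day",
    "r_bn": "V_frac/(nmol day)",
    "f_bn": "S_frac/(nmol day)",
    "r_beta": "nmol/day",
    "d_beta": "1/day",
    "N_c": "-",
    "tau_bar": "day",
    "Delta": "day",
    "Ocy_max": "1/V_osteon",
    "beta_bar": "nmol/V_frac",
    "kappa": "V_osteon/V_frac",
    "k_CSF": "V_frac/day",
    "L_ref": "um nmol/S_frac",
    "s_f": "nmol",
    "s_r": "nmol",
    "c_sec": "nmol/(cell day)",
    "c_abs": "1/(cell day)",
    "r_dmg": "1/day",
}


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants of the multi-scale model.

    Cellular-scale rates are per second, bone-niche rates per day.
    Phenotype-indexed entries are tuples of length ``Phi + 1`` ordered by
    increasing phenotype severity.

    The last block (``k_CSF`` ... ``r_dmg``) holds closure constants of the
    bone niche that are not part of the published rate table: they were
    calibrated once so that the fracture-control run is balance-neutral and
    the default cancer load removes about one percentage point of bone
    mineral density, and are frozen here (see ``docs/methods.md``).
    """

    # -- cellular exchange -------------------------------------------------
    beta_sM: tuple[float, ...] = (1.853, 1.724, 1.614, 1.669)
    R_sM: tuple[float, ...] = (7.47, 6.713, 5.017, 4.128)
    r_syn: float = 133.333
    r_sgn: float = 0.003018
    r_pc: float = 10.0
    r_b: float = 0.0074
    r_u: float = 0.007

    # -- tissue ------------------------------------------------------------
    Phi: int = 3
    r_p: tuple[float, ...] = (-1.0e-6, 1.0e-6, 1.0e-6, 1.0e-6)
    r_a: float = 9.0e-8
    r_d: float = 1.0e-8
    r_m: float = 1.0e-14
    g_p: tuple[float, ...] = (0.12, 0.06, 0.0, -0.06)
    g_a: tuple[float, ...] = (0.12, 0.06, 0.0, -0.06)
    p_Phi: float = 5.0e-7
    C: tuple[float, ...] = (6.0, 6.0, 6.0, 8.0)
    alpha: float = 1.0
    gamma: float = 1.0

    # -- bone niche (published) -------------------------------------------
    f_Ocy: float = 0.00032
    a_Ocy: float = 30.0
    r_Oc: float = 0.8
    a_Oc: float = 0.0625
    p_Lng: float = 50.0
    m_Lng: float = 50.0
    a_Lng: float = 0.1525
    a_Ob: float = 0.1525
    p_RKL: float = 300.0
    r_RKL: float = 2.5
    d_RKL: float = 8.6643
    p_BMP: float = 1.0
    d_BMP: float = 8.6643
    p_CSF: float = 0.1
    d_CSF: float = 69.3147
    r_bn: float = 9.4e-4
    f_bn: float = 5.9098e-6
    r_beta: float = 2.2e-10
    d_beta: float = 0.1189
    N_c: float = 2000.0
    tau_bar: float = 6.02
    Delta: float = 22.36
    Ocy_max: float = 900.0
    beta_bar: float = 8.0e-8
    kappa: float = 1.0

    # -- bone niche closure constants (calibrated, frozen) -----------------
    k_CSF: float = 0.1
    L_ref: float = 1.0
    s_f: float = 46175.883614
    s_r: float = 369.900325
    c_sec: float = 1.975494e-11
    c_abs: float = 1.0e-5
    r_dmg: float = 0.04

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any invariant violation."""
        if int(self.Phi) < 0:
            raise ValidationError("Phi must be a non-negative integer")
        n = int(self.Phi) + 1
        for name in ("beta_sM", "R_sM", "r_p", "g_p", "g_a", "C"):
            vec = getattr(self, name)
            if len(vec) != n:
                raise ValidationError(
                    f"{name} must have length Phi+1={n}, got {len(vec)}"
                )
        # r_p is a *net* per-phenotype rate and may be negative (healthy
        # decline); g_p/g_a are exponents and beta_sM/R_sM must be >= 0.
        nonneg = [
            "beta_sM", "R_sM", "r_syn", "r_sgn", "r_pc", "r_b", "r_u",
            "r_a", "r_d", "r_m", "p_Phi", "alpha", "gamma",
            "f_Ocy", "a_Ocy", "r_Oc", "a_Oc", "p_Lng", "m_Lng", "a_Lng",
            "a_Ob", "p_RKL", "r_RKL", "d_RKL", "p_BMP", "d_BMP", "p_CSF",
            "d_CSF", "r_bn", "f_bn", "r_beta", "d_beta", "N_c", "Delta",
            "Ocy_max", "beta_bar", "kappa",
            "k_CSF", "L_ref", "s_f", "s_r", "c_sec", "c_abs", "r_dmg",
        ]
        for name in nonneg:
            val = getattr(self, name)
            vals = val if isinstance(val, tuple) else (val,)
            for v in vals:
                if not (v >= 0.0):
                    raise ValidationError(f"{name} must be >= 0, got {val}")
        if not (self.tau_bar > 0.0):
            raise ValidationError("delay tau_bar must be strictly positive")
        if not (self.p_Phi <= 1.0):
            raise ValidationError("p_Phi is a probability, must be <= 1")
        for cap in self.C:
            if not (cap > 0.0):
                raise ValidationError(f"cell capacities must be > 0, got {self.C}")


@dataclass(frozen=True)
class InitialState:
    """Initial values of every state variable of the three models.

    Per-phenotype vectors are in nmol (cellular scale) or cells per
    neighbour volume (tissue scale); bone entries use the effective osteon
    reference volumes.  ``BMD`` is a percentage of healthy baseline.
    """

    B_e: tuple[float, ...] = (2.0, 2.0, 2.0, 2.0)
    R: tuple[float, ...] = (2.0, 2.0, 2.0, 2.0)
    B_i: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    B_dr: float = 0.1
    N_neigh: tuple[float, ...] = (6.0, 0.0, 0.0, 0.0)
    Ocy: float = 900.0
    Oc: float = 0.0
    Lng: float = 0.0
    Ob: float = 0.0
    RANKL: float = 0.0
    BMP: float = 0.0
    CSF: float = 0.0
    BMD: float = 100.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            vals = val if isinstance(val, tuple) else (val,)
            for v in vals:
                if not (v >= 0.0):
                    raise ValidationError(f"{f.name} must be >= 0, got {val}")


#: which symbols belong to which configuration section
PARAM_SECTIONS: dict[str, tuple[str, ...]] = {
    "cellular": ("beta_sM", "R_sM", "r_syn", "r_sgn", "r_pc", "r_b", "r_u"),
    "tissue": ("Phi", "r_p", "r_a", "r_d", "r_m", "g_p", "g_a", "p_Phi",
               "C", "alpha", "gamma"),
    "bone": ("f_Ocy", "a_Ocy", "r_Oc", "a_Oc", "p_Lng", "m_Lng", "a_Lng",
             "a_Ob", "p_RKL", "r_RKL", "d_RKL", "p_BMP", "d_BMP", "p_CSF",
             "d_CSF", "r_bn", "f_bn", "r_beta", "d_beta", "N_c", "tau_bar",
             "Delta", "Ocy_max", "beta_bar", "kappa", "k_CSF", "L_ref",
             "s_f", "s_r", "c_sec", "c_abs", "r_dmg"),
}

STATE_SECTIONS: dict[str, tuple[str, ...]] = {
    "cellular": ("B_e", "R", "B_i", "B_dr"),
    "tissue": ("N_neigh",),
    "bone": ("Ocy", "Oc", "Lng", "Ob", "RANKL", "BMP", "CSF", "BMD"),
}


def default_parameters() -> ParameterSet:
    """The published parameter table, phenotype vectors ordered by severity."""
    return ParameterSet()


def default_initial_state() -> InitialState:
    """The published initial-condition table."""
    return InitialState()


def _coerce(cls: type, name: str, value: Any) -> Any:
    proto = getattr(cls(), name)
    if isinstance(proto, tuple):
        if not isinstance(value, (list, tuple)):
            raise ConfigError(f"{name} must be a list, got {value!r}")
        return tuple(float(v) for v in value)
    if isinstance(proto, int) and not isinstance(proto, bool):
        return int(value)
    return float(value)


def _load(cls: type, sections: dict[str, tuple[str, ...]], text: str):
    try:
        doc = yaml.safe_load(io.StringIO(text))
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"configuration parse failure{line}: {exc}") from exc
    if doc is None:
        return cls()
    if not isinstance(doc, dict):
        raise ConfigError("configuration root must be a mapping of sections")
    overrides: dict[str, Any] = {}
    for section, entries in doc.items():
        if section not in sections:
            raise ConfigError(f"unknown configuration section {section!r}")
        if entries is None:
            continue
        if not isinstance(entries, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key, value in entries.items():
            if key not in sections[section]:
                raise ConfigError(
                    f"unknown key {key!r} in section {section!r}"
                )
            overrides[key] = _coerce(cls, key, value)
            logger.info("config override: %s.%s = %r", section, key, value)
    return cls(**overrides)


def load_parameters(config_text: str) -> ParameterSet:
    """Parse a sectioned YAML document into a :class:`ParameterSet`.

    Missing keys fall back to the published defaults; unknown sections or
    keys are rejected; invalid values raise :class:`ValidationError` naming
    the offending symbol.
    """
    return _load(ParameterSet, PARAM_SECTIONS, config_text)


def load_initial_state(config_text: str) -> InitialState:
    """Parse a sectioned YAML document into an :class:`InitialState`."""
    return _load(InitialState, STATE_SECTIONS, config_text)


def _serialize(obj: Any, sections: dict[str, tuple[str, ...]]) -> str:
    doc: dict[str, dict[str, Any]] = {}
    for section, names in sections.items():
        doc[section] = {}
        for name in names:
            val = getattr(obj, name)
            doc[section][name] = list(val) if isinstance(val, tuple) else val
    return yaml.safe_dump(doc, sort_keys=False)


def serialize_parameters(params: ParameterSet) -> str:
    """YAML document such that ``load_parameters(serialize(P)) == P``."""
    return _serialize(params, PARAM_SECTIONS)


def serialize_initial_state(state: InitialState) -> str:
    return _serialize(state, STATE_SECTIONS)


def parameters_hash(params: ParameterSet) -> str:
    """Stable hex digest identifying a parameter set (for run manifests)."""
    return hashlib.sha256(serialize_parameters(params).encode()).hexdigest()[:16]
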