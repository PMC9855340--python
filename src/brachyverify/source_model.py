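"""Analytic source model: radial dose function and 2D anisotropy function.

A high-dose-rate line source is described by its physical constants
(active length L, dose-rate constant Lambda, radionuclide half-life) and
by fitted dosimetric functions that replace the table interpolation a
planning system performs:

* the radial dose function  g_L(r) = h r^i / (1 + j r^k), normalized so
  that g_L(1 cm) is (very nearly) 1;
* the 2D anisotropy function

      F(r, theta) = k(r) + a(r) u^e(r) / (1 + b(r) u^e(r))
                         + a'(r) (1-u)^e'(r) / (1 + b'(r) (1-u)^e'(r)),

  with u = theta/180 and each coefficient itself a three-term fit
  c1 r^c2 + c3 r + c4 in the radial distance.

The module ships a built-in parameter set for the GammaMed Plus HDR
Ir-192 source and can load further models from YAML documents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError, DomainError, NumericError

__all__ = [
    "CoefficientQuad",
    "SourceSpec",
    "eval_coefficient",
    "radial_dose",
    "anisotropy",
    "load_source_spec",
    "builtin_source_names",
    "THETA_CLAMP_DEG",
]

#: Polar-angle clamp (degrees) applied before evaluating the anisotropy
#: fit: the fractional-power terms diverge at the exact poles, where the
#: fitted form was never intended to be evaluated.
THETA_CLAMP_DEG = 0.05


@dataclass(frozen=True)
class CoefficientQuad:
    """One fitted anisotropy coefficient c(r) = c1·r^c2 + c3·r + c4.

    ``c2`` is a dimensionless exponent; absent table entries are exactly
    zero (a zero exponent makes the power term the constant ``c1``).
    """

    c1: float = 0.0
    c2: float = 0.0
    c3: float = 0.0
    c4: float = 0.0

    def __post_init__(self):
        for name in ("c1", "c2", "c3", "c4"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ConfigurationError(f"coefficient {name} is not finite: {v!r}")

    @classmethod
    def from_sequence(cls, seq) -> "CoefficientQuad":
        vals = list(seq)
        if len(vals) != 4:
            raise ConfigurationError(
                f"coefficient quad needs exactly 4 values (c1..c4), got {len(vals)}"
            )
        return cls(*(float(v) for v in vals))

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.c1, self.c2, self.c3, self.c4)


@dataclass(frozen=True)
class SourceSpec:
    """Physical and fitted dosimetric parameters of one line source.

    Units: ``active_length_L`` in cm, ``dose_rate_constant_Lambda`` in
    cGy·h⁻¹·U⁻¹, ``half_life`` in days. ``r_min``/``r_max`` bound the
    validity window of the fitted functions in cm; evaluations outside
    are flagged (not refused) downstream.
    """

    name: str
    active_length_L: float
    dose_rate_constant_Lambda: float
    half_life: float
    radial_h: float
    radial_i: float
    radial_j: float
    radial_k: float
    aniso_k: CoefficientQuad
    aniso_a: CoefficientQuad
    aniso_b: CoefficientQuad
    aniso_e: CoefficientQuad
    aniso_a_prime: CoefficientQuad
    aniso_b_prime: CoefficientQuad
    aniso_e_prime: CoefficientQuad
    r_min: float = 0.2
    r_max: float = 10.0
    delta_g_percent: float = 0.5
    delta_F_percent: float = 0.9

    def __post_init__(self):
        if not (self.active_length_L > 0):
            raise ConfigurationError(
                f"active_length_L must be > 0, got {self.active_length_L!r}")
        if not (self.dose_rate_constant_Lambda > 0):
            raise ConfigurationError(
                f"dose_rate_constant_Lambda must be > 0, got "
                f"{self.dose_rate_constant_Lambda!r}")
        if not (self.half_life > 0):
            raise ConfigurationError(f"half_life must be > 0, got {self.half_life!r}")
        if not (0 < self.r_min < self.r_max):
            raise ConfigurationError(
                f"need 0 < r_min < r_max, got r_min={self.r_min!r}, r_max={self.r_max!r}")
        g1 = radial_dose(self, 1.0)
        if abs(g1 - 1.0) > 0.005:
            raise ConfigurationError(
                f"radial dose function at 1 cm is {g1:.5f}; a fitted g_L must be "
                "normalized to 1 at the reference radius within 0.5%")


def eval_coefficient(r: float, quad: CoefficientQuad) -> float:
    """Evaluate one anisotropy coefficient c(r) = c1·r^c2 + c3·r + c4.

    A zero exponent means a constant term (c1·r^0 = c1 for all r > 0),
    matching fit tables where absent exponents are dashes.
    """
    if not (r > 0):
        raise DomainError(f"coefficient evaluation needs r > 0, got r={r!r}")
    return quad.c1 * r ** quad.c2 + quad.c3 * r + quad.c4


def radial_dose(spec: SourceSpec, r: float) -> float:
    """Radial dose function g_L(r) = h·r^i / (1 + j·r^k).

    Captures the transverse-axis falloff beyond the inverse-square law
    (attenuation and scatter in water); dimensionless, ~1 at r = 1 cm.
    """
    if not (r > 0):
        raise DomainError(f"radial dose function needs r > 0, got r={r!r}")
    value = spec.radial_h * r ** spec.radial_i / (1.0 + spec.radial_j * r ** spec.radial_k)
    if not math.isfinite(value):
        raise NumericError(f"radial dose function non-finite at r={r!r}")
    return value


def anisotropy(spec: SourceSpec, r: float, theta: float) -> float:
    """2D anisotropy function F(r, theta); theta in degrees, in [0, 180].

    theta is clamped away from the exact poles (see
    :data:`THETA_CLAMP_DEG`) where the fractional powers of u and 1-u
    diverge; use :func:`anisotropy_with_flag` to learn whether clamping
    occurred.
    """
    return anisotropy_with_flag(spec, r, theta)[0]


def anisotropy_with_flag(spec: SourceSpec, r: float, theta: float) -> tuple[float, bool]:
    """As :func:`anisotropy`, returning ``(value, theta_was_clamped)``."""
    if not (r > 0):
        raise DomainError(f"anisotropy needs r > 0, got r={r!r}")
    if not (0.0 <= theta <= 180.0):
        raise DomainError(f"anisotropy needs 0 <= theta <= 180 degrees, got {theta!r}")
    clamped = theta < THETA_CLAMP_DEG or theta > 180.0 - THETA_CLAMP_DEG
    th = min(max(theta, THETA_CLAMP_DEG), 180.0 - THETA_CLAMP_DEG)
    u = th / 180.0

    k_r = eval_coefficient(r, spec.aniso_k)
    a_r = eval_coefficient(r, spec.aniso_a)
    b_r = eval_coefficient(r, spec.aniso_b)
    e_r = eval_coefficient(r, spec.aniso_e)
    ap_r = eval_coefficient(r, spec.aniso_a_prime)
    bp_r = eval_coefficient(r, spec.aniso_b_prime)
    ep_r = eval_coefficient(r, spec.aniso_e_prime)

    u_pow = u ** e_r
    v_pow = (1.0 - u) ** ep_r
    den1 = 1.0 + b_r * u_pow
    den2 = 1.0 + bp_r * v_pow
    if den1 == 0.0 or den2 == 0.0:
        raise NumericError(
            f"anisotropy denominator vanished at r={r!r} cm, theta={theta!r} deg")
    value = k_r + a_r * u_pow / den1 + ap_r * v_pow / den2
    if not math.isfinite(value):
        raise NumericError(f"anisotropy non-finite at r={r!r} cm, theta={theta!r} deg")
    return value, clamped


# ---------------------------------------------------------------------------
# Built-in source models and configuration loading
# ---------------------------------------------------------------------------

# GammaMed Plus HDR Ir-192. Radial and anisotropy fit parameters are the
# published analytic fits to Monte Carlo data for this source; L, Lambda
# and the half-life are consensus physical data and may be overridden per
# institution through a YAML source document.
_GAMMAMED_PLUS = {
    "name": "GammaMedPlus-Ir192",
    "active_length_cm": 0.35,
    "dose_rate_constant": 1.118,
    "half_life_days": 73.83,
    "radial": {"h": 1.001, "i": 7.69e-3, "j": 2.1e-4, "k": 2.63},
    "anisotropy": {
        "k": [-2.30569, -1.98e-2, 2.847e-2, 2.27378],
        "a": [0.0, 0.0, -3.25e-1, 11.5962],
        "b": [4.97e-1, -1.46, 5.2e-1, 24.586],
        "e": [-1.7e-3, -2.96, 0.0, 1.469],
        "a_prime": [0.0, 0.0, -6.3265e-1, 17.0192],
        "b_prime": [-14.54, -1.5588e-1, -4.47e-1, 39.889],
        "e_prime": [-1.14e-1, -1.057, -1.81e-2, 1.2924],
    },
}

_BUILTIN_MODELS: dict[str, dict] = {_GAMMAMED_PLUS["name"]: _GAMMAMED_PLUS}


def builtin_source_names() -> list[str]:
    """Names of source models shipped with the package."""
    return sorted(_BUILTIN_MODELS)


def _spec_from_mapping(doc: dict) -> SourceSpec:
    def require(mapping, key, where):
        if not isinstance(mapping, dict) or key not in mapping:
            raise ConfigurationError(f"source model document missing field '{where}{key}'")
        return mapping[key]

    radial = require(doc, "radial", "")
    aniso = require(doc, "anisotropy", "")
    quads = {}
    for key in ("k", "a", "b", "e", "a_prime", "b_prime", "e_prime"):
        quads[key] = CoefficientQuad.from_sequence(require(aniso, key, "anisotropy."))
    kwargs = {}
    if "r_min_cm" in doc:
        kwargs["r_min"] = float(doc["r_min_cm"])
    if "r_max_cm" in doc:
        kwargs["r_max"] = float(doc["r_max_cm"])
    if "delta_g_percent" in doc:
        kwargs["delta_g_percent"] = float(doc["delta_g_percent"])
    if "delta_F_percent" in doc:
        kwargs["delta_F_percent"] = float(doc["delta_F_percent"])
    return SourceSpec(
        name=str(require(doc, "name", "")),
        active_length_L=float(require(doc, "active_length_cm", "")),
        dose_rate_constant_Lambda=float(require(doc, "dose_rate_constant", "")),
        half_life=float(require(doc, "half_life_days", "")),
        radial_h=float(require(radial, "h", "radial.")),
        radial_i=float(require(radial, "i", "radial.")),
        radial_j=float(require(radial, "j", "radial.")),
        radial_k=float(require(radial, "k", "radial.")),
        aniso_k=quads["k"],
        aniso_a=quads["a"],
        aniso_b=quads["b"],
        aniso_e=quads["e"],
        aniso_a_prime=quads["a_prime"],
        aniso_b_prime=quads["b_prime"],
        aniso_e_prime=quads["e_prime"],
        **kwargs,
    )


def load_source_spec(source: str | Path | dict) -> SourceSpec:
    """Load a source model by built-in name, YAML path, or mapping.

    ``source`` may be the name of a shipped model (``"GammaMedPlus-Ir192"``),
    a path to a YAML source document, or an already-parsed mapping with
    the same schema.
    """
    if isinstance(source, dict):
        return _spec_from_mapping(source)
    if isinstance(source, str) and source in _BUILTIN_MODELS:
        return _spec_from_mapping(_BUILTIN_MODELS[source])
    path = Path(source)
    if not path.exists():
        raise ConfigurationError(
            f"unknown source model {source!r}: not a built-in name "
            f"({', '.join(builtin_source_names())}) and no such file")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"source model file {path} is not a mapping document")
    return _spec_from_mapping(doc)
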