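"""Registry of the 22 published CO2-solubility prediction equations.

Every model has the form

    ln(x) = a * ln(P) [+ b * T] [+ c * EEig02d] + d

with x the CO2 solubility in mol CO2 per mol DES, P the pressure in bar,
T the temperature in K and EEig02d the dipole-weighted edge-adjacency
eigenvalue descriptor of the hydrogen-bond donor.  Eight "unfixed
temperature" models (ids 5-10) were fitted across 293-323 K; the rest were
fitted at one of the four temperatures.  The printed "+/-" half-widths are
stored as coefficient standard uncertainties (metadata; they do not enter
prediction).  One- and two-variable models without the structural
descriptor are flagged ``baseline`` — they cannot distinguish donors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable

from .errors import ModelLookupError, PredictionError

RATIOS = ("1:3", "1:4")
FIXED_TEMPERATURES_K = (293.0, 303.0, 313.0, 323.0)
#: Temperature span of the training data; predictions outside are flagged.
TRAINING_T_RANGE_K = (293.0, 323.0)
#: Tolerance for matching a requested T to a fixed-temperature model.
FIXED_T_TOLERANCE_K = 0.5


@dataclass(frozen=True)
class SolubilityModel:
    """One published equation with its printed coefficient uncertainties."""

    eq_id: int
    dataset_id: int
    ratio: str
    fixed_T_K: float | None  # None for the unfixed-temperature models
    a: float                 # on ln(P), always present
    a_unc: float
    b: float | None          # on T (K), unfixed-T three/two-variable models
    b_unc: float | None
    c: float | None          # on EEig02d
    c_unc: float | None
    d: float                 # intercept
    d_unc: float

    @property
    def baseline(self) -> bool:
        """Models without the structural descriptor; kept for completeness
        but judged inadequate for cross-donor prediction."""
        return self.c is None

    @property
    def unfixed(self) -> bool:
        return self.fixed_T_K is None

    def to_dict(self) -> dict:
        out = asdict(self)
        out["provenance"] = "Table 2"
        return out


# (eq, dataset, ratio, fixed_T, a, a_unc, b, b_unc, c, c_unc, d, d_unc)
_TABLE = [
    (5, 1, "1:3", None, 1.0284, 0.0806, None, None, None, None, -5.8136, 0.0939),
    (6, 1, "1:3", None, 1.0382, 0.0676, -0.0144, 0.0037, None, None, -1.3674, 1.1349),
    (7, 1, "1:3", None, 1.0372, 0.029, -0.0171, 0.0016, 0.3067, 0.0244, -1.134, 0.4879),
    (8, 2, "1:4", None, 1.034, 0.0873, None, None, None, None, -5.7909, 0.1016),
    (9, 2, "1:4", None, 1.0408, 0.076, -0.0142, 0.0041, None, None, -1.4155, 1.2787),
    (10, 2, "1:4", None, 1.043, 0.0318, -0.0172, 0.0017, 0.3475, 0.0268, -1.1527, 0.5351),
    (11, 3, "1:3", 293.0, 1.0211, 0.1284, None, None, None, None, -5.6132, 0.1459),
    (12, 3, "1:3", 293.0, 1.036, 0.0813, None, None, 0.4228, 0.1294, -6.3254, 0.2367),
    (13, 4, "1:4", 293.0, 1.0306, 0.1254, None, None, None, None, -5.5946, 0.1423),
    (14, 4, "1:4", 293.0, 1.0402, 0.0679, None, None, 0.4425, 0.1074, -6.3344, 0.1954),
    (15, 5, "1:3", 303.0, 1.043, 0.1452, None, None, None, None, -5.7131, 0.1694),
    (16, 5, "1:3", 303.0, 1.0339, 0.0506, None, None, 0.3113, 0.0396, -6.3119, 0.0963),
    (17, 6, "1:4", 303.0, 1.05, 0.1706, None, None, None, None, -5.6983, 0.1989),
    (18, 6, "1:4", 303.0, 1.0455, 0.0644, None, None, 0.3446, 0.0481, -6.3667, 0.1198),
    (19, 7, "1:3", 313.0, 1.0313, 0.1448, None, None, None, None, -5.8667, 0.1696),
    (20, 7, "1:3", 313.0, 1.0327, 0.0529, None, None, 0.3065, 0.0412, -6.4667, 0.1017),
    (21, 8, "1:4", 313.0, 1.0377, 0.1654, None, None, None, None, -5.842, 0.1925),
    (22, 8, "1:4", 313.0, 1.0579, 0.0646, None, None, 0.3565, 0.0517, -6.5582, 0.1282),
    (23, 9, "1:3", 323.0, 1.0546, 0.1386, None, None, None, None, -6.0674, 0.1637),
    (24, 9, "1:3", 323.0, 1.0509, 0.0571, None, None, 0.2785, 0.0431, -6.6073, 0.1075),
    (25, 10, "1:4", 323.0, 1.0422, 0.1587, None, None, None, None, -6.0222, 0.1879),
    (26, 10, "1:4", 323.0, 1.0312, 0.0678, None, None, 0.3258, 0.0526, -6.6473, 0.129),
]

_REGISTRY = tuple(SolubilityModel(*row) for row in _TABLE)
_BY_ID = {m.eq_id: m for m in _REGISTRY}


def model_registry() -> tuple[SolubilityModel, ...]:
    """All 22 published models, ids 5-26."""
    return _REGISTRY


def get_model(eq_id: int) -> SolubilityModel:
    try:
        return _BY_ID[eq_id]
    except KeyError:
        raise ModelLookupError(
            f"no registry model with id {eq_id}; valid ids are 5-26"
        ) from None


def select_model(ratio: str, T_K: float, mode: str = "auto") -> SolubilityModel:
    """Choose the published model for a molar ratio and temperature.

    ``auto`` prefers the fixed-temperature two-variable (descriptor) model
    when T matches a registry temperature within 0.5 K, falling back to the
    unfixed three-variable model; ``fixed`` requires a match; ``unfixed``
    always returns the three-variable model.
    """
    if ratio not in RATIOS:
        raise ModelLookupError(f"unsupported molar ratio {ratio!r}; choose 1:3 or 1:4")
    if mode not in ("fixed", "unfixed", "auto"):
        raise ModelLookupError(f"unknown selection mode {mode!r}")
    unfixed = next(
        m for m in _REGISTRY if m.unfixed and m.ratio == ratio and not m.baseline
    )
    if mode == "unfixed":
        return unfixed
    match = [
        m for m in _REGISTRY
        if m.fixed_T_K is not None and m.ratio == ratio and not m.baseline
        and abs(T_K - m.fixed_T_K) <= FIXED_T_TOLERANCE_K
    ]
    if match:
        return match[0]
    if mode == "fixed":
        raise ModelLookupError(
            f"no fixed-temperature model at T={T_K} K for ratio {ratio}; "
            f"registry temperatures are {FIXED_TEMPERATURES_K}"
        )
    return unfixed


@dataclass(frozen=True)
class PredictionInput:
    P_bar: float
    T_K: float
    eeig02d: float | None = None
    ratio: str = "1:3"

    def __post_init__(self) -> None:
        if not self.P_bar > 0:
            raise PredictionError(f"pressure must be positive, got {self.P_bar}")
        if not self.T_K > 0:
            raise PredictionError(f"temperature must be positive, got {self.T_K}")
        if self.eeig02d is not None and not math.isfinite(self.eeig02d):
            raise PredictionError("descriptor value must be finite")


@dataclass(frozen=True)
class PredictionResult:
    ln_x: float
    x: float
    eq_id: int
    pressure_extrapolated: bool
    temperature_extrapolated: bool


def predict_ln_x(model: SolubilityModel, inp: PredictionInput) -> float:
    """ln(x) = a*ln(P) [+ b*T] [+ c*EEig02d] + d."""
    if model.fixed_T_K is not None and abs(inp.T_K - model.fixed_T_K) > FIXED_T_TOLERANCE_K:
        raise PredictionError(
            f"model {model.eq_id} was fitted at {model.fixed_T_K} K and cannot be "
            f"evaluated at {inp.T_K} K; use the unfixed-temperature model instead"
        )
    ln_x = model.a * math.log(inp.P_bar) + model.d
    if model.b is not None:
        ln_x += model.b * inp.T_K
    if model.c is not None:
        if inp.eeig02d is None:
            raise PredictionError(
                f"model {model.eq_id} needs an EEig02d descriptor value"
            )
        ln_x += model.c * inp.eeig02d
    return ln_x


def _pressure_range(model: SolubilityModel) -> tuple[float, float]:
    # local import: datasets_io also imports this module
    from .data import catalog_entry

    entry = catalog_entry(model.dataset_id)
    return tuple(entry.P_range_bar)


def predict_x(model: SolubilityModel, inp: PredictionInput) -> PredictionResult:
    """Solubility x = exp(ln_x), with extrapolation flags.

    Predictions are warned, never refused, outside the training window:
    the pressure flag uses the model's own dataset range, the temperature
    flag the overall 293-323 K span.
    """
    ln_x = predict_ln_x(model, inp)
    p_lo, p_hi = _pressure_range(model)
    t_lo, t_hi = TRAINING_T_RANGE_K
    return PredictionResult(
        ln_x=ln_x,
        x=math.exp(ln_x),
        eq_id=model.eq_id,
        pressure_extrapolated=not (p_lo <= inp.P_bar <= p_hi),
        temperature_extrapolated=not (t_lo <= inp.T_K <= t_hi),
    )


def registry_to_json(path=None) -> str:
    """Export the registry (coefficients, uncertainties, provenance)."""
    text = json.dumps([m.to_dict() for m in _REGISTRY], indent=1)
    if path is not None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write(text)
    return text


def registry_from_json(source) -> tuple[SolubilityModel, ...]:
    """Load a registry previously exported with :func:`registry_to_json`."""
    if isinstance(source, str) and source.lstrip().startswith("["):
        raw = json.loads(source)
    else:
        with open(source, "rt", encoding="utf-8") as fh:
            raw = json.load(fh)
    models = []
    for item in raw:
        item = dict(item)
        item.pop("provenance", None)
        models.append(SolubilityModel(**item))
    return tuple(models)


def sign_invariants_hold(models: Iterable[SolubilityModel] | None = None) -> bool:
    """a > 0 always; b < 0 and c > 0 whenever present."""
    for m in models if models is not None else _REGISTRY:
        if m.a <= 0:
            return False
        if m.b is not None and m.b >= 0:
            return False
        if m.c is not None and m.c <= 0:
            return False
    return True
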