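"""Linear QSPR models of ocular tissue permeability.

Each model predicts log10 of the apparent permeability coefficient Papp
(cm/s) as an affine function of molecular descriptors:

    log10 Papp = intercept + sum_i coefficient_i * descriptor_i

Three published models ship built in, one per barrier:

* ``rabbit_cornea``        log10 Papp = -3.885 - 0.183 HBtot + 0.277 logD(7.4)
* ``porcine_cornea``       log10 Papp = -4.6823 - 0.7670 logPSA - 0.1346 HBd
                                         + 3.0024 halogen_ratio
* ``porcine_conjunctiva``  log10 Papp = -4.1594 - 0.6121 logPSA - 0.0792 HBd
                                         + 3.2914 halogen_ratio

Coefficients are stored as the exact decimal literals of the source
regressions and are never refit here.  The signs encode the familiar
physical picture: permeability falls with hydrogen-bonding capacity and
polar surface area, and rises with lipophilicity (logD) and halogenation;
the cornea is more discriminating against hydrophilic solutes than the
conjunctiva (larger logPSA and HBd penalties).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .entities import DESCRIPTOR_FIELDS, DescriptorSet

__all__ = [
    "PermeabilityModel",
    "MissingDescriptorError",
    "builtin_models",
    "load_models",
    "predict_log_papp",
    "predict_papp",
]


class MissingDescriptorError(ValueError):
    """A model was applied to a descriptor set lacking a required field."""


@dataclass(frozen=True)
class PermeabilityModel:
    """Named linear model: intercept plus descriptor-name -> coefficient map.

    Evaluation yields log10 of Papp in cm/s.
    """

    name: str
    intercept: float
    terms: Mapping[str, float]
    citation: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.terms) - set(DESCRIPTOR_FIELDS)
        if unknown:
            raise ValueError(
                f"model {self.name!r} references unknown descriptors {sorted(unknown)}"
            )

    def required(self) -> tuple[str, ...]:
        return tuple(self.terms)


def builtin_models() -> list[PermeabilityModel]:
    """The three built-in tissue models with their published coefficients."""
    return [
        PermeabilityModel(
            name="rabbit_cornea",
            intercept=-3.885,
            terms={"HBtot": -0.183, "logD_7_4": 0.277},
            citation="QSPR regression for rabbit corneal permeability",
        ),
        PermeabilityModel(
            name="porcine_cornea",
            intercept=-4.6823,
            terms={"logPSA": -0.7670, "HBd": -0.1346, "halogen_ratio": 3.0024},
            citation="QSPR regression for porcine corneal permeability",
        ),
        PermeabilityModel(
            name="porcine_conjunctiva",
            intercept=-4.1594,
            terms={"logPSA": -0.6121, "HBd": -0.0792, "halogen_ratio": 3.2914},
            citation="QSPR regression for porcine conjunctival permeability",
        ),
    ]


def load_models(path: str | Path, include_builtin: bool = True) -> list[PermeabilityModel]:
    """Load user model definitions from a JSON config file.

    The file maps model name to ``{"intercept": float, "terms": {...},
    "citation": str}``.  Built-in models are always present unless explicitly
    excluded; a user model with a built-in name overrides it.
    """
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    user = [
        PermeabilityModel(
            name=name,
            intercept=float(spec["intercept"]),
            terms={k: float(v) for k, v in spec.get("terms", {}).items()},
            citation=str(spec.get("citation", "")),
        )
        for name, spec in raw.items()
    ]
    if not include_builtin:
        return user
    names = {m.name for m in user}
    return [m for m in builtin_models() if m.name not in names] + user


def predict_log_papp(model: PermeabilityModel, d: DescriptorSet) -> float:
    """Evaluate a model: intercept + sum of coefficient * descriptor value.

    Raises :class:`MissingDescriptorError` naming the model and the first
    absent descriptor.
    """
    total = model.intercept
    for name, coef in model.terms.items():
        value = d.get(name)
        if value is None:
            raise MissingDescriptorError(
                f"model {model.name!r} requires descriptor {name!r}, "
                f"absent from descriptor set"
            )
        total += coef * value
    return total


def predict_papp(model: PermeabilityModel, d: DescriptorSet) -> float:
    """Apparent permeability in cm/s: 10 ** predict_log_papp."""
    return 10.0 ** predict_log_papp(model, d)
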