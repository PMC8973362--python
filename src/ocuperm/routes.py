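"""Comparative route analysis: percent-of-reference and route dominance.

Topically applied ocular drugs reach intraocular tissue mainly across the
cornea (favouring lipophilic solutes) or across the conjunctiva and sclera
(more permissive to hydrophilic solutes).  Given per-tissue permeability
predictions, this module normalises each compound against a reference drug
and asks which route gains importance relative to that reference: the
route-shift index is the ratio of the conjunctival percent-of-reference to
the rabbit-corneal percent-of-reference, so values above 1 flag a relative
shift toward conjunctival absorption.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .descriptors import LogDProvider, resolve_descriptors
from .entities import MoleculeRecord, ValidationError
from .models import MissingDescriptorError, PermeabilityModel, predict_papp

__all__ = [
    "Route",
    "PermeabilityProfile",
    "round_half_up",
    "percent_of_reference",
    "route_shift_index",
    "classify_route",
    "build_profiles",
]

logger = logging.getLogger(__name__)

#: Tissues entering the route-shift index.
CONJUNCTIVAL_MODEL = "porcine_conjunctiva"
CORNEAL_MODEL = "rabbit_cornea"

#: Relative tie guard for route classification.
_TIE_EPS = 1e-9


class Route(str, Enum):
    CONJUNCTIVAL = "conjunctival"
    CORNEAL = "corneal"
    INDETERMINATE = "indeterminate"


def round_half_up(x: float) -> int:
    """Round to the nearest integer, with .5 ties rounding up."""
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class PermeabilityProfile:
    """Per-compound permeability summary across tissue models.

    ``papp`` holds cm/s values per model (``None`` where descriptors were
    insufficient); ``percent_of_reference`` the unrounded percentages;
    ``percent_display`` the half-up-rounded integers used in reports.
    """

    compound_id: str
    papp: Mapping[str, float | None]
    percent_of_reference: Mapping[str, float | None]
    percent_display: Mapping[str, int | None]
    route_shift_index: float | None
    dominant_route: Route
    is_reference: bool = False


def percent_of_reference(papp_compound: float, papp_reference: float) -> float:
    """Permeability as a percentage of the reference drug's, unrounded."""
    if not papp_compound > 0 or not papp_reference > 0:
        raise ValidationError(
            f"Papp values must be positive, got {papp_compound} and {papp_reference}"
        )
    return 100.0 * papp_compound / papp_reference


def route_shift_index(percentages: Mapping[str, float]) -> float:
    """Conjunctival over rabbit-corneal percent-of-reference.

    Uses unrounded percentages.  > 1 means the compound relies relatively
    more on the conjunctival route than the reference drug does.
    """
    try:
        conj = percentages[CONJUNCTIVAL_MODEL]
        corn = percentages[CORNEAL_MODEL]
    except KeyError as exc:
        raise ValidationError(
            f"route shift needs both {CONJUNCTIVAL_MODEL!r} and {CORNEAL_MODEL!r}: "
            f"missing {exc.args[0]!r}"
        ) from exc
    if conj is None or corn is None:
        raise ValidationError("route shift needs both tissue percentages present")
    return conj / corn


def classify_route(index: float, threshold: float = 1.0) -> Route:
    """Classify route dominance from the shift index.

    A multiplicative tie guard of 1e-9 keeps values numerically equal to the
    threshold in the indeterminate band.
    """
    if index > threshold * (1.0 + _TIE_EPS):
        return Route.CONJUNCTIVAL
    if index < threshold / (1.0 + _TIE_EPS):
        return Route.CORNEAL
    return Route.INDETERMINATE


def _compound_papp(
    record: MoleculeRecord,
    models: Sequence[PermeabilityModel],
    provider: LogDProvider | None,
) -> dict[str, float | None]:
    desc = resolve_descriptors(record, provider=provider)
    out: dict[str, float | None] = {}
    for model in models:
        try:
            out[model.name] = predict_papp(model, desc)
        except MissingDescriptorError as exc:
            logger.warning("compound %s: %s", record.id, exc)
            out[model.name] = None
    return out


def build_profiles(
    records: Iterable[MoleculeRecord],
    models: Sequence[PermeabilityModel],
    reference_id: str,
    reference_papp: Mapping[str, float] | None = None,
    provider: LogDProvider | None = None,
    threshold: float = 1.0,
) -> list[PermeabilityProfile]:
    """Build one permeability profile per compound, reference included.

    The reference compound's Papp values are taken from ``reference_papp``
    when given (the usual case for a reference drug known only through
    published permeability constants), otherwise computed from its own
    descriptors.  The reference profile reads 100% in every tissue with a
    route-shift index of 1 and an indeterminate classification.  Profiles
    preserve input order; a compound lacking a model's descriptors gets
    ``None`` for that model and a logged warning, and the run continues.
    """
    records = list(records)
    by_id = {r.id: r for r in records}
    if len(by_id) != len(records):
        raise ValidationError("duplicate compound ids in records")
    if reference_id not in by_id and reference_papp is None:
        raise ValidationError(f"reference compound {reference_id!r} not in records")

    if reference_papp is not None:
        ref_papp: dict[str, float | None] = {
            m.name: reference_papp.get(m.name) for m in models
        }
    else:
        ref_papp = _compound_papp(by_id[reference_id], models, provider)
    missing_ref = [name for name, v in ref_papp.items() if v is None]
    if missing_ref:
        raise ValidationError(
            f"reference {reference_id!r} lacks Papp for models {missing_ref}"
        )

    profiles: list[PermeabilityProfile] = []
    ids = [r.id for r in records]
    if reference_id not in by_id:
        ids = [reference_id] + ids  # reference known only through constants
    for cid in ids:
        is_ref = cid == reference_id
        papp = (
            dict(ref_papp) if is_ref
            else _compound_papp(by_id[cid], models, provider)
        )
        pct: dict[str, float | None] = {}
        disp: dict[str, int | None] = {}
        for name, value in papp.items():
            if value is None:
                pct[name] = None
                disp[name] = None
            else:
                pct[name] = percent_of_reference(value, ref_papp[name])
                disp[name] = round_half_up(pct[name])
        try:
            index = route_shift_index(pct)
            route = classify_route(index, threshold)
        except ValidationError:
            index = None
            route = Route.INDETERMINATE
        profiles.append(
            PermeabilityProfile(
                compound_id=cid,
                papp=papp,
                percent_of_reference=pct,
                percent_display=disp,
                route_shift_index=index,
                dominant_route=route,
                is_reference=is_ref,
            )
        )
    return profiles
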