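"""Core data types and CSV readers/writers.

Molecules are carried as :class:`MoleculeRecord` objects holding an identifier,
an optional SMILES structure and an optional set of externally supplied
descriptor values.  Descriptor tables and inhibition-constant (Ki) panels are
exchanged as plain UTF-8 CSV files with a header row; permeability profiles are
written back as a CSV report with one row per compound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "DESCRIPTOR_FIELDS",
    "COUNT_FIELDS",
    "DescriptorSet",
    "MoleculeRecord",
    "InhibitionRecord",
    "ValidationError",
    "read_descriptor_table",
    "read_molecules",
    "read_ki_panel",
    "write_profile_table",
    "format_papp",
]

#: Descriptor names a permeability model may reference, in canonical order.
DESCRIPTOR_FIELDS: tuple[str, ...] = (
    "HBd",
    "HBa",
    "HBtot",
    "logP",
    "logD_7_4",
    "logD_8_0",
    "PSA",
    "logPSA",
    "halogen_ratio",
    "MW",
)

#: Integer-valued descriptor fields.
COUNT_FIELDS: frozenset[str] = frozenset({"HBd", "HBa", "HBtot"})

#: Tolerance between a supplied logPSA and log10(PSA); matches 3-decimal
#: printed precision of descriptor tables.
LOGPSA_TOL = 5e-4


class ValidationError(ValueError):
    """A domain invariant was violated by input data."""


@dataclass(frozen=True)
class DescriptorSet:
    """Molecular descriptor vector consumed by the permeability models.

    All fields are optional; absence means "not available", never zero.
    ``provenance`` records, per present field, whether the value was
    ``"computed"`` from structure or ``"supplied"`` externally.

    Units: PSA in Å², MW in g/mol; logP/logD/logPSA are dimensionless log10
    values; halogen_ratio is a fraction of heavy atoms in [0, 1].
    """

    HBd: int | None = None
    HBa: int | None = None
    HBtot: int | None = None
    logP: float | None = None
    logD_7_4: float | None = None
    logD_8_0: float | None = None
    PSA: float | None = None
    logPSA: float | None = None
    halogen_ratio: float | None = None
    MW: float | None = None
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def get(self, name: str) -> float | None:
        if name not in DESCRIPTOR_FIELDS:
            raise KeyError(f"unknown descriptor field {name!r}")
        return getattr(self, name)

    def present_fields(self) -> tuple[str, ...]:
        return tuple(f for f in DESCRIPTOR_FIELDS if getattr(self, f) is not None)

    def evolve(self, **changes) -> "DescriptorSet":
        return replace(self, **changes)

    def validate(self) -> None:
        """Check internal consistency; raise :class:`ValidationError` if violated."""
        for name in ("HBd", "HBa", "HBtot"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")
        if self.HBd is not None and self.HBa is not None and self.HBtot is not None:
            if self.HBtot != self.HBd + self.HBa:
                raise ValidationError(
                    f"HBtot={self.HBtot} inconsistent with HBd+HBa="
                    f"{self.HBd + self.HBa}"
                )
        if self.PSA is not None:
            if self.PSA < 0:
                raise ValidationError(f"PSA must be non-negative, got {self.PSA}")
            if self.PSA > 0 and self.logPSA is not None:
                if abs(self.logPSA - math.log10(self.PSA)) > LOGPSA_TOL:
                    raise ValidationError(
                        f"logPSA={self.logPSA} inconsistent with "
                        f"log10(PSA)={math.log10(self.PSA):.6f}"
                    )
        if self.halogen_ratio is not None and not 0.0 <= self.halogen_ratio <= 1.0:
            raise ValidationError(
                f"halogen_ratio must lie in [0, 1], got {self.halogen_ratio}"
            )
        if self.MW is not None and self.MW <= 0:
            raise ValidationError(f"MW must be positive, got {self.MW}")


@dataclass(frozen=True)
class MoleculeRecord:
    """A compound: short identifier plus structure and/or supplied descriptors."""

    id: str
    smiles: str | None = None
    supplied_descriptors: DescriptorSet | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("molecule id must be non-empty")
        if self.smiles is None and self.supplied_descriptors is None:
            raise ValidationError(
                f"molecule {self.id!r} needs a structure or supplied descriptors"
            )


@dataclass(frozen=True)
class InhibitionRecord:
    """One compound x isoform inhibition constant, in nanomolar."""

    compound_id: str
    isoform: str
    Ki_nM: float

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        if not self.isoform:
            raise ValidationError("isoform must be non-empty")
        if not self.Ki_nM > 0:
            raise ValidationError(
                f"Ki must be positive: {self.compound_id}/{self.isoform} = {self.Ki_nM}"
            )


def _default_column_map() -> dict[str, str]:
    m = {f: f for f in DESCRIPTOR_FIELDS}
    m["compound"] = "id"
    m["id"] = "id"
    return m


def read_descriptor_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[MoleculeRecord]:
    """Read a descriptor table CSV into molecule records.

    Parameters
    ----------
    path
        CSV file with a header row and one compound per data row.
    column_map
        Maps source column names to :class:`DescriptorSet` field names (or to
        ``"id"``/``"smiles"``).  Unmapped columns are ignored.  By default the
        canonical field names plus ``compound``/``id`` map to themselves.

    Every mapped descriptor value carries ``"supplied"`` provenance.  Empty
    cells produce absent fields, never zeros.
    """
    cmap = dict(column_map) if column_map is not None else _default_column_map()
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if not any(cmap.get(c) == "id" for c in df.columns):
        raise ValidationError(
            f"no column maps to 'id' among {list(df.columns)}"
        )
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    for row_idx, row in df.iterrows():
        values: dict[str, float | int] = {}
        cid: str | None = None
        smiles: str | None = None
        for col in df.columns:
            target = cmap.get(col)
            if target is None:
                continue
            cell = row[col]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                continue
            cell = str(cell).strip()
            if cell == "":
                continue
            if target == "id":
                cid = cell
            elif target == "smiles":
                smiles = cell
            elif target in DESCRIPTOR_FIELDS:
                try:
                    num = float(cell.replace("−", "-"))
                except ValueError as exc:
                    raise ValidationError(
                        f"non-numeric value {cell!r} in row {row_idx + 1}, "
                        f"column {col!r}"
                    ) from exc
                values[target] = int(num) if target in COUNT_FIELDS else num
            else:
                raise ValidationError(
                    f"column_map target {target!r} is not a descriptor field"
                )
        if cid is None:
            raise ValidationError(f"row {row_idx + 1} has no compound id")
        if cid in seen:
            raise ValidationError(f"duplicate compound id {cid!r}")
        seen.add(cid)
        desc = None
        if values:
            desc = DescriptorSet(
                **values, provenance={k: "supplied" for k in values}
            )
        records.append(MoleculeRecord(id=cid, smiles=smiles, supplied_descriptors=desc))
    return records


def read_molecules(path: str | Path) -> list[MoleculeRecord]:
    """Read structures from an SDF file or newline-delimited SMILES.

    SMILES files hold one ``SMILES [id]`` pair per line; SDF records take their
    id from the title line or a ``_Name`` property, falling back to a 1-based
    ordinal. Descriptors are not computed here (see ``descriptors.resolve``).
    """
    from rdkit import Chem

    path = Path(path)
    records: list[MoleculeRecord] = []
    seen: set[str] = set()

    def _add(smiles: str, cid: str) -> None:
        if cid in seen:
            raise ValidationError(f"duplicate compound id {cid!r}")
        seen.add(cid)
        records.append(MoleculeRecord(id=cid, smiles=smiles))

    if path.suffix.lower() == ".sdf":
        for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
            if mol is None:
                raise ValidationError(f"unparseable SDF record {i + 1} in {path}")
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            _add(Chem.MolToSmiles(mol), cid or str(i + 1))
    else:
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                if Chem.MolFromSmiles(smiles) is None:
                    raise ValidationError(
                        f"unparseable SMILES {smiles!r} on line {i + 1}"
                    )
                _add(smiles, parts[1].strip() if len(parts) > 1 else str(i + 1))
    return records


def _norm_isoform(name: str) -> str:
    return "_".join(str(name).split())


def read_ki_panel(
    path: str | Path,
    layout: str = "auto",
) -> list[InhibitionRecord]:
    """Read a Ki panel CSV in long or wide layout.

    Long layout has columns ``compound, isoform, Ki_nM``; wide layout has a
    compound column followed by one column per isoform.  ``layout="auto"``
    inspects the header.  Isoform names are whitespace-normalised
    (``"hCA II"`` becomes ``"hCA_II"``); Ki values are parsed as nanomolar.
    """
    if layout not in {"auto", "long", "wide"}:
        raise ValueError(f"layout must be auto/long/wide, got {layout!r}")
    df = pd.read_csv(path, skipinitialspace=True)
    cols = [str(c).strip() for c in df.columns]
    df.columns = cols
    lowered = [c.lower() for c in cols]
    if layout == "auto":
        layout = "long" if "isoform" in lowered and "compound" in lowered else "wide"

    records: list[InhibitionRecord] = []
    seen: set[tuple[str, str]] = set()

    def _add(cid: str, isoform: str, ki) -> None:
        if ki is None or (isinstance(ki, float) and math.isnan(ki)):
            return
        try:
            ki = float(str(ki).replace("−", "-"))
        except ValueError as exc:
            raise ValidationError(
                f"non-numeric Ki {ki!r} for {cid}/{isoform}"
            ) from exc
        key = (cid, isoform)
        if key in seen:
            raise ValidationError(f"duplicate Ki entry for {key}")
        seen.add(key)
        records.append(InhibitionRecord(cid, isoform, ki))

    if layout == "long":
        cmap = {c.lower(): c for c in cols}
        ki_col = next(
            (cmap[k] for k in ("ki_nm", "ki", "ki (nm)") if k in cmap), None
        )
        if ki_col is None:
            raise ValidationError(f"no Ki column found among {cols}")
        for _, row in df.iterrows():
            _add(
                str(row[cmap["compound"]]).strip(),
                _norm_isoform(row[cmap["isoform"]]),
                row[ki_col],
            )
    else:
        id_col = cols[0]
        for _, row in df.iterrows():
            cid = str(row[id_col]).strip()
            for col in cols[1:]:
                _add(cid, _norm_isoform(col), row[col])
    return records


def format_papp(value: float) -> str:
    """Format a permeability in cm/s at 3 significant figures, e.g. ``9.68E-07``."""
    return f"{value:.2E}"


def write_profile_table(profiles: Sequence, path: str | Path) -> None:
    """Write permeability profiles as a CSV report.

    One row per compound; per tissue model a Papp column (3 significant
    figures, scientific notation) and an integer percent-of-reference column.
    Output is byte-stable across runs on identical input.  ``profiles`` are
    :class:`ocuperm.routes.PermeabilityProfile` objects.
    """
    if not profiles:
        raise ValidationError("cannot write an empty profile table")
    model_names: list[str] = []
    for p in profiles:
        for name in p.papp:
            if name not in model_names:
                model_names.append(name)
    header = ["compound"]
    for name in model_names:
        header += [f"{name}_Papp_cm_s", f"{name}_pct_of_ref"]
    lines = [",".join(header)]
    for p in profiles:
        cells = [p.compound_id]
        for name in model_names:
            papp = p.papp.get(name)
            pct = p.percent_display.get(name)
            cells.append(format_papp(papp) if papp is not None else "")
            cells.append(str(pct) if pct is not None else "")
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="")
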