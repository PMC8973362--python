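"""Descriptor computation from structure and merge with supplied values.

Computed-mode definitions (documented, deliberately simple):

* hydrogen-bond donor count = number of hydrogens attached to N or O;
* hydrogen-bond acceptor count = number of N and O atoms (sulfur and
  halogens are excluded by default, overridable);
* polar surface area = topological PSA (Ertl);
* halogen ratio = (#F + #Cl + #Br + #I) / #heavy atoms.

Published descriptor tables often come from other calculators whose counts
differ slightly; supplied values therefore always take precedence over
computed ones.  logP and logD are never estimated internally — they come from
supplied values or from an injected provider — because ionisation-aware
lipophilicity needs a pKa model that is out of scope here.
"""

from __future__ import annotations

import math
from typing import Protocol

from rdkit import Chem
from rdkit.Chem import Descriptors as RDDescriptors
from rdkit.Chem import Lipinski

from .entities import COUNT_FIELDS, DescriptorSet, MoleculeRecord, ValidationError

__all__ = [
    "LogDProvider",
    "parse_structure",
    "count_hbd",
    "count_hba",
    "hb_total",
    "halogen_ratio",
    "log_psa",
    "compute_descriptors",
    "resolve_descriptors",
]

_HALOGENS = {9, 17, 35, 53}


class LogDProvider(Protocol):
    """Contract for an external lipophilicity source.

    Given a SMILES string and a pH, return the log10 distribution coefficient,
    or ``None`` when unavailable.
    """

    def __call__(self, smiles: str, pH: float) -> float | None: ...


def parse_structure(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`ValidationError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable SMILES {smiles!r}")
    return mol


def count_hbd(mol: Chem.Mol) -> int:
    """Number of hydrogens attached to nitrogen or oxygen atoms."""
    return Lipinski.NHOHCount(mol)


def count_hba(mol: Chem.Mol, include_sulfur: bool = False) -> int:
    """Number of acceptor atoms: N and O (optionally also S)."""
    n = Lipinski.NOCount(mol)
    if include_sulfur:
        n += sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 16)
    return n


def hb_total(d: DescriptorSet) -> int:
    """Total hydrogen-bond formers, HBd + HBa.

    A supplied HBtot is honoured; if HBd and HBa are both present as well, the
    three must agree (the :class:`DescriptorSet` invariant enforces this at
    construction, so disagreement cannot reach this point silently).
    """
    if d.HBtot is not None:
        return d.HBtot
    if d.HBd is not None and d.HBa is not None:
        return d.HBd + d.HBa
    raise ValidationError("HBtot requires either HBtot or both HBd and HBa")


def halogen_ratio(mol: Chem.Mol) -> float:
    """Fraction of heavy atoms that are halogens (F, Cl, Br, I).

    Hydrogens are excluded from the denominator, so the value is invariant
    under explicit-hydrogen addition or removal.
    """
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    if not heavy:
        raise ValidationError("structure has no heavy atoms")
    n_hal = sum(1 for a in heavy if a.GetAtomicNum() in _HALOGENS)
    return n_hal / len(heavy)


def log_psa(psa: float) -> float:
    """log10 of polar surface area, at full floating precision.

    The result is never rounded before model use: 3-decimal printed logPSA
    values can shift a permeability prediction in its third significant
    figure.
    """
    if not psa > 0:
        raise ValidationError(f"PSA must be positive for logPSA, got {psa}")
    return math.log10(psa)


def compute_descriptors(
    smiles: str, include_sulfur_hba: bool = False
) -> DescriptorSet:
    """Compute all structure-derivable descriptors for one SMILES."""
    mol = parse_structure(smiles)
    hbd = count_hbd(mol)
    hba = count_hba(mol, include_sulfur=include_sulfur_hba)
    psa = RDDescriptors.TPSA(mol)
    values: dict[str, float | int] = {
        "HBd": hbd,
        "HBa": hba,
        "HBtot": hbd + hba,
        "PSA": psa,
        "halogen_ratio": halogen_ratio(mol),
        "MW": RDDescriptors.MolWt(mol),
    }
    if psa > 0:
        values["logPSA"] = log_psa(psa)
    return DescriptorSet(**values, provenance={k: "computed" for k in values})


def resolve_descriptors(
    record: MoleculeRecord,
    provider: LogDProvider | None = None,
    include_sulfur_hba: bool = False,
) -> DescriptorSet:
    """Merge computed and supplied descriptors for one molecule.

    Precedence rules:

    * supplied values win over computed ones;
    * logP/logD come only from supplied values or the injected ``provider``;
    * logPSA is always recomputed from PSA at full precision whenever PSA is
      present, regardless of a supplied (typically rounded) logPSA;
    * HBtot is filled in from HBd + HBa when derivable.

    Absent required fields are left absent; permeability models fail loudly on
    them at evaluation time.
    """
    values: dict[str, float | int] = {}
    prov: dict[str, str] = {}

    if record.smiles is not None:
        computed = compute_descriptors(record.smiles, include_sulfur_hba)
        for name in computed.present_fields():
            values[name] = computed.get(name)
            prov[name] = "computed"

    supplied = record.supplied_descriptors
    if supplied is not None:
        for name in supplied.present_fields():
            values[name] = supplied.get(name)
            prov[name] = "supplied"

    if provider is not None and record.smiles is not None:
        for name, ph in (("logD_7_4", 7.4), ("logD_8_0", 8.0)):
            if name not in values:
                got = provider(record.smiles, ph)
                if got is not None:
                    values[name] = got
                    prov[name] = "computed"

    if "PSA" in values and values["PSA"] > 0:
        values["logPSA"] = log_psa(values["PSA"])
        prov["logPSA"] = "computed"

    # a supplied donor/acceptor count invalidates a computed total
    if "HBd" in values and "HBa" in values and prov.get("HBtot") != "supplied":
        values["HBtot"] = int(values["HBd"]) + int(values["HBa"])
        prov["HBtot"] = prov["HBd"] if prov["HBd"] == prov["HBa"] else "computed"

    cast = {
        k: (int(v) if k in COUNT_FIELDS else float(v)) for k, v in values.items()
    }
    return DescriptorSet(**cast, provenance=prov)
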