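"""Isoform-selectivity summaries for enzyme inhibition panels.

A panel is a collection of per-compound, per-isoform inhibition constants
(Ki, nM).  The selectivity ratio Ki(off-target)/Ki(target) is the standard
figure of merit: values above 1 mean the compound prefers the target
isoform, and comparing a compound's ratio with a reference inhibitor's
(ratio of ratios) shows whether its selectivity profile improved.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .entities import InhibitionRecord, ValidationError

__all__ = [
    "panel_index",
    "selectivity_ratio",
    "rank_by_potency",
    "selectivity_report",
]


def panel_index(panel: Iterable[InhibitionRecord]) -> dict[tuple[str, str], float]:
    """Index a panel by (compound, isoform), rejecting duplicates."""
    index: dict[tuple[str, str], float] = {}
    for rec in panel:
        key = (rec.compound_id, rec.isoform)
        if key in index:
            raise ValidationError(f"duplicate Ki entry for {key}")
        index[key] = rec.Ki_nM
    return index


def _lookup(index: Mapping[tuple[str, str], float], compound: str, isoform: str) -> float:
    try:
        return index[(compound, isoform)]
    except KeyError:
        raise ValidationError(
            f"no Ki for compound {compound!r}, isoform {isoform!r}"
        ) from None


def selectivity_ratio(
    panel: Iterable[InhibitionRecord],
    compound: str,
    off_target: str,
    target: str,
) -> float:
    """Ki(off_target) / Ki(target) for one compound; > 1 favours the target."""
    index = panel if isinstance(panel, dict) else panel_index(panel)
    return _lookup(index, compound, off_target) / _lookup(index, compound, target)


def rank_by_potency(
    panel: Iterable[InhibitionRecord], isoform: str
) -> list[str]:
    """Compound ids ordered by ascending Ki on one isoform.

    Ties break lexicographically by compound id.  Raises if no compound has a
    Ki for the isoform.
    """
    index = panel if isinstance(panel, dict) else panel_index(panel)
    entries = [(ki, cid) for (cid, iso), ki in index.items() if iso == isoform]
    if not entries:
        raise ValidationError(f"no Ki entries for isoform {isoform!r}")
    return [cid for _, cid in sorted(entries)]


def selectivity_report(
    panel: Iterable[InhibitionRecord],
    target: str,
    reference_id: str,
) -> pd.DataFrame:
    """Per-compound selectivity summary against a reference inhibitor.

    Returns a DataFrame indexed by compound id (panel order) with the target
    Ki, one ``sel_<off_target>`` selectivity-ratio column per off-target
    isoform, and one ``vs_ref_<off_target>`` ratio-of-ratios column (compound
    selectivity over reference selectivity; > 1 means more target-selective
    than the reference).  A missing off-target Ki leaves those cells NaN and
    keeps the row.
    """
    records = list(panel)
    index = panel_index(records)

    compounds: list[str] = []
    for rec in records:
        if rec.compound_id not in compounds:
            compounds.append(rec.compound_id)
    isoforms: list[str] = []
    for rec in records:
        if rec.isoform not in isoforms:
            isoforms.append(rec.isoform)
    off_targets = [iso for iso in isoforms if iso != target]

    if reference_id not in compounds:
        raise ValidationError(f"reference compound {reference_id!r} not in panel")
    for cid in compounds:
        _lookup(index, cid, target)  # target Ki mandatory for every row

    rows = []
    for cid in compounds:
        row: dict[str, float] = {"Ki_target_nM": index[(cid, target)]}
        for off in off_targets:
            key = (cid, off)
            ref_key = (reference_id, off)
            if key in index:
                row[f"sel_{off}"] = index[key] / index[(cid, target)]
            if key in index and ref_key in index:
                ref_sel = index[ref_key] / index[(reference_id, target)]
                row[f"vs_ref_{off}"] = row[f"sel_{off}"] / ref_sel
        rows.append(row)
    columns = ["Ki_target_nM"]
    for off in off_targets:
        columns += [f"sel_{off}", f"vs_ref_{off}"]
    df = pd.DataFrame(rows, index=pd.Index(compounds, name="compound"))
    return df.reindex(columns=columns)
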