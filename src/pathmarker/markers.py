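"""Candidate diagnostic markers: differentially expressed hub genes.

The marker set is the intersection of the differentially expressed genes
with the network hub genes, each marker annotated with its network degree
and DE p-value, optionally flagged when present in a literature-confirmed
gene list.  Symbol matching is case-insensitive after whitespace stripping;
KEGG-id vs symbol namespace mismatches must be resolved upstream by the
id-map.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["intersect_markers", "annotate_literature", "write_marker_table"]


def _norm(symbol: str) -> str:
    return str(symbol).strip().upper()


def intersect_markers(
    deg_table: pd.DataFrame,
    hubs: set[str] | Iterable[str],
    degrees: pd.DataFrame,
) -> pd.DataFrame:
    """Genes that are both differentially expressed and network hubs.

    ``deg_table`` is a (filtered) DE table with gene/PValue/direction
    columns; ``degrees`` supplies the network degree per gene.  The result
    has columns gene, degree, PValue, direction, sorted alphabetically by
    symbol.  An empty intersection is returned as a valid empty table with
    a warning (downstream classification cannot proceed on it).
    """
    if deg_table.empty or not hubs:
        raise ValueError("DEG table and hub set must be non-empty")
    hub_lookup = {_norm(h) for h in hubs}
    degree_lookup = {
        _norm(g): int(d) for g, d in zip(degrees["gene"], degrees["degree"])
    }

    rows = []
    seen: set[str] = set()
    for _, rec in deg_table.iterrows():
        key = _norm(rec["gene"])
        if key in hub_lookup and key not in seen:
            seen.add(key)
            rows.append(
                (rec["gene"], degree_lookup.get(key, 0),
                 float(rec["PValue"]), rec.get("direction", "ns"))
            )
    table = pd.DataFrame(rows, columns=["gene", "degree", "PValue", "direction"])
    if table.empty:
        warnings.warn("DEG/hub intersection is empty", stacklevel=2)
    return table.sort_values("gene", ignore_index=True)


def annotate_literature(
    markers: pd.DataFrame, confirmed: Sequence[str]
) -> pd.DataFrame:
    """Add a boolean ``confirmed`` column for literature-supported symbols.

    Matching is case-insensitive after whitespace stripping, so "adh1a"
    matches "ADH1A".
    """
    confirmed_norm = {_norm(c) for c in confirmed}
    out = markers.copy()
    out["confirmed"] = [
        _norm(g) in confirmed_norm for g in out["gene"]
    ]
    return out


def write_marker_table(markers: pd.DataFrame, path: str | Path) -> None:
    """Marker TSV with Gene/Degree/Pvalue columns plus annotations."""
    out = markers.rename(
        columns={"gene": "Gene", "degree": "Degree", "PValue": "Pvalue"}
    )
    out.to_csv(path, sep="\t", index=False)
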