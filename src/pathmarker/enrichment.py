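"""Gene-set over-representation analysis against GMT collections.

Given a query gene list (typically the differentially expressed genes), a
collection of gene sets and a background universe, each set is scored with
the upper-tail hypergeometric probability of drawing at least the observed
overlap.  The conservative EASE variant (overlap decremented by one before
the tail sum) is available as an option.  Sets with p below a threshold
(default 0.05, raw p — a Benjamini-Hochberg column is reported for
information but not used for selection) are flagged significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeom_test",
    "enrich",
    "write_enrichment_table",
]


@dataclass
class GeneSetCollection:
    """Named gene sets: id -> (description, unique member symbols)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]

    def ids(self) -> list[str]:
        return list(self.sets)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        return cls(
            sets={sid: (sid, frozenset(genes)) for sid, genes in mapping.items()}
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (tab-separated: id, description, member genes...)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line needs >= 3 fields: {line!r}")
        sid, desc, members = fields[0], fields[1], fields[2:]
        if sid in sets:
            raise ValueError(f"duplicate gene-set id {sid!r}")
        sets[sid] = (desc, frozenset(m for m in members if m))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for sid, (desc, members) in collection.sets.items():
        lines.append("\t".join([sid, desc, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeom_test(k: int, m: int, n: int, N: int, ease: bool = False) -> float:
    """Upper-tail hypergeometric p-value for a k-gene overlap.

    Probability of observing an overlap of at least ``k`` between a set of
    size ``m`` and a query of size ``n`` drawn without replacement from a
    universe of ``N`` genes.  With ``ease=True`` the overlap is decremented
    by one before the tail sum (the EASE score), a deliberately
    conservative variant; k = 0 (or EASE with k = 1) returns exactly 1.
    """
    if not (0 <= k <= min(m, n)):
        raise ValueError(f"overlap k={k} inconsistent with margins m={m}, n={n}")
    if m > N or n > N:
        raise ValueError("set or query larger than the universe")
    k_eff = max(0, k - 1) if ease else k
    if k_eff == 0:
        return 1.0
    # P(X >= k_eff) for X ~ Hypergeom(N, m, n)
    return float(stats.hypergeom.sf(k_eff - 1, N, m, n))


def enrich(
    query: Sequence[str],
    sets: GeneSetCollection,
    universe: Sequence[str],
    alpha: float = 0.05,
    ease: bool = False,
) -> pd.DataFrame:
    """Score every gene set against the query; rank by p-value.

    Query genes outside the universe are dropped with a warning; set
    members outside the universe do not count toward the set size.  The
    result has one row per set with columns set_id, name, overlap (k),
    set_size (m), query_size (n), universe_size (N), p_value, fdr,
    significant (p < alpha on the raw p), ordered by increasing p then id.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query")
    stray = query_set - universe_set
    if stray:
        warnings.warn(
            f"{len(stray)} query genes outside the universe were dropped",
            stacklevel=2,
        )
        query_set &= universe_set
    if not query_set:
        raise ValueError("no query genes inside the universe")

    N, n = len(universe_set), len(query_set)
    rows = []
    for sid, (desc, members) in sets.sets.items():
        members_in = members & universe_set
        m = len(members_in)
        k = len(members_in & query_set)
        p = hypergeom_test(k, m, n, N, ease=ease) if m else 1.0
        rows.append((sid, desc, k, m, n, N, p))
    table = pd.DataFrame(
        rows,
        columns=[
            "set_id", "name", "overlap", "set_size",
            "query_size", "universe_size", "p_value",
        ],
    )
    table["fdr"] = stats.false_discovery_control(table["p_value"], method="bh")
    table["significant"] = table["p_value"] < alpha
    return table.sort_values(
        ["p_value", "set_id"], ignore_index=True
    )


def write_enrichment_table(table: pd.DataFrame, path: str | Path) -> None:
    """Enrichment TSV with Term/Count/p-value style columns."""
    out = table.rename(
        columns={"set_id": "Term", "overlap": "Count", "p_value": "p_value"}
    )
    out.to_csv(path, sep="\t", index=False)
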