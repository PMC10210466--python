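"""Over-representation analysis and reference-list overlap reporting.

ORA tests each gene set for enrichment in a query protein set by the
upper-tail hypergeometric probability ``P(X >= k)`` of drawing ``k`` or
more set members in a query of size ``n`` from a universe of size ``N``
containing ``K`` members; p-values are BH-adjusted across the tested
terms. Reference-list overlap reproduces the database-comparison style
of EV proteome characterisation (e.g. fraction of detected proteins
present in ExoCarta or Vesiclepedia).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd
from scipy import stats

from .differential import bh_adjust


@dataclass
class GeneSetCollection:
    """Term identifier -> member identifiers (with optional description)."""

    sets: dict[str, frozenset]
    descriptions: dict[str, str]

    def __post_init__(self) -> None:
        empty = [t for t, members in self.sets.items() if not members]
        if empty:
            raise ValueError(f"gene sets with no members: {empty}")

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        """Parse a GMT file: ``term<TAB>description<TAB>member...``."""
        sets: dict[str, frozenset] = {}
        descriptions: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            term, desc, *members = parts
            sets[term] = frozenset(m for m in members if m)
            descriptions[term] = desc
        return cls(sets=sets, descriptions=descriptions)


read_gmt = GeneSetCollection.from_gmt


def hypergeometric_ora(query, universe, sets: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in the query.

    ``query`` must be a subset of ``universe``; term members are
    intersected with the universe before testing. Returns a DataFrame
    sorted by p-value with columns ``term, description, overlap (k),
    set_size (K), query_size (n), universe_size (N), pvalue,
    adj_pvalue``.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("empty query")
    if not universe:
        raise ValueError("empty universe")
    stray = query - universe
    if stray:
        raise ValueError(f"query identifiers outside the universe: "
                         f"{sorted(stray)[:5]}{'...' if len(stray) > 5 else ''}")
    N, n = len(universe), len(query)
    rows = []
    for term, members in sets.sets.items():
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(in_universe & query)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, sets.descriptions.get(term, ""), k, K, n, N, p))
    out = pd.DataFrame(rows, columns=["term", "description", "overlap",
                                      "set_size", "query_size",
                                      "universe_size", "pvalue"])
    if len(out):
        out["adj_pvalue"] = bh_adjust(out["pvalue"].to_numpy())
        out = out.sort_values("pvalue", kind="mergesort").reset_index(drop=True)
    else:
        out["adj_pvalue"] = pd.Series(dtype=float)
    return out


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 92.45 -> 92.5, unlike banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class OverlapReport:
    """Overlap of a query protein list with one reference database."""

    query_size: int
    reference_name: str
    overlap: int
    percentage: float  # 100 * overlap / query_size, half-up, one decimal

    def __post_init__(self) -> None:
        if not 0 <= self.overlap <= self.query_size:
            raise ValueError("overlap count must lie in [0, query size]")


def reference_overlap(query, reference, name: str = "") -> OverlapReport:
    """Count query identifiers present in a reference list.

    Identifiers are case-normalized (upper) and deduplicated before
    matching; the percentage is relative to the deduplicated query and
    rounded half-up to one decimal place.
    """
    q = {str(x).strip().upper() for x in query if str(x).strip()}
    if not q:
        raise ValueError("empty query")
    ref = {str(x).strip().upper() for x in reference if str(x).strip()}
    k = len(q & ref)
    return OverlapReport(
        query_size=len(q),
        reference_name=name,
        overlap=k,
        percentage=round_half_up(100.0 * k / len(q), 1),
    )


def read_id_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s)
    return out
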