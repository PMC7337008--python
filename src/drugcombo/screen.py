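"""Differential-protein screen: fold-change filter, local term enrichment,
and network degree ranking.

Enrichment is a one-sided hypergeometric tail P(X >= k) over user-supplied
term -> protein maps, with Benjamini-Hochberg adjustment across terms.  An
optional EASE mode (replace k by k - 1) is available but off by default.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InvalidArgumentError, SchemaError

__all__ = [
    "ProteinQuant",
    "DifferentialSplit",
    "EnrichmentResult",
    "filter_differential",
    "enrich_terms",
    "network_degree",
    "read_protein_csv",
    "write_protein_csv",
    "read_term_map_tsv",
    "read_edges_tsv",
]


@dataclass(frozen=True)
class ProteinQuant:
    """Protein id with treated/control fold change (strictly positive)."""

    id: str
    fold_change: float

    def __post_init__(self) -> None:
        if not self.fold_change > 0:
            raise InvalidArgumentError(
                f"fold_change must be positive, got {self.fold_change!r} for {self.id!r}"
            )


@dataclass(frozen=True)
class DifferentialSplit:
    """Partition of a protein table into up / down / unchanged."""

    up: tuple[ProteinQuant, ...]
    down: tuple[ProteinQuant, ...]
    unchanged: tuple[ProteinQuant, ...]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.up), len(self.down), len(self.unchanged))

    @property
    def up_ids(self) -> frozenset[str]:
        return frozenset(p.id for p in self.up)

    @property
    def down_ids(self) -> frozenset[str]:
        return frozenset(p.id for p in self.down)


def filter_differential(
    table: Sequence[ProteinQuant], up: float = 1.5, down: float = 0.67
) -> DifferentialSplit:
    """Strict-threshold split: fold change > up, < down, else unchanged.

    Values exactly at a threshold are classified unchanged (strict
    inequalities).
    """
    if not (0 < down < up):
        raise InvalidArgumentError(f"thresholds must satisfy 0 < down < up, got {down}, {up}")
    ups, downs, rest = [], [], []
    for p in table:
        if p.fold_change > up:
            ups.append(p)
        elif p.fold_change < down:
            downs.append(p)
        else:
            rest.append(p)
    return DifferentialSplit(up=tuple(ups), down=tuple(downs), unchanged=tuple(rest))


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's hypergeometric enrichment against a background universe."""

    term: str
    k: int  # hits in the query set
    K: int  # term size within the background
    n: int  # query set size
    N: int  # background size
    p: float
    p_adj: float


def enrich_terms(
    dep_ids: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    background: Iterable[str],
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each term in the query set.

    Term membership is intersected with the background before counting.
    ``p = P(X >= k)`` for X ~ Hypergeom(N, K, n); ``ease=True`` substitutes
    k - 1 for k (never below 0).  p-values are Benjamini-Hochberg adjusted
    across terms and results are sorted ascending by (p, term).
    """
    background = frozenset(background)
    if not background:
        raise InvalidArgumentError("background must be non-empty")
    deps = frozenset(dep_ids)
    if not deps <= background:
        raise InvalidArgumentError(
            f"{len(deps - background)} query id(s) missing from the background"
        )
    N, n = len(background), len(deps)
    rows = []
    for term in sorted(term_map):
        members = frozenset(term_map[term]) & background
        K = len(members)
        k = len(members & deps)
        k_eff = max(k - 1, 0) if ease else k
        p = float(hypergeom.sf(k_eff - 1, N, K, n))
        p = min(p, 1.0)
        rows.append((term, k, K, p))
    if not rows:
        return []
    p_adj = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(term=term, k=k, K=K, n=n, N=N, p=p, p_adj=float(max(pa, p)))
        for (term, k, K, p), pa in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return results


def network_degree(edges: Iterable[tuple[str, str]]) -> list[tuple[str, int]]:
    """Degree per node from an undirected edge list, ranked.

    Self-loops are dropped and duplicate edges collapsed; degree counts
    distinct neighbours.  Ranking is degree descending, id ascending.
    """
    neighbours: dict[str, set[str]] = {}
    for a, b in edges:
        a, b = str(a), str(b)
        if a == b:
            continue
        neighbours.setdefault(a, set()).add(b)
        neighbours.setdefault(b, set()).add(a)
    ranked = [(node, len(nbrs)) for node, nbrs in neighbours.items()]
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return ranked


# ---------------------------------------------------------------------------
# Plain-text interfaces
# ---------------------------------------------------------------------------


def read_protein_csv(path: str | Path) -> list[ProteinQuant]:
    """CSV with header ``id,fold_change``."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = {"id", "fold_change"} - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
        out = []
        for i, row in enumerate(reader, start=2):
            try:
                out.append(ProteinQuant(id=row["id"], fold_change=float(row["fold_change"])))
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"{path}:{i}: {exc}") from exc
    return out


def write_protein_csv(path: str | Path, table: Sequence[ProteinQuant]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "fold_change"])
        for p in table:
            writer.writerow([p.id, repr(p.fold_change)])


def read_term_map_tsv(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (term, protein) -> term -> protein-set map."""
    term_map: dict[str, set[str]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise SchemaError(f"{path}:{i}: expected 2 columns, got {len(row)}")
            term_map.setdefault(row[0], set()).add(row[1])
    return term_map


def read_edges_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV (id1, id2) edge list."""
    edges = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise SchemaError(f"{path}:{i}: expected 2 columns, got {len(row)}")
            edges.append((row[0], row[1]))
    return edges
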