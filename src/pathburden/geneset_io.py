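"""Load and curate the pathway universe (GO/KEGG gene sets in GMT format).

Gene identity is by HGNC-style symbol, uppercased; no alias resolution is
attempted.  GMT is the standard tab-separated layout: set id, description,
then one gene symbol per column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["GeneSet", "GeneSetCollection", "GmtParseError", "read_gmt", "filter_sets"]


class GmtParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    genes: frozenset[str]
    source: str = "custom"  # GO, KEGG or custom

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.set_id} is empty")
        object.__setattr__(
            self, "genes", frozenset(g.upper() for g in self.genes)
        )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    sets: tuple[GeneSet, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sets", tuple(self.sets))
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate set ids: {dupes}")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.genes
        return frozenset(out)

    @property
    def set_ids(self) -> tuple[str, ...]:
        return tuple(s.set_id for s in self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)


def _infer_source(set_id: str) -> str:
    sid = set_id.upper()
    if sid.startswith("GO:") or sid.startswith("GO_"):
        return "GO"
    if sid.startswith(("KEGG", "HSA", "MAP")):
        return "KEGG"
    return "custom"


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Blank gene tokens are dropped; a line with fewer than three columns or
    a duplicated set id is an error.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip():
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 3:
            raise GmtParseError(
                f"{path}:{lineno}: expected >= 3 tab-separated columns, "
                f"got {len(cols)}"
            )
        set_id, name = cols[0].strip(), cols[1].strip()
        if set_id in seen:
            raise GmtParseError(f"{path}:{lineno}: duplicate set id {set_id!r}")
        seen.add(set_id)
        genes = [g.strip() for g in cols[2:] if g.strip()]
        if not genes:
            raise GmtParseError(f"{path}:{lineno}: set {set_id!r} has no genes")
        sets.append(GeneSet(set_id, name, frozenset(genes), _infer_source(set_id)))
    return GeneSetCollection(tuple(sets), provenance=f"read_gmt:{path}")


def filter_sets(
    collection: GeneSetCollection,
    min_size: int = 1,
    max_size: int | None = None,
    restrict_to: Iterable[str] | None = None,
) -> GeneSetCollection:
    """Intersect with a gene universe and drop sets outside [min, max] size.

    Defaults are a no-op.  Idempotent for fixed arguments.  An empty
    result is valid (the caller may warn).
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if max_size is not None and max_size < min_size:
        raise ValueError("max_size must be >= min_size")
    allowed = (
        None if restrict_to is None else {g.upper() for g in restrict_to}
    )
    kept: list[GeneSet] = []
    for s in collection.sets:
        genes = s.genes if allowed is None else (s.genes & allowed)
        if not genes:
            continue
        if len(genes) < min_size:
            continue
        if max_size is not None and len(genes) > max_size:
            continue
        kept.append(GeneSet(s.set_id, s.name, frozenset(genes), s.source))
    prov = (
        f"{collection.provenance} | filter_sets(min={min_size}, "
        f"max={max_size}, restricted={allowed is not None})"
    )
    return GeneSetCollection(tuple(kept), provenance=prov)
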