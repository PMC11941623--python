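"""Gene-set collections and the tab-delimited GMT format."""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt"]


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets

    def restricted_to(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with a gene universe, dropping emptied terms."""
        kept = {t: g & universe for t, g in self.sets.items() if g & universe}
        return GeneSetCollection(kept, {t: self.descriptions.get(t, "") for t in kept})


def read_gmt(path: str | PathLike) -> GeneSetCollection:
    """Parse a GMT file: term, description, then one gene id per field."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT rows need term, description "
                    f"and at least one gene (got {len(fields)} fields)"
                )
            term, desc, *genes = fields
            if term in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate term {term!r}")
            sets[term] = set(g for g in genes if g)
            descriptions[term] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | PathLike) -> None:
    with open(path, "w") as fh:
        for term in collection.sets:
            desc = collection.descriptions.get(term, "")
            genes = "\t".join(sorted(collection.sets[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")
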