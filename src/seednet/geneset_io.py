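"""Gene lists and gene-set collections: GMT / seed-list I/O and bundled fixtures.

Gene identity throughout the package is the uppercase HGNC-style symbol
string; no remote identifier resolution is ever performed.  Gene-set
collections travel in GMT (Gene Matrix Transposed) format: one set per
line, tab-separated ``set_id <TAB> description <TAB> gene [gene ...]``.
The second column is free text and is ignored on read.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "SeedList",
    "normalize_symbols",
    "read_gmt",
    "write_gmt",
    "read_seed_list",
    "write_seed_list",
    "load_mdd_fixtures",
]


class GmtParseError(ValueError):
    """A GMT line could not be parsed (fewer than three fields)."""


def normalize_symbols(genes: Iterable[str]) -> set[str]:
    """Trim, uppercase and deduplicate gene symbols; empty strings are dropped."""
    out = set()
    for g in genes:
        g = g.strip().upper()
        if g:
            out.add(g)
    return out


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (e.g. one pathway's seed-gene membership)."""

    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        members = frozenset(normalize_symbols(self.members))
        if not members:
            raise ValueError(f"gene set {self.set_id!r} has no members")
        for g in members:
            if any(c.isspace() for c in g):
                raise ValueError(f"gene symbol {g!r} contains whitespace")
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)

    def intersection(self, other: "GeneSet") -> frozenset[str]:
        return self.members & other.members


@dataclass
class GeneSetCollection:
    """An ordered collection of gene sets with unique ids."""

    source_label: str
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate set ids in collection: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)

    @property
    def all_genes(self) -> set[str]:
        """Union of every member gene in the collection."""
        out: set[str] = set()
        for s in self.sets:
            out |= s.members
        return out


@dataclass(frozen=True)
class SeedList:
    """A curated list of disease-associated genes used as analysis seeds."""

    label: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        genes = frozenset(normalize_symbols(self.genes))
        if not genes:
            raise ValueError("seed list is empty")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)


def read_gmt(path: str | Path, source_label: str | None = None) -> GeneSetCollection:
    """Read a GMT file into a :class:`GeneSetCollection`.

    Duplicate genes within a line are collapsed and symbols uppercased.
    Raises :class:`GmtParseError` naming the offending line when a line has
    fewer than three tab-separated fields, and ``ValueError`` on empty files.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            set_id, description = fields[0], fields[1]
            sets.append(GeneSet(set_id=set_id, name=description or set_id,
                                members=frozenset(normalize_symbols(fields[2:]))))
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return GeneSetCollection(source_label=source_label or str(path), sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    """Write a collection to GMT.  Tabs inside names are replaced by spaces so
    the round trip ``read_gmt(write_gmt(c))`` preserves ids and member sets."""
    if not len(collection):
        raise ValueError("refusing to write an empty collection")
    path = Path(path)
    with open(path, "w") as fh:
        for s in collection:
            sid = s.set_id.replace("\t", " ")
            name = s.name.replace("\t", " ")
            fh.write("\t".join([sid, name, *sorted(s.members)]) + "\n")
    return path


def read_seed_list(path: str | Path, label: str | None = None) -> SeedList:
    """Read a seed list from one-symbol-per-line text (first TSV column used)."""
    path = Path(path)
    genes = []
    with open(path) as fh:
        for line in fh:
            sym = line.split("\t")[0].strip()
            if sym and not sym.startswith("#"):
                genes.append(sym)
    return SeedList(label=label or path.stem, genes=frozenset(genes))


def write_seed_list(seed: SeedList, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for g in sorted(seed.genes):
            fh.write(g + "\n")
    return path


def _fixture_path(name: str) -> Path:
    res = importlib.resources.files("seednet") / "fixtures" / name
    p = Path(str(res))
    if not p.exists():
        raise FileNotFoundError(f"bundled fixture missing or corrupt: {name}")
    return p


def load_mdd_fixtures() -> tuple[SeedList, GeneSetCollection, GeneSetCollection]:
    """Load the bundled major-depressive-disorder study fixtures.

    Returns ``(seeds, pathways, connectors)``:

    * ``seeds`` — the seed-gene list: the union of the seed-gene memberships
      of the 73 enriched KEGG pathways plus the individually named candidate
      genes from the source study's gene-curation narrative (131 symbols).
    * ``pathways`` — 73 enriched pathways, each restricted to its seed-gene
      members (the inputs of the cross-talk construction).
    * ``connectors`` — one set holding the 35 non-seed connector genes the
      original subnetwork extraction introduced.

    Everything is packaged; no download is performed.
    """
    pathways = read_gmt(_fixture_path("enriched_pathways.gmt"),
                        source_label="mdd_enriched_pathways")
    seeds = read_seed_list(_fixture_path("seed_genes.tsv"), label="MDDgene")

    conn_genes = []
    with open(_fixture_path("subnetwork_connector_genes.tsv")) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sym_col = header.index("symbol")
        for line in fh:
            conn_genes.append(line.rstrip("\n").split("\t")[sym_col])
    connectors = GeneSetCollection(
        source_label="mdd_subnetwork_connectors",
        sets=[GeneSet(set_id="connector_genes",
                      name="Subnetwork connector genes outside the seed list",
                      members=frozenset(normalize_symbols(conn_genes)))],
    )
    return seeds, pathways, connectors
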