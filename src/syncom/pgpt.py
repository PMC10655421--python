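"""Plant growth-promoting trait (PGPT) screening.

Screens genome annotation tables (genome id → gene symbols) against a gene
catalog of eight trait categories — nitrogen fixation, exopolysaccharide
production, nodulation, ROS scavenging, iron acquisition, potassium
transport, spermidine metabolism and IAA-related tryptophan metabolism —
and reports per-category completeness (fraction of catalog genes present).

Matching is by exact gene symbol, case-insensitively, after whitespace
trimming. Homology search is upstream of this module: inputs are already
annotated symbol sets.

The packaged default catalog is transcribed from its printed source
verbatim. That source enumerates the list with duplicates (``nodX`` and
``nodO`` each appear twice) and states a total of 86 genes that does not
match the number of distinct printed symbols (91); the catalog keeps every
distinct printed symbol — including unusual entries such as ``node``,
``nod`` and the ``*_like`` variants — and records the discrepancy in its
metadata rather than silently editing symbols. Supply a custom catalog to
override.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field

import pandas as pd

from syncom.core import SyncomError, ValidationError

# Distinct printed symbols per category; printed duplicates (nodX, nodO)
# collapsed. See module docstring for the count discrepancy note.
_DEFAULT_CATEGORIES: tuple[tuple[str, tuple[str, ...]], ...] = (
    (
        "nitrogen fixation",
        ("nifA", "nifB", "nifD", "nifE", "nifF", "nifH", "nifHD1", "nifHD2",
         "nifJ", "nifK", "nifM", "nifN", "nifQ", "nifS", "nifT", "nifU",
         "nifV", "nifW", "nifX", "nifZ"),
    ),
    (
        "exopolysaccharide production",
        ("epsE", "epsD", "epsF", "epsH", "epsI", "epsJ", "epsL", "epsM",
         "epsN", "epsO"),
    ),
    (
        "root colonization by nodulation",
        ("nodA", "nodB", "nodC", "node", "nodF", "nodI", "nodJ", "nodU",
         "nod", "nodT", "nolM", "noeA", "noeB", "noeC", "noeD", "noeE",
         "nodN", "nodN_like", "nodO", "nodP", "nodS", "nodS_like", "nodY",
         "nodZ", "nodV", "nodV_like", "nodW", "nodX"),
    ),
    ("oxidative stress ROS scavenging", ("sodN", "sodC", "sod3")),
    ("iron acquisition", ("lipA", "lipB", "lipL", "lipL2", "lipM", "lplA")),
    (
        "salinity stress potassium transport",
        ("kdpA", "kdpB", "kdpC", "kdpD", "kdpE", "kdpF"),
    ),
    (
        "plant embryogenesis spermidine",
        ("puuA", "puuB", "puuC", "puuD", "puuE", "pup"),
    ),
    (
        "IAA-related tryptophan metabolism",
        ("trpA", "trpB", "trpC", "trpCF", "trpD", "trpE", "trpEG", "trpG",
         "trpDG", "trpF", "trpS", "trpR"),
    ),
)

_DEFAULT_METADATA = {
    "source": "printed 86-gene PGPT criterion",
    "note": (
        "printed list contains duplicate symbols (nodX, nodO each twice) and "
        "its stated total of 86 does not equal the 91 distinct printed "
        "symbols retained here"
    ),
    "stated_total": 86,
}


def _norm(symbol: str) -> str:
    return symbol.strip().lower()


@dataclass(frozen=True)
class PGPTCatalog:
    """Ordered trait categories, each a list of gene symbols.

    Symbols are unique across the whole catalog after case-insensitive
    normalization: a symbol belongs to exactly one category.
    """

    categories: tuple[tuple[str, tuple[str, ...]], ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cat, genes in self.categories:
            deduped = []
            for g in genes:
                key = _norm(g)
                if key in seen:
                    if seen[key] != cat:
                        raise ValidationError(
                            f"gene symbol {g!r} appears in two categories: "
                            f"{seen[key]!r} and {cat!r}"
                        )
                    continue  # duplicate within a category: collapse
                seen[key] = cat
                deduped.append(g)
            if tuple(deduped) != tuple(genes):
                object.__setattr__(
                    self,
                    "categories",
                    tuple(
                        (c, tuple(deduped)) if c == cat else (c, gs)
                        for c, gs in self.categories
                    ),
                )

    @property
    def category_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.categories)

    def genes(self, category: str) -> tuple[str, ...]:
        for c, gs in self.categories:
            if c == category:
                return gs
        raise KeyError(category)

    def all_genes(self) -> tuple[str, ...]:
        return tuple(g for _, gs in self.categories for g in gs)

    def __len__(self) -> int:
        return len(self.all_genes())


@dataclass(frozen=True)
class PGPTProfile:
    """One genome's screening result.

    ``completeness[cat]`` = |present ∩ category genes| / |category genes|;
    ``complete[cat]`` is True iff that fraction is exactly 1.
    """

    genome_id: str
    present: dict[str, tuple[str, ...]]
    completeness: dict[str, float]
    complete: dict[str, bool]


def load_catalog(path: "str | os.PathLike | None" = None) -> PGPTCatalog:
    """The default packaged catalog, or a custom one from a JSON file.

    Custom format: ``{"categories": [[name, [symbols...]], ...],
    "metadata": {...}}``. A symbol present in two categories is an error.
    """
    if path is None:
        return PGPTCatalog(categories=_DEFAULT_CATEGORIES,
                           metadata=dict(_DEFAULT_METADATA))
    with open(os.fspath(path)) as fh:
        doc = json.load(fh)
    if "categories" not in doc:
        raise SyncomError(f"{path}: catalog JSON must define 'categories'")
    categories = tuple(
        (str(name), tuple(map(str, genes))) for name, genes in doc["categories"]
    )
    return PGPTCatalog(categories=categories, metadata=doc.get("metadata", {}))


def save_catalog(catalog: PGPTCatalog, path: "str | os.PathLike") -> None:
    with open(os.fspath(path), "w") as fh:
        json.dump(
            {"categories": [[c, list(gs)] for c, gs in catalog.categories],
             "metadata": catalog.metadata},
            fh, indent=1,
        )
        fh.write("\n")


def load_annotations(path: "str | os.PathLike") -> dict[str, set[str]]:
    """Two-column TSV (genome_id, gene_symbol) → annotation table."""
    table: dict[str, set[str]] = {}
    with open(os.fspath(path), newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or (i == 0 and _norm(row[0]) in ("genome_id", "genome")):
                continue
            if len(row) < 2:
                raise SyncomError(f"{path}: line {i + 1}: expected 2 columns")
            table.setdefault(row[0].strip(), set()).add(row[1].strip())
    return table


def screen_genomes(
    annotations: "dict[str, set[str]]",
    catalog: PGPTCatalog | None = None,
) -> list[PGPTProfile]:
    """Per-genome presence/absence and completeness against the catalog.

    One profile per genome, ordered by genome id; matching is exact symbol,
    case-insensitive, whitespace-trimmed.
    """
    if catalog is None:
        catalog = load_catalog()
    profiles = []
    for genome_id in sorted(annotations):
        have = {_norm(g) for g in annotations[genome_id]}
        present: dict[str, tuple[str, ...]] = {}
        completeness: dict[str, float] = {}
        complete: dict[str, bool] = {}
        for cat, genes in catalog.categories:
            hits = tuple(g for g in genes if _norm(g) in have)
            present[cat] = hits
            frac = len(hits) / len(genes) if genes else 0.0
            completeness[cat] = frac
            complete[cat] = len(hits) == len(genes) and bool(genes)
        profiles.append(
            PGPTProfile(genome_id=genome_id, present=present,
                        completeness=completeness, complete=complete)
        )
    return profiles


def presence_matrix(
    profiles: "list[PGPTProfile]",
    catalog: PGPTCatalog | None = None,
) -> pd.DataFrame:
    """Binary genome × gene matrix, genes in catalog order, genomes by id."""
    if catalog is None:
        catalog = load_catalog()
    genes = catalog.all_genes()
    rows = sorted(profiles, key=lambda p: p.genome_id)
    data = []
    for p in rows:
        hit = {_norm(g) for hits in p.present.values() for g in hits}
        data.append([1 if _norm(g) in hit else 0 for g in genes])
    return pd.DataFrame(
        data, index=[p.genome_id for p in rows], columns=list(genes), dtype=int
    )
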