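"""Input parsing, validation and tabular output for interaction networks.

The two inputs are deliberately minimal text formats so that any upstream
differential-expression / target-prediction pipeline can produce them:

* an **interaction table** — headerless, delimiter-separated, one
  ``miRNA<TAB>gene`` pair per line;
* an optional **DE gene list** — headerless, one gene symbol per line,
  defining the universe ``G`` of differentially expressed genes.

Identifiers are opaque strings.  The default case policy preserves them
as written (HUGO symbols are case-sensitive by convention); ``upper`` is
available for messy inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

logger = logging.getLogger("mirnetmapper")

CasePolicy = Literal["preserve", "upper"]
IntersectionPolicy = Literal["strict", "warn"]


@dataclass(frozen=True)
class InteractionTable:
    """A deduplicated, ordered miRNA -> gene edge list.

    ``edges`` preserves first-seen order; the same (miRNA, gene) pair
    never appears twice (an interaction is binary: present or absent).
    """

    edges: tuple[tuple[str, str], ...]
    source_path: str = ""

    def __post_init__(self) -> None:
        for m, g in self.edges:
            if not m.strip() or not g.strip():
                raise ValueError("empty miRNA or gene identifier in edge list")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges in canonical InteractionTable")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def mirnas(self) -> tuple[str, ...]:
        """Distinct miRNA ids in first-seen order."""
        return tuple(dict.fromkeys(m for m, _ in self.edges))

    @property
    def genes(self) -> tuple[str, ...]:
        """Distinct gene ids in first-seen order."""
        return tuple(dict.fromkeys(g for _, g in self.edges))

    def targets_of(self) -> dict[str, set[str]]:
        """Map each miRNA id to its set of target genes."""
        out: dict[str, set[str]] = {}
        for m, g in self.edges:
            out.setdefault(m, set()).add(g)
        return out


@dataclass(frozen=True)
class DEGeneList:
    """The universe of differentially expressed genes (one sign stratum)."""

    genes: frozenset[str]
    source_path: str = ""

    @property
    def size_G(self) -> int:
        return len(self.genes)


@dataclass
class UniverseReport:
    """Result of reconciling an edge list against the DE gene universe."""

    interactions: InteractionTable
    policy: IntersectionPolicy
    dropped_edges: tuple[tuple[str, str], ...]
    targets_outside_de: tuple[str, ...]
    untargeted_de_genes: tuple[str, ...]
    mirnas_lost: tuple[str, ...] = field(default=())


def _canon(token: str, policy: CasePolicy) -> str:
    token = token.strip()
    return token.upper() if policy == "upper" else token


def read_interactions(
    path: str | Path,
    id_case_policy: CasePolicy = "preserve",
    delimiter: str = "\t",
) -> InteractionTable:
    """Read a headerless two-column interaction table.

    Blank lines are skipped.  Duplicate (miRNA, gene) pairs are collapsed
    to one edge (count logged).  Extra columns beyond the second are
    ignored with a warning; a line with fewer than two columns is a hard
    error naming the line number.
    """
    path = Path(path)
    edges: dict[tuple[str, str], None] = {}
    n_dup = 0
    extra_warned = False
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split(delimiter)
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 {delimiter!r}-separated "
                    f"fields (miRNA, gene), got {line!r}"
                )
            if len(fields) > 2 and not extra_warned:
                logger.warning(
                    "%s: line %d has %d fields; columns beyond the second are ignored",
                    path, lineno, len(fields),
                )
                extra_warned = True
            edge = (_canon(fields[0], id_case_policy), _canon(fields[1], id_case_policy))
            if edge in edges:
                n_dup += 1
            else:
                edges[edge] = None
    if not edges:
        raise ValueError(f"{path}: no interactions")
    if n_dup:
        logger.warning("%s: collapsed %d duplicate interaction(s)", path, n_dup)
    return InteractionTable(edges=tuple(edges), source_path=str(path))


def read_de_genes(
    path: str | Path, id_case_policy: CasePolicy = "preserve"
) -> DEGeneList:
    """Read the optional one-column DE gene list; duplicates collapse with a warning."""
    path = Path(path)
    seen: dict[str, None] = {}
    n_dup = 0
    with path.open(encoding="utf-8") as fh:
        for raw in fh:
            token = raw.strip()
            if not token:
                continue
            gene = _canon(token, id_case_policy)
            if gene in seen:
                n_dup += 1
            else:
                seen[gene] = None
    if not seen:
        raise ValueError(f"{path}: empty DE gene list")
    if n_dup:
        logger.warning("%s: collapsed %d duplicate gene symbol(s)", path, n_dup)
    return DEGeneList(genes=frozenset(seen), source_path=str(path))


def validate_universe(
    interactions: InteractionTable,
    de: DEGeneList,
    policy: IntersectionPolicy = "strict",
) -> UniverseReport:
    """Reconcile targets against the DE universe.

    Target-prediction repositories return genome-wide target lists, so an
    edge list may name genes outside the experiment's DE set.  Under
    ``strict`` (the intersection rule) those edges are dropped; under
    ``warn`` they are kept but reported.  Either way the report lists DE
    genes never targeted by any miRNA.
    """
    outside = tuple(dict.fromkeys(g for _, g in interactions.edges if g not in de.genes))
    dropped: tuple[tuple[str, str], ...] = ()
    kept = interactions
    mirnas_lost: tuple[str, ...] = ()
    if policy == "strict" and outside:
        dropped = tuple(e for e in interactions.edges if e[1] not in de.genes)
        surviving = tuple(e for e in interactions.edges if e[1] in de.genes)
        if not surviving:
            raise ValueError(
                "strict intersection with the DE gene list leaves zero edges"
            )
        kept = InteractionTable(edges=surviving, source_path=interactions.source_path)
        mirnas_lost = tuple(m for m in interactions.mirnas if m not in set(kept.mirnas))
        logger.warning(
            "dropped %d edge(s) whose gene is outside the DE list (%d gene(s))",
            len(dropped), len(outside),
        )
    elif outside:
        logger.warning(
            "%d target gene(s) are outside the DE list (kept under policy 'warn')",
            len(outside),
        )
    targeted = set(g for _, g in kept.edges)
    untargeted = tuple(sorted(de.genes - targeted))
    return UniverseReport(
        interactions=kept,
        policy=policy,
        dropped_edges=dropped,
        targets_outside_de=outside,
        untargeted_de_genes=untargeted,
        mirnas_lost=mirnas_lost,
    )


def write_interactions(
    table: InteractionTable, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write the canonical edge list back in the input dialect (headerless)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for m, g in table.edges:
            fh.write(f"{m}{delimiter}{g}\n")


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_table(frame, path: str | Path, fmt: Literal["tsv", "csv"] = "tsv") -> None:
    """Write a pandas DataFrame as headered TSV (default) or CSV."""
    sep = "\t" if fmt == "tsv" else ","
    frame.to_csv(Path(path), sep=sep, index=False)
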