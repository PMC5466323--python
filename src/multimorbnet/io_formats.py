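"""Tabular I/O and interaction-source filtering for the functional interaction
network (FIN) and its companion tables.

The FIN is an undirected simple graph over protein identifiers, assembled by
taking the union of per-source interaction tables after source-specific
confidence filtering:

* ``reactome_fi`` — functional interactions; records flagged *predicted* are
  discarded, as are those with score <= 0.5;
* ``hippie`` — experimental protein-protein interactions; only records with
  score > 0.73 ("high confidence") are kept;
* ``innatedb`` — curated innate-immunity interactions; records are kept only
  when both literature-support counts satisfy hpr < 20 and lpr < 20;
* ``generic`` — a plain edge list, kept unconditionally.

Identifiers are opaque strings (UniProt accessions in practice).  No
gene/protein mapping is performed, so multiple accessions of one gene remain
distinct nodes.  All tables are plain tab-delimited text; pathway member and
edge lists are semicolon-joined within a cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

# Source-specific confidence cuts (all strict inequalities).
REACTOME_MIN_SCORE = 0.5
HIPPIE_MIN_SCORE = 0.73
INNATEDB_MAX_PR = 20


class Source(str, Enum):
    REACTOME_FI = "reactome_fi"
    HIPPIE = "hippie"
    INNATEDB = "innatedb"
    GENERIC = "generic"


class RecordError(ValueError):
    """A malformed record or table row; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def edge_key(a: str, b: str) -> tuple[str, str]:
    """Canonical undirected edge key: the lexicographically sorted pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class InteractionRecord:
    """One row of an interaction table, before or after filtering.

    Optional fields (``score``, ``predicted``, ``hpr``, ``lpr``) are required
    by :func:`filter_interactions` depending on ``source``; a missing required
    field is a :class:`RecordError`, never a silent keep.
    """

    protein_a: str
    protein_b: str
    source: Source = Source.GENERIC
    score: float | None = None
    predicted: bool | None = None
    hpr: int | None = None
    lpr: int | None = None
    line: int | None = None

    def __post_init__(self):
        if not self.protein_a or not self.protein_b:
            raise RecordError("empty protein identifier", self.line)


@dataclass(frozen=True)
class DiseaseProteinSet:
    """A named set of protein identifiers associated with one disease."""

    name: str
    proteins: frozenset[str]

    def __post_init__(self):
        if not self.name:
            raise ValueError("disease name must be non-empty")
        object.__setattr__(self, "proteins", frozenset(self.proteins))

    def __len__(self) -> int:
        return len(self.proteins)

    def restrict_to(self, G: nx.Graph) -> "DiseaseProteinSet":
        """Return the subset of proteins present as nodes of ``G``.

        Disease associations routinely include proteins without reliable
        interactions; restriction to the network is an explicit step so the
        dropped count is visible.
        """
        kept = frozenset(p for p in self.proteins if p in G)
        dropped = len(self.proteins) - len(kept)
        if dropped:
            logger.info(
                "disease %r: %d of %d proteins absent from the network",
                self.name, dropped, len(self.proteins),
            )
        return DiseaseProteinSet(self.name, kept)


@dataclass(frozen=True)
class PathwayAnnotation:
    """A pathway with its member proteins and intra-pathway edge set.

    ``intra_edges`` holds the network edges whose *both* endpoints belong to
    the pathway; this is the edge universe used by the functional-similarity
    statistic.
    """

    name: str
    members: frozenset[str]
    intra_edges: frozenset[tuple[str, str]]

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))
        canon = frozenset(edge_key(a, b) for a, b in self.intra_edges)
        object.__setattr__(self, "intra_edges", canon)
        for a, b in canon:
            if a not in self.members or b not in self.members:
                raise ValueError(
                    f"pathway {self.name!r}: edge ({a}, {b}) has an endpoint "
                    "outside the member set"
                )

    @property
    def n_edges(self) -> int:
        return len(self.intra_edges)


@dataclass(frozen=True)
class CatalogueEntry:
    disease: DiseaseProteinSet
    parents: frozenset[str] = frozenset()


class DiseaseCatalogue:
    """A catalogue of disease protein sets with parent/descendant relations.

    Used as the empirical null reference: random pairs/trios are drawn from
    the catalogue while forbidding combinations in which one disease is an
    ancestor or descendant (subtype) of another.
    """

    def __init__(self, entries: Iterable[CatalogueEntry]):
        self._entries: dict[str, CatalogueEntry] = {}
        for e in entries:
            name = e.disease.name
            if name in self._entries:
                raise ValueError(f"duplicate disease name {name!r} in catalogue")
            self._entries[name] = e
        for name, e in self._entries.items():
            for p in e.parents:
                if p not in self._entries:
                    raise ValueError(f"disease {name!r} has unknown parent {p!r}")
        self._ancestors = {n: self._closure(n) for n in self._entries}
        for n, anc in self._ancestors.items():
            if n in anc:
                raise ValueError(f"catalogue hierarchy contains a cycle at {n!r}")

    def _closure(self, name: str) -> frozenset[str]:
        seen: set[str] = set()
        stack = list(self._entries[name].parents)
        while stack:
            p = stack.pop()
            if p == name:
                raise ValueError(f"catalogue hierarchy contains a cycle at {name!r}")
            if p not in seen:
                seen.add(p)
                stack.extend(self._entries[p].parents)
        return frozenset(seen)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[CatalogueEntry]:
        return iter(self._entries.values())

    @property
    def names(self) -> list[str]:
        return list(self._entries)

    def get(self, name: str) -> DiseaseProteinSet:
        return self._entries[name].disease

    def related(self, a: str, b: str) -> bool:
        """True when one disease is an ancestor/descendant of the other."""
        return a in self._ancestors[b] or b in self._ancestors[a]


# ---------------------------------------------------------------------------
# filtering and network assembly


def _require(rec: InteractionRecord, fieldname: str):
    value = getattr(rec, fieldname)
    if value is None:
        raise RecordError(
            f"{rec.source.value} record missing required field {fieldname!r}",
            rec.line,
        )
    return value


def keep_record(rec: InteractionRecord) -> bool:
    """Apply the per-source confidence filter to one record."""
    if rec.source is Source.REACTOME_FI:
        predicted = _require(rec, "predicted")
        score = _require(rec, "score")
        return (not predicted) and score > REACTOME_MIN_SCORE
    if rec.source is Source.HIPPIE:
        return _require(rec, "score") > HIPPIE_MIN_SCORE
    if rec.source is Source.INNATEDB:
        return _require(rec, "hpr") < INNATEDB_MAX_PR and _require(rec, "lpr") < INNATEDB_MAX_PR
    return True


def filter_interactions(records: Iterable[InteractionRecord]) -> list[InteractionRecord]:
    """Keep records passing their source's confidence filter, order preserved."""
    return [r for r in records if keep_record(r)]


def build_network(records: Iterable[InteractionRecord]) -> nx.Graph:
    """Union of (already filtered) records into an undirected simple graph.

    Duplicate edges from any source or node order collapse to one edge;
    self-loops are dropped with a logged count.
    """
    records = list(records)
    if not records:
        raise ValueError("no interactions: cannot build an empty network")
    G = nx.Graph()
    loops = 0
    for r in records:
        if r.protein_a == r.protein_b:
            loops += 1
            continue
        G.add_edge(*edge_key(r.protein_a, r.protein_b))
    if loops:
        logger.warning("build_network: dropped %d self-loop record(s)", loops)
    if G.number_of_edges() == 0:
        raise ValueError("no interactions: all records were self-loops")
    return G


# ---------------------------------------------------------------------------
# readers / writers

_SOURCE_COLUMNS: dict[Source, tuple[str, ...]] = {
    Source.REACTOME_FI: ("score", "predicted"),
    Source.HIPPIE: ("score",),
    Source.INNATEDB: ("hpr", "lpr"),
}

_TRUE = {"1", "true", "yes", "t"}
_FALSE = {"0", "false", "no", "f"}


def _rows(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (line_number, fields) for non-blank, non-comment lines."""
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if "\t" not in line and ";" not in line and " " not in line.strip():
                # single-column rows are legal for gene lists only; callers
                # that need >1 column raise their own RecordError
                yield ln, [line.strip()]
                continue
            yield ln, [f.strip() for f in line.split("\t")]


def read_interactions(path: str | Path, source: Source | str) -> list[InteractionRecord]:
    """Read a per-source interaction table (TSV with header).

    The generic dialect is two tab-separated columns with an optional
    ``protein_a``/``protein_b`` header and ``#`` comments.
    """
    source = Source(source)
    rows = list(_rows(path))
    if not rows:
        raise RecordError(f"{path}: empty interaction table")
    records: list[InteractionRecord] = []
    if source is Source.GENERIC:
        start = 0
        first = [f.lower() for f in rows[0][1]]
        if first[:2] == ["protein_a", "protein_b"]:
            start = 1
        for ln, fields in rows[start:]:
            if len(fields) < 2:
                raise RecordError("expected two tab-separated identifiers", ln)
            records.append(InteractionRecord(fields[0], fields[1], source, line=ln))
        return records

    header_ln, header = rows[0]
    cols = {name.lower(): i for i, name in enumerate(header)}
    needed = ("protein_a", "protein_b") + _SOURCE_COLUMNS[source]
    for c in needed:
        if c not in cols:
            raise RecordError(f"{path}: missing column {c!r} for source {source.value}", header_ln)
    for ln, fields in rows[1:]:
        if len(fields) < len(header):
            raise RecordError("row has fewer fields than the header", ln)

        def get(c: str) -> str:
            return fields[cols[c]]

        kwargs: dict = {}
        try:
            if "score" in needed:
                kwargs["score"] = float(get("score")) if get("score") else None
            if "predicted" in needed:
                tok = get("predicted").lower()
                if tok in _TRUE:
                    kwargs["predicted"] = True
                elif tok in _FALSE:
                    kwargs["predicted"] = False
                elif tok:
                    raise RecordError(f"unrecognized boolean {tok!r}", ln)
            if "hpr" in needed:
                kwargs["hpr"] = int(get("hpr")) if get("hpr") else None
                kwargs["lpr"] = int(get("lpr")) if get("lpr") else None
        except RecordError:
            raise
        except ValueError as exc:
            raise RecordError(str(exc), ln) from exc
        records.append(
            InteractionRecord(get("protein_a"), get("protein_b"), source, line=ln, **kwargs)
        )
    return records


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a generic two-column edge list into a network."""
    return build_network(read_interactions(path, Source.GENERIC))


def write_edge_list(G: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in sorted(edge_key(u, v) for u, v in G.edges()):
            fh.write(f"{a}\t{b}\n")


def read_disease_sets(path: str | Path) -> list[DiseaseProteinSet]:
    """Read a two-column disease/protein table; duplicate rows collapse."""
    rows = list(_rows(path))
    if not rows:
        raise RecordError(f"{path}: empty disease-set table")
    header = [f.lower() for f in rows[0][1]]
    if header[:2] != ["disease", "protein"]:
        raise RecordError(
            f"{path}: expected header 'disease\\tprotein', got {rows[0][1]!r}",
            rows[0][0],
        )
    order: list[str] = []
    members: dict[str, set[str]] = {}
    for ln, fields in rows[1:]:
        if len(fields) < 2:
            raise RecordError("expected disease\\tprotein", ln)
        disease, protein = fields[0], fields[1]
        if not disease or not protein:
            raise RecordError("empty disease or protein field", ln)
        if disease not in members:
            members[disease] = set()
            order.append(disease)
        members[disease].add(protein)
    return [DiseaseProteinSet(d, frozenset(members[d])) for d in order]


def write_disease_sets(sets: Sequence[DiseaseProteinSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease\tprotein\n")
        for s in sets:
            for p in sorted(s.proteins):
                fh.write(f"{s.name}\t{p}\n")


def _parse_edge_token(token: str, ln: int) -> tuple[str, str]:
    if "|" in token:
        parts = token.split("|")
    else:
        parts = token.split("-")
    if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
        raise RecordError(
            f"cannot parse edge token {token!r} (use 'A|B', or 'A-B' when unambiguous)",
            ln,
        )
    return edge_key(parts[0].strip(), parts[1].strip())


def read_pathways(path: str | Path, network: nx.Graph | None = None) -> list[PathwayAnnotation]:
    """Read pathway rows: name TAB members(;-joined) TAB edges(;-joined).

    When ``network`` is given, intra-pathway edges are intersected with the
    network's edge set, which is the universe FSim operates on.
    """
    rows = list(_rows(path))
    if not rows:
        raise RecordError(f"{path}: empty pathway table")
    start = 0
    if [f.lower() for f in rows[0][1]][:1] == ["pathway"]:
        start = 1
    pathways: list[PathwayAnnotation] = []
    for ln, fields in rows[start:]:
        if len(fields) < 2:
            raise RecordError("expected pathway\\tmembers[\\tedges]", ln)
        name = fields[0]
        members = frozenset(m.strip() for m in fields[1].split(";") if m.strip())
        edges: set[tuple[str, str]] = set()
        if len(fields) > 2 and fields[2]:
            for token in fields[2].split(";"):
                token = token.strip()
                if token:
                    edges.add(_parse_edge_token(token, ln))
        if network is not None:
            edges = {e for e in edges if network.has_edge(*e)}
        edges = {e for e in edges if e[0] in members and e[1] in members}
        pathways.append(PathwayAnnotation(name, members, frozenset(edges)))
    return pathways


def write_pathways(pathways: Sequence[PathwayAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pathway\tmembers\tedges\n")
        for p in pathways:
            members = ";".join(sorted(p.members))
            edges = ";".join(f"{a}|{b}" for a, b in sorted(p.intra_edges))
            fh.write(f"{p.name}\t{members}\t{edges}\n")


def read_catalogue(path: str | Path) -> DiseaseCatalogue:
    """Read a disease catalogue: disease TAB proteins(;-joined) TAB parents."""
    rows = list(_rows(path))
    if not rows:
        raise RecordError(f"{path}: empty catalogue table")
    start = 0
    if [f.lower() for f in rows[0][1]][:1] == ["disease"]:
        start = 1
    entries: list[CatalogueEntry] = []
    for ln, fields in rows[start:]:
        if len(fields) < 2:
            raise RecordError("expected disease\\tproteins[\\tparents]", ln)
        name = fields[0]
        proteins = frozenset(p.strip() for p in fields[1].split(";") if p.strip())
        parents = frozenset()
        if len(fields) > 2 and fields[2]:
            parents = frozenset(p.strip() for p in fields[2].split(";") if p.strip())
        entries.append(CatalogueEntry(DiseaseProteinSet(name, proteins), parents))
    return DiseaseCatalogue(entries)


def write_catalogue(catalogue: DiseaseCatalogue, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease\tproteins\tparents\n")
        for e in catalogue:
            proteins = ";".join(sorted(e.disease.proteins))
            parents = ";".join(sorted(e.parents))
            fh.write(f"{e.disease.name}\t{proteins}\t{parents}\n")


def read_gene_list(path: str | Path) -> frozenset[str]:
    """Read a plain gene/protein list (one identifier per line or column 1)."""
    out: set[str] = set()
    for ln, fields in _rows(path):
        if fields and fields[0] and fields[0].lower() not in {"gene", "geneid", "protein"}:
            out.add(fields[0])
    return frozenset(out)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\n")
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_genie_table(path: str | Path, fdr_max: float | None = None) -> frozenset[str]:
    """Read a literature text-mining output table (gene, n, n_pos, FDR).

    Returns the gene set, optionally filtered to rows with FDR <= ``fdr_max``.
    """
    rows = list(_rows(path))
    if not rows:
        raise RecordError(f"{path}: empty literature table")
    header = [f.lower() for f in rows[0][1]]
    gene_col = None
    for cand in ("geneid", "gene"):
        if cand in header:
            gene_col = header.index(cand)
            break
    if gene_col is None:
        raise RecordError(f"{path}: no 'gene'/'GeneID' column", rows[0][0])
    fdr_col = header.index("fdr") if "fdr" in header else None
    out: set[str] = set()
    for ln, fields in rows[1:]:
        if len(fields) <= gene_col:
            raise RecordError("row shorter than header", ln)
        if fdr_max is not None:
            if fdr_col is None:
                raise RecordError(f"{path}: FDR filter requested but no 'FDR' column", rows[0][0])
            try:
                fdr = float(fields[fdr_col])
            except ValueError as exc:
                raise RecordError(f"bad FDR value {fields[fdr_col]!r}", ln) from exc
            if fdr > fdr_max:
                continue
        out.add(fields[gene_col])
    return frozenset(out)
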