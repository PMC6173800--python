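"""Genomic-neighborhood screening of fap-operon homologs.

The Fap system (functional amyloid in Pseudomonas) is encoded by the six-gene
operon *fapABCDEF*.  Homology searches against large genome collections return
many spurious single-gene hits; bona fide operons are recognised by
colocalization: a hit counts only if it lies within a small genomic distance
(default < 5000 bp) of its second-nearest fap-gene neighbor, inside a cluster
carrying at least four distinct fap components.  This module filters raw hit
tables down to such operon calls, summarises component presence per taxon, and
detects colocalized gene pairs (e.g. fapD/fapF) outside complete operons.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import pandas as pd

COMPONENTS = ("FapA", "FapB", "FapC", "FapD", "FapE", "FapF")

#: Accepted spellings for component labels, case-insensitive ("fapA", "FAPA" ...).
_COMPONENT_LOOKUP = {c.lower(): c for c in COMPONENTS}

HITS_COLUMNS = [
    "protein_id",
    "component",
    "assembly_id",
    "contig_id",
    "start",
    "end",
    "strand",
    "taxon",
]


class ParseError(ValueError):
    """Raised for malformed hit-table input; message names the offending line."""


@dataclass(frozen=True)
class HomologHit:
    """A single fap-component homolog anchored on a genome.

    Coordinates are 1-based and inclusive on both ends, as in GFF3.
    """

    protein_id: str
    component: str
    assembly_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "unknown"
    taxon: str = ""

    def __post_init__(self):
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown Fap component label: {self.component!r}")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"strand must be +, - or unknown, got {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class OperonCall:
    """A cluster of colocalized hits that passes the operon filter."""

    contig_id: str
    members: list[HomologHit]
    distinct_components: frozenset = field(init=False)
    span: tuple[int, int] = field(init=False)

    def __post_init__(self):
        if not self.members:
            raise ValueError("OperonCall requires at least one member")
        contigs = {m.contig_id for m in self.members}
        if contigs != {self.contig_id}:
            raise ValueError("all members must share the call's contig_id")
        self.distinct_components = frozenset(m.component for m in self.members)
        self.span = (min(m.start for m in self.members), max(m.end for m in self.members))

    @property
    def assembly_id(self) -> str:
        return self.members[0].assembly_id


@dataclass
class PresenceMatrix:
    """Per-taxon presence of the six Fap components plus strain counts."""

    table: pd.DataFrame          # taxa x components, boolean
    strain_counts: pd.Series     # taxon -> number of distinct assemblies with >= 1 call


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _normalize_component(label: str, line_no: int) -> str:
    comp = _COMPONENT_LOOKUP.get(label.strip().lower())
    if comp is None:
        raise ParseError(f"line {line_no}: unknown component label {label.strip()!r}")
    return comp


def parse_hits(stream: TextIO | str, format: str = "tsv") -> list[HomologHit]:
    """Parse a homolog hit table into :class:`HomologHit` records.

    Parameters
    ----------
    stream:
        Open text stream or a string containing the table.
    format:
        ``"tsv"`` — header ``protein_id  component  assembly_id  contig_id
        start  end  strand  taxon`` (strand/taxon optional); or ``"gff3"`` —
        standard GFF3 where each feature carries a ``fap_component`` attribute
        (``protein_id``/``ID`` and ``assembly_id`` attributes are honoured).

    Raises
    ------
    ParseError
        On malformed rows or unknown component labels, naming the line number.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    if format == "tsv":
        return _parse_tsv(stream)
    if format == "gff3":
        return _parse_gff3(stream)
    raise ValueError(f"format must be 'tsv' or 'gff3', got {format!r}")


def _parse_tsv(stream: TextIO) -> list[HomologHit]:
    lines = stream.read().splitlines()
    if not lines:
        return []
    header = [h.strip() for h in lines[0].split("\t")]
    required = {"protein_id", "component", "assembly_id", "contig_id", "start", "end"}
    missing = required - set(header)
    if missing:
        raise ParseError(f"line 1: header missing columns {sorted(missing)}")
    idx = {name: i for i, name in enumerate(header)}
    hits = []
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < len(required):
            raise ParseError(f"line {line_no}: expected >= {len(required)} fields, got {len(fields)}")

        def get(col, default=""):
            i = idx.get(col)
            return fields[i].strip() if i is not None and i < len(fields) else default

        try:
            start, end = int(get("start")), int(get("end"))
        except ValueError as exc:
            raise ParseError(f"line {line_no}: non-integer coordinate ({exc})") from None
        strand = get("strand", "unknown") or "unknown"
        if strand == ".":
            strand = "unknown"
        try:
            hits.append(
                HomologHit(
                    protein_id=get("protein_id"),
                    component=_normalize_component(get("component"), line_no),
                    assembly_id=get("assembly_id"),
                    contig_id=get("contig_id"),
                    start=start,
                    end=end,
                    strand=strand,
                    taxon=get("taxon"),
                )
            )
        except ValueError as exc:
            raise ParseError(f"line {line_no}: {exc}") from None
    return _dedup(hits)


def _parse_gff3(stream: TextIO) -> list[HomologHit]:
    hits = []
    for line_no, line in enumerate(stream.read().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"line {line_no}: GFF3 requires 9 tab-separated fields, got {len(fields)}")
        contig, _source, _type, start_s, end_s, _score, strand, _phase, attrs_s = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(f"line {line_no}: non-integer coordinates {start_s!r}/{end_s!r}") from None
        attrs = {}
        for item in attrs_s.strip().split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                attrs[k.strip()] = v.strip()
        if "fap_component" not in attrs:
            raise ParseError(f"line {line_no}: missing fap_component attribute")
        if strand not in ("+", "-"):
            strand = "unknown"
        try:
            hits.append(
                HomologHit(
                    protein_id=attrs.get("protein_id", attrs.get("ID", "")),
                    component=_normalize_component(attrs["fap_component"], line_no),
                    assembly_id=attrs.get("assembly_id", ""),
                    contig_id=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    taxon=attrs.get("taxon", ""),
                )
            )
        except ValueError as exc:
            raise ParseError(f"line {line_no}: {exc}") from None
    return _dedup(hits)


def _dedup(hits: list[HomologHit]) -> list[HomologHit]:
    # duplicates only on identical (protein_id, coordinates); identical
    # coordinates with different protein_ids are legitimate.
    seen, out = set(), []
    for h in hits:
        key = (h.protein_id, h.contig_id, h.start, h.end)
        if key not in seen:
            seen.add(key)
            out.append(h)
    return out


# ---------------------------------------------------------------------------
# colocalization filter
# ---------------------------------------------------------------------------

def gene_gap(a: HomologHit, b: HomologHit, metric: str = "edge") -> float:
    """Genomic distance between two features on the same contig.

    ``edge`` (default): intergenic edge-to-edge distance, 0 for overlapping or
    book-ended features.  ``midpoint``: distance between feature midpoints.
    """
    if metric == "edge":
        return max(0, max(a.start, b.start) - min(a.end, b.end) - 1)
    if metric == "midpoint":
        return abs(a.midpoint - b.midpoint)
    raise ValueError(f"metric must be 'edge' or 'midpoint', got {metric!r}")


def filter_operon_hits(
    hits: Iterable[HomologHit],
    max_gap: int = 5000,
    min_components: int = 4,
    gap_metric: str = "edge",
    count_raw_hits: bool = False,
) -> list[OperonCall]:
    """Reduce raw homolog hits to operon calls.

    A hit is retained iff at least two other fap hits on the same contig lie
    within ``max_gap`` of it (i.e. its second-nearest fap-gene neighbor is
    closer than ``max_gap``).  Retained hits are then single-linkage clustered
    at ``max_gap``, and clusters with at least ``min_components`` distinct
    components (or raw hits, if ``count_raw_hits``) are reported.

    Output is deterministic: calls sorted by (contig, span start), members by
    coordinate.  The result is invariant to input order.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    if min_components < 1:
        raise ValueError("min_components must be >= 1")
    by_contig: dict[tuple[str, str], list[HomologHit]] = {}
    for h in hits:
        by_contig.setdefault((h.assembly_id, h.contig_id), []).append(h)

    calls = []
    for (_asm, contig), group in sorted(by_contig.items()):
        group = sorted(group, key=lambda h: (h.start, h.end, h.protein_id))
        # second-nearest-neighbor rule, per focal hit, before clustering
        kept = []
        for h in group:
            n_close = sum(
                1 for other in group
                if other is not h and gene_gap(h, other, gap_metric) < max_gap
            )
            if n_close >= 2:
                kept.append(h)
        if not kept:
            continue
        # single-linkage clustering at max_gap among retained hits
        clusters: list[list[HomologHit]] = []
        for h in kept:
            current = [h]
            merged = []
            for cl in clusters:
                if any(gene_gap(h, other, gap_metric) < max_gap for other in cl):
                    current = cl + current
                else:
                    merged.append(cl)
            merged.append(current)
            clusters = merged
        for cl in clusters:
            members = sorted(cl, key=lambda h: (h.start, h.end, h.protein_id))
            size = len(members) if count_raw_hits else len({m.component for m in members})
            if size >= min_components:
                calls.append(OperonCall(contig_id=contig, members=members))
    calls.sort(key=lambda c: (c.contig_id, c.span[0], c.span[1]))
    return calls


def detect_colocalized_pairs(
    hits: Iterable[HomologHit],
    comp_a: str = "FapD",
    comp_b: str = "FapF",
    max_gap: int = 5000,
    gap_metric: str = "edge",
) -> list[tuple[HomologHit, HomologHit]]:
    """All same-contig (comp_a, comp_b) hit pairs closer than ``max_gap``.

    Each qualifying pair is reported once, the left-most feature first.
    Used for the conserved fapD/fapF colocalization outside complete operons.
    """
    by_contig: dict[tuple[str, str], list[HomologHit]] = {}
    for h in hits:
        by_contig.setdefault((h.assembly_id, h.contig_id), []).append(h)
    pairs = []
    for _key, group in sorted(by_contig.items()):
        a_hits = [h for h in group if h.component == comp_a]
        b_hits = [h for h in group if h.component == comp_b]
        for a in a_hits:
            for b in b_hits:
                if a is b:
                    continue
                if gene_gap(a, b, gap_metric) < max_gap:
                    first, second = sorted([a, b], key=lambda h: (h.start, h.end, h.protein_id))
                    pairs.append((first, second))
    pairs.sort(key=lambda p: (p[0].contig_id, p[0].start, p[1].start))
    # dedup in the degenerate comp_a == comp_b case where both orders appear
    seen, out = set(), []
    for p in pairs:
        key = tuple(sorted([(h.protein_id, h.contig_id, h.start, h.end) for h in p]))
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# per-taxon summary
# ---------------------------------------------------------------------------

def presence_matrix(
    calls: Iterable[OperonCall],
    taxonomy: dict[str, str] | None = None,
) -> PresenceMatrix:
    """Boolean taxon x component presence matrix with per-taxon strain counts.

    ``taxonomy`` maps assembly_id -> taxon (genus or lineage).  Assemblies
    without a mapping fall back to the hit's own ``taxon`` field, then to
    ``"unclassified"``.  A strain is a distinct assembly with at least one
    operon call.
    """
    taxonomy = taxonomy or {}
    present: dict[str, set[str]] = {}
    strains: dict[str, set[str]] = {}
    for call in calls:
        asm = call.assembly_id
        taxon = taxonomy.get(asm) or call.members[0].taxon or "unclassified"
        present.setdefault(taxon, set()).update(call.distinct_components)
        strains.setdefault(taxon, set()).add(asm)
    taxa = sorted(present)
    table = pd.DataFrame(
        [[c in present[t] for c in COMPONENTS] for t in taxa],
        index=pd.Index(taxa, name="taxon"),
        columns=list(COMPONENTS),
        dtype=bool,
    )
    counts = pd.Series({t: len(strains[t]) for t in taxa}, name="strain_count", dtype=int)
    counts.index.name = "taxon"
    return PresenceMatrix(table=table, strain_counts=counts)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def calls_to_frame(calls: Iterable[OperonCall]) -> pd.DataFrame:
    """Flatten operon calls to one row per member hit."""
    rows = []
    for k, call in enumerate(calls):
        for m in call.members:
            rows.append(
                {
                    "operon_id": k,
                    "contig_id": call.contig_id,
                    "span_start": call.span[0],
                    "span_end": call.span[1],
                    "n_components": len(call.distinct_components),
                    "protein_id": m.protein_id,
                    "component": m.component,
                    "assembly_id": m.assembly_id,
                    "start": m.start,
                    "end": m.end,
                    "strand": m.strand,
                    "taxon": m.taxon,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "operon_id", "contig_id", "span_start", "span_end", "n_components",
            "protein_id", "component", "assembly_id", "start", "end", "strand", "taxon",
        ],
    )


def pairs_to_frame(pairs: Iterable[tuple[HomologHit, HomologHit]]) -> pd.DataFrame:
    rows = []
    for a, b in pairs:
        rows.append(
            {
                "contig_id": a.contig_id,
                "protein_a": a.protein_id, "component_a": a.component,
                "start_a": a.start, "end_a": a.end,
                "protein_b": b.protein_id, "component_b": b.component,
                "start_b": b.start, "end_b": b.end,
                "gap_bp": gene_gap(a, b),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig_id", "protein_a", "component_a", "start_a", "end_a",
            "protein_b", "component_b", "start_b", "end_b", "gap_bp",
        ],
    )


def read_taxonomy(stream: TextIO | str) -> dict[str, str]:
    """Read a two-column assembly_id -> taxon TSV (no header required)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    mapping = {}
    for line in stream.read().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) >= 2:
            if fields[0].strip() == "assembly_id":  # optional header
                continue
            mapping[fields[0].strip()] = fields[1].strip()
    return mapping
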