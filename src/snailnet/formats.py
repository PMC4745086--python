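"""Readers and writers for every external file the pipeline touches.

Supported formats
-----------------
* nucleotide FASTA (read/write), with strict {A,C,G,T,N} alphabet checking
* domain-hit tables in hmmsearch ``--domtblout`` column layout (read)
* protein homology hits in BLAST tabular ``-outfmt 6`` layout (read)
* domain-domain interaction flat files, pipe- or tab-delimited,
  one ``accession, accession, confidence`` triple per line (read)
* interaction networks as SIF, GraphML or two-column edge TSV (read/write)
* gene -> functional-term maps as three-column TSV (read)

Plus :func:`assembly_stats`, which summarises an assembly (count, total
length, mean length, N50).

All readers transparently handle plain gzip (``.gz``) input.
"""

from __future__ import annotations

import gzip
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .errors import FormatError, ValidationError

_VALID_NT = frozenset("ACGTN")
_PFAM_VERSION_RE = re.compile(r"\.\d+$")

NETWORK_FORMATS = ("sif", "graphml", "tsv")


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def strip_accession_version(acc: str) -> str:
    """Drop a trailing ``.N`` version suffix from a Pfam accession.

    DOMINE keys its interactions by unversioned accessions, so every join
    in the pipeline happens on the unversioned form (``PF13465.1`` ->
    ``PF13465``).
    """
    return _PFAM_VERSION_RE.sub("", acc)


def round_half_away(x: float) -> int:
    """Round to the nearest integer with ties going away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """A unigene: identifier plus uppercase nucleotide sequence."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DomainHit:
    """One protein-vs-Pfam-profile hit surviving (or not) the E-value filter."""

    protein_id: str
    domain_name: str
    domain_acc: str
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class HomologyHit:
    """One row of tabular BLAST output."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    bitscore: float
    subject_description: str = ""


@dataclass(frozen=True)
class DomainInteraction:
    """An unordered pair of Pfam accessions with a confidence class.

    ``domain_a <= domain_b`` lexicographically after canonicalisation, so
    two records are equal iff they denote the same unordered pair.
    """

    domain_a: str
    domain_b: str
    confidence: str

    @property
    def pair(self) -> tuple[str, str]:
        return (self.domain_a, self.domain_b)


@dataclass(frozen=True)
class AssemblyStats:
    n_sequences: int
    total_length: int
    mean_length: int
    n50: int


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[SequenceRecord]:
    """Read nucleotide FASTA into a list of :class:`SequenceRecord`.

    Order is preserved; sequences are uppercased. Duplicate identifiers and
    characters outside {A,C,G,T,N} raise :class:`ValidationError`; text
    before the first header raises :class:`FormatError` naming the line.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    chunks: list[str] = []
    cur_line = 0

    def _flush():
        if cur_id is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ValidationError(f"{path}: record '{cur_id}' has an empty sequence")
        bad = set(seq) - _VALID_NT
        if bad:
            raise ValidationError(
                f"{path}: record '{cur_id}' contains invalid characters "
                f"{sorted(bad)}; only A, C, G, T, N are accepted"
            )
        records.append(SequenceRecord(cur_id, seq))

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                cur_id = line[1:].split()[0] if len(line) > 1 else ""
                cur_line = lineno
                if not cur_id:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if cur_id in seen:
                    raise ValidationError(
                        f"{path}:{lineno}: duplicate sequence id '{cur_id}'"
                    )
                seen.add(cur_id)
                chunks = []
            else:
                if cur_id is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                chunks.append(line)
        _flush()
    return records


def write_fasta(records: Iterable, path, width: int = 60) -> None:
    """Write records (anything with ``.id`` and ``.seq``) as FASTA."""
    with open(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.seq
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# tabular hit files
# ---------------------------------------------------------------------------


def read_domain_hits(path, evalue_cutoff: float = 1e-5) -> list[DomainHit]:
    """Parse a domtblout-style domain table, keeping hits with E < cutoff.

    Column positions follow hmmsearch ``--domtblout``: target (protein) id
    in column 1, query (domain) name in column 4, query accession in
    column 5, full-sequence E-value in column 7 and bit score in column 8.
    Comment lines starting with ``#`` are skipped. Pfam accession version
    suffixes are stripped so downstream joins are unversioned.
    """
    hits: list[DomainHit] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 8:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 8 whitespace-delimited "
                    f"columns, found {len(cols)}"
                )
            try:
                evalue = float(cols[6])
                bitscore = float(cols[7])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric E-value or bit score: {exc}"
                ) from None
            if evalue < 0:
                raise ValidationError(f"{path}:{lineno}: negative E-value {evalue}")
            if evalue < evalue_cutoff:
                hits.append(
                    DomainHit(
                        protein_id=cols[0],
                        domain_name=cols[3],
                        domain_acc=strip_accession_version(cols[4]),
                        evalue=evalue,
                        bitscore=bitscore,
                    )
                )
    return hits


def read_blast_hits(path, evalue_cutoff: float = 1e-5) -> list[HomologyHit]:
    """Parse 12-column BLAST ``-outfmt 6`` rows, keeping hits with E < cutoff.

    An optional 13th column is treated as the subject description.
    """
    hits: list[HomologyHit] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) == 1:  # tolerate space-delimited tables
                cols = line.split()
            if len(cols) not in (12, 13):
                raise FormatError(
                    f"{path}:{lineno}: expected 12 (or 13) tab-delimited "
                    f"columns, found {len(cols)}"
                )
            try:
                pident = float(cols[2])
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field: {exc}") from None
            if evalue < 0:
                raise ValidationError(f"{path}:{lineno}: negative E-value {evalue}")
            if not 0.0 <= pident <= 100.0:
                raise ValidationError(
                    f"{path}:{lineno}: percent identity {pident} outside [0, 100]"
                )
            if evalue < evalue_cutoff:
                hits.append(
                    HomologyHit(
                        query_id=cols[0],
                        subject_id=cols[1],
                        percent_identity=pident,
                        evalue=evalue,
                        bitscore=bitscore,
                        subject_description=cols[12] if len(cols) == 13 else "",
                    )
                )
    return hits


def read_ddi_table(
    path, accepted_confidences: set[str] | None = None
) -> list[DomainInteraction]:
    """Read a DOMINE-style domain-domain interaction flat file.

    Each line holds two Pfam accessions and a confidence class, separated
    by ``|`` or by tabs/whitespace. Pairs are deduplicated under unordered
    equality; self-interacting domains (a == a) are retained. If
    ``accepted_confidences`` is None, every confidence class is kept.
    """
    out: list[DomainInteraction] = []
    seen: set[tuple[str, str]] = set()
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("|") if "|" in line else line.split()
            cols = [c.strip() for c in cols]
            if len(cols) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 columns "
                    f"(accession, accession, confidence), found {len(cols)}"
                )
            a = strip_accession_version(cols[0])
            b = strip_accession_version(cols[1])
            conf = cols[2]
            if accepted_confidences is not None and conf not in accepted_confidences:
                continue
            pair = (a, b) if a <= b else (b, a)
            if pair in seen:
                continue
            seen.add(pair)
            out.append(DomainInteraction(pair[0], pair[1], conf))
    return out


def read_term_map(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a TSV of ``subject_id, term_id, term_name`` rows.

    Returns a gene->terms map and a term_id->term_name map.
    """
    gene_terms: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 2 tab-delimited columns"
                )
            gene, term = cols[0], cols[1]
            gene_terms.setdefault(gene, set()).add(term)
            if len(cols) >= 3 and cols[2]:
                term_names.setdefault(term, cols[2])
    return gene_terms, term_names


# ---------------------------------------------------------------------------
# network I/O
# ---------------------------------------------------------------------------


def _as_graph(network) -> nx.Graph:
    if isinstance(network, nx.Graph):
        return network
    graph = getattr(network, "graph", None)
    if isinstance(graph, nx.Graph):
        return graph
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from(network.edges)
    return g


def write_network(network, path, format: str = "sif") -> None:
    """Write a network as SIF, GraphML or 2-column edge TSV.

    SIF and GraphML preserve isolated nodes; the edge TSV represents only
    nodes incident to at least one edge. Reading the written file with
    :func:`read_network` reconstructs the node and edge sets (modulo that
    TSV caveat).
    """
    g = _as_graph(network)
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValidationError(
            f"unknown network format '{format}'; choose from {NETWORK_FORMATS}"
        )
    if fmt == "graphml":
        # stringify node ids so GraphML round-trips losslessly
        nx.write_graphml(nx.relabel_nodes(g, {n: str(n) for n in g.nodes}), path)
        return
    edges = sorted(tuple(sorted((str(u), str(v)))) for u, v in g.edges)
    with open(path, "wt") as fh:
        if fmt == "sif":
            connected = set()
            for u, v in edges:
                fh.write(f"{u}\tinteracts\t{v}\n")
                connected.update((u, v))
            for n in sorted(str(n) for n in g.nodes):
                if n not in connected:
                    fh.write(f"{n}\n")
        else:  # tsv
            for u, v in edges:
                fh.write(f"{u}\t{v}\n")


def read_network(path, format: str = "sif") -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValidationError(
            f"unknown network format '{format}'; choose from {NETWORK_FORMATS}"
        )
    if fmt == "graphml":
        return nx.read_graphml(path)
    g = nx.Graph()
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if fmt == "sif":
                if len(cols) == 1:
                    g.add_node(cols[0])
                elif len(cols) >= 3:
                    src = cols[0]
                    for tgt in cols[2:]:
                        g.add_edge(src, tgt)
                else:
                    raise FormatError(
                        f"{path}:{lineno}: SIF lines need 1 or >= 3 columns"
                    )
            else:  # tsv
                if len(cols) < 2:
                    raise FormatError(
                        f"{path}:{lineno}: edge TSV lines need 2 columns"
                    )
                g.add_edge(cols[0], cols[1])
    return g


# ---------------------------------------------------------------------------
# assembly statistics
# ---------------------------------------------------------------------------


def n50(lengths: Sequence[int]) -> int:
    """Length at which sequences that long or longer hold >= half the total.

    Computed by sorting lengths in descending order and returning the first
    length whose cumulative sum reaches at least total/2 (inclusive).
    """
    if not lengths:
        raise ValidationError("n50 requires at least one sequence length")
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    raise AssertionError("unreachable: cumulative sum always reaches total")


def assembly_stats(records: Sequence) -> AssemblyStats:
    """Summarise an assembly: sequence count, total/mean length and N50.

    Mean length is rounded to the nearest integer, ties away from zero.
    """
    if not records:
        raise ValidationError("assembly_stats requires at least one record")
    lengths = [len(r) for r in records]
    total = sum(lengths)
    return AssemblyStats(
        n_sequences=len(lengths),
        total_length=total,
        mean_length=round_half_away(total / len(lengths)),
        n50=n50(lengths),
    )
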