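"""Annotation transfer from homology hits and domain assignment.

Functional annotation of unigene proteins follows the usual transcriptome
convention: each query inherits the annotation of its most similar subject
(minimal E-value) among hits surviving the E < 1e-5 cutoff, and Pfam
domains are assigned from HMM-search hits surviving the same cutoff.
GO/KEGG/COG terms attach by joining best-hit subject ids against
user-supplied subject->term maps (see :func:`snailnet.formats.read_term_map`).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from .errors import ValidationError
from .formats import DomainHit, HomologyHit


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    best_subject: str
    description: str
    evalue: float
    source_db: str = "Nr"


@dataclass(frozen=True)
class DomainAssignment:
    """A protein and its deduplicated set of unversioned Pfam accessions."""

    protein_id: str
    domains: frozenset[str]


class DomainSummaryRow(NamedTuple):
    domain_name: str
    accession: str
    n_proteins: int


def transfer_best_hit(
    hits: Iterable[HomologyHit], source_db: str = "Nr"
) -> dict[str, GeneAnnotation]:
    """Assign each query the annotation of its most similar subject.

    The winner per query has the smallest E-value; ties go to the larger
    bit score, then the lexicographically smallest subject id.
    """
    best: dict[str, HomologyHit] = {}
    for hit in hits:
        key = (hit.evalue, -hit.bitscore, hit.subject_id)
        cur = best.get(hit.query_id)
        if cur is None or key < (cur.evalue, -cur.bitscore, cur.subject_id):
            best[hit.query_id] = hit
    return {
        q: GeneAnnotation(
            gene_id=q,
            best_subject=h.subject_id,
            description=h.subject_description,
            evalue=h.evalue,
            source_db=source_db,
        )
        for q, h in best.items()
    }


def assign_domains(
    hits: Iterable[DomainHit], evalue_cutoff: float = 1e-5
) -> list[DomainAssignment]:
    """Collect each protein's reliable domains (E < cutoff, deduplicated).

    Proteins with no surviving hit are absent from the output. Results are
    sorted by protein id.
    """
    domains: dict[str, set[str]] = defaultdict(set)
    for hit in hits:
        if hit.evalue < evalue_cutoff:
            domains[hit.protein_id].add(hit.domain_acc)
    return [
        DomainAssignment(pid, frozenset(domains[pid])) for pid in sorted(domains)
    ]


def top_domain_summary(
    assignments: Sequence[DomainAssignment],
    hits: Iterable[DomainHit],
    n: int,
) -> list[DomainSummaryRow]:
    """Rank domains by how many distinct proteins carry them.

    Ties are broken by accession ascending. Domain display names come from
    the first hit naming each accession.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    names: dict[str, str] = {}
    for hit in hits:
        names.setdefault(hit.domain_acc, hit.domain_name)
    counts: dict[str, int] = defaultdict(int)
    for asg in assignments:
        for acc in asg.domains:
            counts[acc] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        DomainSummaryRow(names.get(acc, acc), acc, cnt) for acc, cnt in ranked[:n]
    ]
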