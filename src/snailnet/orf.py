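"""Six-frame longest-ORF protein prediction for assembled unigenes.

Assembled transcripts are frequently 5'-truncated, so candidates are
stop-to-stop codon runs with no start-codon requirement: every maximal
stop-free run in each of the six reading frames is a candidate, including
runs left open at the 3' end. The longest candidate wins, and predictions
shorter than a minimum length (30 amino acids by default) are discarded.

Coordinates are always reported on the forward strand, 0-based half-open,
so that re-translating ``seq[start:end]`` (reverse-complemented first for
negative frames) reproduces the stored protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import reverse_complement

_TABLE = unambiguous_dna_by_id[1]
_FORWARD = dict(_TABLE.forward_table)
_STOPS = frozenset(_TABLE.stop_codons)

FRAME_ORDER = (1, 2, 3, -1, -2, -3)


def translate_codon(codon: str) -> str:
    """Translate one codon; stops give ``*``, any ambiguity gives ``X``.

    A codon containing N is always ``X`` (even when the ambiguity would be
    synonymous), and ``X`` never terminates an ORF.
    """
    if codon in _STOPS:
        return "*"
    return _FORWARD.get(codon, "X")


@dataclass(frozen=True)
class OrfRecord:
    """A predicted ORF: frame, forward-strand coordinates and protein."""

    unigene_id: str
    frame: int
    start: int  # 0-based inclusive, forward strand
    end: int  # 0-based exclusive, forward strand
    protein: str

    def __len__(self) -> int:
        return len(self.protein)


def six_frame_orfs(seq: str) -> list[OrfRecord]:
    """Enumerate every maximal stop-free codon run in all six frames.

    Returns candidates (with empty ``unigene_id``) in frame order
    +1, +2, +3, -1, -2, -3 and by position within each frame. Sequences
    shorter than one codon yield an empty list. Trailing partial codons
    are ignored; a terminal run without a closing stop is still reported.
    """
    seq = seq.upper()
    n = len(seq)
    out: list[OrfRecord] = []
    for frame in FRAME_ORDER:
        strand_seq = seq if frame > 0 else reverse_complement(seq)
        offset = abs(frame) - 1
        n_codons = (n - offset) // 3
        run_start = None  # codon index where current run began
        aas: list[str] = []

        def _close(end_codon: int) -> None:
            nonlocal run_start, aas
            if run_start is None:
                return
            s = offset + 3 * run_start
            e = offset + 3 * end_codon
            if frame > 0:
                start, end = s, e
            else:
                start, end = n - e, n - s
            out.append(OrfRecord("", frame, start, end, "".join(aas)))
            run_start = None
            aas = []

        for ci in range(n_codons):
            codon = strand_seq[offset + 3 * ci : offset + 3 * ci + 3]
            aa = translate_codon(codon)
            if aa == "*":
                _close(ci)
            else:
                if run_start is None:
                    run_start = ci
                aas.append(aa)
        _close(n_codons)
    return out


def select_protein(
    seq: str, min_aa: int = 30, unigene_id: str = ""
) -> OrfRecord | None:
    """Pick the single longest six-frame ORF, or None if below ``min_aa``.

    Ties are broken deterministically: frame order +1, +2, +3, -1, -2, -3,
    then smallest forward-strand start.
    """
    candidates = six_frame_orfs(seq)
    if not candidates:
        return None
    frame_rank = {f: i for i, f in enumerate(FRAME_ORDER)}
    best = min(
        candidates, key=lambda c: (-len(c.protein), frame_rank[c.frame], c.start)
    )
    if len(best.protein) < min_aa:
        return None
    return OrfRecord(unigene_id, best.frame, best.start, best.end, best.protein)


def predict_proteins(records: Iterable, min_aa: int = 30) -> Iterator[OrfRecord]:
    """Run :func:`select_protein` over sequence records, skipping failures."""
    for rec in records:
        orf = select_protein(rec.seq, min_aa=min_aa, unigene_id=rec.id)
        if orf is not None:
            yield orf


def write_protein_fasta(orfs: Sequence[OrfRecord], path, width: int = 60) -> None:
    """Write predicted proteins with frame/coordinate metadata in headers."""
    with open(path, "wt") as fh:
        for orf in orfs:
            sign = "+" if orf.frame > 0 else ""
            fh.write(
                f">{orf.unigene_id} frame={sign}{orf.frame} "
                f"coords={orf.start}-{orf.end}\n"
            )
            for i in range(0, len(orf.protein), width):
                fh.write(orf.protein[i : i + width] + "\n")
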