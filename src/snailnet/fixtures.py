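"""Seeded synthetic inputs with known ground truth for every pipeline stage.

A bundle emulates the post-assembly state of a transcriptome study: unigene
nucleotide sequences with planted ORFs (a fraction deliberately below the
30-amino-acid retention threshold), domain-hit and BLAST-hit tables with
decoy rows above the E-value cutoff, a DOMINE-style domain-interaction
table from which the true protein network is derivable by exhaustive
all-pairs search, a two-tissue negative-binomial count matrix with a
planted differentially-expressed subset, a subject->term map and a seed
terminal list. ``truth.json`` records every generating parameter, so each
stage's output can be scored without external data.

Determinism: all randomness flows from one integer seed through fixed
sub-stream labels (one label per generator), so regenerating a bundle with
the same seed yields byte-identical files and adding a new generator never
perturbs existing outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations_with_replacement
from pathlib import Path

import numpy as np

from .errors import ValidationError

# sub-stream labels (never reorder; append only)
_STREAM_SEQ = 11
_STREAM_DOMAIN = 12
_STREAM_BLAST = 13
_STREAM_DDI = 14
_STREAM_COUNTS = 15
_STREAM_TERMS = 16

_NT = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in _NT
    for b in _NT
    for c in _NT
    if a + b + c not in _STOPS
)
_CODON_AA = {}
from Bio.Data.CodonTable import unambiguous_dna_by_id as _tables  # noqa: E402

_CODON_AA.update(_tables[1].forward_table)

_PFAM_POOL = [
    ("PF00069", "Pkinase"),
    ("PF07714", "Pkinase_Tyr"),
    ("PF13465", "zf-H2C2_2"),
    ("PF00096", "zf-C2H2"),
    ("PF00023", "Ank"),
    ("PF12796", "Ank_2"),
    ("PF00076", "RRM_1"),
    ("PF00400", "WD40"),
    ("PF00071", "Ras"),
    ("PF00001", "7tm_1"),
    ("PF07679", "I-set"),
    ("PF00036", "EF-hand_1"),
]
_CONFIDENCES = ("HC", "MC", "LC", "NA")
_TERM_POOL = [
    ("GO:0008152", "metabolic process"),
    ("GO:0006468", "protein phosphorylation"),
    ("GO:0046872", "metal ion binding"),
    ("GO:0005515", "protein binding"),
    ("GO:0007264", "small GTPase mediated signal transduction"),
    ("GO:0005509", "calcium ion binding"),
    ("GO:0007268", "chemical synaptic transmission"),
    ("GO:0006412", "translation"),
    ("GO:0006351", "transcription"),
    ("GO:0055085", "transmembrane transport"),
]


def _rng(seed: int, label: int) -> np.random.Generator:
    return np.random.default_rng([label, seed])


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _brute_six_frame_runs(seq: str) -> list[tuple[int, int, int, int]]:
    """All maximal stop-free codon runs: (frame, fwd_start, fwd_end, aa_len).

    Independent of :mod:`snailnet.orf`: translates every frame and splits
    on stop codons directly.
    """
    n = len(seq)
    runs = []
    for frame in (1, 2, 3, -1, -2, -3):
        s = seq if frame > 0 else _revcomp(seq)
        off = abs(frame) - 1
        start_c = None
        length = 0
        n_codons = (n - off) // 3

        def emit(end_c):
            nonlocal start_c, length
            if start_c is None:
                return
            lo, hi = off + 3 * start_c, off + 3 * end_c
            if frame > 0:
                runs.append((frame, lo, hi, length))
            else:
                runs.append((frame, n - hi, n - lo, length))
            start_c, length = None, 0

        for ci in range(n_codons):
            codon = s[off + 3 * ci : off + 3 * ci + 3]
            if codon in _STOPS:
                emit(ci)
            else:
                if start_c is None:
                    start_c = ci
                length += 1
        emit(n_codons)
    return runs


def _random_context(rng: np.random.Generator, n_codons: int) -> str:
    """Stop-enriched random nucleotide context (reduces spurious long runs)."""
    parts = []
    for _ in range(n_codons):
        if rng.random() < 0.3:
            parts.append(_STOPS[rng.integers(3)])
        else:
            parts.append("".join(_NT[i] for i in rng.integers(0, 4, 3)))
    return "".join(parts)


def _plant_orf(
    rng: np.random.Generator, aa_len: int, coding: bool, max_tries: int = 500
):
    """Build a unigene with a planted ORF; returns (seq, frame, start, end, protein).

    For coding genes the planted run is the strict six-frame maximum; for
    sub-threshold genes every run is kept below 30 amino acids so no
    protein is predictable at the default cutoff.
    """
    for _ in range(max_tries):
        codons = [
            _NON_STOP_CODONS[i]
            for i in rng.integers(0, len(_NON_STOP_CODONS), aa_len)
        ]
        orf = "".join(codons)
        ctx5 = _random_context(rng, int(rng.integers(4, 12)))
        ctx3 = _random_context(rng, int(rng.integers(4, 12)))
        pad = "".join(_NT[i] for i in rng.integers(0, 4, int(rng.integers(0, 3))))
        sense = pad + ctx5 + "TAA" + orf + "TAA" + ctx3
        s = len(pad) + len(ctx5) + 3
        e = s + 3 * aa_len
        strand = 1 if rng.random() < 0.5 else -1
        if strand == 1:
            seq, start, end = sense, s, e
            frame = (s % 3) + 1
        else:
            seq = _revcomp(sense)
            start, end = len(sense) - e, len(sense) - s
            frame = -((s % 3) + 1)
        runs = _brute_six_frame_runs(seq)
        planted = [r for r in runs if r[:3] == (frame, start, end)]
        others = [r[3] for r in runs if r[:3] != (frame, start, end)]
        if not planted or planted[0][3] != aa_len:
            continue
        if coding and all(o < aa_len for o in others):
            protein = "".join(_CODON_AA[c] for c in codons)
            return seq, frame, start, end, protein
        if not coding and all(o < 30 for o in others):
            protein = "".join(_CODON_AA[c] for c in codons)
            return seq, frame, start, end, protein
    raise ValidationError("failed to plant an unambiguous ORF; seed pathological")


@dataclass(frozen=True)
class FixtureBundle:
    directory: Path
    unigenes: Path
    domain_hits: Path
    blast_hits: Path
    ddi_table: Path
    counts: Path
    term_map: Path
    terminals: Path
    truth_path: Path
    truth: dict


def simulate_powerlaw_histogram(b: float, kmax: int) -> dict[int, int]:
    """Degree histogram with count(k) exactly proportional to k^-b.

    Counts are scaled to 10^12 before rounding so quantisation error is
    negligible relative to any fitting tolerance.
    """
    if b < 0:
        raise ValidationError("exponent b must be >= 0")
    if kmax < 2:
        raise ValidationError("kmax must be >= 2")
    return {k: int(round(1e12 * k**-b)) for k in range(1, kmax + 1)}


def simulate_nb_counts(
    n_genes: int,
    mean_range: tuple[float, float] = (50.0, 500.0),
    alpha: float = 0.05,
    n_de: int = 0,
    lfc: float = 2.0,
    seed: int | np.random.Generator = 0,
):
    """Two-sample negative-binomial counts with a planted DE subset.

    Non-DE genes share their mean across both samples; DE genes differ by
    a factor 2^lfc (half up, half down). Returns (counts[n_genes, 2],
    is_de[n_genes]). ``alpha`` is the NB dispersion; alpha = 0 is rejected
    (use a tiny positive value to approximate Poisson).
    """
    if n_de > n_genes:
        raise ValidationError("n_de must not exceed n_genes")
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    if alpha <= 0:
        raise ValidationError(
            "alpha must be > 0; approximate Poisson with a tiny dispersion"
        )
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, _STREAM_COUNTS)
    lo, hi = mean_range
    means = np.exp(rng.uniform(np.log(lo), np.log(hi), n_genes))
    mu = np.column_stack([means, means.copy()])
    is_de = np.zeros(n_genes, dtype=bool)
    if n_de:
        de_idx = rng.choice(n_genes, size=n_de, replace=False)
        is_de[de_idx] = True
        signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
        mu[de_idx, 1] = mu[de_idx, 0] * 2.0 ** (signs * lfc)
    r = 1.0 / alpha
    counts = rng.negative_binomial(r, r / (r + mu))
    return counts.astype(np.int64), is_de


def simulate_bundle(n_genes: int, seed: int, out_dir) -> FixtureBundle:
    """Write a complete synthetic input bundle plus ``truth.json``.

    30% of unigenes carry a planted ORF below the 30-aa retention rule;
    the rest carry a 30-80 aa ORF that is the strict six-frame maximum.
    Domain assignments are drawn from a 12-accession Pfam pool, the DDI
    table is sampled over that pool, and the true interaction network is
    derived by exhaustive all-pairs search. Counts plant 10% DE genes at
    |log2 fold change| = 2 with NB dispersion 0.05.
    """
    if n_genes < 20:
        raise ValidationError("simulate_bundle needs n_genes >= 20")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth: dict = {"seed": seed, "n_genes": n_genes, "parameters": {}}

    # --- unigenes with planted ORFs -------------------------------------
    rng = _rng(seed, _STREAM_SEQ)
    n_short = int(round(0.3 * n_genes))
    gene_ids = [
        (f"CL{i+1}.Contig1" if i % 5 == 0 else f"Unigene{i+1}")
        for i in range(n_genes)
    ]
    orf_truth = {}
    fasta_lines = []
    for i, gid in enumerate(gene_ids):
        coding = i >= n_short
        aa_len = int(rng.integers(30, 81)) if coding else int(rng.integers(5, 30))
        seq, frame, start, end, protein = _plant_orf(rng, aa_len, coding)
        orf_truth[gid] = {
            "frame": frame,
            "start": start,
            "end": end,
            "protein": protein,
            "coding": coding,
        }
        fasta_lines.append(f">{gid}\n{seq}\n")
    unigenes = out / "unigenes.fasta"
    unigenes.write_text("".join(fasta_lines))
    truth["orfs"] = orf_truth
    truth["parameters"]["min_orf_aa"] = 30
    truth["parameters"]["frac_subthreshold"] = 0.3

    # --- domain hits ------------------------------------------------------
    rng = _rng(seed, _STREAM_DOMAIN)
    proteins = [g for g in gene_ids if orf_truth[g]["coding"]]
    assignments = {}
    lines = ["# synthetic domtblout-style domain hits\n"]
    for pid in proteins:
        n_dom = int(rng.integers(1, 4))
        accs = rng.choice(len(_PFAM_POOL), size=n_dom, replace=False)
        assignments[pid] = sorted(_PFAM_POOL[j][0] for j in accs)
        for j in accs:
            acc, name = _PFAM_POOL[j]
            ev = 10.0 ** -rng.uniform(5.2, 30.0)
            score = float(rng.uniform(25, 300))
            ver = int(rng.integers(1, 30))
            lines.append(
                f"{pid} - 500 {name} {acc}.{ver} 200 {ev:.3e} {score:.1f}\n"
            )
        if rng.random() < 0.4:  # decoy above the cutoff
            j = int(rng.integers(0, len(_PFAM_POOL)))
            acc, name = _PFAM_POOL[j]
            ev = 10.0 ** -rng.uniform(0.0, 4.9)
            lines.append(
                f"{pid} - 500 {name} {acc}.1 200 {ev:.3e} "
                f"{float(rng.uniform(5, 20)):.1f}\n"
            )
    domain_hits = out / "domain_hits.domtbl"
    domain_hits.write_text("".join(lines))
    truth["domain_assignments"] = assignments

    # --- DDI table and true network ---------------------------------------
    rng = _rng(seed, _STREAM_DDI)
    pool = [p[0] for p in _PFAM_POOL]
    all_pairs = list(combinations_with_replacement(sorted(pool), 2))
    chosen = [p for p in all_pairs if rng.random() < 0.25]
    ddi_lines = []
    for a, b in chosen:
        conf = _CONFIDENCES[rng.integers(0, len(_CONFIDENCES))]
        x, y = (a, b) if rng.random() < 0.5 else (b, a)
        ddi_lines.append(f"{x}|{y}|{conf}\n")
    ddi_table = out / "ddi.txt"
    ddi_table.write_text("".join(ddi_lines))
    ddi_set = set(chosen)
    # exhaustive all-pairs reference network
    true_edges = []
    for i, p in enumerate(proteins):
        for q in proteins[i + 1 :]:
            hit = any(
                tuple(sorted((da, db))) in ddi_set
                for da in assignments[p]
                for db in assignments[q]
            )
            if hit:
                true_edges.append(sorted((p, q)))
    truth["ddi_pairs"] = [list(p) for p in sorted(ddi_set)]
    truth["network_edges"] = sorted(true_edges)

    # --- BLAST hits ---------------------------------------------------------
    rng = _rng(seed, _STREAM_BLAST)
    blast_lines = []
    best_hits = {}
    subjects = [f"SP{j:04d}" for j in range(1, 61)]
    for gid in gene_ids:
        n_hits = int(rng.integers(0, 5))
        rows = []
        for _ in range(n_hits):
            subj = subjects[rng.integers(0, len(subjects))]
            ev = 10.0 ** -rng.uniform(5.2, 50.0)
            pident = float(rng.uniform(30, 95))
            score = float(-10 * np.log10(ev) + rng.uniform(-5, 5))
            rows.append((subj, pident, ev, score))
        if rng.random() < 0.3:  # decoy above the cutoff
            subj = subjects[rng.integers(0, len(subjects))]
            rows.append((subj, float(rng.uniform(30, 95)),
                         10.0 ** -rng.uniform(0.0, 4.9), 30.0))
        for subj, pident, ev, score in rows:
            blast_lines.append(
                f"{gid}\t{subj}\t{pident:.2f}\t150\t10\t2\t1\t450\t1\t150\t"
                f"{ev:.3e}\t{score:.1f}\n"
            )
        # brute-force best-hit reference over surviving rows
        kept = [r for r in rows if float(f"{r[2]:.3e}") < 1e-5]
        if kept:
            kept = [(float(f"{ev:.3e}"), -float(f"{sc:.1f}"), subj)
                    for subj, _, ev, sc in kept]
            best_hits[gid] = min(kept)[2]
    blast_hits = out / "blast_hits.tsv"
    blast_hits.write_text("".join(blast_lines))
    truth["best_hits"] = best_hits

    # --- counts ---------------------------------------------------------------
    n_de = max(2, n_genes // 10)
    counts, is_de = simulate_nb_counts(
        n_genes, mean_range=(50.0, 500.0), alpha=0.05, n_de=n_de, lfc=2.0,
        seed=_rng(seed, _STREAM_COUNTS),
    )
    counts_path = out / "counts.tsv"
    with open(counts_path, "wt") as fh:
        fh.write("gene_id\tCNS\tFoot\n")
        for gid, (ca, cb) in zip(gene_ids, counts):
            fh.write(f"{gid}\t{ca}\t{cb}\n")
    truth["de_genes"] = sorted(g for g, d in zip(gene_ids, is_de) if d)
    truth["parameters"]["de_lfc"] = 2.0
    truth["parameters"]["nb_alpha"] = 0.05

    # --- term map and terminals -------------------------------------------
    rng = _rng(seed, _STREAM_TERMS)
    tm_lines = []
    for subj in subjects:
        n_terms = int(rng.integers(1, 4))
        idx = rng.choice(len(_TERM_POOL), size=n_terms, replace=False)
        for j in sorted(idx):
            tid, tname = _TERM_POOL[j]
            tm_lines.append(f"{subj}\t{tid}\t{tname}\n")
    term_map = out / "term_map.tsv"
    term_map.write_text("".join(tm_lines))

    net_nodes = sorted({n for e in true_edges for n in e})
    if net_nodes:
        k = min(5, len(net_nodes))
        idx = rng.choice(len(net_nodes), size=k, replace=False)
        terminal_ids = sorted(net_nodes[j] for j in idx)
    else:
        terminal_ids = []
    terminals = out / "terminals.txt"
    terminals.write_text("".join(t + "\n" for t in terminal_ids))
    truth["terminals"] = terminal_ids

    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, sort_keys=True, indent=2) + "\n")
    return FixtureBundle(
        directory=out,
        unigenes=unigenes,
        domain_hits=domain_hits,
        blast_hits=blast_hits,
        ddi_table=ddi_table,
        counts=counts_path,
        term_map=term_map,
        terminals=terminals,
        truth_path=truth_path,
        truth=truth,
    )
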