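"""Seeded local alignment and reciprocal-best-hit extraction.

The duplicate-gene workflow needs an all-vs-all nucleotide similarity
search within the collapsed transcriptome and a transcript-vs-genome
search. Both run through a k-mer seeded local aligner: a pair is aligned
only where query and subject share at least one exact k-mer (either
strand), and the alignment itself is an affine-gap Smith-Waterman
restricted to a window around the seeded region. For subjects shorter
than roughly twice the query the window covers the whole subject, so the
reported score equals the unrestricted dynamic-programming optimum.

E-values follow the Karlin-Altschul form E = K * m * n * exp(-lambda*S)
with fixed, config-exposed constants; only the ranking of hits and the
threshold crossing matter to the workflow. Precomputed tabular hits can
be substituted for the internal search at every call site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align

from .io import SequenceRecord

__all__ = [
    "ScoringScheme",
    "AlignmentHit",
    "seed_and_extend_align",
    "karlin_altschul_evalue",
    "all_vs_all_self_search",
    "search_against_genome",
    "reciprocal_best_pairs",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Nucleotide scoring: +2 match, -3 mismatch, affine gaps -5/-2."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    karlin_lambda: float = 0.625
    karlin_k: float = 0.41

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")


@dataclass
class AlignmentHit:
    """One local-alignment record (12-column tabular semantics).

    Coordinates are 1-based inclusive; minus-strand subject hits have
    sstart > send. ``query_aln``/``subject_aln`` hold the gapped alignment
    strings for internally computed hits (empty for ingested hits).
    """

    query_id: str
    subject_id: str
    percent_id: float
    align_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    raw_score: int
    query_aln: str = field(default="", repr=False)
    subject_aln: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise ValueError("qstart must not exceed qend")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")

    @property
    def is_minus_strand(self) -> bool:
        return self.sstart > self.send

    @property
    def subject_interval(self) -> tuple[int, int]:
        """Subject span as a forward-strand (start, end) with start <= end."""
        return (min(self.sstart, self.send), max(self.sstart, self.send))

    def to_tabular_line(self) -> str:
        return "\t".join(
            [
                self.query_id,
                self.subject_id,
                f"{self.percent_id:.2f}",
                str(self.align_length),
                str(self.mismatches),
                str(self.gap_opens),
                str(self.qstart),
                str(self.qend),
                str(self.sstart),
                str(self.send),
                f"{self.evalue:.2e}",
                str(self.raw_score),
            ]
        )


def karlin_altschul_evalue(
    raw_score: int, query_len: int, db_len: int, scoring: ScoringScheme
) -> float:
    """E = K * m * n * exp(-lambda * S); monotone decreasing in S."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence lengths must be positive")
    return (
        scoring.karlin_k
        * query_len
        * db_len
        * math.exp(-scoring.karlin_lambda * raw_score)
    )


def _build_aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _seed_windows(
    query: str, subject: str, k: int, min_seeds: int = 1
) -> list[tuple[int, int]]:
    """Subject windows (0-based half-open) around shared exact k-mers.

    Windows seeded by fewer than *min_seeds* k-mer matches are dropped;
    any alignment strong enough to matter carries many seeds, so raising
    the floor only prunes hopeless windows.
    """
    qkmers = set()
    for i in range(len(query) - k + 1):
        qkmers.add(query[i : i + k])
    positions = [
        i for i in range(len(subject) - k + 1) if subject[i : i + k] in qkmers
    ]
    if not positions:
        return []
    return _cluster_positions(positions, k, len(query), len(subject), min_seeds)


def _alignment_stats(aln) -> tuple[int, int, int, int]:
    """(matches, mismatches, gap_opens, columns) from a Bio.Align alignment."""
    a, b = str(aln[0]), str(aln[1])
    matches = mismatches = gap_opens = 0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(a, b):
        if ca == "-":
            if not in_gap_a:
                gap_opens += 1
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            if not in_gap_b:
                gap_opens += 1
            in_gap_a, in_gap_b = False, True
        else:
            in_gap_a = in_gap_b = False
            if ca == cb:
                matches += 1
            else:
                mismatches += 1
    return matches, mismatches, gap_opens, len(a)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def seed_and_extend_align(
    query: SequenceRecord,
    subject: SequenceRecord,
    scoring: ScoringScheme | None = None,
    kmer: int = 11,
    db_len: int | None = None,
    min_window_seeds: int = 1,
) -> AlignmentHit | None:
    """Best seeded local alignment of *query* against either strand of
    *subject*, or ``None`` when no exact k-mer is shared or no alignment
    scores above zero.

    Ties between strands resolve to the plus strand; within a strand the
    leftmost window wins.
    """
    if kmer < 8:
        raise ValueError("kmer must be >= 8")
    scoring = scoring or ScoringScheme()
    if db_len is None:
        db_len = len(subject)
    aligner = _build_aligner(scoring)
    q = query.residues
    best: tuple[float, int, AlignmentHit] | None = None  # (score, strand_rank, hit)
    for strand_rank, (strand, subj_seq) in enumerate(
        [("+", subject.residues), ("-", _revcomp(subject.residues))]
    ):
        for wstart, wend in _seed_windows(q, subj_seq, kmer, min_window_seeds):
            window = subj_seq[wstart:wend]
            alignments = aligner.align(q, window)
            if alignments.score <= 0:
                continue
            if best is not None and alignments.score < best[0]:
                continue
            if (
                best is not None
                and alignments.score == best[0]
                and strand_rank >= best[1]
            ):
                continue
            aln = alignments[0]
            matches, mism, gopens, columns = _alignment_stats(aln)
            q0, q1 = int(aln.coordinates[0, 0]), int(aln.coordinates[0, -1])
            s0, s1 = (
                int(aln.coordinates[1, 0]) + wstart,
                int(aln.coordinates[1, -1]) + wstart,
            )
            if strand == "+":
                sstart, send = s0 + 1, s1
            else:
                L = len(subject)
                sstart, send = L - s0, L - s1 + 1
            score = int(alignments.score)
            hit = AlignmentHit(
                query_id=query.id,
                subject_id=subject.id,
                percent_id=100.0 * matches / columns,
                align_length=columns,
                mismatches=mism,
                gap_opens=gopens,
                qstart=q0 + 1,
                qend=q1,
                sstart=sstart,
                send=send,
                evalue=karlin_altschul_evalue(score, len(query), db_len, scoring),
                raw_score=score,
                query_aln=str(aln[0]),
                subject_aln=str(aln[1]),
            )
            best = (alignments.score, strand_rank, hit)
    return best[2] if best else None


def _mirror_hit(hit: AlignmentHit) -> AlignmentHit:
    """The same alignment viewed with query and subject exchanged."""
    if hit.is_minus_strand:
        qstart, qend = hit.send, hit.sstart
        sstart, send = hit.qend, hit.qstart
        q_aln, s_aln = _revcomp(hit.subject_aln), _revcomp(hit.query_aln)
    else:
        qstart, qend = hit.sstart, hit.send
        sstart, send = hit.qstart, hit.qend
        q_aln, s_aln = hit.subject_aln, hit.query_aln
    return AlignmentHit(
        query_id=hit.subject_id,
        subject_id=hit.query_id,
        percent_id=hit.percent_id,
        align_length=hit.align_length,
        mismatches=hit.mismatches,
        gap_opens=hit.gap_opens,
        qstart=qstart,
        qend=qend,
        sstart=sstart,
        send=send,
        evalue=hit.evalue,
        raw_score=hit.raw_score,
        query_aln=q_aln,
        subject_aln=s_aln,
    )


def all_vs_all_self_search(
    seqs: list[SequenceRecord],
    scoring: ScoringScheme | None = None,
    kmer: int = 11,
    evalue_threshold: float = 1e-20,
) -> list[AlignmentHit]:
    """All-vs-all self search over *seqs* (self-hits excluded).

    Each unordered pair is aligned once and reported in both directions,
    so coverage is symmetric by construction. Hits with E-value above the
    threshold are discarded.
    """
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in self-search input")
    scoring = scoring or ScoringScheme()
    db_len = sum(len(s) for s in seqs)
    # inverted k-mer index (both strands) to restrict alignment to pairs
    # sharing at least one exact seed
    index: dict[str, set[int]] = {}
    for i, s in enumerate(seqs):
        for seq in (s.residues, _revcomp(s.residues)):
            for p in range(len(seq) - kmer + 1):
                index.setdefault(seq[p : p + kmer], set()).add(i)
    shared_kmers: dict[tuple[int, int], int] = {}
    for members in index.values():
        if len(members) > 1:
            mm = sorted(members)
            for a in range(len(mm)):
                for b in range(a + 1, len(mm)):
                    key = (mm[a], mm[b])
                    shared_kmers[key] = shared_kmers.get(key, 0) + 1
    # an alignment crossing the E-value threshold needs on the order of
    # fifty identical bases, i.e. dozens of shared k-mers; pairs sharing
    # only a few k-mers are chance collisions between unrelated
    # sequences and are skipped without aligning
    candidates = [k for k, n in shared_kmers.items() if n >= 4]
    hits: list[AlignmentHit] = []
    for i, j in sorted(candidates):
        hit = seed_and_extend_align(
            seqs[i], seqs[j], scoring, kmer=kmer, db_len=db_len,
            min_window_seeds=4,
        )
        if hit is None or hit.evalue > evalue_threshold:
            continue
        hits.append(hit)
        hits.append(_mirror_hit(hit))
    return hits


def _align_in_window(
    query: SequenceRecord,
    subject: SequenceRecord,
    strand: str,
    wstart: int,
    wend: int,
    aligner,
    scoring: ScoringScheme,
    db_len: int,
) -> AlignmentHit | None:
    """Local alignment of the query against a subject window; *strand*
    selects whether the window is taken from the forward subject or its
    reverse complement (coordinates reported on the forward strand)."""
    window = subject.residues[wstart:wend]
    if strand == "-":
        window = _revcomp(window)
    alignments = aligner.align(query.residues, window)
    if alignments.score <= 0:
        return None
    aln = alignments[0]
    matches, mism, gopens, columns = _alignment_stats(aln)
    q0, q1 = int(aln.coordinates[0, 0]), int(aln.coordinates[0, -1])
    s0, s1 = int(aln.coordinates[1, 0]), int(aln.coordinates[1, -1])
    wlen = wend - wstart
    if strand == "+":
        sstart, send = wstart + s0 + 1, wstart + s1
    else:
        sstart, send = wstart + wlen - s0, wstart + wlen - s1 + 1
    score = int(alignments.score)
    return AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        percent_id=100.0 * matches / columns,
        align_length=columns,
        mismatches=mism,
        gap_opens=gopens,
        qstart=q0 + 1,
        qend=q1,
        sstart=sstart,
        send=send,
        evalue=karlin_altschul_evalue(score, len(query), db_len, scoring),
        raw_score=score,
        query_aln=str(aln[0]),
        subject_aln=str(aln[1]),
    )


def _cluster_positions(
    positions: list[int],
    k: int,
    qlen: int,
    subject_len: int,
    min_seeds: int = 1,
    pad: int | None = None,
) -> list[tuple[int, int]]:
    """Merge sorted seed positions into padded subject windows; windows
    backed by fewer than *min_seeds* seeds are dropped."""
    if pad is None:
        pad = qlen + 50
    windows: list[tuple[int, int]] = []
    start = prev = positions[0]
    count = 1
    for p in positions[1:]:
        if p - prev > qlen:
            if count >= min_seeds:
                windows.append(
                    (max(0, start - pad), min(subject_len, prev + k + pad))
                )
            start = p
            count = 0
        prev = p
        count += 1
    if count >= min_seeds:
        windows.append((max(0, start - pad), min(subject_len, prev + k + pad)))
    return windows


def search_against_genome(
    queries: list[SequenceRecord],
    contigs: list[SequenceRecord],
    scoring: ScoringScheme | None = None,
    kmer: int = 11,
    evalue_threshold: float = 1e-20,
    min_window_seeds: int = 10,
    window_pad: int = 300,
) -> dict[str, list[AlignmentHit]]:
    """Seeded search of many (short) queries against few (long) contigs.

    A k-mer index over the queries (both strands) is matched against one
    linear scan of each contig; seeded regions carrying at least
    *min_window_seeds* seed matches are aligned locally within padded
    windows. Genuine anchors carry dozens to hundreds of seeds even at
    85% identity, while chance k-mer collisions against multi-megabase
    intergenic sequence arrive as isolated or small sparse clusters, so
    the seed floor prunes only hopeless windows. Returns per-query hits
    above threshold.
    """
    scoring = scoring or ScoringScheme()
    aligner = _build_aligner(scoring)
    db_len = sum(len(c) for c in contigs)
    # query k-mer index: kmer -> [(query_idx, strand)]
    index: dict[str, list[tuple[int, str]]] = {}
    for qi, q in enumerate(queries):
        for strand, seq in (("+", q.residues), ("-", _revcomp(q.residues))):
            seen: set[str] = set()
            for i in range(len(seq) - kmer + 1):
                w = seq[i : i + kmer]
                if w not in seen:
                    seen.add(w)
                    index.setdefault(w, []).append((qi, strand))
    results: dict[str, list[AlignmentHit]] = {q.id: [] for q in queries}
    for contig in contigs:
        seq = contig.residues
        # seed positions per (query, strand)
        seeds: dict[tuple[int, str], list[int]] = {}
        for pos in range(len(seq) - kmer + 1):
            entry = index.get(seq[pos : pos + kmer])
            if entry:
                for qi, strand in entry:
                    seeds.setdefault((qi, strand), []).append(pos)
        for (qi, strand), positions in sorted(seeds.items()):
            q = queries[qi]
            for wstart, wend in _cluster_positions(
                positions, kmer, len(q), len(seq), min_window_seeds,
                pad=window_pad,
            ):
                hit = _align_in_window(
                    q, contig, strand, wstart, wend, aligner, scoring, db_len
                )
                if hit is not None and hit.evalue <= evalue_threshold:
                    results[q.id].append(hit)
    # deduplicate overlapping windows / strands: keep distinct intervals,
    # best score per (contig, interval overlap)
    for qid, hits in results.items():
        hits.sort(key=lambda h: (-h.raw_score, h.subject_id, h.subject_interval))
        kept: list[AlignmentHit] = []
        for h in hits:
            redundant = any(
                k.subject_id == h.subject_id
                and not (
                    h.subject_interval[1] < k.subject_interval[0]
                    or h.subject_interval[0] > k.subject_interval[1]
                )
                for k in kept
            )
            if not redundant:
                kept.append(h)
        results[qid] = kept
    return results


def _best_subject(hits_for_query: list[AlignmentHit]) -> AlignmentHit:
    """Top hit by (raw_score desc, align_length desc, subject_id asc)."""
    return min(
        hits_for_query,
        key=lambda h: (-h.raw_score, -h.align_length, h.subject_id),
    )


def reciprocal_best_pairs(
    hits: list[AlignmentHit],
) -> list[tuple[str, str, AlignmentHit]]:
    """Mutual-best-hit pairs: A's top subject is B and B's top subject is A.

    Returns canonically ordered (id_a < id_b) pairs with the pairing hit
    (the one reported from the lexicographically smaller query). Each id
    participates in at most one pair.
    """
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            raise ValueError("self-hit present in reciprocal-best input")
        by_query.setdefault(h.query_id, []).append(h)
    best = {q: _best_subject(hs) for q, hs in by_query.items()}
    pairs: list[tuple[str, str, AlignmentHit]] = []
    for q, hit in best.items():
        s = hit.subject_id
        if q < s and s in best and best[s].subject_id == q:
            pairs.append((q, s, hit))
    pairs.sort(key=lambda p: (p[0], p[1]))
    return pairs
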