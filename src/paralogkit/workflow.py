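"""The duplicate-gene decision procedure.

Four steps turn a transcriptome assembly into labeled paralog pairs:

1. collapse each isogroup (the assembly's cluster of isoforms/alleles of
   one putative gene) to its longest isotig;
2. all-vs-all self search and reciprocal-best-hit pairing, filtered by
   minimum alignment length (>= 300 bp) and percent identity (> 80%);
3. anchor each pair member to the genome assembly; overlapping anchors
   on one contig mean the "pair" is two alleles of one locus (ALLELIC,
   discarded); same-contig anchors more than 5 kb apart indicate a local
   (tandem) duplication;
4. map contigs to chromosomes through the linkage map; pairs on
   different chromosomes are attributed to the ancestral whole-genome
   duplication (WGD), pairs on one chromosome to local duplication (LGD).

Pairs that fall between the rules (same contig, non-overlapping, gap
<= 5 kb) are AMBIGUOUS; pairs missing an anchor or a chromosome are
UNASSIGNED. Each pair carries a free-text evidence trace of the rule
that fired.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from .align import (
    AlignmentHit,
    ScoringScheme,
    all_vs_all_self_search,
    reciprocal_best_pairs,
    search_against_genome,
)
from .io import IsogroupMap, PipelineConfig, SequenceRecord

__all__ = [
    "PairLabel",
    "CandidatePair",
    "GenomeAnchor",
    "ParalogPair",
    "WorkflowSummary",
    "collapse_isogroups",
    "filter_candidate_pairs",
    "anchor_transcripts",
    "assign_chromosome",
    "classify_pair",
    "homeology_concordance",
    "run_workflow",
]


class PairLabel(str, Enum):
    ALLELIC = "ALLELIC"
    LGD = "LGD"
    WGD = "WGD"
    UNASSIGNED = "UNASSIGNED"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class CandidatePair:
    """A reciprocal-best-hit pair with its pairing-alignment statistics."""

    id_a: str
    id_b: str
    percent_id: float
    align_length: int
    evalue: float

    def __post_init__(self) -> None:
        if self.id_a >= self.id_b:
            raise ValueError("pair ids must be in canonical order (id_a < id_b)")
        if not (0 < self.percent_id <= 100):
            raise ValueError("percent_id must lie in (0, 100]")


@dataclass(frozen=True)
class GenomeAnchor:
    """Best genome placement of a transcript: contig, forward-strand
    1-based inclusive interval, strand, alignment score, and (optionally)
    the chromosome the contig maps to."""

    transcript_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    score: int
    chromosome: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError("anchor interval must satisfy 1 <= start <= end")


@dataclass
class ParalogPair:
    pair: CandidatePair
    anchor_a: GenomeAnchor | None
    anchor_b: GenomeAnchor | None
    label: PairLabel
    evidence: str


@dataclass
class WorkflowSummary:
    n_isotigs_in: int = 0
    n_after_collapse: int = 0
    n_candidate_pairs: int = 0
    n_allelic: int = 0
    n_retained: int = 0
    n_chromosome_assigned: int = 0
    n_wgd: int = 0
    n_lgd: int = 0
    n_ambiguous: int = 0


def collapse_isogroups(
    seqs: list[SequenceRecord], isogroup_map: IsogroupMap
) -> list[SequenceRecord]:
    """Keep only the longest isotig per isogroup (ties: smaller id).

    Sequences absent from the map count as singleton isogroups.
    """
    best: dict[str, SequenceRecord] = {}
    for seq in seqs:
        group = isogroup_map.group_of(seq.id)
        cur = best.get(group)
        if cur is None or len(seq) > len(cur) or (
            len(seq) == len(cur) and seq.id < cur.id
        ):
            best[group] = seq
    kept_ids = {s.id for s in best.values()}
    return [s for s in seqs if s.id in kept_ids]


def filter_candidate_pairs(
    pairs: list[CandidatePair], min_len: int = 300, min_id: float = 80.0
) -> list[CandidatePair]:
    """Keep pairs with align_length >= min_len (inclusive) and
    percent_id > min_id (strict)."""
    return [
        p for p in pairs if p.align_length >= min_len and p.percent_id > min_id
    ]


def anchor_transcripts(
    transcripts: list[SequenceRecord],
    genome: list[SequenceRecord] | None = None,
    hits: list[AlignmentHit] | None = None,
    scoring: ScoringScheme | None = None,
    kmer: int = 11,
    evalue_threshold: float = 1e-20,
    score_window: float = 0.10,
    linkage_map: dict[str, str] | None = None,
) -> dict[str, list[GenomeAnchor]]:
    """Anchor transcripts to genome contigs.

    The genome may be given as contig FASTA records (internal seeded
    search) or as precomputed tabular hits. Per transcript the
    best-scoring hit is kept together with any hit within *score_window*
    (10%) of the best score; minus-strand hits are normalized to
    forward-strand intervals. Unanchored transcripts map to empty lists.
    """
    if (genome is None) == (hits is None):
        raise ValueError("provide exactly one of genome or hits")
    scoring = scoring or ScoringScheme()
    per_transcript: dict[str, list[AlignmentHit]] = {t.id: [] for t in transcripts}
    if genome is not None:
        per_transcript = search_against_genome(
            transcripts, genome, scoring, kmer=kmer,
            evalue_threshold=evalue_threshold,
        )
    else:
        for h in hits:
            if h.query_id in per_transcript:
                per_transcript[h.query_id].append(h)
    anchors: dict[str, list[GenomeAnchor]] = {}
    for tid, t_hits in per_transcript.items():
        if not t_hits:
            anchors[tid] = []
            continue
        best_score = max(h.raw_score for h in t_hits)
        kept = [h for h in t_hits if h.raw_score >= (1.0 - score_window) * best_score]
        kept.sort(key=lambda h: (-h.raw_score, h.subject_id, h.subject_interval))
        anchors[tid] = [
            GenomeAnchor(
                transcript_id=tid,
                contig_id=h.subject_id,
                start=h.subject_interval[0],
                end=h.subject_interval[1],
                strand="-" if h.is_minus_strand else "+",
                score=h.raw_score,
                chromosome=(linkage_map or {}).get(h.subject_id),
            )
            for h in kept
        ]
    return anchors


def assign_chromosome(
    anchor: GenomeAnchor, linkage_map: dict[str, str]
) -> str | None:
    """Chromosome of the anchor's contig, or ``None`` when unmapped."""
    return linkage_map.get(anchor.contig_id)


def _gap_between(a: GenomeAnchor, b: GenomeAnchor) -> int:
    """Gap in bp between nearest interval ends; negative means overlap."""
    if a.start > b.start:
        a, b = b, a
    return b.start - a.end - 1


def classify_pair(
    pair: CandidatePair,
    anchors_a: list[GenomeAnchor],
    anchors_b: list[GenomeAnchor],
    linkage_map: dict[str, str] | None = None,
    annotation: dict[str, str] | None = None,
    lgd_min_distance: int = 5000,
) -> ParalogPair:
    """Apply the anchoring rules in order and label the pair.

    Rule order: (1) any anchor combination on one contig with overlapping
    intervals -> ALLELIC; then, on top-scoring anchors: (2) same contig,
    gap > lgd_min_distance (and, when an annotation table is supplied,
    distinct best annotation ids) -> LGD; (3) same contig, gap <=
    lgd_min_distance -> AMBIGUOUS; (4) different contigs -> compare
    chromosomes via the linkage map (same -> LGD, different -> WGD,
    unmapped -> UNASSIGNED); (5) missing anchors -> UNASSIGNED.
    """
    linkage_map = linkage_map or {}
    if not anchors_a or not anchors_b:
        missing = [
            tid
            for tid, anc in ((pair.id_a, anchors_a), (pair.id_b, anchors_b))
            if not anc
        ]
        return ParalogPair(
            pair, anchors_a[0] if anchors_a else None,
            anchors_b[0] if anchors_b else None,
            PairLabel.UNASSIGNED,
            f"unanchored transcript(s): {','.join(missing)}",
        )
    # rule 1: any same-contig overlapping combination
    for aa in anchors_a:
        for ab in anchors_b:
            if aa.contig_id == ab.contig_id and _gap_between(aa, ab) < 0:
                return ParalogPair(
                    pair, aa, ab, PairLabel.ALLELIC,
                    f"overlapping anchors on {aa.contig_id} "
                    f"[{aa.start},{aa.end}] vs [{ab.start},{ab.end}]",
                )
    top_a, top_b = anchors_a[0], anchors_b[0]
    conflict_notes = []
    for tid, anc in ((pair.id_a, anchors_a), (pair.id_b, anchors_b)):
        chroms = {
            linkage_map.get(x.contig_id)
            for x in anc
            if linkage_map.get(x.contig_id) is not None
        }
        if len(chroms) > 1:
            conflict_notes.append(
                f"{tid} multi-anchors span chromosomes {sorted(chroms)}; "
                "top-scoring anchor used"
            )
    suffix = ("; " + "; ".join(conflict_notes)) if conflict_notes else ""
    if top_a.contig_id == top_b.contig_id:
        gap = _gap_between(top_a, top_b)
        if gap > lgd_min_distance:
            if annotation is not None:
                acc_a = annotation.get(pair.id_a)
                acc_b = annotation.get(pair.id_b)
                if acc_a is not None and acc_a == acc_b:
                    return ParalogPair(
                        pair, top_a, top_b, PairLabel.AMBIGUOUS,
                        f"same contig {top_a.contig_id}, gap {gap} bp > "
                        f"{lgd_min_distance} but identical annotation {acc_a}"
                        + suffix,
                    )
            return ParalogPair(
                pair, top_a, top_b, PairLabel.LGD,
                f"same contig {top_a.contig_id}, gap {gap} bp > {lgd_min_distance}"
                + suffix,
            )
        return ParalogPair(
            pair, top_a, top_b, PairLabel.AMBIGUOUS,
            f"same contig {top_a.contig_id}, non-overlapping, gap {gap} bp <= "
            f"{lgd_min_distance}" + suffix,
        )
    chrom_a = assign_chromosome(top_a, linkage_map)
    chrom_b = assign_chromosome(top_b, linkage_map)
    if chrom_a is None or chrom_b is None:
        return ParalogPair(
            pair, top_a, top_b, PairLabel.UNASSIGNED,
            f"contig(s) without chromosome assignment: "
            f"{top_a.contig_id}->{chrom_a}, {top_b.contig_id}->{chrom_b}" + suffix,
        )
    if chrom_a == chrom_b:
        return ParalogPair(
            pair, top_a, top_b, PairLabel.LGD,
            f"different contigs on the same chromosome {chrom_a}" + suffix,
        )
    return ParalogPair(
        pair, top_a, top_b, PairLabel.WGD,
        f"different chromosomes {chrom_a} vs {chrom_b}" + suffix,
    )


def homeology_concordance(
    wgd_pairs: list[ParalogPair],
    known_chromosome_pairs: set[frozenset[str]],
) -> dict:
    """Match WGD pairs' chromosome pairings against a reference set of
    homeologous chromosome pairs (unordered)."""
    counts: Counter[frozenset[str]] = Counter()
    for p in wgd_pairs:
        if p.label is not PairLabel.WGD:
            raise ValueError("homeology concordance expects WGD-labeled pairs")
        if p.anchor_a is None or p.anchor_b is None:
            raise ValueError("WGD pair lacks anchors")
        counts[frozenset({p.anchor_a.chromosome, p.anchor_b.chromosome})] += 1
    n_total = sum(counts.values())
    n_matched = sum(
        n for pair, n in counts.items() if pair in known_chromosome_pairs
    )
    return {
        "n_matched": n_matched,
        "n_total": n_total,
        "fraction": (n_matched / n_total) if n_total else None,
        "per_chromosome_pair": {
            "_".join(sorted(pair)): n for pair, n in sorted(
                counts.items(), key=lambda kv: "_".join(sorted(kv[0]))
            )
        },
    }


def run_workflow(
    transcriptome: list[SequenceRecord],
    isogroup_map: IsogroupMap,
    genome: list[SequenceRecord] | None,
    linkage_map: dict[str, str] | None,
    config: PipelineConfig | None = None,
    annotation: dict[str, str] | None = None,
    self_hits: list[AlignmentHit] | None = None,
    genome_hits: list[AlignmentHit] | None = None,
) -> tuple[list[ParalogPair], WorkflowSummary]:
    """Execute the four workflow steps in order; deterministic given the
    inputs and config. Precomputed tabular hits may replace either
    internal search."""
    config = config or PipelineConfig()
    scoring = ScoringScheme(
        match=config.match,
        mismatch=config.mismatch,
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
        karlin_lambda=config.karlin_lambda,
        karlin_k=config.karlin_k,
    )
    summary = WorkflowSummary(n_isotigs_in=len(transcriptome))
    collapsed = collapse_isogroups(transcriptome, isogroup_map)
    summary.n_after_collapse = len(collapsed)
    if self_hits is None:
        self_hits = all_vs_all_self_search(
            collapsed, scoring, kmer=config.kmer,
            evalue_threshold=config.evalue_threshold,
        )
    elif config.refilter_external_hits:
        self_hits = [h for h in self_hits if h.evalue <= config.evalue_threshold]
    rbh = reciprocal_best_pairs(self_hits)
    candidates = [
        CandidatePair(
            id_a=a, id_b=b, percent_id=h.percent_id,
            align_length=h.align_length, evalue=h.evalue,
        )
        for a, b, h in rbh
    ]
    candidates = filter_candidate_pairs(
        candidates, config.min_alignment_length, config.min_percent_id
    )
    summary.n_candidate_pairs = len(candidates)
    paired_ids = sorted({i for p in candidates for i in (p.id_a, p.id_b)})
    by_id = {s.id: s for s in collapsed}
    to_anchor = [by_id[i] for i in paired_ids]
    anchors = anchor_transcripts(
        to_anchor,
        genome=genome,
        hits=genome_hits,
        scoring=scoring,
        kmer=config.kmer,
        evalue_threshold=config.evalue_threshold,
        score_window=config.anchor_score_window,
        linkage_map=linkage_map,
    )
    results: list[ParalogPair] = []
    for cand in candidates:
        pp = classify_pair(
            cand,
            anchors.get(cand.id_a, []),
            anchors.get(cand.id_b, []),
            linkage_map=linkage_map,
            annotation=annotation,
            lgd_min_distance=config.lgd_min_distance,
        )
        results.append(pp)
        if pp.label is PairLabel.ALLELIC:
            summary.n_allelic += 1
        elif pp.label is PairLabel.WGD:
            summary.n_wgd += 1
        elif pp.label is PairLabel.LGD:
            summary.n_lgd += 1
        elif pp.label is PairLabel.AMBIGUOUS:
            summary.n_ambiguous += 1
    summary.n_retained = summary.n_candidate_pairs - summary.n_allelic
    linkage_map = linkage_map or {}
    summary.n_chromosome_assigned = sum(
        1
        for pp in results
        if pp.label is not PairLabel.ALLELIC
        and pp.anchor_a is not None
        and pp.anchor_b is not None
        and linkage_map.get(pp.anchor_a.contig_id) is not None
        and linkage_map.get(pp.anchor_b.contig_id) is not None
    )
    return results, summary
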