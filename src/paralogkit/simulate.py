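"""Synthetic genomes and transcriptomes with planted duplication events.

The generator emulates the situation the duplicate-gene workflow is
built for: a transcriptome from a lineage that went through an ancestral
whole-genome duplication (every chromosome has a homeolog carrying a
diverged copy of every gene) followed by younger local (tandem) gene
duplications, overlaid with the assembly-level noise the workflow must
see through — isogroup-clustered isoforms and alleles, alleles the
assembler failed to cluster, and duplicate copies drifting out of
protein-coding function.

Divergence within planted pairs is driven by a codon-level mutator that
applies synonymous and nonsynonymous substitutions as independent
Poisson processes over Nei-Gojobori-defined site counts, so that planted
pairs have known expected Ks and Ka. Defaults target the divergence
regime the workflow's thresholds were designed around: whole-genome
duplicates at Ks 0.40 and tandem duplicates at Ks 0.23 (both well inside
the 80%-identity candidate filter), tandem copies 6-50 kb from their
parent (beyond the 5 kb local-duplication cutoff), and alleles at 0.5%
divergence (overlapping genome anchors).

Transcripts are emitted unspliced with transcribed UTR flanks: each
transcript is an exact substring of its contig covering the coding
region plus per-copy 5'/3' UTRs drawn from the flanking sequence, so
genome anchoring is exact by construction while ORF coverage and base
composition vary between genes the way they do in real transcriptomes
(each ancestral gene draws its own GC content). A truth table records
every planted event for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import IsogroupMap, SequenceRecord, write_fasta
from .kaks import CODON_TO_AA, SENSE_CODONS, synonymous_site_fraction

__all__ = [
    "SimulationConfig",
    "GeneCopy",
    "SyntheticDataset",
    "simulate",
    "simulate_ancestral_genes",
    "apply_wgd",
    "apply_lgds",
    "mutate_codon_sequence",
    "add_transcript_variants",
    "emit_dataset",
    "scoreable_pairs",
]

_BASES = "ACGT"
_STOPS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class SimulationConfig:
    """Study conditions for the planted-duplication simulation."""

    n_ancestral_genes: int = 120
    gene_length_range: tuple[int, int] = (200, 400)  # codons
    n_chromosomes: int = 4
    contigs_per_chromosome: int = 2
    wgd: bool = True
    target_ks_wgd: float = 0.40
    target_ks_lgd: float = 0.23
    target_ka_ks: float = 0.21
    lgd_fraction: float = 0.15
    lgd_gap_range: tuple[int, int] = (6000, 50000)
    allelic_fraction: float = 0.20
    allelic_divergence: float = 0.005
    allelic_unclustered_fraction: float = 0.5
    isoform_fraction: float = 0.25
    noncoding_drift_fraction: float = 0.15
    annotation_inheritance: float = 0.5
    noncoding_transcript_fraction: float = 0.5
    noncoding_length_range: tuple[int, int] = (400, 1200)
    go_terms_per_gene: tuple[int, int] = (2, 6)
    n_go_terms_pool: int = 300
    go_turnover: float = 0.10
    min_gene_spacing: int = 10000
    gc_range: tuple[float, float] = (0.43, 0.55)
    utr5_range: tuple[int, int] = (30, 300)
    utr3_range: tuple[int, int] = (50, 600)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "lgd_fraction",
            "allelic_fraction",
            "allelic_unclustered_fraction",
            "isoform_fraction",
            "noncoding_drift_fraction",
            "annotation_inheritance",
            "go_turnover",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.target_ks_wgd <= 0 or self.target_ks_lgd <= 0:
            raise ValueError("target Ks values must be positive")
        if self.lgd_gap_range[0] > self.lgd_gap_range[1]:
            raise ValueError("invalid lgd_gap_range")
        if self.utr5_range[1] + self.utr3_range[1] >= self.lgd_gap_range[0]:
            raise ValueError("UTRs must not be able to swallow the tandem gap")


@dataclass
class GeneCopy:
    """One gene copy: coding sequence plus its eventual contig placement."""

    id: str
    sequence: str  # coding region, frame +1, stop-free until drifted
    chromosome: str
    origin: str  # "ancestral" | "wgd" | "lgd"
    parent: str | None = None
    accession: str | None = None
    go_terms: set[str] = field(default_factory=set)
    coding: bool = True
    lgd_gap: int | None = None  # planted transcript-to-transcript gap
    expected_ks: float = 0.0
    expected_ka: float = 0.0
    realized_syn: int = 0
    realized_non: int = 0
    utr5: int = 0
    utr3: int = 0


def _random_codon_weights(gc_content: float) -> np.ndarray:
    """Sense-codon sampling weights from independent base probabilities
    with the requested GC content (stop codons excluded)."""
    p = {
        "G": gc_content / 2.0,
        "C": gc_content / 2.0,
        "A": (1.0 - gc_content) / 2.0,
        "T": (1.0 - gc_content) / 2.0,
    }
    w = np.array(
        [p[c[0]] * p[c[1]] * p[c[2]] for c in SENSE_CODONS], dtype=float
    )
    return w / w.sum()


def _random_gene_sequence(
    rng: np.random.Generator, n_codons: int, weights: np.ndarray
) -> str:
    idx = rng.choice(len(SENSE_CODONS), size=n_codons, p=weights)
    return "".join(SENSE_CODONS[i] for i in idx)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=n)])


def mutate_codon_sequence(
    seq: str,
    expected_ks: float,
    expected_ka: float,
    rng: np.random.Generator | int,
) -> tuple[str, int, int]:
    """Apply Poisson numbers of synonymous and nonsynonymous single-
    nucleotide substitutions to a stop-free codon sequence.

    Event counts are drawn with expectations expected_ks*S and
    expected_ka*N (Nei-Gojobori site counts of the input); events are
    applied sequentially at uniformly drawn (position, alternative)
    candidates of the required class, redrawing any substitution that
    would create a stop codon. Returns the mutated sequence and the
    realized (synonymous, nonsynonymous) counts.
    """
    if expected_ks < 0 or expected_ka < 0:
        raise ValueError("expected divergence values must be non-negative")
    if len(seq) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if any(c in _STOPS for c in codons):
        raise ValueError("input must be stop-free in frame +1")
    S = sum(synonymous_site_fraction(c) for c in codons)
    N = 3.0 * len(codons) - S
    n_syn = int(rng.poisson(expected_ks * S))
    n_non = int(rng.poisson(expected_ka * N))
    events = ["S"] * n_syn + ["N"] * n_non
    rng.shuffle(events)
    realized = {"S": 0, "N": 0}
    for kind in events:
        for _ in range(10000):
            ci = int(rng.integers(len(codons)))
            pos = int(rng.integers(3))
            alt = _BASES[int(rng.integers(4))]
            codon = codons[ci]
            if alt == codon[pos]:
                continue
            new = codon[:pos] + alt + codon[pos + 1 :]
            if new in _STOPS:
                continue
            syn = CODON_TO_AA[new] == CODON_TO_AA[codon]
            if (kind == "S") == syn:
                codons[ci] = new
                realized[kind] += 1
                break
        else:  # pragma: no cover - pathological sequences only
            raise RuntimeError("could not place substitution")
    return "".join(codons), realized["S"], realized["N"]


def _mutate_nucleotides(
    rng: np.random.Generator, seq: str, rate: float
) -> str:
    """Uniform per-site substitution at the given rate (allele engine)."""
    chars = list(seq)
    n_sites = rng.binomial(len(chars), rate)
    for i in rng.choice(len(chars), size=n_sites, replace=False):
        alts = [b for b in _BASES if b != chars[i]]
        chars[i] = alts[int(rng.integers(3))]
    return "".join(chars)


def _disrupt_coding(rng: np.random.Generator, seq: str) -> str:
    """Coding->noncoding drift: shuffle codons outside a preserved 40%
    anchor region, pepper the outside segments with frameshifting
    single-nucleotide deletions (one per ~20 codons, plus one at each
    anchor boundary), and let the outside sequence decay neutrally
    toward background composition (30% of sites resampled uniformly).

    A single frameshift is invisible to a six-frame ORF scanner — the
    downstream sequence simply reads in a shifted frame — so the
    accumulated indels and neutral substitutions of real pseudogenes
    are what actually destroy open-reading-frame structure.
    """
    codons = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    n = len(codons)
    anchor_start = int(round(0.3 * n))
    anchor_end = min(n, anchor_start + max(1, int(round(0.4 * n))))
    before = codons[:anchor_start]
    after = codons[anchor_end:]
    rng.shuffle(before)
    rng.shuffle(after)

    def decay(block: list[str]) -> str:
        out = "".join(block)
        if not out:
            return out
        chars = list(out)
        k = rng.binomial(len(chars), 0.3)
        for i in rng.choice(len(chars), size=k, replace=False):
            chars[i] = _BASES[int(rng.integers(4))]
        out = "".join(chars)
        cuts = [0] + list(range(60, len(out), 60))  # every ~20 codons
        kept, prev = [], 0
        for c in cuts:
            j = min(c + (int(rng.integers(0, 3)) if c else 0), len(out) - 1)
            kept.append(out[prev:j])
            prev = j + 1
        kept.append(out[prev:])
        return "".join(kept)

    return (
        decay(before)
        + "".join(codons[anchor_start:anchor_end])
        + decay(after)
    )


@dataclass
class SyntheticDataset:
    """Complete simulation state: genome, transcriptome, maps, truth."""

    config: SimulationConfig
    genes: list[GeneCopy]
    gene_order: dict[str, list[str]]  # chromosome -> gene ids in order
    homeolog_pairs: set[frozenset]
    contigs: list[SequenceRecord] = field(default_factory=list)
    linkage_map: dict[str, str] = field(default_factory=dict)
    gene_coords: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    tx_coords: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    spacer_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    transcripts: list[SequenceRecord] = field(default_factory=list)
    isogroup_map: IsogroupMap = field(default_factory=IsogroupMap)
    go_map: dict[str, set[str]] = field(default_factory=dict)
    annotation: dict[str, str] = field(default_factory=dict)
    truth_rows: list[dict] = field(default_factory=list)

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.truth_rows)

    def gene_by_id(self) -> dict[str, GeneCopy]:
        return {g.id: g for g in self.genes}

    def transcript_of(self, gene_id: str) -> str:
        return f"t{gene_id}"


def simulate_ancestral_genes(
    config: SimulationConfig, rng: np.random.Generator
) -> SyntheticDataset:
    """Place stop-free random codon genes on proto-chromosomes, each gene
    drawing its own GC content from ``config.gc_range``."""
    genes: list[GeneCopy] = []
    order: dict[str, list[str]] = {
        f"chr{c + 1:02d}": [] for c in range(config.n_chromosomes)
    }
    chrom_names = sorted(order)
    lo, hi = config.gene_length_range
    for i in range(config.n_ancestral_genes):
        chrom = chrom_names[i % len(chrom_names)]
        n_codons = int(rng.integers(lo, hi + 1))
        gc = float(rng.uniform(*config.gc_range))
        gene = GeneCopy(
            id=f"g{i + 1:04d}",
            sequence=_random_gene_sequence(
                rng, n_codons, _random_codon_weights(gc)
            ),
            chromosome=chrom,
            origin="ancestral",
            accession=f"P{i + 1:05d}",
        )
        genes.append(gene)
        order[chrom].append(gene.id)
    return SyntheticDataset(
        config=config, genes=genes, gene_order=order, homeolog_pairs=set()
    )


def _copy_accession(
    parent: GeneCopy, copy_id: str, config: SimulationConfig,
    rng: np.random.Generator,
) -> str | None:
    """Best-hit accession for a duplicate copy: inherited from the parent
    with probability ``annotation_inheritance``, otherwise a distinct
    accession (a diverged copy often retrieves a different best hit from
    a redundant protein database)."""
    if parent.accession is None:
        return None
    if rng.random() < config.annotation_inheritance:
        return parent.accession
    return f"Q_{copy_id}"


def apply_wgd(state: SyntheticDataset, rng: np.random.Generator) -> None:
    """Duplicate every chromosome to a homeolog; every gene gains a
    diverged partner (expected Ks/Ka at the WGD targets) on it."""
    config = state.config
    by_id = state.gene_by_id()
    new_order: dict[str, list[str]] = {}
    new_genes: list[GeneCopy] = []
    for chrom in sorted(state.gene_order):
        homeolog = f"{chrom}h"
        state.homeolog_pairs.add(frozenset({chrom, homeolog}))
        new_order[homeolog] = []
        for gid in state.gene_order[chrom]:
            gene = by_id[gid]
            exp_ka = config.target_ks_wgd * config.target_ka_ks
            seq, r_syn, r_non = mutate_codon_sequence(
                gene.sequence, config.target_ks_wgd, exp_ka, rng
            )
            copy_id = f"{gid}w"
            copy = GeneCopy(
                id=copy_id,
                sequence=seq,
                chromosome=homeolog,
                origin="wgd",
                parent=gid,
                accession=_copy_accession(gene, copy_id, config, rng),
                expected_ks=config.target_ks_wgd,
                expected_ka=exp_ka,
                realized_syn=r_syn,
                realized_non=r_non,
            )
            new_genes.append(copy)
            new_order[homeolog].append(copy.id)
    state.genes.extend(new_genes)
    state.gene_order.update(new_order)


def apply_lgds(state: SyntheticDataset, rng: np.random.Generator) -> None:
    """Give a sampled fraction of genes a tandem (same-contig) copy at a
    transcript-to-transcript gap drawn from the configured range."""
    config = state.config
    by_id = state.gene_by_id()
    all_ids = sorted(by_id)
    n_lgd = int(round(config.lgd_fraction * len(all_ids)))
    chosen = sorted(
        all_ids[int(i)]
        for i in rng.choice(len(all_ids), size=n_lgd, replace=False)
    )
    for gid in chosen:
        gene = by_id[gid]
        exp_ka = config.target_ks_lgd * config.target_ka_ks
        seq, r_syn, r_non = mutate_codon_sequence(
            gene.sequence, config.target_ks_lgd, exp_ka, rng
        )
        gap = int(rng.integers(config.lgd_gap_range[0], config.lgd_gap_range[1] + 1))
        copy_id = f"{gid}l"
        copy = GeneCopy(
            id=copy_id,
            sequence=seq,
            chromosome=gene.chromosome,
            origin="lgd",
            parent=gid,
            accession=_copy_accession(gene, copy_id, config, rng),
            expected_ks=config.target_ks_lgd,
            expected_ka=exp_ka,
            realized_syn=r_syn,
            realized_non=r_non,
            lgd_gap=gap,
        )
        state.genes.append(copy)
        # tandem: placed immediately after its parent on the chromosome
        chrom_order = state.gene_order[gene.chromosome]
        chrom_order.insert(chrom_order.index(gid) + 1, copy.id)


def _apply_noncoding_drift(
    state: SyntheticDataset, rng: np.random.Generator
) -> None:
    """Frame-disrupt a sampled fraction of duplicate copies; they lose
    their annotation accession and are marked noncoding in truth."""
    config = state.config
    copies = sorted(g.id for g in state.genes if g.origin in ("wgd", "lgd"))
    n_drift = int(round(config.noncoding_drift_fraction * len(copies)))
    if not n_drift:
        return
    chosen = {
        copies[int(i)]
        for i in rng.choice(len(copies), size=n_drift, replace=False)
    }
    for gene in state.genes:
        if gene.id in chosen:
            gene.sequence = _disrupt_coding(rng, gene.sequence)
            gene.coding = False
            gene.accession = None


def _assemble_genome(state: SyntheticDataset, rng: np.random.Generator) -> None:
    """Concatenate spacers and gene copies into contigs, recording exact
    coding and transcript coordinates and the contig->chromosome linkage.

    Each copy's transcript covers its coding region plus 5'/3' UTRs cut
    from the flanking spacer; for tandem copies the spacer to the parent
    is sized so the planted transcript-to-transcript gap is exact.
    """
    config = state.config
    by_id = state.gene_by_id()
    for gene in state.genes:
        gene.utr5 = int(rng.integers(*config.utr5_range))
        gene.utr3 = int(rng.integers(*config.utr3_range))
    for chrom in sorted(state.gene_order):
        gids = state.gene_order[chrom]
        # split into contigs without separating a tandem copy from its parent
        units: list[list[str]] = []
        for gid in gids:
            if by_id[gid].origin == "lgd" and units and by_id[gid].parent in units[-1]:
                units[-1].append(gid)
            else:
                units.append([gid])
        n_contigs = min(config.contigs_per_chromosome, len(units)) or 1
        per = -(-len(units) // n_contigs)
        for ci in range(n_contigs):
            chunk = units[ci * per : (ci + 1) * per]
            if not chunk:
                continue
            contig_id = f"{chrom}_c{ci + 1}"
            parts: list[str] = []
            pos = 0
            lead = int(rng.integers(2000, 5000))
            parts.append(_random_dna(rng, lead))
            pos += lead
            for unit in chunk:
                for idx, gid in enumerate(unit):
                    gene = by_id[gid]
                    if gene.origin == "lgd" and gene.parent in unit:
                        parent = by_id[gene.parent]
                        # spacer sized so the transcript gap equals the
                        # planted gap after both UTRs are cut from it
                        spacer = gene.lgd_gap + parent.utr3 + gene.utr5
                        parts.append(_random_dna(rng, spacer))
                        pos += spacer
                    start = pos + 1
                    parts.append(gene.sequence)
                    pos += len(gene.sequence)
                    state.gene_coords[gid] = (contig_id, start, pos)
                    state.tx_coords[gid] = (
                        contig_id, start - gene.utr5, pos + gene.utr3
                    )
                    next_is_tandem = (
                        idx + 1 < len(unit)
                        and by_id[unit[idx + 1]].origin == "lgd"
                        and by_id[unit[idx + 1]].parent == gid
                    )
                    if next_is_tandem:
                        continue  # the tandem copy brings its own spacer
                    spacer = config.min_gene_spacing + int(rng.integers(0, 4000))
                    # the spacer's middle (clear of both flanking UTRs) is
                    # available as a source of noncoding transcripts
                    state.spacer_intervals.append(
                        (contig_id, pos + 700, pos + spacer - 400)
                    )
                    parts.append(_random_dna(rng, spacer))
                    pos += spacer
            state.contigs.append(
                SequenceRecord(id=contig_id, residues="".join(parts))
            )
            state.linkage_map[contig_id] = chrom


def _add_noncoding_transcripts(
    state: SyntheticDataset, rng: np.random.Generator
) -> None:
    """Emit standalone noncoding transcripts carved from intergenic
    sequence (transcribed spacer, the desk-scale analogue of the large
    unannotated fraction of a real transcriptome assembly). Each forms
    its own singleton isogroup with no annotation hit and no GO terms."""
    config = state.config
    n_nc = int(round(config.noncoding_transcript_fraction * config.n_ancestral_genes))
    if not n_nc or not state.spacer_intervals:
        return
    iso_map = dict(state.isogroup_map.items())
    lo, hi = config.noncoding_length_range
    intervals = sorted(state.spacer_intervals)
    for i in range(n_nc):
        contig_id, s0, s1 = intervals[int(rng.integers(len(intervals)))]
        length = int(rng.integers(lo, hi + 1))
        if s1 - s0 <= length:
            continue
        start = s0 + int(rng.integers(0, s1 - s0 - length))
        contig = next(c for c in state.contigs if c.id == contig_id)
        tid = f"tnc{i + 1:04d}"
        state.transcripts.append(
            SequenceRecord(id=tid, residues=contig.residues[start : start + length])
        )
        iso_map[tid] = f"ig_nc{i + 1:04d}"
        state.tx_coords[tid] = (contig_id, start + 1, start + length)
        state.truth_rows.append(
            {
                "id_a": "",
                "id_b": tid,
                "event": "SINGLETON",
                "chromosome_a": "",
                "chromosome_b": state.linkage_map.get(contig_id, ""),
                "contig": contig_id,
                "gap": -1,
                "expected_ks": 0.0,
                "expected_ka": 0.0,
                "realized_syn": -1,
                "realized_non": -1,
                "coding_a": False,
                "coding_b": False,
                "clustered": False,
            }
        )
    state.isogroup_map = IsogroupMap(iso_map)


def _transcript_sequence(state: SyntheticDataset, gene_id: str) -> str:
    contig_id, start, end = state.tx_coords[gene_id]
    contig = next(c for c in state.contigs if c.id == contig_id)
    return contig.residues[start - 1 : end]


def add_transcript_variants(
    state: SyntheticDataset, rng: np.random.Generator
) -> None:
    """Emit one transcript per gene copy plus sampled allelic variants
    (some left unclustered, emulating assembly failures) and in-frame
    exon-skipping isoforms sharing the parent's isogroup."""
    config = state.config
    by_id = state.gene_by_id()
    iso_map: dict[str, str] = dict(state.isogroup_map.items())
    for gene in sorted(state.genes, key=lambda g: g.id):
        tid = state.transcript_of(gene.id)
        group = f"ig_{gene.id}"
        tx_seq = _transcript_sequence(state, gene.id)
        state.transcripts.append(SequenceRecord(id=tid, residues=tx_seq))
        iso_map[tid] = group
        state.go_map[tid] = set(gene.go_terms)
        if gene.accession is not None:
            state.annotation[tid] = gene.accession
        state.truth_rows.append(
            {
                "id_a": state.transcript_of(gene.parent) if gene.parent else "",
                "id_b": tid,
                "event": gene.origin.upper() if gene.parent else "SINGLETON",
                "chromosome_a": (
                    by_id[gene.parent].chromosome if gene.parent else ""
                ),
                "chromosome_b": gene.chromosome,
                "contig": state.gene_coords.get(gene.id, ("",))[0],
                "gap": gene.lgd_gap if gene.lgd_gap is not None else -1,
                "expected_ks": gene.expected_ks,
                "expected_ka": gene.expected_ka,
                "realized_syn": gene.realized_syn,
                "realized_non": gene.realized_non,
                "coding_a": by_id[gene.parent].coding if gene.parent else True,
                "coding_b": gene.coding,
                "clustered": False,
            }
        )
        if rng.random() < config.allelic_fraction:
            allele_id = f"{tid}a"
            allele_seq = _mutate_nucleotides(
                rng, tx_seq, config.allelic_divergence
            )
            clustered = rng.random() >= config.allelic_unclustered_fraction
            state.transcripts.append(
                SequenceRecord(id=allele_id, residues=allele_seq)
            )
            iso_map[allele_id] = group if clustered else f"ig_{gene.id}_al"
            state.go_map[allele_id] = set(gene.go_terms)
            if gene.accession is not None:
                state.annotation[allele_id] = gene.accession
            state.truth_rows.append(
                {
                    "id_a": tid,
                    "id_b": allele_id,
                    "event": "ALLELIC",
                    "chromosome_a": gene.chromosome,
                    "chromosome_b": gene.chromosome,
                    "contig": state.gene_coords.get(gene.id, ("",))[0],
                    "gap": 0,
                    "expected_ks": 0.0,
                    "expected_ka": 0.0,
                    "realized_syn": -1,
                    "realized_non": -1,
                    "coding_a": gene.coding,
                    "coding_b": gene.coding,
                    "clustered": clustered,
                }
            )
        if rng.random() < config.isoform_fraction:
            iso_id = f"{tid}i"
            # in-frame internal deletion confined to the coding region
            orf_len = len(gene.sequence) - (len(gene.sequence) % 3)
            n = orf_len // 3
            del_len = int(rng.integers(max(1, n // 10), max(2, int(0.3 * n))))
            del_start = int(rng.integers(1, max(2, n - del_len - 1)))
            off = gene.utr5
            iso_seq = (
                tx_seq[: off + 3 * del_start]
                + tx_seq[off + 3 * (del_start + del_len) :]
            )
            state.transcripts.append(SequenceRecord(id=iso_id, residues=iso_seq))
            iso_map[iso_id] = group
            state.go_map[iso_id] = set(gene.go_terms)
            if gene.accession is not None:
                state.annotation[iso_id] = gene.accession
            state.truth_rows.append(
                {
                    "id_a": tid,
                    "id_b": iso_id,
                    "event": "ISOFORM",
                    "chromosome_a": gene.chromosome,
                    "chromosome_b": gene.chromosome,
                    "contig": state.gene_coords.get(gene.id, ("",))[0],
                    "gap": 0,
                    "expected_ks": 0.0,
                    "expected_ka": 0.0,
                    "realized_syn": -1,
                    "realized_non": -1,
                    "coding_a": gene.coding,
                    "coding_b": gene.coding,
                    "clustered": True,
                }
            )
    state.isogroup_map = IsogroupMap(iso_map)


def _assign_go_terms(state: SyntheticDataset, rng: np.random.Generator) -> None:
    config = state.config
    pool = [f"GO:{i + 1:07d}" for i in range(config.n_go_terms_pool)]
    by_id = state.gene_by_id()
    lo, hi = config.go_terms_per_gene
    for gene in sorted(state.genes, key=lambda g: g.id):
        if gene.origin == "ancestral":
            k = int(rng.integers(lo, hi + 1))
            idx = rng.choice(len(pool), size=k, replace=False)
            gene.go_terms = {pool[int(i)] for i in idx}
    for gene in sorted(state.genes, key=lambda g: g.id):
        if gene.origin != "ancestral":
            inherited = set(by_id[gene.parent].go_terms)
            turned: set[str] = set()
            for term in sorted(inherited):
                if rng.random() < config.go_turnover:
                    turned.add(pool[int(rng.integers(len(pool)))])
                else:
                    turned.add(term)
            gene.go_terms = turned


def simulate(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Run the full generator; deterministic given ``config.seed``."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    state = simulate_ancestral_genes(config, rng)
    if config.wgd:
        apply_wgd(state, rng)
    apply_lgds(state, rng)
    _apply_noncoding_drift(state, rng)
    _assign_go_terms(state, rng)
    _assemble_genome(state, rng)
    _add_noncoding_transcripts(state, rng)
    add_transcript_variants(state, rng)
    return state


def emit_dataset(state: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as the plain-text files the pipeline readers
    consume; deterministic given the simulation state."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "transcripts": outdir / "transcripts.fasta",
        "isogroups": outdir / "isogroups.tsv",
        "linkage": outdir / "linkage.tsv",
        "go": outdir / "go.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.tsv",
        "homeologs": outdir / "homeolog_pairs.tsv",
    }
    write_fasta(state.contigs, paths["genome"])
    write_fasta(state.transcripts, paths["transcripts"])
    with open(paths["isogroups"], "w") as fh:
        for tid, group in sorted(state.isogroup_map.items()):
            fh.write(f"{tid}\t{group}\n")
    with open(paths["linkage"], "w") as fh:
        for contig, chrom in sorted(state.linkage_map.items()):
            fh.write(f"{contig}\t{chrom}\n")
    with open(paths["go"], "w") as fh:
        for tid in sorted(state.go_map):
            for term in sorted(state.go_map[tid]):
                fh.write(f"{tid}\t{term}\n")
    with open(paths["annotation"], "w") as fh:
        for tid, acc in sorted(state.annotation.items()):
            fh.write(f"{tid}\t{acc}\n")
    state.truth_table().to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["homeologs"], "w") as fh:
        for pair in sorted("\t".join(sorted(p)) for p in state.homeolog_pairs):
            fh.write(pair + "\n")
    return paths


def scoreable_pairs(state: SyntheticDataset) -> pd.DataFrame:
    """Planted WGD/LGD truth rows the workflow can in principle recover.

    A planted pair is scoreable when both members are still
    protein-coding and each member's nearest planted relative (smallest
    expected divergence, unclustered alleles included) is its partner in
    that pair — reciprocal-best-hit pairing cannot recover a pair whose
    member has a closer planted relative.
    """
    truth = state.truth_table()
    nearest: dict[str, tuple[float, str]] = {}

    def note(a: str, b: str, d: float) -> None:
        for x, y in ((a, b), (b, a)):
            if x not in nearest or d < nearest[x][0]:
                nearest[x] = (d, y)

    for row in state.truth_rows:
        if row["event"] in ("WGD", "LGD"):
            note(row["id_a"], row["id_b"], row["expected_ks"])
        elif row["event"] == "ALLELIC" and not row.get("clustered", False):
            note(row["id_a"], row["id_b"], state.config.allelic_divergence)
    rows = []
    for row in state.truth_rows:
        if row["event"] not in ("WGD", "LGD"):
            continue
        a, b = row["id_a"], row["id_b"]
        if not (row["coding_a"] and row["coding_b"]):
            continue
        if nearest.get(a, (None, b))[1] != b or nearest.get(b, (None, a))[1] != a:
            continue
        rows.append(row)
    return pd.DataFrame(rows) if rows else truth.iloc[0:0]
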