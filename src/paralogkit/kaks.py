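"""Frame selection, ORF extraction, codon back-alignment and Ka/Ks.

For each paralog pair the coding frame is recovered by comparing all 36
combinations of six-frame translations with a local protein alignment
(the in-package analogue of a translated similarity search). The longest
stop-free open reading frame overlapping the translated alignment is
extracted from each sequence (stop-to-stop; no start-codon requirement),
the two peptides are globally aligned, and the protein alignment is
back-expanded to codons.

Synonymous/nonsynonymous divergence uses the Nei-Gojobori counting
method: per-codon synonymous site fractions from the universal genetic
code (changes to stop codons count as nonsynonymous), site totals
averaged over the two sequences, multi-nucleotide codon differences
averaged over all mutational pathways with pathways through stop codons
excluded (all pathways weighted equally if every one is blocked). The
observed proportions pS and pN are converted to distances with the
Jukes-Cantor correction d = -(3/4) ln(1 - (4/3) p). Saturation
(p >= 3/4) and Ks = 0 are reported as flags, never exceptions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from scipy import stats

from .io import SequenceRecord

__all__ = [
    "FramePair",
    "OrfInterval",
    "CodonAlignment",
    "KaKsResult",
    "KaKsFlag",
    "DivergenceEstimate",
    "PairKaKs",
    "best_translated_frames",
    "longest_orf_overlapping",
    "global_protein_align",
    "backalign_codons",
    "nei_gojobori",
    "pair_kaks",
    "divergence_time",
    "compare_divergence_between_origins",
    "synonymous_site_fraction",
    "pathway_differences",
    "jukes_cantor",
]

_STOP_PENALTY = -10

_table = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = "*"
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
)
_BASES = "ACGT"


def translate(seq: str) -> str:
    """Translate a nucleotide string codon by codon; unknown codons -> X."""
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aas.append(CODON_TO_AA.get(seq[i : i + 3], "X"))
    return "".join(aas)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def synonymous_site_fraction(codon: str) -> float:
    """Number of synonymous sites in a sense codon (Nei-Gojobori).

    Each position contributes (synonymous one-nt changes)/3; a change
    into a stop codon counts as nonsynonymous.
    """
    aa = CODON_TO_AA[codon]
    if aa == "*":
        raise ValueError("synonymous sites undefined for stop codons")
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if CODON_TO_AA[alt] == aa:
                s += 1.0 / 3.0
    return s


def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Differences at multiple positions are averaged over all orderings of
    the single-nucleotide steps; orderings passing through a stop codon
    are excluded (if all are blocked, every ordering is weighted equally,
    with steps into or out of stops counted as nonsynonymous).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathway_counts: list[tuple[float, float, bool]] = []
    for order in itertools.permutations(diff_pos):
        current = codon_a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            aa_from, aa_to = CODON_TO_AA[current], CODON_TO_AA[nxt]
            if aa_to == "*":
                # endpoints are sense codons, so a stop can only be an
                # intermediate: this pathway passes through a stop
                through_stop = True
            if aa_from == aa_to and aa_from != "*":
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        pathway_counts.append((sd, nd, through_stop))
    allowed = [(sd, nd) for sd, nd, blocked in pathway_counts if not blocked]
    if not allowed:
        allowed = [(sd, nd) for sd, nd, _ in pathway_counts]
    sd_mean = sum(p[0] for p in allowed) / len(allowed)
    nd_mean = sum(p[1] for p in allowed) / len(allowed)
    return sd_mean, nd_mean


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - (4/3) p); NaN at saturation (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


class KaKsFlag(str, Enum):
    OK = "OK"
    KS_SATURATED = "KS_SATURATED"
    KA_SATURATED = "KA_SATURATED"
    KS_ZERO = "KS_ZERO"
    TOO_SHORT = "TOO_SHORT"


@dataclass
class KaKsResult:
    """Nei-Gojobori site counts, proportions and corrected distances."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    ratio: float | None
    n_codons: int
    flags: tuple[KaKsFlag, ...]

    @property
    def ok(self) -> bool:
        return self.flags == (KaKsFlag.OK,)


@dataclass(frozen=True)
class CodonAlignment:
    """Paired codon columns; '---' marks a gap codon."""

    columns: tuple[tuple[str, str], ...]

    @property
    def n_aligned_codons(self) -> int:
        return sum(1 for a, b in self.columns if a != "---" and b != "---")

    def sequence_a(self) -> str:
        return "".join(a for a, _ in self.columns if a != "---")

    def sequence_b(self) -> str:
        return "".join(b for _, b in self.columns if b != "---")


def nei_gojobori(alignment: CodonAlignment, min_codons: int = 100) -> KaKsResult:
    """Ka/Ks from a codon alignment by Nei-Gojobori counting.

    Columns with a gap, an ambiguous base, or a stop codon in either
    sequence are excluded from site and difference counting, so that
    S + N = 3 x (number of counted columns).
    """
    S_a = S_b = Sd = Nd = 0.0
    n_counted = 0
    for codon_a, codon_b in alignment.columns:
        if "-" in codon_a or "-" in codon_b:
            continue
        if "N" in codon_a or "N" in codon_b:
            continue
        if CODON_TO_AA.get(codon_a, "*") == "*" or CODON_TO_AA.get(codon_b, "*") == "*":
            continue
        n_counted += 1
        S_a += synonymous_site_fraction(codon_a)
        S_b += synonymous_site_fraction(codon_b)
        if codon_a != codon_b:
            sd, nd = pathway_differences(codon_a, codon_b)
            Sd += sd
            Nd += nd
    S = (S_a + S_b) / 2.0
    N = 3.0 * n_counted - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    flags: list[KaKsFlag] = []
    if n_counted < min_codons:
        flags.append(KaKsFlag.TOO_SHORT)
    if math.isnan(Ks):
        flags.append(KaKsFlag.KS_SATURATED)
    if math.isnan(Ka):
        flags.append(KaKsFlag.KA_SATURATED)
    if Ks == 0.0:
        flags.append(KaKsFlag.KS_ZERO)
    ratio = Ka / Ks if Ks and Ks > 0 and not math.isnan(Ks) and not math.isnan(Ka) else None
    if not flags:
        flags.append(KaKsFlag.OK)
    return KaKsResult(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka,
        ratio=ratio, n_codons=n_counted, flags=tuple(flags),
    )


# --- frame selection and ORF extraction -----------------------------------

_FRAMES = (1, 2, 3, -1, -2, -3)


def _protein_matrix():
    m = substitution_matrices.load("BLOSUM62")
    m = m.copy()
    alphabet = m.alphabet
    for aa in alphabet:
        m["*", aa] = _STOP_PENALTY
        m[aa, "*"] = _STOP_PENALTY
    return m


_PROT_MATRIX = _protein_matrix()


def _protein_aligner(mode: str, gap_open: float, gap_extend: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _PROT_MATRIX
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _oriented(seq: str, frame: int) -> str:
    return seq if frame > 0 else _revcomp(seq)


def _frame_translation(seq: str, frame: int) -> str:
    oriented = _oriented(seq, frame)
    return translate(oriented[abs(frame) - 1 :])


@dataclass(frozen=True)
class FramePair:
    """Best-scoring reading-frame combination of a sequence pair.

    ``region_a``/``region_b`` are the nucleotide spans (1-based inclusive,
    on the frame-oriented sequence) covered by the translated alignment.
    """

    frame_a: int
    frame_b: int
    translated_score: float
    region_a: tuple[int, int]
    region_b: tuple[int, int]


def best_translated_frames(
    a: SequenceRecord, b: SequenceRecord
) -> FramePair | None:
    """Frame pair maximizing the local protein-alignment score over all
    36 six-frame translation combinations; ``None`` if no combination
    scores above zero. Stops translate to '*' scored -10 against anything.
    """
    if len(a) < 60 or len(b) < 60:
        return None
    aligner = _protein_aligner("local", -11.0, -1.0)
    trans_a = {f: _frame_translation(a.residues, f) for f in _FRAMES}
    trans_b = {f: _frame_translation(b.residues, f) for f in _FRAMES}
    best: FramePair | None = None
    for fa in _FRAMES:
        pa = trans_a[fa]
        if not pa:
            continue
        for fb in _FRAMES:
            pb = trans_b[fb]
            if not pb:
                continue
            alignments = aligner.align(pa, pb)
            score = alignments.score
            if score <= 0:
                continue
            if best is not None and score <= best.translated_score:
                continue
            aln = alignments[0]
            pa0, pa1 = int(aln.coordinates[0, 0]), int(aln.coordinates[0, -1])
            pb0, pb1 = int(aln.coordinates[1, 0]), int(aln.coordinates[1, -1])
            off_a, off_b = abs(fa) - 1, abs(fb) - 1
            best = FramePair(
                frame_a=fa,
                frame_b=fb,
                translated_score=float(score),
                region_a=(off_a + 3 * pa0 + 1, off_a + 3 * pa1),
                region_b=(off_b + 3 * pb0 + 1, off_b + 3 * pb1),
            )
    return best


@dataclass(frozen=True)
class OrfInterval:
    """1-based inclusive nucleotide span of a stop-free codon run on the
    frame-oriented transcript; length is a multiple of 3."""

    start: int
    end: int

    @property
    def n_codons(self) -> int:
        return (self.end - self.start + 1) // 3


def longest_orf_overlapping(
    seq: SequenceRecord,
    frame: int,
    aligned_region: tuple[int, int],
    min_codons: int = 30,
) -> OrfInterval | None:
    """Longest uninterrupted (stop-free) reading-frame run overlapping the
    translated-alignment region; stop-to-stop, no ATG requirement.

    Returns ``None`` when no overlapping run reaches *min_codons*.
    """
    oriented = _oriented(seq.residues, frame)
    off = abs(frame) - 1
    peptide = translate(oriented[off:])
    runs: list[tuple[int, int]] = []  # codon-index half-open [i0, i1)
    start = 0
    for i, aa in enumerate(peptide + "*"):
        if aa == "*":
            if i > start:
                runs.append((start, i))
            start = i + 1
    best: OrfInterval | None = None
    for i0, i1 in runs:
        nt0, nt1 = off + 3 * i0 + 1, off + 3 * i1
        if nt1 < aligned_region[0] or nt0 > aligned_region[1]:
            continue
        if i1 - i0 < min_codons:
            continue
        if best is None or (i1 - i0) > best.n_codons:
            best = OrfInterval(start=nt0, end=nt1)
    return best


def global_protein_align(
    p1: str, p2: str, gap_open: float = -10.0, gap_extend: float = -1.0
) -> tuple[str, str, float]:
    """Global BLOSUM62 alignment with affine gaps; returns the two gapped
    strings and the score. Ties resolve deterministically (first optimal
    traceback, substitutions preferred over gaps)."""
    if not p1 or not p2:
        raise ValueError("peptides must be non-empty")
    aligner = _protein_aligner("global", gap_open, gap_extend)
    alignments = aligner.align(p1, p2)
    aln = alignments[0]
    return str(aln[0]), str(aln[1]), float(alignments.score)


def backalign_codons(
    aligned_a: str, aligned_b: str, orf_a: str, orf_b: str
) -> CodonAlignment:
    """Expand a gapped protein alignment back to codons.

    Each residue column becomes its source codon, each gap a '---'
    column; the concatenated non-gap codons reconstruct each ORF exactly.
    """
    if len(orf_a) % 3 or len(orf_b) % 3:
        raise ValueError("ORF lengths must be multiples of 3")
    pep_a, pep_b = translate(orf_a), translate(orf_b)
    if pep_a != aligned_a.replace("-", ""):
        raise ValueError("protein alignment does not match translation of ORF a")
    if pep_b != aligned_b.replace("-", ""):
        raise ValueError("protein alignment does not match translation of ORF b")
    columns: list[tuple[str, str]] = []
    ia = ib = 0
    for col, (ra, rb) in enumerate(zip(aligned_a, aligned_b)):
        if ra == "-":
            codon_a = "---"
        else:
            codon_a = orf_a[3 * ia : 3 * ia + 3]
            if CODON_TO_AA.get(codon_a, "X" if "N" in codon_a else None) != ra and ra != "X":
                raise ValueError(f"codon/residue mismatch at column {col}")
            ia += 1
        if rb == "-":
            codon_b = "---"
        else:
            codon_b = orf_b[3 * ib : 3 * ib + 3]
            ib += 1
        columns.append((codon_a, codon_b))
    return CodonAlignment(columns=tuple(columns))


def _clip_orf(
    orf: OrfInterval, region: tuple[int, int], min_codons: int
) -> OrfInterval | None:
    """Intersect an ORF with the translated-alignment region (both are
    codon-aligned in the same frame); ``None`` if too short after
    clipping."""
    start = max(orf.start, region[0])
    end = min(orf.end, region[1])
    if end - start + 1 < 3 * min_codons:
        return None
    return OrfInterval(start=start, end=end)


@dataclass
class PairKaKs:
    """Per-pair result of the frame -> ORF -> alignment -> Ka/Ks chain."""

    id_a: str
    id_b: str
    frames: FramePair | None = None
    orf_a: OrfInterval | None = None
    orf_b: OrfInterval | None = None
    result: KaKsResult | None = None
    status: str = "OK"


def pair_kaks(
    a: SequenceRecord,
    b: SequenceRecord,
    min_codons: int = 100,
    min_orf_codons: int = 30,
) -> PairKaKs:
    """Run the full per-pair chain; failures set ``status`` rather than
    raising (TOO_SHORT when no frame or ORF can be recovered)."""
    out = PairKaKs(id_a=a.id, id_b=b.id)
    frames = best_translated_frames(a, b)
    if frames is None:
        out.status = "TOO_SHORT"
        return out
    out.frames = frames
    orf_a = longest_orf_overlapping(a, frames.frame_a, frames.region_a, min_orf_codons)
    orf_b = longest_orf_overlapping(b, frames.frame_b, frames.region_b, min_orf_codons)
    if orf_a is None or orf_b is None:
        out.status = "TOO_SHORT"
        return out
    # clip each ORF to the translated-alignment span: the stop-free run
    # can read through into non-homologous UTR sequence, and forcing
    # those tails into the global alignment inflates both Ka and Ks
    orf_a = _clip_orf(orf_a, frames.region_a, min_orf_codons)
    orf_b = _clip_orf(orf_b, frames.region_b, min_orf_codons)
    if orf_a is None or orf_b is None:
        out.status = "TOO_SHORT"
        return out
    out.orf_a, out.orf_b = orf_a, orf_b
    nt_a = _oriented(a.residues, frames.frame_a)[orf_a.start - 1 : orf_a.end]
    nt_b = _oriented(b.residues, frames.frame_b)[orf_b.start - 1 : orf_b.end]
    aln_a, aln_b, _score = global_protein_align(translate(nt_a), translate(nt_b))
    codon_aln = backalign_codons(aln_a, aln_b, nt_a, nt_b)
    out.result = nei_gojobori(codon_aln, min_codons=min_codons)
    if KaKsFlag.TOO_SHORT in out.result.flags:
        out.status = "TOO_SHORT"
    return out


# --- divergence-time scaling and group comparisons -------------------------


@dataclass(frozen=True)
class DivergenceEstimate:
    """Relative dating of a duplication class by Ks-ratio scaling."""

    t_point: float
    calibration_t: float
    ks_focal: float
    ks_reference: float


def divergence_time(
    ks_focal: float, ks_reference: float, t_reference_ma: float
) -> DivergenceEstimate:
    """t = t_reference x ks_focal / ks_reference (units: Ma)."""
    if ks_reference <= 0:
        raise ValueError("reference Ks must be positive")
    return DivergenceEstimate(
        t_point=t_reference_ma * ks_focal / ks_reference,
        calibration_t=t_reference_ma,
        ks_focal=ks_focal,
        ks_reference=ks_reference,
    )


def compare_divergence_between_origins(
    percent_id_by_label: dict[str, list[float]],
    ks_by_label: dict[str, list[float]],
) -> dict:
    """Compare percent identity and Ks between duplication origins.

    Percent identities are arcsine-square-root transformed (standard for
    percentage variables), checked for normality (Shapiro-Wilk) and
    compared with a two-sided Mann-Whitney rank test. Ks values are
    natural-log transformed (zeros excluded, count reported), checked for
    normality, and compared with a Welch two-sample t-test.
    """
    labels = sorted(percent_id_by_label)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    la, lb = labels
    report: dict = {"groups": (la, lb)}

    pid_a = np.asarray(percent_id_by_label[la], dtype=float)
    pid_b = np.asarray(percent_id_by_label[lb], dtype=float)
    if len(pid_a) < 2 or len(pid_b) < 2:
        raise ValueError("need >= 2 percent-id observations per group")
    asin_a = np.arcsin(np.sqrt(pid_a / 100.0))
    asin_b = np.arcsin(np.sqrt(pid_b / 100.0))
    mw = stats.mannwhitneyu(pid_a, pid_b, alternative="two-sided")
    report["percent_id"] = {
        "mean": {la: float(pid_a.mean()), lb: float(pid_b.mean())},
        "median": {la: float(np.median(pid_a)), lb: float(np.median(pid_b))},
        "shapiro_p": {
            la: float(stats.shapiro(asin_a).pvalue) if len(asin_a) >= 3 else None,
            lb: float(stats.shapiro(asin_b).pvalue) if len(asin_b) >= 3 else None,
        },
        "mannwhitney_W": float(mw.statistic),
        "p": float(mw.pvalue),
    }

    ks_a = np.asarray(ks_by_label[la], dtype=float)
    ks_b = np.asarray(ks_by_label[lb], dtype=float)
    n_zero = int((ks_a <= 0).sum() + (ks_b <= 0).sum())
    log_a = np.log(ks_a[ks_a > 0])
    log_b = np.log(ks_b[ks_b > 0])
    if len(log_a) < 2 or len(log_b) < 2:
        raise ValueError("need >= 2 positive Ks observations per group")
    tt = stats.ttest_ind(log_a, log_b, equal_var=False)
    report["ks"] = {
        "mean": {la: float(ks_a.mean()), lb: float(ks_b.mean())},
        "median": {la: float(np.median(ks_a)), lb: float(np.median(ks_b))},
        "n_zero_excluded": n_zero,
        "shapiro_p": {
            la: float(stats.shapiro(log_a).pvalue) if len(log_a) >= 3 else None,
            lb: float(stats.shapiro(log_b).pvalue) if len(log_b) >= 3 else None,
        },
        "welch_t": float(tt.statistic),
        "welch_df": float(tt.df),
        "p": float(tt.pvalue),
    }
    return report
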