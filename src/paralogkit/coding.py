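"""Built-in coding-potential scorer.

Scores a transcript's probability of coding for protein on [0, 1], with
the conventional 0.5 threshold separating likely-noncoding (< 0.5) from
likely-coding (> 0.5) sequences. The model is a logistic regression over
three sequence features:

* longest-ORF coverage — the longest stop-free codon run over all six
  reading frames, as a fraction of transcript length;
* in-ORF composition — mean log-likelihood ratio of overlapping
  trinucleotides inside that run, under a coding-composition table
  versus a uniform background (a factorized stand-in for the usual
  hexamer score);
* out-of-ORF composition — the same ratio over the sequence outside the
  run. An intact transcript has untranslated flanks with background
  composition there, while a frame-disrupted (pseudogenizing) duplicate
  still carries coding-like composition outside its surviving ORF
  fragment — the signature that separates the two when ORF coverage
  alone is ambiguous.

It is fitted once, deterministically, on an internally generated corpus
of transcript-like sequences: coding examples are a stop-free,
composition-biased ORF flanked by short untranslated regions, noncoding
examples are uniform random sequences and frame-disrupted coding
sequences (codon-shuffled outside a preserved anchor region, with a
frameshifting single-nucleotide deletion). The regularized fit keeps
scores graded rather than saturated, so within-pair score differences
remain informative. This is a lightweight stand-in scorer with the
standard threshold semantics, not a reimplementation of any published
classifier; externally computed score tables are the higher-fidelity
path and pass through unchanged.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np
from sklearn.linear_model import LogisticRegression

from .io import SequenceRecord

__all__ = ["CodingPotentialModel", "default_model", "coding_potential_score"]

_BASES = "ACGT"
_STOPS = frozenset({"TAA", "TAG", "TGA"})
_MIN_LEN = 60


def _longest_orf(seq: str) -> tuple[str, int, int]:
    """Longest stop-free codon run across six frames.

    Returns (oriented sequence, start, end) with [start, end) the run's
    nucleotide span on that orientation; (seq, 0, 0) when empty.
    """
    best = (seq, 0, 0)
    best_len = 0
    for oriented in (seq, seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]):
        for off in range(3):
            run_start = off
            run = 0
            for i in range(off, len(oriented) - 2, 3):
                if oriented[i : i + 3] in _STOPS:
                    run = 0
                    run_start = i + 3
                else:
                    run += 1
                    if run > best_len:
                        best_len = run
                        best = (oriented, run_start, i + 3)
    return best


class CodingPotentialModel:
    """Deterministic logistic scorer over ORF-coverage and hexamer
    log-odds features."""

    def __init__(self, seed: int = 20140626, corpus_size: int = 300):
        self._seed = seed
        self._corpus_size = corpus_size
        self._hex_logodds: dict[str, float] = {}
        self._clf: LogisticRegression | None = None
        self._fit()

    # -- corpus -------------------------------------------------------

    @staticmethod
    def _random_coding(rng: np.random.Generator, n_codons: int, gc: float) -> str:
        """Stop-free codons from independent base draws at GC *gc*."""
        p = np.array(
            [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        )  # A C G T
        bases = np.array(list("ACGT"))
        codons: list[str] = []
        while len(codons) < n_codons:
            draw = "".join(bases[rng.choice(4, size=3, p=p)])
            if draw not in _STOPS:
                codons.append(draw)
        return "".join(codons)

    @staticmethod
    def _disrupt(rng: np.random.Generator, seq: str) -> str:
        """Coding->noncoding drift as it happens to pseudogenizing
        duplicates: codon shuffle outside a preserved anchor region,
        recurrent frameshifting deletions (one per ~20 codons), and
        neutral decay of 30% of outside sites toward background."""
        codons = [seq[i : i + 3] for i in range(0, len(seq) - 2, 3)]
        n = len(codons)
        a0 = int(round(0.3 * n))
        a1 = min(n, a0 + max(1, int(round(0.4 * n))))
        before = codons[:a0]
        after = codons[a1:]
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
            cuts = [0] + list(range(60, len(out), 60))
            kept, prev = [], 0
            for c in cuts:
                j = min(c + (int(rng.integers(0, 3)) if c else 0), len(out) - 1)
                kept.append(out[prev:j])
                prev = j + 1
            kept.append(out[prev:])
            return "".join(kept)

        return decay(before) + "".join(codons[a0:a1]) + decay(after)

    def _fit(self) -> None:
        rng = np.random.default_rng(self._seed)
        coding, noncoding, coding_orfs = [], [], []
        for _ in range(self._corpus_size):
            n_codons = int(rng.integers(100, 500))
            gc = float(rng.uniform(0.40, 0.58))
            orf = self._random_coding(rng, n_codons, gc)
            coding_orfs.append(orf)
            utr5 = "".join(
                np.array(list(_BASES))[rng.integers(0, 4, int(rng.integers(30, 300)))]
            )
            utr3 = "".join(
                np.array(list(_BASES))[rng.integers(0, 4, int(rng.integers(50, 600)))]
            )
            coding.append(utr5 + orf + utr3)
            if rng.random() < 0.5:
                noncoding.append(
                    "".join(
                        np.array(list(_BASES))[
                            rng.integers(0, 4, size=len(orf) + len(utr5) + len(utr3))
                        ]
                    )
                )
            else:
                noncoding.append(utr5 + self._disrupt(rng, orf) + utr3)
        # trinucleotide factorization keeps the table at 64 entries; a
        # hexamer's log-odds is the sum of its two codons' log-odds.
        # The reference is coding composition vs. a uniform background, so
        # the feature reads "how coding-like is this stretch of sequence"
        counts_c = {"".join(h): 1.0 for h in itertools.product(_BASES, repeat=3)}
        for orf in coding_orfs:
            for i in range(len(orf) - 2):
                tri = orf[i : i + 3]
                if tri in counts_c:
                    counts_c[tri] += 1.0
        tot_c = sum(counts_c.values())
        uniform = 1.0 / 64.0
        self._tri_logodds = {
            tri: math.log((counts_c[tri] / tot_c) / uniform) for tri in counts_c
        }
        X = np.array(
            [self._features(s) for s in coding + noncoding], dtype=float
        )
        y = np.array([1] * len(coding) + [0] * len(noncoding))
        # moderate regularization keeps predicted probabilities graded
        clf = LogisticRegression(C=1.0, max_iter=1000, random_state=0)
        clf.fit(X, y)
        self._clf = clf

    # -- scoring ------------------------------------------------------

    def _composition(self, seq: str) -> float:
        vals = [
            self._tri_logodds.get(seq[i : i + 3], 0.0)
            for i in range(len(seq) - 2)
        ]
        return float(np.mean(vals)) if vals else 0.0

    def _features(self, seq: str) -> tuple[float, float, float]:
        oriented, start, end = _longest_orf(seq)
        coverage = (end - start) / len(seq) if seq else 0.0
        inside = self._composition(oriented[start:end])
        outside_seq = oriented[:start] + oriented[end:]
        outside = self._composition(outside_seq) if len(outside_seq) >= 30 else 0.0
        return (coverage, inside, outside)

    def score(self, seq: str | SequenceRecord) -> float | None:
        """Coding-potential score in [0, 1]; ``None`` for sequences < 60 nt."""
        residues = seq.residues if isinstance(seq, SequenceRecord) else seq.upper()
        if len(residues) < _MIN_LEN:
            return None
        X = np.array([self._features(residues)], dtype=float)
        return float(self._clf.predict_proba(X)[0, 1])


@lru_cache(maxsize=1)
def default_model() -> CodingPotentialModel:
    return CodingPotentialModel()


def coding_potential_score(
    seq: SequenceRecord,
    model: CodingPotentialModel | None = None,
    score_table: dict[str, float] | None = None,
) -> float | None:
    """Score one sequence; an external score table takes precedence over
    the built-in model and is passed through unchanged."""
    if score_table is not None and seq.id in score_table:
        return score_table[seq.id]
    model = model or default_model()
    return model.score(seq)
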