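"""Functional-divergence statistics for paralog pairs.

Paralog pairs are benchmarked against two control pair sets drawn from
the same transcriptome: C1 ("same genes") pairs two isotigs from one
isogroup — splice/allelic variants expected to share function — and C2
("different genes") pairs isotigs from different isogroups. Three
read-outs quantify divergence within pairs:

* annotation-hit concordance (same hit / different hit / no hit) with a
  Pearson chi-square test across the three groups;
* GO-term overlap (Jaccard index) compared by Kruskal-Wallis and
  pairwise Mann-Whitney tests with Bonferroni correction;
* absolute within-pair difference in coding potential, with a label
  permutation test on both the median and the interquartile range.

GO enrichment of a paralog set against the transcriptome background
uses per-term Fisher's exact tests with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import IsogroupMap

__all__ = [
    "ControlKind",
    "ControlPairSet",
    "HitCategory",
    "ConcordanceTable",
    "PermutationResult",
    "EnrichmentResult",
    "build_control_same_isogroup",
    "build_control_different_isogroup",
    "classify_hit_concordance",
    "chi_square_concordance",
    "jaccard_index",
    "compare_jaccard_distributions",
    "pairwise_score_difference",
    "permutation_median_iqr_test",
    "go_enrichment_fisher",
]


class ControlKind(str, Enum):
    C1_SAME_ISOGROUP = "C1_SAME_ISOGROUP"
    C2_DIFFERENT_ISOGROUP = "C2_DIFFERENT_ISOGROUP"


@dataclass
class ControlPairSet:
    kind: ControlKind
    pairs: list[tuple[str, str]]
    seed: int
    n_requested: int
    n_realized: int


def build_control_same_isogroup(
    isogroup_map: IsogroupMap, n: int, seed: int
) -> ControlPairSet:
    """C1: *n* pairs of isotigs from within one isogroup, no isogroup used
    twice. Only isogroups with >= 2 isotigs are eligible."""
    rng = np.random.default_rng(seed)
    eligible = [
        (group, members)
        for group, members in sorted(isogroup_map.groups().items())
        if len(members) >= 2
    ]
    if not eligible:
        raise ValueError("no isogroup has two or more isotigs")
    n_realized = min(n, len(eligible))
    chosen = rng.choice(len(eligible), size=n_realized, replace=False)
    pairs: list[tuple[str, str]] = []
    for idx in chosen:
        members = eligible[int(idx)][1]
        a, b = rng.choice(len(members), size=2, replace=False)
        pairs.append((members[int(a)], members[int(b)]))
    return ControlPairSet(
        kind=ControlKind.C1_SAME_ISOGROUP,
        pairs=pairs,
        seed=seed,
        n_requested=n,
        n_realized=n_realized,
    )


def build_control_different_isogroup(
    isogroup_map: IsogroupMap,
    n: int,
    seed: int,
    ids: list[str] | None = None,
    max_attempts: int = 1000,
) -> ControlPairSet:
    """C2: *n* pairs spanning different isogroups; a rejected same-isogroup
    draw is replaced (rejection sampling, *max_attempts* per slot) and no
    sequence id is used twice across the whole set."""
    rng = np.random.default_rng(seed)
    pool = sorted(ids if ids is not None else list(isogroup_map))
    groups = {sid: isogroup_map.group_of(sid) for sid in pool}
    if len(set(groups.values())) < 2:
        raise ValueError("need sequences from at least two isogroups")
    order = list(rng.permutation(len(pool)))
    unused = [pool[i] for i in order]
    pairs: list[tuple[str, str]] = []
    while len(pairs) < n and len(unused) >= 2:
        first = unused.pop(0)
        second = None
        for _ in range(max_attempts):
            cand_idx = int(rng.integers(len(unused)))
            if groups[unused[cand_idx]] != groups[first]:
                second = unused.pop(cand_idx)
                break
        if second is None:
            break  # slot exhausted; end sampling early
        pairs.append((first, second))
    return ControlPairSet(
        kind=ControlKind.C2_DIFFERENT_ISOGROUP,
        pairs=pairs,
        seed=seed,
        n_requested=n,
        n_realized=len(pairs),
    )


class HitCategory(str, Enum):
    SAME_HIT = "SAME_HIT"
    DIFFERENT_HIT = "DIFFERENT_HIT"
    NO_HIT = "NO_HIT"


@dataclass
class ConcordanceTable:
    """counts[group][category]; rows sum to group sizes."""

    counts: dict[str, dict[HitCategory, int]] = field(default_factory=dict)

    def add(self, group: str, category: HitCategory) -> None:
        row = self.counts.setdefault(
            group, {c: 0 for c in HitCategory}
        )
        row[category] += 1

    def row_total(self, group: str) -> int:
        return sum(self.counts.get(group, {}).values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                group: {c.value: row.get(c, 0) for c in HitCategory}
                for group, row in self.counts.items()
            }
        ).T[[c.value for c in HitCategory]]


def classify_hit_concordance(
    pairs_by_group: dict[str, list[tuple[str, str]]],
    best_hits: dict[str, str],
) -> ConcordanceTable:
    """Classify each pair by annotation-hit concordance.

    SAME_HIT: both members share one best hit; DIFFERENT_HIT: both have
    hits but different ones, or exactly one member has a hit; NO_HIT:
    neither has a hit.
    """
    table = ConcordanceTable()
    for group, pairs in pairs_by_group.items():
        for a, b in pairs:
            hit_a, hit_b = best_hits.get(a), best_hits.get(b)
            if hit_a is None and hit_b is None:
                table.add(group, HitCategory.NO_HIT)
            elif hit_a is not None and hit_a == hit_b:
                table.add(group, HitCategory.SAME_HIT)
            else:
                table.add(group, HitCategory.DIFFERENT_HIT)
    return table


def chi_square_concordance(table: ConcordanceTable) -> tuple[float, int, float]:
    """Pearson chi-square over the groups x categories count table."""
    frame = table.to_frame()
    arr = frame.to_numpy(dtype=float)
    expected = stats.contingency.expected_freq(arr)
    if (expected <= 0).any():
        raise ValueError(
            "zero expected count; merge sparse categories before testing"
        )
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), int(dof), float(p)


def jaccard_index(set_a: set, set_b: set) -> float | None:
    """|A n B| / |A u B|; ``None`` when both sets are empty."""
    union = set_a | set_b
    if not union:
        return None
    return len(set_a & set_b) / len(union)


def compare_jaccard_distributions(
    jaccard_by_group: dict[str, list[float]],
) -> dict:
    """Kruskal-Wallis across groups plus pairwise two-sided Mann-Whitney
    tests with Bonferroni correction."""
    groups = sorted(jaccard_by_group)
    if len(groups) < 2 or any(len(jaccard_by_group[g]) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    samples = [np.asarray(jaccard_by_group[g], dtype=float) for g in groups]
    if all(np.array_equal(s, samples[0]) for s in samples[1:]):
        kw_stat, kw_p = 0.0, 1.0
    else:
        kw_stat, kw_p = stats.kruskal(*samples)
    n_tests = len(groups) * (len(groups) - 1) // 2
    pairwise = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            mw = stats.mannwhitneyu(
                samples[i], samples[j], alternative="two-sided"
            )
            pairwise[(groups[i], groups[j])] = {
                "W": float(mw.statistic),
                "p_raw": float(mw.pvalue),
                "p_bonferroni": float(min(1.0, mw.pvalue * n_tests)),
            }
    return {
        "kruskal_H": float(kw_stat),
        "kruskal_p": float(kw_p),
        "pairwise": pairwise,
        "medians": {g: float(np.median(s)) for g, s in zip(groups, samples)},
    }


def pairwise_score_difference(
    pairs: list[tuple[str, str]], scores: dict[str, float]
) -> tuple[list[float], int]:
    """Absolute within-pair coding-potential differences; pairs with an
    unscored member are dropped (count returned)."""
    diffs: list[float] = []
    dropped = 0
    for a, b in pairs:
        sa, sb = scores.get(a), scores.get(b)
        if sa is None or sb is None:
            dropped += 1
            continue
        diffs.append(abs(sa - sb))
    return diffs, dropped


@dataclass
class PermutationResult:
    observed_median_diff: float
    observed_iqr_diff: float
    p_median: float
    p_iqr: float
    n_rounds: int
    seed: int

    def display_p(self, p: float) -> str:
        return f"< {1.0 / self.n_rounds:g}" if p == 0.0 else f"{p:g}"


def _iqr(a: np.ndarray, axis: int | None = None) -> np.ndarray:
    q75, q25 = np.percentile(a, [75, 25], axis=axis)
    return q75 - q25


def permutation_median_iqr_test(
    group_x,
    group_y,
    n_rounds: int = 100_000,
    seed: int = 0,
    strict: bool = False,
    method: str = "permutation",
    _chunk: int = 2000,
) -> PermutationResult:
    """Permutation test of the group difference in median and in IQR.

    The observed statistics are |median(x) - median(y)| and
    |IQR(x) - IQR(y)|. Each round permutes the pooled values and
    reassigns the original group sizes (``method='bootstrap'`` resamples
    with replacement instead); the p-value is the fraction of rounds with
    a permuted difference >= the observed one (``strict=True`` counts
    only strictly greater rounds, the literal reading of a "greater
    than" rule, at the cost of anti-conservative behavior under ties).
    """
    if n_rounds < 1000:
        raise ValueError("n_rounds must be >= 1000")
    x = np.asarray(group_x, dtype=float)
    y = np.asarray(group_y, dtype=float)
    if len(x) < 5 or len(y) < 5:
        raise ValueError("both groups need >= 5 values")
    if method not in ("permutation", "bootstrap"):
        raise ValueError("method must be 'permutation' or 'bootstrap'")
    obs_med = abs(float(np.median(x)) - float(np.median(y)))
    obs_iqr = abs(float(_iqr(x)) - float(_iqr(y)))
    # sorting the pool makes the resampling invariant to the order the
    # groups were passed in (exact label-exchange symmetry at equal sizes)
    pooled = np.sort(np.concatenate([x, y]))
    nx, n = len(x), len(pooled)
    rng = np.random.default_rng(seed)
    count_med = count_iqr = 0
    done = 0
    while done < n_rounds:
        m = min(_chunk, n_rounds - done)
        if method == "permutation":
            idx = np.argsort(rng.random((m, n)), axis=1)
            perm = pooled[idx]
        else:
            perm = pooled[rng.integers(0, n, size=(m, n))]
        px, py = perm[:, :nx], perm[:, nx:]
        med_diff = np.abs(np.median(px, axis=1) - np.median(py, axis=1))
        iqr_diff = np.abs(_iqr(px, axis=1) - _iqr(py, axis=1))
        if strict:
            count_med += int((med_diff > obs_med).sum())
            count_iqr += int((iqr_diff > obs_iqr).sum())
        else:
            count_med += int((med_diff >= obs_med).sum())
            count_iqr += int((iqr_diff >= obs_iqr).sum())
        done += m
    return PermutationResult(
        observed_median_diff=obs_med,
        observed_iqr_diff=obs_iqr,
        p_median=count_med / n_rounds,
        p_iqr=count_iqr / n_rounds,
        n_rounds=n_rounds,
        seed=seed,
    )


@dataclass
class EnrichmentResult:
    """Per-GO-term enrichment table with BH-adjusted q-values."""

    table: pd.DataFrame
    alpha: float = 0.05

    def significant_terms(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def go_enrichment_fisher(
    foreground_ids: set[str],
    background_ids: set[str],
    go_map: dict[str, set[str]],
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Per-term two-sided Fisher's exact test of foreground vs. rest of
    background, Benjamini-Hochberg adjusted, flagged at q <= alpha."""
    if not foreground_ids:
        raise ValueError("foreground is empty")
    if not foreground_ids <= background_ids:
        raise ValueError("foreground must be a subset of background")
    rest = background_ids - foreground_ids
    terms = sorted(
        {t for sid in background_ids for t in go_map.get(sid, set())}
    )
    rows = []
    for term in terms:
        fg_with = sum(1 for sid in foreground_ids if term in go_map.get(sid, set()))
        rest_with = sum(1 for sid in rest if term in go_map.get(sid, set()))
        table = [
            [fg_with, len(foreground_ids) - fg_with],
            [rest_with, len(rest) - rest_with],
        ]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        bg_with = fg_with + rest_with
        fold = (
            (fg_with / len(foreground_ids)) / (bg_with / len(background_ids))
            if bg_with
            else float("nan")
        )
        rows.append((term, fg_with, bg_with, fold, p))
    frame = pd.DataFrame(
        rows, columns=["term", "n_foreground", "n_background", "fold", "p"]
    ).set_index("term")
    if len(frame):
        _, q, _, _ = multipletests(frame["p"].to_numpy(), method="fdr_bh")
        frame["q"] = q
    else:
        frame["q"] = []
    frame["significant"] = frame["q"] <= alpha
    return EnrichmentResult(table=frame, alpha=alpha)
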