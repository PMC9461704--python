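"""Per-metabolite selection of optimal extraction protocols.

For each metabolite within a tissue, protocols with at least two above-LOD
replicates enter a one-way ANOVA on log2 concentrations, followed by
Tukey's HSD all-pairs post-hoc test (Tukey-Kramer adjustment for unequal
replicate counts, which LOD censoring makes inevitable).  The pairwise
significance pattern is summarised as a compact letter display — groups
share a letter iff they are not significantly different — and the *optimal
set* for the metabolite is the protocol with the highest median yield plus
every protocol sharing a letter with it (i.e. not significantly lower).

Counting, per protocol, how many metabolites include it in their optimal
set gives a tissue-level protocol ranking.

No multiplicity correction is applied across metabolites: each metabolite
is an independent question ("which protocols extract *this* compound
best?"), not a joint hypothesis family.  Treat cross-metabolite
significance claims accordingly.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_model import QuantDataset
from .qc_metrics import above_lod_mask

__all__ = [
    "RankingResult",
    "anova_per_metabolite",
    "tukey_hsd",
    "compact_letter_display",
    "optimal_methods",
    "evaluate_metabolites",
    "rank_protocols",
]


@dataclass
class RankingResult:
    """Outcome of the ANOVA/Tukey/letter pipeline for one metabolite."""

    metabolite_id: str
    tissue: str
    anova_F: float
    anova_p: float
    median_by_protocol: dict[str, float]
    letters_by_protocol: dict[str, str]
    optimal_set: set[str]
    skipped: bool = False
    skip_reason: str | None = None


def anova_per_metabolite(
    values: Sequence[float], protocol_labels: Sequence
) -> tuple[float, float]:
    """One-way fixed-effects ANOVA F and p on the supplied observations.

    Degenerate cases: zero between- and within-group variance yields
    F = 0, p = 1; zero within-group variance with group differences yields
    F = inf, p = 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(protocol_labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    if any(len(g) == 0 for g in groups):  # pragma: no cover - unreachable
        raise ValueError("empty group")
    n = values.size
    k = len(groups)
    grand = values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if df_w <= 0:
        raise ValueError("ANOVA requires replicates (n > k)")
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p


def tukey_hsd(
    values: Sequence[float],
    protocol_labels: Sequence,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey HSD all-pairs comparisons (Tukey-Kramer for unbalanced groups).

    For groups i, j with means m_i, m_j and pooled within-group mean square
    MSW on N-k degrees of freedom, the studentized-range statistic is
    ``q = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))`` and the adjusted
    p-value is the studentized-range survival function at (q; k, N-k).

    Returns one row per unordered pair with columns
    ``protocol_i, protocol_j, mean_diff, p_adjusted, significant``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(protocol_labels)
    names = list(pd.unique(labels))
    groups = {g: values[labels == g] for g in names}
    if len(names) < 2:
        raise ValueError("Tukey HSD requires at least 2 groups")
    if any(len(g) < 2 for g in groups.values()):
        raise ValueError("Tukey HSD requires >= 2 observations per group")
    n = values.size
    k = len(names)
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups.values()) / (n - k)
    rows = []
    for gi, gj in itertools.combinations(names, 2):
        a, b = groups[gi], groups[gj]
        diff = float(a.mean() - b.mean())
        if msw == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            se = np.sqrt(msw / 2.0 * (1.0 / len(a) + 1.0 / len(b)))
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, n - k))
            p = min(max(p, 0.0), 1.0)
        rows.append(
            {
                "protocol_i": gi,
                "protocol_j": gj,
                "mean_diff": diff,
                "p_adjusted": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def compact_letter_display(
    groups: Sequence[str],
    significant_pairs: Sequence[tuple[str, str]],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Parameters
    ----------
    groups
        Group names in display order (conventionally descending median, so
        the best group carries the letter ``a``).
    significant_pairs
        Unordered pairs whose difference is significant; the relation must
        be irreflexive and is treated as symmetric.

    Returns a mapping group -> letter string such that two groups share at
    least one letter iff their pair is *not* significant.
    """
    groups = list(groups)
    pairs = {frozenset(p) for p in significant_pairs}
    if any(len(p) != 2 for p in pairs):
        raise ValueError("significant pairs must be between two distinct groups")

    letters: list[set[str]] = [set(groups)]
    for pair in pairs:
        a, b = tuple(pair)
        new: list[set[str]] = []
        for current in letters:
            if a in current and b in current:
                new.append(current - {a})
                new.append(current - {b})
            else:
                new.append(current)
        # absorb: drop duplicates and proper subsets
        absorbed: list[set[str]] = []
        for cand in sorted(new, key=len, reverse=True):
            if cand and not any(cand <= kept for kept in absorbed):
                absorbed.append(cand)
        letters = absorbed

    rank = {g: i for i, g in enumerate(groups)}
    letters.sort(key=lambda s: (min(rank[g] for g in s), sorted(rank[g] for g in s)))
    alphabet = _letter_labels(len(letters))
    out = {g: "" for g in groups}
    for label, members in zip(alphabet, letters):
        for g in groups:
            if g in members:
                out[g] += label
    return out


def _letter_labels(n: int) -> list[str]:
    """a..z, then aa, ab, ... for pathological group counts."""
    base = list(string.ascii_lowercase)
    labels = list(base)
    while len(labels) < n:
        labels += [x + y for x in base for y in base]
    return labels[:n]


def optimal_methods(
    median_by_protocol: Mapping[str, float],
    letters_by_protocol: Mapping[str, str],
) -> set[str]:
    """Top-median protocol plus all protocols sharing a letter with it."""
    if not median_by_protocol:
        raise ValueError("optimal_methods: empty input")
    best = max(sorted(median_by_protocol), key=lambda p: median_by_protocol[p])
    best_letters = set(letters_by_protocol[best])
    return {
        p
        for p in median_by_protocol
        if set(letters_by_protocol[p]) & best_letters
    } | {best}


def evaluate_metabolites(
    dataset: QuantDataset,
    tissue: str,
    alpha: float = 0.05,
    min_replicates: int = 2,
) -> list[RankingResult]:
    """Run the ANOVA/Tukey/letters pipeline for every metabolite in a tissue.

    Only above-LOD measurements (valid and exceeding the metabolite's LOD)
    enter the analysis, and a protocol is eligible only with at least
    ``min_replicates`` such measurements.  Metabolites with fewer than two
    eligible protocols are returned as skipped, with the reason recorded.
    """
    long = dataset.to_long()
    long = long[long["tissue"] == tissue]
    if long.empty:
        raise ValueError(f"no samples for tissue {tissue!r}")
    long = long[above_lod_mask(long)]

    results: list[RankingResult] = []
    for metabolite in dataset.metabolites["metabolite_id"]:
        sub = long[long["metabolite_id"] == metabolite]
        counts = sub.groupby("protocol", observed=True).size()
        eligible = list(counts[counts >= min_replicates].index)
        if len(eligible) < 2:
            results.append(
                RankingResult(
                    metabolite_id=metabolite,
                    tissue=tissue,
                    anova_F=float("nan"),
                    anova_p=float("nan"),
                    median_by_protocol={},
                    letters_by_protocol={},
                    optimal_set=set(eligible),
                    skipped=True,
                    skip_reason=f"{len(eligible)} protocol(s) with >= {min_replicates} above-LOD replicates",
                )
            )
            continue
        sub = sub[sub["protocol"].isin(eligible)]
        log2_vals = np.log2(sub["concentration"].to_numpy(dtype=float))
        labels = sub["protocol"].to_numpy()
        f, p = anova_per_metabolite(log2_vals, labels)
        pairwise = tukey_hsd(log2_vals, labels, alpha=alpha)
        medians = {
            g: float(np.median(sub.loc[sub["protocol"] == g, "concentration"]))
            for g in eligible
        }
        order = sorted(medians, key=lambda g: (-medians[g], g))
        sig = [
            (r["protocol_i"], r["protocol_j"])
            for _, r in pairwise.iterrows()
            if r["significant"]
        ]
        letters = compact_letter_display(order, sig)
        results.append(
            RankingResult(
                metabolite_id=metabolite,
                tissue=tissue,
                anova_F=f,
                anova_p=p,
                median_by_protocol=medians,
                letters_by_protocol=letters,
                optimal_set=optimal_methods(medians, letters),
            )
        )
    return results


def rank_protocols(
    dataset: QuantDataset,
    tissue: str,
    alpha: float = 0.05,
    min_replicates: int = 2,
    results: list[RankingResult] | None = None,
) -> pd.DataFrame:
    """Protocol ranking for one tissue.

    For each protocol, counts the metabolites for which it belongs to the
    optimal set and for which it has the top median; sorted descending by
    the former, ties broken by the latter, then by label.
    """
    if results is None:
        results = evaluate_metabolites(
            dataset, tissue, alpha=alpha, min_replicates=min_replicates
        )
    protocols = list(
        pd.unique(dataset.samples.loc[dataset.samples["tissue"] == tissue, "protocol"])
    )
    n_optimal = {p: 0 for p in protocols}
    n_top = {p: 0 for p in protocols}
    for res in results:
        if res.skipped or not res.median_by_protocol:
            continue
        best = max(sorted(res.median_by_protocol), key=lambda g: res.median_by_protocol[g])
        n_top[best] = n_top.get(best, 0) + 1
        for p in res.optimal_set:
            n_optimal[p] = n_optimal.get(p, 0) + 1
    table = pd.DataFrame(
        {
            "protocol": protocols,
            "n_metabolites_optimal": [n_optimal[p] for p in protocols],
            "n_metabolites_top_median": [n_top[p] for p in protocols],
        }
    )
    return table.sort_values(
        by=["n_metabolites_optimal", "n_metabolites_top_median", "protocol"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
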