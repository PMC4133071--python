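"""Subset-resampling robustness of the stability rankings.

The full-data ranking of each stability method is compared against the
rankings obtained on stratified subsamples (a fixed number of samples drawn
without replacement from every experimental group).  Each subset ranking is
classified as ``identical`` (same sequence), ``top3_reordered`` (the set of
the first three genes is preserved but not their order, or the tail
differs), or ``different`` (the top-3 set itself changed) — and the class
percentages per method summarize how robust each method is to sample count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import CqMatrix
from .stability import run_method

__all__ = [
    "SubsetEvaluation",
    "draw_subsets",
    "classify_ranking",
    "comparison_ranking",
    "robustness_summary",
    "CLASSES",
]

CLASSES = ["identical", "top3_reordered", "different"]


@dataclass
class SubsetEvaluation:
    """Per-subset classifications and the pooled summary table."""

    per_subset: pd.DataFrame       # stratum, subset, method, class
    summary: pd.DataFrame          # counts per stratum + pooled percentages
    full_rankings: dict = field(default_factory=dict)
    failures: pd.DataFrame | None = None


def draw_subsets(matrix: CqMatrix, per_group: int, n_subsets: int, seed: int):
    """Stratified subsamples: ``per_group`` samples from every group, no replacement."""
    rng = np.random.default_rng(seed)
    groups = matrix.groups
    by_group = {gl: list(idx) for gl, idx in matrix.values.groupby(groups.values).groups.items()}
    for gl, members in by_group.items():
        if len(members) < per_group:
            raise ValueError(f"group {gl!r} has {len(members)} samples < per_group={per_group}")
    subsets = []
    for _ in range(n_subsets):
        chosen = []
        for gl in sorted(by_group):
            members = by_group[gl]
            pick = rng.choice(len(members), size=per_group, replace=False)
            chosen.extend(members[i] for i in sorted(pick))
        subsets.append(chosen)
    return subsets


def classify_ranking(full, sub) -> str:
    """Three-way comparison of a subset ranking against the full-data ranking."""
    full, sub = list(full), list(sub)
    if set(full) != set(sub):
        raise ValueError("rankings cover different gene sets")
    if full == sub:
        return "identical"
    if set(full[:3]) == set(sub[:3]):
        return "top3_reordered"
    return "different"


def comparison_ranking(result) -> list:
    """Ranking used for robustness comparison.

    BestKeeper uses its SD ranking; NormFinder its single-gene ranking;
    GeNorm places the never-excluded final pair jointly first (ordered by
    input gene order, deterministically) followed by the reversed exclusion
    order — all already encoded in each result's ``ranking``.
    """
    return list(result.ranking)


def robustness_summary(matrix: CqMatrix, methods, per_group_sizes=(3, 2),
                       n_subsets: int = 25, seed: int = 0) -> SubsetEvaluation:
    """Run every method on every stratified subset and tabulate classes.

    ``per_group_sizes`` defines the strata (e.g. 3 and 2 samples per
    experimental group); ``n_subsets`` subsets are drawn per stratum.
    Method failures on a subset are recorded and excluded from the
    percentages with a warning column.
    """
    methods = list(methods)
    full_rankings = {m: comparison_ranking(run_method(m, matrix)) for m in methods}

    rows, fails = [], []
    for stratum_i, per_group in enumerate(per_group_sizes):
        subsets = draw_subsets(matrix, per_group, n_subsets, seed + stratum_i)
        for si, samples in enumerate(subsets):
            sub = matrix.subset(samples)
            for m in methods:
                try:
                    ranking = comparison_ranking(run_method(m, sub))
                except Exception as exc:  # noqa: BLE001 - recorded, not raised
                    fails.append({"stratum": per_group, "subset": si, "method": m,
                                  "error": str(exc)})
                    continue
                rows.append({"stratum": per_group, "subset": si, "method": m,
                             "class": classify_ranking(full_rankings[m], ranking)})
    per_subset = pd.DataFrame(rows, columns=["stratum", "subset", "method", "class"])

    parts = []
    for per_group in per_group_sizes:
        sub = per_subset[per_subset["stratum"] == per_group]
        counts = (sub.groupby("method")["class"].value_counts()
                  .unstack(fill_value=0).reindex(columns=CLASSES, fill_value=0))
        counts.insert(0, "stratum", f"{per_group}_per_group")
        parts.append(counts.reset_index())
    pooled = (per_subset.groupby("method")["class"].value_counts(normalize=True)
              .unstack(fill_value=0).reindex(columns=CLASSES, fill_value=0) * 100.0)
    pooled.insert(0, "stratum", "pooled_percent")
    parts.append(pooled.reset_index())
    summary = pd.concat(parts, ignore_index=True).set_index(["stratum", "method"])
    return SubsetEvaluation(per_subset, summary, full_rankings,
                            pd.DataFrame(fails) if fails else None)
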