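"""Reference-gene stability: comparative delta-Ct, BestKeeper, NormFinder, GeNorm.

All four methods consume the calibrated, replicate-averaged Cq matrix and
return a :class:`StabilityResult` whose ``ranking`` lists genes most stable
first (lower stability value = more stable, in every method).

* **Comparative delta-Ct** scores a gene by the mean, over all other genes,
  of the across-sample SD of the pairwise Cq difference.
* **BestKeeper** scores by the raw SD of a gene's Cqs (and CV% = 100*SD/mean)
  and reports all-pairs Pearson correlations; SD > 1 is flagged against the
  method's recommended cutoff.
* **NormFinder** is a model-based variance decomposition into intra-group
  variability and shrunken inter-group deviations; the combined stability is
  low only when both are low, which protects against co-regulated genes.
* **GeNorm** computes the same mean pairwise SD (its M value) but excludes
  the worst gene and recomputes iteratively until two genes remain; the
  final-pair M is checked against the accepted cutoff of 1.5.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import CqMatrix

__all__ = [
    "StabilityResult",
    "delta_ct_stability",
    "bestkeeper",
    "normfinder",
    "genorm",
    "genorm_set_stability",
    "compare_normalization_factors",
    "run_method",
    "STABILITY_METHODS",
    "BESTKEEPER_SD_CUTOFF",
    "GENORM_M_CUTOFF",
]

BESTKEEPER_SD_CUTOFF = 1.0
GENORM_M_CUTOFF = 1.5


@dataclass
class StabilityResult:
    """Per-gene stability values and ranking for one method."""

    method: str
    values: pd.Series           # gene -> stability value
    ranking: list               # most stable first
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.values < -1e-12).any():
            raise ValueError("stability values must be >= 0")


def _as_values(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, CqMatrix) else pd.DataFrame(matrix)


def _mean_pairwise_sd(values: pd.DataFrame) -> pd.Series:
    """For each gene, mean over other genes of SD(Cq_g - Cq_h) across samples."""
    genes = list(values.columns)
    x = values.to_numpy()
    out = {}
    for i, g in enumerate(genes):
        sds = [np.std(x[:, i] - x[:, j], ddof=1) for j in range(len(genes)) if j != i]
        out[g] = float(np.mean(sds))
    return pd.Series(out)


def _rank(values: pd.Series) -> list:
    # stable sort: ties keep input gene order
    return list(values.sort_values(kind="stable").index)


def delta_ct_stability(matrix) -> StabilityResult:
    """Comparative delta-Ct method: mean pairwise SD of Cq differences."""
    values = _as_values(matrix)
    if values.shape[1] < 3:
        raise ValueError("comparative delta-Ct needs >= 3 genes")
    if values.shape[0] < 3:
        raise ValueError("comparative delta-Ct needs >= 3 samples")
    v = _mean_pairwise_sd(values)
    return StabilityResult("deltact", v, _rank(v))


def bestkeeper(matrix) -> StabilityResult:
    """BestKeeper descriptives: per-gene SD, CV% and all-pairs correlations.

    Extras carry the CV% series and ranking, the gene x gene Pearson r and
    p-value matrices, and the genes flagged above the SD cutoff of 1 cycle.
    """
    values = _as_values(matrix)
    if values.shape[1] < 2 or values.shape[0] < 3:
        raise ValueError("BestKeeper needs >= 2 genes and >= 3 samples")
    sd = values.std(ddof=1)
    mean = values.mean()
    if (mean == 0).any():
        raise ValueError("zero-mean Cq column: CV undefined")
    cv = 100.0 * sd / mean
    genes = list(values.columns)
    r = pd.DataFrame(np.eye(len(genes)), index=genes, columns=genes)
    p = pd.DataFrame(np.zeros((len(genes), len(genes))), index=genes, columns=genes)
    for a, b in itertools.combinations(genes, 2):
        res = stats.pearsonr(values[a], values[b])
        r.loc[a, b] = r.loc[b, a] = res.statistic
        p.loc[a, b] = p.loc[b, a] = res.pvalue
    extras = {
        "cv_percent": cv,
        "ranking_cv": _rank(cv),
        "pearson_r": r,
        "pearson_p": p,
        "sd_cutoff": BESTKEEPER_SD_CUTOFF,
        "flagged_genes": list(sd.index[sd > BESTKEEPER_SD_CUTOFF]),
    }
    return StabilityResult("bestkeeper", sd, _rank(sd), extras)


def _normfinder_components(values: pd.DataFrame, groups: pd.Series):
    """Sample-centered per-group gene deviations and within-group SDs.

    Returns (d, sigma, n) all indexed gene x group: d is the raw inter-group
    deviation of the sample-centered Cq, sigma the within-group SD, n the
    group size.
    """
    centered = values.sub(values.mean(axis=1), axis=0)
    glabels = sorted(groups.unique())
    d = pd.DataFrame(index=values.columns, columns=glabels, dtype=float)
    sigma = pd.DataFrame(index=values.columns, columns=glabels, dtype=float)
    n = pd.Series(index=glabels, dtype=float)
    overall = centered.mean()
    for gl in glabels:
        sub = centered[groups.values == gl]
        if len(sub) < 2:
            raise ValueError(f"group {gl!r} has fewer than 2 samples")
        n[gl] = len(sub)
        d[gl] = sub.mean() - overall
        sigma[gl] = sub.std(ddof=1)
    return d, sigma, n


def normfinder(matrix, groups=None) -> StabilityResult:
    """Model-based stability combining intra- and inter-group variation.

    Per-sample means are removed (they carry loading/RT differences common
    to all genes), leaving per-gene per-group deviations ``d_gj`` and
    within-group SDs ``sigma_gj``.  Deviations are shrunken toward zero by
    their signal-to-noise ratio, ``d~ = d * gamma^2 / (gamma^2 +
    sigma^2/n)`` with ``gamma^2`` the across-group variance of ``d``.  The
    stability of gene g is ``mean_j(|d~_gj| + sigma_gj/sqrt(n_j))``; the
    reported intra-/inter-group variations (Table-4 shape) are
    ``mean_j sigma_gj`` and ``mean_j |d~_gj|``.  The best two-gene
    combination minimizes the analogous pair quantity with pair deviation
    ``(d~_g + d~_h)/2`` and pair variance ``(sigma_g^2 + sigma_h^2)/4``.
    """
    values = _as_values(matrix)
    if groups is None:
        if not isinstance(matrix, CqMatrix):
            raise ValueError("groups required when matrix is a bare DataFrame")
        groups = matrix.groups
    groups = pd.Series(np.asarray(groups), index=values.index)
    if values.shape[1] < 3:
        raise ValueError("NormFinder needs >= 3 genes")
    if groups.nunique() < 2:
        raise ValueError("NormFinder needs >= 2 groups")

    d, sigma, n = _normfinder_components(values, groups)
    gamma2 = d.var(axis=1, ddof=1)
    noise = sigma.pow(2).div(n, axis=1)
    denom = noise.add(gamma2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = (gamma2.to_numpy()[:, None] / denom.to_numpy())
    factor = np.nan_to_num(factor, nan=0.0)
    d_shrunk = pd.DataFrame(d.to_numpy() * factor, index=d.index, columns=d.columns)

    intra = sigma.mean(axis=1)
    inter = d_shrunk.abs().mean(axis=1)
    rho = (d_shrunk.abs() + sigma.div(np.sqrt(n), axis=1)).mean(axis=1)

    best_pair, best_pair_value = None, np.inf
    for a, b in itertools.combinations(values.columns, 2):
        pair_d = (d_shrunk.loc[a] + d_shrunk.loc[b]) / 2.0
        pair_sd = np.sqrt((sigma.loc[a] ** 2 + sigma.loc[b] ** 2) / 4.0)
        val = float((pair_d.abs() + pair_sd / np.sqrt(n)).mean())
        if val < best_pair_value:
            best_pair, best_pair_value = (a, b), val

    group_variation = pd.DataFrame({"intra_group": intra, "inter_group": inter})
    extras = {
        "group_variation": group_variation,
        "best_gene": _rank(rho)[0],
        "best_pair": best_pair,
        "best_pair_value": best_pair_value,
        "deviations": d_shrunk,
        "group_sizes": n,
    }
    return StabilityResult("normfinder", rho, _rank(rho), extras)


def genorm(matrix) -> StabilityResult:
    """GeNorm: iterative exclusion of the gene with the highest M value.

    M_g is the mean pairwise SD over the *current* gene set; the gene with
    the highest M is removed (ties broken by removing the gene later in
    input order, logged in extras) and M recomputed, until two genes remain.
    ``values`` holds each gene's M at its removal round (the final pair
    shares the final-round M).  The final-pair M is compared with the
    accepted cutoff of 1.5.
    """
    values = _as_values(matrix)
    if values.shape[1] < 3:
        raise ValueError("GeNorm needs >= 3 genes")
    current = list(values.columns)
    removal_order, removal_m, ties = [], {}, []
    round1 = _mean_pairwise_sd(values)
    while len(current) > 2:
        m = _mean_pairwise_sd(values[current])
        worst_val = m.max()
        worst_candidates = [g for g in current if m[g] == worst_val]
        if len(worst_candidates) > 1:
            ties.append(list(worst_candidates))
        worst = worst_candidates[-1]  # later in input order
        removal_order.append(worst)
        removal_m[worst] = float(m[worst])
        current.remove(worst)
    final_m = float(_mean_pairwise_sd(values[current]).iloc[0])
    for g in current:
        removal_m[g] = final_m
    ranking = list(current) + list(reversed(removal_order))
    vals = pd.Series({g: removal_m[g] for g in values.columns})
    extras = {
        "exclusion_order": removal_order,
        "final_pair": tuple(current),
        "final_pair_m": final_m,
        "m_cutoff": GENORM_M_CUTOFF,
        "final_pair_acceptable": final_m < GENORM_M_CUTOFF,
        "round1_m": round1,
        "ties": ties,
    }
    return StabilityResult("genorm", vals, ranking, extras)


def genorm_set_stability(matrix, genes) -> float:
    """Mean M value of a supplied gene set (set-wise stability of a combo)."""
    values = _as_values(matrix)[list(genes)]
    if values.shape[1] < 2:
        raise ValueError("need >= 2 genes")
    return float(_mean_pairwise_sd(values).mean())


def compare_normalization_factors(matrix: CqMatrix, target_matrix: pd.DataFrame,
                                  combos, efficiencies=None,
                                  sex_column: str = "sex") -> pd.DataFrame:
    """SD of normalized target Cqs under different reference combinations.

    For each combo the normalization factor is the arithmetic mean of the
    combo genes' (optionally efficiency-corrected) Cqs — the Cq-scale
    equivalent of the geometric mean of linear quantities — subtracted from
    each target Cq.  Reported per combo, averaged over target genes:
    the mean within-group SD, the SD of group means (inter-group), and the
    within-sex-group SDs.
    """
    from .normalize import efficiency_correct

    if any(len(c) == 0 for c in combos):
        raise ValueError("empty reference combo")
    ref_vals = matrix.values
    tgt = pd.DataFrame(target_matrix).loc[ref_vals.index]
    if efficiencies is not None:
        ref_vals = ref_vals.apply(lambda col: efficiency_correct(col, efficiencies[col.name]))
        tgt = tgt.apply(lambda col: efficiency_correct(col, efficiencies[col.name]))
    groups = matrix.groups
    sexes = matrix.meta[sex_column] if sex_column in matrix.meta else None

    rows = []
    for combo in combos:
        nf = ref_vals[list(dict.fromkeys(combo))].mean(axis=1)
        dcq = tgt.sub(nf, axis=0)
        intra = dcq.groupby(groups.values).std(ddof=1).mean().mean()
        inter = dcq.groupby(groups.values).mean().std(ddof=1).mean()
        row = {"combo": " + ".join(combo), "avg_intragroup_sd": float(intra),
               "avg_intergroup_sd": float(inter)}
        if sexes is not None:
            for sx, sub in dcq.groupby(sexes.values):
                row[f"avg_{sx}_group_sd"] = float(sub.std(ddof=1).mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("combo")


def _bestkeeper_sd(matrix):
    return bestkeeper(matrix)


STABILITY_METHODS = {
    "deltact": delta_ct_stability,
    "bestkeeper": _bestkeeper_sd,
    "normfinder": normfinder,
    "genorm": genorm,
}


def run_method(name: str, matrix) -> StabilityResult:
    """Run one stability method by registry name."""
    try:
        fn = STABILITY_METHODS[name]
    except KeyError:
        raise ValueError(f"unknown stability method {name!r}; "
                         f"choose from {sorted(STABILITY_METHODS)}") from None
    return fn(matrix)
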