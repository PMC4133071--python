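"""Replicate QC, interplate calibration, duplicate averaging, descriptives.

The processing order is calibrate -> filter -> average: plate offsets are
removed at replicate level first so they cannot inflate within-pair Cq
deltas, then samples failing replicate consistency are dropped whole, then
duplicates are averaged into a complete samples x genes matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "CqMatrix",
    "filter_replicates",
    "interplate_calibrate",
    "average_replicates",
    "describe",
    "preprocess_cq",
]

GROUP_KEY = "group"


@dataclass
class CqMatrix:
    """Calibrated, replicate-averaged Cq values with sample metadata.

    ``values`` is samples x genes (cycles); ``meta`` is indexed by sample
    with at least ``age_dpf`` and ``temperature`` columns (optionally
    ``sex``).  The experimental group key is age x temperature.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.meta = self.meta.loc[self.values.index]
        if self.values.isna().any().any():
            raise ValueError("CqMatrix must be complete (no missing cells)")

    @property
    def genes(self) -> list:
        return list(self.values.columns)

    @property
    def groups(self) -> pd.Series:
        return (self.meta["age_dpf"].astype(str) + "_"
                + self.meta["temperature"].astype(str)).rename(GROUP_KEY)

    def subset(self, samples) -> "CqMatrix":
        return CqMatrix(self.values.loc[samples], self.meta.loc[samples],
                        dict(self.provenance))

    def select_genes(self, genes) -> "CqMatrix":
        return CqMatrix(self.values[list(genes)], self.meta, dict(self.provenance))


def _cal_mask(records: pd.DataFrame) -> pd.Series:
    if "is_calibrator" in records:
        return records["is_calibrator"].astype(bool)
    return pd.Series(False, index=records.index)


def _check_unique_keys(records: pd.DataFrame) -> None:
    dup = records.duplicated(subset=["sample", "gene", "replicate", "plate"])
    if dup.any():
        keys = records.loc[dup, ["sample", "gene", "replicate"]].head()
        raise ValueError(f"duplicate (sample, gene, replicate) keys, e.g.\n{keys}")


def filter_replicates(records: pd.DataFrame, max_delta: float = 1.0,
                      genes=None):
    """Drop whole samples with missing Cqs or replicate range > ``max_delta``.

    A sample is removed across *all* genes as soon as any gene of the QC
    panel (default: every gene present) has a within-reaction Cq range above
    ``max_delta`` cycles, or *any* gene at all has a missing replicate Cq —
    a reaction without a Cq is unusable whatever panel the consistency rule
    covers.  Calibrator rows are passed through untouched.  Returns
    ``(kept_records, report)`` where the report lists each removed sample
    with the offending gene and reason.
    """
    _check_unique_keys(records)
    mask = _cal_mask(records)
    cal = records[mask]
    data = records[~mask]
    panel = set(genes) if genes is not None else set(data["gene"])

    reasons = []
    for (sample, gene), sub in data.groupby(["sample", "gene"], sort=True):
        vals = sub["cq"]
        if vals.isna().any():
            reasons.append({"sample": sample, "gene": gene, "reason": "missing_cq",
                            "delta": np.nan})
        elif gene in panel:
            delta = float(vals.max() - vals.min())
            if delta > max_delta:
                reasons.append({"sample": sample, "gene": gene,
                                "reason": "replicate_delta", "delta": delta})
    report = pd.DataFrame(reasons, columns=["sample", "gene", "reason", "delta"])
    bad = set(report["sample"])
    kept = pd.concat([data[~data["sample"].isin(bad)], cal], ignore_index=True)
    return kept, report


def interplate_calibrate(records: pd.DataFrame, calibrator_ids=None) -> pd.DataFrame:
    """Remove per-plate Cq offsets using interplate calibrator samples.

    For each plate and gene the offset is the plate mean of the calibrator
    Cqs minus their overall mean across plates; it is subtracted from every
    Cq on that plate for that gene, so each gene's calibrator means become
    identical across plates.  The operation is idempotent and preserves
    within-plate Cq differences exactly.
    """
    _check_unique_keys(records)
    if calibrator_ids is None:
        if "is_calibrator" not in records:
            raise ValueError("need calibrator_ids or an is_calibrator column")
        calibrator_ids = sorted(records.loc[records["is_calibrator"] == True, "sample"].unique())  # noqa: E712
    cal = records[records["sample"].isin(calibrator_ids)]
    if cal.empty:
        raise ValueError("no calibrator records found")

    out = records.copy()
    for gene, sub in cal.groupby("gene"):
        plates = set(out.loc[out["gene"] == gene, "plate"].unique())
        have = set(sub["plate"].unique())
        missing = plates - have
        if missing:
            raise ValueError(
                f"plate(s) {sorted(missing)} have no calibrator Cqs for gene {gene}")
        overall = sub["cq"].mean()
        offsets = sub.groupby("plate")["cq"].mean() - overall
        sel = out["gene"] == gene
        out.loc[sel, "cq"] = out.loc[sel, "cq"] - out.loc[sel, "plate"].map(offsets).to_numpy()
    return out


def average_replicates(records: pd.DataFrame, meta: pd.DataFrame) -> CqMatrix:
    """Average replicate Cqs into a samples x genes matrix with metadata."""
    data = records[~_cal_mask(records)]
    values = data.pivot_table(index="sample", columns="gene", values="cq",
                              aggfunc="mean")
    meta_idx = meta.set_index("sample") if "sample" in meta.columns else meta
    missing = values.index.difference(meta_idx.index)
    if len(missing):
        raise ValueError(f"samples lacking metadata: {list(missing)[:5]}")
    values.columns.name = None
    return CqMatrix(values, meta_idx.loc[values.index])


def describe(matrix: CqMatrix) -> pd.DataFrame:
    """Per-gene N, mean, SD, min, max and normality p-value.

    SD is the sample standard deviation (n-1).  Normality is tested with the
    Kolmogorov-Smirnov statistic with estimated parameters (Lilliefors);
    constant columns get a NaN p-value rather than an error.  The test
    variant is recorded in the ``ks_test`` attribute of the result.
    """
    if len(matrix.values) < 3:
        raise ValueError("need at least 3 samples for descriptive statistics")
    rows = []
    for g in matrix.genes:
        col = matrix.values[g].to_numpy()
        if np.std(col) == 0 or len(col) < 4:  # test undefined: NaN, not an error
            p = np.nan
        else:
            _, p = lilliefors(col, dist="norm")
        rows.append({"gene": g, "N": len(col), "mean": col.mean(),
                     "sd": col.std(ddof=1), "min_cq": col.min(),
                     "max_cq": col.max(), "ks_p": p})
    out = pd.DataFrame(rows).set_index("gene")
    out.attrs["ks_test"] = "lilliefors (KS with estimated parameters)"
    return out


def preprocess_cq(records: pd.DataFrame, meta: pd.DataFrame,
                  max_delta: float = 1.0, genes=None):
    """Full preprocessing: calibrate, QC-filter, average.  Returns (matrix, report)."""
    calibrated = interplate_calibrate(records)
    kept, report = filter_replicates(calibrated, max_delta=max_delta, genes=genes)
    matrix = average_replicates(kept, meta)
    matrix.provenance.update({"max_delta": max_delta,
                              "n_removed_samples": int(report["sample"].nunique())})
    return matrix, report
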