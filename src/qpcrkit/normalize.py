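"""Efficiency correction and reference-gene normalization of target Cqs.

Efficiency correction rescales each Cq onto the perfect-doubling scale:
``Cq_corrected = Cq * log(E) / log(2)``, so that one corrected cycle always
represents one two-fold change in template.  Corrected target Cqs are then
normalized by the arithmetic mean of the (corrected) reference-gene Cqs —
the Cq-scale equivalent of dividing by the geometric mean of linear
quantities — and mean-centered per target gene.  With all E = 2 the whole
pipeline reduces to classic delta-Cq normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import CqMatrix

__all__ = [
    "NormalizedExpression",
    "efficiency_correct",
    "normalize_targets",
    "group_summary",
]


@dataclass
class NormalizedExpression:
    """Samples x targets efficiency-corrected, normalized, centered delta-Cqs."""

    values: pd.DataFrame
    meta: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        centered = self.values.mean()
        if (centered.abs() > 1e-9).any():
            raise ValueError("per-gene mean must be 0 after centering")
        if not {"efficiency_method", "reference_combo"} <= set(self.provenance):
            raise ValueError("provenance must name efficiency_method and reference_combo")

    @property
    def groups(self) -> pd.Series:
        return (self.meta["age_dpf"].astype(str) + "_"
                + self.meta["temperature"].astype(str)).rename("group")


def efficiency_correct(cq, e: float):
    """Rescale Cq by ``log(E)/log(2)``; E = 2 is the identity.

    ``cq`` may be a scalar, array or Series; E must lie in (1, 2] — an
    amplification factor at or below 1 means no amplification and admits no
    correction.
    """
    if not np.isfinite(e) or e <= 1.0:
        raise ValueError(f"amplification factor must be > 1, got {e}")
    if e > 2.0:
        raise ValueError(f"amplification factor must be <= 2, got {e}")
    return cq * (np.log(e) / np.log(2.0))


def normalize_targets(target_matrix, reference_matrix, combo,
                      efficiencies=None, method: str = "none") -> NormalizedExpression:
    """Efficiency-correct then normalize target Cqs by a reference combo.

    ``delta_Cq[t, s] = corr(Cq[t, s]) - mean_r corr(Cq[r, s])`` over the
    combo genes, followed by per-target mean-centering across samples.
    ``efficiencies`` maps gene -> per-gene mean amplification factor; when
    omitted every gene uses E = 2 (no correction).
    """
    if not combo:
        raise ValueError("reference combo must be non-empty")
    combo = list(dict.fromkeys(combo))
    ref = reference_matrix.values if isinstance(reference_matrix, CqMatrix) else pd.DataFrame(reference_matrix)
    tgt = pd.DataFrame(target_matrix.values if isinstance(target_matrix, CqMatrix) else target_matrix)
    tgt = tgt.loc[ref.index]
    eff = efficiencies if efficiencies is not None else {}
    for g in list(tgt.columns) + combo:
        if efficiencies is not None and g not in eff:
            raise ValueError(f"no amplification factor supplied for gene {g!r}")

    def corr(col):
        return efficiency_correct(col, eff.get(col.name, 2.0))

    tgt_c = tgt.apply(corr)
    ref_c = ref[combo].apply(corr)
    dcq = tgt_c.sub(ref_c.mean(axis=1), axis=0)
    dcq = dcq - dcq.mean()
    meta = reference_matrix.meta if isinstance(reference_matrix, CqMatrix) else pd.DataFrame(index=ref.index)
    return NormalizedExpression(
        dcq, meta,
        provenance={"efficiency_method": method,
                    "reference_combo": tuple(combo),
                    "centering": "per-target mean over all samples, after normalization"})


def group_summary(norm: NormalizedExpression, grouping: str) -> pd.DataFrame:
    """Per (target gene, group) mean and SD of normalized delta-Cqs.

    ``grouping`` is a metadata column name ("temperature", "sex", ...) or
    "group" for the age x temperature key.  Groups with fewer than two
    samples report NaN SD.
    """
    if grouping == "group":
        key = norm.groups
    elif grouping in norm.meta.columns:
        key = norm.meta[grouping]
    else:
        raise ValueError(f"grouping column {grouping!r} not in metadata")
    rows = []
    for gl, sub in norm.values.groupby(key.values):
        for gene in norm.values.columns:
            col = sub[gene]
            rows.append({"gene": gene, grouping: gl, "n": len(col),
                         "mean": float(col.mean()),
                         "sd": float(col.std(ddof=1)) if len(col) > 1 else np.nan})
    return pd.DataFrame(rows).set_index(["gene", grouping]).sort_index()
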