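"""Synthetic qPCR data with known ground truth.

Two independent generators mirror the two halves of a relative-qPCR study:

* :func:`simulate_cq_dataset` draws quantification-cycle (Cq) tables directly
  on the cycle (log2-quantity) scale, with an additive variance structure —
  per-gene baseline, shared per-sample loading effect, per-group regulation
  offsets, latent co-regulation effects, per-plate offsets and technical
  noise — so that reference-gene stability methods can be validated against
  genes that are stable or regulated *by construction*.
* :func:`simulate_amp_curve` produces raw per-cycle fluorescence traces from
  a mechanistic recursion in which the per-cycle amplification factor decays
  as the product approaches the plateau, so single-reaction efficiency
  estimators can be scored against a known amplification factor ``E0``.

The default :class:`StudyDesign` reproduces a fish gonad development
design: 8 sampling ages (30-135 days post fertilization) x 3 rearing
temperatures x 10 fish = 240 samples, 6 candidate reference genes and 6
sex-differentiation target genes, duplicate reactions, and 3 interplate
calibrator samples run in triplicate on every plate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "REFERENCE_GENES",
    "TARGET_GENES",
    "StudyDesign",
    "CqTruth",
    "CurveTruth",
    "AmpCurve",
    "simulate_cq_dataset",
    "simulate_amp_curve",
    "simulate_curve_set",
    "default_truth",
    "make_fixture_suite",
]

REFERENCE_GENES = ["RPS4", "RPL17", "GAPDH", "ACTB", "UBQ", "B2M"]
TARGET_GENES = ["CYP19a", "AMH", "SOX9", "SOX19", "SOX17", "VASA"]

DEFAULT_AGES = [30, 45, 60, 75, 90, 105, 120, 135]
DEFAULT_TEMPERATURES = ["Low", "Normal", "High"]


@dataclass
class StudyDesign:
    """Factorial sampling design of a gonad-development qPCR study."""

    ages: list = field(default_factory=lambda: list(DEFAULT_AGES))
    temperatures: list = field(default_factory=lambda: list(DEFAULT_TEMPERATURES))
    samples_per_cell: int = 10
    reference_genes: list = field(default_factory=lambda: list(REFERENCE_GENES))
    target_genes: list = field(default_factory=lambda: list(TARGET_GENES))
    replicates_per_reaction: int = 2
    plates: int = 3
    calibrators: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ages or not self.temperatures:
            raise ValueError("ages and temperatures must be non-empty")
        if self.samples_per_cell < 2:
            raise ValueError("samples_per_cell must be >= 2")
        if not self.reference_genes:
            raise ValueError("reference_genes must be non-empty")
        if self.replicates_per_reaction < 1 or self.plates < 1:
            raise ValueError("replicates_per_reaction and plates must be >= 1")

    @property
    def genes(self) -> list:
        return list(self.reference_genes) + list(self.target_genes)

    @property
    def n_groups(self) -> int:
        return len(self.ages) * len(self.temperatures)

    @property
    def n_samples(self) -> int:
        return self.n_groups * self.samples_per_cell


@dataclass
class CqTruth:
    """Latent variance structure behind a simulated Cq table.

    All quantities are in cycles.  ``baseline`` is the per-gene expected Cq
    for an average sample; ``loading_sd`` is the SD of a per-sample effect
    shared by every gene (RNA input / RT yield); ``tech_sd`` is per-gene
    replicate noise; ``group_offsets[gene][(age, temperature)]`` shifts one
    experimental group (a regulated gene); ``sex_offsets[gene][sex]`` shifts
    one sex; ``coreg`` entries ``(gene_a, gene_b, sd)`` add a shared latent
    normal effect to both genes; ``plate_offsets[plate]`` is a fixed
    between-run shift removed later by interplate calibration.

    ``gene_sample_sd`` is gene-specific per-sample biological/assay
    variation shared by both replicates of a reaction (what actually
    separates unstable from stable genes); ``failure_rate`` is the per
    replicate probability of a failed read, which is either a missing Cq or
    a wild value 1.2-3 cycles off (split by ``failure_missing_frac``) — the
    events the replicate-consistency filter is designed to catch.
    """

    baseline: dict
    tech_sd: dict
    loading_sd: float = 0.8
    gene_sample_sd: dict = field(default_factory=dict)
    group_offsets: dict = field(default_factory=dict)
    sex_offsets: dict = field(default_factory=dict)
    coreg: list = field(default_factory=list)
    plate_offsets: dict = field(default_factory=dict)
    failure_rate: float = 0.0
    failure_missing_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.loading_sd < 0:
            raise ValueError("loading_sd must be >= 0")
        if not (0.0 <= self.failure_rate < 1.0):
            raise ValueError("failure_rate must be in [0, 1)")
        for g, sd in list(self.tech_sd.items()) + list(self.gene_sample_sd.items()):
            if sd < 0:
                raise ValueError(f"per-gene SD for {g} must be >= 0")
        for a, b, sd in self.coreg:
            if sd < 0:
                raise ValueError(f"co-regulation sd for ({a}, {b}) must be >= 0")


def default_truth(design: StudyDesign | None = None) -> CqTruth:
    """Truth emulating realistic Cq scales of a fish gonad panel.

    Reference-gene baselines and dispersions sit on the scale of the study's
    descriptive statistics (mean Cq 15.9-21.2, SD 1.1-1.7); B2M carries
    temperature regulation (the consistently least stable gene) and is
    co-regulated with VASA; UBQ and RPS4 share a latent effect (their high
    mutual correlation).  Targets are strongly regulated: CYP19a is
    sex-dimorphic, several targets respond to temperature.
    """
    design = design or StudyDesign()
    baseline = {
        "RPS4": 21.2, "RPL17": 18.4, "GAPDH": 20.2,
        "ACTB": 15.9, "UBQ": 18.3, "B2M": 19.5,
        "CYP19a": 31.9, "AMH": 26.3, "SOX9": 24.8,
        "SOX19": 26.6, "SOX17": 29.4, "VASA": 26.2,
    }
    tech_sd = {g: 0.15 for g in baseline}
    gene_sample_sd = {
        "RPS4": 1.2, "RPL17": 1.05, "GAPDH": 1.2,
        "ACTB": 0.75, "UBQ": 0.55, "B2M": 0.8,
        "CYP19a": 2.5, "AMH": 1.8, "SOX9": 1.3,
        "SOX19": 1.8, "SOX17": 2.0, "VASA": 2.2,
    }
    group_offsets: dict = {}

    def temp_offset(gene: str, by_temp: dict) -> None:
        group_offsets[gene] = {
            (age, t): by_temp.get(t, 0.0) for age in design.ages for t in design.temperatures
        }

    # Mild drift of GAPDH with age, temperature regulation of B2M; targets
    # regulated more strongly (they are differentiation genes, Table-2-scale
    # dispersions arise mostly from this regulation).
    temp_offset("B2M", {"Low": -0.8, "High": 0.9})
    group_offsets["GAPDH"] = {
        (age, t): 0.004 * (age - 82.5) for age in design.ages for t in design.temperatures
    }
    temp_offset("CYP19a", {"Low": 1.2, "High": -1.5})
    temp_offset("AMH", {"Low": -1.6, "High": 0.8})
    temp_offset("SOX19", {"Low": 1.8, "High": -0.9})
    temp_offset("SOX9", {"Low": -0.7, "High": 0.5})
    temp_offset("SOX17", {"Low": 0.6, "High": 0.8})
    temp_offset("VASA", {"Low": -0.5, "High": 1.4})
    sex_offsets = {
        "CYP19a": {"F": -3.0, "M": 3.0},
        "AMH": {"F": 1.0, "M": -1.0},
        "SOX9": {"F": 0.9, "M": -0.9},
        "SOX19": {"F": -2.5, "M": 2.5},
        "SOX17": {"F": -1.2, "M": 1.2},
        "VASA": {"F": -0.3, "M": 0.3},
    }
    coreg = [("UBQ", "RPS4", 0.45), ("VASA", "B2M", 0.9), ("RPS4", "GAPDH", 0.35)]
    plate_offsets = {p: off for p, off in zip(range(1, design.plates + 1),
                                              np.linspace(-0.3, 0.3, design.plates))}
    keep = set(design.genes)
    return CqTruth(
        baseline={g: v for g, v in baseline.items() if g in keep},
        tech_sd={g: v for g, v in tech_sd.items() if g in keep},
        gene_sample_sd={g: v for g, v in gene_sample_sd.items() if g in keep},
        loading_sd=0.8,
        failure_rate=0.01,
        group_offsets={g: v for g, v in group_offsets.items() if g in keep},
        sex_offsets={g: v for g, v in sex_offsets.items() if g in keep},
        coreg=[(a, b, sd) for a, b, sd in coreg if a in keep and b in keep],
        plate_offsets=plate_offsets,
    )


def simulate_cq_dataset(design: StudyDesign, truth: CqTruth | None = None):
    """Draw a replicate-level Cq table plus metadata and latent-truth tables.

    Returns ``(records, meta, latent)``:

    * ``records``: one row per sample x gene x replicate with columns
      ``sample, gene, replicate, plate, cq, is_calibrator``.  Calibrator
      samples appear on *every* plate (run in triplicate) with the same
      latent value, so interplate calibration can recover plate offsets.
    * ``meta``: ``sample, age_dpf, temperature, sex`` for study samples.
    * ``latent``: per sample x gene the noise-free Cq components.
    """
    truth = truth or default_truth(design)
    missing = [g for g in design.genes if g not in truth.baseline]
    if missing:
        raise ValueError(f"truth lacks baselines for genes: {missing}")
    rng = np.random.default_rng(design.seed)

    rows_meta = []
    i = 0
    for age in design.ages:
        for temp in design.temperatures:
            for _ in range(design.samples_per_cell):
                i += 1
                rows_meta.append(
                    {"sample": f"S{i:03d}", "age_dpf": age, "temperature": temp,
                     "sex": "F" if rng.random() < 0.5 else "M"}
                )
    meta = pd.DataFrame(rows_meta)

    n = len(meta)
    loading = rng.normal(0.0, truth.loading_sd, size=n)
    coreg_draws = {
        (a, b): rng.normal(0.0, sd, size=n) for a, b, sd in truth.coreg
    }
    # sample-maximization layout: consecutive samples fill plates in order
    plate_of = np.minimum(np.arange(n) * design.plates // max(n, 1), design.plates - 1) + 1

    latent_rows = []
    rec_rows = []
    for si, row in meta.iterrows():
        for g in design.genes:
            mu = truth.baseline[g] + loading[si]
            mu += truth.group_offsets.get(g, {}).get((row["age_dpf"], row["temperature"]), 0.0)
            mu += truth.sex_offsets.get(g, {}).get(row["sex"], 0.0)
            gs_sd = truth.gene_sample_sd.get(g, 0.0)
            if gs_sd > 0:
                mu += rng.normal(0.0, gs_sd)
            for (a, b), draws in coreg_draws.items():
                if g in (a, b):
                    mu += draws[si]
            plate = int(plate_of[si])
            latent_rows.append({"sample": row["sample"], "gene": g, "latent_cq": mu,
                                "plate": plate})
            for r in range(1, design.replicates_per_reaction + 1):
                cq = mu + truth.plate_offsets.get(plate, 0.0)
                cq += rng.normal(0.0, truth.tech_sd[g])
                if truth.failure_rate > 0 and rng.random() < truth.failure_rate:
                    if rng.random() < truth.failure_missing_frac:
                        cq = np.nan
                    else:
                        cq += rng.choice([-1.0, 1.0]) * rng.uniform(1.2, 3.0)
                rec_rows.append({"sample": row["sample"], "gene": g, "replicate": r,
                                 "plate": plate, "cq": cq, "is_calibrator": False})

    # interplate calibrators: fixed latent value, run in triplicate on every plate
    for ci in range(1, design.calibrators + 1):
        cal_loading = rng.normal(0.0, truth.loading_sd)
        for g in design.genes:
            mu = truth.baseline[g] + cal_loading
            latent_rows.append({"sample": f"CAL{ci}", "gene": g, "latent_cq": mu,
                                "plate": 0})
            for plate in range(1, design.plates + 1):
                for r in range(1, 4):
                    cq = mu + truth.plate_offsets.get(plate, 0.0)
                    cq += rng.normal(0.0, truth.tech_sd[g])
                    rec_rows.append({"sample": f"CAL{ci}", "gene": g, "replicate": r,
                                     "plate": plate, "cq": cq, "is_calibrator": True})

    records = pd.DataFrame(rec_rows)
    latent = pd.DataFrame(latent_rows)
    return records, meta, latent


@dataclass
class CurveTruth:
    """Ground truth for one simulated amplification curve.

    ``e0`` is the amplification factor at the single-molecule limit (2 =
    perfect doubling); ``f0`` the product signal at cycle 1 and ``fmax`` the
    plateau, both in fluorescence units of the instrument scale; the optical
    baseline is ``baseline + drift * cycle`` with additive Gaussian noise.
    """

    e0: float = 1.9
    f0: float = 0.05
    fmax: float = 30000.0
    baseline: float = 3000.0
    drift: float = 5.0
    noise_sd: float = 30.0
    cycles: int = 40

    def __post_init__(self) -> None:
        if not (1.0 < self.e0 <= 2.0):
            raise ValueError("e0 must be in (1, 2]")
        if self.f0 <= 0 or self.fmax <= self.f0:
            raise ValueError("need 0 < f0 < fmax")
        if self.cycles < 25:
            raise ValueError("cycles must be >= 25")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class AmpCurve:
    """One reaction's raw fluorescence trace (no baseline correction)."""

    cycles: np.ndarray
    fluorescence: np.ndarray
    sample: str = ""
    gene: str = ""
    true_e0: float | None = None

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.cycles) != len(self.fluorescence):
            raise ValueError("cycles and fluorescence lengths differ")
        if len(self.cycles) < 25:
            raise ValueError("need >= 25 cycles")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence must be finite")


def simulate_amp_curve(truth: CurveTruth, rng: np.random.Generator | None = None,
                       sample: str = "", gene: str = "") -> AmpCurve:
    """Mechanistic raw-fluorescence curve with efficiency decaying to plateau.

    Product follows ``N_c = N_{c-1} * E_c`` with per-cycle amplification
    factor ``E_c = 1 + (e0 - 1) * (1 - N_{c-1}/fmax)``: growth is geometric
    at ``e0`` while product is scarce and stalls as reagents (dye) deplete.
    Observed fluorescence adds a linearly drifting optical baseline and
    Gaussian read noise.
    """
    rng = rng or np.random.default_rng()
    n = np.empty(truth.cycles)
    n[0] = truth.f0
    for c in range(1, truth.cycles):
        e_c = 1.0 + (truth.e0 - 1.0) * (1.0 - n[c - 1] / truth.fmax)
        n[c] = n[c - 1] * e_c
    cycles = np.arange(1, truth.cycles + 1, dtype=float)
    f = n + truth.baseline + truth.drift * cycles
    if truth.noise_sd > 0:
        f = f + rng.normal(0.0, truth.noise_sd, size=truth.cycles)
    return AmpCurve(cycles, f, sample=sample, gene=gene, true_e0=truth.e0)


def simulate_curve_set(e0_values, n_per_e0: int, seed: int, *,
                       truth_kwargs: dict | None = None) -> list:
    """Batch of mechanistic curves, ``n_per_e0`` reactions per amplification factor."""
    rng = np.random.default_rng(seed)
    out = []
    kw = dict(truth_kwargs or {})
    for e0 in e0_values:
        truth = CurveTruth(e0=e0, **kw)
        for i in range(n_per_e0):
            out.append(simulate_amp_curve(truth, rng, sample=f"E{e0:.2f}_{i+1}",
                                          gene=f"G{e0:.2f}"))
    return out


def _toy_design(seed: int) -> StudyDesign:
    return StudyDesign(ages=[30, 60], temperatures=["Low", "High"],
                       samples_per_cell=8, reference_genes=list("ABCDEF"),
                       target_genes=[], replicates_per_reaction=2, plates=2,
                       calibrators=2, seed=seed)


def stable_panel_truth(genes, shifted_gene: str | None = None,
                       offset: float = 1.5, group=None,
                       tech_sd: float = 0.2, loading_sd: float = 0.6) -> CqTruth:
    """Panel of construction-stable genes, optionally one carrying a group offset."""
    truth = CqTruth(baseline={g: 20.0 + i for i, g in enumerate(genes)},
                    tech_sd={g: tech_sd for g in genes},
                    loading_sd=loading_sd)
    if shifted_gene is not None:
        truth.group_offsets[shifted_gene] = {group: offset}
    return truth


def make_fixture_suite(seed: int, outdir) -> dict:
    """Write a deterministic bundle of small CSV fixtures under ``outdir``.

    Contents: a toy replicate-level Cq dataset ("toy"), a six-gene panel
    where exactly one gene carries a 1.5-cycle offset in one group
    ("stable5_shifted1"), and 300 mechanistic curves (100 per true
    amplification factor in {1.80, 1.90, 2.00}).  Identical seed gives
    byte-identical files.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    design = _toy_design(seed)
    toy_truth = stable_panel_truth(design.reference_genes)
    toy_truth.plate_offsets = {1: -0.4, 2: 0.4}
    records, meta, latent = simulate_cq_dataset(design, toy_truth)
    for name, df in [("toy_records", records), ("toy_meta", meta), ("toy_truth", latent)]:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6f")
        paths[name] = p

    shift_design = _toy_design(seed + 1)
    shift_truth = stable_panel_truth(shift_design.reference_genes, shifted_gene="F",
                                     group=(30, "High"))
    records, meta, latent = simulate_cq_dataset(shift_design, shift_truth)
    offsets = pd.DataFrame(
        [{"gene": g, "group": f"{a}_{t}",
          "offset": shift_truth.group_offsets.get(g, {}).get((a, t), 0.0)}
         for g in shift_design.reference_genes
         for a in shift_design.ages for t in shift_design.temperatures]
    )
    for name, df in [("stable5_shifted1_records", records),
                     ("stable5_shifted1_meta", meta),
                     ("stable5_shifted1_offsets", offsets)]:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6f")
        paths[name] = p

    curves = simulate_curve_set([1.80, 1.90, 2.00], 100, seed + 2)
    rows = []
    for wi, c in enumerate(curves, start=1):
        for cyc, f in zip(c.cycles, c.fluorescence):
            rows.append({"well": f"W{wi:03d}", "sample": c.sample, "gene": c.gene,
                         "true_e0": c.true_e0, "cycle": int(cyc), "fluorescence": f})
    p = outdir / "curves_e0_panel.csv"
    pd.DataFrame(rows).to_csv(p, index=False, float_format="%.4f")
    paths["curves_e0_panel"] = p
    return paths


def curves_from_table(df: pd.DataFrame) -> list:
    """Rebuild :class:`AmpCurve` objects from a long-format curve table."""
    out = []
    for well, sub in df.groupby("well", sort=True):
        sub = sub.sort_values("cycle")
        out.append(AmpCurve(sub["cycle"].to_numpy(), sub["fluorescence"].to_numpy(),
                            sample=str(sub["sample"].iloc[0]), gene=str(sub["gene"].iloc[0]),
                            true_e0=float(sub["true_e0"].iloc[0]) if "true_e0" in sub else None))
    return out
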