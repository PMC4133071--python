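"""Simulate a full gonad-development qPCR study and preprocess it.

The default design is 8 sampling ages x 3 rearing temperatures x 10 fish =
240 samples, 6 candidate reference genes + 6 target genes measured in
duplicate across 3 plates, with 3 interplate calibrator samples run in
triplicate on every plate.  Preprocessing removes plate offsets with the
calibrators, drops samples whose duplicates disagree by more than one cycle
(or lack a Cq), and averages duplicates into a complete matrix.
"""

import qpcrkit as qk

design = qk.StudyDesign(seed=1)
truth = qk.simdata.default_truth(design)
records, meta, latent = qk.simulate_cq_dataset(design, truth)
print(f"simulated {meta.shape[0]} samples x {len(design.genes)} genes "
      f"({len(records)} replicate-level rows incl. calibrators)")

matrix, report = qk.preprocess_cq(records, meta, max_delta=1.0,
                                  genes=design.reference_genes)
print(f"QC removed {report['sample'].nunique()} samples "
      f"({dict(report['reason'].value_counts())}); kept {matrix.values.shape[0]}")

stats = qk.describe(matrix.select_genes(design.reference_genes))
print("\nDescriptive statistics of the reference genes "
      f"[{stats.attrs['ks_test']}]:")
print(stats.round(3).to_string())
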