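"""Rank candidate reference genes with four stability methods.

Comparative delta-Ct, BestKeeper, NormFinder and GeNorm are run on the same
preprocessed matrix; each returns a per-gene stability value (lower = more
stable) and a ranking.  The normalization-factor comparison then shows how
the SD of normalized target Cqs changes with the chosen reference combo.
"""

import pandas as pd

import qpcrkit as qk

design = qk.StudyDesign(seed=1)
records, meta, _ = qk.simulate_cq_dataset(design, qk.simdata.default_truth(design))
matrix, _ = qk.preprocess_cq(records, meta, genes=design.reference_genes)
refs = matrix.select_genes(design.reference_genes)

table = {}
for name in ("deltact", "bestkeeper", "normfinder", "genorm"):
    res = qk.stability.run_method(name, refs)
    table[name] = pd.Series({g: f"{res.values[g]:.3f} (#{res.ranking.index(g)+1})"
                             for g in refs.genes})
print("stability value (rank) per method:")
print(pd.DataFrame(table).to_string())

gn = qk.genorm(refs)
print(f"\nGeNorm final pair: {gn.extras['final_pair']} "
      f"M = {gn.extras['final_pair_m']:.3f} "
      f"(cutoff {gn.extras['m_cutoff']}, acceptable = {gn.extras['final_pair_acceptable']})")
nf = qk.normfinder(refs)
print(f"NormFinder best gene: {nf.extras['best_gene']}; "
      f"best pair: {nf.extras['best_pair']} "
      f"(value {nf.extras['best_pair_value']:.3f})")
bk = qk.bestkeeper(refs)
print(f"BestKeeper genes above SD cutoff {bk.extras['sd_cutoff']}: "
      f"{bk.extras['flagged_genes']}")

combos = [["UBQ"], ["UBQ", "RPS4"], ["UBQ", "RPS4", "RPL17"], ["B2M"]]
nf_table = qk.compare_normalization_factors(
    refs, matrix.values[design.target_genes], combos)
print("\nSD of normalized target Cqs by reference combo:")
print(nf_table.round(3).to_string())
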