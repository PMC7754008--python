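"""Call ceRNA sponge pairs and export the lncRNA-miRNA-mRNA network.

Every differential lncRNA x differential gene pair is scored by (P1) the
hypergeometric significance of their shared differential miRNAs and (P2)
the significance of their expression correlation; the two are combined by
Fisher's method and BH-adjusted.  A pair passes at FDR <= 5% with >= 10
shared miRNAs and pair correlation r > 0.25.
"""

import pandas as pd

from spongenet import diffexpr, sponge
from spongenet.io_formats import write_sif
from spongenet.synthdata import SimConfig, generate_dataset

config = SimConfig(seed=4, n_samples_per_group=15, n_mrna=300, n_lncrna=100,
                   n_mirna=500, n_de_per_class=20, planted_lfc=1.5,
                   n_modules=0, n_triplets=5, shared_mirnas_per_triplet=12,
                   module_strength=0.9)
matrices, sheet, targets, truth = generate_dataset(config)

de = {cls: diffexpr.run_de(matrices[cls], sheet) for cls in matrices}
expr = pd.concat([diffexpr.log2_expression(matrices[cls]) for cls in matrices])
pairs = sponge.call_sponge_pairs(de["lncrna"], de["mrna"], de["mirna"],
                                 expr, targets)

passing = pairs[pairs["passes"]]
print(f"{len(pairs)} candidate pairs, {len(passing)} passing")
print(passing[["lncrna_id", "gene_id", "k", "corr_r", "fdr"]].round(4).head())
print("planted pairs:", [(t.lncrna, t.mrna) for t in truth.triplets])

# mediators of the best pair, ranked by differential p-value, and SIF export
best = passing.iloc[0]
med = sponge.rank_mediators(best, de["mirna"], expr, k_top=20)
print(f"top mediators of {best['lncrna_id']}-{best['gene_id']}:")
print(med.round(4).head())
net = sponge.assemble_network(pairs, {(best["lncrna_id"], best["gene_id"]): med})
write_sif(net, "scratch_network.sif")
print(f"wrote {len(net.sif_edges())} SIF edges (2 per mediating miRNA)")
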