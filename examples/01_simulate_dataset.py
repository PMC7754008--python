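"""Generate a synthetic two-group multi-omics study with recorded truth.

The generator emulates a small bulk RNA-seq comparison of normal vs
placenta percreta (PP) tissue across three RNA classes, planting
differential features, co-expression modules and ceRNA triplets whose
identities are recorded for later scoring.
"""

from spongenet.synthdata import SimConfig, generate_dataset

config = SimConfig(seed=1, n_samples_per_group=4, n_mrna=500, n_lncrna=200,
                   n_mirna=150, n_de_per_class=20, n_modules=2,
                   module_size=50, n_triplets=4, shared_mirnas_per_triplet=12)
matrices, sheet, targets, truth = generate_dataset(config)

for cls, cm in matrices.items():
    print(f"{cls:7s} counts: {cm.n_features} features x {cm.n_samples} samples")
print(f"target map: {len(targets)} miRNA-target edges, "
      f"{len(targets.universe)} miRNAs")
print(f"planted: {sum(len(v) for v in truth.de_features.values())} DE features, "
      f"{len(set(truth.module_assignments.values()))} modules, "
      f"{len(truth.triplets)} ceRNA triplets")
t = truth.triplets[0]
print(f"first triplet: {t.lncrna} <-> {t.mrna} share {len(t.shared_mirnas)} miRNAs")
# Counts are negative-binomial with log-normal per-sample depth; every
# planted id above is what downstream recovery is scored against.
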