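"""Calibration and recovery benchmarks run on the synthetic generator.

These routines define the package's standard evaluation conditions:

* ``null_pass_fraction`` — specificity of the sponge-pair caller when the
  generator plants nothing: the fraction of enumerated candidate pairs
  called passing should sit at or below the nominal FDR.
* ``module_recovery`` — adjusted Rand index between planted module labels
  and detected modules, averaged over seeds.
* ``triplet_recovery`` — recall/precision of planted ceRNA triplet groups
  against decoy pairs, averaged over seeds.

Benchmark problem sizes keep planted features a minority of each RNA class;
median-of-ratios normalization assumes most features are unchanged, and a
generator that violates that assumption would test the wrong thing.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from . import coexpr, diffexpr, sponge
from .synthdata import SimConfig, generate_dataset

# Study conditions for the three benchmarks (see docs for rationale).
NULL_CONFIG = SimConfig(
    n_samples_per_group=4, n_mrna=150, n_lncrna=100, n_mirna=100,
    n_de_per_class=0, planted_lfc=0.0, n_modules=0, n_triplets=0,
    decoy_target_density=0.1,
)
MODULE_CONFIG = SimConfig(
    n_samples_per_group=20, n_mrna=500, n_lncrna=20, n_mirna=20,
    n_de_per_class=0, n_modules=3, module_size=50, module_strength=0.9,
    n_triplets=0,
)
TRIPLET_CONFIG = SimConfig(
    n_samples_per_group=15, n_mrna=300, n_lncrna=100, n_mirna=500,
    n_de_per_class=20, planted_lfc=1.5, n_modules=0, n_triplets=10,
    shared_mirnas_per_triplet=12, module_strength=0.9,
    decoy_target_density=0.02,
)


def _seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def adjusted_rand_index(labels_a: list, labels_b: list) -> float:
    """Adjusted Rand index between two labelings of the same items."""
    if len(labels_a) != len(labels_b):
        raise ValueError("labelings must cover the same items")
    pairs: dict[tuple, int] = {}
    count_a: dict[object, int] = {}
    count_b: dict[object, int] = {}
    for a, b in zip(labels_a, labels_b):
        pairs[(a, b)] = pairs.get((a, b), 0) + 1
        count_a[a] = count_a.get(a, 0) + 1
        count_b[b] = count_b.get(b, 0) + 1
    n = len(labels_a)
    sum_ab = sum(math.comb(c, 2) for c in pairs.values())
    sum_a = sum(math.comb(c, 2) for c in count_a.values())
    sum_b = sum(math.comb(c, 2) for c in count_b.values())
    total = math.comb(n, 2)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ab - expected) / (max_index - expected)


def null_pass_fraction(n_replicates: int = 200, base_seed: int = 0,
                       config: SimConfig = NULL_CONFIG) -> dict:
    """Fraction of enumerated sponge pairs called passing with no plants.

    Returns the mean fraction over replicates, its Monte-Carlo standard
    error, and the total pairs enumerated.
    """
    fractions = []
    total_pairs = 0
    for seed in _seeds(base_seed, n_replicates):
        cfg = replace(config, seed=seed)
        matrices, sheet, targets, _ = generate_dataset(cfg)
        de = {c: diffexpr.run_de(matrices[c], sheet) for c in matrices}
        expr = pd.concat([diffexpr.log2_expression(matrices[c]) for c in matrices])
        pairs = sponge.call_sponge_pairs(de["lncrna"], de["mrna"], de["mirna"],
                                         expr, targets)
        total_pairs += len(pairs)
        if len(pairs):
            fractions.append(float(pairs["passes"].mean()))
        else:
            fractions.append(0.0)
    fractions = np.asarray(fractions)
    se = float(fractions.std(ddof=1) / np.sqrt(len(fractions))) if len(fractions) > 1 else 0.0
    return {"mean_fraction": float(fractions.mean()), "mc_se": se,
            "n_replicates": n_replicates, "total_pairs": total_pairs}


def module_recovery(n_seeds: int = 20, base_seed: int = 0,
                    config: SimConfig = MODULE_CONFIG, beta: int = 6) -> dict:
    """Mean adjusted Rand index of detected vs planted modules.

    ARI is computed over the planted module genes (background genes carry
    no true label).  Uses the default soft-threshold power.
    """
    aris = []
    for seed in _seeds(base_seed, n_seeds):
        cfg = replace(config, seed=seed)
        matrices, _sheet, _targets, truth = generate_dataset(cfg)
        expr = diffexpr.log2_expression(matrices["mrna"])
        corr = coexpr.correlation_matrix(expr)
        adj = coexpr.adjacency(corr, beta=beta)
        tom = coexpr.tom_similarity(adj)
        labels = coexpr.detect_modules(tom)
        planted = sorted(truth.module_assignments)
        true = [truth.module_assignments[g] for g in planted]
        pred = labels.loc[planted].tolist()
        aris.append(adjusted_rand_index(true, pred))
    return {"mean_ari": float(np.mean(aris)), "min_ari": float(np.min(aris)),
            "n_seeds": n_seeds}


def triplet_recovery(n_seeds: int = 20, base_seed: int = 0,
                     config: SimConfig = TRIPLET_CONFIG) -> dict:
    """Mean recall and precision of planted ceRNA pairs among decoys."""
    recalls, precisions, n_pairs = [], [], []
    for seed in _seeds(base_seed, n_seeds):
        cfg = replace(config, seed=seed)
        matrices, sheet, targets, truth = generate_dataset(cfg)
        de = {c: diffexpr.run_de(matrices[c], sheet) for c in matrices}
        expr = pd.concat([diffexpr.log2_expression(matrices[c]) for c in matrices])
        pairs = sponge.call_sponge_pairs(de["lncrna"], de["mrna"], de["mirna"],
                                         expr, targets)
        passing = set(zip(pairs.loc[pairs["passes"], "lncrna_id"],
                          pairs.loc[pairs["passes"], "gene_id"]))
        planted = {(t.lncrna, t.mrna) for t in truth.triplets}
        recalls.append(len(passing & planted) / len(planted))
        precisions.append(len(passing & planted) / len(passing) if passing else 1.0)
        n_pairs.append(len(pairs))
    return {
        "mean_recall": float(np.mean(recalls)),
        "mean_precision": float(np.mean(precisions)),
        "mean_pairs_enumerated": float(np.mean(n_pairs)),
        "n_seeds": n_seeds,
    }
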