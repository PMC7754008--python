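"""Synthetic multi-omics generator with planted, recorded structure.

Emulates the statistical shape of a small two-group bulk RNA-seq study of
placental tissue (normal vs placenta percreta): negative-binomial counts
for three RNA classes (protein-coding, lncRNA, miRNA), per-sample depth
multipliers, planted differential features, planted co-expression modules
whose eigengene tracks the condition, and planted lncRNA-miRNA-mRNA ceRNA
triplets in which the lncRNA and mRNA share many miRNAs, co-vary positively,
and move opposite to their mediators across conditions.  Every plant is
recorded in a :class:`GroundTruth` so downstream inference can be scored.

Noise model
-----------
Counts are NB(mu, phi) with variance ``mu + phi * mu**2``.  Per-feature
baseline means are log-normal around ``baseline_mean`` (sigma 0.5 on the
natural log scale) so expression spans a realistic dynamic range; per-sample
depth multipliers are log-normal(0, 0.1).  All planted signals act on the
log2 mean (exponential link), keeping counts non-negative integers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, SampleSheet, TargetMap

# per-feature baseline spread (natural-log sd) and sample depth spread
_FEATURE_MEAN_SIGMA = 0.5
_SIZE_FACTOR_SIGMA = 0.1


class ConfigurationError(ValueError):
    """Raised when a SimConfig is internally inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated study.

    Defaults mirror the study design being emulated: 4 + 4 samples,
    differential features planted at |log2 fold change| = 1 (the screening
    floor), ceRNA triplets sharing 10+ miRNAs.
    """

    n_samples_per_group: int = 4
    n_mrna: int = 500
    n_lncrna: int = 200
    n_mirna: int = 150
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    n_de_per_class: int = 20
    planted_lfc: float = 1.5
    n_modules: int = 2
    module_size: int = 50
    module_strength: float = 0.8
    module_trait_loading: float = 0.5
    n_triplets: int = 4
    shared_mirnas_per_triplet: int = 12
    decoy_target_density: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_per_group < 1:
            raise ConfigurationError("need at least one sample per group")
        for name in ("n_mrna", "n_lncrna", "n_mirna"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ConfigurationError("baseline_mean and dispersion must be positive")
        if self.n_de_per_class < 0 or self.n_modules < 0 or self.n_triplets < 0:
            raise ConfigurationError("plant counts must be non-negative")
        if not (0 <= self.module_strength < 1):
            raise ConfigurationError("module_strength must be in [0, 1)")
        if not (0 <= self.module_trait_loading <= 1):
            raise ConfigurationError("module_trait_loading must be in [0, 1]")
        if not (0 <= self.decoy_target_density <= 1):
            raise ConfigurationError("decoy_target_density must be in [0, 1]")
        if self.n_modules * self.module_size > self.n_mrna:
            raise ConfigurationError("module genes exceed n_mrna")
        if self.n_triplets and self.shared_mirnas_per_triplet > self.n_mirna:
            raise ConfigurationError("shared_mirnas_per_triplet exceeds n_mirna")
        # triplet members and module genes must not collide with each other
        if self.n_triplets + self.n_modules * self.module_size + self.n_de_per_class > self.n_mrna:
            raise ConfigurationError("planted mRNA features exceed n_mrna")
        if self.n_triplets + self.n_de_per_class > self.n_lncrna:
            raise ConfigurationError("planted lncRNA features exceed n_lncrna")
        if self.n_triplets * self.shared_mirnas_per_triplet + self.n_de_per_class > self.n_mirna:
            raise ConfigurationError("planted miRNA features exceed n_mirna")


@dataclass
class Triplet:
    lncrna: str
    mrna: str
    shared_mirnas: list[str]


@dataclass
class GroundTruth:
    """Record of every planted signal, keyed by generated feature ids.

    ``de_features`` holds only the generically planted differential
    features per class; module genes and triplet members are recorded in
    their own sections (they are differential by construction too, but
    keeping the sections disjoint keeps recovery scoring unambiguous).
    """

    de_features: dict[str, dict[str, float]] = field(default_factory=dict)
    module_assignments: dict[str, int] = field(default_factory=dict)
    triplets: list[Triplet] = field(default_factory=list)
    module_factors: dict[str, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "de_features": self.de_features,
            "module_assignments": self.module_assignments,
            "triplets": [asdict(t) for t in self.triplets],
            "module_factors": self.module_factors,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            de_features={c: dict(v) for c, v in d.get("de_features", {}).items()},
            module_assignments={g: int(m) for g, m in d.get("module_assignments", {}).items()},
            triplets=[Triplet(t["lncrna"], t["mrna"], list(t["shared_mirnas"]))
                      for t in d.get("triplets", [])],
            module_factors={m: list(map(float, f))
                            for m, f in d.get("module_factors", {}).items()},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return (
            self.de_features == other.de_features
            and self.module_assignments == other.module_assignments
            and [(t.lncrna, t.mrna, sorted(t.shared_mirnas)) for t in self.triplets]
            == [(t.lncrna, t.mrna, sorted(t.shared_mirnas)) for t in other.triplets]
            and self.module_factors == other.module_factors
        )


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        return GroundTruth.from_dict(json.load(fh))


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(max(n - 1, 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate_dataset(
    config: SimConfig,
) -> tuple[dict[str, CountMatrix], SampleSheet, TargetMap, GroundTruth]:
    """Simulate one study: three count matrices, sample sheet, targets, truth.

    Deterministic given ``config.seed``: each RNA class and the target map
    draw from their own substream spawned from the master seed, so partial
    re-runs reproduce exactly.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(ss) for name, ss in
               zip(("mrna", "lncrna", "mirna", "targets", "factors"), master.spawn(5))}

    n_per = config.n_samples_per_group
    n_samples = 2 * n_per
    sample_ids = [f"N{i+1}" for i in range(n_per)] + [f"PP{i+1}" for i in range(n_per)]
    groups = ["normal"] * n_per + ["PP"] * n_per
    case = np.array([g == "PP" for g in groups])
    # standardized condition indicator: -1 normal, +1 PP
    x = np.where(case, 1.0, -1.0)

    ids = {
        "mrna": _ids("G", config.n_mrna),
        "lncrna": _ids("L", config.n_lncrna),
        "mirna": _ids("M", config.n_mirna),
    }

    # ---- assign planted roles (deterministic block layout) ----
    truth = GroundTruth(de_features={c: {} for c in ids})
    # triplet members occupy the head of each class, then module genes, then DE plants
    trip_lnc = ids["lncrna"][: config.n_triplets]
    trip_mrna = ids["mrna"][: config.n_triplets]
    trip_mirnas = [
        ids["mirna"][i * config.shared_mirnas_per_triplet:(i + 1) * config.shared_mirnas_per_triplet]
        for i in range(config.n_triplets)
    ]
    module_genes: dict[int, list[str]] = {}
    offset = config.n_triplets
    for m in range(config.n_modules):
        genes = ids["mrna"][offset + m * config.module_size: offset + (m + 1) * config.module_size]
        module_genes[m] = genes
        for g in genes:
            truth.module_assignments[g] = m
    de_start = {
        "mrna": config.n_triplets + config.n_modules * config.module_size,
        "lncrna": config.n_triplets,
        "mirna": config.n_triplets * config.shared_mirnas_per_triplet,
    }
    for cls in ids:
        for j in range(config.n_de_per_class):
            fid = ids[cls][de_start[cls] + j]
            lfc = config.planted_lfc if j % 2 == 0 else -config.planted_lfc
            truth.de_features[cls][fid] = lfc
    for i in range(config.n_triplets):
        truth.triplets.append(Triplet(trip_lnc[i], trip_mrna[i], list(trip_mirnas[i])))

    # ---- latent factors ----
    frng = streams["factors"]
    module_factors = {}
    for m in range(config.n_modules):
        eps = frng.standard_normal(n_samples)
        tl = config.module_trait_loading
        module_factors[m] = tl * x + np.sqrt(max(1 - tl**2, 0.0)) * eps
        truth.module_factors[str(m)] = [float(v) for v in module_factors[m]]
    triplet_factors = {i: frng.standard_normal(n_samples) for i in range(config.n_triplets)}
    size_mult = np.exp(frng.normal(0.0, _SIZE_FACTOR_SIGMA, n_samples))

    # ---- per-class log2 signal matrices ----
    def signal_matrix(cls: str) -> np.ndarray:
        sig = np.zeros((len(ids[cls]), n_samples))
        index = {fid: i for i, fid in enumerate(ids[cls])}
        for fid, lfc in truth.de_features[cls].items():
            sig[index[fid], case] += lfc
        if cls == "mrna":
            for m, genes in module_genes.items():
                for g in genes:
                    sig[index[g]] += config.module_strength * module_factors[m]
        for i, trip in enumerate(truth.triplets):
            f = triplet_factors[i]
            if cls == "lncrna":
                sig[index[trip.lncrna]] += config.module_strength * f
                sig[index[trip.lncrna], case] += config.planted_lfc
            elif cls == "mrna":
                sig[index[trip.mrna]] += config.module_strength * f
                sig[index[trip.mrna], case] += config.planted_lfc
            else:
                for mir in trip.shared_mirnas:
                    sig[index[mir]] -= 0.5 * config.module_strength * f
                    sig[index[mir], case] -= config.planted_lfc
        return sig

    matrices: dict[str, CountMatrix] = {}
    for cls in ("mrna", "lncrna", "mirna"):
        rng = streams[cls]
        base = config.baseline_mean * np.exp(
            rng.normal(0.0, _FEATURE_MEAN_SIGMA, len(ids[cls]))
        )
        mu = base[:, None] * size_mult[None, :] * np.exp2(signal_matrix(cls))
        # NB(mu, phi): shape r = 1/phi, success prob r / (r + mu)
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
        matrices[cls] = CountMatrix(
            counts=pd.DataFrame(counts, index=ids[cls], columns=sample_ids),
            rna_class=cls,
        )

    sheet = SampleSheet(table=pd.DataFrame({"sample_id": sample_ids, "group": groups}))

    # ---- target map: planted triplet edges plus uniform decoys ----
    trng = streams["targets"]
    edges: set[tuple[str, str, str]] = set()
    for trip in truth.triplets:
        for mir in trip.shared_mirnas:
            edges.add((mir, trip.lncrna, "lncrna"))
            edges.add((mir, trip.mrna, "mrna"))
    planted = set(edges)
    all_targets = [(t, "mrna") for t in ids["mrna"]] + [(t, "lncrna") for t in ids["lncrna"]]
    if config.decoy_target_density > 0:
        draw = trng.random((len(ids["mirna"]), len(all_targets)))
        hit = draw < config.decoy_target_density
        for i, j in zip(*hit.nonzero()):
            edge = (ids["mirna"][i], all_targets[j][0], all_targets[j][1])
            if edge not in planted:
                edges.add(edge)
    targets = TargetMap(edges)

    return matrices, sheet, targets, truth
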