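"""End-to-end orchestration: simulate/load -> DE x3 -> WGCNA -> sponge -> hubs.

A single :class:`RunConfig` (YAML-friendly) drives every stage; one seed
governs all randomness; a machine-readable manifest records thresholds,
per-stage output counts and SHA-256 hashes of every written file, so a
re-run with the same config and seed is byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import coexpr, diffexpr, hubs, sponge
from .io_formats import (
    CountMatrix,
    SampleSheet,
    TargetMap,
    read_count_matrix,
    read_gmt,
    read_sample_sheet,
    read_target_map,
    write_count_matrix,
    write_json,
    write_sample_sheet,
    write_sif,
    write_target_map,
)
from .synthdata import ConfigurationError, SimConfig, generate_dataset, write_truth

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; exactly one of ``simulate`` /
    ``inputs`` must be set."""

    seed: int = 0
    simulate: dict | None = None          # SimConfig fields
    inputs: dict | None = None            # paths: mrna, lncrna, mirna, samples, targets[, gmt]
    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    min_shared: int = 10
    min_r: float = 0.25
    fdr: float = 0.05
    r_cutoff: float = 0.5
    k_top: int = 20
    rank_key: str = "p_value"
    sponge_universe: str = "de"
    beta: int | None = None
    signed: bool = False
    min_module_size: int = 30
    cut_height: float = 0.995
    r2_target: float = 0.8
    anchors: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of 'simulate' or 'inputs' must be configured"
            )
        if not (0 < self.p_threshold < 1) or not (0 < self.fdr < 1):
            raise ConfigurationError("p and FDR thresholds must be in (0, 1)")
        if self.lfc_threshold < 0 or self.min_shared < 0 or self.k_top < 1:
            raise ConfigurationError("thresholds out of range")
        if self.rank_key not in ("p_value", "corr_r"):
            raise ConfigurationError(f"unknown rank_key {self.rank_key!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(cfg: RunConfig, out_dir: Path):
    if cfg.simulate is not None:
        sim = SimConfig(**{**cfg.simulate, "seed": cfg.seed})
        matrices, sheet, targets, truth = generate_dataset(sim)
        for cls, cm in matrices.items():
            write_count_matrix(cm, out_dir / f"counts_{cls}.tsv")
        write_sample_sheet(sheet, out_dir / "samples.tsv")
        write_target_map(targets, out_dir / "targets.tsv")
        write_truth(truth, out_dir / "truth.json")
        gmt = None
    else:
        paths = cfg.inputs
        required = {"mrna", "lncrna", "mirna", "samples", "targets"}
        missing = required - set(paths)
        if missing:
            raise ConfigurationError(f"missing input paths: {sorted(missing)}")
        matrices = {cls: read_count_matrix(paths[cls], cls)
                    for cls in ("mrna", "lncrna", "mirna")}
        sheet = read_sample_sheet(paths["samples"])
        targets = read_target_map(paths["targets"])
        gmt = read_gmt(paths["gmt"]) if "gmt" in paths else None
    return matrices, sheet, targets, gmt


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int | dict] = {}

    matrices, sheet, targets, gmt = _load_inputs(cfg, out)

    # ---- differential screening per class ----
    de: dict[str, pd.DataFrame] = {}
    expr_parts = []
    try:
        for cls, cm in matrices.items():
            table = diffexpr.run_de(cm, sheet, cfg.lfc_threshold, cfg.p_threshold)
            table.to_csv(out / f"de_{cls}.tsv", sep="\t", index_label="feature_id")
            de[cls] = table
            counts[f"de_{cls}"] = {
                "features": len(table),
                "up": int((table["call"] == "up").sum()),
                "down": int((table["call"] == "down").sum()),
            }
            expr_parts.append(diffexpr.log2_expression(cm))
    except Exception as exc:  # noqa: BLE001 - stage-named abort
        raise StageError("diffexpr", exc) from exc
    expr = pd.concat(expr_parts)
    if expr.index.duplicated().any():
        raise StageError("diffexpr", ValueError("feature ids collide across RNA classes"))
    trait = sheet.trait_vector(expr.columns)

    # ---- co-expression modules on differential coding genes ----
    try:
        de_genes = de["mrna"].index[de["mrna"]["p_value"] < cfg.p_threshold]
        partition = None
        if len(de_genes) >= 3:
            gene_expr = expr.loc[de_genes]
            beta = cfg.beta
            if beta is None and len(de_genes) < 20:
                beta = 6  # too few genes for a scale-free fit
            partition, fit = coexpr.run_wgcna(
                gene_expr, trait, beta=beta, signed=cfg.signed,
                min_module_size=cfg.min_module_size, cut_height=cfg.cut_height,
                r2_target=cfg.r2_target,
            )
            partition.labels.to_frame().to_csv(out / "modules.tsv", sep="\t",
                                               index_label="feature_id")
            partition.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t",
                                        index_label="module")
            partition.trait_correlations.to_csv(out / "module_trait.tsv", sep="\t",
                                                index_label="module")
            if fit is not None:
                fit.to_csv(out / "soft_threshold.tsv", sep="\t", index=False)
            counts["wgcna"] = {
                "genes": int(len(de_genes)),
                "modules": int((partition.labels != coexpr.UNASSIGNED)
                               .groupby(partition.labels).any().sum()),
            }
        else:
            counts["wgcna"] = {"genes": int(len(de_genes)), "modules": 0}
    except Exception as exc:  # noqa: BLE001
        raise StageError("coexpr", exc) from exc

    # ---- sponge pairs and ceRNA network ----
    try:
        thresholds = sponge.SpongeThresholds(
            min_shared=cfg.min_shared, min_r=cfg.min_r,
            fdr=cfg.fdr, de_p=cfg.p_threshold,
        )
        pairs = sponge.call_sponge_pairs(
            de["lncrna"], de["mrna"], de["mirna"], expr, targets,
            thresholds=thresholds, universe=cfg.sponge_universe,
        )
        pairs.to_csv(out / "sponge_pairs.tsv", sep="\t", index=False)
        mediators = {}
        med_rows = []
        for _, pair in pairs[pairs["passes"]].iterrows():
            med = sponge.rank_mediators(pair, de["mirna"], expr,
                                        k_top=cfg.k_top, rank_key=cfg.rank_key)
            mediators[(pair["lncrna_id"], pair["gene_id"])] = med
            med = med.assign(lncrna_id=pair["lncrna_id"], gene_id=pair["gene_id"])
            med_rows.append(med)
        med_table = (pd.concat(med_rows, ignore_index=True) if med_rows
                     else pd.DataFrame(columns=["mirna_id", "de_p", "r_lnc",
                                                "r_gene", "lncrna_id", "gene_id"]))
        med_table.to_csv(out / "mediators.tsv", sep="\t", index=False)
        network = sponge.assemble_network(pairs, mediators)
        write_sif(network, out / "cerna_network.sif")
        counts["sponge"] = {
            "pairs_enumerated": int(len(pairs)),
            "pairs_passing": int(pairs["passes"].sum()) if len(pairs) else 0,
            "triplets": len(network.triplets),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("sponge", exc) from exc

    # ---- hub selection ----
    try:
        anchors = list(cfg.anchors)
        if not anchors:
            anchors = _default_anchors(de["mrna"], partition, cfg.p_threshold)
        hub_summary = {}
        for anchor in anchors:
            candidates = de["mrna"].index[de["mrna"]["p_value"] < cfg.p_threshold].tolist()
            ranking = hubs.rank_correlated_partners(anchor, expr, candidates, cfg.k_top)
            ranking.partners.to_csv(out / f"hub_partners_{anchor}.tsv", sep="\t",
                                    index=False)
            venn = hubs.select_hub_lncrnas(anchor, de["lncrna"], expr,
                                           r_cutoff=cfg.r_cutoff, k_top=cfg.k_top,
                                           de_p_threshold=cfg.p_threshold)
            write_json(
                {"anchor": anchor, "by_p": venn.list_by_p,
                 "by_basemean": venn.list_by_basemean,
                 "intersection": sorted(venn.intersection)},
                out / f"hub_lncrnas_{anchor}.json",
            )
            hub_summary[anchor] = {"partners": len(ranking.partners),
                                   "hub_lncrnas": len(venn.intersection)}
        counts["hubs"] = hub_summary
    except Exception as exc:  # noqa: BLE001
        raise StageError("hubs", exc) from exc

    # ---- pathway over-representation (optional) ----
    if gmt is not None:
        try:
            universe = set(de["mrna"].index) & set().union(*(p.members for p in gmt))
            query = set(de["mrna"].index[de["mrna"]["call"] != "ns"]) & universe
            if query:
                enr = hubs.ora_enrichment(query, gmt, universe)
                enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                counts["enrichment"] = {"pathways_tested": len(enr)}
            else:
                counts["enrichment"] = {"pathways_tested": 0}
        except Exception as exc:  # noqa: BLE001
            raise StageError("enrichment", exc) from exc

    manifest = {
        "seed": cfg.seed,
        "config": {k: v for k, v in asdict(cfg).items()},
        "counts": counts,
        "files": {p.name: _sha256(p) for p in sorted(out.iterdir())
                  if p.name not in ("manifest.json", "run.log") and p.is_file()},
    }
    write_json(manifest, out / "manifest.json")
    logger.info("pipeline complete: %s", json.dumps(counts, sort_keys=True))
    return manifest


def _default_anchors(de_mrna: pd.DataFrame, partition, p_threshold: float) -> list[str]:
    """Two anchor genes: the most significant differential genes, preferring
    members of the module most correlated with the condition."""
    candidates = de_mrna[de_mrna["p_value"] < p_threshold]
    if partition is not None and partition.trait_correlations is not None \
            and len(partition.trait_correlations):
        tc = partition.trait_correlations
        best = tc["r"].abs().idxmax()
        members = partition.labels.index[partition.labels == best]
        in_module = candidates.loc[candidates.index.intersection(members)]
        if len(in_module) >= 2:
            candidates = in_module
    ordered = candidates.sort_values(by="p_value", kind="mergesort")
    return ordered.index[:2].tolist()
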