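"""Readers and writers for the on-disk artifacts of the pipeline.

Canonical table dialect is TSV (UTF-8, ``#`` comment lines ignored).
Feature identifiers are opaque strings; no identifier mapping is attempted.
All readers validate and reject malformed input rather than coercing it,
and every writer emits deterministically ordered rows so outputs are
byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

RNA_CLASSES = ("mrna", "mirna", "lncrna")
GROUPS = ("normal", "PP")


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class CountMatrix:
    """Raw integer counts for one RNA class, features x samples."""

    counts: pd.DataFrame  # index: feature ids, columns: sample ids
    rna_class: str

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise FormatError(f"unknown RNA class {self.rna_class!r}")
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids: {dups[:5]}")
        if self.counts.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        values = self.counts.to_numpy()
        if values.size and ((values < 0).any() or (values != values.astype(int)).any()):
            raise FormatError("counts must be non-negative integers")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class SampleSheet:
    """Sample-to-condition assignment for the two-group design."""

    table: pd.DataFrame  # columns: sample_id, group

    def __post_init__(self) -> None:
        required = {"sample_id", "group"}
        if not required.issubset(self.table.columns):
            raise FormatError(f"sample sheet needs columns {sorted(required)}")
        if self.table["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in sample sheet")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
        for g in GROUPS:
            if (self.table["group"] == g).sum() == 0:
                raise FormatError(f"group {g!r} has no samples")

    def samples_in(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "sample_id"].tolist()

    @property
    def case_ids(self) -> list[str]:
        return self.samples_in("PP")

    @property
    def control_ids(self) -> list[str]:
        return self.samples_in("normal")

    def trait_vector(self, sample_ids: Sequence[str]) -> pd.Series:
        """Binary condition per sample: 1 = PP (case), 0 = normal."""
        mapping = dict(zip(self.table["sample_id"], self.table["group"]))
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise FormatError(f"samples missing from sheet: {missing[:5]}")
        return pd.Series(
            [1 if mapping[s] == "PP" else 0 for s in sample_ids],
            index=list(sample_ids),
            name="trait",
        )


class TargetMap:
    """miRNA -> target interaction table with fast set views.

    ``universe`` is the set of all miRNA ids carrying at least one edge
    (optionally extended by the caller); queries for unknown ids return
    empty sets rather than raising.
    """

    def __init__(self, edges: Iterable[tuple[str, str, str]]):
        self.edges: set[tuple[str, str, str]] = set()
        self._targets_of: dict[str, set[str]] = {}
        self._mirnas_of: dict[str, set[str]] = {}
        for mirna, target, target_class in edges:
            if target_class not in ("mrna", "lncrna"):
                raise FormatError(f"unknown target class {target_class!r}")
            self.edges.add((mirna, target, target_class))
        for mirna, target, _cls in self.edges:
            self._targets_of.setdefault(mirna, set()).add(target)
            self._mirnas_of.setdefault(target, set()).add(mirna)

    @property
    def universe(self) -> set[str]:
        return set(self._targets_of)

    def targets_of(self, mirna: str) -> set[str]:
        return set(self._targets_of.get(mirna, set()))

    def mirnas_of(self, target: str) -> set[str]:
        return set(self._mirnas_of.get(target, set()))

    def __len__(self) -> int:
        return len(self.edges)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TargetMap) and self.edges == other.edges


@dataclass(frozen=True)
class PathwaySet:
    """One gene set (e.g. a KEGG pathway) from a GMT collection."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"pathway {self.name!r} has no members")


@dataclass
class CeRNANetwork:
    """lncRNA-miRNA-mRNA triplet edges for export.

    Each triplet carries the mediating miRNA's differential-expression p
    and its correlation to the two pair members.
    """

    triplets: list[dict] = field(default_factory=list)
    # keys: lncrna, mirna, mrna, mirna_de_p, r_lnc, r_mrna

    def sif_edges(self) -> list[tuple[str, str, str]]:
        edges = set()
        for t in self.triplets:
            edges.add((t["lncrna"], "lnc_mirna", t["mirna"]))
            edges.add((t["mirna"], "mirna_mrna", t["mrna"]))
        return sorted(edges)


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)


def read_count_matrix(path: str | Path, rna_class: str) -> CountMatrix:
    """Read a TSV count matrix: header of sample ids, first column feature ids."""
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    arr = raw.to_numpy()
    try:
        as_int = raw.astype("int64")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-integer count value ({exc})") from exc
    if (arr != as_int.to_numpy()).any():
        bad = [(str(raw.index[i]), str(raw.columns[j]))
               for i, j in zip(*(arr != as_int.to_numpy()).nonzero())]
        raise FormatError(f"{path}: non-integer counts at cells {bad[:3]}")
    if (as_int.to_numpy() < 0).any():
        bad = [(str(raw.index[i]), str(raw.columns[j]))
               for i, j in zip(*(as_int.to_numpy() < 0).nonzero())]
        raise FormatError(f"{path}: negative count at cells {bad[:3]}")
    cm = CountMatrix(counts=as_int, rna_class=rna_class)
    logger.info("read %s count matrix %s: %d features x %d samples",
                rna_class, path, cm.n_features, cm.n_samples)
    return cm


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="feature_id")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    table = _read_tsv(path)
    return SampleSheet(table=table)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_target_map(path: str | Path) -> TargetMap:
    """Read a 3-column TSV (mirna, target, class); duplicate rows collapse."""
    table = _read_tsv(path)
    expected = ["mirna", "target", "target_class"]
    if list(table.columns[:3]) != expected:
        raise FormatError(f"{path}: expected header {expected}, got {list(table.columns)}")
    tm = TargetMap(table[expected].itertuples(index=False, name=None))
    logger.info("read target map %s: %d edges, %d miRNAs", path, len(tm), len(tm.universe))
    return tm


def write_target_map(tm: TargetMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna\ttarget\ttarget_class\n")
        for mirna, target, cls in sorted(tm.edges):
            fh.write(f"{mirna}\t{target}\t{cls}\n")


def read_gmt(path: str | Path) -> list[PathwaySet]:
    """Read a GMT file: name TAB description TAB member TAB member..."""
    sets: list[PathwaySet] = []
    names: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >=3 fields")
            name, desc, *members = fields
            if name in names:
                raise FormatError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            names.add(name)
            sets.append(PathwaySet(name=name, description=desc,
                                   members=frozenset(m for m in members if m)))
    return sets


def write_gmt(sets: Sequence[PathwaySet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ps in sets:
            fh.write("\t".join([ps.name, ps.description, *sorted(ps.members)]) + "\n")


def write_sif(network: CeRNANetwork, path: str | Path) -> None:
    """Write a Cytoscape SIF export, one edge per line, lexicographic order."""
    with open(path, "w", encoding="utf-8") as fh:
        for source, interaction, target in network.sif_edges():
            fh.write(f"{source}\t{interaction}\t{target}\n")


def write_json(obj: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def setup_logging(level: int = logging.INFO) -> None:
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )
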