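"""Domain types and I/O for gene signatures and expression matrices.

The prognostic liver signature (PLS) partitions its member genes into a
*poor-prognosis* set (induced in livers at high risk of progressing to
hepatocellular carcinoma) and a *good-prognosis* set (suppressed in such
livers), accompanied by a small panel of housekeeping genes used for
per-sample normalization.  Two named versions exist: the full 186-gene
signature and a clinically streamlined 32-gene reduction; both run through
the identical pipeline.

Gene identifiers are matched case-sensitively after whitespace trimming.
No alias or ortholog mapping is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "PrognosticSignature",
    "ExpressionMatrix",
    "CoverageReport",
    "load_gene_sets",
    "write_gmt",
    "build_signature",
    "subset_signature",
    "match_matrix",
    "load_matrix",
    "load_sample_meta",
]


class GeneSetError(ValueError):
    """Malformed gene-set input (parse failure, empty set, overlap)."""


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered collection of unique gene identifiers."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise GeneSetError("gene set must have a non-empty name")
        genes = tuple(g.strip() for g in self.genes)
        if not genes:
            raise GeneSetError(f"gene set {self.name!r} is empty")
        if any(not g for g in genes):
            raise GeneSetError(f"gene set {self.name!r} contains blank identifiers")
        if len(set(genes)) != len(genes):
            seen: set[str] = set()
            deduped = tuple(g for g in genes if not (g in seen or seen.add(g)))
            logger.warning(
                "gene set %r: %d duplicate gene(s) removed",
                self.name,
                len(genes) - len(deduped),
            )
            genes = deduped
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass(frozen=True)
class PrognosticSignature:
    """Poor/good prognosis gene partition plus housekeeping panel.

    ``version`` labels the assay variant: ``full-186`` (the complete
    signature), ``reduced-32`` (the streamlined clinical panel) or
    ``custom``.  For the named versions ``|poor| + |good|`` must equal the
    declared size.
    """

    poor: GeneSet
    good: GeneSet
    housekeeping: GeneSet
    version: str = "custom"

    _DECLARED_SIZES = {"full-186": 186, "reduced-32": 32}

    def __post_init__(self) -> None:
        pg = set(self.poor.genes) & set(self.good.genes)
        if pg:
            raise GeneSetError(
                "poor and good sets overlap: " + ", ".join(sorted(pg))
            )
        hk = set(self.housekeeping.genes) & (set(self.poor.genes) | set(self.good.genes))
        if hk:
            raise GeneSetError(
                "housekeeping genes overlap prognosis sets: " + ", ".join(sorted(hk))
            )
        declared = self._DECLARED_SIZES.get(self.version)
        if declared is not None and len(self.poor) + len(self.good) != declared:
            raise GeneSetError(
                f"version {self.version!r} declares {declared} prognosis genes, "
                f"got {len(self.poor) + len(self.good)}"
            )

    @property
    def prognosis_genes(self) -> tuple[str, ...]:
        return self.poor.genes + self.good.genes

    @property
    def size(self) -> int:
        return len(self.poor) + len(self.good)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a scale flag and sample metadata.

    ``scale`` is ``"counts"`` (non-negative count-like values) or ``"log2"``.
    ``sample_meta`` is indexed by sample id; a ``condition`` column carries
    arm labels and further numeric columns carry per-sample covariates.
    """

    values: pd.DataFrame
    scale: str = "counts"
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("counts", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dups[:5])}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.scale == "counts" and (self.values.to_numpy() < 0).any():
            raise ValueError("count-scale matrix contains negative values")
        if self.sample_meta is not None:
            missing = self.values.columns.difference(self.sample_meta.index)
            if len(missing):
                raise ValueError(f"sample_meta missing samples: {list(missing[:5])}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_with_condition(self, condition: str) -> list[str]:
        if self.sample_meta is None or "condition" not in self.sample_meta:
            raise ValueError("matrix carries no condition labels")
        meta = self.sample_meta.loc[self.sample_ids]
        return list(meta.index[meta["condition"] == condition])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        meta = self.sample_meta.loc[list(samples)] if self.sample_meta is not None else None
        return ExpressionMatrix(self.values[list(samples)], scale=self.scale, sample_meta=meta)


@dataclass(frozen=True)
class CoverageReport:
    """Per-set presence of signature genes in a matrix."""

    found: Mapping[str, tuple[str, ...]]
    missing: Mapping[str, tuple[str, ...]]
    coverage: Mapping[str, float]


def _parse_gmt(path: Path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GeneSetError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), expected >= 3"
                )
            name, desc, *genes = fields
            genes = [g for g in (g.strip() for g in genes) if g]
            if not genes:
                raise GeneSetError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name=name.strip(), genes=tuple(genes), description=desc))
    return sets


def _parse_tsv_sets(path: Path) -> list[GeneSet]:
    # Two columns: set name, gene. An optional header is recognised by a
    # first cell naming the column rather than a set ("set", "name", ...).
    order: list[str] = []
    members: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise GeneSetError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            name, gene = fields[0].strip(), fields[1].strip()
            if lineno == 1 and name.lower() in {"set", "set_name", "name", "signature"}:
                continue
            if name not in members:
                members[name] = []
                order.append(name)
            members[name].append(gene)
    if not order:
        raise GeneSetError(f"{path}: no gene sets found")
    return [GeneSet(name=n, genes=tuple(members[n])) for n in order]


def load_gene_sets(path: str | Path, format: str | None = None) -> list[GeneSet]:
    """Load gene sets from a GMT or two-column TSV file.

    Duplicate genes within a record are removed with a warning; first-seen
    order is preserved.  ``format`` defaults to the file extension
    (``.gmt`` -> GMT, else TSV).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "gmt" if path.suffix.lower() == ".gmt" else "tsv"
    if format == "gmt":
        return _parse_gmt(path)
    if format == "tsv":
        return _parse_tsv_sets(path)
    raise ValueError(f"unknown gene-set format {format!r}")


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    """Write gene sets to a GMT file (tab-separated: name, description, genes)."""
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")


def build_signature(
    poor: GeneSet,
    good: GeneSet,
    housekeeping: GeneSet,
    version: str = "custom",
) -> PrognosticSignature:
    """Assemble a :class:`PrognosticSignature`, enforcing disjointness."""
    return PrognosticSignature(poor=poor, good=good, housekeeping=housekeeping, version=version)


def subset_signature(sig: PrognosticSignature, keep: Sequence[str]) -> PrognosticSignature:
    """Restrict a signature to ``keep``, preserving poor/good membership.

    Housekeeping genes are untouched.  The version label becomes
    ``reduced-32`` when exactly 32 genes are kept, ``custom`` otherwise.
    This mirrors the streamlining of the full signature to the clinical
    panel; the selection of *which* genes to keep is up to the caller.
    """
    keep_set = {g.strip() for g in keep}
    known = set(sig.poor.genes) | set(sig.good.genes)
    unknown = keep_set - known
    if unknown:
        raise GeneSetError(
            "kept genes absent from signature: " + ", ".join(sorted(unknown))
        )
    poor = tuple(g for g in sig.poor.genes if g in keep_set)
    good = tuple(g for g in sig.good.genes if g in keep_set)
    version = "reduced-32" if len(keep_set) == 32 else "custom"
    return PrognosticSignature(
        poor=replace(sig.poor, genes=poor),
        good=replace(sig.good, genes=good),
        housekeeping=sig.housekeeping,
        version=version,
    )


def match_matrix(sig: PrognosticSignature, m: ExpressionMatrix) -> CoverageReport:
    """Report which signature genes are present in a matrix, per set."""
    present = set(m.gene_ids)
    found: dict[str, tuple[str, ...]] = {}
    missing: dict[str, tuple[str, ...]] = {}
    coverage: dict[str, float] = {}
    for label, gs in (("poor", sig.poor), ("good", sig.good), ("housekeeping", sig.housekeeping)):
        f = tuple(g for g in gs.genes if g in present)
        found[label] = f
        missing[label] = tuple(g for g in gs.genes if g not in present)
        coverage[label] = len(f) / len(gs)
    return CoverageReport(found=found, missing=missing, coverage=coverage)


def load_matrix(
    path: str | Path,
    scale: str = "counts",
    meta_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes-x-samples TSV/CSV matrix (gene ids in the first column)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    values = pd.read_csv(path, sep=sep, index_col=0)
    values.index = values.index.astype(str).str.strip()
    values.index.name = None
    values.columns = values.columns.astype(str).str.strip()
    meta = load_sample_meta(meta_path) if meta_path is not None else None
    return ExpressionMatrix(values=values, scale=scale, sample_meta=meta)


def load_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read a sidecar sample-metadata TSV (sample_id, condition, covariates...)."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str).str.strip()
    return meta


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    m.values.to_csv(path, sep=sep, index_label="gene")
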