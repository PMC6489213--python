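"""Domain types and TSV/BED readers and writers.

Conventions
-----------
* All genomic coordinates are 0-based half-open internally.  Probe
  annotation files carry 1-based positions on disk (array-manifest style)
  and are converted on read; writers restore the 1-based convention so
  read/write round-trips are the identity.
* Strand is resolved at read time: for a ``-`` strand gene the
  transcription start site (TSS) is the larger disk coordinate, so
  downstream code never branches on strand except through the
  signed-distance helper in :mod:`methylstate.profiles`.
* Duplicate probe or gene identifiers are an error, never silently
  deduplicated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates an invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ProbeAnnotation:
    """Genomic coordinates of array probes (CpG sites).

    ``table`` is indexed by probe_id with columns ``chrom`` (str) and
    ``pos`` (int, 0-based).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            dups = self.table.index[self.table.index.duplicated()].unique()
            raise ValidationError(f"duplicate probe_id(s) in annotation: {list(dups[:5])}")
        if (self.table["pos"] < 0).any():
            bad = self.table.index[self.table["pos"] < 0][0]
            raise ValidationError(f"negative position for probe {bad!r}")
        if (self.table["chrom"].astype(str).str.len() == 0).any():
            raise ValidationError("empty chromosome name in annotation")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def subset(self, probe_ids: Iterable[str]) -> "ProbeAnnotation":
        return ProbeAnnotation(self.table.loc[list(probe_ids)].copy())

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class BetaMatrix:
    """Probes x samples methylation levels in [0, 1].

    ``beta`` is indexed by probe_id with one column per sample;
    ``detection_p`` (optional) is a parallel frame of the same shape.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.beta.index.is_unique:
            dups = self.beta.index[self.beta.index.duplicated()].unique()
            raise ValidationError(f"duplicate probe_id(s) in beta matrix: {list(dups[:5])}")
        vals = self.beta.to_numpy()
        bad = ~((vals >= 0.0) & (vals <= 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {vals[i, j]!r} outside [0, 1] for probe "
                f"{self.beta.index[i]!r}, sample {self.beta.columns[j]!r}"
            )
        if self.detection_p is not None:
            if self.detection_p.shape != self.beta.shape:
                raise ValidationError(
                    f"detection_p shape {self.detection_p.shape} does not match "
                    f"beta shape {self.beta.shape}"
                )
            self.detection_p = self.detection_p.loc[self.beta.index, self.beta.columns]

    @property
    def probes(self) -> pd.Index:
        return self.beta.index

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    def subset_probes(self, probe_ids: Iterable[str]) -> "BetaMatrix":
        ids = list(probe_ids)
        detp = self.detection_p.loc[ids] if self.detection_p is not None else None
        return BetaMatrix(self.beta.loc[ids].copy(), detp.copy() if detp is not None else None)

    def condition_mean(self, design: "SampleDesign", condition: str) -> pd.Series:
        """Per-probe beta averaged across the samples of one condition."""
        cols = design.samples_for(condition)
        missing = [c for c in cols if c not in self.beta.columns]
        if missing:
            raise ValidationError(f"samples {missing} not present in beta matrix")
        if not cols:
            raise ValidationError(f"condition {condition!r} has no samples")
        return self.beta[cols].mean(axis=1)


@dataclass
class SampleDesign:
    """Mapping of sample id to condition label."""

    conditions: Mapping[str, str]

    def samples_for(self, condition: str) -> list[str]:
        return [s for s, c in self.conditions.items() if c == condition]

    def condition_of(self, sample: str) -> str:
        return self.conditions[sample]

    @property
    def condition_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.conditions.values():
            seen.setdefault(c)
        return list(seen)

    def validate_against(self, matrix: BetaMatrix) -> None:
        missing = [s for s in matrix.samples if s not in self.conditions]
        if missing:
            raise ValidationError(f"samples without condition label: {missing}")


@dataclass(frozen=True)
class GeneModel:
    """A gene with chromosome, strand and transcription start/end sites.

    For ``+`` strand genes tss < tes; for ``-`` strand tss > tes (both as
    0-based coordinates).  ``length`` is always positive.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValidationError(f"gene {self.gene_id!r}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValidationError(f"gene {self.gene_id!r}: - strand requires tss > tes")

    @property
    def length(self) -> int:
        return abs(self.tes - self.tss)

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate (disk convention)."""
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)


@dataclass
class ExpressionTable:
    """Per-gene FPKM for two conditions.

    ``table`` is indexed by gene_id with columns ``fpkm_a`` and ``fpkm_b``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            dups = self.table.index[self.table.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene_id(s) in expression table: {list(dups[:5])}")
        vals = self.table[["fpkm_a", "fpkm_b"]].to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite FPKM value in expression table")
        if (vals < 0).any():
            i = int(np.argwhere((vals < 0).any(axis=1))[0][0])
            raise ValidationError(f"negative FPKM for gene {self.table.index[i]!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class RegionSet:
    """Named list of (chrom, start, end) half-open 0-based intervals.

    Input order is preserved and overlapping intervals are kept as-is
    (no merging on read).
    """

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, (chrom, start, end) in enumerate(self.intervals):
            if start >= end:
                raise ValidationError(
                    f"region set {self.name!r}: interval {i} has start >= end "
                    f"({chrom}:{start}-{end})"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def by_chrom(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.intervals:
            out.setdefault(chrom, []).append((s, e))
        return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in ("probe_id", "gene_id", "chrom", "strand", "sample_id", "condition")})
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    return df


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Read probe annotation TSV (probe_id, chrom, position; position 1-based)."""
    df = _read_tsv(path, ["probe_id", "chrom", "position"])
    pos = df["position"].astype(int)
    if (pos < 1).any():
        bad = df.loc[pos < 1, "probe_id"].iloc[0]
        raise ValidationError(f"{path}: 1-based position < 1 for probe {bad!r}")
    table = pd.DataFrame({"chrom": df["chrom"].values, "pos": (pos - 1).values},
                         index=pd.Index(df["probe_id"], name="probe_id"))
    return ProbeAnnotation(table)


def read_beta_matrix(
    path: str | Path,
    annotation_path: str | Path,
    detection_p_path: str | Path | None = None,
) -> tuple[BetaMatrix, ProbeAnnotation]:
    """Read a beta-value matrix with its probe annotation.

    The matrix TSV has probe_id as its first column and one column per
    sample.  Every probe must appear in the annotation; values must lie
    in [0, 1].
    """
    beta = pd.read_csv(path, sep="\t", index_col=0)
    beta.index = beta.index.astype(str)
    beta.index.name = "probe_id"
    detp = None
    if detection_p_path is not None:
        detp = pd.read_csv(detection_p_path, sep="\t", index_col=0)
        detp.index = detp.index.astype(str)
    matrix = BetaMatrix(beta, detp)
    annotation = read_probe_annotation(annotation_path)
    missing = matrix.probes.difference(annotation.probe_ids)
    if len(missing):
        raise ValidationError(
            f"{path}: probe(s) absent from annotation: {list(missing[:5])}"
        )
    return matrix, annotation.subset(matrix.probes)


def read_regions_bed(path: str | Path, name: str) -> RegionSet:
    """Read a BED3+ file (0-based half-open) into a RegionSet."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: start >= end ({chrom}:{start}-{end})"
                )
            intervals.append((chrom, start, end))
    return RegionSet(name=name, intervals=intervals)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models TSV (gene_id, chrom, strand, start, end).

    On disk start < end always; the strand column decides which end is
    the TSS (start for ``+``, end for ``-``).
    """
    df = _read_tsv(path, ["gene_id", "chrom", "strand", "start", "end"])
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()
        raise ValidationError(f"{path}: duplicate gene_id(s): {list(dups[:5])}")
    genes = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if start >= end:
            raise ValidationError(f"{path}: gene {row.gene_id!r} has start >= end")
        if row.strand == "+":
            tss, tes = start, end
        else:
            tss, tes = end, start
        genes.append(GeneModel(row.gene_id, row.chrom, row.strand, tss, tes))
    return genes


def read_expression_table(path: str | Path) -> ExpressionTable:
    df = _read_tsv(path, ["gene_id", "fpkm_a", "fpkm_b"])
    table = df.set_index("gene_id")[["fpkm_a", "fpkm_b"]].astype(float)
    return ExpressionTable(table)


def read_sample_design(path: str | Path) -> SampleDesign:
    df = _read_tsv(path, ["sample_id", "condition"])
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_id")
    return SampleDesign(dict(zip(df["sample_id"], df["condition"])))


# ---------------------------------------------------------------------------
# writers (round-trip stable)
# ---------------------------------------------------------------------------


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular result as TSV with header (index excluded)."""
    records.to_csv(path, sep="\t", index=False)


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    """Export annotation restoring the 1-based on-disk position convention."""
    out = pd.DataFrame(
        {
            "probe_id": annotation.table.index,
            "chrom": annotation.table["chrom"].values,
            "position": annotation.table["pos"].values + 1,
        }
    )
    write_table(out, path)


def write_beta_matrix(matrix: BetaMatrix, path: str | Path,
                      detection_p_path: str | Path | None = None) -> None:
    matrix.beta.to_csv(path, sep="\t", index=True, index_label="probe_id")
    if detection_p_path is not None and matrix.detection_p is not None:
        matrix.detection_p.to_csv(detection_p_path, sep="\t", index=True,
                                  index_label="probe_id")


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [
        {"gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
         "start": g.start, "end": g.end}
        for g in genes
    ]
    write_table(pd.DataFrame(rows), path)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    out = table.table.reset_index()[["gene_id", "fpkm_a", "fpkm_b"]]
    write_table(out, path)


def write_regions_bed(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    out = pd.DataFrame(
        {"sample_id": list(design.conditions), "condition": list(design.conditions.values())}
    )
    write_table(out, path)
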