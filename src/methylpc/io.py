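"""Data containers and tabular IO for methylation PCA.

The central object is :class:`MethylationMatrix`: an N-probe x M-sample
matrix of M-values (log2 methylated/unmethylated intensity ratio).  Probes
are rows, samples are columns, matching the orientation in which
sample-space PCA is defined.  Side tables — sample metadata, probe
annotation (genomic context), gene models (TSS positions) and probe
exclusion lists — are plain TSV with named headers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

DENSITY_CLASSES = ("HC", "IC", "ICshore", "LC")
REGION_CLASSES = ("intron", "exon", "intergenic")


class MatrixLoadError(ValueError):
    """Raised when a matrix file violates the format contract."""


@dataclass
class MethylationMatrix:
    """Probe x sample matrix of methylation M-values.

    Parameters
    ----------
    probe_ids : list of str
        Row identifiers (CpG probe names), unique.
    sample_ids : list of str
        Column identifiers, unique.
    values : ndarray, shape (n_probes, n_samples)
        Finite M-values.  Missing values are rejected: the PCA downstream
        requires complete data and no imputation is attempted.
    centered : bool
        Whether per-sample (column) means have been subtracted.
    """

    probe_ids: list
    sample_ids: list
    values: np.ndarray
    centered: bool = False
    column_means: np.ndarray | None = None

    def __post_init__(self):
        self.probe_ids = list(self.probe_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixLoadError("values must be 2-D (probes x samples)")
        n, m = self.values.shape
        if n != len(self.probe_ids) or m != len(self.sample_ids):
            raise MatrixLoadError(
                f"shape {self.values.shape} does not match {len(self.probe_ids)} probes "
                f"x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != n:
            dup = _first_duplicate(self.probe_ids)
            raise MatrixLoadError(f"duplicate probe ID: {dup!r}")
        if len(set(self.sample_ids)) != m:
            dup = _first_duplicate(self.sample_ids)
            raise MatrixLoadError(f"duplicate sample ID: {dup!r}")
        if n < 2 or m < 2:
            raise MatrixLoadError(f"need at least 2 probes and 2 samples, got {n}x{m}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise MatrixLoadError(
                f"non-finite value at probe {self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def center_columns(self) -> "MethylationMatrix":
        """Subtract each sample's mean M-value (the x-bar of the model)."""
        if self.centered:
            return self
        means = self.values.mean(axis=0)
        return replace(self, values=self.values - means, centered=True, column_means=means)

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        index = {p: i for i, p in enumerate(self.probe_ids)}
        rows = [index[p] for p in probe_ids]
        return replace(self, probe_ids=list(probe_ids), values=self.values[rows, :])

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in sample_ids]
        return replace(self, sample_ids=list(sample_ids), values=self.values[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass
class SampleMeta:
    """Per-sample phenotypes: individual, tissue, age, batch, cell fractions."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "individual_id", "tissue", "age")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"sample metadata missing column {col!r}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        if (self.table["age"] < 0).any():
            raise ValueError("negative age in metadata")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    def aligned_to(self, sample_ids) -> "SampleMeta":
        """Return metadata reordered to match a matrix's sample order."""
        t = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in t.index]
        if missing:
            raise ValueError(f"metadata missing samples: {missing[:5]}")
        return SampleMeta(t.loc[list(sample_ids)].reset_index())

    def column(self, name) -> np.ndarray:
        return self.table[name].to_numpy()


@dataclass
class ProbeAnnotation:
    """Genomic context per probe: position, CpG-density class, region, CH flag."""

    table: pd.DataFrame

    REQUIRED = ("probe_id", "chromosome", "position", "density_class", "region_class", "is_CH")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"probe annotation missing column {col!r}")
        if self.table["probe_id"].duplicated().any():
            raise ValueError("duplicate probe_id in annotation")
        bad = set(self.table["density_class"]) - set(DENSITY_CLASSES)
        if bad:
            raise ValueError(f"unknown density_class values: {sorted(bad)}")
        bad = set(self.table["region_class"]) - set(REGION_CLASSES)
        if bad:
            raise ValueError(f"unknown region_class values: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    def covers(self, probe_ids) -> bool:
        return set(probe_ids) <= set(self.table["probe_id"])

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("probe_id")


@dataclass
class GeneModel:
    """A gene's transcription start site (1-based) and strand."""

    gene_id: str
    chromosome: str
    strand: str
    tss: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class FilterLists:
    """Probe exclusion inputs: SNP probes, cross-hybridizing probes, QC matrices."""

    snp_probes: set = field(default_factory=set)
    cross_hybridizing: set = field(default_factory=set)
    detection_pvals: np.ndarray | None = None
    bead_counts: np.ndarray | None = None


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# readers / writers


def load_matrix(path) -> MethylationMatrix:
    """Load a probe x sample TSV: header of sample IDs, first column probe IDs."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MatrixLoadError(f"cannot parse {path}: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise MatrixLoadError(f"duplicate probe ID: {dup!r}")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        row = bad.index[0] if len(bad) else "?"
        raise MatrixLoadError(f"non-numeric cell at probe {row!r}, sample {col!r}")
    if df.isna().any().any():
        j = df.isna().any().idxmax() if df.isna().any().any() else None
        col = df.columns[df.isna().any().to_numpy()][0]
        row = df.index[df[col].isna().to_numpy()][0]
        raise MatrixLoadError(f"missing value at probe {row!r}, sample {col!r}")
    return MethylationMatrix(list(df.index), list(df.columns), df.to_numpy(float))


def write_matrix(matrix: MethylationMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="probe_id")


def load_sample_meta(path) -> SampleMeta:
    return SampleMeta(pd.read_csv(path, sep="\t"))


def write_sample_meta(meta: SampleMeta, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def load_probe_annotation(path) -> ProbeAnnotation:
    return ProbeAnnotation(pd.read_csv(path, sep="\t"))


def write_probe_annotation(annotation: ProbeAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def load_gene_models(path, fmt: str = "tsv") -> list:
    """Load gene models from a TSV (gene_id, chromosome, strand, tss) or BED.

    For BED input the TSS is the interval start for + strand genes and the
    interval end for - strand genes (BED starts are 0-based; converted to
    1-based TSS coordinates).
    """
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        return [
            GeneModel(str(r.gene_id), str(r.chromosome), str(r.strand), int(r.tss))
            for r in df.itertuples()
        ]
    if fmt == "bed":
        genes = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.rstrip("\n").split("\t")
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                strand = fields[5] if len(fields) > 5 else "+"
                tss = start + 1 if strand == "+" else end
                genes.append(GeneModel(name, chrom, strand, tss))
        return genes
    raise ValueError(f"unknown gene model format {fmt!r}")


def write_gene_models(genes, path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chromosome, g.strand, g.tss) for g in genes],
        columns=["gene_id", "chromosome", "strand", "tss"],
    ).to_csv(path, sep="\t", index=False)


def load_filter_list(path) -> set:
    """One probe ID per line; blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def beta_to_m(beta, eps: float = 0.0) -> np.ndarray:
    """Convert beta (fraction methylated) to M-value, M = log2(beta/(1-beta)).

    ``eps`` clips beta into [eps, 1-eps] to keep the transform finite at the
    boundaries.
    """
    beta = np.asarray(beta, dtype=float)
    if eps > 0:
        beta = np.clip(beta, eps, 1.0 - eps)
    return np.log2(beta / (1.0 - beta))


# ---------------------------------------------------------------------------
# probe filtering


class FilterError(ValueError):
    pass


def filter_probes(
    matrix: MethylationMatrix,
    annotation: ProbeAnnotation,
    filters: FilterLists,
    detection_alpha: float = 0.01,
    min_beads: int = 3,
):
    """Apply the standard array QC filters, in a fixed order.

    Rules, applied in order with each probe attributed to the first rule that
    removes it:

    1. probes on the X or Y chromosome;
    2. probes with detection p > ``detection_alpha`` in any sample, or a bead
       count below ``min_beads`` in any sample;
    3. SNP-genotyping control probes;
    4. polymorphic / cross-hybridizing probes.

    Returns ``(filtered_matrix, removal_log)`` where the log maps rule name
    to number of probes removed by that rule; counts sum to N_in - N_out.
    """
    if not annotation.covers(matrix.probe_ids):
        missing = sorted(set(matrix.probe_ids) - set(annotation.table["probe_id"]))
        raise FilterError(f"annotation does not cover probes: {missing[:5]}")
    ann = annotation.indexed().loc[matrix.probe_ids]
    n = matrix.n_probes
    removed = np.zeros(n, dtype=bool)
    log = {"XY": 0, "detection_beads": 0, "snp": 0, "crosshyb": 0}

    chrom = ann["chromosome"].astype(str).str.replace("chr", "", regex=False)
    xy = chrom.isin(["X", "Y"]).to_numpy()
    log["XY"] = int(xy.sum())
    removed |= xy

    qc_fail = np.zeros(n, dtype=bool)
    if filters.detection_pvals is not None:
        p = np.asarray(filters.detection_pvals, dtype=float)
        if p.shape != matrix.values.shape:
            raise FilterError(
                f"detection_pvals shape {p.shape} != matrix shape {matrix.values.shape}"
            )
        qc_fail |= (p > detection_alpha).any(axis=1)
    if filters.bead_counts is not None:
        b = np.asarray(filters.bead_counts)
        if b.shape != matrix.values.shape:
            raise FilterError(
                f"bead_counts shape {b.shape} != matrix shape {matrix.values.shape}"
            )
        qc_fail |= (b < min_beads).any(axis=1)
    log["detection_beads"] = int((qc_fail & ~removed).sum())
    removed |= qc_fail

    snp = np.array([p in filters.snp_probes for p in matrix.probe_ids])
    log["snp"] = int((snp & ~removed).sum())
    removed |= snp

    xhyb = np.array([p in filters.cross_hybridizing for p in matrix.probe_ids])
    log["crosshyb"] = int((xhyb & ~removed).sum())
    removed |= xhyb

    keep = [p for p, r in zip(matrix.probe_ids, removed) if not r]
    if not keep:
        raise FilterError("all probes filtered")
    return matrix.subset_probes(keep), log


def write_removal_log(log: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2)


# ---------------------------------------------------------------------------
# lone genes and probe-gene assignment


def compute_lone_genes(genes, exclusion_radius_bp: int = 5000) -> set:
    """Genes whose TSS has no other TSS (any strand, same chromosome)
    strictly within ``exclusion_radius_bp``.

    Two TSSs exactly ``exclusion_radius_bp`` apart do NOT exclude each
    other (strict inequality).
    """
    if not genes:
        raise ValueError("need at least one gene")
    lone = set()
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: (g.tss, g.gene_id))
        tss = np.array([g.tss for g in chrom_genes])
        for i, g in enumerate(chrom_genes):
            # only the nearest sorted neighbours can violate the radius
            near = False
            if i > 0 and g.tss - tss[i - 1] < exclusion_radius_bp:
                near = True
            if i + 1 < len(tss) and tss[i + 1] - g.tss < exclusion_radius_bp:
                near = True
            if not near:
                lone.add(g.gene_id)
    return lone


def assign_probes_to_lone_genes(
    annotation: ProbeAnnotation,
    genes,
    lone: set,
    max_dist_bp: int = 2500,
) -> dict:
    """Map probes to the nearest lone-gene TSS within ``max_dist_bp``.

    Distances are signed relative to gene orientation: negative = upstream
    of the TSS.  For a - strand gene a probe at larger coordinate than the
    TSS is upstream (negative distance).  A probe equidistant from two lone
    TSSs is assigned to the gene with the smaller |distance| and then the
    lexicographically smaller gene ID.
    """
    unknown = lone - {g.gene_id for g in genes}
    if unknown:
        raise ValueError(f"lone IDs not among gene models: {sorted(unknown)[:5]}")
    lone_genes = [g for g in genes if g.gene_id in lone]
    by_chrom = {}
    for g in lone_genes:
        by_chrom.setdefault(g.chromosome, []).append(g)

    assignment = {}
    ann = annotation.table
    chroms = ann["chromosome"].to_numpy()
    positions = ann["position"].to_numpy()
    probe_ids = ann["probe_id"].to_numpy()
    for chrom, chrom_genes in by_chrom.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        for pid, pos in zip(probe_ids[mask], positions[mask]):
            best = None
            for g in chrom_genes:
                d = int(pos - g.tss)
                if g.strand == "-":
                    d = -d
                if abs(d) <= max_dist_bp:
                    key = (abs(d), g.gene_id)
                    if best is None or key < best[0]:
                        best = (key, g.gene_id, d)
            if best is not None:
                assignment[pid] = (best[1], best[2])
    return assignment
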