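"""Core data containers and I/O for methylation beta-value matrices.

A beta value is the proportion of methylated signal at a CpG probe (or,
after aggregation, at a gene promoter) and is bounded in [0, 1].  The
containers here are thin, validated wrappers around pandas objects:

* :class:`BetaMatrix` — features x samples matrix, ``NaN`` marks missing.
* :class:`BatchAssignment` — sample id -> batch id mapping.
* :class:`ProbeAnnotation` / :class:`TSSAnnotation` — genomic annotation
  tables used to restrict probes to promoter windows and to aggregate
  probe-level values to gene level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: gene-name tokens treated as "missing" during cleaning
NA_GENE_TOKENS = frozenset({"", "NA", "."})
#: separators that mark a probe annotated with several gene names at once
GENE_LIST_SEPARATORS = (";", ",")


@dataclass
class BetaMatrix:
    """Features x samples matrix of beta values with missing entries as NaN.

    Parameters
    ----------
    values
        DataFrame indexed by feature id (probe or gene) with sample ids as
        columns.  Non-missing entries must lie in [0, 1].
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if not v.index.is_unique:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if not v.columns.is_unique:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value out of [0, 1]: {arr[i, j]!r} at feature "
                f"{v.index[i]!r}, sample {v.columns[j]!r}"
            )
        self.values = v.astype(float)

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the entry is missing."""
        return self.values.isna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self.values.copy())

    def equals(self, other: "BetaMatrix") -> bool:
        return self.values.equals(other.values)


@dataclass
class BatchAssignment:
    """Mapping from sample id to batch id."""

    mapping: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.mapping)
        if not s.index.is_unique:
            raise ValueError("sample ids in batch assignment must be unique")
        self.mapping = s.astype(str)

    @classmethod
    def from_dict(cls, d: dict) -> "BatchAssignment":
        return cls(pd.Series(d))

    @property
    def sample_ids(self) -> pd.Index:
        return self.mapping.index

    @property
    def batch_ids(self) -> list[str]:
        return sorted(self.mapping.unique())

    def samples_in_batch(self, batch_id: str) -> list:
        return list(self.mapping.index[self.mapping == str(batch_id)])

    def validate_against(self, matrix: BetaMatrix) -> None:
        """Every sample of `matrix` must carry exactly one batch id."""
        missing = matrix.sample_ids.difference(self.mapping.index)
        if len(missing):
            raise ValueError(f"samples without batch assignment: {list(missing)[:5]}")


@dataclass
class ProbeAnnotation:
    """One methylation probe: genomic position and the gene it is mapped to."""

    probe_id: str
    chromosome: str
    position: int
    gene_name: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"probe {self.probe_id}: position must be >= 1 (1-based)")


@dataclass
class TSSAnnotation:
    """Annotated transcription start site of one gene."""

    gene_name: str
    chromosome: str
    tss_position: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss_position < 1:
            raise ValueError("tss_position must be >= 1 (1-based)")


def read_beta_matrix(path, delimiter: str = "\t", na_token: str = "NA") -> BetaMatrix:
    """Read a delimited beta-value matrix.

    First row holds sample ids, first column feature ids.  Cells equal to
    `na_token` become missing entries; any other non-numeric cell or a
    numeric cell outside [0, 1] raises with the offending coordinates.
    """
    df = pd.read_csv(
        path, sep=delimiter, index_col=0, na_values=[na_token],
        keep_default_na=False, float_precision="round_trip",
    )
    if df.columns.size == 0:
        raise ValueError(f"{path}: malformed header (no sample columns)")
    try:
        df = df.astype(float)
    except ValueError:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                raise ValueError(
                    f"{path}: non-numeric cell {df[col][bad].iloc[0]!r} at feature "
                    f"{df.index[bad][0]!r}, sample {col!r}"
                ) from None
        raise
    return BetaMatrix(df)


def write_beta_matrix(matrix: BetaMatrix, path, delimiter: str = "\t", na_token: str = "NA") -> None:
    """Write a matrix so that ``read_beta_matrix`` round-trips it exactly.

    Floats are written with their shortest round-trip representation (the
    default CSV formatting truncates and would break bit-exact round trips).
    """
    matrix.values.to_csv(
        path, sep=delimiter, na_rep=na_token, index_label="feature_id",
        float_format=lambda v: repr(float(v)),
    )


def read_batch_assignment(path, delimiter: str = "\t") -> BatchAssignment:
    """Read a two-column (sample_id, batch_id) table with header."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, batch_id)")
    return BatchAssignment(pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values))


def write_batch_assignment(batches: BatchAssignment, path, delimiter: str = "\t") -> None:
    df = pd.DataFrame({"sample_id": batches.mapping.index, "batch_id": batches.mapping.values})
    df.to_csv(path, sep=delimiter, index=False)


def read_probe_annotation(path, delimiter: str = ",") -> list[ProbeAnnotation]:
    """Read a manifest-like table with columns probe_id, chromosome, position, gene_name."""
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    required = ["probe_id", "chromosome", "position", "gene_name"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if df["probe_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate probe ids")
    return [
        ProbeAnnotation(r.probe_id, r.chromosome, int(r.position), r.gene_name)
        for r in df.itertuples()
    ]


def read_tss_annotation(path, delimiter: str = "\t") -> list[TSSAnnotation]:
    """Read a TSS table.

    Accepts either a 4+ column table with header
    (chromosome, tss_position, strand, gene_name) or headerless 6-column BED
    (chrom, start, end, name, score, strand; the start is taken as the TSS,
    reported 1-based).
    """
    head = pd.read_csv(path, sep=delimiter, nrows=1, header=None, dtype=str)
    first = str(head.iloc[0, 0])
    if first == "chromosome":
        df = pd.read_csv(path, sep=delimiter, dtype=str)
        return [
            TSSAnnotation(r.gene_name, r.chromosome, int(r.tss_position), r.strand)
            for r in df.itertuples()
        ]
    df = pd.read_csv(path, sep=delimiter, header=None, dtype=str)
    if df.shape[1] < 6:
        raise ValueError(f"{path}: expected header or 6-column BED")
    return [
        TSSAnnotation(row[3], row[0], int(row[1]) + 1, row[5])
        for row in df.itertuples(index=False)
    ]


def _gene_name_ok(name: str) -> bool:
    if name is None:
        return False
    name = str(name).strip()
    if name in NA_GENE_TOKENS or name.lower() == "nan":
        return False
    return not any(sep in name for sep in GENE_LIST_SEPARATORS)


def clean_entries(
    matrix: BetaMatrix, annotations: list[ProbeAnnotation]
) -> tuple[BetaMatrix, list[ProbeAnnotation]]:
    """Drop features with unusable gene annotation and all-missing rows.

    A feature is removed when it has no annotation, when its gene name is
    empty/an NA token, or when the gene name lists several genes (separated
    by ';' or ','), i.e. the probe cannot be attributed to a single gene.
    Rows whose values are all missing are removed as well.
    """
    by_probe = {a.probe_id: a for a in annotations}
    keep = []
    n_unannotated = n_badname = n_allmissing = 0
    for fid in matrix.feature_ids:
        ann = by_probe.get(fid)
        if ann is None:
            n_unannotated += 1
            continue
        if not _gene_name_ok(ann.gene_name):
            n_badname += 1
            continue
        if matrix.values.loc[fid].isna().all():
            n_allmissing += 1
            continue
        keep.append(fid)
    logger.info(
        "clean_entries: kept %d / %d features (%d unannotated, %d bad gene name, "
        "%d all-missing)",
        len(keep), matrix.shape[0], n_unannotated, n_badname, n_allmissing,
    )
    kept_matrix = BetaMatrix(matrix.values.loc[keep].copy())
    kept_annotations = [by_probe[fid] for fid in keep]
    return kept_matrix, kept_annotations


def map_probes_to_promoters(
    probes: list[ProbeAnnotation],
    tss: list[TSSAnnotation],
    window_bp: int = 2000,
) -> set[str]:
    """Return probe ids lying within ``window_bp`` of an annotated TSS.

    A probe is kept iff some TSS record matches its gene name AND chromosome
    and ``|position - tss_position| <= window_bp`` (symmetric, inclusive
    window; with a symmetric window the kept set is strand-independent).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    tss_by_gene: dict[tuple[str, str], list[int]] = {}
    for t in tss:
        tss_by_gene.setdefault((t.gene_name, t.chromosome), []).append(t.tss_position)
    kept = set()
    for p in probes:
        for pos in tss_by_gene.get((p.gene_name, p.chromosome), ()):
            if abs(p.position - pos) <= window_bp:
                kept.add(p.probe_id)
                break
    logger.info("map_probes_to_promoters: kept %d / %d probes", len(kept), len(probes))
    return kept


def aggregate_probes_to_genes(matrix: BetaMatrix, probe_to_gene: dict) -> BetaMatrix:
    """Aggregate probe-level rows to gene-level rows by the per-sample mean.

    Missing probe values are ignored in the mean; a gene entry is missing
    only when every contributing probe is missing in that sample.
    """
    if not probe_to_gene:
        raise ValueError("probe_to_gene mapping is empty")
    missing = [f for f in matrix.feature_ids if f not in probe_to_gene]
    if missing:
        raise ValueError(f"features without gene mapping: {missing[:5]}")
    genes = matrix.values.groupby(
        matrix.feature_ids.map(probe_to_gene), sort=True
    ).mean()  # pandas mean skips NaN; all-NaN group -> NaN
    genes.index.name = matrix.values.index.name
    return BetaMatrix(genes)


@dataclass
class GoldStandard:
    """Pristine matrix and the mask of entries that were synthetically shifted."""

    pristine: BetaMatrix
    injected_mask: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.injected_mask.shape != self.pristine.shape:
            raise ValueError("injected_mask shape must match the pristine matrix")
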