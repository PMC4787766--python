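"""Readers, writers and validation for the pipeline's tabular formats.

All on-disk formats are plain TSV with a header row, UTF-8, no quoting:

* ``counts.tsv``     — gene_id column followed by one integer column per sample.
* ``samples.tsv``    — sample_id, condition, time_min, replicate.
* ``genes.tsv``      — gene_id, length_bp, terms (semicolon-separated list).
* ``genesets.tsv``   — set_label, gene_id; one pair per line.  The gene
  universe is persisted under the reserved label ``_universe_``.
* ``promoters.tsv``  — promoter_id, gene_id, then one integer column per motif.

Genome coordinates are deliberately not handled; gene length in bp is a
plain annotation column used only for RPKM normalization.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

#: Experimental conditions of the five-arm design: wild-type MCF10a cells,
#: acute PI3Kalpha inhibition (A66) with EGF, A66 without EGF stimulation,
#: biallelic PTEN deletion, and the activating PIK3CA H1047R knock-in.
CONDITIONS = ("WT", "A66", "A66_noEGF", "PTEN_KO", "PIK3CA_H1047R")

#: EGF stimulation time points in minutes (0 = unstimulated baseline).
TIME_POINTS = (0, 15, 40, 90, 180, 300)

UNIVERSE_LABEL = "_universe_"


class DataValidationError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclasses.dataclass(frozen=True)
class SampleMeta:
    """One sequencing library: condition, EGF time in minutes, replicate."""

    sample_id: str
    condition: str
    time_min: int
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise DataValidationError(
                f"sample {self.sample_id!r}: unknown condition {self.condition!r}; "
                f"expected one of {CONDITIONS}"
            )
        if self.time_min not in TIME_POINTS:
            raise DataValidationError(
                f"sample {self.sample_id!r}: time_min {self.time_min} not in {TIME_POINTS}"
            )
        if self.condition == "A66_noEGF" and self.time_min != 300:
            raise DataValidationError(
                f"sample {self.sample_id!r}: A66_noEGF libraries exist only at 300 min"
            )
        if self.replicate < 1:
            raise DataValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )

    @property
    def group(self) -> str:
        """Condition:time label shared by replicates."""
        return f"{self.condition}:{self.time_min}"


@dataclasses.dataclass
class Dataset:
    """A count matrix with aligned sample metadata and gene annotation.

    Attributes
    ----------
    counts
        genes x samples DataFrame of non-negative integers; columns follow
        the sample sheet order.
    samples
        One :class:`SampleMeta` per column of ``counts``.
    genes
        DataFrame indexed by gene_id with a ``length_bp`` column and a
        ``terms`` column holding lists of annotation term ids.
    """

    counts: pd.DataFrame
    samples: list[SampleMeta]
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.samples) != self.counts.shape[1]:
            raise DataValidationError(
                f"sample sheet has {len(self.samples)} rows but counts has "
                f"{self.counts.shape[1]} columns"
            )
        ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != ids:
            raise DataValidationError("counts columns do not match sample sheet order")
        if len(set(ids)) != len(ids):
            raise DataValidationError("duplicate sample ids in sample sheet")
        triples = [(s.condition, s.time_min, s.replicate) for s in self.samples]
        if len(set(triples)) != len(triples):
            raise DataValidationError(
                "duplicate (condition, time_min, replicate) triples in sample sheet"
            )
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise DataValidationError(f"duplicate gene id {dup!r} in counts")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            bad = np.argwhere((values % 1 != 0) | ~np.isfinite(values))
            if bad.size:
                r, c = bad[0]
                raise DataValidationError(
                    f"non-integer count {values[r, c]} at gene "
                    f"{self.counts.index[r]!r}, sample {self.counts.columns[c]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise DataValidationError(
                f"negative count at gene {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        if not self.genes.index.equals(self.counts.index):
            raise DataValidationError("gene annotation index does not match counts rows")
        if "length_bp" in self.genes and (self.genes["length_bp"] <= 0).any():
            bad = self.genes.index[self.genes["length_bp"] <= 0][0]
            raise DataValidationError(f"gene {bad!r}: length_bp must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_table(self) -> pd.DataFrame:
        """Sample sheet as a DataFrame (one row per library)."""
        return pd.DataFrame(
            [dataclasses.asdict(s) for s in self.samples],
        ).set_index("sample_id")

    def subset_samples(self, mask) -> "Dataset":
        """New Dataset restricted to samples where ``mask`` holds (bool array)."""
        keep = [s for s, m in zip(self.samples, mask) if m]
        return Dataset(
            counts=self.counts.loc[:, [s.sample_id for s in keep]].copy(),
            samples=keep,
            genes=self.genes.copy(),
        )


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets over a common universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if UNIVERSE_LABEL in self.sets:
            raise DataValidationError(f"set label {UNIVERSE_LABEL!r} is reserved")
        for label, members in self.sets.items():
            stray = members - self.universe
            if stray:
                raise DataValidationError(
                    f"set {label!r}: members outside universe: {sorted(stray)[:5]}"
                )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GeneSetCollection)
            and self.sets == other.sets
            and self.universe == other.universe
        )


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing column(s) {missing}")


def read_sample_sheet(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["sample_id", "condition", "time_min", "replicate"], path)
    samples = []
    for i, row in df.iterrows():
        try:
            samples.append(
                SampleMeta(
                    sample_id=row["sample_id"],
                    condition=row["condition"],
                    time_min=int(row["time_min"]),
                    replicate=int(row["replicate"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise DataValidationError(f"{path}: row {i + 2}: {exc}") from exc
    return samples


def read_dataset(counts_path, samples_path, genes_path) -> Dataset:
    """Read and cross-validate a count matrix, sample sheet and annotation.

    Columns of the returned counts follow the sample sheet order.  Errors
    name the offending file, row and column.
    """
    samples = read_sample_sheet(samples_path)
    raw = pd.read_csv(counts_path, sep="\t", dtype=str)
    if raw.columns[0] != "gene_id":
        raise DataValidationError(f"{counts_path}: first column must be 'gene_id'")
    raw = raw.set_index("gene_id")
    sheet_ids = [s.sample_id for s in samples]
    orphans = [c for c in raw.columns if c not in sheet_ids]
    if orphans:
        raise DataValidationError(
            f"{counts_path}: sample column(s) {orphans} absent from {samples_path}"
        )
    missing = [sid for sid in sheet_ids if sid not in raw.columns]
    if missing:
        raise DataValidationError(f"{counts_path}: sample column(s) {missing} missing")
    counts = pd.DataFrame(index=raw.index)
    for col in sheet_ids:
        try:
            counts[col] = raw[col].astype(np.int64)
        except (TypeError, ValueError):
            as_float = raw[col].astype(float)
            bad = as_float.index[(as_float % 1 != 0) | as_float.isna()][0]
            raise DataValidationError(
                f"{counts_path}: non-integer count {raw.loc[bad, col]!r} at "
                f"gene {bad!r}, column {col!r}"
            ) from None
    genes = pd.read_csv(genes_path, sep="\t", dtype={"gene_id": str})
    _require_columns(genes, ["gene_id", "length_bp"], genes_path)
    genes = genes.set_index("gene_id")
    if "terms" in genes.columns:
        genes["terms"] = [
            [] if pd.isna(t) or t == "" else str(t).split(";") for t in genes["terms"]
        ]
    else:
        genes["terms"] = [[] for _ in range(len(genes))]
    genes["length_bp"] = genes["length_bp"].astype(np.int64)
    try:
        genes = genes.loc[counts.index]
    except KeyError:
        stray = counts.index.difference(genes.index)
        raise DataValidationError(
            f"{genes_path}: no annotation for gene(s) {list(stray[:5])}"
        ) from None
    return Dataset(counts=counts, samples=samples, genes=genes)


def write_dataset(dataset: Dataset, out_dir) -> dict[str, Path]:
    """Write counts.tsv, samples.tsv and genes.tsv; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out_dir / "counts.tsv",
        "samples": out_dir / "samples.tsv",
        "genes": out_dir / "genes.tsv",
    }
    dataset.counts.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    dataset.sample_table().to_csv(paths["samples"], sep="\t")
    genes = dataset.genes.copy()
    genes["terms"] = [";".join(t) for t in genes["terms"]]
    genes.rename_axis("gene_id").to_csv(paths["genes"], sep="\t")
    return paths


def write_gene_sets(collection: GeneSetCollection, path) -> Path:
    """Persist a gene-set collection as (set_label, gene_id) pairs."""
    path = Path(path)
    rows = [(UNIVERSE_LABEL, g) for g in sorted(collection.universe)]
    for label in sorted(collection.sets):
        rows.extend((label, g) for g in sorted(collection.sets[label]))
    pd.DataFrame(rows, columns=["set_label", "gene_id"]).to_csv(path, sep="\t", index=False)
    return path


def read_gene_sets(path) -> GeneSetCollection:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["set_label", "gene_id"], path)
    universe = set(df.loc[df["set_label"] == UNIVERSE_LABEL, "gene_id"])
    sets: dict[str, set[str]] = {}
    for label, sub in df[df["set_label"] != UNIVERSE_LABEL].groupby("set_label"):
        sets[str(label)] = set(sub["gene_id"])
    return GeneSetCollection(sets=sets, universe=universe)


def read_motif_matrix(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read promoters.tsv → (promoter x motif site counts, promoter→gene map)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["promoter_id", "gene_id"], path)
    df = df.set_index("promoter_id")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise DataValidationError(f"{path}: duplicate promoter id {dup!r}")
    gene_map = df["gene_id"].astype(str)
    sites = df.drop(columns=["gene_id"]).astype(np.int64)
    if (sites.to_numpy() < 0).any():
        raise DataValidationError(f"{path}: negative site count")
    return sites, gene_map


def write_motif_matrix(sites: pd.DataFrame, gene_map: pd.Series, path) -> Path:
    path = Path(path)
    out = sites.copy()
    out.insert(0, "gene_id", gene_map.loc[sites.index])
    out.rename_axis("promoter_id").to_csv(path, sep="\t")
    return path
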