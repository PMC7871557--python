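"""On-disk formats and in-memory containers for the gene-content pipeline.

All exchange files are UTF-8, tab-separated tables; lines starting with
``#`` are comments.  The three artifacts are

* strain metadata (``strain_id  genome_size_mbp  group  is_focal``),
* a per-strain functional-class gene-count table (strains x class letters),
* a binary gene-family presence/absence matrix (families x strains).

Dendrograms are exchanged as Newick strings with branch lengths equal to
merge-height differences, so re-parsing recovers the cophenetic distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("strain_id", "genome_size_mbp", "group", "is_focal")


@dataclass(frozen=True)
class GenomeRecord:
    """Metadata for one strain.

    Parameters
    ----------
    strain_id:
        Whitespace-free unique token naming the strain.
    genome_size_mbp:
        Genome size in megabase pairs; strictly positive.
    group:
        Free-text taxon label (genus or clade).
    is_focal:
        Whether the strain belongs to the focal group under study
        (e.g. the fructophilic lactic acid bacteria within a family-wide
        strain panel).
    """

    strain_id: str
    genome_size_mbp: float
    group: str
    is_focal: bool

    def __post_init__(self) -> None:
        if not self.strain_id or any(c.isspace() for c in self.strain_id):
            raise ValidationError(
                f"strain_id must be a whitespace-free token, got {self.strain_id!r}"
            )
        if not self.genome_size_mbp > 0:
            raise ValidationError(
                f"genome_size_mbp must be > 0 for {self.strain_id!r}, "
                f"got {self.genome_size_mbp!r}"
            )


@dataclass
class ClassCountTable:
    """Per-strain gene counts in single-letter functional classes.

    ``counts`` is a strains x classes integer DataFrame; the index order is
    the canonical strain order of the dataset.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise ValidationError("duplicate strain_id in class-count table")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate class code in class-count table")
        if (df.values < 0).any():
            raise ValidationError("class counts must be non-negative")
        self.counts = df.astype(np.int64)

    @property
    def strains(self) -> list[str]:
        return list(self.counts.index)

    @property
    def classes(self) -> list[str]:
        return list(self.counts.columns)

    def total_genes(self) -> pd.Series:
        """Total gene count per strain, summed over all classes."""
        return self.counts.sum(axis=1)


@dataclass
class PresenceMatrix:
    """Binary gene-family x strain matrix (pan-genome of metabolic genes).

    ``values`` has family ids on the index, strain ids on the columns and
    entries in {0, 1}.  ``n_dropped`` records how many family rows were
    removed by the prevalence filter at read time.
    """

    values: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            raise ValidationError("duplicate family_id in presence matrix")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate strain_id in presence matrix")
        vals = df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("presence matrix entries must be 0 or 1")
        self.values = df.astype(np.int8)

    @property
    def family_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def strains(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc


def read_metadata(path: str | Path) -> list[GenomeRecord]:
    """Read strain metadata from a TSV file.

    The header must contain ``strain_id``, ``genome_size_mbp``, ``group``
    and ``is_focal`` (0/1).  Duplicate strain ids or non-positive genome
    sizes raise :class:`ValidationError`.
    """
    df = _read_tsv(path)
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["strain_id"])
        if sid in seen:
            raise ValidationError(f"{path}: duplicate strain_id {sid!r}")
        seen.add(sid)
        try:
            size = float(row["genome_size_mbp"])
        except ValueError as exc:
            raise FormatError(
                f"{path}: non-numeric genome_size_mbp for strain {sid!r}"
            ) from exc
        focal_raw = str(row["is_focal"]).strip()
        if focal_raw not in {"0", "1"}:
            raise FormatError(
                f"{path}: is_focal must be 0 or 1 for strain {sid!r}, got {focal_raw!r}"
            )
        records.append(
            GenomeRecord(
                strain_id=sid,
                genome_size_mbp=size,
                group=str(row["group"]),
                is_focal=focal_raw == "1",
            )
        )
    return records


def write_metadata(records: Sequence[GenomeRecord], path: str | Path) -> None:
    df = metadata_frame(records)
    df["is_focal"] = df["is_focal"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def metadata_frame(records: Sequence[GenomeRecord]) -> pd.DataFrame:
    """Tabular view of a metadata record list (column order is canonical)."""
    return pd.DataFrame(
        {
            "strain_id": [r.strain_id for r in records],
            "genome_size_mbp": [r.genome_size_mbp for r in records],
            "group": [r.group for r in records],
            "is_focal": [r.is_focal for r in records],
        }
    )


def focal_strains(records: Sequence[GenomeRecord]) -> list[str]:
    """Strain ids flagged as focal, in metadata order."""
    return [r.strain_id for r in records if r.is_focal]


def read_class_counts(path: str | Path) -> ClassCountTable:
    """Read a strains x classes gene-count TSV (first column ``strain_id``)."""
    df = _read_tsv(path)
    if df.columns[0] != "strain_id":
        raise FormatError(f"{path}: first column must be 'strain_id'")
    df = df.set_index("strain_id")
    try:
        counts = df.astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer cell in class-count table") from exc
    return ClassCountTable(counts)


def write_class_counts(table: ClassCountTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="strain_id")


def read_presence_matrix(path: str | Path, min_prevalence: int = 1) -> PresenceMatrix:
    """Read a binary gene-family x strain matrix.

    The first column holds family ids; remaining columns are strains.
    Cells hold copy counts; any count greater than 1 is coerced to presence
    (1) with a logged warning, so both count and binary matrices are
    accepted.  Families present in fewer than ``min_prevalence`` strains
    are dropped and the dropped-row count is reported on the result.
    """
    df = _read_tsv(path)
    fam_col = df.columns[0]
    df = df.set_index(fam_col)
    df.index.name = "family_id"
    mat = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                mat[i, j] = int(raw)
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"{path}: non-numeric cell at family {df.index[i]!r}, "
                    f"strain {col!r}: {raw!r}"
                ) from exc
    if (mat < 0).any():
        i, j = np.argwhere(mat < 0)[0]
        raise FormatError(
            f"{path}: negative count at family {df.index[i]!r}, strain {df.columns[j]!r}"
        )
    n_coerced = int((mat > 1).sum())
    if n_coerced:
        logger.warning(
            "%s: coerced %d cells with copy count > 1 to presence", path, n_coerced
        )
        mat = np.minimum(mat, 1)
    full = pd.DataFrame(mat, index=df.index, columns=df.columns)
    keep = full.sum(axis=1) >= min_prevalence
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d families below min_prevalence=%d",
            path,
            n_dropped,
            min_prevalence,
        )
    return PresenceMatrix(full.loc[keep], n_dropped=n_dropped)


def write_presence_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="family_id")


def check_strain_order(
    records: Sequence[GenomeRecord], strains: Iterable[str], what: str
) -> None:
    """Enforce that a table's strain order matches the metadata order.

    Mismatches are an error rather than a silent reindex, so that matrix
    columns can never be misaligned with metadata rows.
    """
    expected = [r.strain_id for r in records]
    got = list(strains)
    if expected != got:
        raise ValidationError(
            f"strain order of {what} does not match metadata "
            f"(expected {expected[:5]}..., got {got[:5]}...)"
        )


def write_newick(dendrogram, path: str | Path) -> None:
    """Write a :class:`~flabkit.pan_clustering.Dendrogram` as Newick.

    Branch lengths are merge-height differences (leaves sit at height 0),
    so the cophenetic structure survives a round trip through the file.
    """
    newick = dendrogram.to_newick()
    Path(path).write_text(newick + "\n", encoding="utf-8")
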