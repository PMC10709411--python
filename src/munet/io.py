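"""Readers and writers for the tabular formats shared by every stage.

All feature matrices are oriented features x samples (genes x samples,
loci x samples), both on disk and in memory, following the 450K-array
convention.  Files are tab-delimited text with a single header row of
sample IDs, a first column of feature IDs, and ``NA`` for missing values.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("munet")

_NA_TOKENS = {"", "NA", "NaN", "nan"}


class MatrixFormatError(ValueError):
    """Raised when a delimited matrix file violates the format contract."""


def read_matrix(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a features x samples matrix from delimited text.

    The first row must be a header of sample IDs and the first column the
    feature IDs.  Empty cells and the sentinels ``NA``/``NaN`` become
    missing values.

    Raises
    ------
    MatrixFormatError
        On duplicate feature IDs (named in the message) or ragged rows
        (reported with their 1-based line number).
    """
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise MatrixFormatError(f"{path}: empty file")
        ncol = len(header)
        feature_ids: list[str] = []
        rows: list[list[str]] = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != ncol:
                raise MatrixFormatError(
                    f"{path}: ragged row at line {lineno}: expected "
                    f"{ncol} fields, got {len(rec)}"
                )
            feature_ids.append(rec[0].strip())
            rows.append(rec[1:])
    dupes = sorted(k for k, c in Counter(feature_ids).items() if c > 1)
    if dupes:
        raise MatrixFormatError(f"{path}: duplicate feature IDs: {', '.join(dupes)}")
    samples = [s.strip() for s in header[1:]]
    dup_samples = sorted(k for k, c in Counter(samples).items() if c > 1)
    if dup_samples:
        raise MatrixFormatError(
            f"{path}: duplicate sample IDs: {', '.join(dup_samples)}"
        )
    if rows:
        arr = np.array(
            [[np.nan if cell.strip() in _NA_TOKENS else float(cell) for cell in row]
             for row in rows],
            dtype=float,
        )
    else:
        arr = np.empty((0, len(samples)))
    df = pd.DataFrame(arr, index=feature_ids, columns=samples)
    df.index.name = header[0].strip() or "feature"
    return df


def write_matrix(matrix: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a labeled matrix as delimited text, ``NA`` for missing.

    Values are written with 17 significant digits so that a
    write -> read round trip reproduces them exactly.
    """
    path = Path(path)
    matrix.to_csv(path, sep=sep, na_rep="NA", float_format="%.17g",
                  index_label=matrix.index.name or "feature")


@dataclass(frozen=True)
class LocusGeneMap:
    """Many-to-many mapping between methylation loci and gene symbols.

    A locus mapped to k genes contributes its beta row to each of the k
    genes' gene-level summaries.
    """

    pairs: frozenset[tuple[str, str]]
    _loci_of_gene: dict[str, tuple[str, ...]] = field(
        default_factory=dict, compare=False, repr=False)
    _genes_of_locus: dict[str, tuple[str, ...]] = field(
        default_factory=dict, compare=False, repr=False)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "LocusGeneMap":
        pairset = frozenset((str(l), str(g)) for l, g in pairs)
        loci_of_gene: dict[str, list[str]] = {}
        genes_of_locus: dict[str, list[str]] = {}
        for locus, gene in sorted(pairset):
            loci_of_gene.setdefault(gene, []).append(locus)
            genes_of_locus.setdefault(locus, []).append(gene)
        return cls(
            pairs=pairset,
            _loci_of_gene={g: tuple(v) for g, v in loci_of_gene.items()},
            _genes_of_locus={l: tuple(v) for l, v in genes_of_locus.items()},
        )

    def loci_of(self, gene: str) -> tuple[str, ...]:
        return self._loci_of_gene.get(gene, ())

    def genes_of(self, locus: str) -> tuple[str, ...]:
        return self._genes_of_locus.get(locus, ())

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._loci_of_gene)

    @property
    def loci(self) -> frozenset[str]:
        return frozenset(self._genes_of_locus)

    def loci_per_gene(self) -> pd.Series:
        return pd.Series({g: len(v) for g, v in self._loci_of_gene.items()},
                         dtype=int).sort_index()

    def __len__(self) -> int:
        return len(self.pairs)


def read_locus_gene_map(path: str | Path, sep: str = "\t") -> LocusGeneMap:
    """Read a two-column (locus, gene) table; duplicate pairs collapse."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter=sep)
        for lineno, rec in enumerate(reader, start=1):
            if not rec:
                continue
            if len(rec) != 2:
                raise MatrixFormatError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(rec)}"
                )
            pairs.append((rec[0].strip(), rec[1].strip()))
    if pairs and pairs[0][0].lower() in {"locus", "locus_id", "probe"}:
        pairs = pairs[1:]
    if not pairs:
        raise MatrixFormatError(f"{path}: empty locus-gene map")
    return LocusGeneMap.from_pairs(pairs)


def write_locus_gene_map(lgmap: LocusGeneMap, path: str | Path, sep: str = "\t") -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter=sep)
        writer.writerow(["locus", "gene"])
        writer.writerows(sorted(lgmap.pairs))


def read_clinical(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a clinical table; index = patient ID, one row per patient."""
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"],
                     keep_default_na=True, dtype={0: str})
    df.index = df.index.astype(str).str.strip()
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise MatrixFormatError(f"{path}: duplicate patient IDs: {', '.join(dupes)}")
    return df


def write_clinical(clinical: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    clinical.to_csv(path, sep=sep, na_rep="NA",
                    index_label=clinical.index.name or "id")


def validate_betas(meth: pd.DataFrame) -> None:
    """Check that all non-missing methylation values are in [0, 1]."""
    vals = meth.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError(
            f"beta values outside [0, 1]: range "
            f"[{finite.min():.4g}, {finite.max():.4g}]"
        )


def _canon(sample_id: str) -> str:
    return str(sample_id).strip().upper()


def harmonize_samples(frames: list[pd.DataFrame],
                      axes: list[str],
                      ) -> tuple[list[pd.DataFrame], list[str]]:
    """Intersect sample/patient IDs case-insensitively after trimming.

    ``axes[i]`` is ``"columns"`` for features x samples matrices or
    ``"index"`` for clinical tables keyed by patient ID.  Returns the
    inputs restricted to the shared IDs (in a common sorted order) plus
    the list of IDs dropped from at least one input.  Mismatches are
    reported via the package logger, never silently discarded.
    """
    if len(frames) != len(axes):
        raise ValueError("frames and axes must have equal length")
    key_maps: list[Mapping[str, str]] = []
    for frame, axis in zip(frames, axes):
        ids = frame.columns if axis == "columns" else frame.index
        key_maps.append({_canon(i): i for i in ids})
    shared = set(key_maps[0])
    for km in key_maps[1:]:
        shared &= set(km)
    dropped = sorted(set().union(*key_maps) - shared)
    if dropped:
        logger.info("harmonize_samples: %d IDs absent from at least one input: %s",
                    len(dropped), ", ".join(dropped[:10]))
    out: list[pd.DataFrame] = []
    for frame, axis, km in zip(frames, axes, key_maps):
        keep = [km[k] for k in sorted(shared)]
        out.append(frame.loc[:, keep] if axis == "columns" else frame.loc[keep])
    return out, dropped
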