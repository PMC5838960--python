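"""Reading and preprocessing expression tables.

Genome-scale inputs (read counts from sequencing, intensities from
hybridization) are filtered to detectable miRNAs (maximum across samples
at or above a threshold, default 1), normalized so every sample's total
equals the median total across samples, and log2 transformed with a
pseudocount.  RT-PCR quantitation-cycle (Cq) tables are simply negated:
one PCR cycle is one doubling, so -Cq is already a log2-scale signal, and
no detection filter or total normalization applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .design import SampleManifest

__all__ = [
    "ExpressionTable",
    "Log2Table",
    "read_expression_table",
    "detect_filter",
    "normalize_median_total",
    "to_log2",
    "cq_to_log2",
]

PlatformKind = Literal["counts", "intensity", "cq"]


def _check_frame(values: pd.DataFrame, manifest: SampleManifest) -> None:
    if values.index.has_duplicates:
        dupes = sorted(values.index[values.index.duplicated()].unique().tolist())
        raise ValueError(f"duplicated miRNA ids: {dupes[:10]}")
    expected = manifest.sample_ids
    missing = [s for s in expected if s not in values.columns]
    extra = [c for c in values.columns if c not in expected]
    if missing:
        raise ValueError(f"table is missing manifest samples: {missing}")
    if extra:
        raise ValueError(f"table has columns not in the manifest: {extra}")


@dataclass
class ExpressionTable:
    """miRNA x sample measurement matrix with its manifest and platform kind.

    ``values`` rows are miRNA ids, columns are manifest sample ids (stored
    in manifest order).  Counts and intensities must be nonnegative; Cq
    values are unrestricted.  Missing values are NaN, never zero-coded.
    """

    values: pd.DataFrame
    platform_kind: PlatformKind
    manifest: SampleManifest
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.platform_kind not in ("counts", "intensity", "cq"):
            raise ValueError(f"unknown platform_kind {self.platform_kind!r}")
        _check_frame(self.values, self.manifest)
        self.values = self.values[self.manifest.sample_ids].astype(float)
        if self.platform_kind in ("counts", "intensity"):
            if (self.values.to_numpy() < 0).any():
                raise ValueError(f"{self.platform_kind} values must be nonnegative")

    @property
    def mirna_ids(self) -> list[str]:
        return self.values.index.tolist()

    def subset_samples(self, sample_ids) -> "ExpressionTable":
        sub = self.manifest.subset(sample_ids)
        return ExpressionTable(
            self.values[sub.sample_ids], self.platform_kind, sub, dict(self.provenance)
        )

    def write_tsv(self, path: str | Path, index_label: str = "mirna_id") -> None:
        self.values.to_csv(path, sep="\t", index_label=index_label)


@dataclass
class Log2Table:
    """miRNA x sample matrix of log2-scale signals plus processing provenance."""

    values: pd.DataFrame
    manifest: SampleManifest
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_frame(self.values, self.manifest)
        self.values = self.values[self.manifest.sample_ids].astype(float)

    @property
    def mirna_ids(self) -> list[str]:
        return self.values.index.tolist()


def read_expression_table(
    path: str | Path,
    platform_kind: PlatformKind,
    manifest: SampleManifest,
) -> ExpressionTable:
    """Parse a delimited expression matrix and validate it against the manifest.

    The first column holds miRNA ids, the header row holds sample ids; the
    delimiter is auto-detected between tab and comma.  Errors name the
    offending column or cell.
    """
    path = Path(path)
    header = path.open().readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    raw = pd.read_csv(path, sep=sep, index_col=0)
    raw.index = raw.index.astype(str)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric value {raw.loc[row, col]!r} at miRNA {row!r}, sample {col!r}"
            )
        raw[col] = converted
    return ExpressionTable(
        raw,
        platform_kind,
        manifest,
        provenance={"source": str(path), "delimiter": sep},
    )


def detect_filter(table: ExpressionTable, threshold: float = 1.0) -> ExpressionTable:
    """Keep miRNAs detectable in at least one sample (max across samples >= threshold)."""
    if table.platform_kind == "cq":
        raise ValueError("detection filtering does not apply to Cq tables")
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    keep = table.values.max(axis=1) >= threshold
    if not keep.any():
        warnings.warn("detection filter removed every miRNA", stacklevel=2)
    prov = dict(table.provenance)
    prov["detect_filter"] = {
        "threshold": threshold,
        "retained": int(keep.sum()),
        "removed": int((~keep).sum()),
    }
    return ExpressionTable(table.values.loc[keep], table.platform_kind, table.manifest, prov)


def normalize_median_total(table: ExpressionTable) -> ExpressionTable:
    """Scale each sample so its total equals the median total across samples."""
    if table.platform_kind == "cq":
        raise ValueError("total normalization does not apply to Cq tables")
    totals = table.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total signal: {zero.index.tolist()}")
    median_total = float(totals.median())
    scaled = table.values * (median_total / totals)
    prov = dict(table.provenance)
    prov["normalize_median_total"] = {
        "median_total": median_total,
        "scale_factors": {s: float(median_total / t) for s, t in totals.items()},
    }
    return ExpressionTable(scaled, table.platform_kind, table.manifest, prov)


def to_log2(table: ExpressionTable, pseudocount: float = 1.0) -> Log2Table:
    """log2(value + pseudocount) for counts/intensity tables."""
    if table.platform_kind == "cq":
        raise ValueError("use cq_to_log2 for Cq tables")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    shifted = table.values + pseudocount
    if (shifted.to_numpy() <= 0).any():
        raise ValueError("value + pseudocount must be positive for log2 transform")
    prov = dict(table.provenance)
    prov["log2"] = {"pseudocount": pseudocount}
    return Log2Table(np.log2(shifted), table.manifest, prov)


def cq_to_log2(table: ExpressionTable) -> Log2Table:
    """Negate Cq values to obtain log2-scale signals.

    A difference of one cycle corresponds to a 2-fold abundance difference,
    so -Cq differences are directly comparable to log2 ratios from the
    genome-scale platforms.  No detection filter or normalization is
    applied; whether intensities upstream were background-subtracted is
    the lab's responsibility and is noted in provenance.
    """
    if table.platform_kind != "cq":
        raise ValueError("cq_to_log2 requires a Cq table")
    prov = dict(table.provenance)
    prov["cq_to_log2"] = {"note": "log2 signal = -Cq; no filtering or normalization"}
    return Log2Table(-table.values, table.manifest, prov)
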