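"""Readers and writers for the plain-text formats the package touches.

Intervals travel as BED (0-based, half-open, tab-separated); count and score
matrices as TSV with a feature-id first column and a sample-id header row;
methylation as a TSV with paired ``<sample>.beta`` / ``<sample>.cov`` columns.
Run configuration is a single YAML file that round-trips identically.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger("cellwise")

__all__ = [
    "read_bed",
    "write_bed",
    "read_matrix",
    "write_matrix",
    "read_methylation",
    "write_methylation",
    "RunConfig",
]


class BedParseError(ValueError):
    pass


def read_bed(path: str | Path) -> pd.DataFrame:
    """Parse a BED file into (chrom, start, end[, name]); header lines skipped."""
    rows = []
    has_name = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                logger.info("read_bed: skipping header line %d", lineno)
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise BedParseError(f"{path}:{lineno}: end <= start")
            name = parts[3] if len(parts) > 3 else None
            if has_name is None:
                has_name = name is not None
            rows.append((parts[0], start, end, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    if not has_name:
        df = df.drop(columns="name")
    return df


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end"] + (["name"] if "name" in intervals else [])
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_matrix(path: str | Path, allow_missing: bool = False) -> pd.DataFrame:
    """Features x samples TSV with feature ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(f"{path}: non-numeric cell at feature {bad!r}, sample {col!r}")
    if not allow_missing and df.isna().any().any():
        feat = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing value at feature {feat!r}")
    return df


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def write_methylation(beta: pd.DataFrame, coverage: pd.DataFrame, path: str | Path) -> None:
    paired = {}
    for s in beta.columns:
        paired[f"{s}.beta"] = beta[s]
        paired[f"{s}.cov"] = coverage[s]
    pd.DataFrame(paired, index=beta.index).to_csv(path, sep="\t")


def read_methylation(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = [c[:-5] for c in df.columns if c.endswith(".beta")]
    beta = df[[f"{s}.beta" for s in samples]].set_axis(samples, axis=1)
    cov = df[[f"{s}.cov" for s in samples]].set_axis(samples, axis=1).astype(int)
    return beta, cov


@dataclass
class RunConfig:
    """Configuration of a full synthetic-study pipeline run."""

    seed: int = 0
    n_individuals: int = 50
    alpha: list = field(default_factory=lambda: [16.0, 8.0, 2.0, 8.0, 2.0])
    adjacency_sd: float = 0.5
    neuropil_weight: float = 0.8
    neuropil_cv: float = 0.5
    condition_shift: list = field(default_factory=lambda: [0.0, 0.0, 0.0, 0.0, 0.0])
    n_genes: int = 1500
    n_peaks: int = 1500
    n_sites: int = 600
    markers_per_type: int = 80
    peak_markers_per_type: int = 150
    site_marks_per_type: int = 60
    marker_fold: float = 8.0
    dispersion: float = 0.1
    coverage_mean: float = 30.0
    missing_rate: float = 0.05
    da_fraction: float = 0.0
    da_log2fc: float = 0.5
    dar_fc_fold: float = 4.0
    dar_min_mean: float = 1000.0
    models: list = field(
        default_factory=lambda: ["none", "shuffled", "ordered_factor", "continuous_true"]
    )
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
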