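"""Readers, writers, and the run manifest.

All readers validate rather than coerce: malformed BED lines are rejected
with their line number, duplicate protein ids raise, and blank spectral
cells become zero only with a logged warning. Writers round-trip: every
output re-reads to an equal in-memory object.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from rrnclust.pulldown import SpectralCountTable

logger = logging.getLogger("rrnclust")

__all__ = [
    "read_insertions",
    "write_insertions",
    "read_coverage",
    "write_coverage",
    "read_spectral_table",
    "write_spectral_table",
    "read_foci_csv",
    "write_foci_csv",
    "write_manifest",
]


def read_insertions(path: str | Path) -> pd.DataFrame:
    """Read a BED (0-based, half-open) insertion file.

    Requires >= 3 columns; lines with non-integer coordinates, negative
    starts, or start >= end are rejected with an error naming the line.
    Returns a DataFrame with chrom, start, end.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    chroms, starts, ends = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start {start}")
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}")
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
    return pd.DataFrame({"chrom": chroms,
                         "start": np.array(starts, dtype=np.int64),
                         "end": np.array(ends, dtype=np.int64)})


def write_insertions(df: pd.DataFrame, path: str | Path) -> None:
    """Write chrom/start/end records as 3-column BED."""
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False,
                                         index=False)


def read_coverage(path: str | Path) -> pd.DataFrame:
    """Read per-bin coverage TSV (columns: bin_index, mapped_reads)."""
    df = pd.read_csv(path, sep="\t")
    if not {"bin_index", "mapped_reads"}.issubset(df.columns):
        raise ValueError(f"{path}: expected bin_index and mapped_reads columns")
    if (df["mapped_reads"] < 0).any():
        raise ValueError(f"{path}: negative mapped_reads")
    return df[["bin_index", "mapped_reads"]].astype(np.int64)


def write_coverage(df: pd.DataFrame, path: str | Path) -> None:
    df[["bin_index", "mapped_reads"]].to_csv(path, sep="\t", index=False)


def read_spectral_table(path: str | Path,
                        condition: str = "") -> SpectralCountTable:
    """Read a spectral-count CSV: ``protein`` column + replicate columns.

    Blank cells become 0 with a logged warning; non-numeric counts and
    duplicate protein ids raise.
    """
    df = pd.read_csv(path)
    if "protein" not in df.columns:
        raise ValueError(f"{path}: expected a 'protein' column")
    dup = df["protein"][df["protein"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate protein id {dup.iloc[0]!r}")
    rep_cols = [c for c in df.columns if c != "protein"]
    if len(rep_cols) < 2:
        raise ValueError(f"{path}: need >= 2 replicate columns")
    if df[rep_cols].isna().any().any():
        logger.warning("%s: blank spectral cells treated as 0", path)
        df[rep_cols] = df[rep_cols].fillna(0)
    try:
        counts = df[rep_cols].astype(np.int64).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric spectral counts") from exc
    return SpectralCountTable(proteins=list(df["protein"]), counts=counts,
                              condition=condition)


def write_spectral_table(table: SpectralCountTable, path: str | Path) -> None:
    df = pd.DataFrame(table.counts,
                      columns=[f"rep{j + 1}"
                               for j in range(table.n_replicates)])
    df.insert(0, "protein", table.proteins)
    df.to_csv(path, index=False)


def read_foci_csv(path: str | Path) -> pd.DataFrame:
    """Read a focus-coordinate CSV (image_id, channel, x_px, y_px, intensity)."""
    df = pd.read_csv(path)
    required = {"image_id", "channel", "x_px", "y_px", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    return df


def write_foci_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, params: dict, seed: int | None,
                   inputs: list[str | Path] = (),
                   outputs: list[str | Path] = ()) -> Path:
    """Write a manifest JSON recording parameters, seed, and output hashes.

    Every pipeline output is regenerable from the manifest alone: it echoes
    the full parameter set, the seed, and the sha256 of each input/output.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": seed,
        "parameters": params,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "outputs": {str(p): _sha256(Path(p)) for p in outputs},
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
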