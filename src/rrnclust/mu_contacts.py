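"""Genome-binned Mu-transposition contact profiles.

Mu transposition requires physical contact between the donor phage and its
target DNA, so the per-bin frequency of insertions from a fixed donor locus
is a proxy for chromosomal contact frequency. The pipeline here:

1. partition the genome into ``n_bins`` equal bins (default 100, ~46 kb for
   the 4.64 Mb E. coli chromosome);
2. count insertion sites per bin per replicate;
3. normalize each replicate for sequencing depth and for the replication
   copy-number gradient using each bin's share of total mapped reads:
   ``f_b = (I_b / sum I) / (R_b / sum R)``, then rescale to percent of the
   maximum bin (``p_b``, max = 100);
4. average replicates (mean, sample SD) and compare conditions at the
   rRNA-operon-containing bins with a two-tailed Student t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenomeBinning",
    "InsertionProfile",
    "NormalizedProfile",
    "ConditionSummary",
    "RrnComparison",
    "make_binning",
    "bin_insertions",
    "normalize_profile",
    "aggregate_replicates",
    "compare_rrn_bins",
    "pooled_t_test",
    "heatmap_matrix",
    "render_heatmap",
]


@dataclass(frozen=True)
class GenomeBinning:
    """Equal partition of [0, genome_length) into 1-indexed bins.

    Bin b covers the 0-based half-open interval
    [floor((b-1) * w), floor(b * w)) with w = genome_length / n_bins; the
    last bin extends to the genome end, so the partition is exact and bin
    widths differ by less than 1 bp.
    """

    genome_length_bp: int
    n_bins: int = 100

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.genome_length_bp < self.n_bins:
            raise ValueError("need genome_length_bp >= n_bins >= 1")

    @property
    def width_bp(self) -> float:
        return self.genome_length_bp / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        w = self.genome_length_bp / self.n_bins
        e = np.floor(w * np.arange(self.n_bins + 1)).astype(np.int64)
        e[-1] = self.genome_length_bp
        return e

    def bin_of(self, position: int | np.ndarray) -> np.ndarray:
        """1-based bin index of 0-based genomic position(s)."""
        pos = np.atleast_1d(np.asarray(position, dtype=np.int64))
        if (pos < 0).any() or (pos >= self.genome_length_bp).any():
            bad = pos[(pos < 0) | (pos >= self.genome_length_bp)][0]
            raise ValueError(
                f"position {bad} outside [0, {self.genome_length_bp})")
        idx = np.searchsorted(self.edges, pos, side="right")
        return idx.astype(int)


@dataclass
class InsertionProfile:
    """Raw per-bin insertion counts and coverage for one replicate."""

    counts: np.ndarray          # I_b, length n_bins
    coverage: np.ndarray        # R_b, total mapped reads per bin
    replicate: str = ""
    condition: str = ""
    start_bin: int | None = None


@dataclass
class NormalizedProfile:
    """Depth- and replication-corrected profile for one replicate.

    ``frequency`` is f_b (NaN where coverage is zero and the bin is masked);
    ``percent_of_max`` is p_b in [0, 100] with the maximum unmasked bin at
    exactly 100.
    """

    frequency: np.ndarray
    percent_of_max: np.ndarray
    replicate: str = ""
    condition: str = ""


@dataclass
class ConditionSummary:
    """Per-bin replicate mean and sample SD of percent-of-max."""

    mean: np.ndarray
    sd: np.ndarray
    n_replicates: int
    condition: str = ""


@dataclass
class RrnComparison:
    """Per-bin two-sample t results at rRNA-operon bins."""

    table: pd.DataFrame  # bin, t, p, significant, mean_a, mean_b
    alpha: float = 0.05


def make_binning(genome_length_bp: int, n_bins: int = 100) -> GenomeBinning:
    """Construct the equal genome partition (see :class:`GenomeBinning`)."""
    return GenomeBinning(genome_length_bp=int(genome_length_bp),
                         n_bins=int(n_bins))


def bin_insertions(positions: np.ndarray | pd.Series,
                   binning: GenomeBinning) -> np.ndarray:
    """Count insertion positions (0-based starts) per bin.

    Every position maps to exactly one bin; out-of-range positions raise.
    The returned vector has length ``binning.n_bins`` and sums to the number
    of input records.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size == 0:
        return np.zeros(binning.n_bins, dtype=np.int64)
    bins = binning.bin_of(pos)
    return np.bincount(bins - 1, minlength=binning.n_bins).astype(np.int64)


def normalize_profile(profile: InsertionProfile) -> NormalizedProfile:
    """Depth correction then per-bin coverage (replication) correction.

    f_b = (I_b / sum_b I_b) / (R_b / sum_b R_b); bins with zero coverage are
    masked (NaN) and excluded from the percent-of-max rescaling, which sets
    the largest unmasked f_b to exactly 100.
    """
    counts = np.asarray(profile.counts, dtype=float)
    cov = np.asarray(profile.coverage, dtype=float)
    if counts.shape != cov.shape:
        raise ValueError("counts and coverage must have equal length")
    if counts.sum() <= 0:
        raise ValueError("all-zero insertion counts")
    if cov.sum() <= 0:
        raise ValueError("all-zero coverage")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (counts / counts.sum()) / (cov / cov.sum())
    f[cov == 0] = np.nan
    fmax = np.nanmax(f)
    p = 100.0 * f / fmax if fmax > 0 else np.zeros_like(f)
    return NormalizedProfile(frequency=f, percent_of_max=p,
                             replicate=profile.replicate,
                             condition=profile.condition)


def aggregate_replicates(profiles: list[NormalizedProfile]) -> ConditionSummary:
    """Per-bin mean and sample SD (ddof=1) of percent-of-max over replicates.

    Percent-of-max scaling is applied per replicate before averaging, so the
    SD reflects replicate-to-replicate scaling noise. With a single
    replicate the SD is reported as 0.
    """
    if not profiles:
        raise ValueError("need at least one replicate")
    mats = [p.percent_of_max for p in profiles]
    if len({m.shape for m in mats}) != 1:
        raise ValueError("replicates have mismatched bin counts")
    arr = np.vstack(mats)
    mean = np.nanmean(arr, axis=0)
    sd = (np.nanstd(arr, axis=0, ddof=1) if arr.shape[0] > 1
          else np.zeros(arr.shape[1]))
    return ConditionSummary(mean=mean, sd=sd, n_replicates=arr.shape[0],
                            condition=profiles[0].condition)


def pooled_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample two-tailed Student t (equal-variance, pooled).

    Degenerate conventions: identical constant groups give p = 1; constant
    groups with different means give p = 0 (infinite t).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def compare_rrn_bins(values_a: dict[int, np.ndarray],
                     values_b: dict[int, np.ndarray],
                     rrn_bins: list[int] | None = None,
                     alpha: float = 0.05,
                     welch: bool = False) -> RrnComparison:
    """Per-bin two-tailed t test between two conditions' replicate values.

    ``values_a`` / ``values_b`` map bin index -> replicate percent-of-max
    values. No multiple-testing correction is applied across bins; each bin
    is starred independently at ``alpha``.
    """
    bins = sorted(rrn_bins if rrn_bins is not None else values_a.keys())
    rows = []
    for b in bins:
        a_vals = np.asarray(values_a[b], dtype=float)
        b_vals = np.asarray(values_b[b], dtype=float)
        if welch:
            t, p = stats.ttest_ind(a_vals, b_vals, equal_var=False)
            t, p = float(t), float(p)
        else:
            t, p = pooled_t_test(a_vals, b_vals)
        rows.append({"bin": b, "t": t, "p": p, "significant": p < alpha,
                     "mean_a": a_vals.mean(), "mean_b": b_vals.mean()})
    return RrnComparison(table=pd.DataFrame(rows), alpha=alpha)


def heatmap_matrix(summaries: list[ConditionSummary]) -> pd.DataFrame:
    """Bins x conditions matrix of mean percent-of-max (column order kept)."""
    if not summaries:
        raise ValueError("no conditions")
    n_bins = {len(s.mean) for s in summaries}
    if len(n_bins) != 1:
        raise ValueError("conditions have mismatched bin counts")
    data = {s.condition or f"condition_{i}": s.mean
            for i, s in enumerate(summaries)}
    df = pd.DataFrame(data, index=pd.RangeIndex(1, n_bins.pop() + 1,
                                                name="bin"))
    return df


def render_heatmap(matrix: pd.DataFrame, path: str) -> None:
    """Write a heat-map figure; the 100% bin stands out at the color top."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4 + 0.6 * matrix.shape[1], 8))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="viridis",
                   vmin=0, vmax=100, interpolation="nearest")
    ax.set_xticks(range(matrix.shape[1]), labels=matrix.columns, rotation=45,
                  ha="right")
    ax.set_ylabel("genome bin")
    fig.colorbar(im, ax=ax, label="transposition frequency (% of max)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
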