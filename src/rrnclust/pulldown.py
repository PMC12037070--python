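"""Spectral-count enrichment of dCas9 pulldowns against a control pulldown.

A locus-directed dCas9 pulldown recovers proteins in the locus
neighborhood; a pulldown with a gRNA targeting an unrelated gene (lacZ)
controls for background binding. For every protein and replicate the
analysis forms a depth-normalized log2 target/control count ratio, converts
it to a robust z-score against the bulk of (presumed null) proteins within
the replicate, and calls a protein enriched when its z exceeds the cutoff
(default 2.5) in every replicate. An empirical FDR is attached by
recomputing min-z under all target/control label swaps.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpectralCountTable",
    "EnrichmentConfig",
    "EnrichmentResult",
    "normalize_to_control",
    "z_scores",
    "call_enriched",
    "enrich",
    "intersect_samples",
]


@dataclass
class SpectralCountTable:
    """Protein x replicate integer spectral counts for one condition."""

    proteins: list[str]
    counts: np.ndarray  # shape (n_proteins, n_replicates), non-negative ints
    condition: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (protein x replicate)")
        if len(self.proteins) != self.counts.shape[0]:
            raise ValueError("protein ids and count rows disagree")
        if (self.counts < 0).any():
            raise ValueError("spectral counts must be >= 0")
        if len(set(self.proteins)) != len(self.proteins):
            raise ValueError("duplicate protein ids")

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   condition: str = "") -> "SpectralCountTable":
        """Build from the supplementary-table layout: ``protein`` id column
        plus one numeric column per replicate."""
        if "protein" not in df.columns:
            raise ValueError("expected a 'protein' column")
        rep_cols = [c for c in df.columns if c != "protein"]
        if len(rep_cols) < 2:
            raise ValueError("need >= 2 replicate columns")
        counts = df[rep_cols].to_numpy()
        return cls(proteins=list(df["protein"]), counts=counts,
                   condition=condition)

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class EnrichmentConfig:
    """Enrichment-call parameters.

    z_cutoff
        Per-replicate z threshold (a protein must exceed it per the call
        rule; default all replicates).
    fdr_level
        Empirical (label-permutation) FDR level for the FDR status flag.
    pseudocount
        Added to target and control counts before the log-ratio.
    robust
        Median/MAD z standardization when True; mean/SD when False.
    call_rule
        ``all-replicates`` (default) or ``any-replicate``.
    """

    z_cutoff: float = 2.5
    fdr_level: float = 0.05
    pseudocount: float = 1.0
    robust: bool = True
    call_rule: str = "all-replicates"

    def __post_init__(self) -> None:
        if self.z_cutoff <= 0:
            raise ValueError("z_cutoff must be > 0")
        if not (0 < self.fdr_level < 1):
            raise ValueError("fdr_level must be in (0, 1)")
        if self.call_rule not in ("all-replicates", "any-replicate"):
            raise ValueError("unknown call_rule")


@dataclass
class EnrichmentResult:
    """Per-protein z-scores and calls for one target gRNA."""

    proteins: list[str]
    z: pd.DataFrame            # protein x replicate z-scores
    enriched: list[str]        # proteins passing the call rule at z_cutoff
    fdr: pd.Series             # empirical FDR at each protein's min-z
    fdr_pass: list[str]        # enriched proteins with FDR <= fdr_level
    condition: str = ""


def _align_tables(target: SpectralCountTable,
                  control: SpectralCountTable) -> tuple[list[str], np.ndarray,
                                                        np.ndarray]:
    """Union protein universe; absent proteins get zero counts."""
    if control.n_replicates < target.n_replicates:
        raise ValueError("fewer control than target replicates")
    proteins = list(dict.fromkeys(target.proteins + control.proteins))
    r = target.n_replicates

    def expand(tbl: SpectralCountTable) -> np.ndarray:
        out = np.zeros((len(proteins), r), dtype=float)
        index = {p: i for i, p in enumerate(tbl.proteins)}
        for i, p in enumerate(proteins):
            if p in index:
                out[i] = tbl.counts[index[p], :r]
        return out

    return proteins, expand(target), expand(control)


def normalize_to_control(target: SpectralCountTable,
                         control: SpectralCountTable,
                         config: EnrichmentConfig | None = None,
                         ) -> pd.DataFrame:
    """Per-protein per-replicate log2 target/control ratios.

    Replicate i of the target is paired with replicate i of the control;
    the target column is depth-matched (scaled) to its paired control
    column's total, then
    log2((target_i + pseudocount) / (control_i + pseudocount)).
    Depth-matching within the pair makes the ratios exactly invariant to
    rescaling a target replicate and keeps counts on the control's raw
    scale, where the pseudocount has its usual meaning.
    """
    config = config or EnrichmentConfig()
    proteins, t, c = _align_tables(target, control)
    t_tot = t.sum(axis=0)
    c_tot = c.sum(axis=0)
    if (t_tot == 0).any() or (c_tot == 0).any():
        raise ValueError("a replicate column has zero total counts")
    t_scaled = t * (c_tot / t_tot)
    c_scaled = c
    ratios = np.log2((t_scaled + config.pseudocount)
                     / (c_scaled + config.pseudocount))
    cols = [f"rep{j + 1}" for j in range(t.shape[1])]
    return pd.DataFrame(ratios, index=pd.Index(proteins, name="protein"),
                        columns=cols)


def z_scores(log_ratios: pd.DataFrame,
             config: EnrichmentConfig | None = None) -> pd.DataFrame:
    """Standardize log-ratios within each replicate.

    Robust mode (default): z = (x - median) / (1.4826 * MAD), so the null
    bulk of proteins sits near z = 0 regardless of a minority of true
    positives. Falls back to mean/SD when the MAD is zero; if the SD is
    also zero, all z are 0. With fewer than 10 proteins the scale estimate
    is unstable and a warning is issued.
    """
    config = config or EnrichmentConfig()
    x = log_ratios.to_numpy(dtype=float)
    if x.shape[0] < 10:
        warnings.warn("fewer than 10 proteins: z-scores are unstable",
                      stacklevel=2)
    z = np.zeros_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        if config.robust:
            center = np.median(col)
            scale = 1.4826 * np.median(np.abs(col - center))
            if scale == 0:
                center, scale = col.mean(), col.std(ddof=0)
        else:
            center, scale = col.mean(), col.std(ddof=0)
        z[:, j] = 0.0 if scale == 0 else (col - center) / scale
    return pd.DataFrame(z, index=log_ratios.index,
                        columns=log_ratios.columns)


def _min_z(z: np.ndarray, rule: str) -> np.ndarray:
    # the statistic the call thresholds: min over replicates for the
    # all-replicates rule (top-right-square geometry), max for any-replicate
    return z.min(axis=1) if rule == "all-replicates" else z.max(axis=1)


def call_enriched(z: pd.DataFrame, target: SpectralCountTable,
                  control: SpectralCountTable,
                  config: EnrichmentConfig | None = None) -> EnrichmentResult:
    """Call enriched proteins and attach an empirical permutation FDR.

    A protein is enriched when z > z_cutoff in every replicate (default
    rule). The null distribution of the call statistic (min-z across
    replicates) is built by recomputing the full normalize -> z pipeline
    under every non-identity swap of target/control labels within replicate
    pairs (2^r - 1 swaps for r replicates); a protein's FDR is the expected
    number of null proteins at or above its min-z divided by the observed
    number.
    """
    config = config or EnrichmentConfig()
    stat = _min_z(z.to_numpy(), config.call_rule)
    proteins = list(z.index)
    enriched_mask = stat > config.z_cutoff if config.call_rule != "all-replicates" \
        else (z.to_numpy() > config.z_cutoff).all(axis=1)
    enriched = [p for p, m in zip(proteins, enriched_mask) if m]

    # permutation null: swap target/control within replicate pairs
    r = z.shape[1]
    null_stats: list[np.ndarray] = []
    for pattern in itertools.product([0, 1], repeat=r):
        if not any(pattern):
            continue
        t_cnt = target.counts[:, :r].astype(float).copy()
        c_cnt = control.counts[:, :r].astype(float).copy()
        for j, swap in enumerate(pattern):
            if swap:
                t_cnt[:, j], c_cnt[:, j] = (c_cnt[:, j].copy(),
                                            t_cnt[:, j].copy())
        t_tbl = SpectralCountTable(proteins=target.proteins, counts=t_cnt)
        c_tbl = SpectralCountTable(proteins=control.proteins, counts=c_cnt)
        lr = normalize_to_control(t_tbl, c_tbl, config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            zz = z_scores(lr, config)
        null_stats.append(_min_z(zz.to_numpy(), config.call_rule))
    null = np.concatenate(null_stats) if null_stats else np.array([])
    n_perm = len(null_stats) if null_stats else 1

    fdr_vals = np.ones(len(proteins))
    for i, s in enumerate(stat):
        observed = int((stat >= s).sum())
        expected_null = float((null >= s).sum()) / n_perm if null.size else 0.0
        fdr_vals[i] = min(1.0, expected_null / max(observed, 1))
    fdr = pd.Series(fdr_vals, index=z.index, name="fdr")
    fdr_pass = [p for p in enriched if fdr[p] <= config.fdr_level]
    return EnrichmentResult(proteins=proteins, z=z, enriched=enriched,
                            fdr=fdr, fdr_pass=fdr_pass,
                            condition=target.condition)


def enrich(target: SpectralCountTable, control: SpectralCountTable,
           config: EnrichmentConfig | None = None) -> EnrichmentResult:
    """Full pipeline: control normalization -> z-scores -> enrichment calls."""
    config = config or EnrichmentConfig()
    lr = normalize_to_control(target, control, config)
    z = z_scores(lr, config)
    return call_enriched(z, target, control, config)


def intersect_samples(results: dict[str, EnrichmentResult]) -> pd.DataFrame:
    """Protein membership across samples (the upset-plot table).

    Returns a boolean protein x sample matrix plus an ``n_samples`` column;
    proteins enriched nowhere are omitted. Intersection-pattern counts are
    recoverable by grouping on the sample columns.
    """
    if not results:
        raise ValueError("need at least one result")
    universe = sorted({p for r in results.values() for p in r.enriched})
    data = {name: [p in set(r.enriched) for p in universe]
            for name, r in results.items()}
    df = pd.DataFrame(data, index=pd.Index(universe, name="protein"))
    df["n_samples"] = df.sum(axis=1)
    return df
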