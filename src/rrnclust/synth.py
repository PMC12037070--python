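"""Synthetic data generators with ground truth.

Each generator emulates one class of experimental input:

* :func:`simulate_foci_field` — two-channel fluorescence fields of sparse
  monolayer cells, each carrying one (or two) GFP/CFP locus pairs whose
  physical separation follows a log-normal law with a requested median.
* :func:`simulate_mu_insertions` — genome-binned Mu insertion counts under a
  contact-propensity profile modulated by an ori→ter replication copy-number
  gradient, plus matched per-bin sequencing coverage.
* :func:`simulate_spectral_counts` — negative-binomial spectral-count tables
  for a target pulldown and a control pulldown with a planted enriched subset.

All generators are deterministic given ``seed`` and return a
:class:`SyntheticTruth` carrying the generating parameters' ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FociSimParams",
    "MuSimParams",
    "SpectraSimParams",
    "SyntheticTruth",
    "SimulatedFociField",
    "SimulatedMuExperiment",
    "simulate_foci_field",
    "simulate_mu_insertions",
    "simulate_spectral_counts",
]

#: E. coli MG1655 chromosome length (bp).
MG1655_LENGTH_BP = 4_641_652


@dataclass(frozen=True)
class FociSimParams:
    """Parameters for two-channel focus-field simulation.

    ``clustered_median_nm`` and ``declustered_median_nm`` are the target
    medians of the pair-separation law for the two conditions; the field's
    condition is selected at simulation time. ``distance_spread`` is the
    log-scale sigma of the log-normal separation law (the median is exact by
    construction). Foci are rendered as Gaussian spots of width
    ``psf_sigma_px`` on a noisy background.
    """

    n_cells: int = 200
    foci_per_cell: int = 1
    clustered_median_nm: float = 134.0
    declustered_median_nm: float = 566.0
    distance_spread: float = 0.6
    psf_sigma_px: float = 1.5
    pixel_nm: float = 62.0
    image_shape: tuple[int, int] | None = None
    background_level: float = 200.0
    noise_sd: float = 10.0
    amplitude: float = 1200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.foci_per_cell not in (1, 2):
            raise ValueError("foci_per_cell must be 1 or 2")
        for name in ("clustered_median_nm", "declustered_median_nm",
                     "distance_spread", "pixel_nm", "amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be > 0")
        if self.image_shape is not None and min(self.image_shape) <= 0:
            raise ValueError("image dimensions must be positive")


@dataclass(frozen=True)
class MuSimParams:
    """Parameters for a single-round Mu transposition experiment.

    ``contact_profile`` is the per-bin relative insertion propensity (the
    contact signal the analysis must recover); ``None`` means uniform.
    ``gradient_strength`` interpolates the replication copy-number gradient
    between flat (0) and the full 2x ori:ter ratio (1).
    ``local_contact_weight`` multiplies the donor bin's propensity by
    ``1 + weight`` to emulate elevated self-bin insertion.
    """

    genome_length_bp: int = MG1655_LENGTH_BP
    n_bins: int = 100
    n_insertions: int = 100_000
    start_bin: int = 73
    local_contact_weight: float = 0.0
    contact_profile: tuple[float, ...] | None = None
    ori_bin: int = 90
    gradient_strength: float = 1.0
    n_replicates: int = 3
    reads_per_replicate: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length_bp < self.n_bins or self.n_bins < 1:
            raise ValueError("need genome_length_bp >= n_bins >= 1")
        if self.n_insertions < 0:
            raise ValueError("n_insertions must be >= 0")
        if not (1 <= self.start_bin <= self.n_bins):
            raise ValueError("start_bin out of range")
        if not (1 <= self.ori_bin <= self.n_bins):
            raise ValueError("ori_bin out of range")
        if not (0.0 <= self.gradient_strength <= 1.0):
            raise ValueError("gradient_strength must be in [0, 1]")
        if self.local_contact_weight < 0:
            raise ValueError("local_contact_weight must be >= 0")
        if self.contact_profile is not None:
            prof = np.asarray(self.contact_profile, dtype=float)
            if prof.shape != (self.n_bins,):
                raise ValueError("contact_profile length must equal n_bins")
            if (prof < 0).any() or prof.sum() == 0:
                raise ValueError(
                    "contact_profile entries must be >= 0 and not all zero")


@dataclass(frozen=True)
class SpectraSimParams:
    """Parameters for paired target/control spectral-count tables.

    Counts are negative-binomial with mean ``baseline_mean`` and shape
    ``dispersion`` (variance = mu + mu^2 / dispersion). ``planted`` maps
    protein index -> fold-enrichment applied to the target mean only.
    """

    n_proteins: int = 200
    n_replicates: int = 3
    baseline_mean: float = 20.0
    dispersion: float = 10.0
    planted: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for idx, fold in self.planted.items():
            if not (0 <= idx < self.n_proteins):
                raise ValueError(f"planted index {idx} out of range")
            if fold <= 0:
                raise ValueError("fold-enrichment must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth carried alongside every simulated dataset."""

    true_pair_distances_nm: np.ndarray | None = None
    true_contact_profile: np.ndarray | None = None
    planted_enriched: frozenset[str] = frozenset()


@dataclass
class SimulatedFociField:
    """Rendered two-channel field plus the coordinates that produced it."""

    gfp_image: np.ndarray
    cfp_image: np.ndarray
    coords: pd.DataFrame  # image_id, channel, x_px, y_px, intensity
    truth: SyntheticTruth
    pixel_nm: float


@dataclass
class SimulatedMuExperiment:
    """Per-replicate insertion positions and per-bin coverage, plus truth."""

    insertions: list[pd.DataFrame]  # BED-like: chrom, start, end
    coverage: list[pd.DataFrame]    # bin_index, mapped_reads
    truth: SyntheticTruth
    genome_length_bp: int
    n_bins: int


def _lognormal_with_median(rng: np.random.Generator, median: float,
                           sigma: float, size: int) -> np.ndarray:
    # median of lognormal(mu, sigma) is exp(mu); set mu = log(median)
    return np.exp(rng.normal(math.log(median), sigma, size=size))


def _render_spots(image: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                  amplitude: float, sigma: float) -> None:
    """Add Gaussian spots in-place at sub-pixel centers (x, y) = (col, row)."""
    h, w = image.shape
    r = max(3, int(math.ceil(4 * sigma)))
    for x, y in zip(xs, ys):
        c0, c1 = max(0, int(x) - r), min(w, int(x) + r + 1)
        r0, r1 = max(0, int(y) - r), min(h, int(y) + r + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        cols = np.arange(c0, c1)
        rows = np.arange(r0, r1)
        gx = np.exp(-((cols - x) ** 2) / (2 * sigma**2))
        gy = np.exp(-((rows - y) ** 2) / (2 * sigma**2))
        image[r0:r1, c0:c1] += amplitude * gy[:, None] * gx[None, :]


def simulate_foci_field(
    params: FociSimParams,
    condition: str = "clustered",
    image_id: str = "sim",
) -> tuple[SimulatedFociField, SyntheticTruth]:
    """Simulate one two-channel field of cells carrying GFP/CFP locus pairs.

    Each cell occupies a private rectangle (cells never overlap, as in a
    sparse monolayer). Within a cell, each pair's separation is drawn from a
    log-normal law whose median is the condition's target; the pair's
    orientation is uniform. Foci are rendered as Gaussian spots of amplitude
    ``params.amplitude`` over a constant background with i.i.d. Gaussian
    noise, quantized to 16-bit.

    Returns the simulated field (images + exact coordinate table) and its
    :class:`SyntheticTruth`, whose ``true_pair_distances_nm`` are the exact
    generated separations.
    """
    if condition not in ("clustered", "declustered"):
        raise ValueError("condition must be 'clustered' or 'declustered'")
    median_nm = (params.clustered_median_nm if condition == "clustered"
                 else params.declustered_median_nm)
    rng = np.random.default_rng(params.seed)

    n_pairs = params.n_cells * params.foci_per_cell
    dists_nm = _lognormal_with_median(rng, median_nm, params.distance_spread,
                                      n_pairs)
    angles = rng.uniform(0, 2 * math.pi, size=n_pairs)
    dists_px = dists_nm / params.pixel_nm

    margin = 4.0 * params.psf_sigma_px + 3.0
    # per-cell bounding boxes sized to their own pair geometry
    cell_w = np.empty(params.n_cells)
    cell_h = np.empty(params.n_cells)
    for i in range(params.n_cells):
        sl = slice(i * params.foci_per_cell, (i + 1) * params.foci_per_cell)
        dx = np.abs(dists_px[sl] * np.cos(angles[sl])).max(initial=0.0)
        dy = np.abs(dists_px[sl] * np.sin(angles[sl])).max(initial=0.0)
        cell_w[i] = dx + 2 * margin
        cell_h[i] = dy + 2 * margin

    # shelf packing into a roughly square canvas
    target_w = max(64.0, math.sqrt(float((cell_w * cell_h).sum()) * 1.3))
    if params.image_shape is not None:
        target_w = max(target_w, float(params.image_shape[1]))
    xs0 = np.empty(params.n_cells)
    ys0 = np.empty(params.n_cells)
    cur_x, cur_y, row_h = 0.0, 0.0, 0.0
    for i in range(params.n_cells):
        if cur_x + cell_w[i] > target_w and cur_x > 0:
            cur_y += row_h
            cur_x, row_h = 0.0, 0.0
        xs0[i], ys0[i] = cur_x, cur_y
        cur_x += cell_w[i]
        row_h = max(row_h, cell_h[i])
    canvas_h = int(math.ceil(cur_y + row_h)) + 1
    canvas_w = int(math.ceil(target_w)) + 1
    if params.image_shape is not None:
        canvas_h = max(canvas_h, params.image_shape[0])
        canvas_w = max(canvas_w, params.image_shape[1])

    gfp_x = np.empty(n_pairs)
    gfp_y = np.empty(n_pairs)
    cfp_x = np.empty(n_pairs)
    cfp_y = np.empty(n_pairs)
    for i in range(params.n_cells):
        for j in range(params.foci_per_cell):
            k = i * params.foci_per_cell + j
            dx = dists_px[k] * math.cos(angles[k])
            dy = dists_px[k] * math.sin(angles[k])
            # anchor the GFP focus so both foci stay inside the cell box
            ax = xs0[i] + margin + (max(0.0, -dx))
            ay = ys0[i] + margin + (max(0.0, -dy))
            # jitter within remaining slack, keeping the pair in-box
            slack_x = cell_w[i] - 2 * margin - abs(dx)
            slack_y = cell_h[i] - 2 * margin - abs(dy)
            ax += rng.uniform(0, max(slack_x, 0.0))
            ay += rng.uniform(0, max(slack_y, 0.0))
            gfp_x[k], gfp_y[k] = ax, ay
            cfp_x[k], cfp_y[k] = ax + dx, ay + dy

    shape = (canvas_h, canvas_w)
    gfp_img = np.full(shape, params.background_level, dtype=float)
    cfp_img = np.full(shape, params.background_level, dtype=float)
    _render_spots(gfp_img, gfp_x, gfp_y, params.amplitude, params.psf_sigma_px)
    _render_spots(cfp_img, cfp_x, cfp_y, params.amplitude, params.psf_sigma_px)
    if params.noise_sd > 0:
        gfp_img += rng.normal(0, params.noise_sd, size=shape)
        cfp_img += rng.normal(0, params.noise_sd, size=shape)
    gfp_u16 = np.clip(gfp_img, 0, 65535).astype(np.uint16)
    cfp_u16 = np.clip(cfp_img, 0, 65535).astype(np.uint16)

    coords = pd.DataFrame({
        "image_id": image_id,
        "channel": ["GFP"] * n_pairs + ["CFP"] * n_pairs,
        "x_px": np.concatenate([gfp_x, cfp_x]),
        "y_px": np.concatenate([gfp_y, cfp_y]),
        "intensity": params.amplitude,
    })
    truth = SyntheticTruth(true_pair_distances_nm=dists_nm)
    sim = SimulatedFociField(gfp_image=gfp_u16, cfp_image=cfp_u16,
                             coords=coords, truth=truth,
                             pixel_nm=params.pixel_nm)
    return sim, truth


def copy_number_gradient(n_bins: int, ori_bin: int,
                         gradient_strength: float) -> np.ndarray:
    """Per-bin relative copy number c(b) = 2^(g * (1 - d(b))).

    d(b) is the circular bin distance from ``ori_bin`` normalized by the
    maximum circular distance, so c(ori_bin) = 2^g and c(farthest bin) = 1.
    This is the expected marker-frequency gradient of an asynchronous
    exponentially growing population (ori-proximal DNA at up to twice the
    terminus copy number).
    """
    b = np.arange(1, n_bins + 1)
    raw = np.abs(b - ori_bin)
    circ = np.minimum(raw, n_bins - raw)
    d = circ / circ.max() if circ.max() > 0 else circ.astype(float)
    return np.power(2.0, gradient_strength * (1.0 - d))


def _bin_widths(genome_length_bp: int, n_bins: int) -> np.ndarray:
    width = genome_length_bp / n_bins
    edges = np.floor(width * np.arange(n_bins + 1)).astype(np.int64)
    edges[-1] = genome_length_bp
    return np.diff(edges), edges


def simulate_mu_insertions(
    params: MuSimParams,
) -> tuple[SimulatedMuExperiment, SyntheticTruth]:
    """Simulate per-replicate Mu insertion positions and bin coverage.

    Insertion probability per bin is proportional to the effective contact
    propensity (contact_profile, with the donor bin boosted by
    ``local_contact_weight``) times the replication copy number c(b); each
    replicate draws ``n_insertions`` insertions multinomially and places
    them uniformly within their bin. Coverage reads are drawn multinomially
    with probability proportional to bin width x c(b), so raw insertion
    counts carry the replication bias and coverage is the proxy that removes
    it.
    """
    rng = np.random.default_rng(params.seed)
    n_bins = params.n_bins
    profile = (np.ones(n_bins) if params.contact_profile is None
               else np.asarray(params.contact_profile, dtype=float))
    effective = profile.copy()
    effective[params.start_bin - 1] *= 1.0 + params.local_contact_weight
    cn = copy_number_gradient(n_bins, params.ori_bin, params.gradient_strength)
    widths, edges = _bin_widths(params.genome_length_bp, n_bins)

    p_ins = effective * cn
    p_ins = p_ins / p_ins.sum()
    p_cov = widths * cn
    p_cov = p_cov / p_cov.sum()

    insertions: list[pd.DataFrame] = []
    coverage: list[pd.DataFrame] = []
    for _rep in range(params.n_replicates):
        counts = rng.multinomial(params.n_insertions, p_ins)
        starts = np.empty(params.n_insertions, dtype=np.int64)
        pos = 0
        for b in range(n_bins):
            k = counts[b]
            if k:
                starts[pos:pos + k] = rng.integers(edges[b], edges[b + 1],
                                                   size=k)
                pos += k
        starts = np.sort(starts[:pos])
        insertions.append(pd.DataFrame({
            "chrom": "chr",
            "start": starts,
            "end": starts + 1,
        }))
        reads = rng.multinomial(params.reads_per_replicate, p_cov)
        coverage.append(pd.DataFrame({
            "bin_index": np.arange(1, n_bins + 1),
            "mapped_reads": reads,
        }))

    truth = SyntheticTruth(true_contact_profile=effective / effective.sum())
    sim = SimulatedMuExperiment(insertions=insertions, coverage=coverage,
                                truth=truth,
                                genome_length_bp=params.genome_length_bp,
                                n_bins=n_bins)
    return sim, truth


def simulate_spectral_counts(
    params: SpectraSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate target and control spectral-count tables.

    Both tables share the protein universe and replicate layout. Control
    counts are NB(mean=baseline_mean, shape=dispersion) everywhere; target
    counts follow the same law except planted proteins, whose target mean is
    multiplied by their fold-enrichment. Tables use the supplementary-table
    layout: a ``protein`` id column plus one integer column per replicate.
    """
    rng = np.random.default_rng(params.seed)
    n, r = params.n_proteins, params.n_replicates
    mu_target = np.full(n, params.baseline_mean)
    for idx, fold in params.planted.items():
        mu_target[idx] *= fold

    def nb(mu: np.ndarray, size: tuple[int, int]) -> np.ndarray:
        shape = params.dispersion
        p = shape / (shape + mu[:, None])
        return rng.negative_binomial(shape, np.broadcast_to(p, size))

    control = nb(np.full(n, params.baseline_mean), (n, r))
    target = nb(mu_target, (n, r))

    ids = [f"P{i:04d}" for i in range(n)]
    rep_cols = [f"rep{j + 1}" for j in range(r)]
    target_df = pd.DataFrame(target, columns=rep_cols)
    target_df.insert(0, "protein", ids)
    control_df = pd.DataFrame(control, columns=rep_cols)
    control_df.insert(0, "protein", ids)
    truth = SyntheticTruth(
        planted_enriched=frozenset(ids[i] for i in params.planted))
    return target_df, control_df, truth
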