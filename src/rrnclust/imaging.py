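"""Two-color focus detection and pair-distance analysis.

The measurement chain mirrors standard FROS (fluorescent repressor/operator
or parS-ParB) locus-pair experiments: detect intensity maxima per channel
after background subtraction, pair every GFP focus with its closest CFP
focus, convert pixel separations to nm, and summarize/compare distance
distributions between conditions. A condition is called "de-clustered" when
the median pair distance rises by at least a configured fold change over the
control (default 2.5x); a Mann-Whitney U p-value is reported alongside but
the call follows the fold rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.morphology import disk, white_tophat

__all__ = [
    "ImagingConfig",
    "FociField",
    "PairDistanceSet",
    "DistanceSummary",
    "ComparisonResult",
    "CellMeasurements",
    "detect_foci",
    "match_pairs",
    "to_nm",
    "summarize",
    "compare_conditions",
    "fold_call",
    "measure_cells",
]


@dataclass(frozen=True)
class ImagingConfig:
    """Tunable parameters of the distance pipeline.

    pixel_nm
        Physical pixel size; 62 nm/px for the 100x objective used here.
    maxima_prominence
        Minimum background-subtracted peak intensity for focus detection.
    background_radius_px
        Radius of the white-tophat structuring element (rolling background).
    fold_change_cutoff
        Median fold change (treatment/control) at or above which a
        de-clustering call is made.
    nm_threshold
        Optional absolute treatment-median threshold (nm); when set, the
        call additionally requires the treatment median to exceed it.
    alpha
        Significance level reported with the Mann-Whitney test.
    subpixel
        Refine maxima to intensity-weighted 3x3 centroids when True.
    mutual_nearest / max_distance_px
        Optional pairing restrictions; both off by default (one-directional
        GFP->nearest-CFP matching with CFP reuse allowed).
    """

    pixel_nm: float = 62.0
    maxima_prominence: float = 100.0
    background_radius_px: int = 10
    fold_change_cutoff: float = 2.5
    nm_threshold: float | None = None
    alpha: float = 0.001
    min_separation_px: int = 2
    subpixel: bool = True
    mutual_nearest: bool = False
    max_distance_px: float | None = None

    def __post_init__(self) -> None:
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be > 0")
        if self.fold_change_cutoff <= 1:
            raise ValueError("fold_change_cutoff must be > 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class FociField:
    """Detected foci of one channel of one image."""

    coords: pd.DataFrame  # x_px, y_px, intensity; sorted by intensity desc
    channel: str
    image_id: str = ""

    @property
    def n(self) -> int:
        return len(self.coords)


@dataclass
class PairDistanceSet:
    """GFP->closest-CFP matched pairs; the unit of the distance figures."""

    pairs: pd.DataFrame  # gfp_x, gfp_y, cfp_x, cfp_y, distance_px[, distance_nm]
    n_unmatched: int = 0
    condition: str = ""

    @property
    def n(self) -> int:
        return len(self.pairs)

    def distances_nm(self) -> np.ndarray:
        if "distance_nm" not in self.pairs.columns:
            raise ValueError("distances not yet converted to nm; call to_nm")
        return self.pairs["distance_nm"].to_numpy()


@dataclass(frozen=True)
class DistanceSummary:
    n: int
    median_nm: float
    q1_nm: float
    q3_nm: float


@dataclass(frozen=True)
class ComparisonResult:
    fold_change: float
    u_statistic: float
    p_value: float
    declustered: bool
    control_median_nm: float
    treatment_median_nm: float


@dataclass
class CellMeasurements:
    lengths_um: np.ndarray
    dapi_intensity: np.ndarray  # per-cell mean, background-subtracted


def detect_foci(image: np.ndarray, config: ImagingConfig,
                channel: str = "", image_id: str = "") -> FociField:
    """Detect foci in one channel: background subtraction then local maxima.

    The rolling background is removed with a white top-hat of radius
    ``config.background_radius_px``; local maxima with background-subtracted
    intensity above ``config.maxima_prominence`` are kept and (optionally)
    refined to the intensity-weighted centroid of their 3x3 neighborhood.
    Foci are returned sorted by descending peak intensity.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")

    bs = white_tophat(image, footprint=disk(config.background_radius_px))
    peaks = peak_local_max(bs, min_distance=config.min_separation_px,
                           threshold_abs=config.maxima_prominence,
                           exclude_border=False)
    xs, ys, vals = [], [], []
    h, w = bs.shape
    for r, c in peaks:
        vals.append(bs[r, c])
        if config.subpixel and 1 <= r < h - 1 and 1 <= c < w - 1:
            win = bs[r - 1:r + 2, c - 1:c + 2]
            total = win.sum()
            if total > 0:
                rows, cols = np.mgrid[r - 1:r + 2, c - 1:c + 2]
                ys.append(float((win * rows).sum() / total))
                xs.append(float((win * cols).sum() / total))
                continue
        ys.append(float(r))
        xs.append(float(c))
    coords = pd.DataFrame({"x_px": xs, "y_px": ys, "intensity": vals})
    coords = coords.sort_values("intensity", ascending=False,
                                kind="stable").reset_index(drop=True)
    return FociField(coords=coords, channel=channel, image_id=image_id)


def match_pairs(gfp: FociField, cfp: FociField,
                config: ImagingConfig | None = None) -> PairDistanceSet:
    """Pair every GFP focus with its closest CFP focus (Euclidean, in px).

    Matching is one-directional: a CFP focus may be the partner of several
    GFP foci. GFP foci with no available CFP partner (empty CFP channel, or
    beyond ``max_distance_px`` when configured) are counted as unmatched.
    Ties in distance resolve to the lowest CFP index (deterministic). With
    ``mutual_nearest`` enabled, only reciprocal nearest pairs are kept.
    """
    config = config or ImagingConfig()
    g = gfp.coords[["x_px", "y_px"]].to_numpy(dtype=float)
    c = cfp.coords[["x_px", "y_px"]].to_numpy(dtype=float)
    empty = pd.DataFrame(columns=["gfp_x", "gfp_y", "cfp_x", "cfp_y",
                                  "distance_px"])
    if len(g) == 0:
        return PairDistanceSet(pairs=empty, n_unmatched=0)
    if len(c) == 0:
        return PairDistanceSet(pairs=empty, n_unmatched=len(g))

    tree = cKDTree(c)
    dist, idx = tree.query(g, k=1)
    # cKDTree breaks exact ties arbitrarily; enforce lowest-index convention
    for i in range(len(g)):
        d_all = np.hypot(c[:, 0] - g[i, 0], c[:, 1] - g[i, 1])
        ties = np.flatnonzero(np.isclose(d_all, d_all.min()))
        idx[i] = ties[0]
        dist[i] = d_all[ties[0]]

    keep = np.ones(len(g), dtype=bool)
    if config.max_distance_px is not None:
        keep &= dist <= config.max_distance_px
    if config.mutual_nearest:
        gtree = cKDTree(g)
        _, back = gtree.query(c, k=1)
        keep &= back[idx] == np.arange(len(g))

    pairs = pd.DataFrame({
        "gfp_x": g[keep, 0], "gfp_y": g[keep, 1],
        "cfp_x": c[idx[keep], 0], "cfp_y": c[idx[keep], 1],
        "distance_px": dist[keep],
    })
    return PairDistanceSet(pairs=pairs, n_unmatched=int((~keep).sum()))


def to_nm(pairs: PairDistanceSet, config: ImagingConfig) -> PairDistanceSet:
    """Convert pixel distances to nm with the configured pixel size."""
    if config.pixel_nm <= 0:
        raise ValueError("pixel_nm must be > 0")
    out = pairs.pairs.copy()
    out["distance_nm"] = out["distance_px"] * config.pixel_nm
    return PairDistanceSet(pairs=out, n_unmatched=pairs.n_unmatched,
                           condition=pairs.condition)


def summarize(pairs: PairDistanceSet) -> DistanceSummary:
    """Median and interpolated quartiles (inclusive linear interpolation)."""
    d = pairs.distances_nm()
    if len(d) == 0:
        raise ValueError("cannot summarize an empty pair set")
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    return DistanceSummary(n=len(d), median_nm=float(med),
                           q1_nm=float(q1), q3_nm=float(q3))


def fold_call(control_median_nm: float, treatment_median_nm: float,
              config: ImagingConfig) -> tuple[float, bool]:
    """Apply the de-clustering rule to a pair of medians.

    Returns (fold change, call). The call is true iff the fold change meets
    ``fold_change_cutoff`` and, when ``nm_threshold`` is configured, the
    treatment median also exceeds that absolute distance.
    """
    if control_median_nm <= 0:
        raise ValueError("control median must be > 0")
    fold = treatment_median_nm / control_median_nm
    call = fold >= config.fold_change_cutoff
    if config.nm_threshold is not None:
        call = call and treatment_median_nm > config.nm_threshold
    return fold, call


def compare_conditions(control: PairDistanceSet, treatment: PairDistanceSet,
                       config: ImagingConfig) -> ComparisonResult:
    """Compare two distance distributions.

    Reports the two-sided Mann-Whitney U p-value and the median fold change
    (treatment/control); the de-clustering call follows the fold rule of
    :func:`fold_call`, with p reported for reference.
    """
    dc = control.distances_nm()
    dt = treatment.distances_nm()
    if len(dc) == 0 or len(dt) == 0:
        raise ValueError("both conditions must be non-empty")
    med_c = float(np.median(dc))
    med_t = float(np.median(dt))
    if np.array_equal(np.sort(dc), np.sort(dt)):
        u, p = float(len(dc) * len(dt) / 2), 1.0
    else:
        u, p = stats.mannwhitneyu(dt, dc, alternative="two-sided")
    fold, call = fold_call(med_c, med_t, config)
    return ComparisonResult(fold_change=fold, u_statistic=float(u),
                            p_value=float(p), declustered=call,
                            control_median_nm=med_c, treatment_median_nm=med_t)


def measure_cells(lengths_px: np.ndarray | None,
                  dapi_image: np.ndarray | None = None,
                  masks: list[np.ndarray] | None = None,
                  config: ImagingConfig | None = None) -> CellMeasurements:
    """Scale per-cell lengths to um and quantify nucleoid (DAPI) intensity.

    ``lengths_px`` may instead be derived from ``masks`` (major-axis extent
    is out of scope; masks here only gate the DAPI measurement). DAPI
    intensity per cell is the in-mask mean minus the image background,
    estimated as the median of out-of-mask pixels.
    """
    config = config or ImagingConfig()
    if lengths_px is None and not masks:
        raise ValueError("provide lengths_px or masks")
    lengths_um = (np.asarray(lengths_px, dtype=float) * config.pixel_nm / 1000.0
                  if lengths_px is not None else np.array([]))
    if (lengths_um < 0).any():
        raise ValueError("cell lengths must be >= 0")

    dapi = np.array([])
    if dapi_image is not None and masks:
        img = np.asarray(dapi_image, dtype=float)
        union = np.zeros(img.shape, dtype=bool)
        for m in masks:
            if not m.any():
                raise ValueError("empty cell mask")
            union |= m.astype(bool)
        outside = img[~union]
        background = float(np.median(outside)) if outside.size else 0.0
        dapi = np.array([float(img[m.astype(bool)].mean()) - background
                         for m in masks])
    return CellMeasurements(lengths_um=lengths_um, dapi_intensity=dapi)


def pipeline_median_nm(gfp_image: np.ndarray, cfp_image: np.ndarray,
                       config: ImagingConfig) -> DistanceSummary:
    """Convenience: detect both channels, pair, convert, summarize."""
    gfp = detect_foci(gfp_image, config, channel="GFP")
    cfp = detect_foci(cfp_image, config, channel="CFP")
    pairs = to_nm(match_pairs(gfp, cfp, config), config)
    return summarize(pairs)
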