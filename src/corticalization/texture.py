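"""Texture primitives for peri-implant bone: GLCM difference entropy,
run-length long-run emphasis, and mean optical density.

The three features feed the Corticalization Index (see
:mod:`corticalization.index`):

* **Difference entropy** — Shannon entropy (common logarithm by default) of
  the grey-level difference distribution ``p_{x-y}`` of a co-occurrence
  matrix taken at a 5-pixel offset.  It measures the scatter of bone
  structural elements: high for cancellous (trabecular) bone, low for
  uniform corticalized bone.
* **Long-run emphasis** — the k²-weighted mean run length of the grey-level
  run-length matrix; large for thick, uniformly dense, radio-opaque
  structures.
* **Mean optical density** — the arithmetic mean of the *raw* (un-quantized)
  grey values, a proxy for radiographic bone density.

Grey levels are first reduced to ``Ng`` discrete levels (default 64) so that
the matrices are well populated on clinical ROI sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QuantizationConfig",
    "QuantizedROI",
    "CoocParams",
    "CoocMatrix",
    "RunLengthMatrix",
    "TextureFeatures",
    "quantize",
    "cooc_matrix",
    "difference_entropy",
    "run_length_matrix",
    "long_run_emphasis",
    "compute_features",
    "DIRECTIONS",
]

#: pixel offsets (d_row, d_col) per direction, for unit distance.
#: Angles follow the Haralick convention: 0° is horizontal (to the right),
#: angles increase counter-clockwise.
DIRECTIONS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


@dataclass(frozen=True)
class QuantizationConfig:
    """How raw grey values are reduced to ``n_levels`` discrete levels.

    ``min-max`` maps the patch minimum to level 0 and the maximum to
    ``n_levels - 1`` with uniform bins in between.  ``mean-3sigma`` first
    clips to mean ± 3·SD (a MaZda-style normalization) and then bins that
    fixed range; ``fixed-range`` bins the full dynamic range of the declared
    bit depth.
    """

    n_levels: int = 64
    mode: str = "min-max"
    bit_depth: int = 8  # used only by fixed-range mode

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.mode not in ("min-max", "mean-3sigma", "fixed-range"):
            raise ValueError(f"unknown quantization mode {self.mode!r}")


@dataclass
class QuantizedROI:
    """ROI pixels mapped to ``[0, n_levels - 1]``.

    ``raw_mean`` keeps the mean of the original grey values (the mean
    optical density) because quantization must not touch it.  ``degenerate``
    is set for constant patches, whose texture features are trivial and
    whose Corticalization Index is undefined.
    """

    levels: np.ndarray
    n_levels: int
    raw_mean: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if self.levels.size == 0:
            raise ValueError("empty ROI")
        if self.levels.min() < 0 or self.levels.max() >= self.n_levels:
            raise ValueError("quantized levels outside [0, n_levels - 1]")


@dataclass(frozen=True)
class CoocParams:
    """Co-occurrence parameters: offset distance, directions, symmetry.

    The clinical protocol pairs pixels at a 5-pixel distance, hence
    ``distance=5``.  ``aggregation`` controls how multi-direction feature
    values are combined by :func:`compute_features`:
    ``average-features`` (default) averages the per-direction feature values,
    ``average-matrices`` averages the normalized matrices before the feature,
    and ``per-direction`` returns each direction separately.
    """

    distance: int = 5
    directions: tuple[int, ...] = (0,)
    symmetric: bool = True
    aggregation: str = "average-features"

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        bad = set(self.directions) - set(DIRECTIONS)
        if bad:
            raise ValueError(f"unknown directions {sorted(bad)}; allowed {sorted(DIRECTIONS)}")
        if not self.directions:
            raise ValueError("at least one direction required")
        if self.aggregation not in ("average-features", "average-matrices", "per-direction"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


@dataclass
class CoocMatrix:
    """Normalized grey-level co-occurrence matrix with its |i−j| marginal."""

    entries: np.ndarray  # Ng x Ng, sums to 1
    n_levels: int
    distance: int
    direction: int | None  # None for an averaged matrix
    symmetric: bool

    @property
    def diff_marginal(self) -> np.ndarray:
        """Difference distribution p_{x-y}(i) = Σ_{|r-c|=i} entries[r, c]."""
        ng = self.n_levels
        rows, cols = np.indices((ng, ng))
        diff = np.abs(rows - cols)
        out = np.zeros(ng)
        np.add.at(out, diff.ravel(), self.entries.ravel())
        return out


@dataclass
class RunLengthMatrix:
    """Counts p(i, k) of maximal runs of level i with length k (1-based k)."""

    counts: np.ndarray  # Ng x Kmax integer counts; column j holds length j+1
    n_levels: int
    direction: int

    @property
    def total_runs(self) -> int:
        return int(self.counts.sum())

    @property
    def total_pixels(self) -> int:
        k = np.arange(1, self.counts.shape[1] + 1)
        return int((self.counts * k).sum())


@dataclass
class TextureFeatures:
    """The three primitives of the Corticalization Index."""

    dif_entr: float
    lng_r_emph: float
    mean_optical_density: float
    degenerate: bool = False
    per_direction: dict[int, dict[str, float]] = field(default_factory=dict)


def quantize(patch: np.ndarray, config: QuantizationConfig | None = None) -> QuantizedROI:
    """Reduce a grey-value patch to ``config.n_levels`` discrete levels.

    min-max mode maps [patch min, patch max] onto [0, Ng-1] with Ng
    equal-width bins (the maximum lands in the top bin).  A constant patch
    maps to all-zero levels and is flagged degenerate rather than raising —
    callers decide whether a degenerate ROI is an error.
    """
    config = config or QuantizationConfig()
    arr = np.asarray(patch, dtype=float)
    if arr.size == 0:
        raise ValueError("empty patch")
    ng = config.n_levels
    raw_mean = float(arr.mean())

    if config.mode == "fixed-range":
        lo, hi = 0.0, float((1 << config.bit_depth) - 1)
        values = arr
    elif config.mode == "mean-3sigma":
        mu, sd = arr.mean(), arr.std()
        lo, hi = mu - 3.0 * sd, mu + 3.0 * sd
        values = np.clip(arr, lo, hi)
    else:  # min-max
        lo, hi = float(arr.min()), float(arr.max())
        values = arr

    if hi <= lo:  # constant patch
        levels = np.zeros(arr.shape, dtype=np.int64)
        return QuantizedROI(levels, ng, raw_mean, degenerate=True)

    levels = np.floor((values - lo) / (hi - lo) * ng).astype(np.int64)
    np.clip(levels, 0, ng - 1, out=levels)
    degenerate = bool(levels.min() == levels.max())
    return QuantizedROI(levels, ng, raw_mean, degenerate=degenerate)


def cooc_matrix(roi: QuantizedROI, params: CoocParams | None = None) -> list[CoocMatrix]:
    """Grey-level co-occurrence matrices at the configured offset.

    For each direction, every in-bounds ordered pixel pair ``(p, p + d·dir)``
    increments the cell ``(level(p), level(p + d·dir))``; with
    ``symmetric=True`` the transposed pair is accumulated as well (the
    standard Haralick convention).  The matrix is normalized to sum 1.
    Returns one matrix per requested direction.
    """
    params = params or CoocParams()
    lv = roi.levels
    rows, cols = lv.shape if lv.ndim == 2 else (1, lv.shape[0])
    lv2 = lv.reshape(rows, cols)
    d = params.distance
    if d >= rows and d >= cols:
        raise ValueError(f"offset distance {d} is not smaller than either ROI dimension")
    ng = roi.n_levels
    out: list[CoocMatrix] = []
    for ang in params.directions:
        dr, dc = DIRECTIONS[ang]
        dr, dc = dr * d, dc * d
        # slices selecting source pixels whose offset partner is in bounds
        r_src = slice(max(0, -dr), rows - max(0, dr))
        c_src = slice(max(0, -dc), cols - max(0, dc))
        r_dst = slice(max(0, dr), rows + min(0, dr))
        c_dst = slice(max(0, dc), cols + min(0, dc))
        a = lv2[r_src, c_src].ravel()
        b = lv2[r_dst, c_dst].ravel()
        if a.size == 0:
            raise ValueError(
                f"offset distance {d} leaves no pixel pairs along direction {ang}"
            )
        counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(float)
        if params.symmetric:
            counts = counts + counts.T
        out.append(
            CoocMatrix(
                entries=counts / counts.sum(),
                n_levels=ng,
                distance=d,
                direction=ang,
                symmetric=params.symmetric,
            )
        )
    return out


def difference_entropy(cooc: CoocMatrix | np.ndarray, log_base: float = 10) -> float:
    """Entropy of the difference distribution: −Σ p_{x−y}(i)·log(p_{x−y}(i)).

    ``0·log 0 := 0`` by continuity.  Base 10 (the common logarithm) by
    default; pass ``log_base=np.e`` for natural-log conventions.  The result
    lies in ``[0, log(Ng)]`` and attains the upper bound iff the difference
    distribution is uniform.
    """
    p = np.asarray(cooc.diff_marginal if isinstance(cooc, CoocMatrix) else cooc, dtype=float)
    if p.ndim != 1:
        raise ValueError("difference marginal must be a 1D distribution")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError(f"difference marginal sums to {p.sum()!r}, expected 1")
    if (p < -1e-12).any():
        raise ValueError("difference marginal has negative mass")
    nz = p[p > 0]
    return float(-(nz * (np.log(nz) / np.log(log_base))).sum())


def run_length_matrix(roi: QuantizedROI, direction: int = 0) -> RunLengthMatrix:
    """Count maximal runs of equal level along ``direction``.

    Every ROI pixel belongs to exactly one maximal run per direction, so
    ``Σ_i Σ_k k·p(i,k)`` equals the pixel count.  Directions follow
    :data:`DIRECTIONS`: 0° scans rows, 90° columns, 45°/135° the diagonals.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction}")
    lv = roi.levels
    lv2 = lv.reshape(1, -1) if lv.ndim == 1 else lv
    rows, cols = lv2.shape
    ng = roi.n_levels
    kmax = max(rows, cols)
    counts = np.zeros((ng, kmax), dtype=np.int64)

    if direction == 0:
        lines = [lv2[r, :] for r in range(rows)]
    elif direction == 90:
        lines = [lv2[:, c] for c in range(cols)]
    elif direction == 45:
        # anti-diagonals: moving (-1, +1) stays on constant row+col
        flipped = lv2[::-1, :]
        lines = [np.diagonal(flipped, offset=o) for o in range(-(rows - 1), cols)]
    else:  # 135: moving (-1, -1) stays on constant row-col
        lines = [np.diagonal(lv2, offset=o) for o in range(-(rows - 1), cols)]

    for line in lines:
        n = line.shape[0]
        if n == 0:
            continue
        # boundaries of maximal runs
        breaks = np.flatnonzero(line[1:] != line[:-1])
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks + 1, [n]))
        lengths = ends - starts
        np.add.at(counts, (line[starts], lengths - 1), 1)
    return RunLengthMatrix(counts=counts, n_levels=ng, direction=direction)


def long_run_emphasis(rlm: RunLengthMatrix) -> float:
    """k²-weighted average run length: ΣΣ k²·p(i,k) / ΣΣ p(i,k).

    Always ≥ 1, with equality iff every run has length 1.
    """
    total = rlm.counts.sum()
    if total == 0:
        raise ValueError("empty run-length matrix")
    k = np.arange(1, rlm.counts.shape[1] + 1, dtype=float)
    return float((rlm.counts * k**2).sum() / total)


def compute_features(
    patch: np.ndarray,
    quant_config: QuantizationConfig | None = None,
    cooc_params: CoocParams | None = None,
    log_base: float = 10,
) -> TextureFeatures:
    """Compute the three Corticalization Index primitives for one ROI patch.

    The run-length matrix is scanned along the same directions as the
    co-occurrence offset.  Multi-direction values are combined per
    ``cooc_params.aggregation`` (default: arithmetic mean of the
    per-direction feature values); per-direction values are always retained
    in ``per_direction``.  Mean optical density is the raw-patch mean,
    independent of quantization.

    A constant (degenerate) patch yields ``dif_entr = 0`` with the degenerate
    flag set — its Corticalization Index is undefined downstream.
    """
    cooc_params = cooc_params or CoocParams()
    roi = quantize(patch, quant_config)
    mats = cooc_matrix(roi, cooc_params)
    per_direction: dict[int, dict[str, float]] = {}
    de_vals, lre_vals = [], []
    for mat in mats:
        de = difference_entropy(mat, log_base=log_base)
        rlm = run_length_matrix(roi, direction=mat.direction)
        lre = long_run_emphasis(rlm)
        per_direction[mat.direction] = {"dif_entr": de, "lng_r_emph": lre}
        de_vals.append(de)
        lre_vals.append(lre)

    if cooc_params.aggregation == "average-matrices":
        avg = CoocMatrix(
            entries=np.mean([m.entries for m in mats], axis=0),
            n_levels=roi.n_levels,
            distance=cooc_params.distance,
            direction=None,
            symmetric=cooc_params.symmetric,
        )
        de_agg = difference_entropy(avg, log_base=log_base)
        lre_agg = float(np.mean(lre_vals))
    else:  # average-features and per-direction both report the mean here;
        # per-direction consumers read the per_direction dict
        de_agg = float(np.mean(de_vals))
        lre_agg = float(np.mean(lre_vals))

    return TextureFeatures(
        dif_entr=de_agg,
        lng_r_emph=lre_agg,
        mean_optical_density=roi.raw_mean,
        degenerate=roi.degenerate,
        per_direction=per_direction,
    )
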