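"""Local Lee's L bivariate spatial association with Monte Carlo classes.

Lee's L combines Pearson correlation with the spatial lag (smoothing) of
each variable, so it measures pixel-to-pixel association while
integrating the spatial autocorrelation of both surfaces. The local form
is, with centered variables and spatial weights W:

    L_i = n * (W x~)_i (W y~)_i / sqrt(sum_k x~_k^2 * sum_k y~_k^2)

Significance is assessed per pixel by conditional permutation: y is
permuted across valid cells (x and W fixed), the local L recomputed, and
the observed value ranked among observed + simulated; quantile > 0.975
is a significant positive association, < 0.025 a negative one.

Model -> fit() -> Results shape: :class:`LeeConcordance` holds the two
surfaces and the weights; ``fit()`` returns a :class:`LeeResult` with the
L, rescaled, quantile and class surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .errors import InvalidArgumentError
from .raster import GridSpec, Raster

__all__ = [
    "SpatialWeights",
    "aggregate_mean",
    "build_weights",
    "local_lee",
    "rescale_lee",
    "monte_carlo_classify",
    "LeeConcordance",
    "LeeResult",
]


# ---------------------------------------------------------------------------
# spatial weights


@dataclass
class SpatialWeights:
    """Sparse contiguity weights over the flattened grid."""

    matrix: sparse.csr_matrix
    grid_shape: tuple[int, int]
    scheme: str
    row_standardized: bool

    def n_neighbors(self, row: int, col: int) -> int:
        i = row * self.grid_shape[1] + col
        return int(self.matrix.indptr[i + 1] - self.matrix.indptr[i])


def build_weights(
    grid_shape: tuple[int, int],
    scheme: str = "queen",
    row_standardize: bool = True,
) -> SpatialWeights:
    """Contiguity weights: queen (8-neighborhood), rook (4), or identity.

    ``identity`` makes every cell its own sole neighbor, which reduces
    local Lee's L to a decomposition of the Pearson correlation — useful
    as a degenerate reference. No self-neighbors otherwise.
    """
    rows, cols = grid_shape
    if rows < 2 or cols < 2:
        raise InvalidArgumentError("grid must be at least 2x2")
    if scheme == "identity":
        mat = sparse.identity(rows * cols, format="csr")
        return SpatialWeights(mat, grid_shape, scheme, row_standardize)
    if scheme == "queen":
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    elif scheme == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        raise InvalidArgumentError(f"unknown weights scheme {scheme!r}")
    rr, cc = np.mgrid[0:rows, 0:cols]
    src, dst = [], []
    for dr, dc in offsets:
        ok = (
            (rr + dr >= 0) & (rr + dr < rows) & (cc + dc >= 0) & (cc + dc < cols)
        )
        src.append((rr[ok] * cols + cc[ok]))
        dst.append(((rr[ok] + dr) * cols + (cc[ok] + dc)))
    src = np.concatenate(src)
    dst = np.concatenate(dst)
    mat = sparse.csr_matrix(
        (np.ones(len(src)), (src, dst)), shape=(rows * cols, rows * cols)
    )
    return SpatialWeights(mat, grid_shape, scheme, row_standardize)


def _row_normalize(W: sparse.csr_matrix) -> sparse.csr_matrix:
    rs = np.asarray(W.sum(axis=1)).ravel()
    inv = np.divide(1.0, rs, out=np.zeros_like(rs), where=rs > 0)
    return sparse.diags(inv) @ W


def _as_array(x: Raster | np.ndarray) -> np.ndarray:
    return x.data if isinstance(x, Raster) else np.asarray(x, dtype=float)


def _prepare(
    x: Raster | np.ndarray, y: Raster | np.ndarray, weights: SpatialWeights
):
    xa, ya = _as_array(x), _as_array(y)
    if xa.shape != ya.shape:
        raise InvalidArgumentError("x and y must share one grid")
    if xa.shape != weights.grid_shape:
        raise InvalidArgumentError("weights grid does not match inputs")
    valid = np.isfinite(xa) & np.isfinite(ya)
    idx = np.flatnonzero(valid.ravel())
    if idx.size < 2:
        raise InvalidArgumentError("need at least 2 jointly valid cells")
    xc = xa.ravel()[idx]
    yc = ya.ravel()[idx]
    if xc.std() == 0 or yc.std() == 0:
        raise InvalidArgumentError("zero variance in an input surface")
    W = weights.matrix[idx][:, idx]
    if weights.row_standardized:
        W = _row_normalize(W)
    return xa.shape, idx, xc, yc, W


def _local_l(
    xc: np.ndarray, yc: np.ndarray, W: sparse.csr_matrix
) -> np.ndarray:
    n = xc.size
    xt = xc - xc.mean()
    yt = yc - yc.mean()
    denom = np.sqrt((xt**2).sum() * (yt**2).sum())
    # product grouped first so the statistic is bit-exactly symmetric in (x, y)
    return n * ((W @ xt) * (W @ yt)) / denom


def local_lee(
    x: Raster | np.ndarray, y: Raster | np.ndarray, weights: SpatialWeights
) -> np.ndarray:
    """Per-cell local Lee's L; NaN at cells masked in either input.

    Masked cells are excluded from means, sums, spatial lags and (when
    row-standardized) the row normalization.
    """
    shape, idx, xc, yc, W = _prepare(x, y, weights)
    out = np.full(shape[0] * shape[1], np.nan)
    out[idx] = _local_l(xc, yc, W)
    return out.reshape(shape)


def rescale_lee(L_values: np.ndarray) -> np.ndarray:
    """Center at 0 and rescale to [-1, 1].

    v_i = (L_i - mean(L)) / max_k |L_k - mean(L)| over finite cells;
    an all-equal input maps to all zeros.
    """
    L = np.asarray(L_values, dtype=float)
    finite = np.isfinite(L)
    if not finite.any():
        raise InvalidArgumentError("no finite values to rescale")
    centered = L - L[finite].mean()
    m = np.abs(centered[finite]).max()
    if m == 0:
        return np.where(finite, 0.0, np.nan)
    out = centered / m
    out[~finite] = np.nan
    return out


def aggregate_mean(raster: Raster, factor: int = 10) -> Raster:
    """Block-mean aggregation to a coarser grid (e.g. 30 m -> 300 m).

    Each output cell is the mean of the unmasked cells of its
    factor x factor input block; fully masked blocks are nodata. Partial
    edge blocks use the cells available.
    """
    if factor < 2:
        raise InvalidArgumentError("factor must be >= 2")
    rows, cols = raster.shape
    out_rows = -(-rows // factor)
    out_cols = -(-cols // factor)
    filled = np.where(raster.mask, raster.data, 0.0)
    counts = raster.mask.astype(float)
    r_edges = np.arange(0, rows, factor)
    c_edges = np.arange(0, cols, factor)
    sums = np.add.reduceat(np.add.reduceat(filled, r_edges, axis=0), c_edges, axis=1)
    cnts = np.add.reduceat(np.add.reduceat(counts, r_edges, axis=0), c_edges, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / cnts
    mean[cnts == 0] = np.nan
    g = raster.grid
    new_grid = GridSpec(
        out_rows, out_cols, xll=g.xll,
        yll=g.yll + g.n_rows * g.cell_size - out_rows * factor * g.cell_size,
        cell_size=g.cell_size * factor,
    )
    return Raster(mean, new_grid)


# ---------------------------------------------------------------------------
# Monte Carlo classification


@dataclass
class LeeResult:
    """Local Lee's L surfaces with Monte Carlo significance classes.

    ``classes`` holds 1 (significant positive, quantile > 0.975),
    -1 (significant negative, quantile < 0.025) and 0 elsewhere.
    """

    local_l: np.ndarray
    rescaled: np.ndarray
    quantile: np.ndarray | None
    classes: np.ndarray | None
    n_sims: int
    seed: int | None
    scheme: str
    grid: GridSpec | None = None

    def _raster(self, a: np.ndarray) -> Raster:
        return Raster(a, self.grid)

    @property
    def class_fractions(self) -> dict[str, float]:
        if self.classes is None:
            raise InvalidArgumentError("no Monte Carlo classification was run")
        finite = np.isfinite(self.classes)
        n = int(finite.sum())
        return {
            "positive": float((self.classes[finite] == 1).sum() / n),
            "negative": float((self.classes[finite] == -1).sum() / n),
            "not_significant": float((self.classes[finite] == 0).sum() / n),
        }

    def rasters(self) -> dict[str, Raster]:
        out = {
            "lee_l": self._raster(self.local_l),
            "lee_l_rescaled": self._raster(self.rescaled),
        }
        if self.quantile is not None:
            out["lee_quantile"] = self._raster(self.quantile)
            out["lee_class"] = self._raster(self.classes)
        return out

    def to_metadata(self) -> dict:
        meta = {
            "statistic": "local Lee's L",
            "weights_scheme": self.scheme,
            "n_sims": self.n_sims,
            "seed": self.seed,
        }
        if self.classes is not None:
            meta["class_fractions"] = self.class_fractions
            meta["class_legend"] = {"positive": 1, "negative": -1, "not_significant": 0}
        return meta

    def plot(self, ax=None):
        """Render the rescaled L surface with a light overlay on the
        significant cells; requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.rescaled, cmap="RdBu_r", vmin=-1, vmax=1,
                       interpolation="nearest")
        ax.set_title("rescaled local Lee's L")
        plt.colorbar(im, ax=ax, shrink=0.8)
        if self.classes is not None:
            sig = np.where(np.abs(self.classes) == 1, 1.0, np.nan)
            ax.imshow(sig, cmap="gray", alpha=0.15, interpolation="nearest")
        return ax

    def summary(self) -> str:
        finite = np.isfinite(self.local_l)
        lines = [
            "Local Lee's L spatial concordance",
            "=" * 48,
            f"cells: {int(finite.sum())}   weights: {self.scheme}",
            f"mean L = {self.local_l[finite].mean():+.4f}   "
            f"range = [{self.local_l[finite].min():+.4f}, "
            f"{self.local_l[finite].max():+.4f}]",
        ]
        if self.classes is not None:
            f = self.class_fractions
            lines.append(
                f"Monte Carlo ({self.n_sims} sims): positive {f['positive']:.1%}, "
                f"negative {f['negative']:.1%}, "
                f"not significant {f['not_significant']:.1%}"
            )
        return "\n".join(lines)


def monte_carlo_classify(
    x: Raster | np.ndarray,
    y: Raster | np.ndarray,
    weights: SpatialWeights,
    n_sims: int = 999,
    seed: int = 0,
) -> LeeResult:
    """Per-cell Monte Carlo quantiles and significance classes for Lee's L.

    For each simulation, the y values are permuted across valid cells
    (x and the weights fixed — the conditional-on-x null) and the local L
    recomputed. The per-cell quantile is the rank of the observed value
    among {observed + n_sims simulated} divided by (n_sims + 1), so with
    999 simulations the attainable quantiles are 1/1000 ... 1000/1000.
    """
    if n_sims < 1:
        raise InvalidArgumentError("n_sims must be >= 1")
    shape, idx, xc, yc, W = _prepare(x, y, weights)
    n = xc.size
    xt = xc - xc.mean()
    yt = yc - yc.mean()
    denom = np.sqrt((xt**2).sum() * (yt**2).sum())
    lag_x = W @ xt
    obs = n * lag_x * (W @ yt) / denom
    rng = np.random.default_rng(seed)
    # counts of simulated values strictly below the observed, per cell
    below = np.zeros(n, dtype=np.int64)
    for _ in range(n_sims):
        yp = rng.permutation(yt)  # centering is permutation-invariant
        sim = n * lag_x * (W @ yp) / denom
        below += sim < obs
    quant = (below + 1) / (n_sims + 1)
    classes = np.zeros(n)
    classes[quant > 0.975] = 1
    classes[quant < 0.025] = -1

    def expand(v: np.ndarray) -> np.ndarray:
        out = np.full(shape[0] * shape[1], np.nan)
        out[idx] = v
        return out.reshape(shape)

    grid = x.grid if isinstance(x, Raster) else None
    return LeeResult(
        local_l=expand(obs),
        rescaled=rescale_lee(expand(obs)),
        quantile=expand(quant),
        classes=expand(classes),
        n_sims=n_sims,
        seed=seed,
        scheme=weights.scheme,
        grid=grid,
    )


class LeeConcordance:
    """Spatial-concordance model between two aligned surfaces.

    Parameters
    ----------
    x, y : Raster or 2-D array
        The two surfaces to compare (e.g. rare vs overall species
        richness), already aggregated to the analysis resolution.
    scheme : {"queen", "rook", "identity"}
        Contiguity scheme for the spatial weights (default queen).
    row_standardize : bool
        Row-standardize the weights (default True).
    """

    def __init__(
        self,
        x: Raster | np.ndarray,
        y: Raster | np.ndarray,
        scheme: str = "queen",
        row_standardize: bool = True,
    ):
        self.x = x
        self.y = y
        shape = _as_array(x).shape
        self.weights = build_weights(shape, scheme, row_standardize)

    def fit(self, n_sims: int = 999, seed: int = 0) -> LeeResult:
        """Observed local L plus Monte Carlo quantiles and classes."""
        return monte_carlo_classify(self.x, self.y, self.weights, n_sims, seed)

    def observed(self) -> LeeResult:
        """Observed local L only (no permutation test)."""
        L = local_lee(self.x, self.y, self.weights)
        grid = self.x.grid if isinstance(self.x, Raster) else None
        return LeeResult(
            local_l=L,
            rescaled=rescale_lee(L),
            quantile=None,
            classes=None,
            n_sims=0,
            seed=None,
            scheme=self.weights.scheme,
            grid=grid,
        )
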