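"""Local Moran's I with conditional permutation inference.

The local Moran statistic at location *i* is

    I_i = (Z_i / m) * sum_j W_ij Z_j,      m = sum_i Z_i^2 / N,

where Z are the standardized heights and W is a distance-band spatial
weight matrix (binary 0/1 by default: W_ij = 1 iff 0 < d_ij <= threshold).
Significance is assessed by conditional permutation: Z_i is held fixed
while its neighbors' values are redrawn without replacement from the
other N − 1 observations, giving a pseudo p-value
(R + 1)/(M + 1) one-sided toward the observed direction.  Significant
locations are classified H-H / L-L / L-H / H-L from the signs of
(Z_i, spatial lag); the rest are labeled NS.

:class:`LocalMoran` wraps the whole procedure as a scikit-learn style
estimator; the module functions expose the individual steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .errors import InvalidInputError, InvalidParameterError, NoNeighborsError

DEFAULT_THRESHOLD = 1.75
DEFAULT_PERMUTATIONS = 999
DEFAULT_ALPHA = 0.01

QUADRANT_LABELS = ("HH", "LL", "LH", "HL")

#: conventional LISA cluster-map palette (GeoDa colors)
CLASS_COLORS = {
    "HH": "#d7191c",
    "LL": "#2c7bb6",
    "LH": "#abd9e9",
    "HL": "#fdae61",
    "NS": "#bdbdbd",
}

__all__ = [
    "SpatialWeights",
    "LisaResult",
    "LocalMoran",
    "build_weights",
    "local_moran",
    "permutation_pvalues",
    "classify",
    "moran_scatterplot_data",
    "CLASS_COLORS",
]


@dataclass
class SpatialWeights:
    """Sparse symmetric distance-band neighbor structure.

    ``neighbors[i]`` holds the indices j with 0 < d_ij <= threshold and
    ``weights[i]`` the matching W_ij (all ones for binary style, 1/d_ij
    for inverse-distance style).  Self-neighbors are excluded.
    """

    neighbors: list[np.ndarray]
    weights: list[np.ndarray]
    threshold: float
    style: str = "binary"

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])

    @property
    def islands(self) -> np.ndarray:
        """Indices of isolated points (no neighbor within the threshold)."""
        return np.flatnonzero(self.cardinalities == 0)

    @property
    def s0(self) -> float:
        """Sum of all weights, S0 = ΣΣ W_ij."""
        return float(sum(w.sum() for w in self.weights))

    def lag(self, z: np.ndarray, row_standardize: bool = False) -> np.ndarray:
        """Spatial lag Σ_j W_ij z_j (optionally averaged over neighbors)."""
        z = np.asarray(z, dtype=float)
        out = np.zeros(self.n)
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            if len(nb):
                s = float(w @ z[nb])
                out[i] = s / w.sum() if row_standardize else s
        return out


def build_weights(points, threshold: float = DEFAULT_THRESHOLD, style: str = "binary") -> SpatialWeights:
    """Distance-band weights: all pairs within ``threshold`` meters are neighbors.

    ``style`` is "binary" (0/1, the default) or "inverse_distance"
    (W_ij = 1/d_ij inside the band).  Raises :class:`NoNeighborsError` if
    every point is isolated.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError(f"points must be an (n, 2) array, got shape {pts.shape}")
    if len(pts) < 2:
        raise InvalidInputError(f"need at least 2 points, got {len(pts)}")
    if threshold <= 0:
        raise InvalidParameterError(f"threshold must be > 0, got {threshold}")
    if style not in ("binary", "inverse_distance"):
        raise InvalidParameterError(f"unknown weights style {style!r}")

    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=threshold, output_type="ndarray")
    nbrs: list[list[int]] = [[] for _ in range(len(pts))]
    for i, j in pairs:
        nbrs[i].append(j)
        nbrs[j].append(i)

    neighbors, weights = [], []
    for i, nb in enumerate(nbrs):
        nb = np.array(sorted(nb), dtype=int)
        neighbors.append(nb)
        if style == "binary":
            weights.append(np.ones(len(nb)))
        else:
            d = np.linalg.norm(pts[nb] - pts[i], axis=1)
            weights.append(1.0 / d)

    w = SpatialWeights(neighbors=neighbors, weights=weights, threshold=float(threshold), style=style)
    if w.s0 == 0:
        raise NoNeighborsError(
            f"every point is isolated at threshold {threshold} m; no spatial structure to analyze"
        )
    return w


@dataclass
class LisaResult:
    """Per-point local Moran outputs."""

    I: np.ndarray
    lag: np.ndarray
    quadrant: np.ndarray  # HH | LL | LH | HL
    pseudo_p: np.ndarray | None = None
    significant: np.ndarray | None = None
    class_label: np.ndarray | None = None
    islands: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    m: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        data = {"I": self.I, "lag": self.lag, "quadrant": self.quadrant}
        if self.pseudo_p is not None:
            data["pseudo_p"] = self.pseudo_p
        if self.class_label is not None:
            data["class"] = self.class_label
        return pd.DataFrame(data)


def _quadrants(z: np.ndarray, lag: np.ndarray) -> np.ndarray:
    """Sign classification; zeros count as 'high' (>= 0 -> H)."""
    zh, lh = z >= 0, lag >= 0
    out = np.empty(len(z), dtype=object)
    out[zh & lh] = "HH"
    out[~zh & ~lh] = "LL"
    out[~zh & lh] = "LH"
    out[zh & ~lh] = "HL"
    return out


def local_moran(z, w: SpatialWeights) -> LisaResult:
    """Local Moran statistic, spatial lag and quadrant per point.

    ``z`` must be centered (mean 0); the scaling m = Σz²/N is computed
    over all N points, so z standardized with the population sd gives
    m = 1 and I_i = Z_i Σ_j W_ij Z_j.
    """
    z = np.asarray(z, dtype=float)
    if len(z) != w.n:
        raise InvalidInputError(f"z has {len(z)} values but weights cover {w.n} points")
    m = float(z @ z) / len(z)
    if m == 0:
        raise InvalidInputError("z is identically zero; standardize non-constant heights first")
    lag = w.lag(z)
    I = z / m * lag
    return LisaResult(I=I, lag=lag, quadrant=_quadrants(z, lag), islands=w.islands, m=m)


def _draw_without_replacement(rng: np.random.Generator, m: int, k: int, pool: int) -> np.ndarray:
    """(m, k) index rows drawn without replacement from range(pool).

    Rejection sampling: for the small neighbor counts of a distance-band
    field (k << pool) duplicate rows are rare and are simply redrawn.
    Falls back to argpartition of uniform keys when k is a large share of
    the pool.
    """
    if k > pool:
        raise InvalidInputError(f"cannot draw {k} distinct indices from {pool}")
    if k * k > pool:  # dense case: one uniform sort key per candidate
        keys = rng.random((m, pool))
        return np.argpartition(keys, k - 1, axis=1)[:, :k]
    idx = rng.integers(0, pool, size=(m, k))
    while True:
        s = np.sort(idx, axis=1)
        bad = np.flatnonzero((np.diff(s, axis=1) == 0).any(axis=1)) if k > 1 else np.array([], dtype=int)
        if not len(bad):
            return idx
        idx[bad] = rng.integers(0, pool, size=(len(bad), k))


def permutation_pvalues(
    z,
    w: SpatialWeights,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    alternative: str = "greater",
) -> np.ndarray:
    """Conditional-permutation pseudo p-values for local Moran.

    For each point i the observed Z_i stays in place while the |N(i)|
    neighbor slots are refilled ``n_permutations`` times with values
    sampled without replacement from the other N − 1 observations
    (independent draws per point).  pseudo_p = (R + 1)/(M + 1), so the
    smallest attainable value is 1/(M + 1).  Isolated points get NaN.

    ``alternative`` selects the tail R counts:

    - "greater" (default): permuted I_i >= observed — a test for positive
      local autocorrelation (H-H / L-L clustering).  Under an exchangeable
      null the pseudo p-value is uniform, so the flagged fraction at any
      alpha equals alpha.
    - "directed": one-sided toward the observed side of the permutation
      mean.  Also picks up significant spatial outliers (L-H / H-L), at
      the cost of flagging ~2*alpha under the null (each tail contributes
      alpha) — use a halved alpha if calibration matters.
    """
    z = np.asarray(z, dtype=float)
    if n_permutations < 1:
        raise InvalidParameterError(f"n_permutations must be >= 1, got {n_permutations}")
    if alternative not in ("greater", "directed"):
        raise InvalidParameterError(f"unknown alternative {alternative!r}")
    n = len(z)
    obs = local_moran(z, w)
    rng = np.random.default_rng(seed)

    pvals = np.full(n, np.nan)
    all_idx = np.arange(n)
    for i in range(n):
        k = len(w.neighbors[i])
        if k == 0:
            continue
        others = z[np.delete(all_idx, i)]
        draw = _draw_without_replacement(rng, n_permutations, k, n - 1)
        perm_lag = others[draw] @ w.weights[i]
        perm_I = z[i] / obs.m * perm_lag
        # ties count as "as extreme"; the epsilon absorbs summation-order
        # round-off when a draw reproduces the observed neighbor set
        eps = 1e-12 * (1.0 + abs(obs.I[i]))
        if alternative == "greater" or obs.I[i] >= perm_I.mean():
            r = int((perm_I >= obs.I[i] - eps).sum())
        else:
            r = int((perm_I <= obs.I[i] + eps).sum())
        pvals[i] = (r + 1) / (n_permutations + 1)
    return pvals


def classify(result: LisaResult, alpha: float = DEFAULT_ALPHA) -> LisaResult:
    """Significance labels: quadrant if pseudo_p <= alpha, NS otherwise.

    Isolated points are always NS (their pseudo p-value is undefined) but
    are kept in the output rather than dropped.
    """
    if result.pseudo_p is None:
        raise InvalidInputError("pseudo_p not filled; run permutation_pvalues first")
    if not 0 < alpha < 1:
        raise InvalidParameterError(f"alpha must be in (0, 1), got {alpha}")
    p = result.pseudo_p
    significant = np.where(np.isnan(p), False, p <= alpha)
    labels = np.where(significant, result.quadrant, "NS").astype(object)
    result.significant = significant
    result.class_label = labels
    return result


def moran_scatterplot_data(z, w: SpatialWeights, row_standardize: bool = True) -> pd.DataFrame:
    """Moran scatterplot coordinates: (Z_i, spatial lag, quadrant).

    With row-standardized lag the OLS slope of lag on z equals the global
    Moran's I of the row-standardized weights — the scatterplot's
    defining property.
    """
    z = np.asarray(z, dtype=float)
    if len(z) != w.n:
        raise InvalidInputError(f"z has {len(z)} values but weights cover {w.n} points")
    lag = w.lag(z, row_standardize=row_standardize)
    return pd.DataFrame({"z": z, "lag": lag, "quadrant": _quadrants(z, lag)})


class LocalMoran(BaseEstimator):
    """Local Moran's I cluster detector with permutation inference.

    scikit-learn style estimator: ``fit(X, y)`` takes point coordinates
    ``X`` of shape (n, 2) in meters and centered values ``y`` (z-scores),
    builds distance-band weights, computes the local statistics and the
    conditional-permutation pseudo p-values, and classifies each point.

    Parameters
    ----------
    threshold : float
        Distance band in meters (default 1.75, the farthest distance at
        which every plant still has a neighbor in an adjacent plot).
    style : {"binary", "inverse_distance"}
        Weight style inside the band.
    n_permutations : int
        Conditional permutations per point (default 999).
    alpha : float
        Pseudo p-value threshold for significance (default 0.01).
    seed : int or None
        Seed for the permutation draws.
    alternative : {"greater", "directed"}
        Tail of the permutation test; see :func:`permutation_pvalues`.

    Attributes
    ----------
    weights_ : SpatialWeights
    Is_, lags_ : ndarray
        Local Moran statistics and spatial lags.
    quadrant_ : ndarray of {"HH","LL","LH","HL"}
    p_sim_ : ndarray
        Pseudo p-values (NaN for isolated points).
    significant_ : ndarray of bool
    labels_ : ndarray of {"HH","LL","LH","HL","NS"}
    """

    def __init__(
        self,
        threshold: float = DEFAULT_THRESHOLD,
        style: str = "binary",
        n_permutations: int = DEFAULT_PERMUTATIONS,
        alpha: float = DEFAULT_ALPHA,
        seed: int | None = None,
        alternative: str = "greater",
    ) -> None:
        self.threshold = threshold
        self.style = style
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.seed = seed
        self.alternative = alternative

    def fit(self, X, y) -> "LocalMoran":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise InvalidInputError(f"{len(X)} coordinates but {len(y)} values")
        w = build_weights(X, threshold=self.threshold, style=self.style)
        res = local_moran(y, w)
        res.pseudo_p = permutation_pvalues(y, w, self.n_permutations, self.seed, self.alternative)
        res = classify(res, self.alpha)

        self.weights_ = w
        self.result_ = res
        self.Is_ = res.I
        self.lags_ = res.lag
        self.quadrant_ = res.quadrant
        self.p_sim_ = res.pseudo_p
        self.significant_ = res.significant
        self.labels_ = res.class_label
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y) -> np.ndarray:
        """Fit and return the per-point cluster labels."""
        return self.fit(X, y).labels_


def run_lisa(
    plants: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    style: str = "binary",
    n_permutations: int = DEFAULT_PERMUTATIONS,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
    alternative: str = "greater",
) -> pd.DataFrame:
    """LISA on a plant table with x, y and z columns.

    Returns the table augmented with lag, I, quadrant, pseudo_p and class
    columns, one row per input plant.
    """
    if len(plants) == 0:
        raise InvalidInputError("empty plant table")
    est = LocalMoran(threshold, style, n_permutations, alpha, seed, alternative)
    est.fit(plants[["x", "y"]].to_numpy(), plants["z"].to_numpy())
    out = plants.copy()
    out["lag"] = est.lags_
    out["I"] = est.Is_
    out["quadrant"] = est.quadrant_
    out["pseudo_p"] = est.p_sim_
    out["class"] = est.labels_
    return out
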