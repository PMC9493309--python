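"""Correlation matrix, RMT-based threshold selection, and signed network.

The correlation cutoff for a co-occurrence network is chosen objectively via
the random-matrix-theory transition: at low cutoffs the truncated similarity
matrix behaves like a Gaussian Orthogonal Ensemble (nearest-neighbour
eigenvalue spacings follow the Wigner surmise); once the cutoff exceeds the
noise correlations the matrix decomposes into independent blocks and the
spacings become Poisson (exponential). The chosen threshold is the smallest
cutoff on a grid whose unfolded spacing distribution is consistent with
Poisson statistics (chi-square goodness of fit, p >= alpha) while keeping a
usable number of non-isolated taxa.

Edges of the resulting network keep the correlation sign (positive and
negative associations) and |r| as weight; isolated taxa are excluded, so the
node count matches the "total nodes" convention of co-occurrence studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline
from sklearn.base import BaseEstimator

MIN_NNSD_TAXA = 20  # spacing statistics are meaningless below this spectrum size


class SpectrumError(ValueError):
    """Raised when a spectrum is too small or degenerate for NNSD analysis."""


@dataclass
class CorrelationMatrix:
    taxon_ids: list[str]
    r: np.ndarray
    method: str = "pearson"
    flagged: list[str] = field(default_factory=list)  # zero-variance taxa

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("correlation matrix not symmetric")
        self.r = r


def correlate(matrix, method: str = "pearson") -> CorrelationMatrix:
    """Pairwise taxon correlations across samples (rows = taxa).

    Zero-variance rows are flagged and get r = 0 against all other taxa.
    """
    if isinstance(matrix, pd.DataFrame):
        ids = list(matrix.index)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        ids = [f"T{i}" for i in range(x.shape[0])]
    if x.shape[1] < 3:
        raise ValueError("correlation requires >= 3 samples")
    if x.shape[0] < 2:
        raise ValueError("correlation requires >= 2 taxa")
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 1, x)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sd = x.std(axis=1)
    flagged = [ids[i] for i in np.flatnonzero(sd == 0)]
    xs = x.copy()
    xs[sd == 0] = np.linspace(0, 1, x.shape[1])  # placeholder, zeroed below
    r = np.corrcoef(xs)
    zero = sd == 0
    r[zero, :] = 0.0
    r[:, zero] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(ids, r, method, flagged)


def unfold_eigenvalues(eigenvalues, max_edof: int = 20) -> np.ndarray:
    """Nearest-neighbour spacings of the unfolded spectrum (mean spacing 1).

    A cubic smoothing spline is fitted to the eigenvalue ECDF, with the
    smoothing parameter picked by a GCV grid capped at ``max_edof`` effective
    degrees of freedom so the fit tracks only the global spectral density —
    an interpolating fit would flatten the very fluctuations the NNSD
    measures. Unfolded positions are n*F(lambda); spacings are their sorted
    first differences, rescaled to mean 1.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    n = lam.size
    if n < MIN_NNSD_TAXA:
        raise SpectrumError(f"spectrum too small for NNSD ({n} < {MIN_NNSD_TAXA})")
    if np.isclose(lam[-1], lam[0]):
        raise SpectrumError("degenerate spectrum: all eigenvalues equal")

    f_emp = (np.arange(1, n + 1) - 0.5) / n
    # collapse exact duplicates for the spline (needs strictly increasing x)
    ux, inv = np.unique(lam, return_inverse=True)
    uf = np.bincount(inv, weights=f_emp) / np.bincount(inv)
    m = ux.size
    if m < 5:
        raise SpectrumError("degenerate spectrum: too few distinct eigenvalues")

    best, best_score = None, np.inf
    scale = m * uf.var()
    for s in np.geomspace(1e-6 * scale + 1e-12, 10 * scale + 1e-9, 12):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # fitpack chatter at small s
                spl = UnivariateSpline(ux, uf, k=3, s=s)
        except Exception:  # pragma: no cover - dfitpack corner cases
            continue
        edof = len(spl.get_knots()) + 2
        if edof > min(max_edof, max(4, m - 1)):
            continue
        rss = float(np.sum((spl(ux) - uf) ** 2))
        gcv = (rss / m) / (1.0 - edof / m) ** 2
        if gcv < best_score:
            best, best_score = spl, gcv
    if best is None:  # fall back: straight-line density
        coef = np.polyfit(ux, uf, 1)
        e = n * np.polyval(coef, lam)
    else:
        e = n * best(lam)
    e = np.maximum.accumulate(e)  # enforce monotone unfolding
    spacings = np.diff(e)
    mean = spacings.mean()
    if mean <= 0:
        raise SpectrumError("degenerate spectrum: zero mean spacing")
    return spacings / mean


def _wigner_cdf(s: np.ndarray) -> np.ndarray:
    return 1.0 - np.exp(-np.pi * s**2 / 4.0)


def _poisson_cdf(s: np.ndarray) -> np.ndarray:
    return 1.0 - np.exp(-s)


def nnsd_gof(spacings) -> tuple[float, float, float]:
    """Chi-square fit of the spacing histogram to Poisson and GOE laws.

    Returns ``(chi2_poisson, chi2_goe, p_poisson)``: the goodness of fit
    against the exponential density e^-s and against the Wigner surmise
    (pi*s/2)*exp(-pi*s^2/4), with p from chi2(bins-1) for the Poisson fit.
    Bin count = ceil(sqrt(n)); the last bin absorbs the upper tail.
    """
    s = np.asarray(spacings, dtype=float)
    if s.size == 0:
        raise SpectrumError("empty spacing list")
    if s.max() <= 0:
        raise SpectrumError("all spacings zero")
    n = s.size
    nbins = int(np.ceil(np.sqrt(n)))
    edges = np.linspace(0.0, s.max(), nbins + 1)
    obs, _ = np.histogram(np.clip(s, 0, s.max()), bins=edges)
    obs = obs.astype(float)
    obs[-1] += np.sum(s > edges[-1])  # safety; clip already handles this

    def chi2_against(cdf) -> float:
        p = np.diff(cdf(edges))
        p[-1] += 1.0 - cdf(np.array([edges[-1]]))[0]  # open upper tail
        exp = n * np.maximum(p, 1e-12)
        return float(np.sum((obs - exp) ** 2 / exp))

    chi2_p = chi2_against(_poisson_cdf)
    chi2_g = chi2_against(_wigner_cdf)
    p_poisson = float(stats.chi2.sf(chi2_p, df=max(nbins - 1, 1)))
    return chi2_p, chi2_g, p_poisson


@dataclass
class RmtScan:
    """Per-threshold NNSD statistics and the selected cutoff."""

    thresholds: np.ndarray
    chi2_poisson: np.ndarray
    chi2_goe: np.ndarray
    p_poisson: np.ndarray
    n_kept: np.ndarray
    chosen_threshold: float
    used_fallback: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "n_kept": self.n_kept,
                "chi2_poisson": self.chi2_poisson,
                "chi2_goe": self.chi2_goe,
                "p_poisson": self.p_poisson,
            }
        )


def rmt_threshold_scan(
    corr: CorrelationMatrix,
    t_min: float = 0.30,
    t_max: float = 0.95,
    step: float = 0.01,
    alpha: float = 0.05,
    min_taxa: int = MIN_NNSD_TAXA,
) -> RmtScan:
    """Scan cutoffs for the GOE -> Poisson spacing transition.

    At each cutoff t, |r| < t entries are zeroed, all-zero rows dropped, and
    the NNSD of the truncated similarity matrix tested against Poisson
    statistics. Chosen threshold: the smallest t with p_poisson >= alpha that
    keeps >= ``min_taxa`` non-isolated taxa; if none qualifies, the t with the
    largest p_poisson (with a warning).
    """
    if step <= 0 or t_max < t_min:
        raise ValueError("invalid threshold grid")
    grid = np.round(np.arange(t_min, t_max + step / 2, step), 10)
    r = corr.r
    absr = np.abs(r - np.diag(np.diag(r)))
    chi2_p = np.full(grid.size, np.nan)
    chi2_g = np.full(grid.size, np.nan)
    pvals = np.full(grid.size, np.nan)
    kept = np.zeros(grid.size, dtype=int)
    for idx, t in enumerate(grid):
        mask = absr >= t
        keep = mask.any(axis=1)
        kept[idx] = int(keep.sum())
        if kept[idx] < min_taxa:
            continue
        sub = r[np.ix_(keep, keep)].copy()
        off = np.abs(sub) < t
        np.fill_diagonal(off, False)
        sub[off] = 0.0
        lam = np.linalg.eigvalsh(sub)
        try:
            spacings = unfold_eigenvalues(lam)
            chi2_p[idx], chi2_g[idx], pvals[idx] = nnsd_gof(spacings)
        except SpectrumError:
            continue
    if not (kept >= min_taxa).any():
        raise ValueError(
            f"no threshold keeps >= {min_taxa} taxa; try a smaller t_min"
        )
    ok = ~np.isnan(pvals)
    passing = np.flatnonzero(ok & (pvals >= alpha))
    if passing.size:
        chosen = float(grid[passing[0]])
        fallback = False
    else:
        valid = np.flatnonzero(ok)
        if valid.size == 0:
            raise ValueError("no threshold produced a testable spectrum")
        chosen = float(grid[valid[np.argmax(pvals[valid])]])
        fallback = True
        warnings.warn(
            "no cutoff reached Poisson statistics at alpha="
            f"{alpha}; using argmax p_poisson = {chosen:.2f}",
            stacklevel=2,
        )
    return RmtScan(grid, chi2_p, chi2_g, pvals, kept, chosen, fallback)


def build_network(corr: CorrelationMatrix, threshold: float) -> nx.Graph:
    """Signed co-occurrence graph: edge iff |r| >= threshold; isolates dropped."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    g = nx.Graph()
    r = corr.r
    n = r.shape[0]
    ids = corr.taxon_ids
    for i in range(n):
        for k in range(i + 1, n):
            if abs(r[i, k]) >= threshold:
                g.add_edge(
                    ids[i], ids[k],
                    sign=1 if r[i, k] > 0 else -1,
                    weight=float(abs(r[i, k])),
                )
    return g


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [
        {"node_a": a, "node_b": b, "sign": d.get("sign", 1), "weight": d.get("weight", 1.0)}
        for a, b, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "sign", "weight"]).to_csv(
        path, sep="\t", index=False
    )


class RMTCorrelationNetwork(BaseEstimator):
    """Estimator: samples x taxa matrix -> RMT-thresholded signed network.

    Analogous in shape to covariance-graph estimators: ``fit(X)`` computes the
    taxon correlation matrix, selects the cutoff by the RMT spacing
    transition (unless ``threshold`` pins it), and stores the result.

    Attributes (after fit): ``correlation_``, ``scan_`` (None when pinned),
    ``threshold_``, ``network_``.
    """

    def __init__(
        self,
        corr_method: str = "pearson",
        threshold: float | None = None,
        t_min: float = 0.30,
        t_max: float = 0.95,
        t_step: float = 0.01,
        alpha: float = 0.05,
        min_taxa: int = MIN_NNSD_TAXA,
    ):
        self.corr_method = corr_method
        self.threshold = threshold
        self.t_min = t_min
        self.t_max = t_max
        self.t_step = t_step
        self.alpha = alpha
        self.min_taxa = min_taxa

    def fit(self, X, y=None, feature_names=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x taxa)")
        self.n_features_in_ = X.shape[1]
        mat = X.T  # taxa x samples for correlate()
        if feature_names is not None:
            mat = pd.DataFrame(mat, index=list(feature_names))
        self.correlation_ = correlate(mat, method=self.corr_method)
        if self.threshold is not None:
            self.scan_ = None
            self.threshold_ = float(self.threshold)
        else:
            self.scan_ = rmt_threshold_scan(
                self.correlation_, self.t_min, self.t_max, self.t_step,
                self.alpha, self.min_taxa,
            )
            self.threshold_ = self.scan_.chosen_threshold
        self.network_ = build_network(self.correlation_, self.threshold_)
        return self
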