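"""Rod-outer-segment (ROS) length morphometry.

Lengths (µm) are binned in 2 µm increments, normalised to frequency of
occurrence, and fitted with a one- or two-component Gaussian on the
bin-centre/frequency pairs.  Component areas use the closed form
``area = height · FWHM · sqrt(pi / (4 ln 2))`` and the fraction of the
total fitted area in the longer-mean component quantifies how many ROS
are longer than the main population.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .presets import FWHM_TO_SIGMA

__all__ = [
    "build_histogram",
    "gaussian_area",
    "GaussianComponent",
    "fit_gaussians",
    "area_fraction",
    "compare_group_means",
    "RosMixtureModel",
    "MorphometryResults",
]

_AREA_FACTOR = math.sqrt(math.pi / (4.0 * math.log(2.0)))


def build_histogram(lengths, bin_width: float = 2.0):
    """Histogram of lengths with edges aligned to multiples of
    ``bin_width`` starting at 0; counts normalised by total n.

    Returns ``(edges, normalized_frequencies)`` with frequencies summing
    to 1.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("lengths must be non-empty")
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    n_bins = int(math.ceil(lengths.max() / bin_width))
    n_bins = max(n_bins, 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(lengths, bins=edges)
    return edges, counts / lengths.size


def gaussian_area(height: float, fwhm: float) -> float:
    """Closed-form area of a Gaussian peak:
    ``height · FWHM · sqrt(pi / (4 ln 2))``."""
    if height < 0:
        raise ValueError("height must be non-negative")
    if fwhm <= 0:
        raise ValueError("FWHM must be positive")
    return height * fwhm * _AREA_FACTOR


@dataclass
class GaussianComponent:
    """One fitted histogram peak (centre and FWHM in µm; height in
    normalised frequency per bin)."""

    center: float
    fwhm: float
    height: float

    @property
    def sigma(self) -> float:
        return self.fwhm * FWHM_TO_SIGMA

    @property
    def area(self) -> float:
        return gaussian_area(self.height, self.fwhm)

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.height * np.exp(-0.5 * ((x - self.center) / self.sigma) ** 2)


def _sum_of_gaussians(x, *params):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for c, s, h in zip(params[::3], params[1::3], params[2::3]):
        out += h * np.exp(-0.5 * ((x - c) / s) ** 2)
    return out


def fit_gaussians(
    histogram,
    k: int,
    init_centers=None,
    init_sigma: float | None = None,
    lengths=None,
) -> list[GaussianComponent]:
    """Least-squares fit of ``k`` (1 or 2) Gaussians to a histogram.

    ``histogram`` is an ``(edges, normalized_frequencies)`` pair; the
    fit runs on bin-centre/frequency pairs, empty bins included.  For
    k = 2 the initial centres come from k-means on the raw ``lengths``
    when given, otherwise from the histogram's 25th/75th weighted
    percentiles; initial widths are the data SD.  Components are
    returned ordered by centre; a two-component fit whose centres fall
    within one bin of each other is flagged with a warning.
    """
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    edges, freqs = histogram
    edges = np.asarray(edges, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if np.count_nonzero(freqs) < 2 * k + 2:
        raise ValueError(f"need at least {2 * k + 2} non-empty bins for k={k}")

    mean = float(np.average(centers, weights=freqs))
    sd = math.sqrt(float(np.average((centers - mean) ** 2, weights=freqs)))
    sd = max(sd, float(edges[1] - edges[0]) / 2)
    hmax = float(freqs.max())

    def _p0(cs, ss):
        p = []
        for c, s in zip(cs, ss):
            h = float(np.interp(c, centers, freqs))
            p += [c, s, max(h, hmax / 10)]
        return p

    # candidate starting points; the mixture problem on a dozen bins has
    # local optima (a broad second component absorbing the tail), so the
    # fit is restarted from several inits and the lowest-SSE fit wins
    starts: list[list[float]] = []
    if init_centers is not None:
        ss = [init_sigma or sd] * k
        starts.append(_p0(sorted(init_centers), ss))
    elif k == 1:
        starts.append(_p0([mean], [init_sigma or sd]))
    else:
        if lengths is not None:
            cs, ss = _kmeans_init(np.asarray(lengths, dtype=float))
            starts.append(_p0(cs, ss))
        cum = np.cumsum(freqs) / freqs.sum()
        qcents = [float(np.interp(q, cum, centers)) for q in (0.25, 0.75)]
        starts.append(_p0(qcents, [sd / 2] * 2))
        starts.append(_p0(qcents, [sd] * 2))

    lo = [edges[0], 1e-3, 0.0] * k
    hi = [edges[-1], edges[-1] - edges[0], 2.0 * hmax] * k
    best, best_sse = None, np.inf
    errors = []
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                _sum_of_gaussians, centers, freqs, p0=p0,
                bounds=(lo, hi), maxfev=50000,
            )
        except RuntimeError as err:
            errors.append(str(err))
            continue
        sse = float(np.sum((_sum_of_gaussians(centers, *popt) - freqs) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        raise RuntimeError(
            f"Gaussian fit (k={k}) did not converge from any start: "
            + "; ".join(errors)
        )
    popt = best
    comps = [
        GaussianComponent(float(c), float(s) / FWHM_TO_SIGMA, float(h))
        for c, s, h in zip(popt[::3], popt[1::3], popt[2::3])
    ]
    comps.sort(key=lambda comp: comp.center)
    if k == 2 and abs(comps[1].center - comps[0].center) < edges[1] - edges[0]:
        warnings.warn(
            "two-component fit collapsed: centres within one bin", stacklevel=2
        )
    return comps


def _kmeans_init(lengths: np.ndarray):
    """Two k-means centres on the raw lengths plus within-cluster SDs
    (deterministic seed); ties break toward the lower centre first."""
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=2, n_init=5, random_state=0).fit(lengths.reshape(-1, 1))
    cents = km.cluster_centers_.ravel()
    order = np.argsort(cents)
    centers, sds = [], []
    for idx in order:
        members = lengths[km.labels_ == idx]
        centers.append(float(cents[idx]))
        sds.append(float(members.std()) if len(members) > 1 else 1.0)
    return centers, sds


def area_fraction(components) -> float:
    """Fraction of the total fitted area in the longer-mean component.

    Requires exactly two components; ties in centre break toward the
    first (lower) component being "short".
    """
    if len(components) != 2:
        raise ValueError("area_fraction requires exactly 2 components")
    first, second = sorted(components, key=lambda c: c.center)
    total = first.area + second.area
    if total == 0:
        raise ValueError("zero total fitted area")
    return second.area / total


@dataclass
class ComparisonResult:
    percent_difference: float  # (mean_b - mean_a) / mean_a * 100
    t_statistic: float
    p_value: float
    mean_a: float
    mean_b: float


def compare_group_means(lengths_a, lengths_b, equal_var: bool = False):
    """Percent difference of group means plus an unpaired two-tailed
    t test (Welch by default)."""
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if mean_a == 0:
        raise ValueError("reference group mean is zero")
    t, p = stats.ttest_ind(b, a, equal_var=equal_var)
    return ComparisonResult(
        (mean_b - mean_a) / mean_a * 100.0, float(t), float(p), mean_a, mean_b
    )


@dataclass
class MorphometryResults:
    """Histogram plus fitted mixture for one set of ROS lengths."""

    bin_edges: np.ndarray
    normalized_frequencies: np.ndarray
    components: list[GaussianComponent]

    @property
    def fraction_long(self) -> float:
        """Area fraction of the longer-mean component (two-component
        fits only)."""
        return area_fraction(self.components)

    @property
    def total_area(self) -> float:
        return sum(c.area for c in self.components)

    def summary(self) -> str:
        lines = [f"ROS length mixture fit ({len(self.components)} component(s))"]
        for i, c in enumerate(self.components, 1):
            lines.append(
                f"  peak {i}: centre {c.center:.1f} um, FWHM {c.fwhm:.1f} um, "
                f"height {c.height:.3f}, area {c.area:.3g}"
            )
        lines.append(f"  total fit area: {self.total_area:.3g}")
        if len(self.components) == 2:
            lines.append(f"  fraction long: {self.fraction_long:.0%}")
        return "\n".join(lines)


class RosMixtureModel:
    """Gaussian-mixture morphometry of ROS lengths.

    Bins the lengths in ``bin_width`` (µm) increments, normalises to
    frequency of occurrence, and fits ``k`` Gaussian components to the
    bin-centre/frequency pairs (k-means on the raw lengths initialises
    a two-component fit).
    """

    def __init__(self, lengths, k: int = 1, bin_width: float = 2.0):
        self.lengths = np.asarray(lengths, dtype=float)
        self.k = k
        self.bin_width = bin_width

    def fit(self) -> MorphometryResults:
        edges, freqs = build_histogram(self.lengths, self.bin_width)
        comps = fit_gaussians((edges, freqs), self.k, lengths=self.lengths)
        return MorphometryResults(edges, freqs, comps)
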