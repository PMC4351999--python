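"""ARISA fingerprint statistics.

Fragment-length profiles are binned on a fixed 2-bp grid anchored at the
lower end of the instrument range (half-open bins, boundary peaks go up),
turning each sample into an OTU abundance vector.  On those vectors the
module computes OTU richness, Shannon diversity, Bray-Curtis and Jaccard
dissimilarities, the ANOSIM permutation test, non-metric multidimensional
scaling and between-assay Pearson correlations.

Shannon uses natural log by default (nats); the base is an argument.
Bray-Curtis is quantitative (peak heights); Jaccard is presence/absence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import MDS

__all__ = [
    "Fingerprint",
    "AnosimResult",
    "bin_fragments",
    "bin_edges",
    "build_otu_table",
    "richness",
    "shannon",
    "bray_curtis",
    "jaccard",
    "distance_matrix",
    "anosim",
    "nmds",
    "diversity_stats",
    "compare_primer_sets",
    "DEFAULT_WINDOW",
    "DEFAULT_RANGE",
]

#: 2-bp binning window — the length-difference resolution the method
#: assumes for the ~100-1500 bp intergenic spacer.
DEFAULT_WINDOW: float = 2.0
DEFAULT_RANGE: tuple[float, float] = (100.0, 1500.0)


@dataclass
class Fingerprint:
    """A sample's called peak list: (fragment length, abundance) pairs.

    Fragment lengths may be fractional (capillary sizing); abundances are
    non-negative intensities.
    """

    sample_id: str
    peaks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for length, abundance in self.peaks:
            if abundance < 0:
                raise ValueError(
                    f"negative abundance {abundance} at fragment length {length} "
                    f"in sample {self.sample_id}"
                )


def bin_edges(
    window: float = DEFAULT_WINDOW,
    fragment_range: tuple[float, float] = DEFAULT_RANGE,
) -> np.ndarray:
    lo, hi = fragment_range
    n_bins = int(math.ceil((hi - lo) / window))
    return lo + window * np.arange(n_bins + 1)


def bin_fragments(
    fp: Fingerprint,
    window: float = DEFAULT_WINDOW,
    fragment_range: tuple[float, float] = DEFAULT_RANGE,
) -> np.ndarray:
    """Sum peak abundances into half-open bins tiling ``fragment_range``.

    Peak with length L lands in bin ``floor((L - lo) / window)``; peaks
    outside ``[lo, hi)`` are dropped.  Total in-range abundance is
    conserved.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    lo, hi = fragment_range
    n_bins = int(math.ceil((hi - lo) / window))
    out = np.zeros(n_bins)
    for length, abundance in fp.peaks:
        if abundance < 0:
            raise ValueError(f"negative abundance {abundance}")
        if not (lo <= length < hi):
            continue
        out[int((length - lo) // window)] += abundance
    return out


def build_otu_table(
    fingerprints: Iterable[Fingerprint],
    window: float = DEFAULT_WINDOW,
    fragment_range: tuple[float, float] = DEFAULT_RANGE,
    drop_empty_samples: bool = False,
) -> pd.DataFrame:
    """Samples x bins abundance matrix; columns labeled by bin start."""
    fps = list(fingerprints)
    edges = bin_edges(window, fragment_range)
    data = {fp.sample_id: bin_fragments(fp, window, fragment_range) for fp in fps}
    table = pd.DataFrame.from_dict(data, orient="index", columns=edges[:-1])
    table.index.name = "sample_id"
    if drop_empty_samples:
        table = table.loc[table.sum(axis=1) > 0]
    return table


def richness(vector: Sequence[float]) -> int:
    """Number of non-zero bins (OTU richness)."""
    v = np.asarray(vector, dtype=float)
    _check_profile(v)
    return int(np.count_nonzero(v))


def shannon(vector: Sequence[float], base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over relative abundances.

    Natural log (nats) unless ``base`` is given.
    """
    v = np.asarray(vector, dtype=float)
    _check_profile(v)
    p = v[v > 0] / v.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def _check_profile(v: np.ndarray) -> None:
    if (v < 0).any():
        raise ValueError("abundance vector must be non-negative")
    if v.sum() == 0:
        raise ValueError("abundance vector sums to zero")


def bray_curtis(a: Sequence[float], b: Sequence[float]) -> float:
    """Quantitative Bray-Curtis dissimilarity: sum|a-b| / sum(a+b)."""
    x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    _check_pair(x, y)
    return float(np.abs(x - y).sum() / (x + y).sum())


def jaccard(a: Sequence[float], b: Sequence[float]) -> float:
    """Presence/absence Jaccard dissimilarity: 1 - |A&B| / |A|B|."""
    x, y = np.asarray(a, dtype=float) > 0, np.asarray(b, dtype=float) > 0
    if not (x.any() or y.any()):
        raise ValueError("both profiles are all-zero")
    return float(1.0 - (x & y).sum() / (x | y).sum())


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("profiles must be non-negative")
    if x.sum() + y.sum() == 0:
        raise ValueError("both profiles are all-zero")


def distance_matrix(table: pd.DataFrame, metric: str = "braycurtis") -> pd.DataFrame:
    """Square sample x sample dissimilarity matrix from an OTU table."""
    fn = {"braycurtis": bray_curtis, "jaccard": jaccard}.get(metric)
    if fn is None:
        raise ValueError(f"unknown metric {metric!r}; use 'braycurtis' or 'jaccard'")
    n = len(table)
    vals = table.to_numpy(dtype=float)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fn(vals[i], vals[j])
    return pd.DataFrame(out, index=table.index, columns=table.index)


@dataclass(frozen=True)
class AnosimResult:
    """ANOSIM statistic R in [-1, 1] with its permutation tail probability."""

    R: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str = "permutation"


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return float((rb - rw) / (m / 2.0))


def _within_mask(groups: np.ndarray) -> np.ndarray:
    n = groups.size
    iu = np.triu_indices(n, 1)
    return groups[iu[0]] == groups[iu[1]]


def _distinct_assignments(groups: np.ndarray) -> Iterable[np.ndarray]:
    seen: set[tuple] = set()
    for perm in itertools.permutations(groups.tolist()):
        if perm not in seen:
            seen.add(perm)
            yield np.asarray(perm)


def anosim(
    dist: "pd.DataFrame | np.ndarray",
    groups: Sequence,
    permutations: int = 999,
    seed: int | None = None,
    method: str = "permutation",
) -> AnosimResult:
    """Analysis of similarities (Clarke's R) with a permutation test.

    R = (mean between-group rank - mean within-group rank) / (M/2) over
    the M = n(n-1)/2 ranked upper-triangle dissimilarities.  The p-value
    uses the add-one estimator ``(1 + #{R_perm >= R_obs}) / (1 + n_perm)``
    and is bit-for-bit reproducible under a fixed seed.  With
    ``method="exact"`` every distinct label assignment is enumerated and
    ``p = #{R_perm >= R_obs} / n_assignments`` (the identity included);
    only feasible for small n.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dist must be a square matrix")
    if not np.allclose(d, d.T):
        raise ValueError("dist must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("dist must have a zero diagonal")
    g = np.asarray(list(groups))
    if g.size != d.shape[0]:
        raise ValueError("groups length must match matrix size")
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2].tolist()
        raise ValueError(f"every group needs >=2 members; too small: {small}")

    iu = np.triu_indices(g.size, 1)
    ranks = stats.rankdata(d[iu])
    observed = _anosim_r(ranks, _within_mask(g))

    if method == "exact":
        r_all = np.array([_anosim_r(ranks, _within_mask(p)) for p in _distinct_assignments(g)])
        p_value = float((r_all >= observed - 1e-12).sum() / r_all.size)
        return AnosimResult(observed, p_value, int(r_all.size), seed, "exact")
    if method != "permutation":
        raise ValueError(f"method must be 'permutation' or 'exact', got {method!r}")
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(g)
        if _anosim_r(ranks, _within_mask(perm)) >= observed - 1e-12:
            hits += 1
    p_value = (1 + hits) / (1 + permutations)
    return AnosimResult(observed, float(p_value), permutations, seed, "permutation")


def nmds(
    dist: "pd.DataFrame | np.ndarray",
    n_components: int = 2,
    seed: int | None = 0,
    n_init: int = 8,
    max_iter: int = 500,
) -> tuple[np.ndarray, float]:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    Runs ``n_init`` seeded random starts of SMACOF (scikit-learn's
    non-metric MDS) and keeps the lowest-stress solution.  Returns
    mean-centered coordinates and Kruskal stress-1.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise ValueError("dist must be a square matrix")
    if n < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} samples for {n_components}-D NMDS")
    import inspect

    kwargs: dict = dict(
        n_components=n_components,
        n_init=n_init,
        max_iter=max_iter,
        random_state=seed,
        normalized_stress=True,
    )
    params = inspect.signature(MDS.__init__).parameters
    if "metric_mds" in params:  # scikit-learn >= 1.9 naming
        kwargs.update(metric="precomputed", metric_mds=False)
        if "init" in params:
            kwargs.update(init="random")
    else:
        kwargs.update(dissimilarity="precomputed", metric=False)
    model = MDS(**kwargs)
    coords = model.fit_transform(d)
    coords = coords - coords.mean(axis=0)
    return coords, float(model.stress_)


def diversity_stats(
    otu_table: pd.DataFrame, shannon_base: float | None = None
) -> pd.DataFrame:
    """Per-sample OTU richness and Shannon diversity from an OTU table."""
    rows = {
        sid: {
            "otu_richness": richness(otu_table.loc[sid]),
            "shannon": shannon(otu_table.loc[sid], base=shannon_base),
        }
        for sid in otu_table.index
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


@dataclass(frozen=True)
class PrimerSetComparison:
    r_richness: float
    p_richness: float
    r_shannon: float
    p_shannon: float


def compare_primer_sets(
    stats_a: pd.DataFrame, stats_b: pd.DataFrame
) -> PrimerSetComparison:
    """Pearson correlation of richness and Shannon between two assays.

    Both diversity tables must cover the identical sample set (n >= 3);
    p-values are two-sided t-tests with n - 2 degrees of freedom.
    """
    if set(stats_a.index) != set(stats_b.index):
        raise ValueError("diversity tables must cover identical sample sets")
    if len(stats_a) < 3:
        raise ValueError("need at least 3 matched samples")
    b = stats_b.loc[stats_a.index]
    out = {}
    for col, tag in (("otu_richness", "richness"), ("shannon", "shannon")):
        x = stats_a[col].to_numpy(dtype=float)
        y = b[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"zero variance in {col}; correlation undefined")
        r, p = stats.pearsonr(x, y)
        out[f"r_{tag}"], out[f"p_{tag}"] = float(r), float(p)
    return PrimerSetComparison(**out)
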