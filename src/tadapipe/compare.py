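"""Cross-sample and cross-method comparative statistics.

Covers Pearson correlation matrices and PCA over binned read counts (with
exclusion of bins that are zero, or jointly extreme, in both compared
samples), rank-binned comparison of per-gene occupancy against an external
quantitative transcriptome, and significance of gene-set overlaps against a
fixed sampling pool (hypergeometric for pairs, seeded Monte Carlo for
higher-order intersections).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .genome import GatcFragmentMap
from .signal import FragmentCounts, OccupancyProfile

__all__ = [
    "BinnedMatrix",
    "OverlapResult",
    "build_binned_matrix",
    "pearson_matrix",
    "pca",
    "rank_bin_compare",
    "hypergeometric_overlap",
    "multiset_intersection_test",
]

DEFAULT_UNIVERSE = 20191  # annotated protein-coding genes in the sampling pool
HIGH_QUANTILE = 0.999  # joint-outlier exclusion threshold


@dataclass
class BinnedMatrix:
    """Samples x bins values with a record of globally dropped bins."""

    values: np.ndarray
    sample_ids: list[str]
    mode: str
    filter_log: dict


@dataclass
class OverlapResult:
    set_sizes: tuple
    intersection_size: int
    universe: int
    p_value: float
    method: str  # hypergeometric | monte_carlo


def build_binned_matrix(
    samples: Sequence[FragmentCounts] | Sequence[OccupancyProfile],
    frag_map: GatcFragmentMap,
    mode: str = "gatc",
    bin_size: int = 300,
    genes=None,
) -> BinnedMatrix:
    """Bin per-sample signal for correlation/PCA.

    Modes: ``gatc`` (one bin per fragment), ``window`` (fixed windows of
    ``bin_size`` bp; a fragment's count goes to the window containing its
    midpoint), ``gene`` (one bin per gene: summed counts, or mean occupancy
    when given profiles).  Bins zero in every sample are dropped here and
    logged; the pairwise zero/high-outlier exclusions happen per comparison
    in :func:`pearson_matrix`.
    """
    if bin_size < 1:
        raise ValueError("bin size must be >= 1")
    is_profile = isinstance(samples[0], OccupancyProfile)
    cols = []
    ids = []
    for i, s in enumerate(samples):
        ids.append(getattr(s, "sample_id", None) or getattr(s, "label", "") or f"s{i}")
        if mode == "gatc":
            cols.append(s.scores if is_profile else s.counts.astype(float))
        elif mode == "window":
            if is_profile:
                raise ValueError("window mode requires fragment counts")
            v = []
            mids = (frag_map.starts + frag_map.ends) // 2
            for chrom in frag_map.chroms:
                sl = frag_map.chrom_slice(chrom)
                n_win = -(-frag_map.chrom_length(chrom) // bin_size)
                v.append(
                    np.bincount(
                        mids[sl] // bin_size, weights=s.counts[sl], minlength=n_win
                    )
                )
            cols.append(np.concatenate(v))
        elif mode == "gene":
            if genes is None:
                raise ValueError("gene mode requires gene annotations")
            vals = []
            for g in genes:
                i0, i1 = frag_map.overlapping(g.chrom, g.start, g.end)
                if is_profile:
                    m = s.mask[i0:i1]
                    vals.append(s.scores[i0:i1][m].mean() if m.any() else np.nan)
                else:
                    vals.append(float(s.counts[i0:i1].sum()))
            cols.append(np.asarray(vals))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    values = np.vstack(cols)
    finite = np.isfinite(values)
    values = np.where(finite, values, 0.0)
    nonzero = (values != 0).any(axis=0) & finite.all(axis=0)
    dropped = int((~nonzero).sum())
    return BinnedMatrix(
        values=values[:, nonzero],
        sample_ids=ids,
        mode=mode,
        filter_log={"n_dropped_zero": dropped, "n_dropped_high": 0},
    )


def _pair_filter(x: np.ndarray, y: np.ndarray, high_quantile: float) -> np.ndarray:
    keep = ~((x == 0) & (y == 0))
    if keep.sum() > 2:
        tx = np.quantile(x[keep], high_quantile)
        ty = np.quantile(y[keep], high_quantile)
        keep &= ~((x > tx) & (y > ty))
    return keep


def pearson_matrix(
    matrix: BinnedMatrix, high_quantile: float = HIGH_QUANTILE
) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix with pairwise bin filtering.

    For each sample pair, bins zero in both members and bins above the
    ``high_quantile`` in both members are excluded before correlating
    (guarding against artificial correlation inflation by shared extreme
    bins).  A zero-variance sample yields NaN entries.
    """
    X = matrix.values
    k, n_bins = X.shape
    if n_bins < 2:
        raise ValueError("need >= 2 bins after filtering")
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            keep = _pair_filter(X[i], X[j], high_quantile)
            xi, xj = X[i][keep], X[j][keep]
            if len(xi) < 2 or xi.std() == 0 or xj.std() == 0:
                r[i, j] = r[j, i] = np.nan
            else:
                r[i, j] = r[j, i] = stats.pearsonr(xi, xj)[0]
    return pd.DataFrame(r, index=matrix.sample_ids, columns=matrix.sample_ids)


def pca(matrix: BinnedMatrix, n_components: int | None = None):
    """PCA of samples over bins (bins centred across samples).

    Returns (coordinates DataFrame with PC columns, variance-explained
    fractions ordered decreasingly).
    """
    X = matrix.values
    if X.shape[0] < 3:
        raise ValueError("need >= 3 samples for PCA")
    if n_components is None:
        n_components = min(X.shape[0] - 1, X.shape[1])
    model = PCA(n_components=n_components)
    coords = model.fit_transform(X - X.mean(axis=0))
    df = pd.DataFrame(
        coords,
        index=matrix.sample_ids,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return df, model.explained_variance_ratio_


def rank_bin_compare(
    tada_values: Mapping[str, float] | pd.Series,
    external_values: Mapping[str, float] | pd.Series,
    bin_size: int = 500,
) -> pd.DataFrame:
    """Mean external expression in rank bins of the occupancy score.

    Genes are sorted by descending occupancy score (ties broken by gene id)
    and grouped in consecutive blocks of ``bin_size`` (the last bin may be
    short); each bin reports the mean external value of its genes.  Genes
    missing from either input are dropped and logged in ``attrs``.
    """
    tada = pd.Series(tada_values, dtype=float)
    ext = pd.Series(external_values, dtype=float)
    shared = tada.index.intersection(ext.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between the two inputs")
    t = tada.loc[shared].sort_index()
    order = t.sort_values(ascending=False, kind="stable").index
    bins = np.arange(len(order)) // bin_size
    df = pd.DataFrame(
        {
            "gene_id": order,
            "rank": np.arange(1, len(order) + 1),
            "tada_score": t.loc[order].to_numpy(),
            "external": ext.loc[order].to_numpy(),
            "bin": bins,
        }
    )
    out = (
        df.groupby("bin")
        .agg(
            n_genes=("gene_id", "size"),
            mean_tada=("tada_score", "mean"),
            mean_external=("external", "mean"),
        )
        .reset_index()
    )
    out.attrs["n_dropped"] = int(len(tada) - len(shared) + len(ext) - len(shared))
    return out


def hypergeometric_overlap(
    n1: int, n2: int, k: int, universe: int = DEFAULT_UNIVERSE
) -> OverlapResult:
    """Upper-tail hypergeometric p-value for an observed overlap.

    p = P(X >= k) with X ~ Hypergeometric(universe, n1, n2): the chance
    that two random subsets of the stated sizes share at least ``k``
    members of the sampling pool.
    """
    if n1 > universe or n2 > universe:
        raise ValueError("set sizes exceed the universe")
    if k > min(n1, n2) or k < 0:
        raise ValueError("overlap inconsistent with set sizes")
    p = float(stats.hypergeom.sf(k - 1, universe, n1, n2))
    return OverlapResult(
        set_sizes=(n1, n2),
        intersection_size=k,
        universe=universe,
        p_value=min(max(p, 0.0), 1.0),
        method="hypergeometric",
    )


def multiset_intersection_test(
    sets: Sequence[set],
    universe: int = DEFAULT_UNIVERSE,
    n_draws: int = 100000,
    seed: int = 0,
) -> OverlapResult:
    """Significance of a k-way gene-set intersection against random subsets.

    k = 2 reduces to the exact hypergeometric test.  For k >= 3 the null
    (k uniform random subsets of the observed sizes) is sampled by the
    sequential-hypergeometric chain |A1 ∩ ... ∩ Aj| given the previous
    intersection size, which is distribution-identical to materialising the
    subsets; p = (1 + #{draws with intersection >= observed}) / (1 + n_draws).
    """
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("need >= 2 sets")
    sizes = tuple(len(s) for s in sets)
    observed = len(set.intersection(*sets))
    if len(sets) == 2:
        return hypergeometric_overlap(sizes[0], sizes[1], observed, universe)
    rng = np.random.default_rng(seed)
    inter = np.full(n_draws, sizes[0], dtype=np.int64)
    for s in sizes[1:]:
        inter = rng.hypergeometric(inter, universe - inter, s)
    hits = int(np.sum(inter >= observed))
    return OverlapResult(
        set_sizes=sizes,
        intersection_size=observed,
        universe=universe,
        p_value=(1 + hits) / (1 + n_draws),
        method="monte_carlo",
    )
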