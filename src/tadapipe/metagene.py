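"""Metagene (aggregation) profiles anchored at the TSS and TES.

Each feature contributes one row: flanks are sampled at native per-base
resolution, the gene body is pushed or stretched to a common pseudo-length
by linear interpolation of the per-base score series, and fixed-width bins
average their bases.  Rows from minus-strand features are reversed so that
upstream is always on the left.  Per-base scores come from the covering
GATC fragment; masked fragments yield missing values that are excluded from
bin averages (zero is a meaningful log-ratio value, so missing is never
imputed as 0).  Aggregating over features gives the mean curve with a 95%
confidence band (mean +/- 1.96 * sd / sqrt(n)); an optional z-transform
expresses each bin as its deviation from the mean signal across the plotted
region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation
from .genome import GatcFragmentMap
from .signal import OccupancyProfile

__all__ = [
    "AggregationProfile",
    "feature_signal_row",
    "aggregate",
    "metagene_profile",
    "isoform_end_density",
]


@dataclass
class AggregationProfile:
    bin_centers: np.ndarray  # bp relative to the TSS anchor (upstream negative)
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_features: int
    params: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "mean": self.mean,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def write(self, path: str) -> None:
        df = self.to_frame()
        df["n"] = self.n_features
        df.to_csv(path, sep="\t", index=False)


def _per_base(
    profile: OccupancyProfile, frag_map: GatcFragmentMap, chrom: str, start: int, end: int
) -> np.ndarray:
    """Per-base score series over [start, end); off-chromosome or masked -> NaN."""
    L = frag_map.chrom_length(chrom)
    pos = np.arange(start, end)
    out = np.full(len(pos), np.nan)
    inb = (pos >= 0) & (pos < L)
    if inb.any():
        idx = frag_map.fragments_at(chrom, pos[inb])
        vals = np.where(profile.mask[idx], profile.scores[idx], np.nan)
        out[inb] = vals
    return out


def _resample(values: np.ndarray, target: int) -> np.ndarray:
    """Linearly resample a per-base series to ``target`` points.

    NaNs propagate: an output base is missing if either neighbouring source
    base is missing.
    """
    n = len(values)
    if n == target:
        return values
    if n == 1:
        return np.repeat(values, target)
    x = np.linspace(0, n - 1, target)
    i0 = np.floor(x).astype(int)
    i1 = np.minimum(i0 + 1, n - 1)
    w = x - i0
    return (1 - w) * values[i0] + w * values[i1]


def _bin_means(row: np.ndarray, bin_size: int) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        return np.nanmean(row.reshape(-1, bin_size), axis=1)


def feature_signal_row(
    profile: OccupancyProfile,
    frag_map: GatcFragmentMap,
    feature: GeneAnnotation,
    flank: int = 3000,
    bin_size: int = 10,
    pseudo_length: int = 3000,
) -> np.ndarray | None:
    """One feature's binned signal row: flank | scaled body | flank.

    Returns ``None`` (with a warning) when the row is entirely missing.
    """
    if (2 * flank + pseudo_length) % bin_size:
        raise ValueError("2*flank + pseudo_length must be a multiple of bin_size")
    up = _per_base(profile, frag_map, feature.chrom, feature.start - flank, feature.start)
    body = _per_base(profile, frag_map, feature.chrom, feature.start, feature.end)
    down = _per_base(profile, frag_map, feature.chrom, feature.end, feature.end + flank)
    row = np.concatenate([up, _resample(body, pseudo_length), down])
    if feature.strand == "-":
        row = row[::-1]
    row = _bin_means(row, bin_size)
    if np.all(np.isnan(row)):
        warnings.warn(f"{feature.gene_id}: no signal in the plotted region; dropped")
        return None
    return row


def aggregate(
    rows: np.ndarray,
    zscore: bool = False,
    bin_centers: np.ndarray | None = None,
    params: dict | None = None,
) -> AggregationProfile:
    """Aggregate per-feature rows into a mean curve with a 95% CI band.

    Bin means ignore missing entries; a bin with no observations is missing
    in the output.  With ``zscore`` the curve is re-expressed as deviations
    from the mean signal across the plotted region, in units of its sd.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or len(rows) < 2:
        raise ValueError("need a matrix of >= 2 feature rows")
    n_bin = np.sum(~np.isnan(rows), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(rows, axis=0)
        sd = np.nanstd(rows, axis=0, ddof=1)
    sem = np.where(n_bin > 0, sd / np.sqrt(np.maximum(n_bin, 1)), np.nan)
    ci_low, ci_high = mean - 1.96 * sem, mean + 1.96 * sem
    if zscore:
        grand_mean = np.nanmean(mean)
        grand_sd = np.nanstd(mean)
        mean = (mean - grand_mean) / grand_sd
        ci_low = (ci_low - grand_mean) / grand_sd
        ci_high = (ci_high - grand_mean) / grand_sd
    if bin_centers is None:
        bin_centers = np.arange(rows.shape[1], dtype=float)
    return AggregationProfile(
        bin_centers=np.asarray(bin_centers, dtype=float),
        mean=mean,
        ci_low=ci_low,
        ci_high=ci_high,
        n_features=len(rows),
        params=dict(params or {}, zscore=zscore),
    )


def _centers(flank: int, bin_size: int, pseudo_length: int) -> np.ndarray:
    n_bins = (2 * flank + pseudo_length) // bin_size
    return -flank + (np.arange(n_bins) + 0.5) * bin_size


def metagene_profile(
    profile: OccupancyProfile,
    frag_map: GatcFragmentMap,
    features: Sequence[GeneAnnotation],
    flank: int = 3000,
    bin_size: int = 10,
    pseudo_length: int = 3000,
    zscore: bool = False,
) -> AggregationProfile:
    """TSS/TES-anchored aggregation profile over ``features``."""
    rows = [
        r
        for f in features
        if (r := feature_signal_row(profile, frag_map, f, flank, bin_size, pseudo_length))
        is not None
    ]
    return aggregate(
        np.array(rows),
        zscore=zscore,
        bin_centers=_centers(flank, bin_size, pseudo_length),
        params={"flank": flank, "bin": bin_size, "pseudo_length": pseudo_length},
    )


def isoform_end_density(
    genes: Sequence[GeneAnnotation],
    bin_size: int = 10,
    pseudo_length: int = 3000,
) -> AggregationProfile:
    """Average positional coverage of a gene's isoforms along its body.

    Per gene, each isoform contributes a 0/1 per-base coverage track within
    the longest-transcript extent; tracks are averaged over isoforms,
    oriented 5'->3', scaled to the pseudo-length and aggregated over genes.
    Values are bounded in [0, 1]; a 3'-biased isoform annotation shows up as
    a curve rising towards the 3' end.
    """
    rows = []
    for g in genes:
        L = g.length
        txs = g.transcripts or ((g.gene_id, g.start, g.end),)
        cov = np.zeros(L)
        for _tid, ts, te in txs:
            cov[max(0, ts - g.start) : min(L, te - g.start)] += 1.0
        cov /= len(txs)
        if g.strand == "-":
            cov = cov[::-1]
        rows.append(_bin_means(_resample(cov, pseudo_length), bin_size))
    return aggregate(
        np.array(rows),
        bin_centers=_centers(0, bin_size, pseudo_length),
        params={"flank": 0, "bin": bin_size, "pseudo_length": pseudo_length},
    )
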