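"""Fragment-level DamID signal: read counting, log2 ratios, profile averaging.

The occupancy signal for one fusion/control sample pair is

    score_f = log2( (rpm_fusion_f + psi) / (rpm_control_f + psi) )

per GATC fragment, where rpm = count / library_size * 1e6 and ``psi`` is a
symmetric pseudocount in RPM units (default 0.5).  Fragments with zero
counts in both samples carry no information and are masked invalid rather
than scored 0.  An optional centering step subtracts the mode of the score
distribution (estimated by Gaussian KDE) so that background fragments sit
near 0, and profiles from all fusion x control replicate pairings are
averaged into a single profile per condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.stats import gaussian_kde

from .genome import GatcFragmentMap

__all__ = [
    "FragmentCounts",
    "OccupancyProfile",
    "read_alignments",
    "count_reads",
    "normalize_ratio",
    "center_profile",
    "average_profiles",
    "write_profile",
    "read_profile",
]


@dataclass
class FragmentCounts:
    """Per-sample read counts over the fragments of a map, in map order."""

    sample_id: str
    role: str  # fusion | control
    counts: np.ndarray
    unassigned: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def library_size(self) -> int:
        """Total input reads: assigned + unassigned."""
        return int(self.counts.sum()) + self.unassigned

    def rpm(self) -> np.ndarray:
        lib = self.library_size
        if lib == 0:
            raise ValueError(f"{self.sample_id}: zero library size")
        return self.counts / lib * 1e6


@dataclass
class OccupancyProfile:
    """Per-fragment normalised log2(fusion/control) scores for one condition."""

    scores: np.ndarray
    mask: np.ndarray  # True where the fragment carries a valid score
    fusion_ids: tuple = ()
    control_ids: tuple = ()
    label: str = ""
    fusion_rpm: np.ndarray | None = field(default=None, repr=False)
    control_rpm: np.ndarray | None = field(default=None, repr=False)
    center_shift: float = 0.0

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.scores.shape != self.mask.shape:
            raise ValueError("scores and mask must have the same shape")
        if not np.all(np.isfinite(self.scores[self.mask])):
            raise ValueError("valid scores must be finite")


def read_alignments(path: str, mapq: int = 0) -> pd.DataFrame:
    """Read mapped single-end alignments from SAM or 6-column BED.

    Returns a DataFrame with columns chrom, start, end, strand (0-based
    half-open).  For SAM, unmapped records (flag 4) are skipped and records
    below the MAPQ threshold dropped.
    """
    path = str(path)
    if path.endswith((".sam", ".bam")):
        rows = []
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.mapping_quality < mapq:
                    continue
                rows.append(
                    (
                        rec.reference_name,
                        rec.reference_start,
                        rec.reference_end,
                        "-" if rec.is_reverse else "+",
                    )
                )
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
    )
    return df[["chrom", "start", "end", "strand"]]


def count_reads(
    alignments: pd.DataFrame,
    frag_map: GatcFragmentMap,
    sample_id: str = "",
    role: str = "fusion",
    assign: str = "five_prime",
) -> FragmentCounts:
    """Assign each alignment to exactly one fragment.

    Under the default 5'-base rule an alignment belongs to the fragment
    containing its 5'-most aligned base (start for +, end-1 for -); DamID
    reads begin at methylated GATC cut sites, making this the natural
    anchor.  ``assign="midpoint"`` switches to midpoint assignment.
    Alignments on unknown chromosomes are counted as unassigned.
    """
    if np.any(alignments["end"].to_numpy() <= alignments["start"].to_numpy()):
        raise ValueError("alignment with end <= start")
    counts = np.zeros(frag_map.n_fragments(), dtype=np.int64)
    unassigned = 0
    for chrom, grp in alignments.groupby("chrom", sort=False):
        if chrom not in frag_map.boundaries:
            unassigned += len(grp)
            continue
        start = grp["start"].to_numpy()
        end = grp["end"].to_numpy()
        if assign == "five_prime":
            pos = np.where(grp["strand"].to_numpy() == "-", end - 1, start)
        elif assign == "midpoint":
            pos = (start + end) // 2
        else:
            raise ValueError(f"unknown assignment rule {assign!r}")
        L = frag_map.chrom_length(chrom)
        inside = (pos >= 0) & (pos < L)
        unassigned += int((~inside).sum())
        idx = frag_map.fragments_at(chrom, pos[inside])
        counts += np.bincount(idx, minlength=len(counts))
    return FragmentCounts(sample_id=sample_id, role=role, counts=counts, unassigned=unassigned)


def normalize_ratio(
    fusion: FragmentCounts,
    control: FragmentCounts,
    pseudocount: float = 0.5,
    label: str = "",
) -> OccupancyProfile:
    """Per-fragment log2((rpm_fusion + psi) / (rpm_control + psi)).

    Fragments with zero counts in both samples are masked invalid.
    Scores are invariant to sequencing depth (RPM scaling) and antisymmetric
    under swapping fusion and control.
    """
    if len(fusion.counts) != len(control.counts):
        raise ValueError("fusion and control counts are on different maps")
    rpm_f, rpm_c = fusion.rpm(), control.rpm()
    mask = ~((fusion.counts == 0) & (control.counts == 0))
    scores = np.full(len(rpm_f), np.nan)
    scores[mask] = np.log2((rpm_f[mask] + pseudocount) / (rpm_c[mask] + pseudocount))
    return OccupancyProfile(
        scores=scores,
        mask=mask,
        fusion_ids=(fusion.sample_id,),
        control_ids=(control.sample_id,),
        label=label,
        fusion_rpm=rpm_f,
        control_rpm=rpm_c,
    )


def center_profile(
    profile: OccupancyProfile,
    min_rpm: float = 1.0,
    min_fragments: int = 100,
    grid_points: int = 512,
) -> OccupancyProfile:
    """Subtract the mode of the score distribution so background sits at 0.

    The mode is estimated by a Gaussian kernel density (Silverman bandwidth)
    evaluated on a regular grid spanning the observed score range, over
    fragments with both-sample rpm >= ``min_rpm`` (all valid fragments if
    rpm information is unavailable).  Idempotent to numerical precision.
    """
    eligible = profile.mask.copy()
    if profile.fusion_rpm is not None and profile.control_rpm is not None:
        eligible &= (profile.fusion_rpm >= min_rpm) & (profile.control_rpm >= min_rpm)
    x = profile.scores[eligible]
    if x.size < min_fragments:
        raise ValueError(
            f"only {x.size} fragments with rpm >= {min_rpm}; too few to estimate the "
            "background mode -- skip centering"
        )
    if np.ptp(x) == 0:
        mode = float(x[0])
    else:
        kde = gaussian_kde(x, bw_method="silverman")
        grid = np.linspace(x.min(), x.max(), grid_points)
        mode = float(grid[np.argmax(kde(grid))])
    scores = profile.scores - mode
    scores[~profile.mask] = np.nan
    return replace(profile, scores=scores, center_shift=profile.center_shift - mode)


def average_profiles(profiles: Sequence[OccupancyProfile], label: str = "") -> OccupancyProfile:
    """Per-fragment mean over profiles where the fragment is valid.

    A fragment is valid in the output if it is valid in at least one input;
    provenance lists all contributing sample pairs.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    scores = np.stack([p.scores for p in profiles])
    masks = np.stack([p.mask for p in profiles])
    scores = np.where(masks, scores, np.nan)
    mask = masks.any(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-invalid fragments
        mean = np.nanmean(scores, axis=0)
    mean[~mask] = np.nan
    fusion_ids = tuple(dict.fromkeys(i for p in profiles for i in p.fusion_ids))
    control_ids = tuple(dict.fromkeys(i for p in profiles for i in p.control_ids))
    return OccupancyProfile(
        scores=mean,
        mask=mask,
        fusion_ids=fusion_ids,
        control_ids=control_ids,
        label=label or profiles[0].label,
    )


def write_profile(profile: OccupancyProfile, frag_map: GatcFragmentMap, path: str) -> None:
    """Write a profile as bedGraph (``.bedgraph``) or scored GFF3 (``.gff3``).

    Masked fragments are omitted; scores are written to 6 decimal places.
    """
    path = str(path)
    gff = path.endswith((".gff3", ".gff"))
    with open(path, "w") as fh:
        if gff:
            fh.write("##gff-version 3\n")
            for chrom in frag_map.chroms:
                fh.write(f"##sequence-region {chrom} 1 {frag_map.chrom_length(chrom)}\n")
        else:
            fh.write(f'track type=bedGraph name="{profile.label or "tada"}"\n')
        for chrom in frag_map.chroms:
            for idx, s, e, _term in frag_map.fragments(chrom):
                if not profile.mask[idx]:
                    continue
                v = profile.scores[idx]
                if gff:
                    fh.write(
                        f"{chrom}\ttadapipe\tGATC_frag\t{s + 1}\t{e}\t{v:.6f}\t.\t.\tID=frag{idx}\n"
                    )
                else:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6f}\n")


def read_profile(path: str, frag_map: GatcFragmentMap) -> OccupancyProfile:
    """Read a bedGraph or scored-GFF3 profile back onto a fragment map.

    Intervals must coincide exactly with map fragments; duplicate or
    overlapping intervals raise a format error.
    """
    path = str(path)
    gff = path.endswith((".gff3", ".gff"))
    scores = np.full(frag_map.n_fragments(), np.nan)
    mask = np.zeros(frag_map.n_fragments(), dtype=bool)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if gff:
                chrom, s, e, v = parts[0], int(parts[3]) - 1, int(parts[4]), float(parts[5])
            else:
                chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in frag_map.boundaries:
                raise ValueError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            idx = frag_map.fragment_at(chrom, s)
            if frag_map.starts[idx] != s or frag_map.ends[idx] != e:
                raise ValueError(f"{path}:{ln}: interval does not match a map fragment")
            if mask[idx]:
                raise ValueError(f"{path}:{ln}: overlapping/duplicate interval")
            scores[idx], mask[idx] = v, True
    return OccupancyProfile(scores=scores, mask=mask, label="")
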