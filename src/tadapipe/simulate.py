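"""Synthetic Targeted DamID experiments with ground truth.

The generator produces the statistical structure the analysis assumes:

* a random genome whose GATC motifs occur at the ~1/256 bp density of an
  iid uniform base composition, close to a real compact metazoan genome;
* non-overlapping gene models with 1-3 nested isoforms (shorter isoforms
  preferentially 3'-anchored) and intergenic 21-bp miRNAs;
* a Dam-control channel sampling background chromatin accessibility
  (Gamma-distributed per fragment) and a Dam-fusion channel adding an
  expression-proportional methylation term over expressed gene bodies,
  optionally weighted towards the 3' end (the positional bias seen in
  RNA-polymerase occupancy data);
* replicate noise (per-fragment Gamma perturbation of the propensities)
  and exact multinomial read sampling so per-sample depth is met exactly.

Because reads are assigned to the fragment containing their 5' base, the
multinomial fragment draws *are* the fragment counts; alignments are
materialised (SAM/BED) only when files are requested.  All randomness is
governed by ``SimulationConfig.seed`` via per-stage seed sequences, so every
artifact is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation
from .genome import GatcFragmentMap, build_fragment_map
from .signal import FragmentCounts

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genome",
    "simulate_annotation",
    "simulate_experiment",
    "write_truth",
    "read_truth",
    "write_alignments",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Parameters of a synthetic TaDa experiment.

    Defaults describe a 2-replicate fusion/control design on a 2 Mb
    single-chromosome genome with 400 genes, a quarter of them expressed:
    the standard desk-scale dataset used throughout the test suite.
    Expression levels are log-normal in units of the mean background
    accessibility; see docs/methods.md for the calibration rationale.
    """

    seed: int
    n_chromosomes: int = 1
    chrom_length: int = 2_000_000
    n_genes: int = 400
    gene_length_meanlog: float = 7.6  # ~2 kb median gene
    gene_length_sdlog: float = 0.6
    gene_length_min: int = 300
    gene_length_max: int = 20_000
    n_mirnas: int = 30
    fraction_expressed: float = 0.25
    expression_meanlog: float = 3.0
    expression_sdlog: float = 0.75
    accessibility_shape: float = 2.0
    accessibility_scale: float = 1.0
    genic_bias_3prime: float = 1.0  # weight exponent; 0 = uniform along the body
    bias_floor: float = 0.1  # minimum relative weight at the 5' end
    depth: int = 2_000_000
    n_fusion: int = 2
    n_control: int = 2
    dispersion: float = 0.02  # variance of the per-replicate Gamma noise factor
    read_length: int = 75

    def __post_init__(self):
        if not 0 <= self.fraction_expressed <= 1:
            raise ValueError("fraction_expressed must be in [0, 1]")
        if min(self.n_chromosomes, self.n_genes, self.n_mirnas, self.depth) < 0:
            raise ValueError("counts must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulationTruth:
    """Ground truth: per-gene expression and per-fragment propensities."""

    genes: pd.DataFrame  # gene_id, expressed, expression_level
    fragments: pd.DataFrame | None = None  # accessibility, fusion/control propensity

    @property
    def expressed_ids(self) -> set:
        return set(self.genes.loc[self.genes["expressed"], "gene_id"])


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def simulate_genome(config: SimulationConfig) -> dict[str, str]:
    """IID uniform A/C/G/T chromosomes (expected GATC spacing 256 bp)."""
    if config.chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10 kb")
    rng = _rng(config, 0)
    return {
        f"chr{i + 1}": "".join(_BASES[rng.integers(0, 4, config.chrom_length)])
        for i in range(config.n_chromosomes)
    }


def _place(rng, placed: list[tuple[int, int]], length: int, chrom_len: int):
    """Place an interval uniformly among all non-overlapping positions.

    Equivalent in law to rejection sampling conditioned on feasibility, but
    never fails spuriously at high occupancy.  ``placed`` is kept sorted.
    """
    import bisect

    gaps, prev = [], 0
    for ps, pe in placed:
        gaps.append((prev, ps))
        prev = pe
    gaps.append((prev, chrom_len))
    feasible = [(gs, ge - gs - length + 1) for gs, ge in gaps if ge - gs >= length]
    total = sum(c for _gs, c in feasible)
    if total == 0:
        return None
    r = int(rng.integers(0, total))
    for gs, c in feasible:
        if r < c:
            s = gs + r
            bisect.insort(placed, (s, s + length))
            return s, s + length
        r -= c
    raise AssertionError("unreachable")


def simulate_annotation(
    genome: Mapping[str, str], config: SimulationConfig
) -> list[GeneAnnotation]:
    """Non-overlapping gene models with nested isoforms plus intergenic miRNAs."""
    rng = _rng(config, 1)
    chroms = list(genome)
    chrom_lens = {c: len(genome[c]) for c in chroms}
    total = sum(chrom_lens.values())
    expected = config.n_genes * float(
        np.exp(config.gene_length_meanlog + config.gene_length_sdlog**2 / 2)
    )
    if expected >= 0.6 * total:
        raise ValueError("requested gene content exceeds 60% of the genome")
    weights = np.array([chrom_lens[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[GeneAnnotation] = []
    for i in range(config.n_genes):
        # bounded retries: a freshly drawn long gene may not fit the remaining
        # gaps late in placement, so redraw length and chromosome (this
        # truncates the length distribution to the space still available)
        spot = None
        for _attempt in range(100):
            length = int(
                np.clip(
                    rng.lognormal(config.gene_length_meanlog, config.gene_length_sdlog),
                    config.gene_length_min,
                    config.gene_length_max,
                )
            )
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            spot = _place(rng, placed[chrom], length, chrom_lens[chrom])
            if spot is not None:
                break
        if spot is None:
            raise RuntimeError(
                f"no room left for gene {i + 1}/{config.n_genes}; lower n_genes or "
                "gene lengths"
            )
        s, e = spot
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{i + 1:04d}"
        n_iso = int(rng.integers(1, 4))
        transcripts = [(f"{gid}.1", s, e)]
        for j in range(2, n_iso + 1):
            ilen = max(1, int(length * rng.uniform(0.3, 0.9)))
            three_prime = rng.random() < 0.7
            if (strand == "+") == three_prime:
                ts, te = e - ilen, e  # anchored at the genomic right
            else:
                ts, te = s, s + ilen
            transcripts.append((f"{gid}.{j}", ts, te))
        genes.append(
            GeneAnnotation(
                gene_id=gid,
                name=gid,
                biotype="protein_coding",
                chrom=chrom,
                strand=strand,
                start=s,
                end=e,
                transcripts=tuple(sorted(transcripts)),
            )
        )
    for i in range(config.n_mirnas):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        spot = _place(rng, placed[chrom], 21, chrom_lens[chrom])
        if spot is None:
            raise RuntimeError("could not place miRNA; lower n_mirnas")
        s, e = spot
        mid = f"mir{i + 1:03d}"
        genes.append(
            GeneAnnotation(
                gene_id=mid,
                name=mid,
                biotype="miRNA",
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                start=s,
                end=e,
                transcripts=((f"{mid}.1", s, e),),
            )
        )
    return genes


def simulate_experiment(
    genome: Mapping[str, str],
    annotation: Sequence[GeneAnnotation],
    config: SimulationConfig,
    frag_map: GatcFragmentMap | None = None,
) -> tuple[list[FragmentCounts], SimulationTruth, GatcFragmentMap]:
    """Draw fusion/control replicate fragment counts and the ground truth.

    Control propensity per fragment is its background accessibility
    ``a_f ~ Gamma(shape, scale)``.  Fusion propensity adds, for every
    expressed gene overlapping the fragment, ``expression_g * w(pos)`` with
    ``w(pos) = (pos_frac * (1 - eps) + eps) ** genic_bias_3prime`` evaluated
    at the fragment midpoint along the gene 5'->3'.  Reads per sample are
    multinomial over fragments (exact depth) after a per-replicate Gamma
    noise factor of variance ``dispersion`` perturbs the propensities.
    """
    if frag_map is None:
        frag_map = build_fragment_map(genome)
    rng = _rng(config, 2)
    n_frag = frag_map.n_fragments()
    accessibility = rng.gamma(
        config.accessibility_shape, config.accessibility_scale, size=n_frag
    )
    accessibility = np.maximum(accessibility, 1e-6)

    coding = [g for g in annotation if g.biotype == "protein_coding"]
    n_expr = int(round(config.fraction_expressed * len(coding)))
    expr_idx = rng.choice(len(coding), size=n_expr, replace=False)
    expressed = np.zeros(len(coding), dtype=bool)
    expressed[expr_idx] = True
    levels = np.zeros(len(coding))
    levels[expressed] = rng.lognormal(
        config.expression_meanlog, config.expression_sdlog, size=n_expr
    )

    fusion_prop = accessibility.copy()
    mids = (frag_map.starts + frag_map.ends) / 2
    eps = config.bias_floor
    for g, on, level in zip(coding, expressed, levels):
        if not on:
            continue
        i0, i1 = frag_map.overlapping(g.chrom, g.start, g.end)
        pos_frac = np.clip((mids[i0:i1] - g.start) / g.length, 0.0, 1.0)
        if g.strand == "-":
            pos_frac = 1.0 - pos_frac
        w = (pos_frac * (1 - eps) + eps) ** config.genic_bias_3prime
        fusion_prop[i0:i1] += level * w

    samples: list[FragmentCounts] = []
    for role, prop, n_rep in (
        ("fusion", fusion_prop, config.n_fusion),
        ("control", accessibility, config.n_control),
    ):
        for rep in range(1, n_rep + 1):
            if config.dispersion > 0:
                noise = rng.gamma(
                    1 / config.dispersion, config.dispersion, size=n_frag
                )
            else:
                noise = 1.0
            p = prop * noise
            counts = rng.multinomial(config.depth, p / p.sum())
            samples.append(
                FragmentCounts(sample_id=f"{role}_{rep}", role=role, counts=counts)
            )

    truth = SimulationTruth(
        genes=pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in coding],
                "expressed": expressed,
                "expression_level": levels,
            }
        ),
        fragments=pd.DataFrame(
            {
                "accessibility": accessibility,
                "fusion_propensity": fusion_prop,
                "control_propensity": accessibility,
            }
        ),
    )
    return samples, truth, frag_map


def write_alignments(
    sample: FragmentCounts,
    frag_map: GatcFragmentMap,
    config: SimulationConfig,
    path: str,
) -> None:
    """Materialise a sample's reads as pre-aligned SAM or BED.

    Each read is a ``read_length`` bp alignment anchored at its fragment's
    5' boundary: plus-strand reads start at the fragment start; minus-strand
    reads end just after it (5' base = fragment start either way), split
    half and half deterministically.
    """
    path = str(path)
    sam = path.endswith(".sam")
    rl = config.read_length
    with open(path, "w") as fh:
        if sam:
            fh.write("@HD\tVN:1.6\tSO:coordinate\n")
            for chrom in frag_map.chroms:
                fh.write(f"@SQ\tSN:{chrom}\tLN:{frag_map.chrom_length(chrom)}\n")
        rid = 0
        for chrom in frag_map.chroms:
            L = frag_map.chrom_length(chrom)
            for idx, s, _e, _t in frag_map.fragments(chrom):
                c = int(sample.counts[idx])
                for k in range(c):
                    rid += 1
                    if k % 2 == 0:  # plus strand
                        rs, re_, flag, strand = s, min(s + rl, L), 0, "+"
                    else:  # minus strand, 5' base at the fragment start
                        rs, re_, flag, strand = max(0, s + 1 - rl), s + 1, 16, "-"
                    if sam:
                        fh.write(
                            f"r{rid}\t{flag}\t{chrom}\t{rs + 1}\t42\t{re_ - rs}M\t*\t0\t0\t*\t*\n"
                        )
                    else:
                        fh.write(f"{chrom}\t{rs}\t{re_}\tr{rid}\t0\t{strand}\n")


def write_truth(truth: SimulationTruth, path: str) -> None:
    df = truth.genes.copy()
    df["expressed"] = df["expressed"].astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_truth(path: str) -> SimulationTruth:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = {"gene_id", "expressed", "expression_level"} - set(df.columns)
    if missing:
        raise ValueError(f"truth table missing columns: {sorted(missing)}")
    df["expressed"] = df["expressed"].astype(bool)
    return SimulationTruth(genes=df)
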