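"""Genome sequences and GATC fragment maps.

DamID signal is resolved at the level of *GATC fragments*: the genomic
intervals between consecutive GATC motifs (the Dam methylation substrate).
This module locates GATC motifs, tiles each chromosome into an ordered,
non-overlapping fragment map, and computes fragment-length statistics within
gene bodies.

Fragment boundary convention: an interior boundary is placed at the midpoint
of its GATC motif (``motif_start + 2``), so each motif contributes two bases
to each flanking fragment.  The regions before the first and after the last
motif of a chromosome are retained as *terminal* fragments so that the map
tiles the chromosome exactly; they can be excluded from statistics via the
``terminal`` flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
from pyfaidx import Fasta

__all__ = [
    "find_gatc_sites",
    "GatcFragmentMap",
    "build_fragment_map",
    "read_fasta",
    "write_fasta",
    "fragment_stats_within_genes",
]

_VALID_SEQ = re.compile(r"^[ACGTNacgtn]*$")
_GATC = re.compile("GATC")


def read_fasta(path: str) -> dict[str, str]:
    """Read a (possibly line-wrapped, multi-record) FASTA into chrom -> sequence."""
    fa = Fasta(str(path), rebuild=False, build_index=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def find_gatc_sites(seq: str) -> list[int]:
    """Return 0-based start positions of GATC motifs in ``seq``.

    Matching is case-insensitive; ``N`` never matches.  GATC cannot overlap
    itself, so consecutive positions always differ by >= 4.
    """
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTNacgtn"))
        raise ValueError(f"sequence contains non-nucleotide characters: {bad!r}")
    return [m.start() for m in _GATC.finditer(seq.upper())]


@dataclass
class GatcFragmentMap:
    """Ordered, non-overlapping GATC fragments tiling each chromosome.

    ``boundaries[chrom]`` holds the n+1 fragment boundaries ``[0, m_1, ...,
    m_k, L]`` where ``m_i`` are GATC motif midpoints.  Fragments are indexed
    globally in chromosome insertion order; per-fragment arrays elsewhere in
    the package (counts, scores) follow this global order.
    """

    boundaries: dict[str, np.ndarray]
    _offsets: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        off, self._offsets = 0, {}
        for chrom, b in self.boundaries.items():
            b = np.asarray(b, dtype=np.int64)
            if b[0] != 0 or np.any(np.diff(b) < 1):
                raise ValueError(f"invalid boundaries for {chrom}")
            self.boundaries[chrom] = b
            self._offsets[chrom] = off
            off += len(b) - 1
        self._total = off

    # -- basic geometry -------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self.boundaries)

    def chrom_length(self, chrom: str) -> int:
        return int(self.boundaries[chrom][-1])

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length(c) for c in self.boundaries}

    def n_fragments(self, chrom: str | None = None) -> int:
        if chrom is None:
            return self._total
        return len(self.boundaries[chrom]) - 1

    def offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        off = self._offsets[chrom]
        return slice(off, off + self.n_fragments(chrom))

    def fragments(self, chrom: str) -> Iterator[tuple[int, int, int, bool]]:
        """Yield (global_index, start, end, terminal) for one chromosome."""
        b = self.boundaries[chrom]
        off, n = self._offsets[chrom], len(b) - 1
        for i in range(n):
            yield off + i, int(b[i]), int(b[i + 1]), i == 0 or i == n - 1

    @property
    def starts(self) -> np.ndarray:
        return np.concatenate([b[:-1] for b in self.boundaries.values()])

    @property
    def ends(self) -> np.ndarray:
        return np.concatenate([b[1:] for b in self.boundaries.values()])

    @property
    def terminal(self) -> np.ndarray:
        flags = []
        for b in self.boundaries.values():
            t = np.zeros(len(b) - 1, dtype=bool)
            t[0] = t[-1] = True
            flags.append(t)
        return np.concatenate(flags)

    @property
    def lengths(self) -> np.ndarray:
        return np.concatenate([np.diff(b) for b in self.boundaries.values()])

    # -- lookups ---------------------------------------------------------

    def fragment_at(self, chrom: str, pos: int) -> int:
        """Global index of the fragment containing base ``pos``."""
        b = self.boundaries[chrom]
        if pos < 0 or pos >= b[-1]:
            raise IndexError(f"{chrom}:{pos} outside chromosome")
        return self._offsets[chrom] + int(np.searchsorted(b, pos, side="right")) - 1

    def fragments_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        b = self.boundaries[chrom]
        return self._offsets[chrom] + np.searchsorted(b, pos, side="right") - 1

    def overlapping(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Global index range [i0, i1) of fragments overlapping [start, end) by >= 1 bp."""
        if chrom not in self.boundaries:
            raise KeyError(chrom)
        b = self.boundaries[chrom]
        start = max(start, 0)
        end = min(end, int(b[-1]))
        if end <= start:
            off = self._offsets[chrom]
            return off, off
        i0 = int(np.searchsorted(b, start, side="right")) - 1
        i1 = int(np.searchsorted(b, end, side="left"))
        off = self._offsets[chrom]
        return off + i0, off + i1

    def gatc_sites_in(self, chrom: str, start: int, end: int) -> int:
        """Number of GATC motifs fully contained in [start, end)."""
        b = self.boundaries[chrom][1:-1]  # interior boundaries = motif midpoints
        motif_starts = b - 2
        return int(np.sum((motif_starts >= start) & (motif_starts + 4 <= end)))

    # -- serialisation ---------------------------------------------------

    def to_gff3(self, path: str, include_terminal: bool = True) -> None:
        """Write the map as GFF3 (type ``GATC_frag``, 1-based inclusive)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom in self.boundaries:
                fh.write(f"##sequence-region {chrom} 1 {self.chrom_length(chrom)}\n")
                for idx, s, e, term in self.fragments(chrom):
                    if term and not include_terminal:
                        continue
                    attrs = f"ID=frag{idx};terminal={int(term)}"
                    fh.write(
                        f"{chrom}\ttadapipe\tGATC_frag\t{s + 1}\t{e}\t.\t.\t.\t{attrs}\n"
                    )

    def to_bed(self, path: str, include_terminal: bool = True) -> None:
        with open(path, "w") as fh:
            for chrom in self.boundaries:
                for idx, s, e, term in self.fragments(chrom):
                    if term and not include_terminal:
                        continue
                    fh.write(f"{chrom}\t{s}\t{e}\tfrag{idx}\t0\t.\n")

    @classmethod
    def from_gff3(cls, path: str) -> "GatcFragmentMap":
        intervals: dict[str, list[tuple[int, int]]] = {}
        declared: dict[str, int] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if line.startswith("##sequence-region"):
                    _, chrom, _one, length = line.split()
                    declared[chrom] = int(length)
                    continue
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 9:
                    raise ValueError(f"{path}:{ln}: malformed GFF3 line")
                chrom, _src, ftype, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
                if ftype != "GATC_frag":
                    continue
                intervals.setdefault(chrom, []).append((int(start) - 1, int(end)))
        return cls._from_intervals(intervals, declared)

    @classmethod
    def from_bed(cls, path: str) -> "GatcFragmentMap":
        intervals: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: malformed BED line")
                intervals.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
        return cls._from_intervals(intervals, {})

    @classmethod
    def _from_intervals(
        cls, intervals: dict[str, list[tuple[int, int]]], declared: dict[str, int]
    ) -> "GatcFragmentMap":
        boundaries = {}
        for chrom, ivs in intervals.items():
            ivs = sorted(ivs)
            for (s1, e1), (s2, _e2) in zip(ivs, ivs[1:]):
                if s2 != e1:
                    raise ValueError(f"fragments on {chrom} do not tile: gap/overlap at {e1}")
            b = [ivs[0][0]] + [e for _s, e in ivs]
            if b[0] != 0:
                # terminal fragment was excluded on write; restore tiling from 0
                b = [0] + b
            length = declared.get(chrom)
            if length is not None and b[-1] != length:
                b = b + [length]
            boundaries[chrom] = np.asarray(b, dtype=np.int64)
        return cls(boundaries)


def build_fragment_map(genome: Mapping[str, str]) -> GatcFragmentMap:
    """Tile each chromosome into GATC fragments.

    A chromosome with k motifs at midpoints ``m_1 < ... < m_k`` yields
    fragments ``[0, m_1), [m_1, m_2), ..., [m_k, L)``; with no motifs it
    yields the single terminal fragment ``[0, L)``.
    """
    if not genome:
        raise ValueError("empty genome")
    boundaries = {}
    for chrom, seq in genome.items():
        mids = [s + 2 for s in find_gatc_sites(seq)]
        boundaries[chrom] = np.asarray([0] + mids + [len(seq)], dtype=np.int64)
    return GatcFragmentMap(boundaries)


def fragment_stats_within_genes(
    frag_map: GatcFragmentMap,
    genes: Iterable,
    include_terminal: bool = True,
) -> dict:
    """Fragment-length statistics within gene bodies.

    A fragment is "within" a gene if it overlaps the gene extent (longest
    transcript) by >= 1 bp; the *overlap length* of each (gene, fragment)
    pair enters the mean/median so that per-gene totals are conserved.
    Also reports, per gene, the number of overlapping fragments and the
    number of GATC motifs fully contained in the gene body.
    """
    import pandas as pd

    starts, ends, terminal = frag_map.starts, frag_map.ends, frag_map.terminal
    overlap_lengths: list[np.ndarray] = []
    rows = []
    for g in genes:
        if g.chrom not in frag_map.boundaries:
            raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom!r}")
        i0, i1 = frag_map.overlapping(g.chrom, g.start, g.end)
        idx = np.arange(i0, i1)
        if not include_terminal:
            idx = idx[~terminal[idx]]
        ov = np.minimum(ends[idx], g.end) - np.maximum(starts[idx], g.start)
        overlap_lengths.append(ov)
        rows.append(
            {
                "gene_id": g.gene_id,
                "n_fragments": len(idx),
                "n_gatc_sites": frag_map.gatc_sites_in(g.chrom, g.start, g.end),
            }
        )
    all_ov = np.concatenate(overlap_lengths) if overlap_lengths else np.array([])
    return {
        "mean_length": float(np.mean(all_ov)) if all_ov.size else float("nan"),
        "median_length": float(np.median(all_ov)) if all_ov.size else float("nan"),
        "per_gene": pd.DataFrame(rows),
    }
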