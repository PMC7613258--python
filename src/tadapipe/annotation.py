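"""Gene annotation: GFF3 gene models, longest-transcript extents, extensions.

Gene extents are defined by the span of the longest transcript (ties broken
by lexicographically smallest transcript id); a gene with no transcript
children keeps its own record's span.  All coordinates are stored 0-based
half-open; GFF3's 1-based inclusive coordinates are converted on read/write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import gffutils

__all__ = ["GeneAnnotation", "load_annotation", "write_annotation", "extend_features"]

_GENE_TYPES = {"gene", "ncRNA_gene", "pseudogene"}


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    name: str
    biotype: str  # protein_coding | miRNA | other
    chrom: str
    strand: str
    start: int  # 0-based half-open extent of the longest transcript
    end: int
    transcripts: tuple = field(default_factory=tuple)  # (id, start, end)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


def _biotype(feature, children) -> str:
    bt = feature.attributes.get("biotype", feature.attributes.get("gene_biotype", [None]))[0]
    if bt is None:
        child_types = {c.featuretype for c in children}
        if "miRNA" in child_types:
            bt = "miRNA"
        elif "mRNA" in child_types:
            bt = "protein_coding"
    if bt in ("protein_coding", "miRNA"):
        return bt
    return "other"


def load_annotation(path: str) -> list[GeneAnnotation]:
    """Parse a GFF3 file into one :class:`GeneAnnotation` per gene.

    Transcripts are linked to genes by ``Parent``; orphan transcripts are
    skipped with a warning.  The gene extent is the span of the longest
    transcript (or the gene record's own span when there are none).
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    gene_ids = set()
    genes: list[GeneAnnotation] = []
    for g in db.all_features():
        if g.featuretype not in _GENE_TYPES:
            continue
        gene_ids.add(g.id)
        children = list(db.children(g.id, level=1))
        transcripts = sorted(
            (c.id, c.start - 1, c.end) for c in children if c.featuretype != "exon"
        )
        if transcripts:
            # longest span; ties broken by smallest transcript id
            best_len = max(te - ts for _tid, ts, te in transcripts)
            _tid, start, end = min(t for t in transcripts if t[2] - t[1] == best_len)
        else:
            start, end = g.start - 1, g.end
        name = g.attributes.get("Name", [g.id])[0]
        genes.append(
            GeneAnnotation(
                gene_id=g.id,
                name=name,
                biotype=_biotype(g, children),
                chrom=g.seqid,
                strand=g.strand if g.strand in "+-" else "+",
                start=start,
                end=end,
                transcripts=tuple(transcripts),
            )
        )
    # orphan transcripts: features with a Parent that is not a known gene
    for f in db.all_features():
        parents = f.attributes.get("Parent", [])
        if parents and not any(p in gene_ids for p in parents):
            warnings.warn(f"skipping {f.id}: parent {parents[0]!r} is not a gene")
    return genes


def write_annotation(genes: Iterable[GeneAnnotation], path: str) -> None:
    """Write genes (and their transcripts) as GFF3, 1-based inclusive."""
    tx_type = {"protein_coding": "mRNA", "miRNA": "miRNA"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};Name={g.name};biotype={g.biotype}"
            fh.write(
                f"{g.chrom}\ttadapipe\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for tid, ts, te in g.transcripts:
                t = tx_type.get(g.biotype, "transcript")
                fh.write(
                    f"{g.chrom}\ttadapipe\t{t}\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t"
                    f"ID={tid};Parent={g.gene_id}\n"
                )


def extend_features(
    features: Sequence[GeneAnnotation],
    upstream: int,
    downstream: int,
    chrom_lengths: Mapping[str, int],
) -> list[GeneAnnotation]:
    """Widen feature extents strand-aware (upstream on the 5' side), clamped
    to ``[0, chrom_length)``.  Transcript records are left untouched."""
    if upstream < 0 or downstream < 0:
        raise ValueError("extensions must be >= 0")
    out = []
    for f in features:
        left, right = (upstream, downstream) if f.strand == "+" else (downstream, upstream)
        out.append(
            replace(
                f,
                start=max(0, f.start - left),
                end=min(chrom_lengths[f.chrom], f.end + right),
            )
        )
    return out
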