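"""End-to-end orchestration: map -> count -> profiles -> calls -> metagene -> compare.

A run is described by a JSON or YAML config naming the genome, annotation,
and a sample sheet (sample id, role, alignment path); all stage parameters
have defaults and every random choice is governed by the config seed, so a
rerun with an identical config reproduces byte-identical tables.  All
fusion x control replicate pairings are normalised separately and averaged
into the single condition profile (a 2+2 design yields 4 pairwise profiles).
"""

from __future__ import annotations

import datetime
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annotation import load_annotation
from .calling import call_features, call_mirnas, write_calls
from .compare import build_binned_matrix, pca, pearson_matrix
from .genome import build_fragment_map, read_fasta
from .metagene import metagene_profile
from .signal import (
    average_profiles,
    center_profile,
    count_reads,
    normalize_ratio,
    read_alignments,
    write_profile,
)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "DEFAULT_PARAMS"]

DEFAULT_PARAMS = {
    "pseudocount": 0.5,
    "center": True,
    "min_rpm": 1.0,
    "mapq": 0,
    "fdr": 0.05,
    "permutations": 10000,
    "flank": 3000,
    "bin": 10,
    "pseudo_length": 3000,
    "universe": 20191,
    "bin_size": 300,
    "mirna_extension": 500,
}

_TOP_KEYS = {"genome", "annotation", "samples", "out_dir", "seed", "params"}
_SAMPLE_KEYS = {"id", "role", "path"}


@dataclass
class RunConfig:
    genome: str
    annotation: str
    samples: list[dict]
    out_dir: str
    seed: int = 0
    params: dict = field(default_factory=dict)


def validate_config(config: dict | str | Path) -> RunConfig:
    """Normalise and validate a run config (dict, JSON path or YAML path).

    Fills parameter defaults, rejects unknown keys by name, and requires a
    sample sheet with at least one fusion and one control whose alignment
    paths exist.
    """
    if not isinstance(config, dict):
        text = Path(config).read_text()
        config = (
            json.loads(text) if str(config).endswith(".json") else yaml.safe_load(text)
        )
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("genome", "annotation", "samples", "out_dir"):
        if key not in config:
            raise ValueError(f"config is missing required key {key!r}")
    params = dict(DEFAULT_PARAMS)
    extra = set(config.get("params", {})) - set(DEFAULT_PARAMS)
    if extra:
        raise ValueError(f"unknown parameter keys: {sorted(extra)}")
    params.update(config.get("params", {}))
    samples = []
    roles = set()
    for i, s in enumerate(config["samples"]):
        unknown = set(s) - _SAMPLE_KEYS
        if unknown:
            raise ValueError(f"samples[{i}]: unknown keys {sorted(unknown)}")
        if s.get("role") not in ("fusion", "control"):
            raise ValueError(f"samples[{i}]: role must be fusion or control")
        if not Path(s["path"]).exists():
            raise FileNotFoundError(f"samples[{i}]: alignment file {s['path']} not found")
        roles.add(s["role"])
        samples.append(dict(s))
    for role in ("fusion", "control"):
        if role not in roles:
            raise ValueError(f"sample sheet contains no {role} sample")
    for key in ("genome", "annotation"):
        if not Path(config[key]).exists():
            raise FileNotFoundError(f"{key} file {config[key]} not found")
    return RunConfig(
        genome=str(config["genome"]),
        annotation=str(config["annotation"]),
        samples=samples,
        out_dir=str(config["out_dir"]),
        seed=int(config.get("seed", 0)),
        params=params,
    )


def run_pipeline(config: RunConfig | dict | str | Path) -> Path:
    """Run all stages in fixed order and return the run directory.

    Outputs: fragment map (GFF3), per-sample fragment counts (TSV), one
    bedGraph per fusion x control pairing plus the averaged profile, gene
    and miRNA call tables, the metagene TSV, correlation and PCA tables,
    a log, and a manifest recording every parameter needed to reproduce.
    Any stage failure aborts with the stage name; prior outputs persist.
    """
    if not isinstance(config, RunConfig):
        config = validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params

    log = logging.getLogger("tadapipe.pipeline")
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest = {
        "version": __version__,
        "started": datetime.datetime.now().isoformat(),
        "seed": config.seed,
        "params": p,
        "samples": config.samples,
        "outputs": [],
    }

    def emit(name):
        manifest["outputs"].append(name)
        log.info("wrote %s", name)

    stage = "fragment_map"
    try:
        genome = read_fasta(config.genome)
        frag_map = build_fragment_map(genome)
        frag_map.to_gff3(out / "fragment_map.gff3")
        emit("fragment_map.gff3")

        stage = "count"
        counts = {}
        for s in config.samples:
            aln = read_alignments(s["path"], mapq=p["mapq"])
            counts[s["id"]] = count_reads(
                aln, frag_map, sample_id=s["id"], role=s["role"]
            )
        counts_tsv = out / "fragment_counts.tsv"
        import pandas as pd

        pd.DataFrame({sid: fc.counts for sid, fc in counts.items()}).to_csv(
            counts_tsv, sep="\t", index_label="fragment"
        )
        emit("fragment_counts.tsv")

        stage = "profiles"
        fusion_ids = [s["id"] for s in config.samples if s["role"] == "fusion"]
        control_ids = [s["id"] for s in config.samples if s["role"] == "control"]
        pair_profiles = []
        pairs = list(itertools.product(fusion_ids, control_ids))
        for fid, cid in pairs:
            prof = normalize_ratio(
                counts[fid], counts[cid], pseudocount=p["pseudocount"],
                label=f"{fid}_vs_{cid}",
            )
            if p["center"]:
                prof = center_profile(prof, min_rpm=p["min_rpm"])
            write_profile(prof, frag_map, out / f"profile_{fid}_vs_{cid}.bedgraph")
            emit(f"profile_{fid}_vs_{cid}.bedgraph")
            pair_profiles.append(prof)
        profile = average_profiles(pair_profiles, label="averaged")
        write_profile(profile, frag_map, out / "profile_averaged.bedgraph")
        emit("profile_averaged.bedgraph")
        manifest["pairs"] = [list(pr) for pr in pairs]

        stage = "call"
        genes = load_annotation(config.annotation)
        coding = [g for g in genes if g.biotype == "protein_coding"]
        mirnas = [g for g in genes if g.biotype == "miRNA"]
        gene_calls = call_features(
            profile, coding, frag_map,
            fdr_threshold=p["fdr"], n_permutations=p["permutations"], seed=config.seed,
        )
        write_calls(gene_calls, out / "gene_calls.tsv")
        emit("gene_calls.tsv")
        if mirnas:
            mirna_calls = call_mirnas(
                profile, mirnas, frag_map, extension=p["mirna_extension"],
                fdr_threshold=p["fdr"], n_permutations=p["permutations"],
                seed=config.seed,
            )
            write_calls(mirna_calls, out / "mirna_calls.tsv")
            emit("mirna_calls.tsv")

        stage = "metagene"
        agg = metagene_profile(
            profile, frag_map, coding,
            flank=p["flank"], bin_size=p["bin"], pseudo_length=p["pseudo_length"],
        )
        agg.write(out / "metagene.tsv")
        emit("metagene.tsv")

        stage = "compare"
        bm = build_binned_matrix(list(counts.values()), frag_map, mode="gatc")
        pearson_matrix(bm).to_csv(out / "correlation.tsv", sep="\t")
        emit("correlation.tsv")
        if len(counts) >= 3:
            coords, varfrac = pca(bm)
            coords.to_csv(out / "pca.tsv", sep="\t")
            np.savetxt(out / "pca_variance.tsv", varfrac)
            emit("pca.tsv")
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        manifest["finished"] = datetime.datetime.now().isoformat()
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        log.removeHandler(handler)
        handler.close()
    return out
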