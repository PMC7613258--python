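from types import SimpleNamespace

import numpy as np
import pytest

import tadapipe as tp


@pytest.fixture(scope="session")
def toy_map():
    """Map of 'AAGATCAAAAGATCAA': motifs at 2 and 10, fragments [0,4),[4,12),[12,16)."""
    return tp.build_fragment_map({"chr1": "AAGATCAAAAGATCAA"})


def make_uniform_map(n_fragments: int, spacing: int = 256) -> tp.GatcFragmentMap:
    """A single-chromosome map of equal-sized fragments (for statistic tests)."""
    b = np.arange(0, (n_fragments + 1) * spacing, spacing, dtype=np.int64)
    return tp.GatcFragmentMap({"chr1": b})


def make_profile(scores, mask=None) -> tp.OccupancyProfile:
    scores = np.asarray(scores, dtype=float)
    if mask is None:
        mask = np.isfinite(scores)
    return tp.OccupancyProfile(scores=np.where(mask, scores, np.nan), mask=mask)


@pytest.fixture(scope="session")
def small_experiment():
    """A desk-scale synthetic TaDa experiment shared across tests."""
    cfg = tp.SimulationConfig(
        seed=11, chrom_length=300_000, n_genes=60, n_mirnas=8, depth=300_000
    )
    genome = tp.simulate_genome(cfg)
    annotation = tp.simulate_annotation(genome, cfg)
    samples, truth, frag_map = tp.simulate_experiment(genome, annotation, cfg)
    fusion = [s for s in samples if s.role == "fusion"]
    control = [s for s in samples if s.role == "control"]
    pair_profiles = [
        tp.center_profile(tp.normalize_ratio(f, c)) for f in fusion for c in control
    ]
    profile = tp.average_profiles(pair_profiles)
    return SimpleNamespace(
        cfg=cfg,
        genome=genome,
        annotation=annotation,
        samples=samples,
        truth=truth,
        frag_map=frag_map,
        pair_profiles=pair_profiles,
        profile=profile,
    )
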