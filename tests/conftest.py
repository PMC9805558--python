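"""Shared fixtures: all test data is generated programmatically.

Session-scoped fixtures build one small multi-species scenario and its
database once; per-test fixtures derive from them. Hypothesis runs
derandomized so the suite is reproducible.
"""

from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from mgt import db as db_mod
from mgt import pipeline
from mgt.sim import make_genome, mutate_strain

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref_genome():
    """A 10-kb reference with 20 annotated genes (15 marker-tagged)."""
    return make_genome("s1_ref", 10_000, gc=0.5, n_genes=20, seed=11)


@pytest.fixture(scope="session")
def strain_pair(ref_genome):
    """Reference strain plus a 1%-diverged strain with exact SNV truth."""
    strain, truth = mutate_strain(ref_genome, 0.01, seed=13, strain_id="s1_B")
    return ref_genome, strain, truth


@pytest.fixture(scope="session")
def toy_collection(tmp_path_factory):
    """On-disk 3-species collection (one genome each) + TOC path."""
    root = tmp_path_factory.mktemp("collection")
    species = {
        "s1": [(make_genome("s1_ref", 10_000, n_genes=20, seed=11), True)],
        "s2": [(make_genome("s2_ref", 8_000, n_genes=18, seed=22), True)],
        "s3": [(make_genome("s3_ref", 6_000, n_genes=16, seed=33), True)],
    }
    from mgt.sim import write_collection

    toc = write_collection(root, species)
    return toc, species


@pytest.fixture(scope="session")
def toy_db(toy_collection, tmp_path_factory):
    toc, _species = toy_collection
    out = tmp_path_factory.mktemp("db")
    collection = db_mod.parse_toc(toc)
    return db_mod.build_db(collection, out)


@pytest.fixture(scope="session")
def two_strain_run(tmp_path_factory):
    """10-sample, 10-kb two-strain scenario run through the pipeline.

    Strain B carries ~100 planted SNVs (1% divergence); per-sample
    strain-B proportions span 0.2-0.8 so every planted site is
    polymorphic in the pool. Reads at 20x with 0.1% error.
    """
    root = tmp_path_factory.mktemp("twostrain")
    props = [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.35, 0.45, 0.55]
    cfg = {
        "species": [
            {
                "species_id": "s1",
                "genome_length": 10_000,
                "n_genes": 20,
                "strains": [
                    {"strain_id": "s1_A", "divergence": 0.0},
                    {"strain_id": "s1_B", "divergence": 0.01},
                ],
            }
        ],
        "samples": [
            {
                "sample_id": f"samp{i:02d}",
                "species_coverage": {"s1": 20},
                "proportions": {"s1": {"s1_A": 1 - p, "s1_B": p}},
            }
            for i, p in enumerate(props)
        ],
        "reads": {"error_rate": 0.001},
    }
    scen = pipeline.simulate_scenario(cfg, root / "scen", seed=101)
    run_cfg = {
        "db": {"toc": str(scen / "collection" / "toc.tsv")},
        "samples": [
            {
                "sample_id": f"samp{i:02d}",
                "r1": str(scen / "reads" / f"samp{i:02d}_R1.fq"),
                "r2": str(scen / "reads" / f"samp{i:02d}_R2.fq"),
            }
            for i in range(len(props))
        ],
        "params": {"run_cnv": False, "run_strainmix": False},
    }
    out = pipeline.run_pipeline(run_cfg, root / "run")
    return scen, out, run_cfg
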