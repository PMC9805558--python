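"""End-to-end pipeline orchestration.

Binds the stages together: database build -> per-sample species
screening and customized-target pileup -> across-samples population
SNVs, with optional per-sample CNV estimation and strain-mixture
calls. Also hosts the simulation-scenario driver used by ``mgt sim``.

Reruns from identical config and inputs are byte-identical: every
stage uses fixed sort orders and the run manifest records parameters
and input checksums but no timestamps (timing lives only in logs).
On any stage failure, partial outputs are quarantined under
``<out>/failed/`` before the error propagates.
"""

from __future__ import annotations

import logging
import shutil
from pathlib import Path

import numpy as np
import yaml

from . import cnv as cnv_mod
from . import db as db_mod
from . import popsnv, screen, strainmix
from .io import sha256_file, write_fastq, write_tsv
from .pileup import CNV_FILTERS, FilterParams, iter_sites, single_sample_from_fastq, write_pileup
from .sim import (
    Genome,
    make_genome,
    mutate_strain,
    plant_cnv,
    simulate_reads,
    write_collection,
    write_truth,
)

logger = logging.getLogger(__name__)

DEFAULTS = {
    "min_cov": screen.DEFAULT_MIN_COV,
    "min_identity": screen.DEFAULT_MIN_IDENTITY,
    "min_aln_len": screen.DEFAULT_MIN_ALN_LEN,
    "identity_threshold": db_mod.DEFAULT_IDENTITY,
    "chunk_size": popsnv.DEFAULT_CHUNK_SIZE,
    "workers": 1,
    "pooling": "counts",
    "presence_threshold": cnv_mod.DEFAULT_PRESENCE_THRESHOLD,
    "run_cnv": True,
    "run_strainmix": True,
}


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute db -> screen -> single -> merge (+ cnv + strainmix).

    ``config`` keys: ``db`` ({toc: path} or {dir: path}), ``samples``
    (list of {sample_id, r1, r2}), optional ``params`` overriding
    DEFAULTS, optional ``filters`` / ``site_filters`` dicts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, out)
    except Exception:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for entry in sorted(out.iterdir()):
            if entry.name != "failed":
                shutil.move(str(entry), str(failed / entry.name))
        raise


def _run(config: dict, out: Path) -> Path:
    params = {**DEFAULTS, **config.get("params", {})}
    filters = FilterParams(**config.get("filters", {}))
    site_filters = popsnv.SiteFilters(**config.get("site_filters", {}))

    # --- database
    db_cfg = config["db"]
    if "dir" in db_cfg:
        db = db_mod.load_db(db_cfg["dir"])
    else:
        collection = db_mod.parse_toc(db_cfg["toc"])
        db = db_mod.build_db(
            collection, out / "db", identity_threshold=params["identity_threshold"]
        )

    # --- per-sample: screen, customized target, pileup
    sample_dirs: dict[str, Path] = {}
    all_selected: set[str] = set()
    marker_aligner = None
    mix_calls = []
    for s in config["samples"]:
        sid = s["sample_id"]
        sdir = out / "samples" / sid
        sdir.mkdir(parents=True, exist_ok=True)
        profiles = screen.profile_sample(
            s["r1"], s["r2"], db,
            min_identity=params["min_identity"], min_aln_len=params["min_aln_len"],
        )
        screen.write_profile(sdir / "profile.tsv", profiles)
        selected = screen.select_species(profiles, params["min_cov"])
        all_selected.update(selected)
        target = screen.build_custom_target(selected, db, sdir / "custom_target.fa")
        counts = single_sample_from_fastq(target, s["r1"], s["r2"], params=filters)
        write_pileup(sdir / "snps_pileup.tsv", iter_sites(counts, target))
        sample_dirs[sid] = sdir

        if params["run_cnv"]:
            _sample_cnv(s, sdir, db, selected, profiles, params)
        if params["run_strainmix"]:
            mix_calls.extend(strainmix.call_sample(sdir / "snps_pileup.tsv", sid))

    if params["run_strainmix"]:
        strainmix.write_calls(out / "strain_calls.tsv", mix_calls)

    # --- across-samples merge over the union of selected species
    contig_lengths: dict[str, int] = {}
    ref_seqs: dict[str, str] = {}
    for sp in sorted(all_selected):
        for cid, seq in sorted(db.representative_seqs(sp).items()):
            ref_seqs[f"{sp}|{cid}"] = seq
            contig_lengths[f"{sp}|{cid}"] = len(seq)
    popsnv.merge_samples(
        {sid: d / "snps_pileup.tsv" for sid, d in sample_dirs.items()},
        contig_lengths,
        ref_seqs,
        filters=site_filters,
        method=params["pooling"],
        chunk_size=params["chunk_size"],
        workers=params["workers"],
        out_dir=out / "merge",
    )

    _write_manifest(out, config, params)
    return out


def _sample_cnv(sample_cfg, sdir, db, selected, profiles, params):
    from .io import read_fastq_pairs

    centroid_seqs: dict[str, str] = {}
    species_of: dict[str, str] = {}
    for sp in selected:
        for gid, seq in db.centroid_seqs(sp).items():
            centroid_seqs[gid] = seq
            species_of[gid] = sp
    if not centroid_seqs:
        return
    mmc = {p.species_id: p.median_marker_coverage for p in profiles}
    cnv_mod.run_cnv(
        read_fastq_pairs(sample_cfg["r1"], sample_cfg["r2"]),
        centroid_seqs,
        species_of,
        mmc,
        params=CNV_FILTERS,
        presence_threshold=params["presence_threshold"],
        out_path=sdir / "genes_copynum.tsv",
    )


def _write_manifest(out: Path, config: dict, params: dict) -> None:
    rows = [["param." + k, params[k]] for k in sorted(params)]
    for s in config["samples"]:
        for key in ("r1", "r2"):
            rows.append([f"input.{s['sample_id']}.{key}", sha256_file(s[key])])
    if "toc" in config.get("db", {}):
        rows.append(["input.db.toc", sha256_file(config["db"]["toc"])])
    write_tsv(out / "run_manifest.tsv", ["key", "value"], rows)


# ---------------------------------------------------------------------------
# Simulation scenario driver (``mgt sim community``)


def simulate_scenario(config: dict, out_dir: str | Path, seed: int | None = None) -> Path:
    """Generate a full synthetic scenario: collection, reads and truth.

    Config schema (YAML)::

        seed: 1
        species:
          - species_id: s1
            genome_length: 10000
            n_genes: 30          # first 15 carry the marker panel
            gc: 0.5
            strains:
              - {strain_id: s1_A, divergence: 0.0}
              - {strain_id: s1_B, divergence: 0.01,
                 cnv: [{gene_id: s1_ref_g0016, copies: 2}]}
        samples:
          - sample_id: samp1
            species_coverage: {s1: 20}
            proportions: {s1: {s1_A: 0.7, s1_B: 0.3}}
        reads: {read_len: 100, frag_mean: 300, frag_sd: 30, error_rate: 0.001}
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    read_cfg = {
        "read_len": 100, "frag_mean": 300, "frag_sd": 30, "error_rate": 0.0,
        **config.get("reads", {}),
    }

    ss = np.random.SeedSequence(seed)
    species_seeds = {
        sp["species_id"]: child
        for sp, child in zip(config["species"], ss.spawn(len(config["species"])))
    }

    collection: dict[str, list[tuple[Genome, bool]]] = {}
    strains: dict[str, dict[str, Genome]] = {}
    truth_snvs: dict[str, list] = {}
    truth_cnvs: dict[str, list] = {}
    for sp in config["species"]:
        sid = sp["species_id"]
        gseed, mseed = species_seeds[sid].generate_state(2) % (2**31)
        ref = make_genome(
            f"{sid}_ref",
            sp["genome_length"],
            gc=sp.get("gc", 0.5),
            n_genes=sp.get("n_genes", 30),
            seed=int(gseed),
        )
        collection[sid] = [(ref, True)]
        strains[sid] = {}
        for j, st in enumerate(sp.get("strains", [{"strain_id": f"{sid}_A", "divergence": 0.0}])):
            strain, snvs = mutate_strain(
                ref, st.get("divergence", 0.0), int((mseed + j) % (2**31)),
                strain_id=st["strain_id"],
            )
            for ev in st.get("cnv", []):
                strain, event, snvs = plant_cnv(strain, ev["gene_id"], ev["copies"], snvs)
                truth_cnvs.setdefault(st["strain_id"], []).append(event)
            strains[sid][st["strain_id"]] = strain
            truth_snvs[st["strain_id"]] = snvs

    toc = write_collection(out / "collection", collection)

    composition: dict[str, dict[str, float]] = {}
    sample_rows = []
    sample_seeds = ss.spawn(len(config["samples"]))
    for samp, child in zip(config["samples"], sample_seeds):
        sample_id = samp["sample_id"]
        r1_all, r2_all = [], []
        composition[sample_id] = {}
        sub = child.spawn(len(samp["species_coverage"]))
        for (sid, cov), sp_child in zip(sorted(samp["species_coverage"].items()), sub):
            props = samp.get("proportions", {}).get(sid)
            if props is None:
                first = sorted(strains[sid])[0]
                props = {first: 1.0}
            community = [(strains[sid][st], p) for st, p in sorted(props.items())]
            r1, r2, _ = simulate_reads(
                community, cov, seed=int(sp_child.generate_state(1)[0] % (2**31)), **read_cfg
            )
            r1_all.extend(r1)
            r2_all.extend(r2)
            for st, p in props.items():
                composition[sample_id][st] = p
        rdir = out / "reads"
        rdir.mkdir(exist_ok=True)
        write_fastq(rdir / f"{sample_id}_R1.fq", r1_all)
        write_fastq(rdir / f"{sample_id}_R2.fq", r2_all)
        sample_rows.append(
            [sample_id, str(rdir / f"{sample_id}_R1.fq"), str(rdir / f"{sample_id}_R2.fq")]
        )

    write_truth(out, snvs=truth_snvs, cnvs=truth_cnvs, composition=composition)
    write_tsv(out / "samples.tsv", ["sample_id", "r1", "r2"], sample_rows)
    logger.info("scenario written to %s (toc: %s)", out, toc)
    return out


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
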