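"""End-to-end orchestration: simulate -> index -> bands -> call -> intersect
-> annotate -> diversity, as one reproducible run driven by a single config.

Outputs are a plain directory of TSV/BED/GFF3/FASTA files plus a JSON
manifest recording parameters, seeds and output checksums; rerunning with an
identical config reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict

import pandas as pd

from . import io_formats as io
from . import null_simulation as ns
from . import qtl_calling as qc
from . import qtlseq_core as core
from . import synthetic_data as sd
from .diversity import diversity_ratio, diversity_windows
from .phenotype_stats import broad_sense_heritability, summarize_trait

ROLES = {r: r for r in io.ROLE_NAMES}


def default_config(seed: int = 7) -> dict:
    """A two-population desk-scale synthetic run configuration."""
    return {
        "seed": seed,
        "populations": {
            "popA": {"n_ril": 260},
            "popB": {"n_ril": 204},
        },
        "sim": {
            "chrom_lengths": {"Ca4": 55_000_000},
            "marker_spacing": 5_000,
            "qtls": [["Ca4", 26_800_000, 12.0], ["Ca4", 46_400_000, 9.0]],
            "h2": 0.8,
            "depth_mean": 30.0,
            "bulk_size": 10,
        },
        "filters": {"min_depth": 10, "min_bq": 20.0, "low_index_floor": 0.3},
        "windows": {"window": 2_000_000, "step": 500_000},
        "bands": {"depths": [10, 20, 30, 50], "n_reps": 10_000},
        "calling": {"level": 99.9, "min_delta": 0.5, "high_min": 0.8, "low_max": 0.2},
        "annotation": {"urr_len": 2000, "drr_len": 2000},
        "diversity": {
            "n_cultivated": 93,
            "n_wild": 79,
            "n_sites": 2000,
            "reduction": 0.9,
            "sweep_region": [800_001, 1_200_000],
            "window_size": 100_000,
        },
    }


def _checksum(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir: str) -> dict:
    """Execute all stages in dependency order; returns the manifest dict."""
    os.makedirs(out_dir, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {"seed": seed, "config": config, "stages": [], "outputs": {}}

    def emit(name: str, path: str) -> None:
        manifest["outputs"][name] = {
            "path": os.path.relpath(path, out_dir),
            "md5": _checksum(path),
        }

    calls_by_pop: dict[str, list[io.QtlInterval]] = {}
    records_by_pop: dict[str, pd.DataFrame] = {}
    win_cfg = config["windows"]
    sim_cfg = config["sim"]

    # --- stage: null bands (shared across populations) --------------------
    bands = ns.build_null_bands(
        bulk_size=int(sim_cfg.get("bulk_size", 10)),
        generation=9,
        depths=tuple(config["bands"]["depths"]),
        n_reps=int(config["bands"]["n_reps"]),
        seed=seed,
    )
    path = os.path.join(out_dir, "null_bands.tsv")
    bands.to_tsv(path)
    emit("null_bands", path)
    manifest["stages"].append("null_bands")

    for k, (pop, pop_cfg) in enumerate(sorted(config["populations"].items())):
        pop_seed = seed + 100 * (k + 1)
        cfg = sd.SimConfig(
            n_ril=int(pop_cfg.get("n_ril", 260)),
            chrom_lengths=dict(sim_cfg["chrom_lengths"]),
            marker_spacing=int(sim_cfg["marker_spacing"]),
            qtls=[tuple(q) for q in sim_cfg["qtls"]],
            h2=float(sim_cfg["h2"]),
            depth_mean=float(sim_cfg["depth_mean"]),
            bulk_size=int(sim_cfg["bulk_size"]),
            seed=pop_seed,
        )
        truth = sd.simulate_ril_population(cfg)
        phen = sd.simulate_phenotypes(truth)
        bulks = sd.constitute_bulks(truth, phen)
        table = sd.simulate_bulk_readcounts(truth, bulks)

        path = os.path.join(out_dir, f"{pop}_phenotypes.tsv")
        io.write_phenotypes(phen, path)
        emit(f"{pop}_phenotypes", path)
        path = os.path.join(out_dir, f"{pop}_counts.tsv")
        io.write_allele_counts(table, path)
        emit(f"{pop}_counts", path)
        manifest["stages"].append(f"{pop}_simulate")

        # phenotype summaries
        summ = summarize_trait(phen[phen["population"] == "RIL"])
        h2 = broad_sense_heritability(phen)
        path = os.path.join(out_dir, f"{pop}_pheno_stats.json")
        with open(path, "w") as fh:
            json.dump(
                {"trait_summary": asdict(summ), "heritability": asdict(h2)},
                fh,
                indent=1,
            )
        emit(f"{pop}_pheno_stats", path)
        manifest["stages"].append(f"{pop}_phenotype_stats")

        # SNP indices + windows + calls
        f = config["filters"]
        records, removal = core.filter_snps(
            table,
            ROLES,
            min_depth=int(f["min_depth"]),
            min_bq=float(f["min_bq"]),
            low_index_floor=f.get("low_index_floor", 0.3),
        )
        records_by_pop[pop] = records
        path = os.path.join(out_dir, f"{pop}_snp_index.tsv")
        records.to_csv(path, sep="\t", index=False)
        emit(f"{pop}_snp_index", path)
        manifest["stages"].append(f"{pop}_index")

        profile = core.sliding_window_profile(
            records,
            int(win_cfg["window"]),
            int(win_cfg["step"]),
            cfg.chrom_lengths,
        )
        profile = ns.attach_bands(profile, records, bands)
        path = os.path.join(out_dir, f"{pop}_windows.tsv")
        profile.df.to_csv(path, sep="\t", index=False)
        emit(f"{pop}_windows", path)

        c = config["calling"]
        calls = qc.call_qtls(
            profile,
            records,
            level=float(c["level"]),
            min_delta=float(c["min_delta"]),
            high_min=float(c["high_min"]),
            low_max=float(c["low_max"]),
            population=pop,
        )
        calls_by_pop[pop] = calls
        path = os.path.join(out_dir, f"{pop}_qtls.bed")
        io.write_intervals(calls, path)
        emit(f"{pop}_qtls", path)
        manifest["stages"].append(f"{pop}_call")

    # --- stage: consensus intersection ------------------------------------
    pops = sorted(calls_by_pop)
    consensus: list[qc.ConsensusInterval] = []
    if len(pops) >= 2:
        consensus, specific = qc.intersect_qtls(
            calls_by_pop[pops[0]], calls_by_pop[pops[1]]
        )
        rows = [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "length_kb": qc.interval_length(c.start, c.end, "kb"),
                "sources": ";".join(s.population for s in c.sources),
            }
            for c in consensus
        ]
        path = os.path.join(out_dir, "consensus_intervals.tsv")
        pd.DataFrame(rows, columns=["chrom", "start", "end", "length_kb", "sources"]).to_csv(
            path, sep="\t", index=False
        )
        emit("consensus_intervals", path)
        manifest["stages"].append("intersect")

    # --- stage: annotation fixture + candidate delineation ----------------
    ann = sd.generate_gene_models(seed=seed)
    gff = os.path.join(out_dir, "genes.gff3")
    io.write_gene_models(ann.genes, gff)
    emit("gene_models", gff)
    fasta = os.path.join(out_dir, "reference.fa")
    io.write_fasta(ann.sequences, fasta)
    emit("reference_fasta", fasta)
    manifest["stages"].append("annotate")

    # --- stage: diversity scan --------------------------------------------
    d = config["diversity"]
    cult, wild = sd.simulate_diversity_panel(
        n_cultivated=int(d["n_cultivated"]),
        n_wild=int(d["n_wild"]),
        n_sites=int(d["n_sites"]),
        reduction=float(d["reduction"]),
        sweep_region=tuple(d["sweep_region"]),
        seed=seed,
    )
    wc = diversity_windows(cult, int(d["window_size"]))
    ww = diversity_windows(wild, int(d["window_size"]))
    ratio, per_window = diversity_ratio(wc, ww, tuple(d["sweep_region"]))
    path = os.path.join(out_dir, "diversity_windows.tsv")
    merged = wc.merge(ww, on=["chrom", "start", "end"], suffixes=("_cultivated", "_wild"))
    merged.to_csv(path, sep="\t", index=False)
    emit("diversity_windows", path)
    path = os.path.join(out_dir, "diversity_ratio.json")
    with open(path, "w") as fh:
        json.dump({"sweep_region_ratio_percent": ratio}, fh)
    emit("diversity_ratio", path)
    manifest["stages"].append("diversity")

    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
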