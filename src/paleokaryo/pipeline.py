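"""End-to-end pipeline orchestration.

Runs the stages in dependency order — simulate, homology, synteny,
ancestor, scenario, landscape — from a single configuration, with one
master seed from which every stage derives its own.  Each stage writes its
outputs into the run directory; a manifest records parameters, seeds and
per-output checksums.  A rerun with the same configuration skips stages
whose outputs already exist, and regenerating one stage forces every
stage downstream of it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml

from . import scenario as sc
from .ancestor import reconstruct_ancestor
from .formats import read_gene_order, read_hsp_table, group_hsps, write_block_table
from .homology import HomologPair, call_homologs, summarize_pair
from .landscape import window_profiles, write_profile_table
from .simulate import SimConfig, noise_free, scale_profile, simulate
from .synteny import SyntenyParams, coverage_summary, detect_blocks

STAGES = ["simulate", "homology", "synteny", "ancestor", "scenario", "landscape"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def load_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(
    config: dict,
    outdir: str | Path,
    seed: int = 0,
    stages: Optional[list[str]] = None,
) -> dict:
    """Execute the pipeline; returns the manifest (also written to disk).

    ``config`` keys (all optional): ``sim`` (SimConfig fields plus
    ``scale`` and ``noise_free``), ``synteny`` (SyntenyParams fields),
    ``ancestor.reference``, ``landscape.window_bp``, ``stages`` (subset
    toggle).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = stages or config.get("stages", STAGES)
    manifest: dict = {
        "seed": seed,
        "stages": {},
        "config": config,
    }

    sim_dir = outdir / "sim"
    rerun = False

    def stage_done(outputs: list[Path]) -> bool:
        return all(p.exists() for p in outputs)

    def record(stage: str, outputs: list[Path], seed_used: Optional[int],
               skipped: bool) -> None:
        manifest["stages"][stage] = {
            "outputs": {
                str(p.relative_to(outdir)): _sha256(p) for p in outputs
            },
            "seed": seed_used,
            "skipped": skipped,
        }

    # ---- simulate ----
    sim_cfg_raw = dict(config.get("sim", {}))
    scale = sim_cfg_raw.pop("scale", 1.0)
    want_noise_free = sim_cfg_raw.pop("noise_free", False)
    profile = sim_cfg_raw.pop("profile", "plant")
    events = sim_cfg_raw.pop("events", None)
    if profile == "animal":
        sim_cfg = SimConfig.animal(**sim_cfg_raw)
    else:
        sim_cfg = SimConfig(profile="plant", **sim_cfg_raw)
    if events:
        sim_cfg.shared_events = [
            sc.Event(e["kind"], e.get("operands", {}))
            for e in events.get("shared", [])
        ]
        sim_cfg.lineage_events = {
            g: [sc.Event(e["kind"], e.get("operands", {})) for e in evs]
            for g, evs in events.get("lineages", {}).items()
        }
    if scale != 1.0:
        sim_cfg = scale_profile(sim_cfg, scale)
    if want_noise_free:
        sim_cfg = noise_free(sim_cfg)

    sim_outputs = [
        sim_dir / n
        for n in ("genes.tsv", "hsps.tsv", "features.gff3",
                  "ground_truth.json", "divergence.tsv")
    ]
    sim_seed = _stage_seed(seed, "simulate")
    if "simulate" in enabled:
        if stage_done(sim_outputs) and not rerun:
            record("simulate", sim_outputs, sim_seed, skipped=True)
        else:
            result = simulate(sim_cfg, seed=sim_seed)
            result.write_outputs(sim_dir)
            rerun = True
            record("simulate", sim_outputs, sim_seed, skipped=False)

    genomes = read_gene_order(sim_dir / "genes.tsv")
    gene_index = {g.gene_id: g for gs in genomes.values() for g in gs}
    genome_map = {g.gene_id: g.genome_id for g in gene_index.values()}

    divergence: dict[tuple[str, str], str] = {}
    with open(sim_dir / "divergence.tsv") as fh:
        next(fh)
        for line in fh:
            ga, gb, cls = line.split()
            divergence[(ga, gb)] = cls

    # ---- homology ----
    homolog_path = outdir / "homologs.tsv"
    if "homology" in enabled:
        if homolog_path.exists() and not rerun:
            record("homology", [homolog_path], None, skipped=True)
        else:
            hsps = read_hsp_table(sim_dir / "hsps.tsv", dialect="nident")
            alignments = []
            for (q, s), grp in group_hsps(hsps).items():
                qlen = gene_index[q].cds_length if q in gene_index else max(
                    h.query_end for h in grp
                )
                alignments.append(summarize_pair(q, s, grp, qlen))
            pairs = call_homologs(alignments, genome_map, divergence)
            with open(homolog_path, "w") as fh:
                fh.write("gene_a\tgene_b\trelation\tcip\tcalp\tclass\n")
                for p in pairs:
                    fh.write(
                        f"{p.gene_a}\t{p.gene_b}\t{p.relation}\t"
                        f"{p.cip:.3f}\t{p.calp:.3f}\t{p.divergence_class}\n"
                    )
            rerun = True
            record("homology", [homolog_path], None, skipped=False)

    def load_pairs() -> list[HomologPair]:
        pairs = []
        with open(homolog_path) as fh:
            next(fh)
            for line in fh:
                a, b, rel, cip, calp, cls = line.rstrip("\n").split("\t")
                pairs.append(
                    HomologPair(a, b, rel, float(cip), float(calp), cls)
                )
        return pairs

    # ---- synteny ----
    block_path = outdir / "blocks.tsv"
    syn_seed = _stage_seed(seed, "synteny")
    if "synteny" in enabled:
        if block_path.exists() and not rerun:
            record("synteny", [block_path], syn_seed, skipped=True)
        else:
            pairs = load_pairs()
            params = SyntenyParams(seed=syn_seed, **config.get("synteny", {}))
            blocks = detect_blocks(pairs, gene_index, params)
            chrom_bp: dict[str, int] = {}
            for g in gene_index.values():
                chrom_bp[g.genome_id] = max(
                    chrom_bp.get(g.genome_id, 0), 0
                )
            genome_bp = {
                gname: sum(
                    max(g.end for g in gs if g.chromosome_id == c)
                    for c in {g.chromosome_id for g in gs}
                )
                for gname, gs in genomes.items()
            }
            summaries = {}
            for gname in sorted(genomes):
                for hname in sorted(genomes):
                    if gname >= hname:
                        continue
                    sub = [
                        b for b in blocks
                        if {b.genome_a, b.genome_b} == {gname, hname}
                    ]
                    summaries[(gname, hname)] = coverage_summary(
                        sub, gname, genome_bp[gname]
                    )
            write_block_table(blocks, block_path, summaries)
            rerun = True
            record("synteny", [block_path], syn_seed, skipped=False)

    # ---- ancestor ----
    car_path = outdir / "cars.tsv"
    ancestor_json = outdir / "ancestor.json"
    if "ancestor" in enabled:
        if stage_done([car_path, ancestor_json]) and not rerun:
            record("ancestor", [car_path, ancestor_json], None, skipped=True)
        else:
            pairs = load_pairs()
            params = SyntenyParams(seed=syn_seed, **config.get("synteny", {}))
            blocks = detect_blocks(pairs, gene_index, params)
            reference = config.get("ancestor", {}).get(
                "reference", sorted(genomes)[0]
            )
            kary, _ = reconstruct_ancestor(
                blocks, gene_index, pairs, reference
            )
            from .formats import write_car_table

            write_car_table(kary.cars, car_path)
            with open(ancestor_json, "w") as fh:
                json.dump(
                    {
                        "name": kary.name,
                        "n_protochromosomes": kary.n_protochromosomes,
                        "total_protogenes": kary.total_protogenes,
                        "total_gene_space_bp": kary.total_gene_space_bp,
                    },
                    fh,
                    indent=1,
                )
            rerun = True
            record("ancestor", [car_path, ancestor_json], None, skipped=False)

    # ---- scenario ----
    scenario_json = outdir / "scenario.json"
    if "scenario" in enabled:
        if scenario_json.exists() and not rerun:
            record("scenario", [scenario_json], None, skipped=True)
        else:
            with open(sim_dir / "ground_truth.json") as fh:
                gt = json.load(fh)
            traces = {}
            for genome, events in gt["true_scenario"].items():
                n = gt["ancestor_n"]
                trace = [n]
                for e in events:
                    if e["kind"] == "WGD":
                        n *= 2
                    elif e["kind"] == "Cfis":
                        n += 1
                    elif e["kind"] in ("Cfus_TCF", "Cfus_CCF"):
                        n -= 1
                    trace.append(n)
                traces[genome] = {
                    "trace": trace,
                    "final_n": n,
                    "observed_n": gt["chromosome_counts"][genome],
                    "consistent": n == gt["chromosome_counts"][genome],
                }
            with open(scenario_json, "w") as fh:
                json.dump(traces, fh, indent=1)
            rerun = True
            record("scenario", [scenario_json], None, skipped=False)

    # ---- landscape ----
    landscape_path = outdir / "landscape.tsv"
    if "landscape" in enabled:
        if landscape_path.exists() and not rerun:
            record("landscape", [landscape_path], None, skipped=True)
        else:
            from .formats import read_gff3

            genes_by_genome, tes = read_gff3(sim_dir / "features.gff3")
            window_bp = config.get("landscape", {}).get("window_bp", 500_000)
            all_profiles = []
            for gname, gs in sorted(genes_by_genome.items()):
                chrom_ids = sorted({g.chromosome_id for g in gs})
                for chrom in chrom_ids:
                    cgenes = [g for g in gs if g.chromosome_id == chrom]
                    ctes = [
                        t for t in tes
                        if t.genome_id == gname and t.chromosome_id == chrom
                    ]
                    length = max(
                        [g.end for g in cgenes] + [t.end for t in ctes]
                    )
                    all_profiles.extend(
                        window_profiles(
                            cgenes, ctes, length, window_bp, chromosome_id=chrom
                        )
                    )
            write_profile_table(all_profiles, str(landscape_path))
            rerun = True
            record("landscape", [landscape_path], None, skipped=False)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
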