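"""End-to-end orchestration: simulate -> QC -> markers -> BSA -> regions.

Stages communicate only through files in standard formats (VCF / FASTQ /
TSV / BED), so each stage is independently runnable and testable.  A run is
described by one YAML config with stage toggles and parameters; a manifest
records inputs, the parameter hash, and SHA-256 checksums of every output,
so identical config + seed reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from cottonbsa import markers as mk
from cottonbsa import pheno, readqc, regions as rg, stats, vcfio
from cottonbsa.config import SimulationConfig
from cottonbsa.simulate import (
    select_bulks,
    simulate_pool_counts,
    simulate_population,
    write_fixtures,
)

STAGE_ORDER = ("simulate", "readqc", "markers", "bsa", "regions", "pheno")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_pipeline_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def validate_config(cfg: dict, out_dir: Path) -> None:
    """Fail fast, before any stage runs."""
    stages = cfg.get("stages", list(STAGE_ORDER))
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if "readqc" in stages and not cfg.get("readqc", {}).get("fastq"):
        raise ValueError("readqc stage enabled but no 'readqc.fastq' input given")
    sim_on = "simulate" in stages
    for stage in ("markers", "bsa"):
        if stage in stages and not sim_on and not cfg.get(stage, {}).get("input"):
            raise ValueError(f"{stage} stage enabled but no input configured")
    if "regions" in stages and not sim_on and "bsa" not in stages:
        raise ValueError("regions stage needs the bsa stage or a tracks input")
    for stage in stages:
        inp = cfg.get(stage, {}).get("input")
        if inp and not Path(inp).exists():
            raise ValueError(f"{stage} input {inp} does not exist")


def run_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Execute the enabled stages in fixed order and write a run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    validate_config(cfg, out_dir)
    stages = cfg.get("stages", list(STAGE_ORDER))
    seed = int(cfg.get("seed", 0))
    outputs: dict[str, str] = {}

    def emit(name: str, path: Path) -> None:
        outputs[name] = str(path.relative_to(out_dir))

    sim_paths = None
    try:
        if "simulate" in stages:
            sim_kwargs = dict(cfg.get("simulation", {}))
            sim_kwargs["seed"] = seed
            sim_config = SimulationConfig(**sim_kwargs)
            pop = simulate_population(sim_config)
            bulks = select_bulks(pop, sim_config.bulk_size)
            counts = simulate_pool_counts(pop, bulks, sim_config)
            sim_dir = out_dir / "simulate"
            sim_paths = write_fixtures(pop, counts, sim_dir)
            geno_path = sim_dir / "genotypes.tsv"
            _write_genotypes(pop, geno_path)
            sim_paths["genotypes"] = geno_path
            for name, p in sim_paths.items():
                emit(f"simulate/{name}", p)

        if "readqc" in stages:
            qc_cfg = cfg.get("readqc", {})
            rules = readqc.GBS_RULES if qc_cfg.get("mode", "GBS") == "GBS" else readqc.RESEQ_RULES
            reads = list(readqc.read_fastq(qc_cfg["fastq"]))
            kept, report = readqc.filter_reads(reads, rules)
            qc_dir = out_dir / "readqc"
            qc_dir.mkdir(exist_ok=True)
            readqc.write_fastq(kept, qc_dir / "filtered.fastq")
            pd.DataFrame(report.to_rows()).to_csv(
                qc_dir / "filter_report.tsv", sep="\t", index=False
            )
            emit("readqc/filtered", qc_dir / "filtered.fastq")
            emit("readqc/report", qc_dir / "filter_report.tsv")

        counts_path = (
            cfg.get("bsa", {}).get("input")
            or (sim_paths and sim_paths["counts"])
        )

        if "markers" in stages:
            geno_input = cfg.get("markers", {}).get("input") or (
                sim_paths and sim_paths["genotypes"]
            )
            mk_dir = out_dir / "markers"
            mk_dir.mkdir(exist_ok=True)
            _run_marker_stage(
                Path(geno_input),
                Path(counts_path),
                mk_dir,
                population_type=cfg.get("markers", {}).get("population_type", "F2"),
            )
            emit("markers/patterns", mk_dir / "pattern_counts.tsv")
            emit("markers/filter_report", mk_dir / "filter_report.tsv")

        tracks = None
        if "bsa" in stages:
            counts = vcfio.read_pool_counts_tsv(counts_path)
            tracks = stats.compute_tracks(
                counts, min_depth=cfg.get("bsa", {}).get("min_depth", stats.DEFAULT_MIN_DEPTH)
            )
            thresholds = stats.track_thresholds(tracks)
            bsa_dir = out_dir / "bsa"
            bsa_dir.mkdir(exist_ok=True)
            tracks.to_csv(bsa_dir / "tracks.tsv", sep="\t", index=False)
            pd.DataFrame(
                [
                    {
                        "statistic": t.statistic,
                        "median": t.median,
                        "sd": t.sd,
                        "cutoff": t.cutoff,
                    }
                    for t in thresholds.values()
                ]
            ).to_csv(bsa_dir / "thresholds.tsv", sep="\t", index=False)
            emit("bsa/tracks", bsa_dir / "tracks.tsv")
            emit("bsa/thresholds", bsa_dir / "thresholds.tsv")

        if "regions" in stages:
            if tracks is None:
                raise ValueError("regions stage requires bsa tracks")
            rcfg = cfg.get("regions", {})
            thresholds = stats.track_thresholds(tracks)
            delta_regions = rg.call_regions(
                tracks,
                thresholds["abs_delta_snp_index"],
                min_snps=rcfg.get("min_snps", rg.DEFAULT_MIN_SNPS),
                max_gap=rcfg.get("max_gap", rg.DEFAULT_MAX_GAP),
                source="delta",
            )
            ed_regions = rg.call_regions(
                tracks,
                thresholds["ED4"],
                min_snps=rcfg.get("min_snps", rg.DEFAULT_MIN_SNPS),
                max_gap=rcfg.get("max_gap", rg.DEFAULT_MAX_GAP),
                source="ED",
            )
            common = rg.count_snps_in_regions(
                tracks, rg.intersect_region_sets(delta_regions, ed_regions)
            )
            reg_dir = out_dir / "regions"
            reg_dir.mkdir(exist_ok=True)
            for name, rs in (
                ("delta", delta_regions),
                ("ed", ed_regions),
                ("common", common),
            ):
                rg.regions_to_frame(rs).to_csv(
                    reg_dir / f"{name}_regions.tsv", sep="\t", index=False
                )
                rg.regions_to_bed(rs).to_csv(
                    reg_dir / f"{name}_regions.bed", sep="\t", index=False, header=False
                )
                emit(f"regions/{name}", reg_dir / f"{name}_regions.tsv")
                emit(f"regions/{name}_bed", reg_dir / f"{name}_regions.bed")
            qtl_path = rcfg.get("qtl_intervals")
            if qtl_path:
                qtls = vcfio.read_qtl_intervals(qtl_path)
                reports = []
                for row in qtls.itertuples(index=False):
                    qtl = rg.GenomicInterval(str(row.chrom), int(row.start), int(row.end), source="QTL")
                    rep = rg.overlap_with_qtl(common, qtl)
                    rep.insert(0, "qtl", row.name)
                    reports.append(rep)
                pd.concat(reports, ignore_index=True).to_csv(
                    reg_dir / "qtl_overlap.tsv", sep="\t", index=False
                )
                emit("regions/qtl_overlap", reg_dir / "qtl_overlap.tsv")

        if "pheno" in stages:
            pheno_input = cfg.get("pheno", {}).get("input") or (
                sim_paths and sim_paths["phenotypes"]
            )
            table = vcfio.read_phenotypes_tsv(pheno_input)
            summary = pheno.summary_table({"population": table["NFFB"].to_numpy()})
            ph_dir = out_dir / "pheno"
            ph_dir.mkdir(exist_ok=True)
            summary.to_csv(ph_dir / "summary.tsv", sep="\t", index=False)
            emit("pheno/summary", ph_dir / "summary.tsv")
    except Exception as exc:
        manifest = {
            "status": "failed",
            "failed_stage": _current_stage(exc, stages),
            "error": str(exc),
            "partial_outputs": outputs,
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise

    param_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "status": "ok",
        "seed": seed,
        "stages": list(stages),
        "parameter_hash": param_hash,
        "config": cfg,
        "outputs": {
            name: {"path": rel, "sha256": _sha256(out_dir / rel)}
            for name, rel in outputs.items()
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _current_stage(exc: Exception, stages) -> str:
    # best effort: the stage name is carried in the exception message when known
    for s in stages:
        if s in str(exc):
            return s
    return "unknown"


def _write_genotypes(pop, path: Path) -> None:
    codes = pop.genotype_codes()
    ids = [f"{c}_{p}" for c, p in zip(pop.markers["chrom"], pop.markers["pos"])]
    df = pd.DataFrame(codes, columns=ids)
    df.insert(0, "plant_id", [f"plant_{i:04d}" for i in range(pop.n_plants)])
    df.to_csv(path, sep="\t", index=False)


def _run_marker_stage(
    geno_path: Path, counts_path: Path, out_dir: Path, population_type: str = "F2"
) -> mk.MarkerFilterReport:
    """Classify parental patterns and filter mapping markers on a genotype TSV."""
    geno = pd.read_csv(geno_path, sep="\t")
    counts = vcfio.read_pool_counts_tsv(counts_path)
    marker_ids = [c for c in geno.columns if c != "plant_id"]
    n_plants = len(geno)

    p1_calls, p2_calls, progeny_calls, patterns = [], [], [], []
    for j, mid in enumerate(marker_ids):
        ref, alt = counts.loc[j, "ref"], counts.loc[j, "alt"]
        p1, p2 = (ref, ref), (alt, alt)
        patterns.append(mk.classify_pattern(p1, p2))
        p1_calls.append(p1)
        p2_calls.append(p2)
        code_map = {"AA": (ref, ref), "Aa": tuple(sorted((ref, alt))), "aa": (alt, alt)}
        progeny_calls.append([code_map.get(c) for c in geno[mid]])

    pd.Series(patterns).value_counts().rename_axis("pattern").reset_index(
        name="n_markers"
    ).to_csv(out_dir / "pattern_counts.tsv", sep="\t", index=False)

    marker_table = pd.DataFrame(
        {
            "id": marker_ids,
            "chrom": counts["chrom"],
            "pos": counts["pos"],
        }
    )
    aaxbb = [j for j, p in enumerate(patterns) if p == "aaxbb"]
    report = mk.filter_aaxbb_markers(
        marker_table.iloc[aaxbb].reset_index(drop=True),
        [progeny_calls[j] for j in aaxbb],
        [p1_calls[j] for j in aaxbb],
        [p2_calls[j] for j in aaxbb],
        n_plants,
        population_type=population_type,
    )
    report.to_frame().to_csv(out_dir / "filter_report.tsv", sep="\t", index=False)
    return report
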