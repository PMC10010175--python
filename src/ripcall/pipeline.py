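"""End-to-end orchestration: simulate/load -> call -> subtract -> overlap ->
annotate -> enrich, driven by a YAML config, with a checksummed manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from . import __version__
from .annotation_metrics import (
    classify_targets,
    compare_region_distributions,
    coverage_track,
    gene_counts,
    region_counts,
    region_distribution,
    rpkm,
    sample_correlation,
)
from .enrichment import (
    gene_enrichment,
    gene_results_frame,
    gene_set_overlap,
    kmer_enrichment,
    motif_results_frame,
    extract_peak_sequences,
    read_term_map,
    term_enrichment,
    term_results_frame,
)
from .genome_model import (
    INTERGENIC,
    assign_reads_to_genes,
    read_alignments,
    read_annotation,
    write_bed,
)
from .peak_calling import call_peaks, replicate_overlap, subtract_input, write_peaks_bed
from .synthetic_data import (
    SimulationConfig,
    simulate_genome,
    simulate_reads,
    write_fasta,
    write_ground_truth,
    write_gtf,
)

logger = logging.getLogger(__name__)

#: width of the summit-centred window used for motif analysis (bp)
MOTIF_WINDOW = 100

_PARAM_DEFAULTS = {
    "n_iter": 500,
    "alpha": 0.05,
    "k": 4,
    "min_lfc": 1.0,
    "ignore_strand": False,
    "seed": 0,
}

_TOP_KEYS = {"simulation", "paths", "parameters", "output_dir"}
_PATH_KEYS = {"annotation", "genome", "ip_reads", "input_reads", "term_map"}


@dataclasses.dataclass
class PipelineConfig:
    output_dir: Path
    parameters: dict[str, Any]
    simulation: Optional[SimulationConfig] = None
    paths: Optional[dict[str, Any]] = None


def validate_config(source: str | Path | Mapping[str, Any]) -> PipelineConfig:
    """Normalise a YAML config file (or an equivalent dict), injecting defaults.

    Unknown keys are rejected; parameters are range-checked.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(_TOP_KEYS)}"
        )
    if "output_dir" not in raw:
        raise ValueError("config requires output_dir")

    params = dict(_PARAM_DEFAULTS)
    user_params = raw.get("parameters") or {}
    unknown = set(user_params) - set(_PARAM_DEFAULTS)
    if unknown:
        raise ValueError(
            f"unknown parameters {sorted(unknown)}; valid: {sorted(_PARAM_DEFAULTS)}"
        )
    params.update(user_params)
    if not 0 < params["alpha"] <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {params['alpha']}")
    if params["n_iter"] < 1:
        raise ValueError(f"n_iter must be >= 1, got {params['n_iter']}")
    if not 2 <= params["k"] <= 8:
        raise ValueError(f"k must lie in [2, 8], got {params['k']}")

    sim_cfg = None
    paths = None
    if "simulation" in raw and raw["simulation"] is not None:
        sim_block = dict(raw["simulation"])
        valid = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(sim_block) - valid
        if unknown:
            raise ValueError(
                f"unknown simulation keys {sorted(unknown)}; valid: {sorted(valid)}"
            )
        for tup_key in ("gene_length_range", "exons_per_gene_range", "exon_length_range", "expression_lognormal"):
            if tup_key in sim_block:
                sim_block[tup_key] = tuple(sim_block[tup_key])
        sim_block.setdefault("seed", params["seed"])
        sim_cfg = SimulationConfig(**sim_block)
        sim_cfg.validate()
    else:
        paths = dict(raw.get("paths") or {})
        unknown = set(paths) - _PATH_KEYS
        if unknown:
            raise ValueError(
                f"unknown path keys {sorted(unknown)}; valid: {sorted(_PATH_KEYS)}"
            )
        for role in ("annotation", "ip_reads", "input_reads"):
            if role not in paths:
                raise ValueError(f"config missing required role: {role}")
        for role in ("annotation", "genome", "term_map"):
            if role in paths and not Path(paths[role]).exists():
                raise ValueError(f"{role} path does not exist: {paths[role]}")
        for role in ("ip_reads", "input_reads"):
            entries = paths[role]
            if not isinstance(entries, list) or not entries:
                raise ValueError(f"{role} must be a non-empty list of read files")
            for p in entries:
                if not Path(p).exists():
                    raise ValueError(f"{role} path does not exist: {p}")
    return PipelineConfig(Path(raw["output_dir"]), params, sim_cfg, paths)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the full analysis; returns the run report (also written to disk).

    Stage order: (simulate) -> assign -> call peaks per sample/replicate ->
    input subtraction per replicate -> replicate overlap -> region and
    target metrics, RPKM/correlations, coverage tracks -> peak sequences ->
    k-mer motifs -> gene enrichment -> bound-vs-enriched overlap -> term
    enrichment.  On any stage failure a FAILED marker naming the stage is
    left in the output directory and the error re-raised.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger("ripcall").addHandler(handler)
    report: dict[str, Any] = {
        "version": __version__,
        "parameters": config.parameters,
        "stages": {},
    }
    stage = "setup"
    t_start = time.time()
    try:
        params = config.parameters
        seed = int(params["seed"])
        ignore_strand = bool(params["ignore_strand"])

        genome = None
        truth = None
        if config.simulation is not None:
            stage = "simulate"
            t0 = time.time()
            sim = config.simulation
            genome, annotation, truth = simulate_genome(sim)
            reads = simulate_reads(sim, annotation, truth)
            write_fasta(genome, out / "genome.fa")
            write_gtf(annotation, out / "annotation.gtf")
            write_ground_truth(truth, out / "ground_truth.tsv")
            replicates = sorted({rep for (_, rep) in reads})
            for (sample, rep), rs in reads.items():
                write_bed(rs, out / f"reads_{sample}_rep{rep}.bed")
            report["stages"][stage] = {
                "genes": len(annotation),
                "planted_sites": len(truth.planted_sites),
                "reads_per_sample": {f"{s}_rep{r}": len(v) for (s, r), v in reads.items()},
                "seconds": round(time.time() - t0, 2),
            }
        else:
            stage = "load"
            t0 = time.time()
            annotation = read_annotation(config.paths["annotation"])
            known = {g.chrom for g in annotation}
            reads = {}
            for role, sample in (("ip_reads", "IP"), ("input_reads", "input")):
                for i, path in enumerate(config.paths[role], start=1):
                    reads[(sample, i)] = read_alignments(path, sample, i, known)
            replicates = sorted({rep for (s, rep) in reads if s == "IP"})
            if config.paths.get("genome"):
                import pyfaidx

                genome = pyfaidx.Fasta(str(config.paths["genome"]))
            report["stages"][stage] = {
                "genes": len(annotation),
                "reads_per_sample": {f"{s}_rep{r}": len(v) for (s, r), v in reads.items()},
                "seconds": round(time.time() - t0, 2),
            }

        stage = "assign"
        t0 = time.time()
        buckets = {
            key: assign_reads_to_genes(rs, annotation, ignore_strand)
            for key, rs in reads.items()
        }
        report["stages"][stage] = {
            "assigned": {
                f"{s}_rep{r}": sum(len(v) for g, v in b.items() if g != INTERGENIC)
                for (s, r), b in buckets.items()
            },
            "intergenic": {
                f"{s}_rep{r}": len(b.get(INTERGENIC, ()))
                for (s, r), b in buckets.items()
            },
            "seconds": round(time.time() - t0, 2),
        }

        stage = "call_peaks"
        t0 = time.time()
        peaks = {}
        for (sample, rep), bucket in sorted(buckets.items()):
            peaks[(sample, rep)] = call_peaks(
                bucket,
                annotation,
                n_iter=int(params["n_iter"]),
                alpha=float(params["alpha"]),
                seed=seed,
                sample_id=sample,
                replicate_id=rep,
            )
            write_peaks_bed(peaks[(sample, rep)], out / f"peaks_{sample}_rep{rep}.bed")
        report["stages"][stage] = {
            "peaks": {f"{s}_rep{r}": len(v) for (s, r), v in peaks.items()},
            "seconds": round(time.time() - t0, 2),
        }

        stage = "subtract_input"
        t0 = time.time()
        final_by_rep = {}
        for rep in replicates:
            input_rep = rep if ("input", rep) in peaks else min(
                r for (s, r) in peaks if s == "input"
            )
            final_by_rep[rep] = subtract_input(
                peaks[("IP", rep)], peaks[("input", input_rep)]
            )
            write_peaks_bed(final_by_rep[rep], out / f"peaks_IP_rep{rep}.subtracted.bed")
        report["stages"][stage] = {
            "peaks": {f"rep{r}": len(v) for r, v in final_by_rep.items()},
            "seconds": round(time.time() - t0, 2),
        }

        stage = "replicate_overlap"
        t0 = time.time()
        if len(replicates) >= 2:
            overlapped = replicate_overlap(
                final_by_rep[replicates[0]], final_by_rep[replicates[1]]
            )
            for rep in replicates[2:]:
                overlapped = replicate_overlap(overlapped, final_by_rep[rep])
        else:
            overlapped = final_by_rep[replicates[0]]
        write_peaks_bed(overlapped, out / "peaks_overlap.bed")
        report["stages"][stage] = {
            "peaks": len(overlapped),
            "seconds": round(time.time() - t0, 2),
        }

        stage = "annotate"
        t0 = time.time()
        items = {f"{s}_rep{r}": rs for (s, r), rs in reads.items()}
        counts_df = region_counts(items, annotation, ignore_strand)
        region_df = counts_df.div(counts_df.sum(axis=1), axis=0)
        region_df.to_csv(out / "region_distribution_reads.tsv", sep="\t")
        ip_rows = [r for r in counts_df.index if r.startswith("IP")]
        input_rows = [r for r in counts_df.index if r.startswith("input")]
        if ip_rows and input_rows:
            comparison = compare_region_distributions(
                counts_df.loc[ip_rows].sum().to_dict(),
                counts_df.loc[input_rows].sum().to_dict(),
            )
            comparison.to_csv(
                out / "region_comparison.tsv", sep="\t", index=False, float_format="%.6g"
            )
        if overlapped:
            peak_region_df = region_distribution(
                {"overlap_peaks": overlapped}, annotation, ignore_strand
            )
            peak_region_df.to_csv(out / "region_distribution_peaks.tsv", sep="\t")
        targets = classify_targets(overlapped, annotation)
        targets.to_csv(out / "target_classes.tsv", sep="\t")
        table = gene_counts(
            {f"{s}_rep{r}": b for (s, r), b in buckets.items()}, annotation
        )
        table.counts.to_csv(out / "gene_counts.tsv", sep="\t")
        rpkm_df = rpkm(table)
        rpkm_df.to_csv(out / "rpkm.tsv", sep="\t", float_format="%.6g")
        correlations = {}
        cols = list(rpkm_df.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                try:
                    correlations[f"{a}|{b}"] = sample_correlation(rpkm_df, a, b)
                except ValueError:
                    correlations[f"{a}|{b}"] = None
        with open(out / "correlations.json", "w") as fh:
            json.dump(correlations, fh, indent=1, sort_keys=True)
        for (sample, rep), rs in sorted(reads.items()):
            track = coverage_track(rs, track_name=f"{sample}_rep{rep}")
            (out / f"coverage_{sample}_rep{rep}.bedgraph").write_text(track)
        report["stages"][stage] = {
            "region_fractions": region_df.round(4).to_dict(),
            "target_classes": targets["count"].to_dict(),
            "correlations": {
                k: (round(v, 4) if v is not None else None)
                for k, v in correlations.items()
            },
            "seconds": round(time.time() - t0, 2),
        }

        stage = "motifs"
        t0 = time.time()
        n_motifs = 0
        if genome is not None and overlapped:
            k = int(params["k"])
            usable = [p for p in overlapped if p.interval.length >= k]
            seqs = extract_peak_sequences(usable, genome, window=MOTIF_WINDOW)
            motifs = kmer_enrichment(seqs, k=k, seed=seed)
            motif_results_frame(motifs).to_csv(
                out / "motifs.tsv", sep="\t", index=False, float_format="%.6g"
            )
            n_motifs = sum(1 for m in motifs if m.q_value <= float(params["alpha"]))
            report["stages"][stage] = {
                "significant_kmers": n_motifs,
                "top_kmer": motifs[0].kmer if motifs else None,
                "seconds": round(time.time() - t0, 2),
            }
        else:
            report["stages"][stage] = {"skipped": "no genome sequence or no peaks"}

        stage = "gene_enrichment"
        t0 = time.time()
        rep0 = replicates[0]
        ip_col = f"IP_rep{rep0}"
        input_col = f"input_rep{rep0}"
        enr = gene_enrichment(
            table, ip_col, input_col,
            alpha=float(params["alpha"]), min_lfc=float(params["min_lfc"]),
        )
        gene_results_frame(enr).to_csv(
            out / "gene_enrichment.tsv", sep="\t", index=False, float_format="%.6g"
        )
        enriched_genes = {r.gene_id for r in enr if r.status == "enriched"}
        bound_genes = {p.gene_id for p in overlapped if p.gene_id != INTERGENIC}
        venn = gene_set_overlap(bound_genes, enriched_genes)
        with open(out / "bound_vs_enriched.json", "w") as fh:
            json.dump(
                {
                    "only_bound": venn.counts[0],
                    "common": venn.counts[1],
                    "only_enriched": venn.counts[2],
                    "common_genes": list(venn.common),
                },
                fh,
                indent=1,
            )
        report["stages"][stage] = {
            "tested": len(enr),
            "enriched": len(enriched_genes),
            "bound": len(bound_genes),
            "bound_and_enriched": venn.counts[1],
            "seconds": round(time.time() - t0, 2),
        }

        stage = "term_enrichment"
        if config.paths and config.paths.get("term_map"):
            t0 = time.time()
            term_map = read_term_map(config.paths["term_map"])
            universe = set(table.counts.index)
            query = bound_genes & universe
            terms = term_enrichment(query, term_map, universe)
            term_results_frame(terms).to_csv(
                out / "term_enrichment.tsv", sep="\t", index=False, float_format="%.6g"
            )
            report["stages"][stage] = {
                "terms_tested": len(terms),
                "seconds": round(time.time() - t0, 2),
            }
        else:
            report["stages"][stage] = {"skipped": "no term map supplied"}

        stage = "manifest"
        manifest = {}
        for path in sorted(out.iterdir()):
            if path.name in ("run.log", "manifest.json", "report.json"):
                continue
            manifest[path.name] = _sha256(path)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        report["wall_seconds"] = round(time.time() - t_start, 2)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        return report
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logging.getLogger("ripcall").removeHandler(handler)
        handler.close()
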