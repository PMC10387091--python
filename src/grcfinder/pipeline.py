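"""End-to-end orchestration on synthetic data, with a reproducibility manifest.

``run_pipeline`` wires the stages in dependency order on a simulated
dataset: genome + reads -> three-channel identification + barcode
expansion -> coverage normalisation, windowed copy number and corrected
GRC size -> gene annotation via the bundled translated scan.  Stage
outputs are plain-text files in the run directory; ``manifest.json``
records the config, a config hash and output checksums so an unchanged
config reproduces byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np

from . import coverage as cov
from . import genes as genes_mod
from . import identify as ident
from .config import RunConfig
from .io import CoverageTrack, write_bed, write_fasta, write_fastq_barcoded, write_paf
from .simulate import (
    SimConfig,
    assembly_alignments,
    reference_alignments,
    simulate_genome,
    simulate_reads,
)

logger = logging.getLogger("grcfinder")

__all__ = ["run_pipeline", "default_sim_config"]


def default_sim_config(seed: int = 0) -> SimConfig:
    """A small but structurally complete simulated study."""
    from .simulate import GeneModel, GrcSegment

    return SimConfig(
        seed=seed,
        a_genome={"A1": 120_000, "A2": 80_000},
        grc_segments=(
            GrcSegment("A1", 10_000, 40_000, divergence=0.01, copy_number=1),
            GrcSegment("A1", 60_000, 70_000, divergence=0.01, copy_number=3),
            GrcSegment("A2", 20_000, 30_000, divergence=0.005, copy_number=2,
                       copy_divergence=0.02),
        ),
        repeat_monomer="ACCCTAGGGTTTAGGGTTCAGGGTTAGGGTTAGGGTTAGG",
        repeat_array_length=5_000,
        gene_models=(
            GeneModel("geneA", "A2", ((40_002, 40_602), (41_000, 41_600)),
                      fraction_retained=1.0),
            GeneModel("geneB", "A2", ((50_001, 50_901),),
                      fraction_retained=0.5, premature_stop=True),
        ),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: RunConfig,
    outdir: Path,
    sim_config: Optional[SimConfig] = None,
) -> dict:
    """Run simulate -> identify -> coverage -> genes; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_config = sim_config or default_sim_config(config.seed)

    logger.info("simulating genome (seed=%d)", sim_config.seed)
    a_seqs, grc_seqs, truth = simulate_genome(sim_config)
    sim = simulate_reads(sim_config, truth)
    write_fasta(a_seqs, outdir / "a_genome.fasta")
    write_fasta(grc_seqs, outdir / "grc_assembly.fasta")
    for (tissue, sample), reads in sim.reads.items():
        write_fastq_barcoded(reads, outdir / f"{tissue}_{sample}.fastq")
    n_reads = {f"{t}/{s}": len(r) for (t, s), r in sim.reads.items()}
    logger.info("reads per sample: %s", n_reads)

    combined = truth.combined_sequences()
    lengths = {k: len(v) for k, v in combined.items()}

    # ---- identification (channels a+b, expansion) -------------------------
    testis_keys = sim.samples("testis")
    kidney_keys = sim.samples("kidney")
    t0 = testis_keys[0]
    k0 = kidney_keys[0]
    testis_depth = cov.depth_from_alignments(assembly_alignments(truth, sim, "testis"), lengths)
    kidney_depth = cov.depth_from_alignments(assembly_alignments(truth, sim, "kidney"), lengths)
    regions = []
    for name in sorted(grc_seqs):
        regions.extend(
            ident.germline_specific_regions(
                CoverageTrack(name, testis_depth[name], tissue="testis"),
                CoverageTrack(name, kidney_depth[name], tissue="kidney"),
                min_len=config.min_region_len,
            )
        )
    write_bed(regions, outdir / "germline_specific_regions.bed")
    logger.info("channel (a): %d regions", len(regions))

    selection = ident.reads_overlapping(
        regions, assembly_alignments(truth, sim, "testis"), min_overlap=config.min_overlap
    )
    logger.info("channel (a): %d barcodes", len(selection))

    # restrict each stream to its own sample
    by_sample = {
        key: (
            (r, a)
            for r, a in reference_alignments(truth, sim, key[0])
            if r.sample == key[1]
        )
        for key in testis_keys + kidney_keys
    }
    calls = ident.call_variants_pileup(by_sample, a_seqs, min_alt_reads=config.min_alt_reads)
    germ = ident.germline_specific_snps(calls, min_alt_reads=config.min_alt_reads)
    logger.info("channel (b): %d calls, %d germline-specific", len(calls), len(germ))
    kmers: set[str] = set()
    for call in germ:
        kmers |= ident.snp_to_kmers(call, a_seqs, k=config.kmer_k)
    kidney_reads = [r for key in kidney_keys for r in sim.reads[key]]
    surviving = ident.filter_kmers_against_soma(kmers, kidney_reads)
    logger.info("channel (b): %d kmers, %d survive soma filter", len(kmers), len(surviving))
    testis_reads = [r for key in testis_keys for r in sim.reads[key]]
    selection = selection.merge(ident.match_kmers(surviving, testis_reads))

    recruited = ident.expand_barcodes(selection, testis_reads)
    logger.info("expansion: %d barcodes -> %d reads", len(selection), len(recruited))
    write_fastq_barcoded(recruited, outdir / "grc_reads.fastq")
    with open(outdir / "barcodes.tsv", "w") as fh:
        fh.write("barcode\tchannels\n")
        for bc in sorted(selection.barcodes):
            fh.write(f"{bc}\t{','.join(sorted(selection.provenance[bc]))}\n")

    # ---- coverage & copy number ------------------------------------------
    grc_names = sorted(grc_seqs)
    a_names = sorted(a_seqs)
    size_rows = []
    window_rows = []
    for t_key, k_key in zip(testis_keys, kidney_keys):
        td = cov.depth_from_alignments(
            (p for p in assembly_alignments(truth, sim, "testis") if p[0].sample == t_key[1]),
            lengths,
        )
        kd = cov.depth_from_alignments(
            (p for p in assembly_alignments(truth, sim, "kidney") if p[0].sample == k_key[1]),
            lengths,
        )
        constants = cov.estimate_constants(
            {n: td[n] for n in grc_names},
            {n: kd[n] for n in grc_names},
            {n: td[n] for n in a_names},
            {n: kd[n] for n in a_names},
            sample=t_key[1],
        )
        windows = cov.copy_number_windows(
            {n: td[n] for n in grc_names},
            {n: kd[n] for n in grc_names},
            constants,
            window=config.window,
        )
        est = cov.grc_size_estimate(windows)
        logger.info(
            "%s: single-copy depth %.0f, ratio %.3f, corrected size %.0f bp (%.2fx)",
            t_key[1], constants.single_copy_grc_depth, constants.ratio,
            est.size_bp, est.inflation,
        )
        size_rows.append((t_key[1], constants.ratio, est.size_bp, est.assembly_bp, est.inflation))
        window_rows.extend(windows)
    with open(outdir / "copy_number_windows.tsv", "w") as fh:
        fh.write("scaffold\tstart\tend\tsample\tcopy_number\n")
        for w in window_rows:
            fh.write(
                f"{w.scaffold}\t{w.window.start}\t{w.window.end}\t{w.sample}\t{w.copy_number:.4f}\n"
            )
    with open(outdir / "grc_size.tsv", "w") as fh:
        fh.write("sample\tratio\tcorrected_bp\tassembly_bp\tinflation\n")
        for row in size_rows:
            fh.write("\t".join(f"{v:.4f}" if isinstance(v, float) else str(v) for v in row) + "\n")

    # ---- gene annotation ---------------------------------------------------
    cds = {}
    for gene in sim_config.gene_models:
        seq = "".join(
            truth.a_sequences[gene.scaffold][s:e] for s, e in sorted(gene.exons)
        )
        cds[gene.gene_id] = seq
    gene_rows = []
    if cds:
        hits = genes_mod.translated_search(cds, grc_seqs)
        exons = genes_mod.annotate_exons(hits, evalue_max=config.evalue_max)
        by_gene: dict[str, list] = {}
        for e in exons:
            by_gene.setdefault(e.gene_id, []).append(e)
        scaffold_cn = {
            name: float(np.mean([w.copy_number for w in window_rows if w.scaffold == name]))
            for name in grc_names
        }
        for gene_id, gexons in sorted(by_gene.items()):
            covered = sorted(iv for e in gexons for iv in [e.cds_interval])
            merged_bp = 0
            cur_s, cur_e = None, None
            for s, e in covered:
                if cur_s is None or s > cur_e:
                    if cur_s is not None:
                        merged_bp += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            if cur_s is not None:
                merged_bp += cur_e - cur_s
            raw = min(1.0, merged_bp / len(cds[gene_id]))
            comp = genes_mod.completeness(raw, 1.0, floor=config.completeness_floor)
            stops = sum(
                genes_mod.premature_stop(
                    grc_seqs[e.region.scaffold][e.region.start : e.region.end], e.strand
                )
                for e in gexons
                if len(e.region) >= 3
            )
            cn = genes_mod.gene_copy_number(gexons, scaffold_cn)
            gene_rows.append((gene_id, raw, comp, stops, cn))
            logger.info(
                "gene %s: raw %.2f, completeness %.2f, stop exons %d, cn %.2f",
                gene_id, raw, comp, stops, cn,
            )
    with open(outdir / "genes.tsv", "w") as fh:
        fh.write("gene\traw_prop_grc\tnorm_completeness\tpremature_stop_exons\tcopy_number\n")
        for g, raw, comp, stops, cn in gene_rows:
            fh.write(f"{g}\t{raw:.4f}\t{comp:.4f}\t{stops}\t{cn:.4f}\n")

    # ---- manifest ----------------------------------------------------------
    config_text = config.to_yaml()
    manifest = {
        "config": yaml_safe(config_text),
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "sim_seed": sim_config.seed,
        "reads_per_sample": n_reads,
        "n_regions": len(regions),
        "n_barcodes": len(selection),
        "n_recruited_reads": len(recruited),
        "outputs": {},
    }
    for path in sorted(outdir.glob("*")):
        if path.name != "manifest.json" and path.is_file():
            manifest["outputs"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def yaml_safe(text: str) -> dict:
    import yaml

    return yaml.safe_load(text)
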