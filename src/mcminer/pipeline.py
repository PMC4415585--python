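"""End-to-end pipeline: simulate -> profile -> bin -> complete -> recruit -> stats.

Composes the whole analysis on a synthetic enrichment experiment: generate a
natural community and stressed microcosms, emit assembly-like contigs from
each microcosm, bin contig sections by tetranucleotide distance, score bin
completeness, recruit natural and microcosm reads back to the contigs at an
identity threshold, and summarise per-bin proportions, enrichment factors
and coherence in one table. Every stage writes plain-text artifacts into the
run directory, stamped with the configuration hash.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binning, composition, io, markers, recruitment, stats, synthetic

log = logging.getLogger("mcminer")


@dataclass
class PipelineConfig:
    """Parameters of a full synthetic-experiment run (all stages)."""

    n_genomes: int = 5
    genome_length_bp: int = 120_000
    gc_low: float = 0.40
    gc_high: float = 0.68
    composition_divergence: float = 1.0
    n_marker_families: int = 40
    esc_labels: tuple[str, ...] = ("ethanol", "metals", "mercury")
    enriched_per_esc: int = 2
    multiplier_log10_range: tuple[float, float] = (2.0, 5.0)
    dna_decline_range: tuple[float, float] = (0.03, 0.6)
    n_reads_per_sample: int = 20_000
    read_length: float = 350.0
    read_length_sd: float = 30.0
    error_rate: float = 0.01
    coverage_per_abundance: float = 100.0
    assembly_floor_coverage: float = 5.0
    section_len: int = 20_000
    section_min_len: int = 10_000
    linkage: str = "average"
    identity_threshold: float = 0.97
    min_detect_reads: int = 10
    seed: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["esc_labels"] = list(self.esc_labels)
        d["multiplier_log10_range"] = list(self.multiplier_log10_range)
        d["dna_decline_range"] = list(self.dna_decline_range)
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    run_dir: Path
    genomes: dict[str, synthetic.AnnotatedGenome]
    summary: pd.DataFrame
    bin_evaluations: dict[str, binning.BinEvaluation] = field(default_factory=dict)


def _spread(lo: float, hi: float, n: int) -> list[float]:
    if n == 1:
        return [0.5 * (lo + hi)]
    return list(np.linspace(lo, hi, n))


def build_genomes(cfg: PipelineConfig) -> dict[str, synthetic.AnnotatedGenome]:
    gcs = _spread(cfg.gc_low, cfg.gc_high, cfg.n_genomes)
    genomes = {}
    for i in range(cfg.n_genomes):
        spec = synthetic.GenomeSpec(
            genome_id=f"G{i:02d}",
            length_bp=cfg.genome_length_bp,
            gc_target=float(gcs[i]),
            composition_divergence=cfg.composition_divergence,
            taxon_label=f"Genus{chr(65 + i % 26)}",
            n_marker_families=cfg.n_marker_families,
            seed=cfg.seed * 1000 + i,
        )
        genomes[spec.genome_id] = synthetic.generate_genome(spec)
    return genomes


def build_scenarios(cfg: PipelineConfig) -> list[synthetic.EnrichmentScenario]:
    rng = np.random.default_rng(cfg.seed + 17)
    ids = [f"G{i:02d}" for i in range(cfg.n_genomes)]
    lo, hi = cfg.multiplier_log10_range
    dlo, dhi = cfg.dna_decline_range
    scenarios = []
    for lab in cfg.esc_labels:
        chosen = rng.choice(cfg.n_genomes, size=cfg.enriched_per_esc, replace=False)
        mult = {ids[int(c)]: float(10 ** rng.uniform(lo, hi)) for c in chosen}
        scenarios.append(
            synthetic.EnrichmentScenario(
                esc_label=lab,
                multipliers=mult,
                dna_decline_factor=float(rng.uniform(dlo, dhi)),
            )
        )
    return scenarios


def run_pipeline(cfg: PipelineConfig, run_dir: str | Path) -> PipelineResult:
    """Run the full synthetic experiment and write artifacts under run_dir."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg_dict = cfg.to_dict()
    chash = io.config_hash(cfg_dict)
    io.write_config({**cfg_dict, "config_hash": chash}, run_dir / "config.yaml")
    stage = "simulate"
    try:
        genomes = build_genomes(cfg)
        io.write_fasta(
            [composition.SequenceRecord(g.genome_id, g.sequence) for g in genomes.values()],
            run_dir / "genomes.fasta",
        )
        natural = synthetic.generate_community(
            sorted(genomes), model="uniform", seed=cfg.seed, condition_label="natural"
        )
        scenarios = build_scenarios(cfg)
        natural_reads = synthetic.simulate_reads(
            natural, genomes, cfg.n_reads_per_sample,
            mean_length=cfg.read_length, length_sd=cfg.read_length_sd,
            error_rate=cfg.error_rate, seed=cfg.seed + 100, sample_id="natural",
        )
        limit_natural = recruitment.detection_limit_pct(
            len(natural_reads), cfg.min_detect_reads
        )
        log.info("natural detection limit: %.4g%%", limit_natural)

        marker_set = markers.default_marker_set(cfg.n_marker_families)
        summary_rows = []
        bin_evals: dict[str, binning.BinEvaluation] = {}

        for si, scen in enumerate(scenarios):
            stage = f"esc:{scen.esc_label}"
            microcosm = synthetic.apply_esc(natural, scen)
            micro_reads = synthetic.simulate_reads(
                microcosm, genomes, cfg.n_reads_per_sample,
                mean_length=cfg.read_length, length_sd=cfg.read_length_sd,
                error_rate=cfg.error_rate, seed=cfg.seed + 200 + si,
                sample_id=scen.esc_label,
            )
            contigs = synthetic.emit_contigs(
                microcosm, genomes,
                coverage_per_abundance=cfg.coverage_per_abundance,
                assembly_floor_coverage=cfg.assembly_floor_coverage,
                seed=cfg.seed + 300 + si,
            )
            if not contigs.contigs:
                continue
            io.write_fasta(
                [composition.SequenceRecord(c.contig_id, c.sequence) for c in contigs.contigs],
                run_dir / f"contigs_{scen.esc_label}.fasta",
            )
            # --- composition + binning on 10-20 kb sections
            frags, meta_rows, truth = [], [], {}
            for c in contigs.contigs:
                rec = composition.SequenceRecord(c.contig_id, c.sequence)
                for fr in composition.fragment_sections(
                    rec, cfg.section_len, cfg.section_min_len
                ):
                    frags.append(fr)
                    truth[fr.id] = c.source
                    meta_rows.append(
                        (fr.id, c.contig_id, c.mean_coverage,
                         composition.gc_content(fr.sequence), len(fr))
                    )
            frag_meta = pd.DataFrame(
                meta_rows, columns=["fragment_id", "contig_id", "coverage", "gc", "length"]
            ).set_index("fragment_id")
            profiles = [composition.tetra_profile(f.sequence) for f in frags]
            n_sources = len({c.source for c in contigs.contigs})
            if len(frags) < 2:
                continue
            dist = binning.pairwise_distance(profiles, ids=[f.id for f in frags])
            tree = binning.build_tree(dist, linkage=cfg.linkage)
            (run_dir / f"dendrogram_{scen.esc_label}.nwk").write_text(tree.to_newick() + "\n")
            bins = binning.extract_bins(tree, n_bins=n_sources)
            for b in bins:
                binning.bin_coherence(b, frag_meta)
            bin_evals[scen.esc_label] = binning.evaluate_binning(bins, truth)
            io.write_tsv(
                pd.DataFrame(
                    [(f, b.bin_id) for b in bins for f in b.fragment_ids],
                    columns=["fragment_id", "bin_id"],
                ),
                run_dir / f"bins_{scen.esc_label}.tsv",
                meta={"config_hash": chash},
            )
            # --- recruitment of microcosm + natural reads to contigs
            stage = f"recruit:{scen.esc_label}"
            structures = [
                composition.SequenceRecord(c.contig_id, c.sequence) for c in contigs.contigs
            ]
            policy = recruitment.MappingPolicy(identity_threshold=cfg.identity_threshold)
            micro_res = {
                r.structure_id: r
                for r in recruitment.map_reads(micro_reads, structures, policy)
            }
            nat_res = {
                r.structure_id: r
                for r in recruitment.map_reads(natural_reads, structures, policy)
            }
            limit_micro = recruitment.detection_limit_pct(
                len(micro_reads), cfg.min_detect_reads
            )
            log.info(
                "%s detection limit: %.4g%%", scen.esc_label, limit_micro
            )
            # --- per-bin summary (proportion, enrichment, completion, ...)
            for b in bins:
                contig_ids = b.contig_ids
                micro_pct = sum(micro_res[c].proportion_pct for c in contig_ids)
                nat_pct = sum(nat_res[c].proportion_pct for c in contig_ids)
                micro_reads_n = sum(micro_res[c].reads_mapped for c in contig_ids)
                nat_detected = sum(nat_res[c].reads_mapped for c in contig_ids) >= cfg.min_detect_reads
                if micro_pct > 0:
                    ef = recruitment.enrichment_factor(
                        micro_pct,
                        nat_pct if nat_detected else None,
                        limit_natural,
                        structure_id=b.bin_id,
                    )
                    factor, lower = ef.factor, ef.is_lower_bound
                else:
                    factor, lower = float("nan"), False
                tally = markers.tally_markers(contig_ids, contigs.annotations)
                comp = markers.completion_score(tally, marker_set, bin_id=b.bin_id)
                cat = markers.catalog_functions(b.bin_id, contig_ids, contigs.annotations)
                summary_rows.append(
                    {
                        "esc": scen.esc_label,
                        "bin_id": b.bin_id,
                        "n_contigs": len(contig_ids),
                        "microcosm_pct": round(micro_pct, 4),
                        "natural_pct": round(nat_pct, 4),
                        "enrichment_factor": factor,
                        "enrichment_lower_bound": lower,
                        "detected_microcosm": micro_reads_n >= cfg.min_detect_reads,
                        "coverage_mean": round(b.coverage_mean, 2),
                        "coverage_cv": round(b.coverage_cv, 4),
                        "gc_mean": round(b.gc_mean, 4),
                        "total_length_bp": b.total_length,
                        "trna_classes": markers.count_trna_classes(
                            contig_ids, contigs.annotations
                        ),
                        "completion": round(comp.fraction_present, 4),
                        "duplicated_markers": comp.duplicated_families,
                        "n_genes": cat.gene_count,
                        "n_functions": len(cat),
                    }
                )
        stage = "summarise"
        summary = pd.DataFrame(summary_rows)
        io.write_tsv(summary, run_dir / "summary.tsv", meta={"config_hash": chash})
        (run_dir / "manifest.json").write_text(
            json.dumps(
                {
                    "config_hash": chash,
                    "seed": cfg.seed,
                    "n_samples": len(cfg.esc_labels) + 1,
                    "stages": ["simulate", "profile", "bin", "complete", "recruit", "stats"],
                },
                indent=2,
            )
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return PipelineResult(
        config=cfg, run_dir=run_dir, genomes=genomes,
        summary=summary, bin_evaluations=bin_evals,
    )
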