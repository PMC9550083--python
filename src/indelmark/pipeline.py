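"""End-to-end marker-development pipeline: catalog → specific set → flanks →
primers → in-silico PCR → named markers → band matrix → distances/tree.

Every stage writes its TSV into the output directory and contributes a count
to the run report, mirroring the accounting a marker-development study keeps
(input InDels → group-common → specific >10 bp → designable → pairs found →
discriminating → named). Outputs are deterministic for a fixed config/seed
and contain no timestamps, so a rerun is byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import epcr_gel, genome_io, indel_catalog, marker_analysis, primer_engine
from .errors import DesignError, IndelMarkError
from .genome_io import ReferenceGenome, SampleCallSet
from .primer_engine import DesignConstraints
from .epcr_gel import GelModel


@dataclass
class PipelineConfig:
    """Everything a full run needs; paths may be None for in-memory runs."""

    reference_path: str | None = None
    vcf_dir: str | None = None
    groups_path: str | None = None        # TSV: sample_id, group
    gff3_path: str | None = None
    outdir: str = "indelmark_out"
    target_group: str = "javanica-like"
    min_indel_len: int = 10
    flank: int = 200
    require_homozygous: bool = False
    min_qual: float | None = None
    keep_only_discriminating: bool = True
    linked_gene_window: int = 50_000
    dropout_rate: float = 0.0
    seed: int = 0
    constraints: DesignConstraints = field(default_factory=DesignConstraints)
    gel: GelModel = field(default_factory=GelModel)


def load_callsets(config: PipelineConfig) -> list[SampleCallSet]:
    """Read per-sample VCFs named <sample_id>.vcf from ``vcf_dir`` with group
    labels from the groups TSV."""
    groups = pd.read_csv(config.groups_path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(groups.columns):
        raise DesignError("groups file needs sample_id and group columns")
    callsets = []
    for _, row in groups.iterrows():
        path = Path(config.vcf_dir) / f"{row['sample_id']}.vcf"
        if not path.exists():
            raise DesignError(f"missing VCF for sample {row['sample_id']}: {path}")
        callsets.append(
            genome_io.read_sample_vcf(path, row["sample_id"], row["group"],
                                      min_qual=config.min_qual)
        )
    return callsets


def run_pipeline(
    config: PipelineConfig,
    reference: ReferenceGenome | None = None,
    callsets: list[SampleCallSet] | None = None,
) -> dict:
    """Execute every stage; returns the run report (also written as JSON).

    ``reference``/``callsets`` may be passed in-memory (e.g. straight from the
    synthetic generator); otherwise they are loaded from the configured paths.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if reference is None:
            reference = genome_io.read_fasta(config.reference_path)
        if callsets is None:
            callsets = load_callsets(config)
        if not callsets:
            raise DesignError("no call sets: empty VCF directory?")
        group_labels = sorted({cs.group for cs in callsets})
        if len(group_labels) != 2:
            raise DesignError(f"expected two groups, got {group_labels}")
        if config.target_group not in group_labels:
            raise DesignError(
                f"target group {config.target_group!r} not among {group_labels}"
            )
        other_label = next(g for g in group_labels if g != config.target_group)
        by_group = {
            g: [cs for cs in callsets if cs.group == g] for g in group_labels
        }
        for g, members in by_group.items():
            if len(members) < 2:
                raise DesignError(f"group {g!r} has fewer than 2 samples")

        report: dict = {
            "n_samples": len(callsets),
            "n_input_indel_calls": sum(len(cs.variants) for cs in callsets),
            "n_snp_records_dropped": sum(cs.n_snps_dropped for cs in callsets),
        }

        stage = "catalog"
        cat_target = indel_catalog.group_common(
            by_group[config.target_group], reference,
            require_homozygous=config.require_homozygous)
        cat_other = indel_catalog.group_common(
            by_group[other_label], reference,
            require_homozygous=config.require_homozygous)
        report["n_group_common_target"] = len(cat_target.common)
        report["n_group_common_other"] = len(cat_other.common)
        for name, cat in (("target", cat_target), ("other", cat_other)):
            frame = pd.DataFrame(
                [
                    {"chromosome": v.chromosome, "position_1based": v.pos,
                     "ref": v.ref, "alt": v.alt, "indel_length": v.length}
                    for v in sorted(cat.common)
                ],
                columns=["chromosome", "position_1based", "ref", "alt",
                         "indel_length"],
            )
            frame.to_csv(out / f"catalog_{name}.tsv", sep="\t", index=False)

        stage = "specific"
        spec = indel_catalog.specific_indels(
            cat_target, cat_other, min_len=config.min_indel_len)
        report["n_specific_gt_minlen"] = len(spec.variants)
        spec.to_frame().to_csv(out / "specific_indels.tsv", sep="\t", index=False)

        stage = "density"
        dens = indel_catalog.density_table(cat_target.common, reference.lengths)
        dens.check()
        per_chrom = dens.per_chromosome.copy()
        per_chrom["density_per_mb"] = per_chrom["density_per_mb"].round(2)
        per_chrom.to_csv(out / "density_per_chromosome.tsv", sep="\t", index=False)
        dens.windows.to_csv(out / "density_windows.tsv", sep="\t", index=False)
        indel_catalog.between_group_diff(
            cat_target, cat_other, reference.chromosomes
        ).to_csv(out / "between_group_diff.tsv", sep="\t", index=False)

        stage = "design"
        panel = primer_engine.design_panel(
            reference, spec.variants, config.constraints, flank=config.flank)
        report["n_templates_designable"] = sum(
            1 for t, _ in panel if t.designable)
        report["n_pairs_designed"] = sum(1 for _, p in panel if p is not None)

        stage = "epcr"
        carried = {
            cs.sample_id: {
                indel_catalog.normalize(c.chrom, c.pos, c.ref, c.alt,
                                        reference).key
                for c in cs.variants
            }
            for cs in callsets
        }
        groups_map = {cs.sample_id: cs.group for cs in callsets}
        records = epcr_gel.evaluate_markers(
            [(t, p) for t, p in panel if p is not None],
            carried, groups_map, gel=config.gel)
        counts = {c: 0 for c in (epcr_gel.FAILED, epcr_gel.MONOMORPHIC,
                                 epcr_gel.NONDISCRIMINATING,
                                 epcr_gel.DISCRIMINATING_BI,
                                 epcr_gel.DISCRIMINATING_MULTI)}
        for r in records:
            counts[r.classification] += 1
        report["classification_counts"] = counts

        stage = "naming"
        if config.keep_only_discriminating:
            kept = [r for r in records
                    if r.classification in epcr_gel.DISCRIMINATING]
        else:
            kept = records
        named = epcr_gel.assign_ij_names(kept, reference.chromosomes)
        report["n_named_markers"] = len(named)

        if config.gff3_path:
            genes = genome_io.read_gff3_genes(config.gff3_path)
            epcr_gel.annotate_linked_genes(named, genes,
                                           window=config.linked_gene_window)

        if named:
            marker_frame = pd.DataFrame(
                [
                    {
                        "marker_name": r.ij_name,
                        "chromosome": r.variant.chromosome,
                        "position_1based": r.variant.pos,
                        "indel_length": r.variant.length,
                        "forward_primer": r.pair.forward.sequence,
                        "reverse_primer": r.pair.reverse.sequence,
                        "product_size_ref": r.size_ref,
                        "product_size_alt": r.size_alt,
                        "tm_f": r.pair.forward.tm,
                        "tm_r": r.pair.reverse.tm,
                        "classification": r.classification,
                        "linked_genes": ";".join(r.linked_genes),
                    }
                    for r in named
                ]
            )
            genome_io.write_marker_table(marker_frame, out / "markers.tsv")
            map_table, map_counts = epcr_gel.physical_map(
                named, reference.lengths)
            map_table.to_csv(out / "physical_map.tsv", sep="\t", index=False)
            map_counts.rename_axis("chromosome").to_csv(
                out / "physical_map_counts.tsv", sep="\t")

        stage = "apply"
        if named:
            from .synthetic_data import simulate_band_matrix

            bm = simulate_band_matrix(
                [r.variant for r in named], callsets,
                marker_names=[r.ij_name for r in named],
                dropout_rate=config.dropout_rate, seed=config.seed)
            marker_analysis.write_band_matrix(bm, out / "band_matrix.tsv")
            disc_report, disc_summary = marker_analysis.discrimination_report(bm)
            disc_report.to_csv(out / "discrimination_report.tsv",
                               sep="\t", index=False)
            report["band_matrix_summary"] = disc_summary
            dist = marker_analysis.genetic_distance(bm)
            dist.round(6).to_csv(out / "genetic_distance.tsv", sep="\t")
            if not dist.isna().to_numpy().any():
                tree = marker_analysis.upgma_tree(dist)
                (out / "upgma.nwk").write_text(tree + "\n")
                within, between = marker_analysis.mean_group_distances(
                    dist, bm.groups)
                report["mean_within_group_distance"] = within
                report["mean_between_group_distance"] = between
    except IndelMarkError as exc:
        raise DesignError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
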