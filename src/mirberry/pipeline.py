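"""End-to-end orchestration: clean -> collapse -> classify -> novel ->
targets -> enrich, with table-style reports and a JSON run summary.

Every stage writes its report into the run directory; the summary JSON
collects every printed count so downstream checks (and re-runs) can diff a
whole run in one file.  Identical inputs and seed give byte-identical
summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import enrich as enrich_mod
from . import novelminer, preprocess, tagspace, targets
from .annotate import (
    CATEGORY_LABELS as TAG_LABELS,
    CascadeParams,
    category_percentages,
    classify_all,
    family_statistics,
)
from .io import ensure_dir, write_fasta, write_tsv
from .novelminer import NovelParams
from .preprocess import AccountingReport, PreprocessParams
from .targets import TargetParams

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    fastq: str
    refs_dir: str
    outdir: str
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    cascade: CascadeParams = field(default_factory=CascadeParams)
    novel: NovelParams = field(default_factory=NovelParams)
    targets: TargetParams = field(default_factory=TargetParams)
    enrich_alpha: float = 0.05
    joint_go_namespaces: bool = False
    force: bool = False

    def validate(self) -> None:
        for path in (self.fastq, self.refs_dir):
            if not Path(path).exists():
                raise PipelineError(f"input path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(
            fastq=data["fastq"], refs_dir=data["refs_dir"], outdir=data["outdir"]
        )
        for section, target in (
            ("preprocess", cfg.preprocess),
            ("cascade", cfg.cascade),
            ("novel", cfg.novel),
            ("targets", cfg.targets),
        ):
            for key, value in (data.get(section) or {}).items():
                if not hasattr(target, key):
                    raise PipelineError(f"unknown {section} parameter {key!r}")
                setattr(target, key, value)
        cfg.enrich_alpha = float(data.get("enrich_alpha", 0.05))
        cfg.joint_go_namespaces = bool(data.get("joint_go_namespaces", False))
        return cfg


def _round6(x: float) -> float:
    return float(f"{x:.6g}")


def render_accounting(report: AccountingReport) -> list[tuple[str, int, str]]:
    """Accounting rows with 3-decimal percentages, partition asserted."""
    removed = sum(getattr(report, c) for c in preprocess.REMOVAL_CATEGORIES)
    if (
        report.high_quality < 0
        or report.clean < 0
        or report.low_quality + removed + report.clean != report.raw
    ):
        raise PipelineError("accounting categories do not partition the raw total")
    return [
        (label, count, "" if pct is None else f"{pct:.3f}")
        for label, count, pct in report.as_rows()
    ]


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the JSON-serializable run summary."""
    config.validate()
    from .io import load_references

    outdir = ensure_dir(config.outdir)
    summary_path = outdir / "summary.json"
    if summary_path.exists() and not config.force:
        raise PipelineError(
            f"{summary_path} exists; pass force=True (or --force) to overwrite"
        )
    refs = load_references(config.refs_dir)
    summary: dict = {}

    logger.info("stage clean: %s", config.fastq)
    clean_reads, report = preprocess.run_preprocess(config.fastq, config.preprocess)
    write_tsv(render_accounting(report), outdir / "accounting.tsv",
              header=("type", "count", "percent"))
    write_fasta(clean_reads, outdir / "clean.fasta")
    summary["accounting"] = {k: v for k, v in report.counts().items()}
    summary["accounting_percent"] = {
        k: report.percentage(v) for k, v in report.counts().items() if k != "raw"
    }
    logger.info("clean reads: %d / %d raw", report.clean, report.raw)

    logger.info("stage collapse")
    tags = tagspace.collapse(seq for _, seq in clean_reads)
    if sum(t.count for t in tags) != len(clean_reads):
        raise PipelineError("tag counts do not conserve the clean-read total")
    write_fasta(
        [(f"tag_{i + 1}_x{t.count}", t.sequence) for i, t in enumerate(tags)],
        outdir / "tags.fasta",
    )
    dist_reads = tagspace.size_distribution(tags, "reads") if tags else {}
    dist_unique = tagspace.size_distribution(tags, "unique") if tags else {}
    write_tsv(
        [
            (l, f"{dist_reads.get(l, 0.0):.3f}", f"{dist_unique.get(l, 0.0):.3f}")
            for l in sorted(set(dist_reads) | set(dist_unique))
        ],
        outdir / "size_distribution.tsv",
        header=("length_nt", "percent_reads", "percent_unique_tags"),
    )
    spectrum = tagspace.abundance_spectrum(tags)
    write_tsv(
        [(label, n, f"{pct:.3f}") for label, (n, pct) in spectrum.items()],
        outdir / "abundance_spectrum.tsv",
        header=("count_class", "unique_tags", "percent"),
    )
    summary["unique_tags"] = len(tags)
    summary["size_distribution_reads"] = {
        str(k): _round6(v) for k, v in dist_reads.items()
    }
    summary["abundance_spectrum"] = {
        label: [n, _round6(pct)] for label, (n, pct) in spectrum.items()
    }

    logger.info("stage classify")
    annotations, table2 = classify_all(tags, refs, config.cascade)
    pct = category_percentages(table2)
    write_tsv(
        [("All unique tags", len(tags), "")]
        + [
            (TAG_LABELS[cat], table2[cat], f"{pct[cat]:.3f}")
            for cat in table2
        ],
        outdir / "tag_categories.tsv",
        header=("category", "count", "percent"),
    )
    write_tsv(
        [
            (
                a.tag.sequence,
                a.category,
                a.reference_id,
                a.mismatches,
                a.family,
                a.tag.count,
            )
            for a in annotations
        ],
        outdir / "annotations.tsv",
        header=("tag", "category", "reference_id", "mismatches", "family", "reads"),
    )
    summary["tag_categories"] = dict(table2)
    summary["tag_category_percent"] = {k: _round6(v) for k, v in pct.items()}

    conserved = [a for a in annotations if a.category == "conserved-miRNA"]
    families, r, p = family_statistics(annotations)
    write_tsv(
        [(f.family, f.members, f.reads) for f in families],
        outdir / "family_statistics.tsv",
        header=("family", "members", "reads"),
    )
    summary["conserved"] = {
        "unique_tags": len(conserved),
        "reads": int(sum(a.tag.count for a in conserved)),
        "families": len(families),
        "member_read_pearson_r": None if r is None else _round6(r),
        "member_read_pearson_p": None if p is None else _round6(p),
    }
    if conserved:
        comp = tagspace.nucleotide_composition([a.tag.sequence for a in conserved])
        write_tsv(
            [
                (i + 1, *(f"{row[b]:.3f}" for b in "ACGU"))
                for i, row in enumerate(comp.positional)
            ],
            outdir / "conserved_composition.tsv",
            header=("position", "A", "C", "G", "U"),
        )
        summary["conserved"]["first_base_percent"] = {
            b: _round6(v) for b, v in comp.positional[0].items()
        }
        summary["conserved"]["overall_base_percent"] = {
            b: _round6(v) for b, v in comp.overall.items()
        }

    logger.info("stage novel")
    candidates, orf_map = novelminer.mine_novel(
        annotations, refs.ests, refs.cross_species, config.novel
    )
    write_tsv(
        [
            (
                c.mature.sequence,
                c.mature.count,
                c.est_id,
                c.strand,
                c.window_start,
                c.window_end,
                None if c.structure is None else f"{c.structure.mfe:.2f}",
                None if c.metrics is None else f"{c.metrics.gc:.4f}",
                None if c.metrics is None else f"{c.metrics.amfe:.3f}",
                None if c.metrics is None else f"{c.metrics.mfei:.4f}",
                None if c.duplex is None else c.duplex.max_bulge,
                None if c.duplex is None else c.duplex.max_adjacent_mismatches,
                *(c.rules.get(f"r{i}") for i in range(1, 8)),
                c.cross_species_unique,
                c.accepted,
            )
            for c in candidates
        ],
        outdir / "novel_candidates.tsv",
        header=(
            "mature", "reads", "est", "strand", "window_start", "window_end",
            "mfe", "gc", "amfe", "mfei", "max_bulge", "max_adjacent_mm",
            "r1", "r2", "r3", "r4", "r5", "r6", "r7",
            "cross_species_unique", "accepted",
        ),
    )
    accepted = [c for c in candidates if c.accepted]
    fasta_entries = []
    structure_lines = []
    for i, c in enumerate(accepted):
        stem = f"novel_{i + 1}"
        fasta_entries.append((f"{stem}_mature", c.mature.sequence))
        if c.star_sequence:
            fasta_entries.append((f"{stem}_star", c.star_sequence))
        if c.structure is not None:
            fasta_entries.append((f"{stem}_precursor", c.structure.sequence))
            structure_lines.append(
                f">{stem}\n{c.structure.sequence}\n"
                f"{c.structure.pairing} ({c.structure.mfe:.2f})\n"
            )
    write_fasta(fasta_entries, outdir / "novel_accepted.fasta")
    (outdir / "novel_structures.txt").write_text("".join(structure_lines))
    orf_rows = []
    for mature_seq in sorted(orf_map):
        for o in orf_map[mature_seq]:
            orf_rows.append((mature_seq, o.frame, o.start, o.end, o.peptide_length))
    write_tsv(orf_rows, outdir / "mipep_orfs.tsv",
              header=("mature", "frame", "start", "end", "peptide_aa"))
    mfeis = sorted(c.metrics.mfei for c in accepted if c.metrics is not None)
    summary["novel"] = {
        "candidates": len(candidates),
        "accepted": len(accepted),
        "mfei_min": _round6(mfeis[0]) if mfeis else None,
        "mfei_max": _round6(mfeis[-1]) if mfeis else None,
        "mfei_mean": _round6(sum(mfeis) / len(mfeis)) if mfeis else None,
        "with_mipep_orf": sum(1 for v in orf_map.values() if v),
    }

    logger.info("stage targets")
    # one representative tag per matched known miRNA: fewest mismatches,
    # then most reads
    best_tag: dict[str, tuple] = {}
    for a in conserved:
        rank = (a.mismatches, -a.tag.count, a.tag.sequence)
        if a.reference_id not in best_tag or rank < best_tag[a.reference_id]:
            best_tag[a.reference_id] = rank
    mirna_set = {rid: rank[2] for rid, rank in best_tag.items()}
    for i, c in enumerate(accepted):
        mirna_set[f"novel_{i + 1}"] = c.mature.sequence
    hits = targets.predict_targets(mirna_set, refs.cdna, config.targets)
    write_tsv(
        [
            (
                h.mirna_id, h.transcript_id, h.start, h.end,
                f"{h.expectation:.2f}",
                None if h.upe is None else f"{h.upe:.2f}", h.mode,
            )
            for h in hits
        ],
        outdir / "target_hits.tsv",
        header=("mirna", "transcript", "start", "end", "expectation", "upe", "mode"),
    )
    summary["targets"] = {
        "hits": len(hits),
        "target_genes": len({h.transcript_id for h in hits}),
        "cleavage": sum(1 for h in hits if h.mode == "cleavage"),
        "translational_repression": sum(
            1 for h in hits if h.mode == "translational-repression"
        ),
    }

    logger.info("stage enrich")
    target_genes = sorted({h.transcript_id for h in hits})
    results = enrich_mod.enrich(
        target_genes, refs.go_table, refs.go_namespaces,
        alpha=config.enrich_alpha, joint_namespaces=config.joint_go_namespaces,
    )
    write_tsv(
        [
            (
                r.go_id, r.namespace, r.k, r.m, r.n, r.N,
                f"{r.pvalue:.6g}", f"{r.adjusted_pvalue:.6g}", r.enriched,
            )
            for r in results
        ],
        outdir / "enrichment.tsv",
        header=("go_id", "namespace", "k", "m", "n", "N", "p", "adjusted_p", "enriched"),
    )
    summary["enrichment"] = {
        "terms_tested": len(results),
        "enriched": sorted(r.go_id for r in results if r.enriched),
    }

    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    logger.info("run complete: %s", summary_path)
    return summary
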