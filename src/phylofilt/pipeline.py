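"""One-command orchestration: config-driven runs with provenance.

A run config (YAML) names the inputs per fraction and the parameter blocks
for QC, filtering, annotation and the cross-fraction comparison.  Each
stage writes plain-text outputs in the formats of :mod:`phylofilt.io`, so
any stage can equally be driven by real external-tool outputs (QIIME /
Swarm / BLAST tabular) instead of the built-in stand-ins.  Identical
config + inputs yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as pio
from .annotate import annotate, superkingdom_profile, top_hit_per_query
from .filters import (
    per_replicate_retention,
    retention_report,
    run_cascade,
)
from .fractions import compare_fractions
from .model import (
    OtuTable,
    StringencyLevel,
    UNKNOWN_LABEL,
    ValidationError,
    standard_levels,
)
from .annotate import TaxonomyMap
from .phylotypes import aggregate_to_phylotypes
from .qc import QcParams, qc_fastq

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``raw`` is the parsed YAML mapping; input paths are checked for
    existence at validation time so a typo aborts before any output is
    written.
    """

    raw: dict
    output_dir: Path
    seed: int = 0
    source: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        out = Path(raw.get("output_dir", "phylofilt_out"))
        cfg = cls(raw=raw, output_dir=out, seed=int(raw.get("seed", 0)), source=path)
        cfg.validate()
        return cfg

    def _input_paths(self) -> list[Path]:
        paths: list[Path] = []

        def walk(node):
            if isinstance(node, dict):
                for key, value in node.items():
                    if key in {"fastq", "table", "taxonomy", "hits", "lineages"} and isinstance(
                        value, str
                    ):
                        paths.append(Path(value))
                    else:
                        walk(value)
            elif isinstance(node, list):
                for item in node:
                    walk(item)

        walk(self.raw)
        return paths

    def validate(self) -> None:
        for p in self._input_paths():
            if not p.exists():
                raise ValidationError(f"input path does not exist: {p}")

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Paths of everything one run produced, plus stage tallies."""

    output_dir: Path
    outputs: dict[str, str] = field(default_factory=dict)
    tallies: dict[str, dict] = field(default_factory=dict)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def _load_otus(block: dict) -> OtuTable:
    return pio.read_otu_table(block["table"], block.get("taxonomy"))


def _krona_entries(table: OtuTable):
    pt = aggregate_to_phylotypes(table)
    for plabel in pt.counts.index:
        yield int(pt.counts.loc[plabel].sum()), pt.lineages[plabel]


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the configured stages and write the report bundle.

    Stages (each optional in the config): ``qc`` — FASTQ trimming and
    quality filtering; ``amplicon`` — per-fraction stringency cascade with
    retention report, per-replicate retention and Krona export;
    ``metagenome`` — BLAST top-hit annotation, superkingdom profile and
    Krona export; ``compare_fractions`` — genus-or-fallback presence–
    absence between the metagenome and the amplicon fractions at every
    level.  A provenance block (config hash, seed, stage tallies) is
    always written last.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(output_dir=out)
    raw = config.raw

    # --- QC ---------------------------------------------------------------
    if "qc" in raw:
        block = raw["qc"]
        params = QcParams(
            trim_head=int(block.get("trim_head", 10)),
            trim_tail=int(block.get("trim_tail", 10)),
            min_fraction=float(block.get("min_fraction", 0.95)),
            q_threshold=int(block.get("q_threshold", 20)),
        )
        kept, stats = qc_fastq(pio.parse_fastq(block["fastq"]), params)
        kept_path = out / "qc_kept.fastq"
        pio.write_fastq(kept, kept_path)
        _write_json(out / "qc_stats.json", stats.__dict__)
        bundle.outputs["qc_kept"] = str(kept_path)
        bundle.tallies["qc"] = dict(stats.__dict__)

    # --- amplicon cascade ---------------------------------------------------
    amplicon_otus: dict[str, OtuTable] = {}
    for fraction, block in (raw.get("amplicon") or {}).items():
        otus = _load_otus(block)
        amplicon_otus[fraction] = otus
        cascade = run_cascade(otus)
        report = retention_report(cascade)
        report_path = out / f"filter_report_{fraction}.tsv"
        report.as_frame().to_csv(report_path, sep="\t")
        per_rep: dict[str, dict] = {}
        t1 = StringencyLevel.from_name("T1", otus.n_replicates)
        rep_stats, mean_pct = per_replicate_retention(otus, t1)
        per_rep["T1"] = {
            "replicates": {r: list(v) for r, v in rep_stats.items()},
            "mean_pct": mean_pct,
        }
        _write_json(
            out / f"filter_summary_{fraction}.json",
            {
                "levels": {n: s.__dict__ for n, s in report.levels.items()},
                "per_replicate": per_rep,
            },
        )
        for name, ptab in cascade.phylotype_tables.items():
            pio.write_phylotype_table(ptab, out / f"phylotypes_{fraction}_{name}.tsv")
        (out / f"krona_{fraction}.txt").write_text(
            pio.write_krona_text(list(_krona_entries(otus)))
        )
        bundle.outputs[f"filter_report_{fraction}"] = str(report_path)
        bundle.tallies[f"amplicon_{fraction}"] = {
            n: s.phylotype_count for n, s in report.levels.items()
        }

    # --- metagenome annotation ---------------------------------------------
    annotation = None
    if "metagenome" in raw:
        block = raw["metagenome"]
        gated = pio.parse_blast_tabular(
            block["hits"], float(block.get("max_evalue", 1e-5))
        )
        taxmap = TaxonomyMap(
            pio.read_lineage_map(block["taxonomy"]), source=block.get("source", "user")
        )
        tophits = top_hit_per_query(gated.hits)
        annotation = annotate(tophits, taxmap)
        profile = superkingdom_profile(annotation)
        _write_json(out / "superkingdom_profile.json", profile)
        ann_path = out / "annotation.tsv"
        with open(ann_path, "w") as fh:
            fh.write("query_id\tsubject_id\tbit_score\tevalue\tlineage\n")
            for qid, (lin, hit) in annotation.assignments.items():
                fh.write(
                    f"{qid}\t{hit.subject_id}\t{hit.bit_score}\t{hit.evalue}\t"
                    f"{lin.to_string() if not lin.is_empty else UNKNOWN_LABEL}\n"
                )
        lineage_counts: dict[tuple, int] = {}
        for lin, _hit in annotation.assignments.values():
            lineage_counts[lin.ranks] = lineage_counts.get(lin.ranks, 0) + 1
        from .model import Lineage

        (out / "krona_metagenome.txt").write_text(
            pio.write_krona_text(
                [(c, Lineage(r)) for r, c in sorted(lineage_counts.items())]
            )
        )
        bundle.outputs["annotation"] = str(ann_path)
        bundle.tallies["metagenome"] = {
            "queries_annotated": len(annotation),
            "hits_discarded_by_evalue": gated.n_discarded,
            "unknown_subject": annotation.n_unknown_subject,
        }

    # --- fraction comparison ------------------------------------------------
    if "compare_fractions" in raw:
        block = raw["compare_fractions"] or {}
        if annotation is None:
            raise ValidationError("compare_fractions requires a metagenome block")
        for fraction in ("prokaryote", "eukaryote"):
            if fraction not in amplicon_otus:
                raise ValidationError(
                    f"compare_fractions requires amplicon fraction {fraction!r}"
                )
        level_names = block.get("levels") or list(standard_levels())
        regions_summary: dict[str, dict] = {}
        n_reps = amplicon_otus["prokaryote"].n_replicates
        for name in level_names:
            level = StringencyLevel.from_name(name, n_reps)
            report = compare_fractions(
                annotation,
                amplicon_otus["prokaryote"],
                amplicon_otus["eukaryote"],
                level,
            )
            regions_summary[name] = {
                "regions": {
                    "+".join(sorted(k)): len(v) for k, v in report.venn.regions.items()
                },
                "pairwise_shared_pct": {
                    f"{a}|{b}": rec.shared_pct for (a, b), rec in report.pairwise.items()
                },
            }
        frac_path = out / "fraction_comparison.json"
        _write_json(frac_path, regions_summary)
        bundle.outputs["fraction_comparison"] = str(frac_path)
        bundle.tallies["compare_fractions"] = {
            name: sum(d["regions"].values()) for name, d in regions_summary.items()
        }

    _write_json(
        out / "provenance.json",
        {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stages": bundle.tallies,
        },
    )
    bundle.outputs["provenance"] = str(out / "provenance.json")
    return bundle
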