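"""Pipeline orchestration: quantify -> DE -> classify -> associate -> report.

Each stage writes its table under the output directory; ``manifest.json``
records the files, the configuration hash, and package versions so a run
can be audited.  Reruns of the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from . import association, diffexpr, em, intervals, report
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class PipelineConfig:
    """Inputs, thresholds, and switches for one pipeline run."""

    output_dir: str = "telex_out"
    genes_gtf: Optional[str] = None
    tes_bed: Optional[str] = None
    counts: Optional[str] = None
    compat: Optional[str] = None
    gene_counts: Optional[str] = None
    sample_sheet: Optional[str] = None
    control_label: str = "control"
    lfc_threshold: float = 1.5
    alpha_de: float = 0.05
    alpha_pair: float = 0.05
    raw_counts: bool = False
    pooled_dispersion: bool = False
    strict_te_classes: bool = False
    synthetic: bool = False
    synthetic_n_genes: int = 120
    synthetic_n_te: int = 240
    seed: int = 1
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0:
            raise ValueError("lfc_threshold must be positive")
        for name in ("alpha_de", "alpha_pair"):
            a = getattr(self, name)
            if not 0 < a <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def analysis_params(self) -> dict:
        """Config fields that affect analysis results (where the outputs
        are written and how chatty the log is are excluded)."""
        d = asdict(self)
        d.pop("output_dir")
        d.pop("log_level")
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.analysis_params(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class RunReport:
    de_summary: report.DESummary
    pair_summary: association.PairSummary
    negative_genes: association.NegativeGeneTable
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "de_summary": self.de_summary.to_dict(),
            "pair_summary": self.pair_summary.to_dict(),
            "negative_genes": self.negative_genes.to_dict(),
            "provenance": self.provenance,
        }


def _require(path: Optional[str], what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"missing required input: {what}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found at {p}")
    return p


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False,
               index_label: Optional[str] = None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format=FLOAT_FORMAT)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run all stages and write outputs + manifest under output_dir."""
    outdir = Path(config.output_dir)
    written: dict[str, str] = {}

    # --- stage 0: inputs (synthetic generation or files on disk);
    # inputs are validated/read before the output directory is created
    if config.synthetic:
        dataset = simulate_dataset(
            SimulationConfig(
                seed=config.seed,
                n_genes=config.synthetic_n_genes,
                n_te=config.synthetic_n_te,
            )
        )
        outdir.mkdir(parents=True, exist_ok=True)
        synth_dir = outdir / "synthetic"
        for name, p in dataset.write(synth_dir).items():
            written[f"synthetic/{name}"] = str(p)
        genes = dataset.annotation.genes
        tes = dataset.annotation.tes
        counts = dataset.counts
        sample_sheet = dataset.sample_sheet
    else:
        genes = intervals.read_gene_annotation(_require(config.genes_gtf, "genes_gtf"))
        tes = intervals.read_te_annotation(
            _require(config.tes_bed, "tes_bed"), strict=config.strict_te_classes
        )
        sample_sheet = pd.read_csv(
            _require(config.sample_sheet, "sample_sheet"), sep="\t"
        )
        outdir.mkdir(parents=True, exist_ok=True)
        if config.compat is not None:
            counts = _quantify(config, outdir, written)
        else:
            counts = pd.read_csv(
                _require(config.counts, "counts"), sep="\t", index_col=0
            )

    conditions = pd.Series(
        sample_sheet["condition"].to_numpy(), index=sample_sheet["sample_id"]
    )
    counts = counts[sample_sheet["sample_id"].tolist()]
    te_ids = {t.te_id for t in tes}
    te_class_map = {t.te_id: t.te_class for t in tes}

    # --- stage: differential expression (genes and TE loci together)
    de = diffexpr.run_de(
        counts,
        conditions,
        control=config.control_label,
        lfc_threshold=config.lfc_threshold,
        alpha=config.alpha_de,
        pooled_dispersion=config.pooled_dispersion,
    )
    de_path = outdir / "de_results.tsv"
    _write_tsv(de.reset_index(drop=True), de_path)
    written["de_results"] = str(de_path)
    volcano = de.reset_index(drop=True)[["feature_id", "log2fc", "p_adj"]].copy()
    import numpy as np

    volcano["neg_log10_p_adj"] = -np.log10(volcano["p_adj"].clip(lower=1e-300))
    volcano_path = outdir / "volcano_source.tsv"
    _write_tsv(volcano, volcano_path)
    written["volcano_source"] = str(volcano_path)

    # --- stage: positional classification of TE loci
    classifications = intervals.classify_all(tes, genes)
    cls_df = intervals.classification_frame(classifications)
    cls_path = outdir / "classification.tsv"
    _write_tsv(cls_df, cls_path)
    written["classification"] = str(cls_path)

    # --- stage: gene-TE association
    de_tes = de[de["feature_id"].isin(te_ids)]
    pairs = association.build_pairs(de_tes, cls_df)
    expr = association.transform_expression(counts, raw_counts=config.raw_counts)
    scored = association.score_pairs(pairs, expr)
    scored_path = outdir / "pairs_all.tsv"
    _write_tsv(scored, scored_path)
    written["pairs_all"] = str(scored_path)
    selected = association.select_pairs(scored, alpha_pair=config.alpha_pair)
    sub_meta = pd.DataFrame(
        {
            "te_id": [t.te_id for t in tes],
            "te_subfamily": [t.subfamily for t in tes],
            "te_class": [t.te_class for t in tes],
        }
    )
    selected_out = selected.merge(sub_meta, on="te_id", how="left")[
        ["gene_id", "te_id", "te_subfamily", "te_class", "location",
         "slope", "lm_p", "correlation", "sign"]
    ]
    sel_path = outdir / "pairs_significant.tsv"
    _write_tsv(selected_out, sel_path)
    written["pairs_significant"] = str(sel_path)

    # --- stage: report
    de_summary = report.summarize_de(de_tes, te_class_map)
    pair_summary = association.summarize_pairs(selected)
    neg_table = association.negative_pair_gene_table(selected)
    gene_list_path = outdir / "candidate_genes.txt"
    all_neg_genes = sorted(
        {g for genes_ in neg_table.genes_by_location.values() for g in genes_}
    )
    gene_list_path.write_text("".join(f"{g}\n" for g in all_neg_genes))
    written["candidate_genes"] = str(gene_list_path)

    run_report = RunReport(
        de_summary=de_summary,
        pair_summary=pair_summary,
        negative_genes=neg_table,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "telex_version": __version__,
            "config": config.analysis_params(),
        },
    )
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(run_report.to_dict(), indent=2, sort_keys=True))
    written["report"] = str(report_path)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps({"files": written}, indent=2, sort_keys=True))
    return run_report


def _quantify(config: PipelineConfig, outdir: Path, written: dict[str, str]) -> pd.DataFrame:
    """EM quantification stage from a compatibility TSV."""
    tables = em.read_compat_table(_require(config.compat, "compat"))
    per_sample = [em.em_assign(t) for t in tables]
    gene_counts = None
    if config.gene_counts is not None:
        gene_counts = pd.read_csv(
            _require(config.gene_counts, "gene_counts"), sep="\t", index_col=0
        )
    counts = em.build_count_matrix(per_sample, gene_counts)
    path = outdir / "quantified_counts.tsv"
    counts.to_csv(path, sep="\t", index_label="feature_id", float_format=FLOAT_FORMAT)
    written["quantified_counts"] = str(path)
    return counts
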