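"""Synthetic two-condition TE/gene datasets with ground truth.

The generator emulates the statistical structure the pipeline assumes in a
statin-style contrast: a toy chromosome of non-overlapping gene models, TE
loci placed to realize known positional labels (including discard cases),
negative-binomial counts for 11 control and 11 treated samples with
planted log2 fold changes on TE loci, signed gene-TE couplings through a
shared lognormal latent factor, and read-compatibility tables with known
locus abundances and a tunable ambiguous-read fraction.

Everything is driven by one integer seed through numpy's PCG64 generator,
so identical configurations produce identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .em import CompatibilityTable
from .intervals import GeneModel, GenomicInterval, TELocus

#: TE class sampling weights: SINE-predominant, then LINE, as in human
#: transcriptomes.
CLASS_WEIGHTS = {"SINE": 0.45, "LINE": 0.30, "LTR": 0.15, "DNA": 0.10}

SUBFAMILY_POOL = {
    "SINE": [("AluSq2", "Alu"), ("AluY", "Alu"), ("AluJb", "Alu"),
             ("MIRb", "MIR"), ("MIR3", "MIR")],
    "LINE": [("L1HS", "L1"), ("L1PA2", "L1"), ("L1MB7", "L1"), ("L2a", "L2")],
    "LTR": [("THE1B", "ERVL-MaLR"), ("MER41B", "ERV1"), ("LTR7", "ERVK")],
    "DNA": [("Tigger1", "TcMar-Tigger"), ("MER5A", "hAT-Charlie"),
            ("Charlie1a", "hAT-Charlie")],
}

#: Genic label weights used for the non-intergenic share of loci.
GENIC_LABEL_WEIGHTS = {
    "INTRONIC": 0.45,
    "EXON": 0.20,
    "DISCARDED": 0.20,
    "START_CODON": 0.075,
    "STOP_CODON": 0.075,
}

CHROM = "chrS"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the analyzed contrast: 11 samples per condition (22
    cell populations), NB dispersion 0.05, planted TE effects of
    |log2FC| = 3 with a 35/65 up/down split, and gene-TE couplings of
    effect size 1.5 (log2-scale latent amplitude) with an even sign split.
    """

    seed: int = 1
    n_genes: int = 120
    n_te: int = 240
    n_samples_per_condition: int = 11
    nb_dispersion: float = 0.05
    mean_log_expression: float = 5.0
    planted_de: Optional[list[tuple[str, float]]] = None
    planted_couplings: Optional[list[tuple[str, str, str, float]]] = None
    intergenic_fraction: float = 0.3
    ambiguity_rate: float = 0.3
    de_fraction: float = 0.15
    de_up_fraction: float = 0.35
    de_log2fc: float = 3.0
    coupling_fraction: float = 0.5
    coupling_effect: float = 1.5

    def __post_init__(self) -> None:
        for name in ("intergenic_fraction", "ambiguity_rate", "de_fraction",
                     "de_up_fraction", "coupling_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be nonnegative")
        if self.n_genes < 1 or self.n_te < 1:
            raise ValueError("need at least one gene and one TE")


@dataclass
class Annotation:
    genes: list[GeneModel]
    tes: list[TELocus]
    truth: pd.DataFrame  # te_id, true_label, true_gene_id, true_distance
    chrom_length: int


def generate_annotation(config: SimulationConfig) -> Annotation:
    """Toy chromosome with non-overlapping genes and label-planted TE loci."""
    rng = np.random.default_rng([config.seed, 101])
    genes: list[GeneModel] = []
    cursor = 5000
    for i in range(config.n_genes):
        gene_id = f"g{i + 1:04d}"
        n_exons = int(rng.integers(2, 5))
        exon_lens = rng.integers(300, 801, n_exons)
        intron_lens = rng.integers(800, 2001, max(n_exons - 1, 0))
        exons = []
        pos = cursor
        for j in range(n_exons):
            exons.append(GenomicInterval(CHROM, pos, pos + int(exon_lens[j]), "+"))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        body = GenomicInterval(CHROM, cursor, pos, "+")
        start_codon = GenomicInterval(CHROM, exons[0].start + 10, exons[0].start + 13, "+")
        stop_codon = GenomicInterval(CHROM, exons[-1].end - 13, exons[-1].end - 10, "+")
        genes.append(GeneModel(gene_id, gene_id.upper(), body, exons,
                               start_codon, stop_codon))
        cursor = pos + int(rng.integers(4000, 9001))
    chrom_length = cursor + 5000

    genic_labels = list(GENIC_LABEL_WEIGHTS)
    genic_p = np.array([GENIC_LABEL_WEIGHTS[l] for l in genic_labels])
    genic_p /= genic_p.sum()
    class_names = list(CLASS_WEIGHTS)
    class_p = np.array([CLASS_WEIGHTS[c] for c in class_names])

    tes: list[TELocus] = []
    truth_rows = []
    used_ids: set[str] = set()
    attempts = 0
    while len(tes) < config.n_te:
        attempts += 1
        if attempts > 50 * config.n_te:
            raise RuntimeError(
                "could not place requested TE loci; increase gene count or "
                "reduce n_te (longer chromosome needed)"
            )
        te_len = int(rng.integers(150, 401))
        if rng.random() < config.intergenic_fraction:
            label = "INTERGENIC"
        else:
            label = genic_labels[int(rng.choice(len(genic_labels), p=genic_p))]
        placed = _place_te(rng, genes, label, te_len, chrom_length)
        if placed is None:
            continue
        start, end, true_gene, dist = placed
        te_class = class_names[int(rng.choice(len(class_names), p=class_p))]
        subfamily, family = SUBFAMILY_POOL[te_class][
            int(rng.integers(len(SUBFAMILY_POOL[te_class])))
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        te = TELocus.from_fields(CHROM, start, end, subfamily, family, te_class, strand)
        if te.te_id in used_ids:
            continue
        used_ids.add(te.te_id)
        tes.append(te)
        truth_rows.append((te.te_id, label,
                           true_gene if label != "DISCARDED" else "", dist))
    truth = pd.DataFrame(
        truth_rows, columns=["te_id", "true_label", "true_gene_id", "true_distance"]
    )
    return Annotation(genes, tes, truth, chrom_length)


def _place_te(
    rng: np.random.Generator,
    genes: list[GeneModel],
    label: str,
    te_len: int,
    chrom_length: int,
):
    """Coordinates realizing ``label``; returns (start, end, gene_id, dist)
    or None when the sampled host cannot host the label."""
    gi = int(rng.integers(len(genes)))
    g = genes[gi]
    if label == "INTERGENIC":
        slot = int(rng.integers(len(genes) + 1))
        left_end = genes[slot - 1].body.end if slot > 0 else None
        right_start = genes[slot].body.start if slot < len(genes) else None
        lo = (left_end + 50) if left_end is not None else 100
        hi = (right_start - 50 - te_len) if right_start is not None else (
            chrom_length - 200 - te_len
        )
        if hi <= lo:
            return None
        start = int(rng.integers(lo, hi + 1))
        end = start + te_len
        cand = []
        if left_end is not None:
            cand.append((start - left_end, genes[slot - 1].gene_id))
        if right_start is not None:
            cand.append((right_start - end, genes[slot].gene_id))
        dist, gene_id = min(cand)
        return start, end, gene_id, int(dist)
    if label == "INTRONIC":
        introns = [
            (g.exons[j].end, g.exons[j + 1].start)
            for j in range(len(g.exons) - 1)
            if g.exons[j + 1].start - g.exons[j].end >= te_len + 40
        ]
        if not introns:
            return None
        s, e = introns[int(rng.integers(len(introns)))]
        start = int(rng.integers(s + 20, e - 20 - te_len + 1))
        return start, start + te_len, g.gene_id, 0
    if label == "EXON":
        if len(g.exons) < 2:
            return None
        j = int(rng.integers(len(g.exons) - 1))  # straddle right edge into intron
        exon = g.exons[j]
        a_hi = min(140, te_len - 20, len(exon) - 20)
        if a_hi < 20:
            return None
        a = int(rng.integers(20, a_hi + 1))
        start = exon.end - a
        return start, start + te_len, g.gene_id, 0
    if label == "START_CODON":
        a = int(rng.integers(10, 121))
        start = g.exons[0].start - a
        return start, g.exons[0].start + 20, g.gene_id, 0
    if label == "STOP_CODON":
        a = int(rng.integers(10, 121))
        start = g.exons[-1].end - 20
        return start, g.exons[-1].end + a, g.gene_id, 0
    if label == "DISCARDED":
        exons = [e for e in g.exons if len(e) >= te_len + 40]
        if not exons:
            te_len = min(te_len, max(len(e) for e in g.exons) - 40)
            exons = [e for e in g.exons if len(e) >= te_len + 40]
        exon = exons[int(rng.integers(len(exons)))]
        start = int(rng.integers(exon.start + 20, exon.end - 20 - te_len + 1))
        return start, start + te_len, g.gene_id, 0
    raise ValueError(f"unknown label {label}")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    annotation: Annotation
    counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    truth_de: pd.DataFrame          # feature_id, true_log2fc
    couplings: list[tuple[str, str, str, float]]  # gene, te, sign, effect

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .intervals import write_te_bed

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes_gtf": outdir / "genes.gtf",
            "tes_bed": outdir / "tes.bed",
            "counts": outdir / "counts.tsv",
            "sample_sheet": outdir / "sample_sheet.tsv",
            "truth_classification": outdir / "truth_classification.tsv",
            "truth_de": outdir / "truth_de.tsv",
            "truth_couplings": outdir / "truth_couplings.tsv",
        }
        write_gtf(self.annotation.genes, paths["genes_gtf"])
        write_te_bed(self.annotation.tes, paths["tes_bed"])
        self.counts.to_csv(paths["counts"], sep="\t", index_label="feature_id")
        self.sample_sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
        self.annotation.truth.to_csv(paths["truth_classification"], sep="\t", index=False)
        self.truth_de.to_csv(paths["truth_de"], sep="\t", index=False)
        pd.DataFrame(
            self.couplings, columns=["gene_id", "te_id", "sign", "effect"]
        ).to_csv(paths["truth_couplings"], sep="\t", index=False)
        return paths


def generate_counts(
    config: SimulationConfig, annotation: Annotation
) -> SyntheticDataset:
    """NB counts over genes + TE loci with planted effects and couplings."""
    rng = np.random.default_rng([config.seed, 202])
    gene_ids = [g.gene_id for g in annotation.genes]
    te_ids = [t.te_id for t in annotation.tes]
    features = gene_ids + te_ids
    n_per = config.n_samples_per_condition
    samples = [f"control_{i + 1:02d}" for i in range(n_per)] + [
        f"treated_{i + 1:02d}" for i in range(n_per)
    ]
    treated = np.array([0] * n_per + [1] * n_per, dtype=float)

    planted_de = config.planted_de
    if planted_de is None:
        n_de = max(1, round(config.de_fraction * len(te_ids)))
        chosen = rng.choice(len(te_ids), size=min(n_de, len(te_ids)), replace=False)
        planted_de = []
        for k in chosen:
            up = rng.random() < config.de_up_fraction
            planted_de.append(
                (te_ids[int(k)], config.de_log2fc if up else -config.de_log2fc)
            )
    lfc = {fid: 0.0 for fid in features}
    for fid, v in planted_de:
        if fid not in lfc:
            raise ValueError(f"planted DE feature {fid} does not exist")
        lfc[fid] = float(v)

    couplings = config.planted_couplings
    if couplings is None:
        gene_of = dict(
            zip(annotation.truth["te_id"], annotation.truth["true_gene_id"])
        )
        eligible = [fid for fid, _ in planted_de if gene_of.get(fid)]
        taken_genes: set[str] = set()
        couplings = []
        for k, te in enumerate(eligible):
            if rng.random() >= config.coupling_fraction:
                continue
            gene = gene_of[te]
            if gene in taken_genes:
                continue
            taken_genes.add(gene)
            sign = "POSITIVE" if len(couplings) % 2 == 0 else "NEGATIVE"
            couplings.append((gene, te, sign, config.coupling_effect))
    for gene, te, sign, _ in couplings:
        if gene not in lfc or te not in lfc:
            raise ValueError(f"planted coupling ({gene}, {te}) references "
                             "unknown features")
        if sign not in {"POSITIVE", "NEGATIVE"}:
            raise ValueError(f"coupling sign must be POSITIVE/NEGATIVE, got {sign}")

    base_log = rng.normal(config.mean_log_expression, 0.7, size=len(features))
    lib = rng.uniform(0.7, 1.3, size=len(samples))
    ln2 = np.log(2.0)

    log_mu = base_log[:, None] + np.log(lib)[None, :]
    fidx = {fid: i for i, fid in enumerate(features)}
    for fid, v in lfc.items():
        if v:
            log_mu[fidx[fid]] += v * ln2 * treated
    for gene, te, sign, effect in couplings:
        z = rng.standard_normal(len(samples))
        log_mu[fidx[gene]] += effect * ln2 * z
        s = 1.0 if sign == "POSITIVE" else -1.0
        log_mu[fidx[te]] += s * effect * ln2 * z

    mu = np.exp(log_mu)
    alpha = config.nb_dispersion
    if alpha < 1e-10:
        mat = rng.poisson(mu)
    else:
        r = 1.0 / alpha
        p = r / (r + mu)
        mat = rng.negative_binomial(r, p)
    counts = pd.DataFrame(mat.astype(float), index=features, columns=samples)
    sample_sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "condition": ["control"] * n_per + ["treated"] * n_per,
        }
    )
    truth_de = pd.DataFrame(
        {"feature_id": features, "true_log2fc": [lfc[f] for f in features]}
    )
    return SyntheticDataset(
        config=config,
        annotation=annotation,
        counts=counts,
        sample_sheet=sample_sheet,
        truth_de=truth_de,
        couplings=list(couplings),
    )


def simulate_dataset(config: Optional[SimulationConfig] = None) -> SyntheticDataset:
    config = config or SimulationConfig()
    annotation = generate_annotation(config)
    return generate_counts(config, annotation)


def generate_compat(
    n_loci: int,
    true_abundances: Sequence[float],
    n_reads: int,
    ambiguity_rate: float,
    seed: int | np.random.Generator,
    sample_id: str = "sample_1",
    locus_ids: Optional[Sequence[str]] = None,
) -> tuple[CompatibilityTable, dict[str, int]]:
    """Compatibility table drawn from known locus abundances.

    Reads are multinomial draws from ``true_abundances``; with probability
    ``ambiguity_rate`` a read's compatibility set is its true locus plus
    1-3 uniformly chosen confounder loci.  Returns the table and the true
    per-locus read counts.
    """
    p = np.asarray(true_abundances, dtype=float)
    if p.size != n_loci:
        raise ValueError("abundances length must equal n_loci")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("abundances must sum to 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng([int(seed), 303])
    )
    ids = list(locus_ids) if locus_ids is not None else [
        f"te{i + 1:03d}" for i in range(n_loci)
    ]
    tab = CompatibilityTable(sample_id)
    truth: dict[str, int] = {lid: 0 for lid in ids}
    if n_reads == 0:
        return tab, truth
    draws = rng.multinomial(n_reads, p)
    groups: dict[frozenset[str], int] = {}
    for i, c in enumerate(draws):
        truth[ids[i]] = int(c)
        if c == 0:
            continue
        n_amb = int(rng.binomial(c, ambiguity_rate)) if n_loci > 1 else 0
        if c - n_amb > 0:
            tab.unique_counts[ids[i]] = tab.unique_counts.get(ids[i], 0) + (c - n_amb)
        others = np.array([j for j in range(n_loci) if j != i])
        for _ in range(n_amb):
            k = int(rng.integers(1, min(3, len(others)) + 1))
            conf = rng.choice(others, size=k, replace=False)
            key = frozenset([ids[i]] + [ids[int(j)] for j in conf])
            groups[key] = groups.get(key, 0) + 1
    tab.ambiguous_groups.extend(sorted(groups.items(), key=lambda kv: sorted(kv[0])))
    return tab, truth


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            def line(feature: str, iv: GenomicInterval) -> str:
                return (
                    f"{iv.chrom}\ttelex\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\t{attrs}\n"
                )
            fh.write(line("gene", g.body))
            for e in g.exons:
                fh.write(line("exon", e))
            if g.start_codon:
                fh.write(line("start_codon", g.start_codon))
            if g.stop_codon:
                fh.write(line("stop_codon", g.stop_codon))
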