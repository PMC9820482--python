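"""EM assignment of ambiguous reads to TE loci.

Reads mapping to repetitive loci are often compatible with several genomic
copies of a subfamily.  We model reads as draws from a multinomial mixture
over loci and resolve the ambiguity with expectation-maximization:

* E-step — each ambiguous read group is split across its compatible loci
  in proportion to the current locus abundances;
* M-step — locus abundance is reset to unique reads plus assigned
  fractions.

Reads with identical compatibility sets are grouped (a sufficient
statistic), so the iteration cost scales with the number of distinct sets,
not the number of reads.  Total read mass is conserved on every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class CompatibilityTable:
    """Per-sample read-to-locus compatibility, grouped by set.

    ``unique_counts`` maps a locus to its count of uniquely mapping reads;
    ``ambiguous_groups`` holds (locus set, read count) pairs with set size
    >= 2.
    """

    sample_id: str
    unique_counts: dict[str, int] = field(default_factory=dict)
    ambiguous_groups: list[tuple[frozenset[str], int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for locus, n in self.unique_counts.items():
            if n < 0:
                raise ValueError(f"negative unique count for {locus}")
        for group, n in self.ambiguous_groups:
            if len(group) < 2:
                raise ValueError("ambiguous group must contain >= 2 loci")
            if n <= 0:
                raise ValueError("ambiguous group read count must be positive")

    @property
    def locus_universe(self) -> set[str]:
        universe = set(self.unique_counts)
        for group, _ in self.ambiguous_groups:
            universe |= group
        return universe

    @property
    def total_reads(self) -> float:
        return sum(self.unique_counts.values()) + sum(
            n for _, n in self.ambiguous_groups
        )


@dataclass
class LocusCounts:
    sample_id: str
    counts: dict[str, float]
    n_iterations: int
    converged: bool


def em_assign(
    compat: CompatibilityTable,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> LocusCounts:
    """Fractionally assign reads to loci by EM.

    Abundances start uniform across the locus universe, so fully symmetric
    ambiguity resolves to an even split.  A group whose compatible loci all
    have zero current abundance is split uniformly for that iteration.
    Convergence is declared when the largest absolute abundance change
    falls below ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    loci = sorted(compat.locus_universe)
    if not loci:
        raise ValueError("empty locus universe")
    index = {locus: i for i, locus in enumerate(loci)}
    n = len(loci)

    unique = np.zeros(n)
    for locus, c in compat.unique_counts.items():
        unique[index[locus]] = c
    groups = [
        (np.fromiter((index[l] for l in group), dtype=int), float(c))
        for group, c in compat.ambiguous_groups
    ]

    if not groups:
        return LocusCounts(
            compat.sample_id, dict(zip(loci, unique.tolist())), 1, True
        )

    total = unique.sum() + sum(c for _, c in groups)
    abundance = np.full(n, total / n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        assigned = unique.copy()
        for idx, c in groups:
            w = abundance[idx]
            s = w.sum()
            if s > 0:
                assigned[idx] += c * w / s
            else:
                assigned[idx] += c / len(idx)
        delta = np.max(np.abs(assigned - abundance))
        abundance = assigned
        if delta < tol:
            converged = True
            break
    return LocusCounts(
        compat.sample_id, dict(zip(loci, abundance.tolist())), it, converged
    )


def read_compat_table(path: str | Path) -> list[CompatibilityTable]:
    """Read compatibility tables from the TSV dialect
    ``sample_id<TAB>locus_ids(comma-joined)<TAB>read_count``.

    Singleton locus lists are unique reads; multi-locus lists are ambiguous
    groups.  Repeated (sample, set) lines accumulate.
    """
    path = Path(path)
    by_sample: dict[str, CompatibilityTable] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(cols)}"
                )
            sample_id, loci_s, count_s = cols
            loci = [l for l in loci_s.split(",") if l]
            count = int(count_s)
            tab = by_sample.setdefault(sample_id, CompatibilityTable(sample_id))
            if len(loci) == 1:
                tab.unique_counts[loci[0]] = tab.unique_counts.get(loci[0], 0) + count
            else:
                tab.ambiguous_groups.append((frozenset(loci), count))
    return list(by_sample.values())


def write_compat_table(tables: Iterable[CompatibilityTable], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tab in tables:
            for locus in sorted(tab.unique_counts):
                fh.write(f"{tab.sample_id}\t{locus}\t{tab.unique_counts[locus]}\n")
            for group, c in sorted(
                tab.ambiguous_groups, key=lambda g: sorted(g[0])
            ):
                fh.write(f"{tab.sample_id}\t{','.join(sorted(group))}\t{c}\n")


def build_count_matrix(
    per_sample: Sequence[LocusCounts],
    gene_counts: Optional[pd.DataFrame | str | Path] = None,
) -> pd.DataFrame:
    """Merge per-sample EM locus counts (and optional gene counts) into one
    features x samples matrix.

    Fractional EM counts are preserved.  A locus absent from a sample is 0.
    Feature ids must be unique across the gene and TE namespaces.
    """
    if not per_sample:
        raise ValueError("no samples provided")
    te = pd.DataFrame(
        {lc.sample_id: pd.Series(lc.counts, dtype=float) for lc in per_sample}
    ).fillna(0.0)
    te = te.sort_index()
    if gene_counts is None:
        return te
    if not isinstance(gene_counts, pd.DataFrame):
        gene_counts = pd.read_csv(gene_counts, sep="\t", index_col=0)
    dup = set(te.index) & set(gene_counts.index)
    if dup:
        raise ValueError(
            f"duplicate feature ids across gene and TE namespaces: {sorted(dup)[:5]}"
        )
    gene_counts = gene_counts.reindex(columns=te.columns, fill_value=0.0)
    return pd.concat([gene_counts.astype(float), te])
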