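import numpy as np
import pandas as pd
import pytest

from telex.intervals import GeneModel, GenomicInterval, TELocus


@pytest.fixture
def toy_gene():
    """Gene on chr1 spanning [100, 1000) with exons [100,200) and [800,1000),
    start codon just inside the first exon, stop codon just inside the last."""
    return GeneModel(
        gene_id="g1",
        gene_name="G1",
        body=GenomicInterval("chr1", 100, 1000, "+"),
        exons=[
            GenomicInterval("chr1", 100, 200, "+"),
            GenomicInterval("chr1", 800, 1000, "+"),
        ],
        start_codon=GenomicInterval("chr1", 110, 113, "+"),
        stop_codon=GenomicInterval("chr1", 987, 990, "+"),
    )


def make_te(chrom, start, end, subfamily="AluSq2", family="Alu", te_class="SINE",
            strand="+"):
    return TELocus.from_fields(chrom, start, end, subfamily, family, te_class, strand)


def nb_counts(rng, mu, dispersion, size=None):
    """NB draws parameterized by mean and dispersion (var = mu + a*mu^2)."""
    if dispersion < 1e-10:
        return rng.poisson(mu, size=size)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + np.asarray(mu, dtype=float)), size=size)


def two_group_counts(rng, n_features, n_per_group, dispersion, lfc=None,
                     mean_log=5.0):
    """Features x samples NB count table for a two-condition contrast.

    ``lfc`` is a per-feature log2 fold change applied to the treated half.
    Returns (counts DataFrame, condition Series).
    """
    mu = np.exp(rng.normal(mean_log, 0.7, n_features))
    lib = rng.uniform(0.7, 1.3, 2 * n_per_group)
    m = mu[:, None] * lib[None, :]
    if lfc is not None:
        m[:, n_per_group:] *= 2.0 ** np.asarray(lfc, dtype=float)[:, None]
    counts = pd.DataFrame(
        nb_counts(rng, m, dispersion).astype(float),
        index=[f"f{i:04d}" for i in range(n_features)],
        columns=[f"c{i:02d}" for i in range(n_per_group)]
        + [f"t{i:02d}" for i in range(n_per_group)],
    )
    cond = pd.Series(
        ["control"] * n_per_group + ["treated"] * n_per_group, index=counts.columns
    )
    return counts, cond
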