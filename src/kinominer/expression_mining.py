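"""RNA-seq mining: RPKM, TMM scaling, expression calls and Poisson DE tests.

Expression is quantified as RPKM (reads per kilobase of transcript per
million mapped reads); genes below 1 RPKM are called non-expressed.
Between-sample depth differences are corrected with the trimmed mean of
M-values (TMM) scaling factor.  Differential expression between two
libraries uses the Audic-Claverie exact conditional Poisson test -- the
probability of the second library's count given the first, which avoids the
influence of sequencing depth and gene length -- with Benjamini-Hochberg
adjustment within each contrast and a minimum fold-change gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix

DEFAULT_ALPHA = 0.001
DEFAULT_MIN_FOLD = 2.0
DEFAULT_RPKM_THRESHOLD = 1.0


@dataclass(frozen=True)
class ExpressionCall:
    gene_id: str
    sample_id: str
    rpkm: float
    expressed: bool


@dataclass(frozen=True)
class DEResult:
    """Per-gene result of one treatment-vs-control contrast."""

    gene_id: str
    contrast: tuple[str, str]   # (treatment sample, control sample)
    p_value: float
    adjusted_p: float
    direction: str              # "up", "down" or "none"
    fold_change: float          # treatment rate / control rate


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------

def rpkm(count: float, gene_length_bp: int, library_size: int) -> float:
    """RPKM = 1e9 * count / (library_size * gene_length_bp)."""
    if gene_length_bp < 1 or library_size < 1:
        raise ValueError("gene length and library size must be >= 1")
    return 1.0e9 * count / (library_size * gene_length_bp)


def rpkm_matrix(counts: CountMatrix) -> pd.DataFrame:
    """Gene x sample RPKM values."""
    c = counts.counts.to_numpy(dtype=float)
    lengths = counts.gene_lengths.to_numpy(dtype=float)[:, None]
    libs = counts.library_sizes.to_numpy(dtype=float)[None, :]
    return pd.DataFrame(1.0e9 * c / (libs * lengths),
                        index=counts.counts.index,
                        columns=counts.counts.columns)


def expressed_matrix(counts: CountMatrix,
                     threshold: float = DEFAULT_RPKM_THRESHOLD) -> pd.DataFrame:
    """Boolean gene x sample matrix: expressed iff RPKM >= threshold."""
    return rpkm_matrix(counts) >= threshold


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def tmm_factor(test_counts: np.ndarray, ref_counts: np.ndarray,
               n_test: float | None = None, n_ref: float | None = None,
               trim_m: float = 0.30, trim_a: float = 0.05) -> float:
    """Trimmed-mean-of-M-values scaling factor of a test sample vs a reference.

    Genes with a zero count in either sample are excluded.  Per remaining
    gene, ``M = log2((x/Nx) / (r/Nr))`` and ``A = 0.5 log2(x r / (Nx Nr))``;
    the top and bottom ``trim_m`` of genes by M and ``trim_a`` by A are
    trimmed, and the factor is ``2**`` of the weighted mean of the surviving
    M values, weighted by inverse approximate (delta-method binomial)
    variances ``1/x - 1/Nx + 1/r - 1/Nr``.  Returns 1.0 when nothing
    survives trimming.
    """
    x = np.asarray(test_counts, dtype=float)
    r = np.asarray(ref_counts, dtype=float)
    if x.shape != r.shape:
        raise ValueError("samples must cover the same gene set")
    if x.sum() == 0 or r.sum() == 0:
        raise ValueError("TMM factor is undefined for an all-zero sample")
    n_x = float(x.sum()) if n_test is None else float(n_test)
    n_r = float(r.sum()) if n_ref is None else float(n_ref)

    keep = (x > 0) & (r > 0)
    x, r = x[keep], r[keep]
    if x.size == 0:
        return 1.0

    m = np.log2((x / n_x) / (r / n_r))
    a = 0.5 * np.log2((x * r) / (n_x * n_r))
    weights = 1.0 / (1.0 / x - 1.0 / n_x + 1.0 / r - 1.0 / n_r)

    n = m.size
    m_rank = stats.rankdata(m, method="ordinal") - 1
    a_rank = stats.rankdata(a, method="ordinal") - 1
    keep_m = (m_rank >= trim_m * n) & (m_rank < (1.0 - trim_m) * n)
    keep_a = (a_rank >= trim_a * n) & (a_rank < (1.0 - trim_a) * n)
    kept = keep_m & keep_a
    if not kept.any():
        return 1.0
    return float(2.0 ** (np.sum(weights[kept] * m[kept]) / np.sum(weights[kept])))


def choose_reference_sample(counts: CountMatrix) -> str:
    """Sample whose upper quartile of scaled counts is closest to the mean
    upper quartile (the standard TMM reference convention)."""
    scaled = counts.counts.to_numpy(dtype=float) / \
        counts.library_sizes.to_numpy(dtype=float)[None, :]
    uq = np.quantile(scaled, 0.75, axis=0)
    idx = int(np.argmin(np.abs(uq - uq.mean())))
    return counts.sample_ids[idx]


# ---------------------------------------------------------------------------
# Audic-Claverie Poisson test
# ---------------------------------------------------------------------------

def poisson_de_test(x, y, n1, n2):
    """Two-sided Audic-Claverie exact test; vectorized over gene arrays.

    Conditional on ``x`` reads in library 1 (size ``n1``), the count in
    library 2 follows

        P(Y = y | x) = (n2/n1)**y (x+y)! / (x! y! (1 + n2/n1)**(x+y+1)),

    which is negative binomial with ``x + 1`` successes and success
    probability ``n1 / (n1 + n2)``.  The two-sided p-value doubles the
    smaller of the lower tail ``P(Y <= y)`` and the strict upper tail
    ``P(Y > y)``; because ``P(Y <= y | x; n1, n2) = P(X > x | y; n2, n1)``
    exactly (an incomplete-beta identity), this choice of tails makes the
    p-value exactly exchangeable under swapping ``(x, n1) <-> (y, n2)``.
    A gene with no reads in either library is uninformative and gets p = 1.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    scalar = x.ndim == 0
    x, y = np.atleast_1d(x), np.atleast_1d(y)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    if n1 < 1 or n2 < 1:
        raise ValueError("library sizes must be >= 1")
    q = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, q)
    upper = stats.nbinom.sf(y, x + 1, q)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    p = np.where((x == 0) & (y == 0), 1.0, p)
    return float(p[0]) if scalar else p


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(p_values, dtype=float),
                         method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# per-contrast DE calling
# ---------------------------------------------------------------------------

def call_de(counts: CountMatrix,
            contrasts: Sequence[tuple[str, str]],
            alpha: float = DEFAULT_ALPHA,
            min_fold: float = DEFAULT_MIN_FOLD,
            use_tmm: bool = True) -> list[DEResult]:
    """Call up/down regulation per gene for each (treatment, control) pair.

    Library sizes are multiplied by the pairwise TMM factor before testing
    so that depth and composition differences do not masquerade as
    regulation.  Within each contrast, p-values are Benjamini-Hochberg
    adjusted; a gene is "up" when significant at ``alpha`` with a
    normalized treatment/control rate ratio of at least ``min_fold``
    ("down" symmetric), else "none".
    """
    results: list[DEResult] = []
    for treatment, control in contrasts:
        if treatment not in counts.counts.columns:
            raise KeyError(f"unknown treatment sample {treatment!r}")
        if control not in counts.counts.columns:
            raise KeyError(f"unknown control sample {control!r}")
        x = counts.counts[treatment].to_numpy()
        y = counts.counts[control].to_numpy()
        n1 = float(counts.library_sizes[treatment])
        n2 = float(counts.library_sizes[control])
        if use_tmm:
            n1 *= tmm_factor(x, y, n1, n2)
        p = poisson_de_test(x, y, n1, n2)
        adj = benjamini_hochberg(p)

        rate1 = x / n1
        rate2 = y / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = np.where(
                (rate1 == 0) & (rate2 == 0), 1.0, rate1 / rate2
            )
        for g, gene in enumerate(counts.gene_ids):
            direction = "none"
            if adj[g] <= alpha:
                if fold[g] >= min_fold:
                    direction = "up"
                elif fold[g] <= 1.0 / min_fold:
                    direction = "down"
            results.append(DEResult(
                gene_id=gene,
                contrast=(treatment, control),
                p_value=float(p[g]),
                adjusted_p=float(adj[g]),
                direction=direction,
                fold_change=float(fold[g]),
            ))
    return results


def expression_calls(counts: CountMatrix,
                     threshold: float = DEFAULT_RPKM_THRESHOLD
                     ) -> list[ExpressionCall]:
    """Flat list of per-gene, per-sample expression calls."""
    rp = rpkm_matrix(counts)
    calls = []
    for sample in counts.sample_ids:
        col = rp[sample]
        for gene in counts.gene_ids:
            value = float(col[gene])
            calls.append(ExpressionCall(gene, sample, value,
                                        value >= threshold))
    return calls
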