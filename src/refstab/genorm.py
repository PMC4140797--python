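"""geNorm-style reference-gene stability analysis.

The workflow, applied to a complete CT table:

1.  ΔCT transform: per gene, subtract the highest CT (the sample with the
    lowest expression) from every CT and take ``2**-ΔCT``, yielding
    relative quantities (rq) with minimum 1 per gene.
2.  Stability measure M: for a gene *j*, the arithmetic mean over all
    partner genes *k* of the standard deviation across samples of
    ``log2(rq_j / rq_k)``.  A gene that co-varies proportionally with the
    others has small M; lower M = more stable.
3.  Stepwise exclusion: repeatedly drop the gene with the highest M and
    recompute, until two genes remain (their mutual M is, by construction,
    identical).
4.  Normalization factors and pairwise variation: ``NF_n`` is the
    per-sample geometric mean of the *n* most stable genes' rq;
    ``V_{n/n+1}`` is the SD across samples of ``log2(NF_n / NF_{n+1})``.
    ``V < 0.15`` means the (n+1)-th gene adds nothing, so the smallest
    such *n* is the optimal number of reference genes.

All standard deviations are sample SDs (n−1 denominator) and all ratio
work happens in log2 space to avoid over/underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .io import CtTable

DEFAULT_V_CUTOFF = 0.15


# ---------------------------------------------------------------------------
# ΔCT transform
# ---------------------------------------------------------------------------

@dataclass
class RelativeQuantityMatrix:
    """Relative quantities ``2**-ΔCT`` (genes × samples).

    Per gene the sample with the highest CT (lowest expression) is the
    anchor and has rq exactly 1; all other samples have rq ≥ 1.
    """

    rq: pd.DataFrame
    anchor: pd.Series  # gene -> sample id holding the maximum CT

    @property
    def gene_ids(self) -> list[str]:
        return list(self.rq.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rq.columns)


def delta_ct_transform(table: CtTable) -> RelativeQuantityMatrix:
    """Convert CT values to relative quantities via the ΔCT method.

    ``ΔCT = CT − max(CT)`` per gene, then ``rq = 2**-ΔCT``; one CT cycle
    equals one two-fold expression step (100% amplification efficiency).
    Missing CTs are rejected — subset or collapse replicates first.
    """
    if table.n_missing:
        mask = table.ct.isna()
        pairs = [(g, s) for g, row in mask.iterrows() for s, bad in row.items() if bad]
        raise InputError(f"missing CT values at (gene, sample): {pairs}")
    ct = table.ct
    anchor = ct.idxmax(axis=1)
    rq = np.power(2.0, ct.max(axis=1).to_numpy()[:, None] - ct.to_numpy())
    return RelativeQuantityMatrix(
        pd.DataFrame(rq, index=ct.index, columns=ct.columns), anchor
    )


# ---------------------------------------------------------------------------
# Stability measure M
# ---------------------------------------------------------------------------

@dataclass
class GenormResult:
    """M values, and — after ranking — the stepwise exclusion trace."""

    m: pd.Series                       # M per gene, current gene set
    pairwise_sd: pd.DataFrame          # V_jk = SD of log2(rq_j/rq_k)
    exclusion_order: list[str] = field(default_factory=list)  # least stable first
    rounds: list[pd.Series] = field(default_factory=list)     # M per exclusion round
    final_pair: tuple[str, str] | None = None

    def stability_order(self) -> list[str]:
        """Genes from most to least stable.

        The final pair comes first (ordered by their last-round M, which
        is tied, then by input order); then the excluded genes in reverse
        order of exclusion.
        """
        if self.final_pair is None:
            raise InputError("stability_order requires a ranked result (genorm_rank)")
        return list(self.final_pair) + list(reversed(self.exclusion_order))


def _pairwise_log_sd(log_rq: pd.DataFrame) -> pd.DataFrame:
    genes = log_rq.index
    arr = log_rq.to_numpy()
    n = len(genes)
    out = np.zeros((n, n))
    for j in range(n):
        diff = arr[j][None, :] - arr
        out[j] = diff.std(axis=1, ddof=1)
    return pd.DataFrame(out, index=genes, columns=genes)


def genorm_m(rq: RelativeQuantityMatrix | pd.DataFrame) -> GenormResult:
    """Compute the stability measure M for every gene in the current set.

    ``M_j = mean_{k != j} SD_samples( log2(rq_j / rq_k) )``.
    """
    mat = rq.rq if isinstance(rq, RelativeQuantityMatrix) else rq
    if len(mat.index) < 2:
        raise InputError("geNorm needs at least 2 genes")
    if len(mat.columns) < 2:
        raise InputError("geNorm needs at least 2 samples (SD undefined otherwise)")
    if (mat.to_numpy() <= 0).any():
        raise InputError("relative quantities must be strictly positive")
    log_rq = np.log2(mat)
    vjk = _pairwise_log_sd(log_rq)
    n = len(mat.index)
    m = (vjk.sum(axis=1)) / (n - 1)  # diagonal is zero, mean over k != j
    return GenormResult(m=m, pairwise_sd=vjk)


def genorm_rank(rq: RelativeQuantityMatrix | pd.DataFrame) -> GenormResult:
    """Stepwise exclusion of the least stable gene until two remain.

    Ties on the maximum M are broken by removing the gene that occurs
    later in input order, making the procedure deterministic.
    """
    mat = rq.rq if isinstance(rq, RelativeQuantityMatrix) else rq
    if len(mat.index) < 2:
        raise InputError("geNorm ranking needs at least 2 genes")
    rounds: list[pd.Series] = []
    exclusion: list[str] = []
    current = mat
    first = genorm_m(current)
    rounds.append(first.m)
    while len(current.index) > 2:
        m = rounds[-1]
        worst_val = m.max()
        # later-in-input-order tie break: scan from the end
        worst = next(g for g in reversed(list(m.index)) if m[g] == worst_val)
        exclusion.append(worst)
        current = current.drop(index=worst)
        rounds.append(genorm_m(current).m)
    final = tuple(current.index)
    return GenormResult(
        m=first.m,
        pairwise_sd=first.pairwise_sd,
        exclusion_order=exclusion,
        rounds=rounds,
        final_pair=final,  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# Normalization factors and pairwise variation
# ---------------------------------------------------------------------------

@dataclass
class PairwiseVariationSeries:
    """NF_n per sample, the V_{n/n+1} series and the optimal gene count.

    ``no_v_below_cutoff`` is set when no V in the series falls below the
    cutoff; ``optimal_n`` is then the total number of genes.
    """

    nf: pd.DataFrame            # samples × n (columns n = 2 .. n_genes)
    v: pd.Series                # index n = 2 .. n_genes-1; V_{n/n+1}
    cutoff: float
    optimal_n: int
    no_v_below_cutoff: bool
    gene_order: list[str]       # most to least stable


def optimal_gene_count(
    v: Mapping[int, float] | Sequence[float], cutoff: float = DEFAULT_V_CUTOFF
) -> tuple[int, bool]:
    """Apply the V-cutoff rule to a V_{n/n+1} series.

    ``v`` maps n to V_{n/n+1} (a bare sequence is taken to start at
    n = 2).  Returns ``(optimal_n, no_v_below_cutoff)``: the smallest
    n ≥ 2 with ``V_{n/n+1} < cutoff``, scanning upward; if none qualifies,
    optimal_n is the largest n+1 seen and the flag is set.
    """
    if isinstance(v, Mapping):
        items = sorted(v.items())
    else:
        items = list(enumerate(v, start=2))
    if not items:
        raise InputError("empty pairwise-variation series")
    for n, val in items:
        if val < cutoff:
            return n, False
    return items[-1][0] + 1, True


def pairwise_variation(
    rq: RelativeQuantityMatrix | pd.DataFrame,
    ranking: GenormResult | None = None,
    cutoff: float = DEFAULT_V_CUTOFF,
) -> PairwiseVariationSeries:
    """Compute NF_n, the V_{n/n+1} series and the optimal gene count.

    Genes are taken most→least stable from ``ranking`` (computed here if
    omitted).  ``NF_n`` is the per-sample geometric mean of the top *n*
    genes' rq; ``V_{n/n+1}`` the sample SD of ``log2(NF_n/NF_{n+1})``.
    """
    mat = rq.rq if isinstance(rq, RelativeQuantityMatrix) else rq
    if len(mat.index) < 3:
        raise InputError("pairwise variation needs at least 3 genes")
    if ranking is None or ranking.final_pair is None:
        ranking = genorm_rank(mat)
    order = ranking.stability_order()
    log_rq = np.log2(mat.loc[order].to_numpy())
    n_genes = len(order)
    # log2(NF_n) = mean of the top-n genes' log2 rq, per sample
    log_nf = np.cumsum(log_rq, axis=0) / np.arange(1, n_genes + 1)[:, None]
    nf = pd.DataFrame(
        np.power(2.0, log_nf[1:]).T, index=mat.columns,
        columns=range(2, n_genes + 1),
    )
    diffs = log_nf[1:-1] - log_nf[2:]          # log2(NF_n / NF_{n+1}), n = 2..G-1
    v_vals = diffs.std(axis=1, ddof=1)
    v = pd.Series(v_vals, index=range(2, n_genes))
    optimal_n, flag = optimal_gene_count(dict(v.items()), cutoff)
    return PairwiseVariationSeries(
        nf=nf, v=v, cutoff=cutoff, optimal_n=optimal_n,
        no_v_below_cutoff=flag, gene_order=order,
    )
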