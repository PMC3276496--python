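"""Transcriptome diversity, gene specificity and specialization.

Given relative frequencies p_ij (gene i, condition j; columns sum to 1)
over t conditions and G genes, this module computes the
information-theoretic summary statistics of a multi-condition expression
experiment:

* diversity      H_j   = -sum_i p_ij log(p_ij)            (Shannon entropy
  of condition j's transcriptome; 0 <= H_j <= log G),
* specificity    S_i   = (1/t) sum_j (p_ij/pbar_i) log(p_ij/pbar_i)
  with pbar_i = (1/t) sum_j p_ij  (0 for a gene expressed uniformly
  across conditions, log t for a gene exclusive to one condition),
* specialization delta_j = sum_i p_ij S_i                 (expression-
  weighted average specificity of condition j's transcriptome),

all in bits by default (log base 2; the base is configurable and every
statistic scales by 1/log2(base)).  Terms with p_ij = 0 contribute 0.

The three quantities are tied together by the mutual information between
gene identity and condition under a uniform condition prior:

    MI = (1/t) sum_j sum_i p_ij log(p_ij / pbar_i)
       = sum_i pbar_i S_i  =  (1/t) sum_j delta_j,

an algebraic identity this module also evaluates as a numerical
self-check (both residuals are reported).

Entropies are plug-in (maximum-likelihood) estimates and therefore
biased downward at finite sequencing depth, to first order by
(G_observed - 1)/(2 N ln 2) bits; the Miller-Madow correction is
available behind a flag, and :func:`bootstrap_stats` quantifies the
count-sampling uncertainty by multinomial resampling.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .counts_io import CountMatrix
from .diffexpr import FrequencyMatrix, to_frequencies

__all__ = [
    "TranscriptomeStats",
    "transcriptome_diversity",
    "gene_specificity",
    "transcriptome_specialization",
    "mi_decomposition",
    "transcriptome_stats",
    "bootstrap_stats",
]


def _log(x: np.ndarray, base: float) -> np.ndarray:
    return np.log2(x) / np.log2(base)


@dataclasses.dataclass
class TranscriptomeStats:
    """Per-condition (Hj, deltaj), per-gene Si, and the MI decomposition."""

    condition_ids: list[str]
    Hj: pd.Series  # diversity per condition
    deltaj: pd.Series  # specialization per condition
    Si: pd.Series  # specificity per gene (NaN where pbar_i = 0)
    p_bar: pd.Series  # mean frequency per gene over conditions
    MI: float
    log_base: float
    t: int
    G: int

    @property
    def residual_gene(self) -> float:
        """| MI - sum_i pbar_i Si |  (gene-side identity)."""
        return float(
            abs(self.MI - math.fsum(self.p_bar * self.Si.fillna(0.0)))
        )

    @property
    def residual_condition(self) -> float:
        """| MI - mean_j deltaj |  (condition-side identity)."""
        return float(abs(self.MI - float(self.deltaj.mean())))

    def to_dict(self) -> dict:
        return {
            "log_base": self.log_base,
            "t": self.t,
            "G": self.G,
            "MI": self.MI,
            "residual_gene": self.residual_gene,
            "residual_condition": self.residual_condition,
            "per_condition": {
                c: {"Hj": float(self.Hj[c]), "deltaj": float(self.deltaj[c])}
                for c in self.condition_ids
            },
        }


def transcriptome_diversity(
    f: FrequencyMatrix | pd.DataFrame,
    log_base: float = 2.0,
    miller_madow: bool = False,
    depths: pd.Series | None = None,
) -> pd.Series:
    """Shannon entropy H_j of each condition's frequency distribution.

    ``miller_madow=True`` adds the first-order bias correction
    (m_j - 1)/(2 N_j ln(base)), where m_j is the number of genes observed
    in condition j; it requires ``depths`` (per-library read totals).
    """
    freqs = f.freqs if isinstance(f, FrequencyMatrix) else f
    p = freqs.to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * _log(np.where(p > 0, p, 1.0), log_base), 0.0)
    # fsum: exactly rounded, so the result is independent of gene order
    h = -np.array([math.fsum(col) for col in plogp.T])
    if miller_madow:
        if depths is None:
            raise ValueError("Miller-Madow correction requires library depths")
        m_obs = (p > 0).sum(axis=0)
        n = depths.reindex(freqs.columns).to_numpy(float)
        h = h + (m_obs - 1) / (2.0 * n * np.log(log_base))
    return pd.Series(h, index=freqs.columns, name="Hj")


def gene_specificity(
    f: FrequencyMatrix | pd.DataFrame,
    log_base: float = 2.0,
    condition_weights: pd.Series | None = None,
) -> pd.Series:
    """Specificity S_i of each gene's across-condition profile.

    With uniform condition weights (default, weight 1/t each),
    S_i ranges from 0 (identical relative frequency in every condition)
    to log(t) (expression confined to a single condition).  Genes with
    pbar_i = 0 get NaN.  ``condition_weights`` switches to a non-uniform
    prior over conditions (e.g. read-depth weights); weights are
    normalized to sum to 1.
    """
    freqs = f.freqs if isinstance(f, FrequencyMatrix) else f
    t = freqs.shape[1]
    if t < 2:
        raise ValueError("specificity requires at least 2 conditions")
    p = freqs.to_numpy(float)
    if condition_weights is None:
        w = np.full(t, 1.0 / t)
    else:
        w = condition_weights.reindex(freqs.columns).to_numpy(float)
        w = w / w.sum()
    pbar = p @ w
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p / pbar[:, None]
        terms = np.where(
            p > 0, ratio * _log(np.where(p > 0, ratio, 1.0), log_base), 0.0
        )
    s = terms @ w
    s[pbar == 0] = np.nan
    return pd.Series(s, index=freqs.index, name="Si")


def transcriptome_specialization(
    f: FrequencyMatrix | pd.DataFrame, Si: pd.Series
) -> pd.Series:
    """Specialization delta_j = sum_i p_ij S_i per condition.

    Genes with undefined specificity (never expressed) have p_ij = 0
    everywhere and contribute nothing.
    """
    freqs = f.freqs if isinstance(f, FrequencyMatrix) else f
    if not freqs.index.equals(Si.index):
        raise ValueError("Si index does not match the frequency matrix genes")
    s = Si.fillna(0.0).to_numpy(float)
    terms = freqs.to_numpy(float) * s[:, None]
    return pd.Series(
        [math.fsum(col) for col in terms.T],  # gene-order independent
        index=freqs.columns,
        name="deltaj",
    )


def transcriptome_stats(
    source: CountMatrix | FrequencyMatrix,
    log_base: float = 2.0,
    condition_weights: pd.Series | None = None,
    miller_madow: bool = False,
) -> TranscriptomeStats:
    """Compute the full (Hj, Si, deltaj, MI) summary in one pass."""
    if isinstance(source, CountMatrix):
        depths = source.depths
        f = to_frequencies(source)
    else:
        depths = None
        f = source
    freqs = f.freqs
    t = freqs.shape[1]
    if condition_weights is None:
        w = pd.Series(np.full(t, 1.0 / t), index=freqs.columns)
    else:
        w = condition_weights.reindex(freqs.columns).astype(float)
        w = w / w.sum()
    Hj = transcriptome_diversity(
        f, log_base, miller_madow=miller_madow, depths=depths
    )
    Si = gene_specificity(f, log_base, condition_weights=condition_weights)
    deltaj = transcriptome_specialization(f, Si)
    p_bar = pd.Series(
        freqs.to_numpy(float) @ w.to_numpy(float), index=freqs.index, name="p_bar"
    )
    mi = float((deltaj * w).sum())
    return TranscriptomeStats(
        condition_ids=list(freqs.columns),
        Hj=Hj,
        deltaj=deltaj,
        Si=Si,
        p_bar=p_bar,
        MI=mi,
        log_base=log_base,
        t=t,
        G=freqs.shape[0],
    )


def mi_decomposition(stats: TranscriptomeStats) -> dict:
    """Mutual information and the two identity residuals.

    MI (gene identity vs condition, uniform condition prior) must equal
    both sum_i pbar_i S_i and mean_j delta_j; the residuals measure how
    far floating-point evaluation strays from the algebraic identity.
    """
    return {
        "MI": stats.MI,
        "residual_gene": stats.residual_gene,
        "residual_condition": stats.residual_condition,
    }


def bootstrap_stats(
    m: CountMatrix,
    B: int = 200,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Percentile bootstrap intervals for (Hj, deltaj) per condition.

    Each replicate redraws every library as a multinomial of its observed
    depth N_j from the observed frequencies p_hat_.j, then recomputes the
    statistics.  Returns a DataFrame indexed by condition with columns
    Hj, Hj_lo, Hj_hi, deltaj, deltaj_lo, deltaj_hi.  Deterministic given
    the seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    base_stats = transcriptome_stats(m, log_base=log_base)
    counts = m.counts.to_numpy()
    depths = counts.sum(axis=0)
    probs = counts / depths
    H_reps = np.empty((B, m.counts.shape[1]))
    d_reps = np.empty((B, m.counts.shape[1]))
    for b in range(B):
        resampled = np.column_stack(
            [
                rng.multinomial(depths[j], probs[:, j])
                for j in range(counts.shape[1])
            ]
        )
        fb = pd.DataFrame(
            resampled / depths, index=m.counts.index, columns=m.counts.columns
        )
        H_reps[b] = transcriptome_diversity(fb, log_base).to_numpy()
        Si = gene_specificity(fb, log_base)
        d_reps[b] = transcriptome_specialization(fb, Si).to_numpy()
    alpha = (1.0 - level) / 2.0
    q = [100 * alpha, 100 * (1 - alpha)]
    H_lo, H_hi = np.percentile(H_reps, q, axis=0)
    d_lo, d_hi = np.percentile(d_reps, q, axis=0)
    return pd.DataFrame(
        {
            "Hj": base_stats.Hj,
            "Hj_lo": H_lo,
            "Hj_hi": H_hi,
            "deltaj": base_stats.deltaj,
            "deltaj_lo": d_lo,
            "deltaj_hi": d_hi,
        },
        index=m.counts.columns,
    )
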