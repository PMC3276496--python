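"""Fold-change differential-expression calling and overlap partitioning.

Counts are first converted to per-library relative frequencies
p_ij = x_ij / N_j, so that calls are invariant to sequencing depth.  For
each treatment j the expression ratio of gene g against the untreated
control is r_gj = p_gj / p_g,control, and the gene is called

* ``up``        when r_gj >= up_threshold   (default 2.0, inclusive),
* ``down``      when r_gj <= down_threshold (default 0.5, inclusive),
* ``unchanged`` otherwise,
* ``excluded``  when the gene has fewer than ``min_count`` reads in both
  of the compared libraries (a 2-fold call from 1-vs-0 reads is sampling
  noise, not regulation).

A gene expressed in the treatment but absent from the control has an
infinite ratio and is called up provided it clears the read filter
("sentinel" policy); a "pseudocount" policy that adds 1/N_j to both
frequencies is available instead.

The per-treatment calls are then collapsed into sign patterns — one
symbol of {+, -, 0} per treatment — and genes are partitioned by
pattern, yielding the familiar two-block overlap table (upregulated
patterns over {+, 0}, downregulated patterns over {-, 0}).
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .counts_io import CountMatrix

__all__ = [
    "FrequencyMatrix",
    "DECallMatrix",
    "OverlapPartition",
    "to_frequencies",
    "expression_ratio",
    "call_de",
    "compute_de",
    "overlap_partition",
]

UP, DOWN, UNCHANGED, EXCLUDED = "up", "down", "unchanged", "excluded"
_SYMBOL = {UP: "+", DOWN: "-", UNCHANGED: "0"}

ZeroPolicy = Literal["sentinel", "pseudocount"]


@dataclasses.dataclass
class FrequencyMatrix:
    """Per-condition relative frequencies p_ij; every column sums to 1."""

    freqs: pd.DataFrame
    control_id: str

    @property
    def gene_ids(self) -> list[str]:
        return list(self.freqs.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.freqs.columns)

    @property
    def n_conditions(self) -> int:
        return self.freqs.shape[1]


@dataclasses.dataclass
class DECallMatrix:
    """Per-gene, per-treatment expression ratios and categorical calls."""

    ratios: pd.DataFrame  # genes x treatments, float (inf allowed, NaN = excluded)
    calls: pd.DataFrame  # genes x treatments, values in {up,down,unchanged,excluded}
    up_threshold: float
    down_threshold: float

    @property
    def gene_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def treatment_ids(self) -> list[str]:
        return list(self.calls.columns)

    def symbols(self) -> pd.DataFrame:
        """Calls as {+, -, 0} symbols; excluded cells become NA."""
        return self.calls.replace(_SYMBOL).where(self.calls != EXCLUDED)


@dataclasses.dataclass
class OverlapPartition:
    """Partition of genes by their sign pattern over chosen treatments."""

    treatments_considered: list[str]
    pattern_counts: dict[tuple[str, ...], int]
    n_excluded: int

    @property
    def n_genes(self) -> int:
        return sum(self.pattern_counts.values()) + self.n_excluded

    def count(self, pattern: Sequence[str]) -> int:
        return self.pattern_counts.get(tuple(pattern), 0)

    def direction_tables(self) -> dict[str, pd.DataFrame]:
        """Two-block rendering: upregulated patterns (over {+,0}, not
        all-zero) then downregulated (over {-,0}), each ordered with the
        all-signed pattern first, then by number of signed symbols
        descending, then positionally."""
        out = {}
        for block, sym in (("upregulated", "+"), ("downregulated", "-")):
            rows = []
            for pat, n in self.pattern_counts.items():
                if sym in pat and set(pat) <= {sym, "0"}:
                    rows.append((pat, n))
            rows.sort(
                key=lambda r: (
                    -sum(s != "0" for s in r[0]),
                    tuple(0 if s != "0" else 1 for s in r[0]),
                )
            )
            out[block] = pd.DataFrame(
                {
                    "pattern": ["".join(p) for p, _ in rows],
                    **{
                        t: [p[i] for p, _ in rows]
                        for i, t in enumerate(self.treatments_considered)
                    },
                    "genes": [n for _, n in rows],
                }
            )
        return out

    def to_dict(self) -> dict:
        return {
            "treatments_considered": self.treatments_considered,
            "pattern_counts": {
                "".join(k): v for k, v in self.pattern_counts.items()
            },
            "n_excluded": self.n_excluded,
            "n_genes": self.n_genes,
        }


def to_frequencies(m: CountMatrix) -> FrequencyMatrix:
    """Normalize counts column-wise: p_ij = x_ij / N_j."""
    totals = m.counts.sum(axis=0)
    if (totals <= 0).any():
        empty = list(totals.index[totals <= 0])
        raise ValueError(f"cannot normalize empty libraries: {empty}")
    return FrequencyMatrix(
        freqs=m.counts.astype(float) / totals, control_id=m.control_id
    )


def expression_ratio(
    f: FrequencyMatrix,
    treatment: str,
    control: str | None = None,
    policy: ZeroPolicy = "sentinel",
    pseudo: float | None = None,
) -> pd.Series:
    """Per-gene frequency ratio r_g = p_g,treatment / p_g,control.

    Under the default ``sentinel`` policy, a zero control frequency with
    positive treatment frequency yields ``inf`` (the limit of the ratio as
    the control frequency goes to 0 from above) and a gene absent from
    both libraries yields ``NaN``.  Under ``pseudocount``, ``pseudo`` (a
    frequency, by default the smallest resolvable one for each library —
    it is the caller's job to pass 1/N) is added to both numerator and
    denominator, so every ratio is finite.
    """
    control = f.control_id if control is None else control
    for label in (treatment, control):
        if label not in f.freqs.columns:
            raise KeyError(f"unknown condition {label!r}")
    if treatment == control:
        raise ValueError("treatment and control must differ")
    p_t = f.freqs[treatment].to_numpy(float)
    p_c = f.freqs[control].to_numpy(float)
    if policy == "pseudocount":
        eps = 1e-9 if pseudo is None else float(pseudo)
        r = (p_t + eps) / (p_c + eps)
    elif policy == "sentinel":
        with np.errstate(divide="ignore", invalid="ignore"):
            r = p_t / p_c
        # 0/0 -> NaN already; x/0 -> inf already
    else:
        raise ValueError(f"unknown zero policy {policy!r}")
    return pd.Series(r, index=f.freqs.index, name=treatment)


def call_de(
    ratios: pd.Series | pd.DataFrame,
    up_threshold: float = 2.0,
    down_threshold: float = 0.5,
    excluded: pd.Series | pd.DataFrame | None = None,
):
    """Categorize ratios with inclusive thresholds.

    ``up`` iff r >= up_threshold, ``down`` iff r <= down_threshold,
    ``unchanged`` otherwise; NaN ratios and any position flagged in
    ``excluded`` become ``excluded``.
    """
    if not (up_threshold > 1.0 > down_threshold > 0.0):
        raise ValueError(
            "thresholds must satisfy up > 1 > down > 0, got "
            f"up={up_threshold}, down={down_threshold}"
        )
    r = ratios.astype(float)
    values = np.full(r.shape, UNCHANGED, dtype=object)
    arr = r.to_numpy(float)
    values[arr >= up_threshold] = UP
    values[arr <= down_threshold] = DOWN
    mask = np.isnan(arr)
    if excluded is not None:
        mask = mask | excluded.to_numpy(bool)
    values[mask] = EXCLUDED
    if isinstance(r, pd.Series):
        return pd.Series(values, index=r.index, name=r.name)
    return pd.DataFrame(values, index=r.index, columns=r.columns)


def compute_de(
    m: CountMatrix,
    up_threshold: float = 2.0,
    down_threshold: float = 0.5,
    policy: ZeroPolicy = "sentinel",
    min_count: int = 3,
    ratio_on: Literal["frequencies", "counts"] = "frequencies",
) -> DECallMatrix:
    """Full DE calling for every treatment against the control.

    ``ratio_on="counts"`` skips library-size normalization (a sensitivity
    mode: ratios are taken on raw counts, so unequal depths shift calls).
    ``min_count`` excludes genes with fewer than that many reads in both
    of the two compared libraries; set 0 to disable (genes absent from
    both libraries are still excluded, their ratio being undefined).
    """
    m.require_valid()
    if ratio_on == "frequencies":
        f = to_frequencies(m)
    else:
        f = FrequencyMatrix(freqs=m.counts.astype(float), control_id=m.control_id)
    treatments = m.treatment_ids
    ratios = {}
    excluded = {}
    ctrl_counts = m.counts[m.control_id]
    for t in treatments:
        pseudo = 1.0 / float(m.depths[t]) if ratio_on == "frequencies" else 1.0
        ratios[t] = expression_ratio(
            f, t, m.control_id, policy=policy, pseudo=pseudo
        )
        excluded[t] = (
            m.counts[t].combine(ctrl_counts, max) < min_count
            if min_count > 0
            else (m.counts[t] + ctrl_counts) == 0
        )
    ratio_df = pd.DataFrame(ratios)
    excl_df = pd.DataFrame(excluded)
    calls = call_de(ratio_df, up_threshold, down_threshold, excluded=excl_df)
    return DECallMatrix(
        ratios=ratio_df,
        calls=calls,
        up_threshold=up_threshold,
        down_threshold=down_threshold,
    )


def overlap_partition(
    d: DECallMatrix, treatments: Sequence[str] | None = None
) -> OverlapPartition:
    """Partition genes by sign pattern over the chosen treatments.

    Every gene with no excluded call among the chosen treatments
    contributes to exactly one pattern (the all-zero pattern collects the
    everywhere-unchanged genes); genes excluded in any chosen treatment
    are tallied separately, so pattern counts sum to the number of
    non-excluded genes.
    """
    treatments = list(d.treatment_ids if treatments is None else treatments)
    if not treatments:
        raise ValueError("treatment set must be non-empty")
    for t in treatments:
        if t not in d.calls.columns:
            raise KeyError(f"unknown treatment {t!r}")
    sub = d.calls[treatments]
    excluded_mask = (sub == EXCLUDED).any(axis=1)
    symbols = sub[~excluded_mask].replace(_SYMBOL)
    counts: dict[tuple[str, ...], int] = {}
    grouped = symbols.groupby(treatments, sort=False).size() if treatments else None
    for pattern, n in grouped.items():
        key = (pattern,) if isinstance(pattern, str) else tuple(pattern)
        counts[key] = int(n)
    counts = dict(sorted(counts.items()))  # canonical order, gene-order free
    return OverlapPartition(
        treatments_considered=treatments,
        pattern_counts=counts,
        n_excluded=int(excluded_mask.sum()),
    )
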