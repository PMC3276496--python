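"""Ground-truth expression distributions and multinomial count libraries.

This module simulates the data-generating process behind a multiplexed
tag-count expression experiment: each library (condition) j is one
multinomial draw of N_j reads from a condition-specific frequency vector
p_.j over G genes.  The control column is drawn from a heavy-tailed
baseline abundance distribution (log-normal by default, the norm for
cDNA tag libraries); each treatment column is derived from the baseline
by multiplying a chosen module of induced genes by a fold factor > 1 and
a module of repressed genes by a factor in (0, 1), then renormalizing to
sum to 1.  Because of the renormalization the realized treatment/control
frequency ratio of a module gene is fold / Z_j, where
Z_j = sum_i baseline_i * fold_ij is the renormalization constant — a
closed, auditable transformation recorded per treatment.

Every stage is deterministic given the seed: a single global seed is
expanded into independent substreams (truth, sampling, replicates) via
``numpy.random.SeedSequence.spawn``.

Defaults emulate a six-condition design of ~44k genes and ~160k reads
per library (~955k reads in total), with 0.5% of genes induced 10-fold
and 0.5% repressed 10-fold per treatment.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counts_io import CountMatrix

__all__ = [
    "ModuleSpec",
    "SyntheticTruth",
    "RecoveryReport",
    "make_truth",
    "sample_libraries",
    "recovery_experiment",
    "counts_from_patterns",
]

DEFAULT_CONDITIONS = ("C", "E", "JA", "W", "F", "S")
DEFAULT_N_GENES = 44_156
DEFAULT_DEPTH = 159_207  # ~955k reads split evenly over six libraries

BASELINE, INDUCED, REPRESSED = "baseline", "induced", "repressed"


@dataclasses.dataclass(frozen=True)
class ModuleSpec:
    """Per-treatment DE module: fractions of genes and their fold factors."""

    frac_induced: float = 0.005
    frac_repressed: float = 0.005
    induced_fold: float = 10.0
    repressed_fold: float = 0.1

    def validate(self) -> None:
        if not (0 <= self.frac_induced and 0 <= self.frac_repressed):
            raise ValueError("module fractions must be non-negative")
        if self.frac_induced + self.frac_repressed > 1:
            raise ValueError(
                "induced + repressed fractions exceed 1: "
                f"{self.frac_induced} + {self.frac_repressed}"
            )
        if self.induced_fold <= 1:
            raise ValueError("induced_fold must exceed 1")
        if not (0 < self.repressed_fold < 1):
            raise ValueError("repressed_fold must lie in (0, 1)")


@dataclasses.dataclass
class SyntheticTruth:
    """Known expression distributions plus the module bookkeeping.

    ``fold_factors`` holds the pre-normalization multiplicative effect of
    every (gene, treatment) pair (1.0 outside the modules);
    ``renorm_constants`` the per-treatment Z_j, so the realized
    treatment/control frequency ratio of gene i is
    fold_factors[i, j] / Z_j.
    """

    true_freqs: pd.DataFrame  # genes x conditions, columns sum to 1
    control_id: str
    fold_factors: pd.DataFrame  # genes x treatments
    renorm_constants: pd.Series  # Z_j per treatment
    depths: pd.Series  # N_j per condition
    seed: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.true_freqs.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.true_freqs.columns)

    @property
    def treatment_ids(self) -> list[str]:
        return [c for c in self.condition_ids if c != self.control_id]

    def module_assignment(self) -> pd.DataFrame:
        """Category per (gene, treatment): baseline / induced / repressed."""
        cats = pd.DataFrame(
            BASELINE, index=self.fold_factors.index,
            columns=self.fold_factors.columns, dtype=object,
        )
        cats[self.fold_factors > 1] = INDUCED
        cats[self.fold_factors < 1] = REPRESSED
        return cats

    def realized_ratios(self) -> pd.DataFrame:
        """True treatment/control frequency ratios after renormalization."""
        return self.fold_factors / self.renorm_constants


def _baseline_frequencies(
    n_genes: int, rng: np.random.Generator, model: str, sigma: float
) -> np.ndarray:
    if model == "lognormal":
        raw = rng.lognormal(mean=0.0, sigma=sigma, size=n_genes)
    elif model == "zipf":
        ranks = rng.permutation(n_genes) + 1
        raw = 1.0 / ranks.astype(float)
    else:
        raise ValueError(f"unknown baseline model {model!r}")
    return raw / raw.sum()


def make_truth(
    n_genes: int = DEFAULT_N_GENES,
    condition_ids: Sequence[str] = DEFAULT_CONDITIONS,
    control_id: str = "C",
    modules: Mapping[str, ModuleSpec] | ModuleSpec | None = None,
    baseline_model: str = "lognormal",
    sigma: float = 2.0,
    depths: int | Mapping[str, int] = DEFAULT_DEPTH,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw a ground-truth frequency matrix with known DE modules.

    ``modules`` may be a single :class:`ModuleSpec` applied to every
    treatment, a mapping from treatment id to spec (missing treatments
    get empty modules), or None for the default spec everywhere.
    Module membership is drawn independently per treatment.
    """
    condition_ids = list(condition_ids)
    if control_id not in condition_ids:
        raise ValueError(f"control {control_id!r} not in {condition_ids}")
    treatments = [c for c in condition_ids if c != control_id]
    if isinstance(modules, ModuleSpec) or modules is None:
        spec = modules or ModuleSpec()
        modules = {t: spec for t in treatments}
    for t, sp in modules.items():
        if t not in treatments:
            raise ValueError(f"module treatment {t!r} is not a treatment")
        sp.validate()

    ss = np.random.SeedSequence(seed)
    rng_base, rng_mod = (np.random.default_rng(s) for s in ss.spawn(2))
    baseline = _baseline_frequencies(n_genes, rng_base, baseline_model, sigma)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]

    folds = pd.DataFrame(1.0, index=gene_ids, columns=treatments)
    freqs = {control_id: baseline}
    renorm = {}
    for t in treatments:
        sp = modules.get(t, ModuleSpec(0.0, 0.0))
        n_up = int(round(sp.frac_induced * n_genes))
        n_dn = int(round(sp.frac_repressed * n_genes))
        chosen = rng_mod.choice(n_genes, size=n_up + n_dn, replace=False)
        fold = np.ones(n_genes)
        fold[chosen[:n_up]] = sp.induced_fold
        fold[chosen[n_up:]] = sp.repressed_fold
        if np.all(fold == 1.0):  # empty module: treatment equals control
            freqs[t] = baseline
            z = 1.0
        else:
            scaled = baseline * fold
            z = scaled.sum()
            freqs[t] = scaled / z
        folds[t] = fold
        renorm[t] = z

    if isinstance(depths, Mapping):
        depth_series = pd.Series(
            {c: int(depths[c]) for c in condition_ids}, dtype=np.int64
        )
    else:
        depth_series = pd.Series(
            int(depths), index=condition_ids, dtype=np.int64
        )
    if (depth_series <= 0).any():
        raise ValueError("library depths must be positive")

    return SyntheticTruth(
        true_freqs=pd.DataFrame(freqs, index=gene_ids)[condition_ids],
        control_id=control_id,
        fold_factors=folds,
        renorm_constants=pd.Series(renorm, dtype=float),
        depths=depth_series,
        seed=seed,
    )


def sample_libraries(
    truth: SyntheticTruth,
    depths: int | Mapping[str, int] | None = None,
    seed: int | np.random.Generator = 0,
) -> CountMatrix:
    """One multinomial library per condition; column sums equal depths."""
    if depths is None:
        depth_series = truth.depths
    elif isinstance(depths, Mapping):
        depth_series = pd.Series(
            {c: int(depths[c]) for c in truth.condition_ids}
        )
    else:
        depth_series = pd.Series(int(depths), index=truth.condition_ids)
    if (depth_series <= 0).any():
        raise ValueError("library depths must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cols = {}
    for cond in truth.condition_ids:
        p = truth.true_freqs[cond].to_numpy(float)
        cols[cond] = rng.multinomial(int(depth_series[cond]), p / p.sum())
    counts = pd.DataFrame(cols, index=truth.true_freqs.index, dtype=np.int64)
    return CountMatrix(counts=counts, control_id=truth.control_id)


@dataclasses.dataclass
class RecoveryReport:
    """How well the pipeline recovers known truth over replicates."""

    per_condition: pd.DataFrame  # Hj/deltaj bias and RMSE per condition
    de_rates: dict  # sensitivity, specificity, false-discovery proportion
    replicates: int
    seed: int
    depths: dict

    def to_dict(self) -> dict:
        return {
            "per_condition": {
                str(c): {k: float(v) for k, v in row.items()}
                for c, row in self.per_condition.iterrows()
            },
            "de_rates": self.de_rates,
            "replicates": self.replicates,
            "seed": self.seed,
            "depths": self.depths,
        }


def recovery_experiment(
    truth_params: Mapping | None = None,
    depths: int | Mapping[str, int] | None = None,
    replicates: int = 20,
    seed: int = 0,
    up_threshold: float = 2.0,
    down_threshold: float = 0.5,
    min_count: int = 3,
    detectable_freq: float = 1e-4,
) -> RecoveryReport:
    """Simulate, re-estimate, and score: the oracle loop for the pipeline.

    Per replicate a fresh truth is drawn (``truth_params`` are keyword
    arguments for :func:`make_truth`; the replicate seed is injected),
    libraries are sampled, and the estimators are run.  Scores:

    * per condition, bias and RMSE of the plug-in diversity H_j and
      specialization delta_j against their values on the true
      frequencies;
    * DE confusion rates against the module assignment — sensitivity
      (induced or repressed genes called in the matching direction),
      the same restricted to genes whose control frequency is at least
      ``detectable_freq``, specificity, and the false-discovery
      proportion among up/down calls.
    """
    from .diffexpr import DOWN, UP, compute_de
    from .infotheo import transcriptome_stats

    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    params = dict(truth_params or {})
    params.pop("seed", None)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(replicates)

    H_err, d_err = [], []
    tp = fp = fn = tn = 0
    tp_det = fn_det = 0
    cond_index = None
    for rep, child in enumerate(child_seeds):
        truth_seed, sample_seed = child.spawn(2)
        truth = make_truth(
            seed=int(truth_seed.generate_state(1)[0] % (2**31)), **params
        )
        m = sample_libraries(
            truth, depths=depths, seed=np.random.default_rng(sample_seed)
        )
        cond_index = truth.condition_ids

        true_stats = transcriptome_stats(
            _as_freq(truth.true_freqs, truth.control_id)
        )
        est_stats = transcriptome_stats(m)
        H_err.append((est_stats.Hj - true_stats.Hj).to_numpy())
        d_err.append((est_stats.deltaj - true_stats.deltaj).to_numpy())

        de = compute_de(
            m,
            up_threshold=up_threshold,
            down_threshold=down_threshold,
            min_count=min_count,
        )
        cats = truth.module_assignment()
        ctrl_freq = (
            truth.true_freqs[truth.control_id]
        )
        detectable = ctrl_freq >= detectable_freq
        for t in truth.treatment_ids:
            called = de.calls[t]
            truly_up = cats[t] == INDUCED
            truly_dn = cats[t] == REPRESSED
            truly_de = truly_up | truly_dn
            hit = (truly_up & (called == UP)) | (truly_dn & (called == DOWN))
            tp += int(hit.sum())
            fn += int((truly_de & ~hit).sum())
            called_de = called.isin([UP, DOWN])
            fp += int((~truly_de & called_de).sum())
            tn += int((~truly_de & ~called_de).sum())
            tp_det += int((hit & detectable).sum())
            fn_det += int((truly_de & ~hit & detectable).sum())

    H_err = np.array(H_err)
    d_err = np.array(d_err)
    per_condition = pd.DataFrame(
        {
            "Hj_bias": H_err.mean(axis=0),
            "Hj_rmse": np.sqrt((H_err**2).mean(axis=0)),
            "deltaj_bias": d_err.mean(axis=0),
            "deltaj_rmse": np.sqrt((d_err**2).mean(axis=0)),
        },
        index=cond_index,
    )
    n_called = tp + fp
    de_rates = {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "sensitivity_detectable": (
            tp_det / (tp_det + fn_det) if tp_det + fn_det else float("nan")
        ),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "false_discovery_proportion": (
            fp / n_called if n_called else float("nan")
        ),
        "detectable_freq": detectable_freq,
    }
    depths_used = (
        dict(depths)
        if isinstance(depths, Mapping)
        else {"all": depths if depths is not None else "truth-default"}
    )
    return RecoveryReport(
        per_condition=per_condition,
        de_rates=de_rates,
        replicates=replicates,
        seed=seed,
        depths=depths_used,
    )


def _as_freq(freqs: pd.DataFrame, control_id: str):
    from .diffexpr import FrequencyMatrix

    return FrequencyMatrix(freqs=freqs, control_id=control_id)


def counts_from_patterns(
    pattern_counts: Mapping[str, int],
    treatments: Sequence[str],
    control_id: str = "C",
    base_count: int = 40,
    up_factor: int = 4,
    down_factor: int = 4,
    total_depth: int = 200_000,
) -> CountMatrix:
    """Synthetic count matrix realizing prescribed sign-pattern multiplicities.

    A construction oracle for the overlap partition: for every pattern
    string (one of ``+ - 0`` per treatment) and requested gene count,
    genes are given ``base_count`` reads in the control and
    ``base_count * up_factor`` (for ``+``), ``base_count // down_factor``
    (for ``-``) or ``base_count`` (for ``0``) reads in each treatment.
    One filler gene per matrix pads every library to ``total_depth`` so
    that all depths are equal and frequency ratios equal count ratios;
    the filler's own ratios stay within the unchanged band provided
    ``total_depth`` is large relative to the patterned genes.

    The result is a synthetic stand-in with known partition structure,
    not data from any real experiment.
    """
    treatments = list(treatments)
    rows: dict[str, dict[str, int]] = {}
    k = 0
    for pattern, n in pattern_counts.items():
        if len(pattern) != len(treatments):
            raise ValueError(
                f"pattern {pattern!r} does not match {len(treatments)} treatments"
            )
        for _ in range(int(n)):
            row = {control_id: base_count}
            for sym, t in zip(pattern, treatments):
                if sym == "+":
                    row[t] = base_count * up_factor
                elif sym == "-":
                    row[t] = base_count // down_factor
                elif sym == "0":
                    row[t] = base_count
                else:
                    raise ValueError(f"bad symbol {sym!r} in {pattern!r}")
            rows[f"p{k:04d}"] = row
            k += 1
    df = pd.DataFrame.from_dict(rows, orient="index")[
        [control_id] + treatments
    ].astype(np.int64)
    filler = total_depth - df.sum(axis=0)
    if (filler <= 0).any():
        raise ValueError("total_depth too small for the requested patterns")
    ratio = filler / filler[control_id]
    if (ratio >= 2.0).any() or (ratio <= 0.5).any():
        raise ValueError(
            "filler gene would itself be called DE; raise total_depth"
        )
    df.loc["filler"] = filler.astype(np.int64)
    return CountMatrix(counts=df, control_id=control_id)
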