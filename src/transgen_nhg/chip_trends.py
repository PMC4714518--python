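"""Generation-delta analysis of ChIP signals and transgenerational trend calls.

Pol II (elongating, Ser2P) and H3K9me3 occupancy are quantified as RPKM
over gene bodies. The central quantities are per-gene generation ratios
(e.g. Pol II at 23C-G4 over 15C-G3), gene-set shift tests against the
genomic background (one-sided Wilcoxon), and two per-gene trend calls on
the six 23 °C generations:

* cumulative: positive Spearman rank correlation of expression with the
  generation index (one-sided p < 0.05) AND at least a 2-fold span from the
  first to the last 23 °C generation;
* persistent: post-stress (p15C) expression still >= 2x the 15 °C baseline.

"Trend of progressive increase" is not a formalized notion in the source
experiments; Spearman plus a fold-span guard is this package's documented
operationalization (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix
from .stats_core import spearman_trend, wilcoxon_one_sided

G23_SERIES = ("23C-G1", "23C-G2", "23C-G3", "23C-G4", "23C-G5", "23C-G6")


@dataclass
class TrendConfig:
    trend_p_cutoff: float = 0.05
    span_fold_cutoff: float = 2.0
    persistence_fold_cutoff: float = 2.0
    pseudocount: float = 0.1


def _column_for(signal: ExpressionMatrix, generation: str, genotype: str | None = None) -> pd.Series:
    cols = [
        s.sample_id
        for s in signal.samples
        if s.generation == generation and (genotype is None or s.genotype == genotype)
    ]
    if not cols:
        raise ValueError(f"generation {generation!r} absent from the signal matrix")
    return signal.values[cols].mean(axis=1)


def generation_delta(
    signal: ExpressionMatrix,
    gen_num: str,
    gen_den: str,
    pseudocount: float = 0.1,
    genotype: str | None = None,
) -> pd.Series:
    """Per-gene ratio of RPKM between two generations.

    ``ratio = (RPKM_num + c) / (RPKM_den + c)`` with pseudocount ``c``
    (default 0.1 RPKM) guarding silent genes.
    """
    num = _column_for(signal, gen_num, genotype)
    den = _column_for(signal, gen_den, genotype)
    ratio = (num + pseudocount) / (den + pseudocount)
    ratio.name = f"delta[{gen_num}/{gen_den}]"
    return ratio


def set_shift_test(
    deltas: pd.Series,
    gene_set: set[str],
    background: set[str] | None = None,
) -> tuple[float, float, float]:
    """Is a gene set's delta distribution shifted up against the background?

    Returns (set median, background median, one-sided Wilcoxon p for
    set > background). Background defaults to all genes in the delta vector.
    """
    in_set = deltas.index.isin(gene_set)
    if in_set.sum() < 2:
        raise ValueError("gene_set must have >= 2 members in the delta universe")
    if background is None:
        bg = deltas[~in_set]
    else:
        bg = deltas[deltas.index.isin(background - gene_set)]
    set_vals = deltas[in_set].to_numpy()
    bg_vals = bg.to_numpy()
    p = wilcoxon_one_sided(set_vals, bg_vals, alternative="greater")
    return float(np.median(set_vals)), float(np.median(bg_vals)), p


@dataclass
class TrendCall:
    gene_id: str
    trend_statistic: float
    trend_p: float
    span_fold: float
    cumulative: bool


def call_cumulative(
    series: pd.Series | np.ndarray,
    gene_id: str = "",
    config: TrendConfig = TrendConfig(),
) -> TrendCall:
    """Cumulative-activation call on the six 23 °C generations.

    ``series`` holds normalized expression for 23C-G1..23C-G6 in
    chronological order (six values).
    """
    values = np.asarray(series, dtype=float)
    if values.size != len(G23_SERIES):
        raise ValueError(f"need all {len(G23_SERIES)} heat generations, got {values.size}")
    rho, p = spearman_trend(values)
    first = values[0] + config.pseudocount
    last = values[-1] + config.pseudocount
    span = last / first
    cumulative = (rho > 0) and (p < config.trend_p_cutoff) and (span >= config.span_fold_cutoff)
    return TrendCall(gene_id, rho, p, float(span), bool(cumulative))


def call_persistent(
    p15_values: pd.Series | np.ndarray,
    baseline: float,
    config: TrendConfig = TrendConfig(),
) -> list[bool]:
    """Persistence call per post-stress generation.

    A p15C generation is persistent when its value is at least
    ``persistence_fold_cutoff`` times the 15 °C baseline mean (pseudocount
    applied to both sides).
    """
    base = float(baseline) + config.pseudocount
    if base <= 0:
        raise ValueError("baseline must be positive after pseudocount")
    values = np.asarray(p15_values, dtype=float) + config.pseudocount
    return [bool(v >= config.persistence_fold_cutoff * base) for v in values]


def trend_table(
    expression: pd.DataFrame,
    config: TrendConfig = TrendConfig(),
) -> pd.DataFrame:
    """Cumulative-trend calls for every row of a genes x generations table.

    ``expression`` columns must be the six 23 °C generation labels.
    """
    missing = [g for g in G23_SERIES if g not in expression.columns]
    if missing:
        raise ValueError(f"missing generations: {missing}")
    rows = []
    for gid, row in expression[list(G23_SERIES)].iterrows():
        call = call_cumulative(row.to_numpy(), gid, config)
        rows.append(
            {
                "gene_id": gid,
                "trend_statistic": call.trend_statistic,
                "trend_p": call.trend_p,
                "span_fold": call.span_fold,
                "cumulative": call.cumulative,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
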