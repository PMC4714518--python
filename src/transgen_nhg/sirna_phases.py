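"""Phase-based analysis of antisense siRNA expression.

The 12 generations are divided chronologically into four phases of three
generations each: phase I (15C-G1..G3), II (23C-G1..G3), III (23C-G4..G6)
and IV (p15C-G1..G3). For each phase, per-gene size-factor-normalized mean
antisense siRNA counts are compared between the wild type and the
*hrde-1* mutant with the NB exact test (2-fold, FDR <= 0.1 cutoffs), and
the resulting call sets are cross-tabulated against mRNA-level calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr_classify import ClassifyConfig, _block, de_table
from .io_formats import CountMatrix, GENERATIONS

PHASES: dict[str, tuple[str, ...]] = {
    "I": ("15C-G1", "15C-G2", "15C-G3"),
    "II": ("23C-G1", "23C-G2", "23C-G3"),
    "III": ("23C-G4", "23C-G5", "23C-G6"),
    "IV": ("p15C-G1", "p15C-G2", "p15C-G3"),
}

assert tuple(g for ph in PHASES.values() for g in ph) == GENERATIONS


def phase_means(counts: CountMatrix, genotype: str, repeat: int = 1) -> pd.DataFrame:
    """Per-gene, per-phase size-factor-normalized mean counts.

    Size factors are computed once over all 12 generations of the genotype;
    the phase mean averages the three member generations.
    """
    from .stats_core import size_factors

    blocks = {}
    for phase, gens in PHASES.items():
        blocks[phase] = _block(counts, genotype, repeat, gens)
    all_counts = np.hstack([blocks[p] for p in PHASES])
    sf = size_factors(all_counts)
    out = {}
    col = 0
    for phase in PHASES:
        n = blocks[phase].shape[1]
        out[phase] = (blocks[phase] / sf[col : col + n][None, :]).mean(axis=1)
        col += n
    return pd.DataFrame(out, index=pd.Index(counts.gene_ids, name="gene_id"))


@dataclass
class SirnaCalls:
    phase: str
    up_in_mutant: set[str]
    down_in_mutant: set[str]
    table: pd.DataFrame


def call_sirna_changes(
    wt: CountMatrix,
    mutant: CountMatrix,
    phase: str,
    config: ClassifyConfig = ClassifyConfig(),
    repeat: int = 1,
) -> SirnaCalls:
    """Mutant-vs-WT differential antisense siRNA call for one phase.

    The three generations of the phase serve as replicates in the NB test.
    Up (increased in mutant) and down sets are disjoint by construction.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    if wt.gene_ids != mutant.gene_ids:
        raise ValueError("gene universes differ between genotypes")
    gens = PHASES[phase]
    a = _block(wt, "WT", repeat, gens)
    b = _block(mutant, "hrde1", repeat, gens)
    tab = de_table(a, b, wt.gene_ids, config.pseudocount)
    sig = tab["q"] <= config.fdr_cutoff
    up = set(tab.index[sig & (tab["fold"] >= config.fold_cutoff)])
    down = set(tab.index[sig & (tab["fold"] <= 1.0 / config.fold_cutoff)])
    return SirnaCalls(phase=phase, up_in_mutant=up, down_in_mutant=down, table=tab)


def retention_fraction(calls_earlier: set[str], calls_later: set[str]) -> float:
    """Fraction of genes called in an earlier phase that remain called later."""
    if not calls_earlier:
        return float("nan")
    return len(calls_earlier & calls_later) / len(calls_earlier)


def crosstab_sirna_mrna(
    sirna_set: set[str],
    mrna_set: set[str],
    universe: list[str],
) -> dict:
    """2x2 cross-tabulation of siRNA-changed vs mRNA-changed genes.

    Returns the contingency counts, the overlap fraction of the mRNA set
    with the siRNA set, and a hypergeometric enrichment p for the overlap.
    """
    if not universe:
        raise ValueError("gene universe is empty")
    uni = set(universe)
    a = sirna_set & uni
    b = mrna_set & uni
    both = len(a & b)
    n = len(uni)
    table = {
        "both": both,
        "sirna_only": len(a) - both,
        "mrna_only": len(b) - both,
        "neither": n - len(a) - len(b) + both,
    }
    frac_of_mrna = both / len(b) if b else float("nan")
    frac_of_sirna = both / len(a) if a else float("nan")
    # upper-tail hypergeometric: P(overlap >= observed)
    p = float(stats.hypergeom.sf(both - 1, n, len(a), len(b))) if a and b else 1.0
    return {
        "table": table,
        "overlap_fraction_of_mrna_set": frac_of_mrna,
        "overlap_fraction_of_sirna_set": frac_of_sirna,
        "hypergeom_p": p,
    }


def target_set_summary(
    means: pd.DataFrame,
    gene_lists: dict[str, list[str]],
) -> pd.DataFrame:
    """Five-number summaries of per-phase siRNA means for named gene lists.

    List members absent from the universe are dropped with a warning; an
    empty list after filtering is an error. Quartiles use the linear-
    interpolation midpoint rule (numpy default).
    """
    import warnings

    rows = []
    for name, genes in gene_lists.items():
        present = [g for g in genes if g in means.index]
        dropped = len(genes) - len(present)
        if dropped:
            warnings.warn(f"list {name!r}: dropped {dropped} genes absent from the universe")
        if not present:
            raise ValueError(f"list {name!r} is empty after filtering to the universe")
        sub = means.loc[present]
        for phase in means.columns:
            v = sub[phase].to_numpy()
            q0, q1, q2, q3, q4 = np.quantile(v, [0, 0.25, 0.5, 0.75, 1])
            rows.append(
                {
                    "list": name,
                    "phase": phase,
                    "n": len(v),
                    "min": q0,
                    "q1": q1,
                    "median": q2,
                    "q3": q3,
                    "max": q4,
                }
            )
    return pd.DataFrame(rows)
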