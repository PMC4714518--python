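"""Temperature-sensitive gene calling and the nuclear-RNAi gene-set cascade.

The calling scheme follows the multigenerational design: for each genotype
and biological repeat, generations are grouped into a 15 °C block
(15C-G1..G3) and a 23 °C block (23C-G2..G6; 23C-G1 is excluded because it
straddles the temperature shift, and the post-stress p15C generations are
excluded to avoid carry-over effects). Generations within a block are
treated as replicates for the NB test — they are successive generations,
not i.i.d. biological replicates, which is a deliberate and documented
simplification of the design.

Derived sets:

* heat-induced / heat-repressed per genotype (>= 2-fold, FDR <= 0.1, called
  in both biological repeats),
* NHGs (nuclear RNAi-repressed heat-inducible genes): heat-induced in the
  *hrde-1* mutant but not in WT,
* high-stringent NHGs: NHGs with >= 2-fold HRDE-1-dependent repression at
  23 °C in both repeats,
* HRDE-1-repressed sets per temperature block, and the 23 °C-unique subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, SampleMeta
from .stats_core import bh_fdr, estimate_dispersion, nb_exact_test_table, size_factors

#: generation blocks used for temperature-sensitive calling
G15 = ("15C-G1", "15C-G2", "15C-G3")
G23 = ("23C-G2", "23C-G3", "23C-G4", "23C-G5", "23C-G6")
GP15 = ("p15C-G1", "p15C-G2", "p15C-G3")

TEMPERATURE_GROUPS = {"G15": G15, "G23": G23, "Gp15": GP15}


@dataclass(frozen=True)
class ClassifyConfig:
    """Thresholds for differential calling."""

    fold_cutoff: float = 2.0
    fdr_cutoff: float = 0.1
    require_both_repeats: bool = True
    #: apply the FDR threshold inside the high-stringent filter as well
    #: (the fold requirement alone is also defensible; see methods note)
    hs_require_fdr: bool = True
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.fold_cutoff <= 1:
            raise ValueError("fold_cutoff must exceed 1")
        if not (0 < self.fdr_cutoff < 1):
            raise ValueError("fdr_cutoff must be in (0, 1)")


# ---------------------------------------------------------------------------
# generic two-group NB differential test on count blocks
# ---------------------------------------------------------------------------

def de_table(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    gene_ids: list[str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Two-group NB exact test over genes.

    Columns: ``mean_a``/``mean_b`` (size-factor-normalized group means),
    ``fold`` (B over A; when either mean is 0 the pseudocount is added to
    both means for the ratio only), ``p``, ``q``.
    """
    counts_a = np.atleast_2d(np.asarray(counts_a))
    counts_b = np.atleast_2d(np.asarray(counts_b))
    combined = np.hstack([counts_a, counts_b])
    sf = size_factors(combined)
    n_a = counts_a.shape[1]
    groups = [np.arange(n_a), np.arange(n_a, combined.shape[1])]
    alphas = estimate_dispersion(combined, sf, groups)
    sf_a, sf_b = sf[:n_a], sf[n_a:]
    mean_a = (counts_a / sf_a[None, :]).mean(axis=1)
    mean_b = (counts_b / sf_b[None, :]).mean(axis=1)
    either_zero = (mean_a == 0) | (mean_b == 0)
    fold = np.where(
        either_zero,
        (mean_b + pseudocount) / (mean_a + pseudocount),
        np.divide(mean_b, np.maximum(mean_a, 1e-300)),
    )
    p = nb_exact_test_table(counts_a, counts_b, sf_a, sf_b, alphas)
    q = bh_fdr(p)
    return pd.DataFrame(
        {"mean_a": mean_a, "mean_b": mean_b, "fold": fold, "p": p, "q": q},
        index=pd.Index(gene_ids, name="gene_id"),
    )


def _block(counts: CountMatrix, genotype: str, repeat: int, generations: tuple[str, ...]) -> np.ndarray:
    def pred(s: SampleMeta) -> bool:
        return (
            s.genotype == genotype and s.repeat_id == repeat and s.generation in generations
        )

    sub = counts.select(pred)
    present = {s.generation for s in sub.samples}
    missing = [g for g in generations if g not in present]
    if missing:
        raise ValueError(
            f"missing generation samples for genotype={genotype} repeat={repeat}: {missing}"
        )
    # order columns chronologically
    ordered = sorted(sub.samples, key=lambda s: generations.index(s.generation))
    return sub.counts[[s.sample_id for s in ordered]].to_numpy()


def _repeats_of(counts: CountMatrix, genotype: str) -> list[int]:
    return sorted({s.repeat_id for s in counts.samples if s.genotype == genotype})


@dataclass
class TsCalls:
    """Per-repeat temperature-sensitive test tables plus intersected calls."""

    genotype: str
    tables: dict[int, pd.DataFrame]
    heat_induced: set[str]
    heat_repressed: set[str]


def _called(table: pd.DataFrame, config: ClassifyConfig, direction: str) -> set[str]:
    sig = table["q"] <= config.fdr_cutoff
    if direction == "up":
        hit = table["fold"] >= config.fold_cutoff
    else:
        hit = table["fold"] <= 1.0 / config.fold_cutoff
    return set(table.index[sig & hit])


def _combine_repeats(per_repeat: list[set[str]], require_both: bool) -> set[str]:
    if not per_repeat:
        return set()
    if require_both:
        return set.intersection(*per_repeat)
    return set.union(*per_repeat)


def call_temperature_sensitive(
    counts: CountMatrix,
    genotype: str,
    config: ClassifyConfig = ClassifyConfig(),
) -> TsCalls:
    """Heat-induced / heat-repressed calls for one genotype.

    Per biological repeat, tests the 23 °C block (23C-G2..G6) against the
    15 °C block (15C-G1..G3); per-repeat significant sets are intersected
    when ``require_both_repeats`` is set.
    """
    repeats = _repeats_of(counts, genotype)
    if not repeats:
        raise ValueError(f"no samples for genotype {genotype!r}")
    tables: dict[int, pd.DataFrame] = {}
    induced, repressed = [], []
    for rep in repeats:
        a = _block(counts, genotype, rep, G15)
        b = _block(counts, genotype, rep, G23)
        tab = de_table(a, b, counts.gene_ids, config.pseudocount)
        tables[rep] = tab
        induced.append(_called(tab, config, "up"))
        repressed.append(_called(tab, config, "down"))
    return TsCalls(
        genotype=genotype,
        tables=tables,
        heat_induced=_combine_repeats(induced, config.require_both_repeats),
        heat_repressed=_combine_repeats(repressed, config.require_both_repeats),
    )


def call_hrde1_repressed(
    counts_wt: CountMatrix,
    counts_mut: CountMatrix,
    group: tuple[str, ...],
    config: ClassifyConfig = ClassifyConfig(),
) -> tuple[set[str], dict[int, pd.DataFrame]]:
    """Genes derepressed in the mutant (fold mut/WT >= cutoff, q <= cutoff)
    within one temperature block, per repeat, intersected across the repeats
    present in both genotypes."""
    if counts_wt.gene_ids != counts_mut.gene_ids:
        raise ValueError("gene universes differ between genotypes")
    reps = sorted(set(_repeats_of(counts_wt, "WT")) & set(_repeats_of(counts_mut, "hrde1")))
    if not reps:
        raise ValueError("no biological repeat present in both genotypes")
    tables: dict[int, pd.DataFrame] = {}
    calls = []
    for rep in reps:
        wt = _block(counts_wt, "WT", rep, group)
        mut = _block(counts_mut, "hrde1", rep, group)
        if wt.shape[1] < 2 or mut.shape[1] < 2:
            raise ValueError("each genotype needs >= 2 samples in the group")
        tab = de_table(wt, mut, counts_wt.gene_ids, config.pseudocount)
        tables[rep] = tab
        calls.append(_called(tab, config, "up"))
    return _combine_repeats(calls, config.require_both_repeats), tables


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCascade:
    """The named gene sets derived from WT and mutant calls."""

    heat_induced_wt: set[str]
    heat_repressed_wt: set[str]
    heat_induced_mut: set[str]
    heat_repressed_mut: set[str]
    nhg: set[str]
    high_stringent_nhg: set[str]
    hrde1_repressed_15C: set[str] = field(default_factory=set)
    hrde1_repressed_23C: set[str] = field(default_factory=set)
    hrde1_repressed_p15C: set[str] = field(default_factory=set)
    hrde1_repressed_23C_unique: set[str] = field(default_factory=set)

    def summary(self) -> dict:
        wt_n = len(self.heat_induced_wt)
        mut_n = len(self.heat_induced_mut)
        overlap = len(self.heat_induced_wt & self.heat_induced_mut)
        out = {
            "heat_induced_wt": wt_n,
            "heat_repressed_wt": len(self.heat_repressed_wt),
            "heat_induced_mut": mut_n,
            "heat_repressed_mut": len(self.heat_repressed_mut),
            "wt_mut_overlap": overlap,
            "nhg": len(self.nhg),
            "high_stringent_nhg": len(self.high_stringent_nhg),
            "hrde1_repressed_15C": len(self.hrde1_repressed_15C),
            "hrde1_repressed_23C": len(self.hrde1_repressed_23C),
            "hrde1_repressed_p15C": len(self.hrde1_repressed_p15C),
            "hrde1_repressed_23C_unique": len(self.hrde1_repressed_23C_unique),
        }
        out.update(cascade_arithmetic(wt_n, mut_n, overlap))
        return out


def cascade_arithmetic(
    wt_induced: int,
    mut_induced: int,
    overlap: int,
    repressed_23c: int | None = None,
    repressed_both_temp: int | None = None,
) -> dict:
    """Venn arithmetic of the cascade from set sizes alone.

    Given the number of heat-induced genes in WT and mutant and their
    overlap: the NHG count (mutant-only members), the mutant/WT ratio and
    the WT overlap percentage. Optionally, given the 23 °C HRDE-1-repressed
    count and how many of those are shared with 15 °C or post-15 °C, the
    23 °C-unique count.
    """
    out = {
        "nhg_count": mut_induced - overlap,
        "mut_wt_induced_ratio": round(mut_induced / wt_induced, 1) if wt_induced else float("inf"),
        "wt_overlap_percent": round(100.0 * overlap / wt_induced) if wt_induced else float("nan"),
    }
    if repressed_23c is not None and repressed_both_temp is not None:
        out["hrde1_repressed_23C_unique"] = repressed_23c - repressed_both_temp
    return out


def build_cascade(
    wt_calls: TsCalls,
    mut_calls: TsCalls,
    counts_wt: CountMatrix,
    counts_mut: CountMatrix,
    config: ClassifyConfig = ClassifyConfig(),
) -> GeneSetCascade:
    """Derive the full gene-set cascade from per-genotype calls.

    NHG = heat-induced in the mutant minus heat-induced in WT. The
    high-stringent subset additionally requires >= fold-cutoff
    mutant-over-WT expression at 23 °C in both repeats (with the FDR
    threshold too unless ``hs_require_fdr`` is off). HRDE-1-repressed sets
    are computed per temperature block; the 23 °C-unique set removes genes
    shared with either 15 °C block.
    """
    if counts_wt.gene_ids != counts_mut.gene_ids:
        raise ValueError("gene universes differ between genotypes")
    nhg = mut_calls.heat_induced - wt_calls.heat_induced

    hs_config = config if config.hs_require_fdr else ClassifyConfig(
        fold_cutoff=config.fold_cutoff, fdr_cutoff=1.0 - 1e-12,
        require_both_repeats=config.require_both_repeats,
    )
    rep23, tables23 = call_hrde1_repressed(counts_wt, counts_mut, G23, config)
    if config.hs_require_fdr:
        hs_pass = rep23
    else:
        per_rep = [set(t.index[t["fold"] >= config.fold_cutoff]) for t in tables23.values()]
        hs_pass = _combine_repeats(per_rep, config.require_both_repeats)
    high_stringent = nhg & hs_pass

    rep15, _ = call_hrde1_repressed(counts_wt, counts_mut, G15, config)
    rep_p15, _ = call_hrde1_repressed(counts_wt, counts_mut, GP15, config)
    return GeneSetCascade(
        heat_induced_wt=wt_calls.heat_induced,
        heat_repressed_wt=wt_calls.heat_repressed,
        heat_induced_mut=mut_calls.heat_induced,
        heat_repressed_mut=mut_calls.heat_repressed,
        nhg=nhg,
        high_stringent_nhg=high_stringent,
        hrde1_repressed_15C=rep15,
        hrde1_repressed_23C=rep23,
        hrde1_repressed_p15C=rep_p15,
        hrde1_repressed_23C_unique=rep23 - (rep15 | rep_p15),
    )


# ---------------------------------------------------------------------------
# published high-stringent NHG table
# ---------------------------------------------------------------------------

def load_table1_fixture() -> pd.DataFrame:
    """The packaged table of the 41 published high-stringent NHGs.

    Columns: ``gene_name``, ``common_name``, ``chromosome``,
    ``transposon_note``. Indexed by gene_name.
    """
    ref = resources.files("transgen_nhg.data") / "table1_high_stringent_nhgs.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    expected = ["gene_name", "common_name", "chromosome", "transposon_note"]
    if list(df.columns) != expected:
        raise ValueError(f"high-stringent NHG fixture corrupted: columns {list(df.columns)}")
    return df.set_index("gene_name")


def lookup_high_stringent_nhg(gene_name: str) -> dict | None:
    """Row of the published table for one gene, or None when absent."""
    df = load_table1_fixture()
    if gene_name not in df.index:
        return None
    row = df.loc[gene_name]
    return {"gene_name": gene_name, **row.to_dict()}
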