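"""Seeded generator of a synthetic 12-generation temperature-shift experiment.

Emulates the structure of the real multigenerational dataset — 12 labeled
generations (15C-G1..G3, 23C-G1..G6, p15C-G1..G3), two genotypes (WT and
the *hrde-1* mutant), mRNA-seq in two biological repeats, antisense
small-RNA-seq, and Pol II / H3K9me3 ChIP-seq for the six ChIP'd
generations — together with a small synthetic genome (6 chromosomes, one
of them "X"), gene models, LTR retrotransposon intervals, and a ground
truth object recording every planted gene class and expected mean.

Planted classes and their mRNA trajectories (B = per-gene baseline):

======================  ==========================  ===========================
class                   WT                          *hrde-1* mutant
======================  ==========================  ===========================
null / sirna_loss       B everywhere                B everywhere
wt_heat_induced         B; heat_fold x B at 23 °C   same as WT
heat_repressed          B; B / heat_fold at 23 °C   same as WT
nhg                     B everywhere                B/heat_fold at 15 °C, B at 23 °C
high_stringent_nhg      B / heat_fold everywhere    B/heat_fold at 15 °C, B at 23 °C
cumulative_nhg          B / heat_fold everywhere    grows cum_factor^k over 23C-Gk,
                                                    decays 0.5/generation in p15C
hrde1_repressed         B / hrde1_fold everywhere   B everywhere
======================  ==========================  ===========================

The 23C-G1 transition generation (temperature shifted during
embryogenesis) receives half of any temperature effect on the log scale.
Counts are negative binomial with variance ``mu + alpha mu^2`` at constant
dispersion, with a per-library lognormal depth factor. One RNG stream per
output is derived from the master seed by stable hashing of its role, so
adding an output never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CountMatrix,
    GENERATIONS,
    GeneModel,
    IntervalSet,
    SampleMeta,
    write_gene_models,
)

CHIP_GENERATIONS = ("15C-G3", "23C-G2", "23C-G4", "23C-G6", "p15C-G1", "p15C-G2")

CLASSES = (
    "wt_heat_induced",
    "heat_repressed",
    "nhg",
    "high_stringent_nhg",
    "cumulative_nhg",
    "hrde1_repressed",
    "sirna_loss",
    "null",
)

G23_LABELS = tuple(g for g in GENERATIONS if g.startswith("23C"))
G15_LABELS = ("15C-G1", "15C-G2", "15C-G3")
P15_LABELS = ("p15C-G1", "p15C-G2", "p15C-G3")


@dataclass
class SimConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    n_genes: int = 2000
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "chrI": 1_450_000,
            "chrII": 1_450_000,
            "chrIII": 1_450_000,
            "chrIV": 1_450_000,
            "chrV": 1_450_000,
            "chrX": 1_250_000,
        }
    )
    x_chrom: str = "chrX"
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "wt_heat_induced": 0.015,
            "heat_repressed": 0.010,
            "nhg": 0.035,
            "high_stringent_nhg": 0.015,
            "cumulative_nhg": 0.003,
            "hrde1_repressed": 0.010,
            "sirna_loss": 0.025,
        }
    )
    heat_fold: float = 8.0
    hrde1_fold: float = 4.0
    cumulative_factor: float = 1.5
    persistence_decay: float = 0.5
    #: lognormal baseline expression: exp(N(log_mu, sigma))
    baseline_log_mu: float = float(np.log(60.0))
    baseline_sigma: float = 1.2
    #: minimum baseline for genes carrying a planted effect
    planted_baseline_floor: float = 50.0
    dispersion: float = 0.1
    library_depth_sigma: float = 0.2
    mean_gene_length: int = 2920
    gene_length_sd: int = 600
    ltr_genome_fraction: float = 0.004
    ltr_length: int = 450
    nhg_ltr_linkage: float = 0.35
    seed: int = 7

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if total > 1:
            raise ValueError(f"class proportions sum to {total} > 1")
        unknown = set(self.class_proportions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown class names: {sorted(unknown)}")


def _rng(seed: int, role: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(role.encode())])
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if alpha < 1e-12:
        out[pos] = rng.poisson(mu[pos])
    else:
        r = 1.0 / alpha
        out[pos] = rng.negative_binomial(r, r / (r + mu[pos]))
    return out


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(
    config: SimConfig,
) -> tuple[dict[str, int], list[GeneModel], IntervalSet, pd.Series]:
    """Synthesize chromosome sizes, gene models, LTR intervals and labels.

    Genes are placed without overlap on each chromosome (count proportional
    to chromosome length). Class labels are assigned up front because two
    placement constraints depend on them: a configured fraction of
    NHG-family genes gets an LTR interval planted inside the gene, and
    sirna_loss genes are kept off the X chromosome (emulating the strong
    X-depletion of siRNA-responsive loci).
    """
    rng = _rng(config.seed, "genome")
    chrom_sizes = dict(config.chrom_sizes)
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)

    # genes per chromosome, proportional to length
    n_per = np.floor(config.n_genes * sizes / sizes.sum()).astype(int)
    while n_per.sum() < config.n_genes:
        n_per[int(rng.integers(len(chroms)))] += 1

    lengths = np.clip(
        rng.normal(config.mean_gene_length, config.gene_length_sd, config.n_genes),
        800,
        8000,
    ).astype(int)

    genes: list[GeneModel] = []
    gi = 0
    for c_idx, chrom in enumerate(chroms):
        n = n_per[c_idx]
        glens = lengths[gi : gi + n]
        leftover = chrom_sizes[chrom] - int(glens.sum())
        if leftover < n + 1:
            raise ValueError(f"overcrowded genome: cannot place {n} genes on {chrom}")
        gaps = rng.dirichlet(np.ones(n + 1)) * leftover
        pos = 0
        for k in range(n):
            pos += int(gaps[k])
            start = pos
            end = start + int(glens[k])
            strand = "+" if rng.random() < 0.5 else "-"
            exon = int(glens[k] * rng.uniform(0.55, 0.95))
            genes.append(GeneModel(f"g{gi + k:05d}", chrom, start, end, strand, exon))
            pos = end
        gi += n

    labels = _assign_labels(config, genes, rng)

    ltr = _place_ltrs(config, genes, labels, chrom_sizes, rng)
    return chrom_sizes, genes, ltr, labels


def _assign_labels(
    config: SimConfig, genes: list[GeneModel], rng: np.random.Generator
) -> pd.Series:
    n = len(genes)
    labels = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    off_x = [i for i in order if genes[i].chrom != config.x_chrom]
    used: set[int] = set()
    # sirna_loss first: constrained off the X chromosome
    n_sirna = int(round(config.class_proportions.get("sirna_loss", 0) * n))
    for i in off_x[:n_sirna]:
        labels[i] = "sirna_loss"
        used.add(i)
    pool = [i for i in order if i not in used]
    pos = 0
    for cls in ("wt_heat_induced", "heat_repressed", "nhg", "high_stringent_nhg",
                "cumulative_nhg", "hrde1_repressed"):
        k = int(round(config.class_proportions.get(cls, 0) * n))
        for i in pool[pos : pos + k]:
            labels[i] = cls
        pos += k
    return pd.Series(labels, index=[g.gene_id for g in genes], name="class")


def _place_ltrs(
    config: SimConfig,
    genes: list[GeneModel],
    labels: pd.Series,
    chrom_sizes: dict[str, int],
    rng: np.random.Generator,
) -> IntervalSet:
    budget = config.ltr_genome_fraction * sum(chrom_sizes.values())
    records: list[tuple] = []
    spent = 0.0
    nhg_family = [
        g for g in genes if labels[g.gene_id] in ("nhg", "high_stringent_nhg", "cumulative_nhg")
    ]
    linked = [g for g in nhg_family if rng.random() < config.nhg_ltr_linkage]
    for k, g in enumerate(linked):
        L = min(config.ltr_length, g.gene_length_bp)
        start = g.start + int(rng.integers(0, g.gene_length_bp - L + 1))
        records.append((g.chrom, start, start + L, f"LTR_linked_{k}"))
        spent += L
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    k = 0
    while spent < budget:
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        L = config.ltr_length
        start = int(rng.integers(0, chrom_sizes[chrom] - L))
        records.append((chrom, start, start + L, f"LTR_bg_{k}"))
        spent += L
        k += 1
    return IntervalSet.from_records(records, chrom_sizes)


# ---------------------------------------------------------------------------
# expected means
# ---------------------------------------------------------------------------

def _mrna_multiplier(cls: str, genotype: str, config: SimConfig) -> dict[str, float]:
    hf = config.heat_fold
    half = np.sqrt(hf)
    out = {g: 1.0 for g in GENERATIONS}
    if cls == "wt_heat_induced":
        for g in G23_LABELS:
            out[g] = hf
        out["23C-G1"] = half
    elif cls == "heat_repressed":
        for g in G23_LABELS:
            out[g] = 1.0 / hf
        out["23C-G1"] = 1.0 / half
    elif cls == "nhg":
        if genotype == "hrde1":
            for g in G15_LABELS + P15_LABELS:
                out[g] = 1.0 / hf
            out["23C-G1"] = 1.0 / half
    elif cls == "high_stringent_nhg":
        if genotype == "WT":
            out = {g: 1.0 / hf for g in GENERATIONS}
        else:
            for g in G15_LABELS + P15_LABELS:
                out[g] = 1.0 / hf
            out["23C-G1"] = 1.0 / half
    elif cls == "cumulative_nhg":
        if genotype == "WT":
            out = {g: 1.0 / hf for g in GENERATIONS}
        else:
            for g in G15_LABELS:
                out[g] = 1.0 / hf
            for k, g in enumerate(G23_LABELS, start=1):
                out[g] = (1.0 / hf) * config.cumulative_factor ** k
            last = out["23C-G6"]
            for k, g in enumerate(P15_LABELS, start=1):
                out[g] = last * config.persistence_decay ** k
    elif cls == "hrde1_repressed":
        if genotype == "WT":
            out = {g: 1.0 / config.hrde1_fold for g in GENERATIONS}
    return out


def _sirna_multiplier(cls: str, genotype: str, config: SimConfig) -> dict[str, float]:
    out = {g: 1.0 for g in GENERATIONS}
    stress_and_after = G23_LABELS + P15_LABELS
    if cls == "sirna_loss" and genotype == "hrde1":
        for g in stress_and_after:
            out[g] = 0.2
    elif cls == "cumulative_nhg":
        if genotype == "WT":
            for g in G23_LABELS:
                out[g] = 2.0
        else:
            for g in stress_and_after:
                out[g] = 0.5
    elif cls == "high_stringent_nhg" and genotype == "hrde1":
        for g in stress_and_after:
            out[g] = 0.5
    return out


@dataclass
class GroundTruth:
    """Planted labels and expected per-sample means of the simulation."""

    config: SimConfig
    labels: pd.Series
    baseline_mrna: pd.Series
    baseline_sirna: pd.Series
    mrna_mean: dict[str, pd.DataFrame]
    sirna_mean: dict[str, pd.DataFrame]
    pol2_mean: dict[str, pd.DataFrame]
    h3k9_mean: dict[str, pd.DataFrame]

    def class_set(self, cls: str) -> set[str]:
        return set(self.labels.index[self.labels == cls])

    def truth_sets(self) -> dict[str, set[str]]:
        """Expected cascade membership implied by the planted trajectories."""
        nhg_family = (
            self.class_set("nhg")
            | self.class_set("high_stringent_nhg")
            | self.class_set("cumulative_nhg")
        )
        hs_family = self.class_set("high_stringent_nhg") | self.class_set("cumulative_nhg")
        return {
            "heat_induced_wt": self.class_set("wt_heat_induced"),
            "heat_repressed_wt": self.class_set("heat_repressed"),
            "heat_induced_mut": self.class_set("wt_heat_induced") | nhg_family,
            "heat_repressed_mut": self.class_set("heat_repressed"),
            "nhg": nhg_family,
            "high_stringent_nhg": hs_family,
            "hrde1_repressed_15C": self.class_set("hrde1_repressed"),
            "hrde1_repressed_23C": self.class_set("hrde1_repressed") | hs_family,
            "hrde1_repressed_p15C": self.class_set("hrde1_repressed"),
            "hrde1_repressed_23C_unique": hs_family,
            "sirna_loss": self.class_set("sirna_loss"),
            "cumulative_nhg": self.class_set("cumulative_nhg"),
        }


def _build_truth(config: SimConfig, labels: pd.Series) -> GroundTruth:
    rng = _rng(config.seed, "baselines")
    n = len(labels)
    base = np.exp(rng.normal(config.baseline_log_mu, config.baseline_sigma, n))
    planted = (labels != "null").to_numpy()
    base[planted] = np.maximum(base[planted], config.planted_baseline_floor)
    baseline_mrna = pd.Series(base, index=labels.index)

    target_like = labels.isin(
        ["nhg", "high_stringent_nhg", "cumulative_nhg", "sirna_loss", "hrde1_repressed"]
    ).to_numpy()
    s_base = np.exp(rng.normal(np.log(20.0), 1.0, n))
    s_base[target_like] = np.maximum(
        np.exp(rng.normal(np.log(200.0), 0.8, target_like.sum())), 100.0
    )
    baseline_sirna = pd.Series(s_base, index=labels.index)

    mrna_mean: dict[str, pd.DataFrame] = {}
    sirna_mean: dict[str, pd.DataFrame] = {}
    pol2_mean: dict[str, pd.DataFrame] = {}
    h3k9_mean: dict[str, pd.DataFrame] = {}
    h3k9_high = labels.isin(
        ["nhg", "high_stringent_nhg", "cumulative_nhg", "hrde1_repressed"]
    ).to_numpy()
    for genotype in ("WT", "hrde1"):
        m = pd.DataFrame(0.0, index=labels.index, columns=list(GENERATIONS))
        s = pd.DataFrame(0.0, index=labels.index, columns=list(GENERATIONS))
        for cls in CLASSES:
            idx = labels == cls
            if not idx.any():
                continue
            mm = _mrna_multiplier(cls, genotype, config)
            sm = _sirna_multiplier(cls, genotype, config)
            for g in GENERATIONS:
                m.loc[idx, g] = baseline_mrna[idx] * mm[g]
                s.loc[idx, g] = baseline_sirna[idx] * sm[g]
        mrna_mean[genotype] = m
        sirna_mean[genotype] = s
        # Pol II occupancy tracks transcription
        pol2_mean[genotype] = np.maximum(0.25 * m[list(CHIP_GENERATIONS)], 2.0)
        # H3K9me3: high on nuclear-RNAi targets, HRDE-1-dependent, mild
        # reduction under heat
        h = pd.DataFrame(20.0, index=labels.index, columns=list(CHIP_GENERATIONS))
        high_level = 150.0 if genotype == "WT" else 50.0
        h.loc[h3k9_high, :] = high_level
        hot = [g for g in CHIP_GENERATIONS if g.startswith("23C")]
        h.loc[h3k9_high, hot] = high_level * 0.7
        h3k9_mean[genotype] = h
    return GroundTruth(
        config=config,
        labels=labels,
        baseline_mrna=baseline_mrna,
        baseline_sirna=baseline_sirna,
        mrna_mean=mrna_mean,
        sirna_mean=sirna_mean,
        pol2_mean=pol2_mean,
        h3k9_mean=h3k9_mean,
    )


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _library_spec() -> list[tuple[str, str, int, tuple[str, ...]]]:
    spec = []
    for genotype in ("WT", "hrde1"):
        for rep in (1, 2):
            spec.append(("mRNA", genotype, rep, GENERATIONS))
        spec.append(("sRNA", genotype, 1, GENERATIONS))
        spec.append(("chip_pol2", genotype, 1, CHIP_GENERATIONS))
        spec.append(("chip_h3k9me3", genotype, 1, CHIP_GENERATIONS))
    return spec


def simulate_counts(
    config: SimConfig, truth: GroundTruth
) -> dict[tuple[str, str, int], CountMatrix]:
    """Draw NB counts for every library of the design.

    Returns matrices keyed by (library, genotype, repeat): mRNA in two
    biological repeats, sRNA and both ChIP marks in one, ChIP restricted to
    the six profiled generations.
    """
    mean_of = {
        "mRNA": truth.mrna_mean,
        "sRNA": truth.sirna_mean,
        "chip_pol2": truth.pol2_mean,
        "chip_h3k9me3": truth.h3k9_mean,
    }
    out: dict[tuple[str, str, int], CountMatrix] = {}
    for library, genotype, rep, gens in _library_spec():
        rng = _rng(config.seed, f"counts/{library}/{genotype}/r{rep}")
        means = mean_of[library][genotype]
        cols = {}
        samples = []
        for gen in gens:
            depth = float(np.exp(rng.normal(0.0, config.library_depth_sigma)))
            mu = means[gen].to_numpy() * depth
            sid = f"{genotype}_{library}_r{rep}_{gen}"
            cols[sid] = _nb_draw(rng, mu, config.dispersion)
            samples.append(
                SampleMeta(sample_id=sid, genotype=genotype, generation=gen,
                           repeat_id=rep, library=library)
            )
        df = pd.DataFrame(cols, index=truth.labels.index)
        df.index.name = "gene_id"
        out[(library, genotype, rep)] = CountMatrix(df, samples)
    return out


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

@dataclass
class SyntheticExperiment:
    config: SimConfig
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    ltr: IntervalSet
    truth: GroundTruth
    counts: dict[tuple[str, str, int], CountMatrix]

    def mrna(self, genotype: str) -> CountMatrix:
        """Both mRNA repeats of a genotype merged into one matrix."""
        mats = [self.counts[("mRNA", genotype, r)] for r in (1, 2)]
        df = pd.concat([m.counts for m in mats], axis=1)
        samples = [s for m in mats for s in m.samples]
        return CountMatrix(df, samples)

    def write_tree(self, outdir: str | Path, force: bool = False) -> dict[str, int]:
        """Emit the full file tree the io layer reads; returns file line counts."""
        outdir = Path(outdir)
        if outdir.exists() and any(outdir.iterdir()) and not force:
            raise FileExistsError(f"output directory {outdir} is not empty (use force)")
        outdir.mkdir(parents=True, exist_ok=True)
        written: dict[str, int] = {}
        for (library, genotype, rep), cm in self.counts.items():
            name = f"{library}_{genotype}_r{rep}.tsv"
            cm.write(outdir / name)
            written[name] = cm.n_genes + 1
        pd.Series(self.chrom_sizes).to_csv(
            outdir / "chrom_sizes.tsv", sep="\t", header=False
        )
        written["chrom_sizes.tsv"] = len(self.chrom_sizes)
        write_gene_models(self.genes, outdir / "genes.tsv")
        written["genes.tsv"] = len(self.genes) + 1
        self.ltr.write_bed(outdir / "ltr.bed")
        written["ltr.bed"] = len(self.ltr)
        truth_payload = {
            "seed": self.config.seed,
            "config": {
                k: v for k, v in dataclasses.asdict(self.config).items()
                if not isinstance(v, dict)
            },
            "class_labels": self.truth.labels.to_dict(),
            "truth_sets": {k: sorted(v) for k, v in self.truth.truth_sets().items()},
        }
        (outdir / "truth.json").write_text(json.dumps(truth_payload, indent=1, sort_keys=True))
        written["truth.json"] = 1
        return written


def simulate_experiment(config: SimConfig | None = None) -> SyntheticExperiment:
    """Generate the complete seeded synthetic experiment."""
    config = config or SimConfig()
    chrom_sizes, genes, ltr, labels = simulate_genome(config)
    truth = _build_truth(config, labels)
    counts = simulate_counts(config, truth)
    return SyntheticExperiment(
        config=config, chrom_sizes=chrom_sizes, genes=genes, ltr=ltr,
        truth=truth, counts=counts,
    )


def null_config(seed: int, n_genes: int = 2000) -> SimConfig:
    """A configuration with no planted effects (pure NB noise)."""
    return SimConfig(
        n_genes=n_genes,
        class_proportions={c: 0.0 for c in CLASSES if c != "null"},
        seed=seed,
    )
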