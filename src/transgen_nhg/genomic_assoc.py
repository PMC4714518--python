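"""Interval-overlap statistics for the NHG gene sets.

Three analyses:

* Monte Carlo association between a set of genomic regions and an
  annotation (LTR retrotransposons): the fraction F of regions overlapping
  the annotation (optionally extended by a flank) is compared against F for
  random fixed-length regions dropped uniformly on the genome, 100,000
  draws by default.
* Chromosome arm/center enrichment: each autosome is split into two arms
  (outer quarter each) and a center (middle half); the X chromosome is
  split into two parts at 1/6 of its length. Observed set membership per
  region is tested against the all-gene occupancy by chi-square.
* Chromosome depletion: Monte Carlo (equivalently hypergeometric) test of
  whether a gene set is under-represented on one chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneModel, IntervalSet
from .stats_core import chi_square_gof


@dataclass
class AssocConfig:
    flank_bp: int = 0
    n_sims: int = 100_000
    region_length_bp: int = 2920  # mean NHG size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.region_length_bp <= 0:
            raise ValueError("region_length_bp must be positive")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")


@dataclass
class OverlapResult:
    f_observed: float
    null_f: np.ndarray
    n_sims: int
    config: AssocConfig

    @property
    def p_empirical(self) -> float:
        return float(np.mean(self.null_f >= self.f_observed - 1e-12))

    def p_text(self) -> str:
        p = self.p_empirical
        return f"< {1.0 / self.n_sims:g}" if p == 0 else f"{p:g}"


def randomized_empirical_p(
    null_draws: np.ndarray,
    observed: float,
    u: float,
    tail: str = "greater",
) -> float:
    """Tie-randomized empirical p-value for a discrete Monte Carlo statistic.

    ``(# strictly beyond + U * (1 + # tied)) / (n + 1)`` with ``U ~ U(0,1)``.
    For an observation drawn from the same null this is exactly uniform,
    which makes it the right quantity for calibration checks; the plain
    ``p_empirical`` (ties counted fully, no add-one) is deliberately
    conservative and is what analyses report.
    """
    null_draws = np.asarray(null_draws, dtype=float)
    if tail == "greater":
        beyond = np.sum(null_draws > observed + 1e-12)
    else:
        beyond = np.sum(null_draws < observed - 1e-12)
    ties = np.sum(np.abs(null_draws - observed) <= 1e-12)
    return float((beyond + u * (1 + ties)) / (null_draws.size + 1))


# ---------------------------------------------------------------------------
# merged-annotation overlap machinery
# ---------------------------------------------------------------------------

class _MergedAnnotation:
    """Flank-extended, clipped, merged annotation, per chromosome, as sorted
    start/end arrays supporting vectorized point-set overlap queries."""

    def __init__(self, annot: IntervalSet, flank_bp: int):
        self.per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in annot.df.groupby("chrom"):
            size = annot.chrom_sizes[chrom]
            starts = np.maximum(sub["start"].to_numpy() - flank_bp, 0)
            ends = np.minimum(sub["end"].to_numpy() + flank_bp, size)
            order = np.argsort(starts, kind="mergesort")
            starts, ends = starts[order], ends[order]
            m_starts, m_ends = [], []
            for s, e in zip(starts, ends):
                if m_ends and s <= m_ends[-1]:
                    m_ends[-1] = max(m_ends[-1], e)
                else:
                    m_starts.append(s)
                    m_ends.append(e)
            self.per_chrom[chrom] = (np.asarray(m_starts), np.asarray(m_ends))

    def hits(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean vector: does [start, end) share >= 1 bp with the merged
        annotation on ``chrom``?"""
        if chrom not in self.per_chrom:
            return np.zeros(len(starts), dtype=bool)
        a_starts, a_ends = self.per_chrom[chrom]
        # first merged interval whose end exceeds the query start
        i = np.searchsorted(a_ends, starts, side="right")
        ok = i < len(a_starts)
        out = np.zeros(len(starts), dtype=bool)
        out[ok] = a_starts[i[ok]] < ends[ok]
        return out


def overlap_fraction(query: IntervalSet, annot: IntervalSet, flank_bp: int = 0) -> float:
    """Fraction of query regions sharing >= 1 bp with the annotation
    extended by ``flank_bp`` on both sides (clipped at chromosome ends)."""
    if len(query) == 0:
        raise ValueError("query interval set is empty")
    merged = _MergedAnnotation(annot, flank_bp)
    n_hit = 0
    for chrom, sub in query.df.groupby("chrom"):
        n_hit += int(merged.hits(chrom, sub["start"].to_numpy(), sub["end"].to_numpy()).sum())
    return n_hit / len(query)


def mc_overlap_test(
    f_observed: float,
    n_regions: int,
    annot: IntervalSet,
    chrom_sizes: dict[str, int],
    config: AssocConfig,
) -> OverlapResult:
    """Monte Carlo null for the overlap fraction.

    Each simulated region has the fixed configured length; its chromosome is
    drawn with probability proportional to length and its start uniformly in
    ``[0, L - region_length]``, so regions never cross a chromosome end.
    The empirical p is the fraction of simulations with F >= the observed F.
    """
    rng = np.random.default_rng(config.seed)
    L = config.region_length_bp
    chroms = [c for c, s in chrom_sizes.items() if s >= L]
    if not chroms:
        raise ValueError("region_length_bp exceeds every chromosome length")
    if len(annot) == 0:
        warnings.warn("annotation is empty; p = 1 by construction")
        return OverlapResult(f_observed, np.ones(config.n_sims), config.n_sims, config)
    merged = _MergedAnnotation(annot, config.flank_bp)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    null_f = np.empty(config.n_sims)
    chunk = max(1, min(config.n_sims, 4_000_000 // max(n_regions, 1)))
    done = 0
    while done < config.n_sims:
        n = min(chunk, config.n_sims - done)
        ci = rng.choice(len(chroms), size=(n, n_regions), p=probs)
        starts = np.floor(
            rng.random((n, n_regions)) * (sizes[ci] - L + 1)
        ).astype(np.int64)
        hit = np.zeros((n, n_regions), dtype=bool)
        for k, chrom in enumerate(chroms):
            mask = ci == k
            if mask.any():
                s = starts[mask]
                hit[mask] = merged.hits(chrom, s, s + L)
        null_f[done : done + n] = hit.mean(axis=1)
        done += n
    return OverlapResult(float(f_observed), null_f, config.n_sims, config)


def ltr_association(
    query: IntervalSet,
    annot: IntervalSet,
    chrom_sizes: dict[str, int],
    config: AssocConfig,
) -> OverlapResult:
    """Observed overlap fraction of ``query`` plus its Monte Carlo null."""
    f_obs = overlap_fraction(query, annot, config.flank_bp)
    return mc_overlap_test(f_obs, len(query), annot, chrom_sizes, config)


# ---------------------------------------------------------------------------
# chromosome partition statistics
# ---------------------------------------------------------------------------

@dataclass
class ChromPartition:
    """Labeled regions tiling each chromosome.

    Autosomes: left arm = first quarter, center = middle half, right arm =
    last quarter. The X chromosome is split into two parts at 1/6 of its
    length. Boundaries are half-open toward the chromosome start, so a gene
    midpoint exactly on the arm/center boundary belongs to the center.
    """

    chrom_sizes: dict[str, int]
    x_chrom: str = "chrX"
    regions: dict[str, list[tuple[str, int, int]]] = field(init=False)

    def __post_init__(self) -> None:
        self.regions = {}
        for chrom, size in self.chrom_sizes.items():
            if chrom == self.x_chrom:
                cut = size // 6
                self.regions[chrom] = [("part1", 0, cut), ("part2", cut, size)]
            else:
                q = size // 4
                self.regions[chrom] = [
                    ("left_arm", 0, q),
                    ("center", q, size - q),
                    ("right_arm", size - q, size),
                ]

    def assign(self, chrom: str, position: int) -> str:
        for label, start, end in self.regions[chrom]:
            if start <= position < end:
                return label
        raise ValueError(f"position {position} outside {chrom}")


def arm_center_enrichment(
    gene_set: set[str],
    all_genes: list[GeneModel],
    partition: ChromPartition,
) -> pd.DataFrame:
    """Observed vs expected per-region counts and chi-square p per chromosome.

    Genes are assigned to regions by midpoint; expected counts are
    proportional to the all-gene occupancy of each region. Chromosomes with
    a region holding zero genes overall are skipped with a warning.
    """
    rows = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in all_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, genes in sorted(by_chrom.items()):
        labels = [partition.assign(chrom, g.midpoint) for g in genes]
        region_names = [r[0] for r in partition.regions[chrom]]
        total = np.array([labels.count(r) for r in region_names], dtype=float)
        if (total == 0).any():
            warnings.warn(f"{chrom}: a partition region holds zero genes; skipped")
            continue
        in_set = np.array(
            [
                sum(1 for g, lab in zip(genes, labels) if lab == r and g.gene_id in gene_set)
                for r in region_names
            ],
            dtype=float,
        )
        if in_set.sum() == 0:
            p = 1.0
            stat = 0.0
        else:
            stat, p = chi_square_gof(in_set, total)
        expected = total * in_set.sum() / total.sum()
        for r, obs, exp in zip(region_names, in_set, expected):
            rows.append(
                {
                    "chrom": chrom,
                    "region": r,
                    "observed": int(obs),
                    "expected": exp,
                    "direction": "enriched" if obs > exp else ("depleted" if obs < exp else "equal"),
                    "chi2": stat,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def chrom_depletion_test(
    gene_set: set[str],
    all_genes: list[GeneModel],
    chrom: str,
    n_sims: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Fold-depletion of a gene set on one chromosome plus a Monte Carlo p.

    Fold = expected fraction / observed fraction of set genes on ``chrom``
    (``inf`` when the observed count is 0, i.e. a lower bound). p is the
    fraction of ``n_sims`` same-size uniform draws from the gene universe
    whose chromosome count is <= the observed count; this converges to the
    hypergeometric lower tail.
    """
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    universe = [g.gene_id for g in all_genes]
    on_chrom = {g.gene_id for g in all_genes if g.chrom == chrom}
    if not on_chrom:
        raise ValueError(f"chromosome {chrom!r} absent from the gene universe")
    universe_set = set(universe)
    members = [g for g in gene_set if g in universe_set]
    observed = sum(1 for g in members if g in on_chrom)
    n_set = len(members)
    if n_set == 0:
        raise ValueError("gene_set has no member in the gene universe")
    expected_frac = len(on_chrom) / len(universe)
    obs_frac = observed / n_set
    fold = float("inf") if observed == 0 else expected_frac / obs_frac
    rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(len(on_chrom), len(universe) - len(on_chrom), n_set, size=n_sims)
    p = float(np.mean(draws <= observed))
    return fold, p
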