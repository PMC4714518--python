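"""File formats and per-gene quantification for the 12-generation experiment.

The experimental design is a multigenerational temperature shift in
*C. elegans*: three generations at 15 °C, six at 23 °C, three back at
15 °C, for two genotypes (wild type and the *hrde-1* nuclear-RNAi mutant),
assayed by mRNA-seq, antisense small-RNA-seq and Pol II / H3K9me3 ChIP-seq.
Everything downstream starts from per-gene integer count matrices plus
genomic annotations, which this module reads, validates and writes.

Conventions
-----------
* All genomic intervals are 0-based half-open (BED). GFF3 input (1-based
  closed) is converted on read.
* Count tables are TSV with a ``gene_id`` first column; sample metadata
  lives in a sidecar TSV (``<counts>.meta.tsv`` by default).
* The 12 generation labels are a closed vocabulary; a label determines its
  temperature (``15C-*``/``p15C-*`` -> 15 °C, ``23C-*`` -> 23 °C).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

#: The 12 generation labels of the temperature-shift design, in chronological
#: order: 15 °C x3, 23 °C x6, post-stress 15 °C x3.
GENERATIONS: tuple[str, ...] = (
    "15C-G1", "15C-G2", "15C-G3",
    "23C-G1", "23C-G2", "23C-G3", "23C-G4", "23C-G5", "23C-G6",
    "p15C-G1", "p15C-G2", "p15C-G3",
)

GENERATION_INDEX: dict[str, int] = {g: i for i, g in enumerate(GENERATIONS)}

GENOTYPES = ("WT", "hrde1")

LIBRARIES = ("mRNA", "sRNA", "chip_pol2", "chip_h3k9me3", "chip_input")


def temperature_of(generation: str) -> int:
    """Temperature (°C) implied by a generation label."""
    if generation not in GENERATION_INDEX:
        raise ValueError(f"unknown generation label: {generation!r}")
    return 23 if generation.startswith("23C") else 15


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequencing library."""

    sample_id: str
    genotype: str
    generation: str
    repeat_id: int
    library: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.generation not in GENERATION_INDEX:
            raise ValueError(f"unknown generation label: {self.generation!r}")
        if self.repeat_id not in (1, 2):
            raise ValueError(f"repeat_id must be 1 or 2, got {self.repeat_id!r}")
        if self.library not in LIBRARIES:
            raise ValueError(f"library must be one of {LIBRARIES}, got {self.library!r}")

    @property
    def temperature(self) -> int:
        return temperature_of(self.generation)


class CountMatrix:
    """Genes x samples integer counts with validated sample metadata.

    ``counts`` is a pandas DataFrame indexed by gene_id with one column per
    sample_id, in the same order as ``samples``.
    """

    def __init__(self, counts: pd.DataFrame, samples: Sequence[SampleMeta]):
        counts = counts.copy()
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene_id: {dup!r}")
        sample_ids = [s.sample_id for s in samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample_id in metadata")
        if list(counts.columns) != sample_ids:
            raise ValueError("count columns do not match sample metadata order")
        if len(counts):
            arr = counts.to_numpy()
            if not np.issubdtype(arr.dtype, np.number):
                raise ValueError("counts must be numeric")
            if np.any(arr < 0) or np.any(arr != np.floor(arr)):
                bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))[0]
                raise ValueError(
                    f"negative or non-integer count at gene {counts.index[bad[0]]!r}, "
                    f"sample {counts.columns[bad[1]]!r}"
                )
        self.counts = counts.astype(np.int64)
        self.samples = list(samples)

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def total_per_sample(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def select(self, predicate: Callable[[SampleMeta], bool]) -> "CountMatrix":
        """Sub-matrix of the samples for which ``predicate`` is true."""
        keep = [s for s in self.samples if predicate(s)]
        return CountMatrix(self.counts[[s.sample_id for s in keep]], keep)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.samples == other.samples and self.counts.equals(other.counts)

    # -- I/O -------------------------------------------------------------
    def write(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        path = Path(path)
        meta_path = Path(meta_path) if meta_path else default_meta_path(path)
        out = self.counts.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False)
        pd.DataFrame(
            [dataclasses.asdict(s) for s in self.samples]
        ).to_csv(meta_path, sep="\t", index=False)


def default_meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.tsv") if path.suffix != ".tsv" \
        else path.with_name(path.name[: -len(".tsv")] + ".meta.tsv")


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "genotype", "generation", "repeat_id", "library"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    return [
        SampleMeta(
            sample_id=str(r.sample_id),
            genotype=str(r.genotype),
            generation=str(r.generation),
            repeat_id=int(r.repeat_id),
            library=str(r.library),
        )
        for r in df.itertuples()
    ]


def read_counts(path: str | Path, meta_path: str | Path | None = None) -> CountMatrix:
    """Read a counts TSV plus its sidecar metadata into a CountMatrix.

    The first column must be ``gene_id``; every remaining header column must
    have a metadata row. Gene order is preserved.
    """
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else default_meta_path(path)
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ValueError(f"first column of {path} must be 'gene_id', got {df.columns[0]!r}")
    df = df.set_index("gene_id")
    metas = {m.sample_id: m for m in read_sample_meta(meta_path)}
    samples = []
    for sid in df.columns:
        if sid not in metas:
            raise ValueError(f"sample {sid!r} in counts header has no metadata row")
        samples.append(metas[sid])
    return CountMatrix(df, samples)


# ---------------------------------------------------------------------------
# gene models and interval sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One gene: 0-based half-open genomic span plus summed exon length."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exon_length_bp: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (0 < self.exon_length_bp <= self.gene_length_bp):
            raise ValueError(
                f"{self.gene_id}: exon_length_bp must be in (0, gene_length], "
                f"got {self.exon_length_bp} vs {self.gene_length_bp}"
            )

    @property
    def gene_length_bp(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """A set of (chrom, start, end[, name, strand]) records on a sized genome."""

    def __init__(self, df: pd.DataFrame, chrom_sizes: dict[str, int]):
        df = df.copy().reset_index(drop=True)
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"interval table missing column {col!r}")
        if "name" not in df.columns:
            df["name"] = "."
        if "strand" not in df.columns:
            df["strand"] = None
        if len(df):
            if (df["start"] >= df["end"]).any():
                bad = df[df["start"] >= df["end"]].iloc[0]
                raise ValueError(f"empty or inverted interval {bad.chrom}:{bad.start}-{bad.end}")
            for chrom, sub in df.groupby("chrom"):
                if chrom not in chrom_sizes:
                    raise ValueError(f"unknown chromosome {chrom!r}")
                if (sub["start"] < 0).any() or (sub["end"] > chrom_sizes[chrom]).any():
                    raise ValueError(f"interval outside chromosome {chrom!r} bounds")
        self.df = df
        self.chrom_sizes = dict(chrom_sizes)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        chrom_sizes: dict[str, int],
    ) -> "IntervalSet":
        """Build from (chrom, start, end[, name[, strand]]) tuples."""
        rows = []
        for rec in records:
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            name = rec[3] if len(rec) > 3 else "."
            strand = rec[4] if len(rec) > 4 else None
            rows.append({"chrom": chrom, "start": start, "end": end, "name": name, "strand": strand})
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
        return cls(df, chrom_sizes)

    def write_bed(self, path: str | Path) -> None:
        out = self.df[["chrom", "start", "end"]].copy()
        if self.df["strand"].notna().any():
            out["name"] = self.df["name"]
            out["score"] = 0
            out["strand"] = self.df["strand"].fillna(".")
        out.to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    if df["chrom"].duplicated().any():
        raise ValueError("duplicate chromosome in sizes file")
    return dict(zip(df["chrom"], df["size"].astype(int)))


def read_intervals(path: str | Path, chrom_sizes: dict[str, int] | str | Path) -> IntervalSet:
    """Read a BED3/BED6 file (0-based half-open) and validate against sizes."""
    if not isinstance(chrom_sizes, dict):
        chrom_sizes = read_chrom_sizes(chrom_sizes)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names
    keep = [c for c in ("chrom", "start", "end", "name", "strand") if c in df.columns]
    return IntervalSet(df[keep], chrom_sizes)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from the 7-column TSV or from GFF3.

    TSV columns: gene_id, chrom, start, end, strand, gene_length, exon_length
    (0-based half-open). GFF3 (detected by ``##gff`` header or ``.gff``/
    ``.gff3`` suffix) is converted from 1-based closed coordinates; exon
    length is the summed span of ``exon`` features per gene, defaulting to
    the gene span when a gene has no exon rows.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if path.suffix.lower() in (".gff", ".gff3") or first.startswith("##gff"):
        return _read_gff3(path)
    df = pd.read_csv(path, sep="\t")
    genes = []
    for r in df.itertuples():
        gm = GeneModel(
            gene_id=str(r.gene_id), chrom=str(r.chrom), start=int(r.start),
            end=int(r.end), strand=str(r.strand), exon_length_bp=int(r.exon_length),
        )
        if int(r.gene_length) != gm.gene_length_bp:
            raise ValueError(f"{gm.gene_id}: gene_length column disagrees with end - start")
        genes.append(gm)
    _check_unique([g.gene_id for g in genes])
    return genes


def _read_gff3(path: Path) -> list[GeneModel]:
    cols = ["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attrs"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=cols)

    def attr(s: str, key: str) -> str | None:
        for field in s.split(";"):
            if field.startswith(key + "="):
                return field[len(key) + 1:]
        return None

    genes: dict[str, dict] = {}
    for r in df[df["type"] == "gene"].itertuples():
        gid = attr(r.attrs, "ID") or attr(r.attrs, "gene_id")
        if gid is None:
            raise ValueError("gene feature without ID attribute")
        genes[gid] = {"chrom": r.chrom, "start": int(r.start) - 1, "end": int(r.end),
                      "strand": r.strand, "exon": 0}
    for r in df[df["type"] == "exon"].itertuples():
        parent = attr(r.attrs, "Parent") or attr(r.attrs, "gene_id")
        if parent in genes:
            genes[parent]["exon"] += int(r.end) - (int(r.start) - 1)
    out = []
    for gid, g in genes.items():
        exon = g["exon"] or (g["end"] - g["start"])
        out.append(GeneModel(gid, g["chrom"], g["start"], g["end"], g["strand"], exon))
    _check_unique([g.gene_id for g in out])
    return out


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "gene_length": [g.gene_length_bp for g in genes],
            "exon_length": [g.exon_length_bp for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def _check_unique(ids: list[str]) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate gene_id: {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def count_tags(
    alignments: IntervalSet,
    genes: Sequence[GeneModel],
    orientation: str,
) -> pd.Series:
    """Strand-aware per-gene tag counting.

    A tag is counted for a gene iff it overlaps the gene span by >= 1 bp and
    its strand matches (``sense``) or opposes (``antisense``) the gene's
    strand. A tag overlapping k genes increments all k: no fractional
    assignment is attempted.
    """
    if orientation not in ("sense", "antisense"):
        raise ValueError("orientation must be 'sense' or 'antisense'")
    strands = alignments.df["strand"]
    if len(alignments) and (strands.isna().any() or (~strands.isin(["+", "-"])).any()):
        raise ValueError("strandless alignment in strand-aware counting mode")

    trees: dict[str, IntervalTree] = {}
    for idx, g in enumerate(genes):
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, idx)
    counts = np.zeros(len(genes), dtype=np.int64)
    gene_strand = np.array([g.strand for g in genes])
    for r in alignments.df.itertuples():
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(r.start, r.end):
            gidx = hit.data
            same = gene_strand[gidx] == r.strand
            if (orientation == "sense") == same:
                counts[gidx] += 1
    return pd.Series(counts, index=[g.gene_id for g in genes], name=orientation)


@dataclass
class ExpressionMatrix:
    """RPKM values (genes x samples) with the sample metadata they came from."""

    values: pd.DataFrame
    samples: list[SampleMeta]

    def column(self, sample_id: str) -> pd.Series:
        return self.values[sample_id]


def rpkm(
    counts: CountMatrix,
    lengths: pd.Series | dict[str, int],
    length_basis: str = "exon",
) -> ExpressionMatrix:
    """Reads per kilobase of feature per million mapped reads.

    ``value = count / (library_total / 1e6) / (length_bp / 1e3)``.
    Per the field convention followed here, RNA libraries (mRNA/sRNA) use the
    summed exon length, ChIP libraries the full gene length; ``length_basis``
    records which was supplied.
    """
    if length_basis not in ("gene", "exon"):
        raise ValueError("length_basis must be 'gene' or 'exon'")
    lengths = pd.Series(lengths)
    missing = [g for g in counts.gene_ids if g not in lengths.index]
    if missing:
        raise ValueError(f"missing length for counted gene(s), e.g. {missing[0]!r}")
    lengths = lengths.reindex(counts.gene_ids).astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = counts.total_per_sample.astype(float)
    if (totals <= 0).any():
        zero = totals.index[totals <= 0][0]
        raise ValueError(f"zero library total for sample {zero!r}")
    vals = counts.counts.div(totals / 1e6, axis=1).div(lengths / 1e3, axis=0)
    return ExpressionMatrix(vals, list(counts.samples))
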