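"""Readers and writers for the external formats the pipeline touches.

Gene models come in as GFF3 + CDS FASTA and are normalised into an ordered
internal representation (:class:`GeneSet`); homolog anchors as two-column
tabular files; bisulfite calls as allc-style per-cytosine tables; and the
per-gene results go out as a fixed-schema TSV mirroring the usual
"gene list with synteny, methylation and GC content" supplementary layout.

Coordinates are 1-based inclusive at the GFF3 boundary and 0-based
half-open everywhere inside the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Union

import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

PathOrStream = Union[str, IO]

#: fixed column order of the per-gene metrics table
GENE_TABLE_COLUMNS = [
    "gene_id",
    "species",
    "chrom",
    "ordinal",
    "syntenic",
    "gc3_50",
    "gc3_full",
    "copy_class",
    "mCG",
    "mCHG",
    "mCHH",
    "filter_status",
]

_FLOAT_COLUMNS = ("gc3_50", "gc3_full", "mCG", "mCHG", "mCHH")


@dataclass
class GeneModel:
    """One gene: location, gene-order rank and the CDS of its first splice variant.

    ``start``/``end`` are 0-based half-open genomic coordinates; ``ordinal``
    is the 0-based rank of the gene among genes on its chromosome sorted by
    start.  ``cds`` holds the coding sequence of the first mRNA encountered
    in the annotation (5'->3' in coding orientation) and may be ``None``
    when no matching FASTA record was found — such genes are excluded later
    by the CDS filters, not at load time.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    ordinal: int = -1
    cds: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass
class GeneSet:
    """All genes of one species, with a dense per-chromosome gene order."""

    species_tag: str
    genes: dict[str, GeneModel] = field(default_factory=dict)
    chrom_order: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def by_chromosome(self) -> dict[str, list[GeneModel]]:
        """Genes grouped by chromosome, sorted by ordinal."""
        out: dict[str, list[GeneModel]] = {c: [] for c in self.chrom_order}
        for g in self.genes.values():
            out.setdefault(g.chrom, []).append(g)
        for genes in out.values():
            genes.sort(key=lambda g: g.ordinal)
        return out

    def assign_ordinals(self) -> None:
        """(Re)assign 0-based per-chromosome ordinals by start coordinate.

        Ties on start are broken by end then gene id so the ranking is
        deterministic; ordinals form a dense 0..n-1 sequence per chromosome.
        """
        per_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes.values():
            per_chrom.setdefault(g.chrom, []).append(g)
        for chrom, genes in per_chrom.items():
            genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
            for i, g in enumerate(genes):
                g.ordinal = i
        self.chrom_order = sorted(per_chrom)


@dataclass(frozen=True)
class AnchorPair:
    """A homologous gene pair between two genomes (one dot in a dot plot)."""

    gene_a: str
    gene_b: str
    score: Optional[float] = None


@dataclass(frozen=True)
class MethylationCall:
    """Per-cytosine bisulfite counts in a collapsed CG/CHG/CHH context."""

    chrom: str
    pos: int  # 1-based position of the cytosine
    strand: str
    context: str
    m_reads: int
    total_reads: int


class MethylationCallSet:
    """Per-cytosine methylation calls held as a DataFrame.

    Columns: chrom, pos (1-based), strand, context (collapsed to
    CG/CHG/CHH), m_reads, total_reads, covered (total_reads > 0).
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_uncovered(self) -> int:
        return int((~self.df["covered"]).sum())

    def calls(self) -> Iterable[MethylationCall]:
        for row in self.df.itertuples(index=False):
            yield MethylationCall(
                row.chrom, int(row.pos), row.strand, row.context,
                int(row.m_reads), int(row.total_reads),
            )


@dataclass
class GeneMetrics:
    """One row of the per-gene results table."""

    gene_id: str
    species: str
    chrom: str
    ordinal: int
    syntenic: Optional[bool] = None
    gc3_50: Optional[float] = None
    gc3_full: Optional[float] = None
    copy_class: Optional[str] = None
    mCG: Optional[float] = None
    mCHG: Optional[float] = None
    mCHH: Optional[float] = None
    filter_status: str = "pass"


def _open(source: PathOrStream, mode: str = "r"):
    if isinstance(source, str):
        return open(source, mode), True
    return source, False


def collapse_context(context: str) -> str:
    """Collapse a cytosine context string to CG / CHG / CHH.

    Accepts raw trinucleotides (``CAG`` -> CHG, ``CCC`` -> CHH,
    ``CGA`` -> CG) as well as already-collapsed labels.
    """
    c = context.upper()
    if not c.startswith("C") or len(c) < 2:
        raise ValueError(f"unrecognisable cytosine context {context!r}")
    if c[1] == "G":
        return "CG"
    if len(c) < 3:
        raise ValueError(f"unrecognisable cytosine context {context!r}")
    if c[2] == "G":
        return "CHG"
    return "CHH"


def read_gene_models(
    gff3: PathOrStream, cds_fasta: PathOrStream, species_tag: str
) -> GeneSet:
    """Load gene models from GFF3 and attach the first splice variant's CDS.

    One :class:`GeneModel` is produced per ``gene`` feature.  When a gene
    has several mRNA children, the first mRNA in file order supplies the
    CDS (looked up in the FASTA by mRNA id, falling back to the gene id).
    Genes whose CDS id is missing from the FASTA are retained without a
    CDS and a warning is logged; downstream filters exclude them.

    Ordinals are assigned per chromosome by start coordinate.
    """
    fasta_handle, close_fa = _open(cds_fasta)
    try:
        cds_by_id = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_handle, "fasta")}
    finally:
        if close_fa:
            fasta_handle.close()

    handle, close_me = _open(gff3)
    genes: dict[str, GeneModel] = {}
    first_mrna: dict[str, str] = {}  # gene_id -> id of first mRNA in file order
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise ValueError(
                    f"malformed GFF3 at line {lineno}: expected 9 tab-separated fields"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ValueError(f"malformed GFF3 at line {lineno}: {exc}") from exc
            ftype = feat.featuretype
            if ftype == "gene":
                gid = feat.attributes.get("ID", [None])[0]
                if gid is None:
                    raise ValueError(f"gene without ID at line {lineno}")
                genes[gid] = GeneModel(
                    gene_id=gid,
                    chrom=feat.seqid,
                    strand=feat.strand if feat.strand in "+-" else "+",
                    start=feat.start - 1,  # GFF3 1-based inclusive -> half-open
                    end=feat.end,
                )
            elif ftype == "mRNA":
                mid = feat.attributes.get("ID", [None])[0]
                parent = feat.attributes.get("Parent", [None])[0]
                if parent is not None and parent not in first_mrna and mid is not None:
                    first_mrna[parent] = mid
    finally:
        if close_me:
            handle.close()

    n_missing = 0
    for gid, gene in genes.items():
        mid = first_mrna.get(gid)
        if mid is not None:
            logger.debug("gene %s: first splice variant %s", gid, mid)
        seq = cds_by_id.get(mid) if mid is not None else None
        if seq is None:
            seq = cds_by_id.get(gid)
        if seq is None:
            n_missing += 1
            logger.warning("gene %s: no CDS record in FASTA; retained without cds", gid)
        gene.cds = seq
    if n_missing:
        logger.warning("%s: %d genes without a CDS record", species_tag, n_missing)

    gs = GeneSet(species_tag=species_tag, genes=genes)
    gs.assign_ordinals()
    return gs


def read_anchor_pairs(
    source: PathOrStream, geneset_a: GeneSet, geneset_b: GeneSet
) -> list[AnchorPair]:
    """Read homolog anchor pairs from a tab-separated file.

    The first two columns are gene ids in genomes A and B (BLAST
    outfmt-6-like files work as-is); an optional third numeric column is
    kept as the score.  Rows whose ids do not resolve in the gene sets are
    dropped with a logged count; duplicated pairs are de-duplicated.
    """
    handle, close_me = _open(source)
    try:
        pairs: list[AnchorPair] = []
        seen: set[tuple[str, str]] = set()
        n_dropped = 0
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"anchor line with fewer than 2 columns: {line!r}")
            ga, gb = parts[0], parts[1]
            if ga not in geneset_a or gb not in geneset_b:
                n_dropped += 1
                continue
            if (ga, gb) in seen:
                continue
            seen.add((ga, gb))
            score = None
            if len(parts) >= 3:
                try:
                    score = float(parts[2])
                except ValueError:
                    score = None
            pairs.append(AnchorPair(ga, gb, score))
    finally:
        if close_me:
            handle.close()
    if n_dropped:
        logger.info("dropped %d anchor rows with unresolvable gene ids", n_dropped)
    if not pairs:
        raise ValueError("no resolvable anchor pairs")
    return pairs


def read_methylation_calls(source: PathOrStream) -> MethylationCallSet:
    """Read an allc-style per-cytosine table.

    Expected columns (tab-separated, no header): chrom, pos (1-based),
    strand, context string, methylated reads, total reads.  A seventh
    binomial-call column, as emitted by common callers, is ignored.
    Context strings are collapsed to CG/CHG/CHH; zero-coverage rows are
    retained but flagged ``covered=False``.
    """
    handle, close_me = _open(source)
    try:
        df = pd.read_csv(
            handle,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2, 3, 4, 5],
            names=["chrom", "pos", "strand", "context", "m_reads", "total_reads"],
            dtype={"chrom": str, "strand": str, "context": str},
        )
    finally:
        if close_me:
            handle.close()
    bad = df.index[df["m_reads"] > df["total_reads"]]
    if len(bad):
        i = int(bad[0])
        raise ValueError(
            f"m_reads > total_reads at row {i} "
            f"({df.loc[i, 'chrom']}:{df.loc[i, 'pos']})"
        )
    df["context"] = df["context"].map(collapse_context)
    df["covered"] = df["total_reads"] > 0
    return MethylationCallSet(df)


def _fmt(value, column: str) -> str:
    if value is None:
        return "NA"
    if column in _FLOAT_COLUMNS:
        if isinstance(value, float) and math.isnan(value):
            return "NA"
        return f"{value:.4f}"
    if column == "syntenic":
        return str(int(value))
    return str(value)


def write_gene_table(records: Iterable[GeneMetrics], dest: PathOrStream) -> None:
    """Write per-gene metrics as a TSV with the fixed column schema.

    Floats are printed at 4 decimals; undefined values as ``NA``;
    ``syntenic`` as 0/1.
    """
    handle, close_me = _open(dest, "w")
    try:
        handle.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for rec in records:
            handle.write(
                "\t".join(_fmt(getattr(rec, c), c) for c in GENE_TABLE_COLUMNS) + "\n"
            )
    finally:
        if close_me:
            handle.close()


def read_gene_table(source: PathOrStream) -> list[GeneMetrics]:
    """Parse a gene-metrics TSV back into records (round-trip of writer)."""
    handle, close_me = _open(source)
    try:
        line = handle.readline()
        while line.startswith("#"):
            line = handle.readline()
        header = line.rstrip("\n").split("\t")
        if header != GENE_TABLE_COLUMNS:
            raise ValueError("unexpected gene table header")
        out = []
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            vals = dict(zip(GENE_TABLE_COLUMNS, line.rstrip("\n").split("\t")))
            out.append(
                GeneMetrics(
                    gene_id=vals["gene_id"],
                    species=vals["species"],
                    chrom=vals["chrom"],
                    ordinal=int(vals["ordinal"]),
                    syntenic=None if vals["syntenic"] == "NA" else bool(int(vals["syntenic"])),
                    gc3_50=None if vals["gc3_50"] == "NA" else float(vals["gc3_50"]),
                    gc3_full=None if vals["gc3_full"] == "NA" else float(vals["gc3_full"]),
                    copy_class=None if vals["copy_class"] == "NA" else vals["copy_class"],
                    mCG=None if vals["mCG"] == "NA" else float(vals["mCG"]),
                    mCHG=None if vals["mCHG"] == "NA" else float(vals["mCHG"]),
                    mCHH=None if vals["mCHH"] == "NA" else float(vals["mCHH"]),
                    filter_status=vals["filter_status"],
                )
            )
        return out
    finally:
        if close_me:
            handle.close()


def read_gene_table_xlsx(path: str, sheet=0) -> list[GeneMetrics]:
    """Thin adapter reading an XLSX per-gene list into the same schema.

    Column names must match :data:`GENE_TABLE_COLUMNS`; missing optional
    columns are filled with NA.  Intended for externally published
    per-gene supplementary tables.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    out = []
    for _, row in df.iterrows():
        def get(col, cast=None):
            if col not in df.columns or pd.isna(row[col]):
                return None
            return cast(row[col]) if cast else row[col]

        out.append(
            GeneMetrics(
                gene_id=str(row["gene_id"]),
                species=str(get("species") or ""),
                chrom=str(get("chrom") or ""),
                ordinal=int(get("ordinal", int) or 0),
                syntenic=None if get("syntenic") is None else bool(int(row["syntenic"])),
                gc3_50=get("gc3_50", float),
                gc3_full=get("gc3_full", float),
                copy_class=get("copy_class", str),
                mCG=get("mCG", float),
                mCHG=get("mCHG", float),
                mCHH=get("mCHH", float),
                filter_status=str(get("filter_status") or "pass"),
            )
        )
    return out
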