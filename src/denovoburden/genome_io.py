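"""Gene models, SV sites and de novo calls: containers and flat-file I/O.

All internal coordinates are 0-based half-open.  GFF3 input (1-based,
end-inclusive) is converted on read; BED input is taken as-is.  Every other
module attaches its rates and tests to the :class:`GeneModel` defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

logger = logging.getLogger("denovoburden")

#: de novo consequence classes understood by the framework
LOF_SNV_CLASSES = frozenset(
    {"nonsense", "frameshift", "splice_acceptor", "splice_donor"}
)
CONSEQUENCE_CLASSES = LOF_SNV_CLASSES | {"synonymous", "missense", "cnv_lof"}


class ValidationError(ValueError):
    """An input record violates a container invariant."""


class ParseError(ValueError):
    """A line of an input stream could not be parsed."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A canonical protein-coding transcript with its exon structure.

    ``exons`` are 0-based half-open intervals, sorted and non-overlapping.
    ``transcript_length_bp`` is the summed exon length; ``gene_length_bp``
    the genomic span ``tx_end - tx_start``.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds_length_bp: int = 0
    is_autosomal: bool = True

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValidationError(
                f"{self.gene_id}: tx_start {self.tx_start} >= tx_end {self.tx_end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValidationError(
                    f"{self.gene_id}: exon ({start}, {end}) has end <= start"
                )
            if start < self.tx_start or end > self.tx_end:
                raise ValidationError(
                    f"{self.gene_id}: exon ({start}, {end}) outside transcript "
                    f"bounds [{self.tx_start}, {self.tx_end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"{self.gene_id}: exons overlap or are unsorted at ({start}, {end})"
                )
            prev_end = end

    @property
    def gene_length_bp(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def transcript_length_bp(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class ConstraintRecord:
    """Per-gene constraint metrics from a population reference."""

    gene_id: str
    pli: float
    loeuf: float
    missense_z: float
    oe_lof: float = float("nan")
    cds_length_bp: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pli <= 1.0:
            raise ValidationError(f"{self.gene_id}: pLI {self.pli} outside [0, 1]")
        if self.loeuf < 0:
            raise ValidationError(f"{self.gene_id}: negative LOEUF {self.loeuf}")


@dataclass(frozen=True)
class SVSite:
    """One deletion site segregating in a population catalog."""

    chrom: str
    start: int
    end: int
    sv_type: str = "DEL"
    population: str = "ALL"
    allele_count: int = 1

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValidationError(f"end {self.end} <= start {self.start}")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SDPair:
    """A segmental-duplication pair; NAHR between close pairs mediates CNVs."""

    interval_a: tuple[str, int, int]
    interval_b: tuple[str, int, int]

    @property
    def separation_bp(self) -> int:
        """Gap between the two members; 0 if they touch, overlap or sit on
        different chromosomes (treated as not-a-pair by callers)."""
        ca, sa, ea = self.interval_a
        cb, sb, eb = self.interval_b
        if ca != cb:
            return 0
        return max(0, max(sa, sb) - min(ea, eb))


@dataclass(frozen=True)
class DnmRecord:
    """One de novo call.  ``mpc`` is meaningful only for missense records;
    a single CNV event may appear once per overlapped gene."""

    sample_id: str
    gene_id: str
    consequence: str
    mpc: float | None = None
    cohort: str = "default"
    amino_acid_position: int | None = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise ValidationError(f"unknown consequence {self.consequence!r}")

    @property
    def is_lof(self) -> bool:
        return self.consequence in LOF_SNV_CLASSES or self.consequence == "cnv_lof"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _lines(stream: Iterable[str] | TextIO):
    for i, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        yield i, line


def read_gene_models(stream: Iterable[str]) -> list[GeneModel]:
    """Parse a GFF3-style annotation into :class:`GeneModel` records.

    Expects ``transcript`` features carrying ``ID=``, ``gene_id=`` and
    optionally ``canonical=``/``biotype=`` attributes, and ``exon`` features
    carrying ``Parent=``.  1-based inclusive GFF3 coordinates are converted
    to 0-based half-open.  Non-canonical or non-protein-coding transcripts
    are dropped with a logged count.
    """
    transcripts: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    dropped = 0
    for lineno, line in _lines(stream):
        parts = line.split("\t")
        if len(parts) != 9:
            raise ParseError(f"line {lineno}: expected 9 columns, got {len(parts)}")
        chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = parts
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer coordinates") from exc
        attrs = dict(
            kv.split("=", 1) for kv in attrs_s.split(";") if "=" in kv
        )
        if ftype in {"transcript", "mRNA"}:
            if (
                attrs.get("canonical", "1") not in {"1", "true", "True"}
                or attrs.get("biotype", "protein_coding") != "protein_coding"
            ):
                dropped += 1
                continue
            tid = attrs.get("ID", attrs.get("gene_id", f"tx{lineno}"))
            transcripts[tid] = {
                "gene_id": attrs.get("gene_id", tid),
                "chrom": chrom,
                "strand": strand,
                "tx_start": start1 - 1,
                "tx_end": end1,
                "cds_length_bp": int(attrs.get("cds_length", 0)),
            }
        elif ftype == "exon":
            parent = attrs.get("Parent")
            if parent is None:
                raise ParseError(f"line {lineno}: exon without Parent attribute")
            exons.setdefault(parent, []).append((start1 - 1, end1))
    if dropped:
        logger.info("read_gene_models: dropped %d non-canonical transcripts", dropped)
    models = []
    for tid, tx in transcripts.items():
        ex = tuple(sorted(exons.get(tid, [])))
        chrom = tx["chrom"]
        models.append(
            GeneModel(
                gene_id=tx["gene_id"],
                chrom=chrom,
                strand=tx["strand"],
                tx_start=tx["tx_start"],
                tx_end=tx["tx_end"],
                exons=ex,
                cds_length_bp=tx["cds_length_bp"],
                is_autosomal=chrom not in {"chrX", "chrY", "X", "Y"},
            )
        )
    return models


def write_gene_models(models: Sequence[GeneModel], stream: TextIO) -> None:
    """Inverse of :func:`read_gene_models` (canonical transcripts only)."""
    stream.write("##gff-version 3\n")
    for g in models:
        attrs = f"ID={g.gene_id}.t1;gene_id={g.gene_id};canonical=1;biotype=protein_coding;cds_length={g.cds_length_bp}"
        stream.write(
            f"{g.chrom}\t.\ttranscript\t{g.tx_start + 1}\t{g.tx_end}\t.\t{g.strand}\t.\t{attrs}\n"
        )
        for s, e in g.exons:
            stream.write(
                f"{g.chrom}\t.\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}.t1\n"
            )


def read_sv_sites(stream: Iterable[str]) -> list[SVSite]:
    """Parse BED-like SV records (chrom, start, end[, type, population, AC]).

    Non-deletion records are filtered out with a logged count; coordinates
    are validated (0-based half-open, end > start).
    """
    sites = []
    filtered = 0
    for lineno, line in _lines(stream):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"line {lineno}: expected >=3 columns")
        chrom, start_s, end_s = parts[:3]
        sv_type = parts[3] if len(parts) > 3 else "DEL"
        population = parts[4] if len(parts) > 4 else "ALL"
        allele_count = int(parts[5]) if len(parts) > 5 else 1
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer coordinates") from exc
        if sv_type != "DEL":
            filtered += 1
            continue
        try:
            sites.append(
                SVSite(chrom, start, end, sv_type, population, allele_count)
            )
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from exc
    if filtered:
        logger.info("read_sv_sites: filtered %d non-DEL records", filtered)
    return sites


def write_sv_sites(sites: Sequence[SVSite], stream: TextIO) -> None:
    for s in sites:
        stream.write(
            f"{s.chrom}\t{s.start}\t{s.end}\t{s.sv_type}\t{s.population}\t{s.allele_count}\n"
        )


def read_sd_pairs(stream: Iterable[str]) -> list[SDPair]:
    """Parse SD pairs: chromA startA endA chromB startB endB."""
    pairs = []
    for lineno, line in _lines(stream):
        parts = line.split("\t")
        if len(parts) < 6:
            raise ParseError(f"line {lineno}: expected 6 columns")
        try:
            pairs.append(
                SDPair(
                    (parts[0], int(parts[1]), int(parts[2])),
                    (parts[3], int(parts[4]), int(parts[5])),
                )
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
    return pairs


def read_constraints(stream: Iterable[str]) -> dict[str, ConstraintRecord]:
    """Parse a constraint TSV with header gene_id/pli/loeuf/missense_z[/oe_lof/cds_length]."""
    it = _lines(stream)
    try:
        _, header = next(it)
    except StopIteration:
        return {}
    cols = header.split("\t")
    idx = {c: i for i, c in enumerate(cols)}
    for required in ("gene_id", "pli", "loeuf", "missense_z"):
        if required not in idx:
            raise ParseError(f"constraint table missing column {required!r}")
    out = {}
    for lineno, line in it:
        parts = line.split("\t")
        rec = ConstraintRecord(
            gene_id=parts[idx["gene_id"]],
            pli=float(parts[idx["pli"]]),
            loeuf=float(parts[idx["loeuf"]]),
            missense_z=float(parts[idx["missense_z"]]),
            oe_lof=float(parts[idx["oe_lof"]]) if "oe_lof" in idx else float("nan"),
            cds_length_bp=int(parts[idx["cds_length"]]) if "cds_length" in idx else 0,
        )
        out[rec.gene_id] = rec
    return out


def read_dnm_table(stream: Iterable[str], cohort: str | None = None) -> list[DnmRecord]:
    """Parse a DNM TSV with header sample/gene/consequence[/mpc/cohort/aa_pos]."""
    it = _lines(stream)
    try:
        _, header = next(it)
    except StopIteration:
        return []
    idx = {c: i for i, c in enumerate(header.split("\t"))}
    for required in ("sample", "gene", "consequence"):
        if required not in idx:
            raise ParseError(f"DNM table missing column {required!r}")

    def _opt(parts, col, cast):
        if col not in idx or idx[col] >= len(parts):
            return None
        v = parts[idx[col]]
        return cast(v) if v not in {"", "NA", "."} else None

    records = []
    for lineno, line in it:
        parts = line.split("\t")
        records.append(
            DnmRecord(
                sample_id=parts[idx["sample"]],
                gene_id=parts[idx["gene"]],
                consequence=parts[idx["consequence"]],
                mpc=_opt(parts, "mpc", float),
                cohort=cohort or (_opt(parts, "cohort", str) or "default"),
                amino_acid_position=_opt(parts, "aa_pos", int),
            )
        )
    return records


def read_chrom_sizes(stream: Iterable[str]) -> dict[str, int]:
    """Parse a two-column chrom\tlength table."""
    out = {}
    for lineno, line in _lines(stream):
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"line {lineno}: expected 2 columns")
        out[parts[0]] = int(parts[1])
    return out


# ---------------------------------------------------------------------------
# interval semantics
# ---------------------------------------------------------------------------


def overlaps_exon(site: SVSite, gene: GeneModel) -> bool:
    """True iff the deletion intersects >=1 exon (half-open intersection).

    A deletion ending exactly at an exon start, or starting exactly at an
    exon end, does not overlap. Any overlap length >= 1 bp counts: the CNV
    class of interest is exon-deleting deletions, with no minimum overlap.
    """
    if site.chrom != gene.chrom:
        return False
    for ex_start, ex_end in gene.exons:
        if site.start < ex_end and ex_start < site.end:
            return True
        if ex_start >= site.end:
            break
    return False
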