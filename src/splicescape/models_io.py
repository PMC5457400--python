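"""Domain types and readers/writers for the formats the pipeline touches.

All genomic intervals are 0-based half-open and sorted by genomic
coordinate; GTF/GFF3 I/O converts to/from 1-based inclusive at the file
boundary.  Every sequence-facing operation hands out 5'->3'
transcript-oriented sequence; genomic coordinates are retained for
reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

Interval = tuple[int, int]

_VALID_STRANDS = {"+", "-"}


class ModelError(ValueError):
    """Raised when a gene/transcript model violates its invariants."""


class ParseError(ValueError):
    """Raised on malformed input records; message names the offending line."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class TranscriptModel:
    """One isoform: an ordered exon chain on a chromosome strand."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise ModelError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ModelError(f"{self.transcript_id}: transcript has no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in self.exons:
            if s >= e:
                raise ModelError(f"{self.transcript_id}: empty exon ({s},{e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 - e1 < 1:
                raise ModelError(
                    f"{self.transcript_id}: exons ({s1},{e1}) and ({s2},{e2}) "
                    "overlap or are adjacent (intron must be >= 1 nt)"
                )

    # -- derived geometry ------------------------------------------------
    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> list[Interval]:
        """Introns in genomic order."""
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    def exons_transcription_order(self) -> list[Interval]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start (boundary position)."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def tts(self) -> int:
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0]


@dataclass
class GeneModel:
    """A locus: >=1 isoform sharing chromosome and strand."""

    gene_id: str
    transcripts: list[TranscriptModel]
    reference_transcript_id: str | None = None

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ModelError(f"{self.gene_id}: gene has no transcripts")
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ModelError(f"{self.gene_id}: duplicate transcript ids")
        t0 = self.transcripts[0]
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ModelError(
                    f"{self.gene_id}: transcript {t.transcript_id} carries "
                    f"gene_id {t.gene_id}"
                )
            if (t.chrom, t.strand) != (t0.chrom, t0.strand):
                raise ModelError(
                    f"{self.gene_id}: transcripts disagree on chrom/strand"
                )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> Interval:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass
class SpliceJunction:
    """An intron boundary pair with spliceosome subtype annotation.

    ``donor_pos``/``acceptor_pos`` are the genomic boundary coordinates of
    the intron (half-open interval endpoints); the donor precedes the
    acceptor in transcription order, so on the minus strand the donor is
    the genomically-right boundary.
    """

    gene_id: str
    donor_pos: int
    acceptor_pos: int
    strand: str
    donor_dinucleotide: str = "NN"
    acceptor_dinucleotide: str = "NN"
    subtype: str = "unclassified"
    is_alternative: bool = False

    @property
    def interval(self) -> Interval:
        """Genomic intron interval (start, end)."""
        lo, hi = sorted((self.donor_pos, self.acceptor_pos))
        return (lo, hi)


@dataclass
class PeptideObservation:
    peptide_sequence: str
    sample_id: str
    spectral_count: int

    def __post_init__(self) -> None:
        if self.spectral_count < 0:
            raise ModelError(
                f"peptide {self.peptide_sequence}: negative spectral count"
            )
        bad = set(self.peptide_sequence) - set("ACDEFGHIKLMNPQRSTVWY")
        if bad:
            raise ModelError(
                f"peptide {self.peptide_sequence}: non-standard residues {bad}"
            )


class ExpressionMatrix:
    """FPKM per transcript x sample, with a sample -> condition map."""

    def __init__(self, values: pd.DataFrame, conditions: Mapping[str, str]):
        if (values.values < 0).any():
            raise ModelError("FPKM values must be non-negative")
        missing = set(values.columns) - set(conditions)
        if missing:
            raise ModelError(f"samples without condition assignment: {missing}")
        self.values = values.astype(float)
        self.conditions = dict(conditions)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def condition_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            c = self.conditions[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.conditions[s] == condition]

    def condition_means(self) -> pd.DataFrame:
        """Mean FPKM per transcript x condition."""
        groups = {c: self.samples_of(c) for c in self.condition_names}
        return pd.DataFrame(
            {c: self.values[cols].mean(axis=1) for c, cols in groups.items()}
        )

    def gene_totals(self, genes: Iterable[GeneModel]) -> pd.DataFrame:
        """Summed isoform FPKM per gene x sample."""
        rows = {}
        for g in genes:
            tids = [t.transcript_id for t in g.transcripts]
            present = [t for t in tids if t in self.values.index]
            rows[g.gene_id] = self.values.loc[present].sum(axis=0)
        return pd.DataFrame(rows).T

    def check_against(self, genes: Iterable[GeneModel]) -> list[str]:
        """Return transcript ids in the matrix that no gene model explains."""
        known = {
            t.transcript_id for g in genes for t in g.transcripts
        }
        unknown = [t for t in self.values.index if t not in known]
        if unknown:
            warnings.warn(
                f"{len(unknown)} expression rows do not match any transcript "
                f"(e.g. {unknown[:3]})",
                stacklevel=2,
            )
        return unknown


# ---------------------------------------------------------------------------
# GTF / GFF3
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk and '"' not in chunk:  # GFF3 dialect
            key, _, val = chunk.partition("=")
            attrs[key.strip()] = val.strip()
        else:
            key, _, val = chunk.partition(" ")
            attrs[key.strip()] = val.strip().strip('"')
    return attrs


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF or GFF3.

    Accepts both ``gene_id "x"; transcript_id "y"`` (GTF) and
    ``ID=/Parent=`` chains (GFF3).  Only ``exon`` features are structural;
    ``mRNA``/``transcript`` features are used to resolve GFF3 parent
    chains.  File coordinates (1-based inclusive) are converted to the
    internal 0-based half-open convention.
    """
    path = Path(path)
    tx_parent: dict[str, str] = {}  # GFF3: transcript ID -> gene ID
    exon_rows: list[tuple[int, str, int, int, str, dict[str, str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            _, _, ftype, start_s, end_s, _, strand, _, attr_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path.name}:{lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            attrs = _parse_gtf_attributes(attr_s)
            if ftype in ("mRNA", "transcript") and "ID" in attrs:
                parent = attrs.get("Parent") or attrs.get("gene_id")
                if parent:
                    tx_parent[attrs["ID"]] = parent
            if ftype != "exon":
                continue
            exon_rows.append((lineno, fields[0], start, end, strand, attrs))

    by_tx: dict[str, dict] = {}
    for lineno, chrom, start, end, strand, attrs in exon_rows:
        tid = attrs.get("transcript_id") or attrs.get("Parent")
        if tid is None:
            raise ParseError(
                f"{path.name}:{lineno}: exon without transcript_id/Parent"
            )
        gid = attrs.get("gene_id") or tx_parent.get(tid)
        if gid is None:
            raise ParseError(
                f"{path.name}:{lineno}: cannot resolve gene for transcript {tid}"
            )
        rec = by_tx.setdefault(
            tid, {"gene_id": gid, "chrom": chrom, "strand": strand, "exons": []}
        )
        if rec["chrom"] != chrom:
            raise ParseError(
                f"{path.name}:{lineno}: transcript {tid} spans two "
                f"chromosomes ({rec['chrom']} and {chrom})"
            )
        rec["exons"].append((start - 1, end))  # to 0-based half-open

    by_gene: dict[str, list[TranscriptModel]] = {}
    for tid, rec in by_tx.items():
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=rec["exons"],
        )
        by_gene.setdefault(rec["gene_id"], []).append(t)
    return [GeneModel(gid, txs) for gid, txs in by_gene.items()]


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF (exon features, 1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            for t in g.transcripts:
                for s, e in t.exons:
                    attrs = (
                        f'gene_id "{g.gene_id}"; '
                        f'transcript_id "{t.transcript_id}";'
                    )
                    fh.write(
                        f"{t.chrom}\tsplicescape\texon\t{s + 1}\t{e}\t.\t"
                        f"{t.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------

def infer_conditions(samples: Iterable[str]) -> dict[str, str]:
    """Map ``<condition>_rep<k>``-style sample names to conditions.

    Samples without a ``_rep`` suffix are their own condition.
    """
    out = {}
    for s in samples:
        base, sep, tail = s.rpartition("_rep")
        out[s] = base if sep and tail.isdigit() else s
    return out


def read_expression(
    path: str | Path,
    conditions: Mapping[str, str] | None = None,
    genes: Iterable[GeneModel] | None = None,
) -> ExpressionMatrix:
    """Read an FPKM table (first column transcript_id, one column per sample)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
                raise ParseError(
                    f"{path.name}: empty FPKM cell at row {df.index[i]!r}, "
                    f"column {col!r}"
                )
            try:
                v = float(raw)
            except ValueError:
                raise ParseError(
                    f"{path.name}: non-numeric FPKM {raw!r} at row "
                    f"{df.index[i]!r}, column {col!r}"
                ) from None
            if v < 0:
                raise ParseError(
                    f"{path.name}: negative FPKM {v} at row {df.index[i]!r}, "
                    f"column {col!r}"
                )
    values = df.astype(float)
    cond = dict(conditions) if conditions else infer_conditions(values.columns)
    mat = ExpressionMatrix(values, cond)
    if genes is not None:
        mat.check_against(genes)
    return mat


def write_expression(mat: ExpressionMatrix, path: str | Path) -> None:
    mat.values.to_csv(path, sep="\t", index_label="transcript_id", float_format="%.6g")


# ---------------------------------------------------------------------------
# Peptide observation TSV
# ---------------------------------------------------------------------------

def read_peptide_observations(path: str | Path) -> list[PeptideObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "sample": str})
    out = []
    for _, row in df.iterrows():
        out.append(
            PeptideObservation(
                peptide_sequence=row["peptide"],
                sample_id=str(row["sample"]),
                spectral_count=int(row["spectral_count"]),
            )
        )
    return out


def write_peptide_observations(
    obs: Iterable[PeptideObservation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tsample\tspectral_count\n")
        for o in obs:
            fh.write(f"{o.peptide_sequence}\t{o.sample_id}\t{o.spectral_count}\n")


# ---------------------------------------------------------------------------
# Sequence extraction
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> dict[str, str]:
    """Load a (toy-scale) genome FASTA fully into memory."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _fetch(genome: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    try:
        seq = genome[chrom]
    except KeyError:
        raise ModelError(f"chromosome {chrom!r} missing from genome") from None
    if start < 0 or end > len(seq):
        raise ModelError(
            f"interval ({start},{end}) out of bounds for {chrom} "
            f"(length {len(seq)})"
        )
    return seq[start:end]


def spliced_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """5'->3' mature transcript sequence (exons concatenated, strand applied)."""
    forward = "".join(_fetch(genome, t.chrom, s, e) for s, e in t.exons)
    return forward if t.strand == "+" else reverse_complement(forward)


def premrna_sequence(gene: GeneModel, genome: Mapping[str, str]) -> str:
    """5'->3' unspliced (genomic-span) sequence of the locus."""
    s, e = gene.span
    forward = _fetch(genome, gene.chrom, s, e)
    return forward if gene.strand == "+" else reverse_complement(forward)


def intron_sequence(
    chrom: str, strand: str, intron: Interval, genome: Mapping[str, str]
) -> str:
    """Intron sequence 5'->3' in transcription orientation."""
    raw = _fetch(genome, chrom, intron[0], intron[1])
    return raw if strand == "+" else reverse_complement(raw)


def extract_sequences(
    genes: Iterable[GeneModel], genome: Mapping[str, str]
) -> list[GeneModel]:
    """Populate every transcript's ``sequence`` field in place."""
    genes = list(genes)
    for g in genes:
        for t in g.transcripts:
            t.sequence = spliced_sequence(t, genome)
    return genes


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def write_bed6(
    rows: Iterable[tuple[str, int, int, str, float, str]], path: str | Path
) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")
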