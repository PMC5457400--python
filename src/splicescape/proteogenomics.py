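"""ORF prediction, in-silico trypsinolysis, and peptide specificity.

An isoform-specific peptide (ISP) is a tryptic peptide whose sequence
occurs in the digest of exactly one isoform ORF of exactly one gene; the
observation of ISPs from two or more isoforms of the same locus is the
proteome-level evidence that the locus translates alternative isoforms.
I and L are indistinguishable by mass spectrometry, so peptide identity
is compared after collapsing I to L by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .models_io import ExpressionMatrix, PeptideObservation

STOP_CODONS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {}


def _build_codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for c in STOP_CODONS:
        table[c] = "*"
    return table


def translate(cds: str) -> str:
    """Translate an in-frame CDS; trailing stop is dropped."""
    global _CODON_TABLE
    if not _CODON_TABLE:
        _CODON_TABLE = _build_codon_table()
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = _CODON_TABLE.get(cds[i : i + 3], "X")
        if aa == "*":
            break
        aas.append(aa)
    return "".join(aas)


@dataclass
class OrfRecord:
    orf_id: str
    transcript_id: str
    start: int               # 0-based offset on the spliced transcript
    end: int                 # half-open end (includes the stop codon if any)
    frame: int
    protein_sequence: str
    utr5_length: int
    partial: bool = False    # no stop codon before the transcript end


def predict_orfs(
    transcript_id: str,
    sequence: str,
    min_len: int = 100,
    require_atg: bool = True,
    include_partial: bool = True,
) -> list[OrfRecord]:
    """Longest-ORF scan over the three sense frames.

    ``min_len`` is the minimum protein length in codons.  Within each
    stop-free stretch the first qualifying start is used (longest ORF);
    the returned list is sorted longest-first, so the primary ORF is
    element 0.  ``utr5_length`` is the start offset on the spliced
    transcript.
    """
    seq = sequence.upper()
    n = len(seq)
    orfs: list[OrfRecord] = []
    for frame in range(3):
        start: int | None = None
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if start is None:
                if (codon == "ATG") if require_atg else (codon not in STOP_CODONS):
                    start = i
            if codon in STOP_CODONS and start is not None:
                protein = translate(seq[start : i])
                if len(protein) >= min_len:
                    orfs.append(
                        OrfRecord(
                            orf_id="",
                            transcript_id=transcript_id,
                            start=start,
                            end=i + 3,
                            frame=frame,
                            protein_sequence=protein,
                            utr5_length=start,
                        )
                    )
                start = None
            i += 3
        if start is not None and include_partial:
            end = start + ((n - start) // 3) * 3
            protein = translate(seq[start : end])
            if len(protein) >= min_len:
                orfs.append(
                    OrfRecord(
                        orf_id="",
                        transcript_id=transcript_id,
                        start=start,
                        end=end,
                        frame=frame,
                        protein_sequence=protein,
                        utr5_length=start,
                        partial=True,
                    )
                )
    orfs.sort(key=lambda o: (-len(o.protein_sequence), o.start, o.frame))
    for i, o in enumerate(orfs):
        o.orf_id = f"{transcript_id}.orf{i + 1}"
    return orfs


def primary_orf(
    transcript_id: str, sequence: str, min_len: int = 100, require_atg: bool = True
) -> OrfRecord | None:
    orfs = predict_orfs(transcript_id, sequence, min_len, require_atg)
    return orfs[0] if orfs else None


# ---------------------------------------------------------------------------
# Tryptic digestion
# ---------------------------------------------------------------------------

def digest_trypsin(protein: str, max_missed: int = 1) -> list[tuple[str, int]]:
    """In-silico trypsinolysis: (peptide, missed cleavages) pairs.

    Cleaves C-terminal of K or R except when the next residue is P (Keil
    rule); peptides with up to ``max_missed`` internal uncleaved sites
    are emitted as concatenations of adjacent fully-cleaved fragments.
    """
    protein = protein.upper()
    if not protein:
        return []
    cuts = [0]
    for i, aa in enumerate(protein[:-1]):
        if aa in "KR" and protein[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein))
    fragments = [protein[a:b] for a, b in zip(cuts, cuts[1:])]
    peptides = []
    for i in range(len(fragments)):
        for m in range(min(max_missed, len(fragments) - i - 1) + 1):
            peptides.append(("".join(fragments[i : i + m + 1]), m))
    return peptides


def _canonical(peptide: str, il_equivalence: bool) -> str:
    return peptide.replace("I", "L") if il_equivalence else peptide


def digest_set(
    protein: str,
    max_missed: int = 1,
    min_len: int = 7,
    max_len: int = 50,
    il_equivalence: bool = True,
) -> set[str]:
    """Canonicalised, length-filtered digest of one protein."""
    return {
        _canonical(p, il_equivalence)
        for p, _ in digest_trypsin(protein, max_missed)
        if min_len <= len(p) <= max_len
    }


# ---------------------------------------------------------------------------
# Peptide specificity
# ---------------------------------------------------------------------------

@dataclass
class PeptideRecord:
    sequence: str                      # canonical (I->L when collapsed)
    parent_orf_ids: set[str]
    transcript_ids: set[str]
    gene_ids: set[str]
    specificity: str                   # isoform_specific | gene_unique_shared | multi_gene
    missed_cleavages: int


def classify_peptides(
    orfs_by_gene: Mapping[str, Sequence[OrfRecord]],
    min_len: int = 7,
    max_len: int = 50,
    il_equivalence: bool = True,
    max_missed: int = 1,
) -> dict[str, PeptideRecord]:
    """Specificity classes for every peptide of an ORF database.

    Occurrence is exact membership of the peptide in each ORF's digest
    (not substring matching against the protein): an observed tryptic
    peptide must be producible by digestion.  ``isoform_specific``
    requires exactly one containing isoform ORF within a single gene;
    peptides shared by >=2 isoforms of one gene are
    ``gene_unique_shared``; anything found in two genes is ``multi_gene``.
    """
    records: dict[str, PeptideRecord] = {}
    for gene_id, orfs in orfs_by_gene.items():
        for orf in orfs:
            for pep, missed in digest_trypsin(orf.protein_sequence, max_missed):
                if not (min_len <= len(pep) <= max_len):
                    continue
                key = _canonical(pep, il_equivalence)
                rec = records.get(key)
                if rec is None:
                    rec = PeptideRecord(
                        sequence=key,
                        parent_orf_ids=set(),
                        transcript_ids=set(),
                        gene_ids=set(),
                        specificity="",
                        missed_cleavages=missed,
                    )
                    records[key] = rec
                rec.parent_orf_ids.add(orf.orf_id)
                rec.transcript_ids.add(orf.transcript_id)
                rec.gene_ids.add(gene_id)
                rec.missed_cleavages = min(rec.missed_cleavages, missed)
    for rec in records.values():
        if len(rec.gene_ids) > 1:
            rec.specificity = "multi_gene"
        elif len(rec.transcript_ids) == 1:
            rec.specificity = "isoform_specific"
        else:
            rec.specificity = "gene_unique_shared"
    return records


# ---------------------------------------------------------------------------
# Observed-peptide mapping
# ---------------------------------------------------------------------------

@dataclass
class GeneEvidence:
    gene_id: str
    observed_peptides: set[str] = field(default_factory=set)
    isp_spectra_by_isoform: dict[str, int] = field(default_factory=dict)
    total_spectra: int = 0

    @property
    def confirmed(self) -> bool:
        return bool(self.observed_peptides)

    @property
    def has_isp(self) -> bool:
        return bool(self.isp_spectra_by_isoform)

    @property
    def as_confirmed(self) -> bool:
        """AS confirmed at proteome level: ISPs from >= 2 distinct isoforms."""
        return len(self.isp_spectra_by_isoform) >= 2


@dataclass
class MappingSummary:
    genes: dict[str, GeneEvidence]
    unmapped: list[str]

    @property
    def confirmed_genes(self) -> set[str]:
        return {g for g, ev in self.genes.items() if ev.confirmed}

    @property
    def genes_with_isp(self) -> set[str]:
        return {g for g, ev in self.genes.items() if ev.has_isp}

    @property
    def as_confirmed_genes(self) -> set[str]:
        return {g for g, ev in self.genes.items() if ev.as_confirmed}


def map_observed_peptides(
    observations: Iterable[PeptideObservation],
    records: Mapping[str, PeptideRecord],
    il_equivalence: bool = True,
) -> MappingSummary:
    """Join observed peptides to the specificity database.

    Observed peptides absent from the database are reported as unmapped,
    never silently dropped.
    """
    genes: dict[str, GeneEvidence] = {}
    unmapped: list[str] = []
    for obs in observations:
        key = _canonical(obs.peptide_sequence, il_equivalence)
        rec = records.get(key)
        if rec is None:
            unmapped.append(obs.peptide_sequence)
            continue
        for gid in rec.gene_ids:
            ev = genes.setdefault(gid, GeneEvidence(gene_id=gid))
            ev.observed_peptides.add(key)
            ev.total_spectra += obs.spectral_count
            if rec.specificity == "isoform_specific":
                (tid,) = rec.transcript_ids
                ev.isp_spectra_by_isoform[tid] = (
                    ev.isp_spectra_by_isoform.get(tid, 0) + obs.spectral_count
                )
    return MappingSummary(genes=genes, unmapped=unmapped)


def correlate_spectra_fpkm(
    summary: MappingSummary,
    expr: ExpressionMatrix,
    condition: str,
) -> tuple[float, float, int]:
    """Rank correlation between isoform FPKM and ISP spectral counts.

    Pools (isoform FPKM, normalised spectra) points over all genes with
    ISP evidence; spectra are normalised within each gene so abundant
    genes do not dominate.  Returns (rho, p, n_points).
    """
    means = expr.condition_means()
    xs, ys = [], []
    for ev in summary.genes.values():
        total = sum(ev.isp_spectra_by_isoform.values())
        if total == 0:
            continue
        for tid, count in ev.isp_spectra_by_isoform.items():
            if tid in means.index:
                xs.append(means.loc[tid, condition])
                ys.append(count / total)
    if len(xs) < 3:
        return (float("nan"), float("nan"), len(xs))
    res = spearmanr(xs, ys)
    return (float(res.statistic), float(res.pvalue), len(xs))


def orfs_per_gene_table(
    orfs_by_gene: Mapping[str, Sequence[OrfRecord]],
    isoforms_by_gene: Mapping[str, int],
) -> pd.DataFrame:
    """Per-gene isoform count vs number of distinct predicted ORFs."""
    rows = []
    for gid, n_iso in isoforms_by_gene.items():
        orfs = orfs_by_gene.get(gid, [])
        unique_proteins = {o.protein_sequence for o in orfs}
        rows.append(
            {
                "gene_id": gid,
                "n_isoforms": n_iso,
                "n_unique_orfs": len(unique_proteins),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
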