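"""Synthetic genomes, transcript catalogues, expression, MS and lncRNA data
with a planted ground-truth registry.

Every generator is a pure function of its parameters and a seed, so each
pipeline stage can be tested against exactly known truth without any
external download.  The gene builder works on a local transcription-
oriented axis and mirrors coordinates for minus-strand genes; splice-site
consensus bases are written only on the intron side of each signal
(donor +1..+10, acceptor -14..-1, U12 branch box), so planted coding
sequence in exons is never disturbed, and alternative donors/acceptors
and cassette exons are placed inside the reference intron for the same
reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models_io import (
    ExpressionMatrix,
    GeneModel,
    Interval,
    PeptideObservation,
    TranscriptModel,
    premrna_sequence,
    reverse_complement,
    spliced_sequence,
    write_expression,
    write_fasta,
    write_gene_models,
    write_peptide_observations,
)
from .proteogenomics import PeptideRecord, predict_orfs

# Intron-side consensus written into synthetic splice sites; argmax rows of
# the default PPMs in as_events, so planted junctions score maximally.
U2_DONOR_MOTIF = "GTAAGTATTT"
U2_ACCEPTOR_MOTIF = "TTTTTCCTTTTCAG"
U12_DONOR_MOTIF = "ATATCCTTTC"
U12_BRANCH_MOTIF = "TTCCTTAAC"
U12_BRANCH_OFFSET = 30  # branch box written at acceptor-30 .. acceptor-21

STOPS = {"TAA", "TAG", "TGA"}
NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
]

# Planted event mix per 40 genes; intron retention dominates, as in moss.
DEFAULT_EVENTS = {
    "intron_retention": 8,
    "alt_donor": 5,
    "alt_acceptor": 5,
    "exon_skipping": 6,
    "mutually_exclusive_exons": 2,
    "alt_tss": 3,
    "alt_tts": 2,
}


def scaled_default_events(n_genes: int) -> dict[str, int]:
    """The default event mix scaled to the catalogue size (density per 40)."""
    return {
        et: max(1, round(n * n_genes / 40)) for et, n in DEFAULT_EVENTS.items()
    }

DEFAULT_CONDITIONS = ("gametophore", "protonema", "protoplast")


# ---------------------------------------------------------------------------
# Ground truth registry
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Registry of everything the generators planted."""

    events: list[dict] = field(default_factory=list)
    u12_genes: list[str] = field(default_factory=list)
    orfs: dict[str, dict] = field(default_factory=dict)  # tid -> utr5/n_codons
    das_genes: dict[str, float] = field(default_factory=dict)  # gene -> dIF
    de_genes: dict[str, float] = field(default_factory=dict)   # gene -> log2fc
    abundances: dict[str, dict[str, float]] = field(default_factory=dict)
    lnc_sites: list[dict] = field(default_factory=list)
    lnc_classes: dict[str, str] = field(default_factory=dict)
    coregulated_pairs: list[dict] = field(default_factory=list)
    ms_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "events": self.events,
            "u12_genes": self.u12_genes,
            "orfs": self.orfs,
            "das_genes": self.das_genes,
            "de_genes": self.de_genes,
            "abundances": self.abundances,
            "lnc_sites": self.lnc_sites,
            "lnc_classes": self.lnc_classes,
            "coregulated_pairs": self.coregulated_pairs,
            "ms_params": self.ms_params,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        gt = cls(**{k: d[k] for k in d})
        gt.events = [
            {**e, "interval": tuple(e["interval"])} for e in gt.events
        ]
        for s in gt.lnc_sites:
            s["lnc_interval"] = tuple(s["lnc_interval"])
            s["target_interval"] = tuple(s["target_interval"])
        return gt

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def event_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.events:
            out[e["event_type"]] = out.get(e["event_type"], 0) + 1
        return out


@dataclass
class SyntheticDataset:
    genome: dict[str, str]
    genes: list[GeneModel]
    ground_truth: GroundTruth
    free_slots: list[Interval] = field(default_factory=list)
    reserved: list[Interval] = field(default_factory=list)  # motif writes
    lncrnas: list[TranscriptModel] = field(default_factory=list)
    expression: ExpressionMatrix | None = None
    observations: list[PeptideObservation] | None = None

    @property
    def chrom(self) -> str:
        return next(iter(self.genome))

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "genes": outdir / "genes.gtf",
            "ground_truth": outdir / "ground_truth.json",
        }
        write_fasta(self.genome, paths["genome"])
        write_gene_models(self.genes, paths["genes"])
        self.ground_truth.save(paths["ground_truth"])
        if self.lncrnas:
            paths["lncrnas"] = outdir / "lncrnas.gtf"
            lnc_genes = [
                GeneModel(t.gene_id, [t]) for t in self.lncrnas
            ]
            write_gene_models(lnc_genes, paths["lncrnas"])
            paths["lnc_classes"] = outdir / "lncrna_classes.tsv"
            with open(paths["lnc_classes"], "w") as fh:
                fh.write("transcript_id\tclass_code\n")
                for t in self.lncrnas:
                    code = self.ground_truth.lnc_classes[t.transcript_id]
                    fh.write(f"{t.transcript_id}\t{code}\n")
        if self.expression is not None:
            paths["expression"] = outdir / "expression.tsv"
            write_expression(self.expression, paths["expression"])
        if self.observations is not None:
            paths["peptides"] = outdir / "peptides_observed.tsv"
            write_peptide_observations(self.observations, paths["peptides"])
        return paths


# ---------------------------------------------------------------------------
# Gene and genome construction
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int) -> list[str]:
    return ["ACGT"[i] for i in rng.integers(0, 4, n)]


def _scrub_atg(chars: list[str]) -> list[str]:
    s = "".join(chars)
    while "ATG" in s:
        i = s.index("ATG")
        s = s[:i + 2] + "C" + s[i + 3:]
    return list(s)


@dataclass
class _LocalGene:
    """A gene on its local transcription axis (0 = TSS, plus orientation)."""

    gene_id: str
    length: int
    seq: list[str]
    transcripts: dict[str, list[Interval]]  # tid -> local exons
    events: list[dict]
    orfs: dict[str, dict]
    reserved: list[Interval]


def _write_motif(g: _LocalGene, pos: int, motif: str) -> None:
    g.seq[pos : pos + len(motif)] = list(motif)
    g.reserved.append((pos, pos + len(motif)))


def _write_intron_motifs(g: _LocalGene, intron: Interval, u12: bool) -> None:
    d, a = intron
    if u12:
        _write_motif(g, d, U12_DONOR_MOTIF)
        _write_motif(g, a - U12_BRANCH_OFFSET, U12_BRANCH_MOTIF)
        _write_motif(g, a - 2, "AC")
    else:
        _write_motif(g, d, U2_DONOR_MOTIF)
        _write_motif(g, a - len(U2_ACCEPTOR_MOTIF), U2_ACCEPTOR_MOTIF)


def _build_local_gene(
    gene_id: str,
    rng: np.random.Generator,
    event_types: Sequence[str],
    u12: bool,
    exon_count: tuple[int, int] = (5, 6),
    exon_codons: tuple[int, int] = (40, 50),
    intron_len: tuple[int, int] = (100, 170),
    cds_codons: tuple[int, int] = (155, 200),
) -> _LocalGene:
    n_exons = int(rng.integers(exon_count[0], exon_count[1] + 1))
    # exon lengths are multiples of 3 so cassette events stay in frame
    exon_lens = [3 * int(rng.integers(*exon_codons)) for _ in range(n_exons)]
    intron_lens = [int(rng.integers(*intron_len)) for _ in range(n_exons - 1)]

    # choose structural slots for the planted events up-front
    slots: dict[str, int] = {}
    taken: set[int] = set()
    for et in event_types:
        if et in ("alt_tss", "alt_tts"):
            continue
        if et == "exon_skipping":
            choices = [i for i in range(1, n_exons - 1)
                       if i not in taken and i - 1 not in taken]
        elif et == "mutually_exclusive_exons":
            # needs exon slot+1 internal and a roomy downstream intron
            choices = [i for i in range(0, n_exons - 2)
                       if i not in taken and i + 1 not in taken]
        else:
            choices = [i for i in range(n_exons - 1) if i not in taken]
        if not choices:
            raise ValueError(f"{gene_id}: no free slot for {et}")
        slot = int(rng.choice(choices))
        slots[et] = slot
        taken.add(slot)
        if et == "mutually_exclusive_exons":
            intron_lens[slot + 1] = 260

    exons: list[Interval] = []
    pos = 0
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < n_exons - 1:
            pos += intron_lens[i]
    length = pos
    introns = [(e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:])]

    g = _LocalGene(
        gene_id=gene_id,
        length=length,
        seq=_random_bases(rng, length),
        transcripts={},
        events=[],
        orfs={},
        reserved=[],
    )
    for intron in introns:
        _write_intron_motifs(g, intron, u12)

    ref_id = f"{gene_id}.t1"
    g.transcripts[ref_id] = list(exons)

    # Embed the reference ORF: ATG-free 5' UTR, stop-free codons, stop.
    spliced_len = sum(e - s for s, e in exons)
    utr5 = int(rng.integers(30, 100))  # always within the first exon
    n_codons = int(rng.integers(*cds_codons))
    cds_len = 3 * (n_codons + 1) + 3  # ATG + codons + stop
    while utr5 + cds_len + 10 > spliced_len:
        n_codons -= 10
        cds_len = 3 * (n_codons + 1) + 3
    if n_codons < 100:
        raise ValueError(f"{gene_id}: transcript too short for a planted ORF")
    codons = [NONSTOP_CODONS[i] for i in rng.integers(0, len(NONSTOP_CODONS), n_codons)]
    content = (
        _scrub_atg(_random_bases(rng, utr5))
        + list("ATG" + "".join(codons) + "TAA")
        + _random_bases(rng, spliced_len - utr5 - cds_len)
    )
    # scatter spliced content into exon positions
    k = 0
    for s, e in exons:
        for p in range(s, e):
            g.seq[p] = content[k]
            k += 1
    g.orfs[ref_id] = {"utr5": utr5, "n_codons": n_codons + 1}

    # Build one variant isoform per planted event.
    var_idx = 2
    for et in event_types:
        tid = f"{gene_id}.t{var_idx}"
        var_idx += 1
        if et == "intron_retention":
            i = slots[et]
            d, a = introns[i]
            var = exons[: i] + [(exons[i][0], exons[i + 1][1])] + exons[i + 2 :]
            g.events.append(
                {"gene_id": gene_id, "event_type": et, "interval": (d, a),
                 "variant": tid}
            )
        elif et == "alt_donor":
            i = slots[et]
            d, a = introns[i]
            delta = 3 * int(rng.integers(6, 15))  # in-frame, 18..42 nt
            vd = d + delta  # variant exon extends into the intron
            var = list(exons)
            var[i] = (var[i][0], vd)
            _write_motif(g, vd, U2_DONOR_MOTIF)
            g.events.append(
                {"gene_id": gene_id, "event_type": et, "interval": (d, vd),
                 "variant": tid}
            )
        elif et == "alt_acceptor":
            i = slots[et]
            d, a = introns[i]
            delta = 3 * int(rng.integers(6, 15))  # in-frame, 18..42 nt
            va = a - delta  # variant exon extends left into the intron
            var = list(exons)
            var[i + 1] = (va, var[i + 1][1])
            _write_motif(g, va - len(U2_ACCEPTOR_MOTIF), U2_ACCEPTOR_MOTIF)
            g.events.append(
                {"gene_id": gene_id, "event_type": et, "interval": (va, a),
                 "variant": tid}
            )
        elif et == "exon_skipping":
            i = slots[et]  # skip exon i (internal)
            var = exons[: i] + exons[i + 1 :]
            g.events.append(
                {"gene_id": gene_id, "event_type": et, "interval": exons[i],
                 "variant": tid}
            )
        elif et == "mutually_exclusive_exons":
            i = slots[et]  # ref exon i+1 is the cassette; eY goes in intron i+1
            ex = exons[i + 1]
            d2, a2 = introns[i + 1]
            ys = d2 + len(U2_DONOR_MOTIF) + len(U2_ACCEPTOR_MOTIF) + 6
            ye = ys + 60
            if ye + len(U2_DONOR_MOTIF) + len(U2_ACCEPTOR_MOTIF) + 6 > a2:
                raise ValueError(f"{gene_id}: cassette intron too small")
            var = exons[: i + 1] + [(ys, ye)] + exons[i + 2 :]
            _write_motif(g, ys - len(U2_ACCEPTOR_MOTIF), U2_ACCEPTOR_MOTIF)
            _write_motif(g, ye, U2_DONOR_MOTIF)
            g.events.append(
                {"gene_id": gene_id, "event_type": et,
                 "interval": (ex[0], ye), "variant": tid}
            )
        elif et == "alt_tss":
            ref_utr5 = g.orfs[ref_id]["utr5"]
            first_len = exons[0][1] - exons[0][0]
            hi = min(first_len - 20, ref_utr5 - 5)
            if hi <= 12:
                raise ValueError(f"{gene_id}: first exon too short for alt TSS")
            delta = int(rng.integers(12, hi))
            var = [(exons[0][0] + delta, exons[0][1])] + exons[1:]
            g.orfs[tid] = {
                "utr5": ref_utr5 - delta,
                "n_codons": g.orfs[ref_id]["n_codons"],
            }
            g.events.append(
                {"gene_id": gene_id, "event_type": et,
                 "interval": (exons[0][0], exons[0][0] + delta),
                 "variant": tid}
            )
        elif et == "alt_tts":
            last_len = exons[-1][1] - exons[-1][0]
            delta = int(rng.integers(12, max(13, last_len - 20)))
            var = exons[:-1] + [(exons[-1][0], exons[-1][1] - delta)]
            g.events.append(
                {"gene_id": gene_id, "event_type": et,
                 "interval": (exons[-1][1] - delta, exons[-1][1]),
                 "variant": tid}
            )
        else:
            raise ValueError(f"unknown event type {et!r}")
        g.transcripts[tid] = var
    return g


def generate_genome_and_genes(
    n_genes: int = 40,
    events_per_type: Mapping[str, int] | None = None,
    n_u12_genes: int = 2,
    n_extra_isoform_genes: int = 2,
    seed: int = 0,
    chrom: str = "chr1",
    spacer_len: tuple[int, int] = (500, 900),
) -> SyntheticDataset:
    """Random genome + multi-isoform gene catalogue with planted AS events.

    Event instances from ``events_per_type`` (intron retention dominant by
    default) are dealt one per gene; ``n_extra_isoform_genes`` of the
    event-carrying genes additionally receive an alternative-TSS isoform,
    giving 3-isoform loci.  ``n_u12_genes`` loci are written with
    AT-AC/branch-box minor-spliceosome introns (single-isoform so the
    U2/U12 census stays clean).  Genes alternate strand; intergenic
    spacers are recorded as free slots for lncRNA placement.
    """
    capacity = n_genes - n_u12_genes
    if events_per_type is None:
        events_per_type = scaled_default_events(n_genes)
        # fit the default mix into small catalogues, round-robin by type
        pools = {et: events_per_type[et] for et in sorted(events_per_type)}
        instances = []
        while len(instances) < capacity and any(pools.values()):
            for et in list(pools):
                if pools[et] > 0 and len(instances) < capacity:
                    instances.append(et)
                    pools[et] -= 1
        instances.sort()
    else:
        instances = []
        for et in sorted(events_per_type):
            instances.extend([et] * events_per_type[et])
    rng = np.random.default_rng(seed)
    if len(instances) + n_u12_genes > n_genes:
        raise ValueError("more planted events + U12 genes than genes")

    gt = GroundTruth()
    genes: list[GeneModel] = []
    genome_parts: list[str] = []
    free_slots: list[Interval] = []
    reserved: list[Interval] = []
    offset = 0
    extra_left = n_extra_isoform_genes
    for gi in range(n_genes):
        gene_id = f"g{gi + 1:03d}"
        u12 = len(instances) <= gi < len(instances) + n_u12_genes
        event_types: list[str] = [instances[gi]] if gi < len(instances) else []
        if event_types and event_types[0] != "alt_tss" and extra_left > 0:
            event_types.append("alt_tss")
            extra_left -= 1
        local = _build_local_gene(gene_id, rng, event_types, u12)

        spacer = int(rng.integers(*spacer_len))
        genome_parts.append("".join(_random_bases(rng, spacer)))
        free_slots.append((offset, offset + spacer))
        offset += spacer

        strand = "+" if rng.integers(0, 2) == 0 else "-"
        L = local.length
        if strand == "+":
            seq = "".join(local.seq)
            def glb(iv: Interval) -> Interval:
                return (offset + iv[0], offset + iv[1])
        else:
            seq = reverse_complement("".join(local.seq))
            def glb(iv: Interval) -> Interval:
                return (offset + L - iv[1], offset + L - iv[0])
        genome_parts.append(seq)

        txs = [
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=[glb(iv) for iv in exons],
            )
            for tid, exons in local.transcripts.items()
        ]
        genes.append(
            GeneModel(gene_id, txs, reference_transcript_id=f"{gene_id}.t1")
        )
        for ev in local.events:
            gt.events.append({**ev, "interval": glb(ev["interval"])})
        gt.orfs.update(local.orfs)
        if u12:
            gt.u12_genes.append(gene_id)
        reserved.extend(glb(iv) for iv in local.reserved)
        offset += L
    tail = int(rng.integers(*spacer_len))
    genome_parts.append("".join(_random_bases(rng, tail)))
    free_slots.append((offset, offset + tail))
    return SyntheticDataset(
        genome={chrom: "".join(genome_parts)},
        genes=genes,
        ground_truth=gt,
        free_slots=free_slots,
        reserved=reserved,
    )


# ---------------------------------------------------------------------------
# Random structures for oracle testing (no motifs, no ORFs)
# ---------------------------------------------------------------------------

def random_gene_models(
    n_genes: int, seed: int = 0, max_isoforms: int = 4
) -> list[GeneModel]:
    """Random 2-4-isoform gene structures for oracle equivalence testing.

    Isoforms are random walks over a shared exon scaffold with random
    boundary jitter, retention, skipping and end variation; no sequence
    or planted-truth guarantees, only structural validity.
    """
    rng = np.random.default_rng(seed)
    genes = []
    for gi in range(n_genes):
        gene_id = f"r{gi + 1:03d}"
        n_exons = int(rng.integers(3, 7))
        scaffold = []
        pos = int(rng.integers(0, 50))
        for _ in range(n_exons):
            el = int(rng.integers(30, 120))
            scaffold.append((pos, pos + el))
            pos += el + int(rng.integers(40, 120))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        n_iso = int(rng.integers(2, max_isoforms + 1))
        txs = []
        for ti in range(n_iso):
            exons = [list(e) for e in scaffold]
            for _ in range(int(rng.integers(0, 3))):
                op = rng.integers(0, 4)
                if op == 0 and len(exons) > 2:  # skip an internal exon
                    del exons[int(rng.integers(1, len(exons) - 1))]
                elif op == 1:  # retain an intron
                    if len(exons) > 1:
                        i = int(rng.integers(0, len(exons) - 1))
                        exons[i] = [exons[i][0], exons[i + 1][1]]
                        del exons[i + 1]
                elif op == 2:  # jitter a boundary into the intron
                    if len(exons) > 1:
                        i = int(rng.integers(0, len(exons) - 1))
                        gap = exons[i + 1][0] - exons[i][1]
                        if gap > 24:
                            if rng.integers(0, 2) == 0:
                                exons[i][1] += int(rng.integers(8, gap - 8))
                            else:
                                exons[i + 1][0] -= int(rng.integers(8, gap - 8))
                else:  # trim an end
                    if rng.integers(0, 2) == 0:
                        exons[0][0] += int(
                            rng.integers(0, max(1, exons[0][1] - exons[0][0] - 10))
                        )
                    else:
                        exons[-1][1] -= int(
                            rng.integers(0, max(1, exons[-1][1] - exons[-1][0] - 10))
                        )
            txs.append(
                TranscriptModel(
                    transcript_id=f"{gene_id}.t{ti + 1}",
                    gene_id=gene_id,
                    chrom="chrR",
                    strand=strand,
                    exons=[tuple(e) for e in exons],
                )
            )
        genes.append(GeneModel(gene_id, txs))
    return genes


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression(
    ds: SyntheticDataset,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    replicates: int = 5,
    n_das: int = 8,
    das_dif: Sequence[float] = (30.0, 50.0, 70.0),
    n_de: int = 6,
    de_log2fc: float = 3.0,
    noise_cv: float = 0.1,
    utr5_association: bool = False,
    base_log_mean: float = 1.5,
    base_log_sd: float = 0.8,
    seed: int = 0,
) -> ExpressionMatrix:
    """FPKM matrix with planted isoform switches and DE genes.

    Condition means are exact by construction (a planted dIF of 60 is the
    computed dIF when ``noise_cv`` is 0); samples add multiplicative
    lognormal noise with the given coefficient of variation.  DAS genes
    swap the fractions of their two leading isoforms between the first
    two conditions; DE genes shift their total FPKM by ``de_log2fc`` in
    the second condition.  With ``utr5_association`` the isoform
    fractions of genes with known planted 5' UTR lengths decrease with
    UTR length.
    """
    rng = np.random.default_rng(seed)
    gt = ds.ground_truth
    # genes under the planted UTR-length/expression law are excluded from
    # switch/DE planting so the monotone map stays intact
    assoc_genes = {
        g.gene_id
        for g in ds.genes
        if utr5_association
        and len(g.transcripts) >= 2
        and all(t.transcript_id in gt.orfs for t in g.transcripts)
    }
    multi = [
        g
        for g in ds.genes
        if len(g.transcripts) >= 2 and g.gene_id not in assoc_genes
    ]
    das_pool = [g.gene_id for g in multi]
    rng.shuffle(das_pool)
    das_genes = das_pool[: min(n_das, len(das_pool))]
    de_pool = [
        g.gene_id
        for g in ds.genes
        if g.gene_id not in das_genes and g.gene_id not in assoc_genes
    ]
    rng.shuffle(de_pool)
    de_genes = de_pool[: min(n_de, len(de_pool))]

    mean_rows: dict[str, dict[str, float]] = {}
    for gi, g in enumerate(ds.genes):
        tids = sorted(t.transcript_id for t in g.transcripts)
        k = len(tids)
        if g.gene_id in assoc_genes:
            # global monotone law: FPKM decreases with 5' UTR length
            for tid in tids:
                v = 25.0 * float(np.exp(-gt.orfs[tid]["utr5"] / 60.0))
                mean_rows[tid] = {c: v for c in conditions}
            continue
        total = float(np.exp(rng.normal(base_log_mean, base_log_sd)))
        totals = {c: total for c in conditions}
        if g.gene_id in de_genes:
            # keep planted DE genes above the detection floor
            total = max(total, 1.0)
            totals = {c: total for c in conditions}
            sign = 1 if rng.integers(0, 2) == 0 else -1
            totals[conditions[1]] = total * 2 ** (sign * de_log2fc)
            gt.de_genes[g.gene_id] = float(sign * de_log2fc)

        base_frac = rng.dirichlet(np.full(k, 2.0))

        fracs = {c: base_frac.copy() for c in conditions}
        if g.gene_id in das_genes and k >= 2:
            dif = float(das_dif[len(gt.das_genes) % len(das_dif)])
            share = 0.9 if k > 2 else 1.0
            a = (share + dif / 100.0) / 2.0
            b = share - a
            rest = base_frac[2:]
            rest = (
                rest / rest.sum() * (1 - share)
                if k > 2 and rest.sum() > 0
                else np.full(k - 2, (1 - share) / max(k - 2, 1))
            )
            f1 = np.concatenate(([a, b], rest))
            f2 = np.concatenate(([b, a], rest))
            fracs[conditions[0]] = f1
            fracs[conditions[1]] = f2
            if len(conditions) > 2:
                for c in conditions[2:]:
                    fracs[c] = f1.copy()
            gt.das_genes[g.gene_id] = dif

        for i, tid in enumerate(tids):
            mean_rows[tid] = {
                c: totals[c] * fracs[c][i] for c in conditions
            }
    for tid, row in mean_rows.items():
        gt.abundances[tid] = {c: float(v) for c, v in row.items()}

    samples = [
        (c, f"{c}_rep{r + 1}") for c in conditions for r in range(replicates)
    ]
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    data = {}
    for c, sname in samples:
        col = []
        for tid in sorted(mean_rows):
            mu = mean_rows[tid][c]
            if noise_cv > 0:
                mu *= float(np.exp(rng.normal(-sigma**2 / 2, sigma)))
            col.append(mu)
        data[sname] = col
    values = pd.DataFrame(data, index=sorted(mean_rows))

    # lncRNA expression.  Planted co-regulated lncRNAs track their target
    # gene's per-sample total affinely (monotone, hence Spearman rho = 1
    # before downstream noise); the rest get independent lognormal noise.
    tx_by_gene = {
        g.gene_id: [t.transcript_id for t in g.transcripts] for g in ds.genes
    }
    for lnc in ds.lncrnas:
        tid = lnc.transcript_id
        target_gene = next(
            (s["target_gene"] for s in gt.lnc_sites if s["lncrna_id"] == tid),
            None,
        )
        if target_gene is not None:
            totals = values.loc[tx_by_gene[target_gene]].sum(axis=0)
            scale = float(np.exp(rng.normal(-1.0, 0.3)))
            row = 0.6 + scale * totals
            gt.coregulated_pairs.append(
                {"lncrna_id": tid, "target_gene": target_gene}
            )
        else:
            base = float(np.exp(rng.normal(0.5, 0.7)))
            noise = np.exp(rng.normal(-sigma**2 / 2, sigma, len(values.columns))) \
                if noise_cv > 0 else np.ones(len(values.columns))
            row = pd.Series(base * noise, index=values.columns)
        values.loc[tid] = row
        gt.abundances[tid] = {
            c: float(row[[s for cc, s in samples if cc == c]].mean())
            for c in conditions
        }
    values = values.sort_index()
    expr = ExpressionMatrix(values, {s: c for c, s in samples})
    ds.expression = expr
    return expr


# ---------------------------------------------------------------------------
# MS observations
# ---------------------------------------------------------------------------

def generate_ms_observations(
    records: Mapping[str, PeptideRecord],
    abundances: Mapping[str, float],
    n_spectra: int = 4000,
    mode: str = "abundance",
    isp_detectability: float = 1.0,
    dominant_w: float = 1.0,
    sample_id: str = "MS1",
    gene_of_transcript: Mapping[str, str] | None = None,
    seed: int = 0,
) -> list[PeptideObservation]:
    """Sample spectral counts from a peptide database.

    Peptide sampling weight is the summed abundance of its parent
    isoforms times a detectability factor (``isp_detectability`` applies
    to isoform-specific peptides only, emulating detection biased
    against ISPs).  ``mode="equal"`` ignores abundances;
    ``mode="dominant"`` keeps, per gene, only the most abundant isoform
    (weight ``dominant_w``) with the rest at ``1 - dominant_w`` —
    at 1.0 this emulates single-isoform translation, yielding no ISPs
    from minor isoforms.
    """
    if mode not in ("abundance", "equal", "dominant"):
        raise ValueError(f"unknown mode {mode!r}")
    ab = dict(abundances)
    if mode == "equal":
        ab = {t: 1.0 for t in ab}
    elif mode == "dominant":
        if gene_of_transcript is None:
            raise ValueError("dominant mode needs gene_of_transcript")
        by_gene: dict[str, list[str]] = {}
        for t, g in gene_of_transcript.items():
            by_gene.setdefault(g, []).append(t)
        ab2 = {}
        for g, tids in by_gene.items():
            tids = sorted(tids)
            best = max(tids, key=lambda t: (abundances.get(t, 0.0), t))
            total = sum(abundances.get(t, 0.0) for t in tids)
            for t in tids:
                ab2[t] = total * (
                    dominant_w if t == best
                    else (1 - dominant_w) / max(len(tids) - 1, 1)
                )
        ab = ab2
    keys = sorted(records)
    weights = np.array(
        [
            sum(ab.get(t, 0.0) for t in records[k].transcript_ids)
            * (
                isp_detectability
                if records[k].specificity == "isoform_specific"
                else 1.0
            )
            for k in keys
        ]
    )
    if weights.sum() <= 0:
        return []
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_spectra, weights / weights.sum())
    return [
        PeptideObservation(
            peptide_sequence=keys[i], sample_id=sample_id,
            spectral_count=int(c),
        )
        for i, c in enumerate(counts)
        if c > 0
    ]


# ---------------------------------------------------------------------------
# lncRNAs with planted complementary sites
# ---------------------------------------------------------------------------

def _wobble(segment: list[str], target_window: str, wobble_frac: float,
            rng: np.random.Generator) -> tuple[list[str], int]:
    """Turn a fraction of WC pairs into G:U wobbles (target G or T only)."""
    eligible = [i for i, b in enumerate(target_window) if b in "GT"]
    n = int(round(wobble_frac * len(target_window)))
    n = min(n, len(eligible))
    changed = 0
    if n > 0:
        # segment is the reverse complement: target position i pairs
        # segment position len-1-i
        for i in rng.choice(len(eligible), size=n, replace=False):
            tpos = eligible[i]
            spos = len(target_window) - 1 - tpos
            segment[spos] = "T" if target_window[tpos] == "G" else "G"
            changed += 1
    return segment, changed


def generate_lncrnas(
    ds: SyntheticDataset,
    n_intergenic: int = 6,
    n_cisnat: int = 2,
    site_length: int = 45,
    wobble_frac: float = 0.0,
    gc_content_site: bool = False,
    lnc_len: tuple[int, int] = (350, 550),
    seed: int = 0,
) -> list[TranscriptModel]:
    """Plant intergenic and cis-NAT lncRNAs with complementary sites.

    Each intergenic lncRNA carries one antiparallel-complementary window
    into a target gene's pre-mRNA, centred on an alternative splice
    junction boundary (from the planted AS events), so site recovery,
    junction-context classification and alternative-junction enrichment
    are all testable against ground truth.  ``gc_content_site`` rewrites
    the (intron-interior) target window as G/C-only so a perfect site of
    length L scores exactly 4L.  cis-NAT lncRNAs are antisense
    single-exon transcripts copied from the opposite strand of a host
    gene, hence perfectly complementary to it.
    """
    rng = np.random.default_rng(seed)
    gt = ds.ground_truth
    chrom = ds.chrom
    genome = list(ds.genome[chrom])
    reserved = list(ds.reserved)
    lncs: list[TranscriptModel] = []

    # candidate alternative boundaries: retained-intron events planted
    ir_events = [
        e for e in gt.events if e["event_type"] == "intron_retention"
    ]
    slot_iter = iter(
        sorted(ds.free_slots, key=lambda iv: iv[1] - iv[0], reverse=True)
    )

    gene_by_id = {g.gene_id: g for g in ds.genes}
    for li in range(n_intergenic):
        lnc_id = f"lnc{li + 1:03d}"
        ev = ir_events[li % len(ir_events)] if ir_events else None
        target_gene = gene_by_id[ev["gene_id"]] if ev else ds.genes[li % len(ds.genes)]
        span_s, span_e = target_gene.span
        strand = target_gene.strand

        if ev is not None and not gc_content_site:
            # centre the window on the intron-retention donor boundary
            boundary = ev["interval"][0] if strand == "+" else ev["interval"][1]
            axis = boundary - span_s if strand == "+" else span_e - boundary
            ts = max(0, axis - site_length // 2)
        else:
            # an intron-interior window, clear of motif writes
            iv = ev["interval"] if ev else None
            if iv is None:
                t0 = target_gene.transcripts[0]
                iv = t0.introns[0]
            lo, hi = iv[0] + 14, iv[1] - 18
            if gc_content_site:
                window = None
                for gs in range(lo, hi - site_length):
                    cand = (gs, gs + site_length)
                    if not any(
                        cand[0] < r[1] and r[0] < cand[1] for r in reserved
                    ):
                        window = cand
                        break
                if window is None:
                    continue
                gc = ["GC"[i] for i in rng.integers(0, 2, site_length)]
                genome[window[0] : window[1]] = gc
                reserved.append(window)
                axis0 = (
                    window[0] - span_s if strand == "+" else span_e - window[1]
                )
                ts = axis0
            else:
                gs = int(rng.integers(lo, max(lo + 1, hi - site_length)))
                ts = gs - span_s if strand == "+" else span_e - (gs + site_length)
        te = ts + site_length

        premrna = premrna_sequence(
            target_gene, {chrom: "".join(genome)}
        )
        window_seq = premrna[ts:te]
        segment = list(reverse_complement(window_seq))
        segment, n_wob = _wobble(segment, window_seq, wobble_frac, rng)

        total_len = int(rng.integers(*lnc_len))
        for _ in range(20):
            body = _random_bases(rng, total_len)
            off = int(rng.integers(10, total_len - site_length - 10))
            body[off : off + site_length] = segment
            if not predict_orfs(lnc_id, "".join(body), min_len=100):
                break
        slot = next(slot_iter, None)
        if slot is None or slot[1] - slot[0] < total_len + 20:
            raise ValueError("no free genome slot large enough for lncRNA")
        gs0 = slot[0] + 10
        genome[gs0 : gs0 + total_len] = body
        lnc = TranscriptModel(
            transcript_id=lnc_id,
            gene_id=f"{lnc_id}.locus",
            chrom=chrom,
            strand="+",
            exons=[(gs0, gs0 + total_len)],
        )
        lncs.append(lnc)
        gt.lnc_classes[lnc_id] = "u"
        gt.lnc_sites.append(
            {
                "lncrna_id": lnc_id,
                "target_gene": target_gene.gene_id,
                "target_id": f"{target_gene.gene_id}.premrna",
                "lnc_interval": (off, off + site_length),
                "target_interval": (ts, te),
                "wobbles": n_wob,
                "context": "junction" if (ev and not gc_content_site) else "intronic",
            }
        )

    for ci in range(n_cisnat):
        lnc_id = f"lncNAT{ci + 1:02d}"
        host = ds.genes[(ci * 7 + 3) % len(ds.genes)]
        hs, he = host.span
        length = min(300, he - hs - 20)
        gs0 = hs + 10
        anti_strand = "-" if host.strand == "+" else "+"
        lnc = TranscriptModel(
            transcript_id=lnc_id,
            gene_id=f"{lnc_id}.locus",
            chrom=chrom,
            strand=anti_strand,
            exons=[(gs0, gs0 + length)],
        )
        lncs.append(lnc)
        gt.lnc_classes[lnc_id] = "x"

    ds.genome[chrom] = "".join(genome)
    ds.reserved = reserved
    ds.lncrnas = lncs
    return lncs


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------

def generate_dataset(
    seed: int = 0,
    n_genes: int = 40,
    events_per_type: Mapping[str, int] | None = None,
    noise_cv: float = 0.1,
    replicates: int = 5,
    with_lncrnas: bool = True,
    with_ms: bool = True,
    ms_mode: str = "dominant",
    isp_detectability: float = 1.0,
    n_spectra: int = 4000,
) -> SyntheticDataset:
    """Full synthetic study: genome, genes, lncRNAs, expression, MS data.

    The default MS mode is dominant-isoform translation, which reproduces
    the qualitative transcriptome/proteome gap the detectability
    simulation quantifies.
    """
    from .proteogenomics import classify_peptides, primary_orf

    ds = generate_genome_and_genes(
        n_genes=n_genes, events_per_type=events_per_type, seed=seed
    )
    if with_lncrnas:
        generate_lncrnas(ds, seed=seed + 1)
    generate_expression(
        ds, replicates=replicates, noise_cv=noise_cv, seed=seed + 2
    )
    if with_ms:
        orfs_by_gene = {}
        gene_of_transcript = {}
        for g in ds.genes:
            orfs = []
            for t in g.transcripts:
                seq = spliced_sequence(t, ds.genome)
                orf = primary_orf(t.transcript_id, seq)
                if orf is not None:
                    orfs.append(orf)
                gene_of_transcript[t.transcript_id] = g.gene_id
            if orfs:
                orfs_by_gene[g.gene_id] = orfs
        records = classify_peptides(orfs_by_gene)
        cond = DEFAULT_CONDITIONS[0]
        abundances = {
            t: v.get(cond, 0.0)
            for t, v in ds.ground_truth.abundances.items()
        }
        ds.observations = generate_ms_observations(
            records,
            abundances,
            n_spectra=n_spectra,
            mode=ms_mode,
            isp_detectability=isp_detectability,
            gene_of_transcript=gene_of_transcript,
            seed=seed + 3,
        )
        ds.ground_truth.ms_params = {
            "mode": ms_mode,
            "isp_detectability": isp_detectability,
            "n_spectra": n_spectra,
        }
    return ds
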