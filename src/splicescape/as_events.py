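"""Alternative-splicing event classification and splice-junction typing.

Events are classified per locus by comparing isoforms pairwise against
each other and against the hypothetical pre-mRNA (the exon-interval union
of all isoforms).  Junctions are catalogued with alternative/constitutive
status and typed U2 vs U12 by log-odds scoring against position
probability matrices for the donor, acceptor and branch-point motifs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .models_io import (
    GeneModel,
    Interval,
    SpliceJunction,
    TranscriptModel,
    reverse_complement,
)

EVENT_TYPES = (
    "intron_retention",
    "alt_donor",
    "alt_acceptor",
    "exon_skipping",
    "mutually_exclusive_exons",
    "alt_tss",
    "alt_tts",
)


@dataclass(frozen=True)
class ASEvent:
    gene_id: str
    event_type: str
    interval: Interval
    involved_transcript_ids: frozenset[str]
    annotated: bool = True


# ---------------------------------------------------------------------------
# Pre-mRNA construction
# ---------------------------------------------------------------------------

def union_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    ivs = sorted(intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def build_pre_mrna(gene: GeneModel) -> TranscriptModel:
    """Hypothetical pre-mRNA: union of all exons, introns = the complement.

    Returned as a TranscriptModel whose exons are the union blocks; its
    introns are the regions no isoform ever includes.
    """
    exons = union_intervals(
        iv for t in gene.transcripts for iv in t.exons
    )
    return TranscriptModel(
        transcript_id=f"{gene.gene_id}.premrna",
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        exons=exons,
    )


def premrna_unspliced_model(gene: GeneModel) -> TranscriptModel:
    """The fully unspliced molecule: one exon spanning the whole locus."""
    return TranscriptModel(
        transcript_id=f"{gene.gene_id}.premrna",
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        exons=[gene.span],
    )


# ---------------------------------------------------------------------------
# Event classification
# ---------------------------------------------------------------------------

def _covers(outer: Interval, inner: Interval) -> bool:
    return outer[0] <= inner[0] and outer[1] >= inner[1]


def _overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _internal_exons(t: TranscriptModel) -> list[Interval]:
    return t.exons[1:-1]


def _pair_events(a: TranscriptModel, b: TranscriptModel) -> list[tuple[str, Interval]]:
    """All AS events distinguishing isoforms a and b (order-free)."""
    strand = a.strand
    events: list[tuple[str, Interval]] = []

    # Intron retention: an exon of one isoform fully covers an intron of
    # the other.
    for x, y in ((a, b), (b, a)):
        for intron in y.introns:
            if any(_covers(exon, intron) for exon in x.exons):
                events.append(("intron_retention", intron))

    # Skipped-exon candidates: internal exon of one isoform wholly inside
    # an intron of the other.
    skipped: dict[int, list[Interval]] = {0: [], 1: []}
    for idx, (x, y) in enumerate(((a, b), (b, a))):
        for exon in _internal_exons(x):
            if any(_covers(intron, exon) for intron in y.introns):
                skipped[idx].append(exon)

    # Mutually exclusive exons: a skipped exon of each isoform, disjoint,
    # with no exon of either isoform between them (same cassette slot).
    used_a: set[Interval] = set()
    used_b: set[Interval] = set()
    all_exons = a.exons + b.exons
    for ea in skipped[0]:
        for eb in skipped[1]:
            if eb in used_b or _overlap(ea, eb):
                continue
            gap = (min(ea[1], eb[1]), max(ea[0], eb[0]))
            if gap[0] < gap[1] and any(_overlap(gap, e) for e in all_exons):
                continue
            events.append(
                ("mutually_exclusive_exons",
                 (min(ea[0], eb[0]), max(ea[1], eb[1])))
            )
            used_a.add(ea)
            used_b.add(eb)
            break
    for ea in skipped[0]:
        if ea not in used_a:
            events.append(("exon_skipping", ea))
    for eb in skipped[1]:
        if eb not in used_b:
            events.append(("exon_skipping", eb))

    # Alternative donor/acceptor: overlapping introns sharing one boundary;
    # the flanking exons at the differing boundary must overlap (otherwise
    # the difference is an exon-level event, handled above).
    def _exon_starting(t: TranscriptModel, pos: int) -> Interval | None:
        for e in t.exons:
            if e[0] == pos:
                return e
        return None

    def _exon_ending(t: TranscriptModel, pos: int) -> Interval | None:
        for e in t.exons:
            if e[1] == pos:
                return e
        return None

    for ia in a.introns:
        for ib in b.introns:
            if ia == ib or not _overlap(ia, ib):
                continue
            if ia[0] == ib[0] and ia[1] != ib[1]:
                # right (genomic) boundary differs
                ea, eb = _exon_starting(a, ia[1]), _exon_starting(b, ib[1])
                if ea and eb and _overlap(ea, eb):
                    etype = "alt_acceptor" if strand == "+" else "alt_donor"
                    events.append(
                        (etype, (min(ia[1], ib[1]), max(ia[1], ib[1])))
                    )
            elif ia[1] == ib[1] and ia[0] != ib[0]:
                ea, eb = _exon_ending(a, ia[0]), _exon_ending(b, ib[0])
                if ea and eb and _overlap(ea, eb):
                    etype = "alt_donor" if strand == "+" else "alt_acceptor"
                    events.append(
                        (etype, (min(ia[0], ib[0]), max(ia[0], ib[0])))
                    )

    # Alternative transcription start / termination sites.
    if a.tss != b.tss:
        lo, hi = sorted((a.tss, b.tss))
        events.append(("alt_tss", (lo, hi)))
    if a.tts != b.tts:
        lo, hi = sorted((a.tts, b.tts))
        events.append(("alt_tts", (lo, hi)))
    return events


def classify_as_events(gene: GeneModel) -> list[ASEvent]:
    """Classify AS events for a locus; deduplicated by (type, interval)."""
    if len(gene.transcripts) < 2:
        return []
    merged: dict[tuple[str, Interval], set[str]] = {}
    for a, b in combinations(gene.transcripts, 2):
        for etype, iv in _pair_events(a, b):
            merged.setdefault((etype, iv), set()).update(
                (a.transcript_id, b.transcript_id)
            )
    ref = gene.reference_transcript_id
    out = []
    for (etype, iv), tids in sorted(merged.items()):
        out.append(
            ASEvent(
                gene_id=gene.gene_id,
                event_type=etype,
                interval=iv,
                involved_transcript_ids=frozenset(tids),
                annotated=(ref is None or ref in tids),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Junction catalogue
# ---------------------------------------------------------------------------

def catalogue_junctions(
    gene: GeneModel,
    genome: Mapping[str, str] | None = None,
    events: Sequence[ASEvent] | None = None,
) -> list[SpliceJunction]:
    """All distinct introns of a locus, with alternative status set.

    A junction is alternative iff some isoform whose genomic span covers
    it does not splice it identically, or iff it borders an AS event
    interval.  Dinucleotides are read from the intron ends in
    transcription orientation (minus-strand introns are reverse-
    complemented, so a genomic ``CT..AC`` reports as ``GT..AG``).
    """
    if events is None:
        events = classify_as_events(gene)
    strand = gene.strand
    introns: dict[Interval, None] = {}
    for t in gene.transcripts:
        for iv in t.introns:
            introns.setdefault(iv, None)

    out = []
    for iv in sorted(introns):
        alt = False
        for t in gene.transcripts:
            if _covers(t.span, iv) and iv not in t.introns:
                alt = True
                break
        if not alt:
            for ev in events:
                touches = _overlap(ev.interval, iv) or bool(
                    {iv[0], iv[1]} & {ev.interval[0], ev.interval[1]}
                )
                if touches:
                    alt = True
                    break
        donor_pos, acceptor_pos = (
            (iv[0], iv[1]) if strand == "+" else (iv[1], iv[0])
        )
        dd, ad = "NN", "NN"
        if genome is not None:
            if iv[1] - iv[0] < 4:
                warnings.warn(
                    f"{gene.gene_id}: intron {iv} shorter than 4 nt; "
                    "dinucleotides left unclassified",
                    stacklevel=2,
                )
            else:
                raw = genome[gene.chrom][iv[0] : iv[1]]
                if strand == "+":
                    dd, ad = raw[:2], raw[-2:]
                else:
                    rc = reverse_complement(raw)
                    dd, ad = rc[:2], rc[-2:]
        out.append(
            SpliceJunction(
                gene_id=gene.gene_id,
                donor_pos=donor_pos,
                acceptor_pos=acceptor_pos,
                strand=strand,
                donor_dinucleotide=dd,
                acceptor_dinucleotide=ad,
                is_alternative=alt,
            )
        )
    return out


def junctions_for_typing(
    gene: GeneModel,
    junctions: Sequence[SpliceJunction],
    events: Sequence[ASEvent] | None = None,
) -> list[SpliceJunction]:
    """Filter junctions before spliceosome typing.

    Excludes junctions adjacent to any isoform's first exon (transcription
    order) and junctions flanking a retained intron, which carry atypical
    signal context.
    """
    if events is None:
        events = classify_as_events(gene)
    ir_intervals = [
        ev.interval for ev in events if ev.event_type == "intron_retention"
    ]
    first_exon_donors = set()
    for t in gene.transcripts:
        first = t.exons_transcription_order()[0]
        # the junction leaving the first exon starts at its 3' boundary
        donor = first[1] if t.strand == "+" else first[0]
        first_exon_donors.add(donor)
    out = []
    for j in junctions:
        if j.donor_pos in first_exon_donors:
            continue
        if any(
            j.interval == ir or j.interval[0] in ir or j.interval[1] in ir
            for ir in ir_intervals
        ):
            continue
        out.append(j)
    return out


# ---------------------------------------------------------------------------
# Position probability matrices and U2/U12 typing
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
PPM_EPS = 0.01


@dataclass
class PositionProbabilityMatrix:
    """Per-position base probabilities for a splice-signal window.

    ``offset`` is the window start relative to the splice-site boundary
    (negative = exonic side for donors, intronic side for acceptors).
    """

    label: str
    offset: int
    probs: np.ndarray  # shape (L, 4), columns A C G T

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"PPM {self.label}: rows must sum to 1")
        if (self.probs < PPM_EPS - 1e-12).any():
            raise ValueError(f"PPM {self.label}: probability below floor {PPM_EPS}")

    def __len__(self) -> int:
        return self.probs.shape[0]


def score_ppm(window: str, ppm: PositionProbabilityMatrix) -> float:
    """Log-odds score in bits against a uniform background.

    Ambiguous bases (anything outside ACGT) contribute 0.
    """
    if len(window) != len(ppm):
        raise ValueError(
            f"window length {len(window)} != PPM length {len(ppm)}"
        )
    score = 0.0
    for i, base in enumerate(window.upper()):
        j = _BASE_INDEX.get(base)
        if j is None:
            continue
        score += math.log2(ppm.probs[i, j] / 0.25)
    return score


def _ppm_rows(consensus: Sequence[tuple[str | None, float]]) -> np.ndarray:
    """Build probability rows from (base, probability) pairs.

    ``(None, _)`` rows are uniform.  The remaining mass at informative
    positions is spread equally over the other three bases, respecting
    the floor PPM_EPS.
    """
    rows = []
    for base, p in consensus:
        if base is None:
            rows.append([0.25, 0.25, 0.25, 0.25])
            continue
        rest = (1.0 - p) / 3.0
        row = [rest] * 4
        row[_BASE_INDEX[base]] = p
        rows.append(row)
    return np.array(rows)


def default_ppms() -> dict[str, PositionProbabilityMatrix]:
    """Default plant-consensus PPMs for U2 and U12 splice signals.

    Exon-side positions are uniform (uninformative) so coding sequence
    abutting the splice site does not perturb typing.  U2 donor/acceptor
    follow the GT..AG major-spliceosome consensus; the U12 donor follows
    the AT-AC minor-spliceosome consensus (ATATCCTT) and the U12 branch
    the TTCCTTAAC box, scanned upstream of the acceptor.
    """
    u2_donor = _ppm_rows(
        [(None, 0)] * 3
        + [("G", 0.97), ("T", 0.97), ("A", 0.65), ("A", 0.70), ("G", 0.80),
           ("T", 0.80), ("A", 0.50), ("T", 0.40), ("T", 0.40), ("T", 0.35)]
    )
    polyy = [("T", 0.45)] * 5 + [("C", 0.45)] * 2 + [("T", 0.45)] * 4
    u2_acceptor = _ppm_rows(
        polyy + [("C", 0.55), ("A", 0.97), ("G", 0.97)] + [(None, 0)] * 3
    )
    u12_donor = _ppm_rows(
        [(None, 0)] * 3
        + [("A", 0.95), ("T", 0.95), ("A", 0.90), ("T", 0.90), ("C", 0.90),
           ("C", 0.85), ("T", 0.85), ("T", 0.80), ("T", 0.50), ("C", 0.40)]
    )
    u12_branch = _ppm_rows(
        [("T", 0.70), ("T", 0.80), ("C", 0.85), ("C", 0.85), ("T", 0.90),
         ("T", 0.90), ("A", 0.95), ("A", 0.70), ("C", 0.60)]
    )
    return {
        "U2_donor": PositionProbabilityMatrix("U2_donor", -3, u2_donor),
        "U2_acceptor": PositionProbabilityMatrix("U2_acceptor", -14, u2_acceptor),
        "U12_donor": PositionProbabilityMatrix("U12_donor", -3, u12_donor),
        "U12_branch": PositionProbabilityMatrix("U12_branch", -40, u12_branch),
    }


def ppms_to_yaml(ppms: Mapping[str, PositionProbabilityMatrix], path: str | Path) -> None:
    doc = {
        label: {
            "offset": int(p.offset),
            "rows": [
                {b: float(p.probs[i, j]) for b, j in _BASE_INDEX.items()}
                for i in range(len(p))
            ],
        }
        for label, p in ppms.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def ppms_from_yaml(path: str | Path) -> dict[str, PositionProbabilityMatrix]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = {}
    for label, spec in doc.items():
        rows = np.array(
            [[row[b] for b in ("A", "C", "G", "T")] for row in spec["rows"]]
        )
        out[label] = PositionProbabilityMatrix(label, int(spec["offset"]), rows)
    return out


# Window geometry (transcription-relative offsets, see default_ppms).
DONOR_EXONIC = 3      # donor window covers exon -3..-1 plus intron +1..+10
DONOR_INTRONIC = 10
ACCEPTOR_INTRONIC = 14  # acceptor window covers intron -14..-1 plus exon +1..+3
ACCEPTOR_EXONIC = 3
BRANCH_SCAN = (10, 40)  # scan branch PPM within intron -40..-10 of the acceptor


def junction_windows(
    junction: SpliceJunction, chrom_seq: str
) -> tuple[str | None, str | None, str | None]:
    """(donor window, acceptor window, branch scan region), 5'->3'.

    Returns None components when the genomic context is out of bounds or
    the intron is too short to carry the motif.
    """
    s, e = junction.interval
    strand = junction.strand
    L = len(chrom_seq)

    def cut(a: int, b: int) -> str | None:
        if a < 0 or b > L or a >= b:
            return None
        return chrom_seq[a:b]

    if strand == "+":
        donor = cut(s - DONOR_EXONIC, s + DONOR_INTRONIC)
        acceptor = cut(e - ACCEPTOR_INTRONIC, e + ACCEPTOR_EXONIC)
        branch = cut(max(e - BRANCH_SCAN[1], s), e - BRANCH_SCAN[0])
    else:
        donor = cut(e - DONOR_INTRONIC, e + DONOR_EXONIC)
        donor = reverse_complement(donor) if donor else None
        acceptor = cut(s - ACCEPTOR_EXONIC, s + ACCEPTOR_INTRONIC)
        acceptor = reverse_complement(acceptor) if acceptor else None
        branch = cut(s + BRANCH_SCAN[0], min(s + BRANCH_SCAN[1], e))
        branch = reverse_complement(branch) if branch else None
    if donor is not None and len(donor) != DONOR_EXONIC + DONOR_INTRONIC:
        donor = None
    if acceptor is not None and len(acceptor) != ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC:
        acceptor = None
    return donor, acceptor, branch


def classify_junction_subtype(
    junction: SpliceJunction,
    chrom_seq: str,
    ppms: Mapping[str, PositionProbabilityMatrix] | None = None,
    min_score: float = 0.0,
) -> str:
    """Type a junction U2 vs U12 by summed log-odds; ties resolve to U2.

    U2 score = donor + acceptor; U12 score = donor + best branch-window
    score in the scan region.  Both below ``min_score`` -> unclassified;
    missing sequence context -> unclassified.
    """
    if ppms is None:
        ppms = default_ppms()
    donor, acceptor, branch_region = junction_windows(junction, chrom_seq)
    if donor is None or acceptor is None:
        return "unclassified"
    u2 = score_ppm(donor, ppms["U2_donor"]) + score_ppm(
        acceptor, ppms["U2_acceptor"]
    )
    branch_ppm = ppms["U12_branch"]
    best_branch = -math.inf
    if branch_region is not None and len(branch_region) >= len(branch_ppm):
        for i in range(len(branch_region) - len(branch_ppm) + 1):
            best_branch = max(
                best_branch,
                score_ppm(branch_region[i : i + len(branch_ppm)], branch_ppm),
            )
    u12 = score_ppm(donor, ppms["U12_donor"]) + (
        best_branch if best_branch > -math.inf else -1e9
    )
    if u2 < min_score and u12 < min_score:
        return "unclassified"
    return "U2" if u2 >= u12 else "U12"


def type_junctions(
    gene: GeneModel,
    genome: Mapping[str, str],
    ppms: Mapping[str, PositionProbabilityMatrix] | None = None,
    min_score: float = 0.0,
    events: Sequence[ASEvent] | None = None,
) -> list[SpliceJunction]:
    """Catalogue and subtype all junctions of a locus."""
    junctions = catalogue_junctions(gene, genome, events=events)
    chrom_seq = genome[gene.chrom]
    for j in junctions:
        j.subtype = classify_junction_subtype(j, chrom_seq, ppms, min_score)
    return junctions
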