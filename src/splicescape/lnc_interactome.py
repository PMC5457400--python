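"""lncRNA filtering, cis-NAT classification, and RNA-RNA duplex mapping.

Antiparallel complementarity between a lncRNA and an (pre-)mRNA is
scored by local alignment of the *reversed* lncRNA against the target
under a base-pairing substitution matrix (G:C = +4, A:U = +2, G:U wobble
= +1, anything else -6) with affine gap costs (a gap of length k costs
20 + 8k).  Reversing without complementing plus pairing scores is
physically equivalent to reverse-complementing plus identity matching,
and keeps both reported intervals in each molecule's native 5'->3'
orientation.  Interaction sites on pre-mRNA are classified by their
position relative to exon-intron junctions, and enrichment of
alternative junctions among interacted junctions is assessed by Fisher's
exact test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact, spearmanr

from .models_io import (
    ExpressionMatrix,
    GeneModel,
    Interval,
    SpliceJunction,
    TranscriptModel,
)
from .proteogenomics import predict_orfs

logger = logging.getLogger(__name__)


@dataclass
class PairingScoreScheme:
    """RNA duplex pairing scores (DNA alphabet: U is written T).

    Watson-Crick G:C and A:U pairs score +4 and +2, the G:U wobble +1,
    and every other juxtaposition -6.  A gap of length k costs
    ``gap_open + gap_extend * k``.
    """

    gc: int = 4
    at: int = 2
    gt: int = 1
    mismatch: int = -6
    gap_open: int = 20
    gap_extend: int = 8

    def matrix(self) -> np.ndarray:
        """5x5 score table over A,C,G,T,N (N never pairs)."""
        idx = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
        m = np.full((5, 5), self.mismatch, dtype=np.int32)
        for a, b, s in (
            ("G", "C", self.gc),
            ("A", "T", self.at),
            ("G", "T", self.gt),
        ):
            m[idx[a], idx[b]] = s
            m[idx[b], idx[a]] = s
        m[4, :] = self.mismatch
        m[:, 4] = self.mismatch
        return m


@dataclass
class InteractionSite:
    lncrna_id: str
    target_id: str
    lnc_interval: Interval      # on the lncRNA, native 5'->3'
    target_interval: Interval   # on the target molecule, native 5'->3'
    score: float
    length: int                 # alignment columns
    site_class: str = "exonic"  # exonic | intronic | junction_spanning
    spans_alternative_junction: bool = False


_ENCODE = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _ENCODE[ord(b)] = i
    _ENCODE[ord(b.lower())] = i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


NEG = -1e9


def _affine_local_dp(
    x: np.ndarray,
    y: np.ndarray,
    pair: np.ndarray,
    open_cost: float,
    ext_cost: float,
    xmask: np.ndarray,
    ymask: np.ndarray,
) -> tuple[float, tuple[int, int, int, int, int]] | None:
    """Smith-Waterman with affine gaps (Gotoh), row-vectorised.

    Returns (best score, (x_start, x_end, y_start, y_end, n_columns)) of
    the optimal local alignment, or None if no positive-scoring cell
    exists.  ``open_cost`` is the total cost of a length-1 gap
    (gap_open + gap_extend).  Masked positions cannot be paired.
    """
    n, m = len(x), len(y)
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, :] = NEG
    ext = ext_cost
    for i in range(1, n + 1):
        srow = pair[x[i - 1], y].astype(float)
        if xmask[i - 1]:
            srow = np.full(m, NEG)
        else:
            srow = np.where(ymask, NEG, srow)
        prev = np.maximum.reduce(
            [M[i - 1, :-1], Ix[i - 1, :-1], Iy[i - 1, :-1], np.zeros(m)]
        )
        M[i, 1:] = srow + prev
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] - open_cost, Ix[i - 1, 1:] - ext)
        # Iy[i, j] = max_{k<j} M[i, k] - open - ext*(j-1-k)
        #          = running_max(M[i, k] + ext*k) - open - ext*(j-1) ... computed by scan
        shifted = M[i, :-1] + ext * np.arange(m)
        running = np.maximum.accumulate(shifted)
        Iy[i, 1:] = running - open_cost - ext * np.arange(m)
    best = np.unravel_index(np.argmax(M), M.shape)
    best_score = M[best]
    if best_score <= 0:
        return None

    # Traceback from the best M cell.
    i, j = int(best[0]), int(best[1])
    state = "M"
    xe, ye = i, j
    cols = 0
    while True:
        if state == "M":
            cols += 1
            s = float(pair[x[i - 1], y[j - 1]])
            prev_val = M[i, j] - s
            if prev_val <= 1e-9:
                i, j = i - 1, j - 1
                break
            for cand, name in ((M[i - 1, j - 1], "M"), (Ix[i - 1, j - 1], "Ix"),
                               (Iy[i - 1, j - 1], "Iy")):
                if abs(cand - prev_val) < 1e-6:
                    state = name
                    break
            else:  # numerical fallback: restart as local start
                i, j = i - 1, j - 1
                break
            i, j = i - 1, j - 1
        elif state == "Ix":
            cols += 1
            if abs(Ix[i, j] - (M[i - 1, j] - open_cost)) < 1e-6:
                state = "M"
            i -= 1
        else:  # Iy
            cols += 1
            if abs(Iy[i, j] - (M[i, j - 1] - open_cost)) < 1e-6:
                state = "M"
            j -= 1
    xs, ys = i, j
    return float(best_score), (xs, xe, ys, ye, cols)


def align_duplex(
    lnc_seq: str,
    target_seq: str,
    scheme: PairingScoreScheme | None = None,
    min_score: float = 100.0,
    min_len: int = 25,
    convention: str = "antiparallel",
    lncrna_id: str = "lncrna",
    target_id: str = "target",
    max_sites: int = 50,
) -> list[InteractionSite]:
    """All non-overlapping locally optimal duplex sites, sorted by score.

    The lncRNA is reversed (not complemented) and locally aligned to the
    target under the pairing matrix, which models antiparallel
    hybridisation; ``convention="parallel"`` scores the unreversed
    orientation for comparison.  After each optimal site both aligned
    intervals are masked and the search repeats until the score drops
    below ``min_score``.  Reported lncRNA intervals are mapped back to
    the native 5'->3' orientation.
    """
    if scheme is None:
        scheme = PairingScoreScheme()
    if not lnc_seq or not target_seq:
        return []
    if convention not in ("antiparallel", "parallel"):
        raise ValueError(f"unknown convention {convention!r}")
    q = lnc_seq[::-1] if convention == "antiparallel" else lnc_seq
    x = _encode(q)
    y = _encode(target_seq)
    pair = scheme.matrix()
    open_cost = float(scheme.gap_open + scheme.gap_extend)
    xmask = np.zeros(len(x), dtype=bool)
    ymask = np.zeros(len(y), dtype=bool)
    L = len(lnc_seq)
    sites = []
    for _ in range(max_sites):
        hit = _affine_local_dp(
            x, y, pair, open_cost, float(scheme.gap_extend), xmask, ymask
        )
        if hit is None:
            break
        score, (xs, xe, ys, ye, cols) = hit
        if score < min_score:
            break
        xmask[xs:xe] = True
        ymask[ys:ye] = True
        if cols < min_len:
            continue
        if convention == "antiparallel":
            lnc_iv = (L - xe, L - xs)
        else:
            lnc_iv = (xs, xe)
        sites.append(
            InteractionSite(
                lncrna_id=lncrna_id,
                target_id=target_id,
                lnc_interval=lnc_iv,
                target_interval=(ys, ye),
                score=score,
                length=cols,
            )
        )
    sites.sort(key=lambda s: (-s.score, s.target_interval))
    return sites


# ---------------------------------------------------------------------------
# Candidate filtering and cis-NAT classification
# ---------------------------------------------------------------------------

LNC_CLASS_CODES = {"u": "intergenic", "x": "antisense", "s": "same_strand_novel"}


def filter_lncrna_candidates(
    candidates: Sequence[TranscriptModel],
    expr: ExpressionMatrix | None,
    class_codes: Mapping[str, str],
    min_length: int = 200,
    min_fpkm: float = 0.5,
    max_orf_codons: int = 100,
) -> list[TranscriptModel]:
    """Apply the lncRNA candidate filters.

    Keeps transcripts that are longer than ``min_length`` nt, reach
    ``min_fpkm`` in at least one condition, carry an unannotated assembly
    class code (u/x/s), and whose longest ORF stays below
    ``max_orf_codons`` (coding-potential stand-in).
    """
    means = expr.condition_means() if expr is not None else None
    kept = []
    for t in candidates:
        if class_codes.get(t.transcript_id) not in LNC_CLASS_CODES:
            continue
        seq = t.sequence
        if seq is None:
            raise ValueError(f"{t.transcript_id}: sequence not loaded")
        if len(seq) <= min_length:
            continue
        if means is not None:
            if t.transcript_id not in means.index:
                continue
            if means.loc[t.transcript_id].max() < min_fpkm:
                continue
        if predict_orfs(t.transcript_id, seq, min_len=max_orf_codons):
            continue  # coding potential
        kept.append(t)
    return kept


def classify_cis_nat(
    lncrnas: Sequence[TranscriptModel],
    genes: Sequence[GeneModel],
) -> dict[str, tuple[str, list[str]]]:
    """Classify each lncRNA as cis_NAT / same_strand_overlap / intergenic.

    cis-NAT: >= 1 nt genomic overlap with a protein-coding locus on the
    opposite strand.  Returns {lnc_id: (class, overlapped gene ids)}.
    """
    out = {}
    for lnc in lncrnas:
        s, e = lnc.span
        anti, same = [], []
        for g in genes:
            gs, ge = g.span
            if g.chrom != lnc.chrom or not (s < ge and gs < e):
                continue
            (anti if g.strand != lnc.strand else same).append(g.gene_id)
        if anti:
            out[lnc.transcript_id] = ("cis_NAT", anti)
        elif same:
            out[lnc.transcript_id] = ("same_strand_overlap", same)
        else:
            out[lnc.transcript_id] = ("intergenic", [])
    return out


# ---------------------------------------------------------------------------
# Site context classification and junction enrichment
# ---------------------------------------------------------------------------

def _to_premrna_axis(premrna: TranscriptModel, genomic_pos: int) -> int:
    """Genomic coordinate -> position on the 5'->3' pre-mRNA axis."""
    span_start, span_end = premrna.span
    return (
        genomic_pos - span_start
        if premrna.strand == "+"
        else span_end - genomic_pos
    )


def junction_boundaries_on_axis(
    premrna: TranscriptModel, junctions: Sequence[SpliceJunction]
) -> dict[int, bool]:
    """{axis position of each junction boundary: boundary is alternative}.

    Both ends of every catalogued junction contribute, so boundaries of
    a retained intron (which sit inside an exon-union block) are still
    represented.
    """
    bounds: dict[int, bool] = {}
    for j in junctions:
        for pos in (j.donor_pos, j.acceptor_pos):
            axis = _to_premrna_axis(premrna, pos)
            bounds[axis] = bounds.get(axis, False) or j.is_alternative
    return bounds


def classify_site(
    site: InteractionSite,
    premrna: TranscriptModel,
    junctions: Sequence[SpliceJunction] = (),
) -> InteractionSite:
    """Set site_class and spans_alternative_junction on a pre-mRNA site.

    The target interval is on the pre-mRNA 5'->3' axis.  A site is
    junction-spanning when it strictly covers at least one exon-intron
    boundary of any catalogued junction; otherwise it is exonic or
    intronic according to the exon-union blocks.  It spans an
    alternative junction when a covered boundary belongs to a junction
    flagged alternative.
    """
    ts, te = site.target_interval
    bounds = junction_boundaries_on_axis(premrna, junctions)
    covered = [b for b in bounds if ts < b < te]
    if covered:
        site.site_class = "junction_spanning"
        site.spans_alternative_junction = any(bounds[b] for b in covered)
    else:
        site.spans_alternative_junction = False
        in_exon = False
        for s, e in premrna.exons:
            lo, hi = sorted(
                (_to_premrna_axis(premrna, s), _to_premrna_axis(premrna, e))
            )
            if lo <= ts and te <= hi:
                in_exon = True
                break
        site.site_class = "exonic" if in_exon else "intronic"
    return site


def junction_enrichment(
    sites: Sequence[InteractionSite],
    junctions: Sequence[SpliceJunction],
    premrna_by_gene: Mapping[str, TranscriptModel],
    gene_of_target: Mapping[str, str],
) -> tuple[float | None, float | None, np.ndarray]:
    """Fisher's exact test: alternative junctions among interacted ones.

    A junction is "interacted" when some site on its gene's pre-mRNA
    covers one of its boundary coordinates.  Returns (odds ratio with
    Haldane correction when a cell is zero, two-sided exact p, the 2x2
    table [[alt_hit, alt_miss], [const_hit, const_miss]]).  With an
    empty margin the test is undefined and (None, None, table) is
    returned.
    """
    hit_bounds: dict[str, set[int]] = {}
    for site in sites:
        gid = gene_of_target.get(site.target_id)
        if gid is None or gid not in premrna_by_gene:
            continue
        ts, te = site.target_interval
        hit_bounds.setdefault(gid, set()).update(range(ts + 1, te))

    a = b = c = d = 0
    for j in junctions:
        pm = premrna_by_gene.get(j.gene_id)
        if pm is None:
            continue
        bounds = {
            _to_premrna_axis(pm, j.donor_pos),
            _to_premrna_axis(pm, j.acceptor_pos),
        }
        interacted = bool(bounds & hit_bounds.get(j.gene_id, set()))
        if j.is_alternative:
            a += interacted
            b += not interacted
        else:
            c += interacted
            d += not interacted
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("junction enrichment undefined: empty margin in %s", table.tolist())
        return None, None, table
    p = fisher_two_sided(table)
    odds = odds_ratio_haldane(table)
    return float(odds), float(p), table


def fisher_two_sided(table: np.ndarray | Sequence[Sequence[int]]) -> float:
    """Two-sided exact p: sum of hypergeometric table probabilities <= observed's."""
    return float(fisher_exact(np.asarray(table), alternative="two-sided")[1])


def odds_ratio_haldane(table: np.ndarray | Sequence[Sequence[int]]) -> float:
    """Sample odds ratio; Haldane 0.5 correction when any cell is zero."""
    (a, b), (c, d) = np.asarray(table)
    if min(a, b, c, d) == 0:
        return float(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)))
    return float((a * d) / (b * c))


# ---------------------------------------------------------------------------
# Expression correlation of interacting pairs
# ---------------------------------------------------------------------------

def spearman_permutation(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = 8,
    n_mc: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rho with a one-sided (positive) permutation p-value.

    Exact enumeration of all n! orderings for n <= ``exact_max_n``;
    Monte-Carlo beyond.  Ties use average ranks.  Constant vectors make
    rho undefined (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(set(x)) == 1 or len(set(y)) == 1:
        return (float("nan"), float("nan"))
    rho = float(spearmanr(x, y).statistic)
    if n <= exact_max_n:
        perms = permutations(range(n))
        count = 0
        total = 0
        for pi in perms:
            r = spearmanr(x, y[list(pi)]).statistic
            count += r >= rho - 1e-12
            total += 1
        p = count / total
        if 1.0 / total > 0.05:
            logger.warning(
                "only %d samples: permutation p cannot fall below %.3f",
                n, 1.0 / total,
            )
    else:
        rng = np.random.default_rng(seed)
        count = sum(
            spearmanr(x, rng.permutation(y)).statistic >= rho - 1e-12
            for _ in range(n_mc)
        )
        p = (count + 1) / (n_mc + 1)
    return rho, float(p)


def correlate_pairs(
    sites: Sequence[InteractionSite],
    expr: ExpressionMatrix,
    gene_of_target: Mapping[str, str] | None = None,
    min_rho: float = 0.8,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[dict]:
    """Per-pair lncRNA/target expression correlation across samples.

    Returns one record per distinct (lncRNA, target) pair with rho, the
    permutation p, and a ``coregulated`` flag at rho > ``min_rho`` and
    p < ``alpha``.
    """
    pairs = sorted({(s.lncrna_id, s.target_id) for s in sites})
    out = []
    for lnc_id, target_id in pairs:
        key = target_id
        if key not in expr.values.index and gene_of_target:
            key = gene_of_target.get(target_id, target_id)
        if lnc_id not in expr.values.index or key not in expr.values.index:
            continue
        x = expr.values.loc[lnc_id].to_numpy()
        y = expr.values.loc[key].to_numpy()
        rho, p = spearman_permutation(x, y, seed=seed)
        out.append(
            {
                "lncrna_id": lnc_id,
                "target_id": target_id,
                "rho": rho,
                "pvalue": p,
                "coregulated": bool(
                    np.isfinite(rho) and rho > min_rho and p < alpha
                ),
            }
        )
    return out


# ---------------------------------------------------------------------------
# Shared interaction sites between isoform groups
# ---------------------------------------------------------------------------

def common_site_fraction(
    sites_ref: Sequence[tuple[str, str, Interval]],
    sites_alt: Sequence[tuple[str, str, Interval]],
) -> tuple[float, int, int, int]:
    """Jaccard-style shared fraction of interaction sites.

    Sites are (lncrna_id, gene_id, genomic interval) after projecting
    target coordinates to the genome; two sites are the same when they
    share lncRNA and gene and their intervals overlap by >= 1 nt.
    Overlapping sites are merged into clusters; returns
    (shared/union, n_shared, n_ref_only, n_alt_only).
    """
    groups: dict[tuple[str, str], list[tuple[Interval, str]]] = {}
    for origin, sites in (("ref", sites_ref), ("alt", sites_alt)):
        for lnc, gene, iv in sites:
            groups.setdefault((lnc, gene), []).append((iv, origin))
    shared = ref_only = alt_only = 0
    for members in groups.values():
        members.sort()
        clusters: list[tuple[int, int, set[str]]] = []
        for (s, e), origin in members:
            if clusters and s < clusters[-1][1]:
                cs, ce, origins = clusters[-1]
                clusters[-1] = (cs, max(ce, e), origins | {origin})
            else:
                clusters.append((s, e, {origin}))
        for _, _, origins in clusters:
            if origins == {"ref"}:
                ref_only += 1
            elif origins == {"alt"}:
                alt_only += 1
            else:
                shared += 1
    union = shared + ref_only + alt_only
    frac = shared / union if union else float("nan")
    return frac, shared, ref_only, alt_only


def project_site_to_genomic(
    site: InteractionSite, transcript: TranscriptModel
) -> Interval:
    """Map a site's target interval (spliced-transcript axis) to genomic.

    Returns the genomic envelope (start of first touched base, end of
    last), which may span introns for junction-crossing sites.
    """
    order = transcript.exons_transcription_order()
    positions = []
    offset = 0
    ts, te = site.target_interval
    for s, e in order:
        length = e - s
        lo = max(ts - offset, 0)
        hi = min(te - offset, length)
        if lo < hi:
            if transcript.strand == "+":
                positions.extend((s + lo, s + hi))
            else:
                positions.extend((e - hi, e - lo))
        offset += length
    if not positions:
        raise ValueError("site does not touch the transcript")
    return (min(positions), max(positions))
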