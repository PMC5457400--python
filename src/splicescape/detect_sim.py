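"""In-silico AS detectability: how many loci would look alternatively
spliced at the proteome level if all isoforms were translated equally.

For each gene observed in the MS data, the tryptic peptides of all its
isoform ORFs are pooled (a peptide shared by k isoforms appears k times —
equal molar abundance semantics), the same number of peptides as actually
observed for the gene is drawn at random without replacement, and the
gene counts as AS-distinguishable when the draw contains isoform-specific
peptides from at least two distinct isoforms.  Repeating the draw gives
the expected count and its spread, to compare with the observed count.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .proteogenomics import OrfRecord, PeptideRecord, _canonical, digest_trypsin

PoolEntry = tuple[str, str]  # (canonical peptide, transcript_id)


def gene_peptide_pool(
    orfs: Sequence[OrfRecord],
    min_len: int = 7,
    max_len: int = 50,
    il_equivalence: bool = True,
    max_missed: int = 1,
    frame: str = "multiset",
) -> list[PoolEntry]:
    """Sampling pool for one gene.

    ``frame="multiset"``: concatenation of every isoform's digest, so a
    peptide shared by k isoforms appears k times (equal-expression
    semantics).  ``frame="distinct"``: one entry per distinct
    (peptide, isoform) never duplicated across isoforms — uniform over
    distinct peptides, each attributed to an arbitrary carrier.
    The pool is canonically sorted so downstream seeding is independent
    of input order.
    """
    entries: list[PoolEntry] = []
    for orf in orfs:
        peps = {
            _canonical(p, il_equivalence)
            for p, _ in digest_trypsin(orf.protein_sequence, max_missed)
            if min_len <= len(p) <= max_len
        }
        entries.extend((pep, orf.transcript_id) for pep in peps)
    if frame == "distinct":
        seen: dict[str, PoolEntry] = {}
        for pep, tid in sorted(entries):
            seen.setdefault(pep, (pep, tid))
        entries = list(seen.values())
    elif frame != "multiset":
        raise ValueError(f"unknown sampling frame {frame!r}")
    return sorted(entries)


@dataclass
class DetectabilityResult:
    per_replicate: np.ndarray        # AS-distinguishable gene count, per replicate
    per_replicate_ge1: np.ndarray    # genes with >=1 ISP drawn, per replicate
    observed: int | None
    n_reps: int
    seed: int
    n_genes: int
    skipped_genes: list[str]

    @property
    def mean(self) -> float:
        return float(self.per_replicate.mean())

    @property
    def sd(self) -> float:
        return float(self.per_replicate.std(ddof=1)) if self.n_reps > 1 else 0.0

    @property
    def ratio(self) -> float | None:
        if self.observed is None or self.observed <= 0:
            return None
        return self.mean / self.observed


def _gene_rng(seed: int, gene_id: str) -> np.random.Generator:
    """Stable per-gene substream: gene-order independent, seed below 2^32."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(gene_id.encode())])
    )


def simulate_detection(
    pools: Mapping[str, Sequence[PoolEntry]],
    observed_counts: Mapping[str, int],
    isp_records: Mapping[str, PeptideRecord],
    n_reps: int = 100,
    seed: int = 0,
    observed_as_genes: int | None = None,
) -> DetectabilityResult:
    """Resample peptide draws and count AS-distinguishable genes.

    ``observed_counts[g]`` is the number of peptides identified for gene
    g in the real MS data; the simulation draws that many from g's pool
    without replacement (all of them when the pool is smaller).  A drawn
    peptide is isoform evidence when its specificity in ``isp_records``
    is ``isoform_specific``.  Fully reproducible from ``seed``; each
    gene uses its own RNG substream so results do not depend on gene
    order.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    counts = np.zeros(n_reps, dtype=int)
    counts_ge1 = np.zeros(n_reps, dtype=int)
    skipped = []
    n_genes = 0
    for gene_id in sorted(observed_counts):
        n_g = observed_counts[gene_id]
        pool = sorted(pools.get(gene_id, ()))  # canonical order before seeding
        if not pool:
            if n_g > 0:
                skipped.append(gene_id)
            continue
        n_genes += 1
        k = min(n_g, len(pool))
        if k == 0:
            continue
        # precompute which pool entries are isoform evidence
        evidence_tid = np.array(
            [
                tid
                if (rec := isp_records.get(pep)) is not None
                and rec.specificity == "isoform_specific"
                else ""
                for pep, tid in pool
            ],
            dtype=object,
        )
        rng = _gene_rng(seed, gene_id)
        m = len(pool)
        for rep in range(n_reps):
            idx = rng.choice(m, size=k, replace=False)
            tids = {t for t in evidence_tid[idx] if t}
            if tids:
                counts_ge1[rep] += 1
            if len(tids) >= 2:
                counts[rep] += 1
    return DetectabilityResult(
        per_replicate=counts,
        per_replicate_ge1=counts_ge1,
        observed=observed_as_genes,
        n_reps=n_reps,
        seed=seed,
        n_genes=n_genes,
        skipped_genes=skipped,
    )


def compare_to_observed(
    result: DetectabilityResult,
    observed_as_genes: int,
    large_factor: float = 10.0,
) -> dict:
    """Expected-vs-observed report for the detectability simulation."""
    if observed_as_genes > 0:
        ratio = result.mean / observed_as_genes
        verdict = (
            "expected >> observed"
            if ratio > large_factor
            else "expected comparable to observed"
        )
    else:
        ratio = None
        verdict = "ratio undefined (observed count is 0)"
    return {
        "expected_mean": result.mean,
        "expected_sd": result.sd,
        "observed": observed_as_genes,
        "ratio": ratio,
        "verdict": verdict,
        "n_reps": result.n_reps,
    }
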