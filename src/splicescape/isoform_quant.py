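"""Isoform usage, isoform-switch scoring, and DAS/DE calling.

Isoform fraction (IF) is the percentage contribution of a transcript to
its gene's total FPKM in a condition; dIF is the difference of IF between
two conditions in percentage points.  The switch score per gene and
condition pair is the square root of the Jensen-Shannon divergence
(base-2 logarithm) between the gene's isoform-fraction vectors, which
lies in [0, 1].  A gene is differentially alternatively spliced (DAS)
when some isoform moves by more than the dIF threshold (default 20
percentage points) and the gene-level permutation test on the switch
score is significant after Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .models_io import ExpressionMatrix, GeneModel

logger = logging.getLogger(__name__)

DEFAULT_DIF_THRESHOLD = 20.0
DEFAULT_FPKM_FLOOR = 0.2
DEFAULT_LFC = 2.0
DEFAULT_FDR = 0.05


def isoform_fractions(
    expr: ExpressionMatrix,
    genes: Iterable[GeneModel],
    per_sample: bool = False,
) -> pd.DataFrame:
    """IF table: percent of gene FPKM per transcript x condition.

    Where a gene's total FPKM is zero in a condition the IF is undefined
    and reported as NaN (never as 0).  With ``per_sample`` the columns
    are samples instead of condition means.
    """
    values = expr.values if per_sample else expr.condition_means()
    rows = []
    index = []
    gene_of = {}
    for g in genes:
        tids = [t.transcript_id for t in g.transcripts if t.transcript_id in values.index]
        if not tids:
            continue
        sub = values.loc[tids]
        total = sub.sum(axis=0)
        frac = 100.0 * sub.div(total.where(total > 0), axis=1)
        rows.append(frac)
        index.extend(tids)
        for tid in tids:
            gene_of[tid] = g.gene_id
    if not rows:
        return pd.DataFrame()
    out = pd.concat(rows)
    out.insert(0, "gene_id", [gene_of[t] for t in out.index])
    return out


def compute_dif(
    if_table: pd.DataFrame, condition_pair: tuple[str, str]
) -> pd.Series:
    """dIF = IF(contrast) - IF(reference), percentage points.

    Transcripts with undefined IF on either side are skipped (NaN) and
    logged.  Per gene, the defined dIF values sum to 0.
    """
    ref, contrast = condition_pair
    dif = if_table[contrast] - if_table[ref]
    n_skipped = int(dif.isna().sum())
    if n_skipped:
        logger.info(
            "dIF undefined for %d transcripts (gene FPKM zero in %s or %s)",
            n_skipped, ref, contrast,
        )
    dif.name = "dIF"
    return dif


def switch_score(p: Sequence[float], q: Sequence[float]) -> float:
    """Square root of the Jensen-Shannon divergence (base 2) of p vs q.

    Inputs are isoform-fraction vectors of one gene; they are
    renormalised to sum to 1.  Returns a value in [0, 1]; 0 iff the
    renormalised distributions are equal, 1 for disjoint support.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.sum() <= 0 or q.sum() <= 0:
        logger.warning("switch_score undefined for zero-sum fraction vector")
        return float("nan")
    d = float(jensenshannon(p / p.sum(), q / q.sum(), base=2))
    # jensenshannon already returns the square root of the divergence
    return min(max(d, 0.0), 1.0)


@dataclass
class DasResult:
    """Per-gene DAS table plus the per-isoform usage table."""

    genes: pd.DataFrame      # index gene_id: sqrt_jsd, max_abs_dif, pvalue, qvalue, das
    isoforms: pd.DataFrame   # index transcript_id: gene_id, IF per condition, dIF, das
    significance: str        # "permutation" or "none"


def _gene_sqrt_jsd(sub_ref: np.ndarray, sub_con: np.ndarray) -> float:
    """sqrt-JSD between mean isoform-abundance vectors of two sample sets."""
    p = sub_ref.mean(axis=1)
    q = sub_con.mean(axis=1)
    if p.sum() <= 0 or q.sum() <= 0:
        return float("nan")
    return switch_score(p, q)


def call_das(
    expr: ExpressionMatrix,
    genes: Iterable[GeneModel],
    condition_pair: tuple[str, str],
    dif_threshold: float = DEFAULT_DIF_THRESHOLD,
    fdr: float = DEFAULT_FDR,
    max_permutations: int = 2000,
    seed: int = 0,
    significance_mode: str = "auto",
) -> DasResult:
    """Call DAS genes/isoforms between two conditions.

    With replicates, gene-level significance is a permutation test on the
    sqrt-JSD switch score across condition labels (exhaustive when the
    number of label assignments is small, else Monte-Carlo), corrected by
    Benjamini-Hochberg across genes.  Without replicates — or with
    ``significance_mode="threshold_only"`` — only the dIF threshold
    applies and the result is marked ``significance="none"``.

    Note the granularity of an exhaustive label permutation: with r
    replicates per condition the smallest attainable p is
    2/C(2r, r) (the observed labelling and its mirror), so at least 4
    replicates per condition are required before p can fall below 0.05.
    """
    genes = [g for g in list(genes) if len(g.transcripts) >= 2]
    ref, contrast = condition_pair
    samples_ref = expr.samples_of(ref)
    samples_con = expr.samples_of(contrast)
    if not samples_ref or not samples_con:
        raise ValueError(f"no samples for condition pair {condition_pair}")
    if significance_mode not in ("auto", "permutation", "threshold_only"):
        raise ValueError(f"unknown significance_mode {significance_mode!r}")
    have_replicates = (
        significance_mode != "threshold_only"
        and len(samples_ref) > 1
        and len(samples_con) > 1
    )
    if significance_mode == "permutation" and not (
        len(samples_ref) > 1 and len(samples_con) > 1
    ):
        raise ValueError("permutation mode requires replicates in both conditions")

    if_table = isoform_fractions(expr, genes)
    dif = compute_dif(if_table, condition_pair)

    all_samples = samples_ref + samples_con
    n_ref = len(samples_ref)
    assignments = list(combinations(range(len(all_samples)), n_ref))
    rng = np.random.default_rng(seed)
    exhaustive = len(assignments) <= max_permutations

    gene_rows = {}
    iso_das = pd.Series(False, index=if_table.index)
    for g in genes:
        tids = [
            t.transcript_id
            for t in g.transcripts
            if t.transcript_id in expr.values.index
        ]
        if len(tids) < 2:
            continue
        sub = expr.values.loc[tids, all_samples].to_numpy()
        obs = _gene_sqrt_jsd(sub[:, :n_ref], sub[:, n_ref:])
        gdif = dif.loc[tids]
        max_abs = float(gdif.abs().max())
        pval = np.nan
        if have_replicates and np.isfinite(obs):
            if exhaustive:
                chosen = assignments
            else:
                idx = rng.choice(len(assignments), size=max_permutations, replace=False)
                chosen = [assignments[i] for i in idx]
            count = 0
            for comb in chosen:
                mask = np.zeros(len(all_samples), dtype=bool)
                mask[list(comb)] = True
                stat = _gene_sqrt_jsd(sub[:, mask], sub[:, ~mask])
                if np.isfinite(stat) and stat >= obs - 1e-12:
                    count += 1
            # the identity assignment is always in the exhaustive set, so
            # count >= 1 and p is never 0
            pval = count / len(chosen)
        gene_rows[g.gene_id] = {
            "sqrt_jsd": obs,
            "max_abs_dif": max_abs,
            "pvalue": pval,
        }
    gene_df = pd.DataFrame.from_dict(gene_rows, orient="index")
    if gene_df.empty:
        return DasResult(gene_df, if_table.assign(dIF=dif, das=iso_das),
                         "permutation" if have_replicates else "none")

    if have_replicates:
        ok = gene_df["pvalue"].notna()
        qvals = pd.Series(np.nan, index=gene_df.index)
        if ok.any():
            qvals.loc[ok] = multipletests(
                gene_df.loc[ok, "pvalue"], method="fdr_bh"
            )[1]
        gene_df["qvalue"] = qvals
        gene_df["das"] = (
            (gene_df["max_abs_dif"] > dif_threshold)
            & (gene_df["pvalue"] < 0.05)
            & (gene_df["qvalue"] < fdr)
        )
        significance = "permutation"
    else:
        gene_df["qvalue"] = np.nan
        gene_df["das"] = gene_df["max_abs_dif"] > dif_threshold
        significance = "none"

    das_genes = set(gene_df.index[gene_df["das"]])
    iso_df = if_table.assign(dIF=dif)
    iso_df["das"] = [
        (abs(d) > dif_threshold) and (gid in das_genes) if np.isfinite(d) else False
        for d, gid in zip(iso_df["dIF"], iso_df["gene_id"])
    ]
    return DasResult(gene_df, iso_df, significance)


def call_de(
    expr: ExpressionMatrix,
    genes: Iterable[GeneModel],
    condition_pair: tuple[str, str],
    floor: float = DEFAULT_FPKM_FLOOR,
    lfc: float = DEFAULT_LFC,
) -> pd.DataFrame:
    """Fold-change DE calls on gene-level FPKM (sum of isoform FPKM).

    Genes below the FPKM floor in both conditions are excluded; remaining
    values are clamped to the floor before the log-ratio, and a gene is
    DE iff |log2(FPKM_contrast / FPKM_ref)| exceeds ``lfc``.
    """
    ref, contrast = condition_pair
    genes = list(genes)
    totals = expr.gene_totals(genes)
    means = pd.DataFrame(
        {
            c: totals[expr.samples_of(c)].mean(axis=1)
            for c in (ref, contrast)
        }
    )
    keep = (means[ref] >= floor) | (means[contrast] >= floor)
    means = means[keep]
    clamped = means.clip(lower=floor)
    log2fc = np.log2(clamped[contrast] / clamped[ref])
    out = pd.DataFrame(
        {
            "fpkm_ref": means[ref],
            "fpkm_contrast": means[contrast],
            "log2fc": log2fc,
            "de": log2fc.abs() > lfc,
        }
    )
    out["direction"] = np.where(
        ~out["de"], "none", np.where(out["log2fc"] > 0, "up", "down")
    )
    return out


def utr5_expression_association(
    utr5_lengths: dict[str, int],
    expr: ExpressionMatrix,
    condition: str,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman correlation between 5'-UTR length and FPKM.

    Returns (rho, permutation p, one-sided for negative association).
    Undefined (NaN, NaN) with fewer than 3 isoforms with both values.
    """
    tids = [t for t in utr5_lengths if t in expr.values.index]
    if len(tids) < 3:
        return (float("nan"), float("nan"))
    x = np.array([utr5_lengths[t] for t in tids], dtype=float)
    y = expr.condition_means().loc[tids, condition].to_numpy()
    if len(set(y)) == 1 or len(set(x)) == 1:
        # all ranks tied on one side: average ranking makes rho 0
        return (0.0, 1.0)
    rho = spearmanr(x, y).statistic
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        r = spearmanr(x, rng.permutation(y)).statistic
        if r <= rho + 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return float(rho), float(p)
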