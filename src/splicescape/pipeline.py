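"""End-to-end pipeline: models_io -> as_events -> isoform_quant ->
proteogenomics -> detect_sim -> lnc_interactome, with a run manifest.

Every stage writes its outputs before the next starts; all randomness
derives from the single configured seed, so a rerun with the same config
produces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .as_events import (
    build_pre_mrna,
    classify_as_events,
    type_junctions,
)
from .detect_sim import compare_to_observed, gene_peptide_pool, simulate_detection
from .isoform_quant import call_das, call_de, isoform_fractions
from .lnc_interactome import (
    InteractionSite,
    PairingScoreScheme,
    align_duplex,
    classify_cis_nat,
    classify_site,
    common_site_fraction,
    correlate_pairs,
    filter_lncrna_candidates,
    junction_enrichment,
    project_site_to_genomic,
)
from .models_io import (
    extract_sequences,
    premrna_sequence,
    read_expression,
    read_gene_models,
    read_genome,
    read_peptide_observations,
    spliced_sequence,
    write_bed6,
    write_fasta,
)
from .proteogenomics import (
    classify_peptides,
    map_observed_peptides,
    primary_orf,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and thresholds of a pipeline run."""

    genome: str = "genome.fa"
    genes: str = "genes.gtf"
    expression: str = "expression.tsv"
    lncrnas: str | None = "lncrnas.gtf"
    lnc_classes: str | None = "lncrna_classes.tsv"
    peptides: str | None = "peptides_observed.tsv"
    outdir: str = "run"
    seed: int = 0
    condition_ref: str | None = None       # default: first two conditions
    condition_contrast: str | None = None
    dif_threshold: float = 20.0
    fpkm_floor: float = 0.2
    lfc: float = 2.0
    fdr: float = 0.05
    lnc_min_fpkm: float = 0.5
    mrna_min_fpkm: float = 1.0
    min_score: float = 100.0
    min_len: int = 25
    detect_reps: int = 100
    min_orf: int = 100
    pep_len: tuple[int, int] = (7, 50)
    rho_threshold: float = 0.8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        if isinstance(cfg.pep_len, list):
            cfg.pep_len = tuple(cfg.pep_len)
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (not the outdir)."""
        doc = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str, index_label=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# splicescape config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", float_format="%.6g", index_label=index_label)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Raises with the stage name on failure; outputs of completed stages
    are preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("splicescape")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": chash,
        "seed": config.seed,
        "stages": [],
    }
    stage_name = "models_io"
    try:
        # ---- stage 1: models_io -------------------------------------
        t0 = time.time()
        for key in ("genome", "genes", "expression"):
            p = Path(getattr(config, key))
            if not p.exists():
                raise FileNotFoundError(f"input {key} file not found: {p}")
        genome = read_genome(config.genome)
        genes = read_gene_models(config.genes)
        genes.sort(key=lambda g: g.gene_id)
        extract_sequences(genes, genome)
        expr = read_expression(config.expression)
        conds = expr.condition_names
        ref = config.condition_ref or conds[0]
        contrast = config.condition_contrast or conds[1]
        lncs = []
        lnc_classes = {}
        if config.lncrnas and Path(config.lncrnas).exists():
            lnc_genes = read_gene_models(config.lncrnas)
            lncs = sorted(
                (t for g in lnc_genes for t in g.transcripts),
                key=lambda t: t.transcript_id,
            )
            for t in lncs:
                t.sequence = spliced_sequence(t, genome)
            if config.lnc_classes and Path(config.lnc_classes).exists():
                cl = pd.read_csv(config.lnc_classes, sep="\t")
                lnc_classes = dict(zip(cl["transcript_id"], cl["class_code"]))
            else:
                lnc_classes = {t.transcript_id: "u" for t in lncs}
        observations = None
        if config.peptides and Path(config.peptides).exists():
            observations = read_peptide_observations(config.peptides)
        manifest["stages"].append(
            {"name": stage_name, "seconds": round(time.time() - t0, 3)}
        )

        # ---- stage 2: as_events -------------------------------------
        stage_name = "as_events"
        t0 = time.time()
        events_by_gene = {}
        junctions_by_gene = {}
        ev_rows, jn_rows = [], []
        for g in genes:
            events = classify_as_events(g)
            events_by_gene[g.gene_id] = events
            junctions = type_junctions(g, genome, events=events)
            junctions_by_gene[g.gene_id] = junctions
            for ev in events:
                ev_rows.append(
                    {
                        "gene_id": g.gene_id,
                        "event_type": ev.event_type,
                        "start": ev.interval[0],
                        "end": ev.interval[1],
                        "transcripts": ",".join(
                            sorted(ev.involved_transcript_ids)
                        ),
                        "annotated": ev.annotated,
                    }
                )
            for j in junctions:
                jn_rows.append(
                    {
                        "gene_id": g.gene_id,
                        "chrom": g.chrom,
                        "start": j.interval[0],
                        "end": j.interval[1],
                        "strand": j.strand,
                        "donor": j.donor_dinucleotide,
                        "acceptor": j.acceptor_dinucleotide,
                        "subtype": j.subtype,
                        "is_alternative": j.is_alternative,
                    }
                )
        _write_tsv(pd.DataFrame(ev_rows), outdir / "as_events.tsv", chash)
        _write_tsv(pd.DataFrame(jn_rows), outdir / "junctions.tsv", chash)
        write_bed6(
            (
                (r["chrom"], r["start"], r["end"],
                 f"{r['gene_id']}|{r['subtype']}|"
                 f"{'alt' if r['is_alternative'] else 'const'}",
                 0.0, r["strand"])
                for r in jn_rows
            ),
            outdir / "junctions.bed",
        )
        manifest["stages"].append(
            {"name": stage_name, "seconds": round(time.time() - t0, 3)}
        )

        # ---- stage 3: isoform_quant ---------------------------------
        stage_name = "isoform_quant"
        t0 = time.time()
        das = call_das(
            expr,
            genes,
            (ref, contrast),
            dif_threshold=config.dif_threshold,
            fdr=config.fdr,
            seed=config.seed,
        )
        _write_tsv(das.isoforms, outdir / "isoform_usage.tsv", chash,
                   index_label="transcript_id")
        _write_tsv(das.genes, outdir / "das_genes.tsv", chash,
                   index_label="gene_id")
        de = call_de(
            expr, genes, (ref, contrast),
            floor=config.fpkm_floor, lfc=config.lfc,
        )
        _write_tsv(de, outdir / "de_genes.tsv", chash, index_label="gene_id")
        manifest["stages"].append(
            {"name": stage_name, "seconds": round(time.time() - t0, 3)}
        )

        # ---- stage 4: proteogenomics --------------------------------
        stage_name = "proteogenomics"
        t0 = time.time()
        orfs_by_gene = {}
        proteins = {}
        for g in genes:
            orfs = []
            for t in g.transcripts:
                orf = primary_orf(
                    t.transcript_id, t.sequence, min_len=config.min_orf
                )
                if orf is not None:
                    orfs.append(orf)
                    proteins[orf.orf_id] = orf.protein_sequence
            if orfs:
                orfs_by_gene[g.gene_id] = orfs
        write_fasta(proteins, outdir / "orfs.faa")
        records = classify_peptides(
            orfs_by_gene,
            min_len=config.pep_len[0],
            max_len=config.pep_len[1],
        )
        pep_rows = [
            {
                "peptide": rec.sequence,
                "specificity": rec.specificity,
                "genes": ",".join(sorted(rec.gene_ids)),
                "transcripts": ",".join(sorted(rec.transcript_ids)),
                "missed_cleavages": rec.missed_cleavages,
            }
            for rec in sorted(records.values(), key=lambda r: r.sequence)
        ]
        _write_tsv(pd.DataFrame(pep_rows), outdir / "peptides.tsv", chash)
        summary = None
        if observations is not None:
            summary = map_observed_peptides(observations, records)
            ev_rows = [
                {
                    "gene_id": gid,
                    "n_observed_peptides": len(ev.observed_peptides),
                    "total_spectra": ev.total_spectra,
                    "n_isoforms_with_isp": len(ev.isp_spectra_by_isoform),
                    "as_confirmed": ev.as_confirmed,
                }
                for gid, ev in sorted(summary.genes.items())
            ]
            _write_tsv(
                pd.DataFrame(ev_rows), outdir / "gene_evidence.tsv", chash
            )
        manifest["stages"].append(
            {"name": stage_name, "seconds": round(time.time() - t0, 3)}
        )

        # ---- stage 5: detect_sim ------------------------------------
        stage_name = "detect_sim"
        t0 = time.time()
        if summary is not None:
            pools = {
                gid: gene_peptide_pool(
                    orfs,
                    min_len=config.pep_len[0],
                    max_len=config.pep_len[1],
                )
                for gid, orfs in orfs_by_gene.items()
            }
            observed_counts = {
                gid: len(ev.observed_peptides)
                for gid, ev in summary.genes.items()
            }
            result = simulate_detection(
                pools,
                observed_counts,
                records,
                n_reps=config.detect_reps,
                seed=config.seed,
            )
            report = compare_to_observed(
                result, len(summary.as_confirmed_genes)
            )
            _write_tsv(
                pd.DataFrame(
                    {
                        "replicate": range(1, result.n_reps + 1),
                        "as_distinguishable": result.per_replicate,
                        "ge1_isp": result.per_replicate_ge1,
                    }
                ),
                outdir / "detectability.tsv",
                chash,
            )
            with open(outdir / "detectability_summary.json", "w") as fh:
                json.dump(report, fh, indent=1, sort_keys=True)
        manifest["stages"].append(
            {"name": stage_name, "seconds": round(time.time() - t0, 3)}
        )

        # ---- stage 6: lnc_interactome -------------------------------
        stage_name = "lnc_interactome"
        t0 = time.time()
        if lncs:
            kept = filter_lncrna_candidates(
                lncs, expr, lnc_classes, min_fpkm=config.lnc_min_fpkm
            )
            nat = classify_cis_nat(kept, genes)
            means = expr.condition_means()
            scheme = PairingScoreScheme()
            all_junctions = [
                j for js in junctions_by_gene.values() for j in js
            ]
            premrna_by_gene = {}
            gene_of_target = {}
            sites: list[InteractionSite] = []
            expressed = [
                g
                for g in genes
                if any(
                    t.transcript_id in means.index
                    and means.loc[t.transcript_id].max() > config.mrna_min_fpkm
                    for t in g.transcripts
                )
            ]
            for g in expressed:
                pm = build_pre_mrna(g)
                premrna_by_gene[g.gene_id] = pm
                gene_of_target[pm.transcript_id] = g.gene_id
                target_seq = premrna_sequence(g, genome)
                for lnc in kept:
                    sites.extend(
                        classify_site(
                            s, pm, junctions_by_gene[g.gene_id]
                        )
                        for s in align_duplex(
                            lnc.sequence,
                            target_seq,
                            scheme,
                            min_score=config.min_score,
                            min_len=config.min_len,
                            lncrna_id=lnc.transcript_id,
                            target_id=pm.transcript_id,
                        )
                    )
            # mRNA-level sites for reference vs alternative isoform groups
            ref_sites, alt_sites = [], []
            for g in expressed:
                if len(g.transcripts) < 2:
                    continue
                for t in g.transcripts:
                    is_ref = t.transcript_id == (
                        g.reference_transcript_id or g.transcripts[0].transcript_id
                    )
                    for lnc in kept:
                        for s in align_duplex(
                            lnc.sequence,
                            t.sequence,
                            scheme,
                            min_score=config.min_score,
                            min_len=config.min_len,
                            lncrna_id=lnc.transcript_id,
                            target_id=t.transcript_id,
                        ):
                            entry = (
                                lnc.transcript_id,
                                g.gene_id,
                                project_site_to_genomic(s, t),
                            )
                            (ref_sites if is_ref else alt_sites).append(entry)
            frac, n_shared, n_ref, n_alt = common_site_fraction(
                ref_sites, alt_sites
            )
            site_rows = [
                {
                    "lncrna_id": s.lncrna_id,
                    "target_id": s.target_id,
                    "lnc_start": s.lnc_interval[0],
                    "lnc_end": s.lnc_interval[1],
                    "target_start": s.target_interval[0],
                    "target_end": s.target_interval[1],
                    "score": s.score,
                    "length": s.length,
                    "site_class": s.site_class,
                    "spans_alternative_junction": s.spans_alternative_junction,
                }
                for s in sites
            ]
            _write_tsv(pd.DataFrame(site_rows), outdir / "lnc_sites.tsv", chash)
            bed_rows = []
            for s in sites:
                g = premrna_by_gene[gene_of_target[s.target_id]]
                span_s, span_e = g.span
                ts, te = s.target_interval
                if g.strand == "+":
                    giv = (span_s + ts, span_s + te)
                else:
                    giv = (span_e - te, span_e - ts)
                bed_rows.append(
                    (g.chrom, giv[0], giv[1],
                     f"{s.lncrna_id}|{s.target_id}|{s.site_class}",
                     s.score, g.strand)
                )
            write_bed6(bed_rows, outdir / "lnc_sites.bed")
            odds, pval, table = junction_enrichment(
                sites, all_junctions, premrna_by_gene, gene_of_target
            )
            corr = correlate_pairs(
                sites, expr, gene_of_target, min_rho=config.rho_threshold,
                seed=config.seed,
            )
            _write_tsv(
                pd.DataFrame(corr), outdir / "lnc_correlations.tsv", chash
            )
            with open(outdir / "lnc_summary.json", "w") as fh:
                json.dump(
                    {
                        "n_lncrnas_kept": len(kept),
                        "n_cis_nat": sum(
                            1 for v in nat.values() if v[0] == "cis_NAT"
                        ),
                        "n_premrna_sites": len(sites),
                        "junction_enrichment_odds_ratio": odds,
                        "junction_enrichment_p": pval,
                        "enrichment_table": table.tolist(),
                        "common_site_fraction": None
                        if frac != frac
                        else frac,
                        "n_shared_sites": n_shared,
                        "n_ref_only_sites": n_ref,
                        "n_alt_only_sites": n_alt,
                    },
                    fh,
                    indent=1,
                    sort_keys=True,
                )
        manifest["stages"].append(
            {"name": stage_name, "seconds": round(time.time() - t0, 3)}
        )
    except Exception:
        logger.exception("pipeline failed in stage %s", stage_name)
        manifest["failed_stage"] = stage_name
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        root.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline failed in stage {stage_name}") from None
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    root.removeHandler(handler)
    handler.close()
    return outdir
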