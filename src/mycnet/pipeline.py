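"""End-to-end driver chaining all analysis stages on one study.

CT preprocessing → differential filtering (miRNA ΔCT and mRNA probes) →
probe collapsing → seed-site target mapping with anticorrelation pairing →
promoter PWM scanning at a p-value-calibrated cutoff → gene-set enrichment
→ two-arm network assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import diffexpr, enrichment, qpcr, targets
from .network import RegulatoryNetwork, assemble_network
from .pwm import MotifHit, ScanSummary, background_probs, calibrate_threshold, scan_promoters
from .simulate import SyntheticStudy

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    detected_mirnas: int
    sig_mirnas: diffexpr.SignificantSet
    sig_probes: diffexpr.SignificantSet
    genes: diffexpr.CollapsedGenes
    predictions: list[targets.TargetPrediction]
    pairs: targets.PairSet
    mss_cutoff: float
    motif_hits: list[MotifHit]
    scan_summary: ScanSummary
    enrichment_up: list[enrichment.EnrichmentResult] = field(default_factory=list)
    enrichment_down: list[enrichment.EnrichmentResult] = field(default_factory=list)
    network: RegulatoryNetwork = None


def run_study(study: SyntheticStudy, *, fc_cutoff: float = 2.0,
              p_cutoff: float = 0.05, min_dct: float = 10.0,
              background_threshold: float = 4.0, alpha: float = 0.01,
              css_cutoff: float = 0.75, mode: str = "moderate") -> PipelineResult:
    """Run the full pipeline on a (synthetic or loaded) study."""
    # miRNA branch: censor → ΔCT vs U6 → detection filter → differential
    censored = qpcr.censor_ct(study.mirna_ct)
    dct = qpcr.normalize_delta_ct(censored)
    detected = qpcr.detection_filter(dct, cutoff=min_dct)
    mirna_matrix = diffexpr.ExpressionMatrix(detected.values, feature_kind="mirna")
    mirna_results = diffexpr.differential_test(mirna_matrix, study.design)
    sig_mirnas = diffexpr.apply_thresholds(mirna_results, fc_cutoff, p_cutoff)

    # mRNA branch: background elimination → differential → probe collapsing
    filtered = diffexpr.background_filter(study.mrna_matrix, background_threshold)
    mrna_results = diffexpr.differential_test(filtered, study.design)
    sig_probes = diffexpr.apply_thresholds(mrna_results, fc_cutoff, p_cutoff)
    genes = diffexpr.collapse_probes_to_genes(sig_probes, study.probe2gene)
    log.info("significant: %d miRNAs, %d probes → %d unique genes",
             len(sig_mirnas.features), len(sig_probes.features), len(genes.genes))

    # post-transcriptional arm: seed sites of sig miRNAs in sig-gene UTRs,
    # intersected with opposite DE directions
    sig_mir_records = [m for m in study.mirna_seqs
                       if m.id in sig_mirnas.features]
    sig_utrs = [u for u in study.utrs if u.gene_id in genes.genes]
    predictions = targets.predict_all(sig_mir_records, sig_utrs, mode=mode)
    pairs = targets.anticorrelated_pairs(
        sig_mirnas.up, sig_mirnas.down, genes.up, genes.down, predictions)

    # transcriptional arm: promoter scan of significant genes
    probs = background_probs(study.config.gc_background if study.config else None)
    mss_cutoff = calibrate_threshold(study.pwm, probs=probs, alpha=alpha, seed=0)
    sig_promoters = [r for r in study.promoters if r.gene_id in genes.genes]
    hits, summary = scan_promoters(study.pwm, sig_promoters, mss_cutoff,
                                   css_cutoff, pvalue_probs=probs)

    # enrichment of up/down gene lists against the array universe
    universe = sorted(set(study.probe2gene.values()))
    enr_up = enr_down = []
    if genes.up:
        enr_up = enrichment.filter_and_rank(
            enrichment.fisher_enrichment(genes.up, universe, study.genesets))
    if genes.down:
        enr_down = enrichment.filter_and_rank(
            enrichment.fisher_enrichment(genes.down, universe, study.genesets))

    net = assemble_network(genes.directions(), hits, pairs)
    return PipelineResult(
        detected_mirnas=len(detected.values),
        sig_mirnas=sig_mirnas, sig_probes=sig_probes, genes=genes,
        predictions=predictions, pairs=pairs, mss_cutoff=mss_cutoff,
        motif_hits=hits, scan_summary=summary,
        enrichment_up=enr_up, enrichment_down=enr_down, network=net,
    )


def network_matches_truth(result: PipelineResult, truth: dict) -> bool:
    """True when both arms and the overlap equal the planted truth exactly."""
    net = result.network
    return (set(net.motif_arm) == set(truth["motif_arm"])
            and set(net.mirna_arm) == set(truth["mirna_arm"])
            and net.overlap == set(truth["overlap"]))
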