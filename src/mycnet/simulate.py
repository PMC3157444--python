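"""Synthetic two-condition studies with known planted truth.

Generates everything the pipeline consumes — a log2 mRNA probe matrix, a
miRNA CT matrix with a U6 control row, probe→gene mapping, promoter/UTR/
mature-miRNA sequences, gene sets — for a two-group design (wild type vs
c-Myc knockdown) with planted differential effects, promoter E-box motif
instances, 3′UTR seed sites and one enriched gene-set term.

Background sequence is i.i.d. at a configured GC fraction and is *clean*:
chance seed sites (for any simulated miRNA, at moderate stringency) and
chance PWM windows above the study's calibrated score cutoff are rewritten
away, so the planted truth is exactly the set of sites the sequence
contains. That is what makes end-to-end recovery against truth a sharp
test rather than a statistical one.

All randomness flows from ``SimulationConfig.seed``; a fixed seed gives
byte-identical studies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .diffexpr import ExpressionMatrix, GroupDesign
from .enrichment import GeneSetAnnotation
from .pwm import (PWM, PromoterRegion, background_probs, build_pwm,
                  calibrate_threshold, scan_promoters, _window_scores)
from .qpcr import CtMatrix
from .targets import (MiRNARecord, UTRRecord, predict_targets_moderate,
                      seed_site_patterns, wobble_site_patterns)

#: synthetic Myc/Max E-box count matrix (consensus CCACGTGG, CACGT core);
#: a stand-in fixture, not a TRANSFAC matrix
DEFAULT_MYC_MAX_COUNTS = np.array([
    #  A   C   G   T
    [2, 14,  2,  2],   # C
    [1, 16,  2,  1],   # C
    [18, 0,  1,  1],   # A
    [0, 19,  1,  0],   # C
    [0,  1, 19,  0],   # G
    [1,  0,  0, 19],   # T
    [1,  1, 17,  1],   # G
    [2,  2, 14,  2],   # G
])


def default_myc_max_pwm() -> PWM:
    """The synthetic E-box PWM used when no matrix is supplied."""
    return build_pwm(DEFAULT_MYC_MAX_COUNTS, id="MycMax_Ebox_synthetic")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design.

    Two replicates per group, log2 effects of ±2 on planted genes with
    0.25 log2 units of replicate noise, ΔΔCT shifts of 3 cycles (8-fold)
    on planted miRNAs with 0.25-cycle CT noise, 2 kb upstream promoter
    spans, and a U6 control near 20 cycles.
    """

    n_genes: int = 200
    n_mirnas: int = 40
    n_replicates_per_group: int = 2
    frac_de_genes_up: float = 0.1
    frac_de_genes_down: float = 0.1
    mrna_effect_log2: float = 2.0
    mrna_noise_sd: float = 0.25
    mirna_effect_dct: float = -3.0   # ΔΔCT shift for up-miRNAs; negative = higher expression
    ct_noise_sd: float = 0.25
    frac_de_mirnas_up: float = 0.2
    frac_de_mirnas_down: float = 0.1
    n_motif_genes: int = 12
    n_mirna_target_genes: int = 9
    n_overlap_genes: int = 4
    promoter_len_upstream: int = 2000
    first_exon_len: int = 300
    utr_len: int = 300
    gc_background: float = 0.42
    frac_multi_probe: float = 0.2
    frac_background_genes: float = 0.1
    background_level: float = 2.0
    baseline_low: float = 6.0
    baseline_high: float = 12.0
    ct_baseline_low: float = 22.0
    ct_baseline_high: float = 28.0
    frac_low_expressed_mirnas: float = 0.15
    u6_ct: float = 20.0
    u6_sd: float = 0.05
    motif_mutations: int = 0
    scan_alpha: float = 0.01
    css_cutoff: float = 0.75
    n_genesets: int = 10
    geneset_size: int = 15
    enriched_term_frac_de: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_replicates_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")
        for name in ("frac_de_genes_up", "frac_de_genes_down",
                     "frac_de_mirnas_up", "frac_de_mirnas_down",
                     "gc_background", "frac_multi_probe",
                     "frac_background_genes", "frac_low_expressed_mirnas",
                     "enriched_term_frac_de"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_de_genes_up + self.frac_de_genes_down > 1:
            raise ValueError("frac_de_genes_up + frac_de_genes_down exceeds 1")
        for name in ("promoter_len_upstream", "first_exon_len", "utr_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("mrna_noise_sd", "ct_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_overlap_genes > min(self.n_motif_genes,
                                      self.n_mirna_target_genes):
            raise ValueError("n_overlap_genes exceeds an arm size")


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    mrna_matrix: ExpressionMatrix
    mirna_ct: CtMatrix
    probe2gene: dict[str, str]
    design: GroupDesign
    promoters: list[PromoterRegion]
    utrs: list[UTRRecord]
    mirna_seqs: list[MiRNARecord]
    genesets: list[GeneSetAnnotation]
    pwm: PWM
    truth: dict = field(default_factory=dict)


_BASES = "ACGT"
_ROTATE = {"A": "C", "C": "G", "G": "T", "T": "A"}


def _random_seq(rng, length: int, probs) -> list[str]:
    return [_BASES[i] for i in rng.choice(4, size=length, p=probs)]


def _moderate_patterns(seed: str) -> list[str]:
    pats = seed_site_patterns(seed)
    return [pats["8mer"], pats["7mer-m8"], pats["7mer-A1"],
            *wobble_site_patterns(seed)]


def _seed_conflicts(new_seed: str, accepted: list[str]) -> bool:
    """True when the new seed could cross-react with an accepted one.

    Rejects seeds closer than 2 mismatches to an accepted seed, and seeds
    whose moderate-stringency site patterns occur inside the other seed's
    planted 8mer site string (in either direction) — either situation
    would let one miRNA's planted site double as a hit for another.
    """
    site_new = seed_site_patterns(new_seed)["8mer"]
    for old in accepted:
        if sum(a != b for a, b in zip(new_seed, old)) < 2:
            return True
        site_old = seed_site_patterns(old)["8mer"]
        if any(p in site_old for p in _moderate_patterns(new_seed)):
            return True
        if any(p in site_new for p in _moderate_patterns(old)):
            return True
    return False


def _draw_mirna_seqs(rng, ids: list[str], probs_rna) -> list[MiRNARecord]:
    records, seeds = [], []
    for mid in ids:
        for _ in range(2000):
            seq = "".join("ACGU"[i] for i in rng.choice(4, size=22, p=probs_rna))
            if not _seed_conflicts(seq[1:8], seeds):
                seeds.append(seq[1:8])
                records.append(MiRNARecord(mid, seq))
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw a non-cross-reactive miRNA seed")
    return records


def _mutated_consensus(pwm: PWM, n_mutations: int) -> str:
    """Consensus with ``n_mutations`` substitutions at lowest-info positions."""
    word = list(pwm.consensus)
    order = np.argsort(pwm.info, kind="stable")
    for pos in order[:n_mutations]:
        ranked = np.argsort(pwm.freqs[pos])[::-1]
        word[pos] = _BASES[ranked[1]]  # second-most-frequent base
    return "".join(word)


def _revcomp_dna(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


def _overlaps(start: int, end: int, spans) -> bool:
    return any(start < e and s < end for s, e in spans)


def _scrub_promoters(seqs: dict[str, list[str]], protected, pwm: PWM,
                     cutoff: float, rng, probs,
                     max_passes: int = 200) -> None:
    """Resample away chance windows scoring ≥ cutoff on either strand.

    Windows overlapping a planted span are left alone; every other
    offending window has its unprotected positions redrawn from the
    background distribution, repeated until a scan pass is clean.
    A resampled window re-offends with probability ≈ alpha, so the number
    of offenders shrinks geometrically.
    """
    from .pwm import _encode

    mats = [pwm, pwm.reverse_complement()]
    dirty = set(seqs)
    for _ in range(max_passes):
        if not dirty:
            return
        next_dirty = set()
        for gene in sorted(dirty):
            chars = seqs[gene]
            spans = protected.get(gene, [])
            codes = _encode("".join(chars))
            for mat in mats:
                mss, _ = _window_scores(mat, codes)
                for i in np.flatnonzero(mss >= cutoff):
                    i = int(i)
                    if _overlaps(i, i + len(mat), spans):
                        continue
                    for j in range(i, i + len(mat)):
                        if not _overlaps(j, j + 1, spans):
                            chars[j] = _BASES[int(rng.choice(4, p=probs))]
                    next_dirty.add(gene)
        dirty = next_dirty
    raise RuntimeError("promoter background could not be scrubbed of chance motifs")


def _scrub_utrs(seqs: dict[str, list[str]], protected,
                patterns: dict[str, list[str]], rng, probs,
                max_passes: int = 200) -> None:
    """Resample away chance seed-site occurrences for any simulated miRNA."""
    dirty = set(seqs)
    for _ in range(max_passes):
        if not dirty:
            return
        next_dirty = set()
        for gene in sorted(dirty):
            chars = seqs[gene]
            s = "".join(chars)
            spans = [sp for sp, _ in protected.get(gene, [])]
            for mid in sorted(patterns):
                for pat in patterns[mid]:
                    start = s.find(pat)
                    while start != -1:
                        end = start + len(pat)
                        free = [j for j in range(start, end)
                                if not _overlaps(j, j + 1, spans)]
                        # fully protected occurrences are planted sites
                        if free:
                            for j in free:
                                chars[j] = _BASES[int(rng.choice(4, p=probs))]
                            s = "".join(chars)
                            next_dirty.add(gene)
                        start = s.find(pat, start + 1)
        dirty = next_dirty
    raise RuntimeError("UTR background could not be scrubbed of chance seed sites")


def _verify_clean(study: "SyntheticStudy", mss_cutoff: float,
                  protected_prom, protected_utr) -> None:
    """Assert the only surviving sites are the planted ones."""
    hits, _ = scan_promoters(study.pwm, study.promoters, mss_cutoff,
                             study.config.css_cutoff)
    tss = {r.gene_id: r.tss_offset for r in study.promoters}
    L = len(study.pwm)
    for h in hits:
        abs_start = h.start + tss[h.gene_id]
        if not _overlaps(abs_start, abs_start + L,
                         protected_prom.get(h.gene_id, [])):
            raise RuntimeError(
                f"unplanted motif hit survived scrubbing: {h.gene_id} @ {h.start}")
    for utr in study.utrs:
        for mir in study.mirna_seqs:
            allowed = [sp for sp, owner in protected_utr.get(utr.gene_id, [])
                       if owner == mir.id]
            for site in predict_targets_moderate(mir, utr):
                if not _overlaps(site.start, site.end, allowed):
                    raise RuntimeError(
                        f"unplanted seed site survived scrubbing: "
                        f"{mir.id} in {utr.gene_id} @ {site.start}")


def generate_study(config: SimulationConfig, pwm: PWM | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study; deterministic for a fixed seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    pwm = pwm if pwm is not None else default_myc_max_pwm()
    L = len(pwm)

    genes = [f"Gene{i:04d}" for i in range(1, cfg.n_genes + 1)]
    mirna_ids = [f"miR-{i:03d}" for i in range(1, cfg.n_mirnas + 1)]
    r = cfg.n_replicates_per_group
    wt = [f"wt_{i+1}" for i in range(r)]
    kd = [f"kd_{i+1}" for i in range(r)]
    groups = {**{s: "wt" for s in wt}, **{s: "myc_kd" for s in kd}}
    design = GroupDesign(groups=groups, reference="wt", test="myc_kd")

    at = (1 - cfg.gc_background) / 2
    gc = cfg.gc_background / 2
    probs_dna = np.array([at, gc, gc, at])

    # --- gene partitions ---------------------------------------------------
    n_bg = round(cfg.frac_background_genes * cfg.n_genes)
    n_up = round(cfg.frac_de_genes_up * cfg.n_genes)
    n_down = round(cfg.frac_de_genes_down * cfg.n_genes)
    if n_bg + n_up + n_down > cfg.n_genes:
        raise ValueError("more background + DE genes requested than genes exist")
    perm = rng.permutation(cfg.n_genes)
    bg_genes = sorted(genes[i] for i in perm[:n_bg])
    up_genes = sorted(genes[i] for i in perm[n_bg:n_bg + n_up])
    down_genes = sorted(genes[i] for i in perm[n_bg + n_up:n_bg + n_up + n_down])
    de_genes = up_genes + down_genes
    directions = {**{g: "up" for g in up_genes}, **{g: "down" for g in down_genes}}

    n_arm = cfg.n_motif_genes + cfg.n_mirna_target_genes - cfg.n_overlap_genes
    if n_arm > len(de_genes):
        raise ValueError(
            f"arms need {n_arm} distinct DE genes but only {len(de_genes)} are planted")
    arm_pool = [de_genes[i] for i in rng.permutation(len(de_genes))[:n_arm]]
    overlap_genes = sorted(arm_pool[:cfg.n_overlap_genes])
    motif_only = arm_pool[cfg.n_overlap_genes:cfg.n_motif_genes]
    target_only = arm_pool[cfg.n_motif_genes:]
    motif_genes = sorted(overlap_genes + motif_only)
    target_genes = sorted(overlap_genes + target_only)

    # --- miRNA partitions --------------------------------------------------
    n_low = round(cfg.frac_low_expressed_mirnas * cfg.n_mirnas)
    n_mi_up = round(cfg.frac_de_mirnas_up * cfg.n_mirnas)
    n_mi_down = round(cfg.frac_de_mirnas_down * cfg.n_mirnas)
    if n_low + n_mi_up + n_mi_down > cfg.n_mirnas:
        raise ValueError("more low-expressed + DE miRNAs requested than miRNAs exist")
    mperm = rng.permutation(cfg.n_mirnas)
    low_mirnas = sorted(mirna_ids[i] for i in mperm[:n_low])
    mi_up = sorted(mirna_ids[i] for i in mperm[n_low:n_low + n_mi_up])
    mi_down = sorted(mirna_ids[i] for i in mperm[n_low + n_mi_up:
                                                 n_low + n_mi_up + n_mi_down])

    need_down = any(directions[g] == "up" for g in target_genes)
    need_up = any(directions[g] == "down" for g in target_genes)
    if (need_down and not mi_down) or (need_up and not mi_up):
        raise ValueError(
            "target genes require oppositely-directed DE miRNAs that were not planted")

    probs_rna = probs_dna  # same composition, U in place of T
    mirna_seqs = _draw_mirna_seqs(rng, mirna_ids, probs_rna)
    seq_by_id = {m.id: m for m in mirna_seqs}

    target_assignment = {}
    for g in target_genes:
        pool = mi_up if directions[g] == "down" else mi_down
        target_assignment[g] = pool[int(rng.integers(len(pool)))]

    # --- mRNA probe matrix -------------------------------------------------
    baselines = {}
    for g in genes:
        if g in bg_genes:
            baselines[g] = cfg.background_level + rng.uniform(-0.5, 0.5)
        else:
            baselines[g] = rng.uniform(cfg.baseline_low, cfg.baseline_high)
    n_multi = round(cfg.frac_multi_probe * cfg.n_genes)
    multi = set(genes[i] for i in rng.permutation(cfg.n_genes)[:n_multi])

    probe2gene, probe_rows, probe_ids = {}, [], []
    samples = wt + kd
    for g in genes:
        n_probes = 2 if g in multi else 1
        for k in range(1, n_probes + 1):
            pid = f"{g}_p{k}"
            probe2gene[pid] = g
            effect = np.zeros(len(samples))
            if g in directions:
                shift = cfg.mrna_effect_log2 if directions[g] == "up" else -cfg.mrna_effect_log2
                effect[len(wt):] = shift
            row = baselines[g] + effect + rng.normal(0, cfg.mrna_noise_sd,
                                                     len(samples))
            probe_ids.append(pid)
            probe_rows.append(row)
    mrna = ExpressionMatrix(
        pd.DataFrame(np.array(probe_rows), index=probe_ids, columns=samples),
        feature_kind="mrna_probe",
    )

    # --- miRNA CT matrix ---------------------------------------------------
    ct_rows = []
    for m in mirna_ids:
        if m in low_mirnas:
            base = rng.uniform(33.0, 37.0)
        else:
            base = rng.uniform(cfg.ct_baseline_low, cfg.ct_baseline_high)
        shift = np.zeros(len(samples))
        if m in mi_up:
            shift[len(wt):] = cfg.mirna_effect_dct
        elif m in mi_down:
            shift[len(wt):] = -cfg.mirna_effect_dct
        ct_rows.append(base + shift + rng.normal(0, cfg.ct_noise_sd, len(samples)))
    u6_row = rng.normal(cfg.u6_ct, cfg.u6_sd, len(samples))
    ct = np.minimum(np.vstack([ct_rows, u6_row]), 35.0)  # emit censored
    mirna_ct = CtMatrix(
        pd.DataFrame(ct, index=mirna_ids + ["U6"], columns=samples),
        control_id="U6", sample_groups=dict(groups),
    )

    # --- promoters with planted motifs ------------------------------------
    prom_len = cfg.promoter_len_upstream + cfg.first_exon_len
    planted_word = (_mutated_consensus(pwm, cfg.motif_mutations)
                    if cfg.motif_mutations else pwm.consensus)
    prom_chars = {g: _random_seq(rng, prom_len, probs_dna) for g in genes}
    protected_prom: dict[str, list[tuple[int, int]]] = {}
    motif_truth: dict[str, list[dict]] = {}
    for g in motif_genes:
        pos = int(rng.integers(0, prom_len - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        word = planted_word if strand == "+" else _revcomp_dna(planted_word)
        prom_chars[g][pos:pos + L] = list(word)
        protected_prom.setdefault(g, []).append((pos, pos + L))
        motif_truth.setdefault(g, []).append(
            {"start_rel_tss": pos - cfg.promoter_len_upstream, "strand": strand})

    bg_probs = background_probs(cfg.gc_background)
    mss_cutoff = calibrate_threshold(pwm, probs=bg_probs, alpha=cfg.scan_alpha,
                                     seed=int(rng.integers(2**31)))
    _scrub_promoters(prom_chars, protected_prom, pwm, mss_cutoff, rng, probs_dna)
    promoters = [PromoterRegion(g, "".join(prom_chars[g]),
                                cfg.promoter_len_upstream, prom_len)
                 for g in genes]

    # --- UTRs with planted seed sites --------------------------------------
    if cfg.utr_len < 8:
        raise ValueError("utr_len must be at least 8 to hold an 8mer site")
    utr_chars = {g: _random_seq(rng, cfg.utr_len, probs_dna) for g in genes}
    protected_utr: dict[str, list[tuple[tuple[int, int], str]]] = {}
    pair_truth = []
    for g in target_genes:
        mir = seq_by_id[target_assignment[g]]
        site = seed_site_patterns(mir.seed)["8mer"]
        pos = int(rng.integers(0, cfg.utr_len - 8 + 1))
        utr_chars[g][pos:pos + 8] = list(site)
        protected_utr.setdefault(g, []).append(((pos, pos + 8), mir.id))
        pair_truth.append({"mirna": mir.id, "gene": g, "utr_start": pos})
    patterns = {m.id: _moderate_patterns(m.seed) for m in mirna_seqs}
    _scrub_utrs(utr_chars, protected_utr, patterns, rng, probs_dna)
    utrs = [UTRRecord(g, "".join(utr_chars[g])) for g in genes]

    # --- gene sets ----------------------------------------------------------
    genesets = []
    size = min(cfg.geneset_size, cfg.n_genes)
    k_de = min(round(cfg.enriched_term_frac_de * size), len(de_genes))
    non_de = sorted(set(genes) - set(de_genes))
    planted_members = (
        [de_genes[i] for i in rng.permutation(len(de_genes))[:k_de]]
        + [non_de[i] for i in rng.permutation(len(non_de))[:size - k_de]]
    )
    genesets.append(GeneSetAnnotation(
        "GO:0000001", "planted enriched term", frozenset(planted_members)))
    for t in range(2, cfg.n_genesets + 1):
        members = [genes[i] for i in rng.permutation(cfg.n_genes)[:size]]
        genesets.append(GeneSetAnnotation(
            f"GO:{t:07d}", f"synthetic term {t}", frozenset(members)))

    truth = {
        "de_genes_up": up_genes,
        "de_genes_down": down_genes,
        "de_mirnas_up": mi_up,
        "de_mirnas_down": mi_down,
        "low_expressed_mirnas": low_mirnas,
        "background_genes": bg_genes,
        "motif_sites": motif_truth,
        "target_pairs": sorted(pair_truth, key=lambda d: (d["mirna"], d["gene"])),
        "motif_arm": motif_genes,
        "mirna_arm": target_genes,
        "overlap": overlap_genes,
        "enriched_term": "GO:0000001",
        "mss_cutoff": mss_cutoff,
    }

    study = SyntheticStudy(
        config=cfg, mrna_matrix=mrna, mirna_ct=mirna_ct,
        probe2gene=probe2gene, design=design, promoters=promoters,
        utrs=utrs, mirna_seqs=mirna_seqs, genesets=genesets, pwm=pwm,
        truth=truth,
    )
    if cfg.motif_mutations == 0:
        _verify_clean(study, mss_cutoff, protected_prom, protected_utr)
    return study


# --- persistence -----------------------------------------------------------

_FILES = {
    "mrna": "mrna_log2.tsv",
    "mirna_ct": "mirna_ct.tsv",
    "probe2gene": "probe2gene.tsv",
    "design": "design.tsv",
    "promoters": "promoters.fa",
    "utrs": "utrs.fa",
    "mirnas": "mirnas.fa",
    "genesets": "genesets.gmt",
    "pwm": "pwm.jaspar",
    "truth": "truth.json",
    "config": "config.yaml",
    "manifest": "study.yaml",
}


def write_study(study: SyntheticStudy, directory) -> dict[str, Path]:
    """Write the study as TSV/FASTA/GMT/JASPAR text plus a truth manifest."""
    from .pwm import write_jaspar

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {k: d / v for k, v in _FILES.items()}

    mio.write_matrix(study.mrna_matrix.values, paths["mrna"], index_name="probe")
    mio.write_matrix(study.mirna_ct.values, paths["mirna_ct"], index_name="mirna")
    mio.write_two_column(study.probe2gene, paths["probe2gene"],
                         columns=("probe", "gene"))
    mio.write_two_column(study.design.groups, paths["design"],
                         columns=("sample", "group"))
    mio.write_promoters(study.promoters, paths["promoters"])
    mio.write_utrs(study.utrs, paths["utrs"])
    mio.write_mirnas(study.mirna_seqs, paths["mirnas"])
    mio.write_gmt(study.genesets, paths["genesets"])
    write_jaspar([study.pwm], paths["pwm"])
    paths["truth"].write_text(json.dumps(study.truth, indent=2, sort_keys=True) + "\n")
    paths["config"].write_text(yaml.safe_dump(dataclasses.asdict(study.config),
                                              sort_keys=True))
    manifest = {
        "files": {k: v for k, v in _FILES.items() if k != "manifest"},
        "control_id": study.mirna_ct.control_id,
        "reference_group": study.design.reference,
        "test_group": study.design.test,
    }
    paths["manifest"].write_text(yaml.safe_dump(manifest, sort_keys=True))
    return paths


def read_study(directory) -> SyntheticStudy:
    """Reload a study written by :func:`write_study` (lossless round trip)."""
    from .pwm import read_pwms

    d = Path(directory)
    manifest = yaml.safe_load((d / _FILES["manifest"]).read_text())
    cfg = SimulationConfig(**yaml.safe_load((d / _FILES["config"]).read_text()))
    groups = mio.read_two_column(d / _FILES["design"])
    design = GroupDesign(groups=groups,
                         reference=manifest["reference_group"],
                         test=manifest["test_group"])
    mrna = ExpressionMatrix(mio.read_matrix(d / _FILES["mrna"], "probe"),
                            feature_kind="mrna_probe")
    mirna_ct = CtMatrix(mio.read_matrix(d / _FILES["mirna_ct"], "mirna"),
                        control_id=manifest["control_id"],
                        sample_groups=groups)
    return SyntheticStudy(
        config=cfg,
        mrna_matrix=mrna,
        mirna_ct=mirna_ct,
        probe2gene=mio.read_two_column(d / _FILES["probe2gene"]),
        design=design,
        promoters=mio.read_promoters(d / _FILES["promoters"]),
        utrs=mio.read_utrs(d / _FILES["utrs"]),
        mirna_seqs=mio.read_mirnas(d / _FILES["mirnas"]),
        genesets=mio.read_gmt(d / _FILES["genesets"]),
        pwm=read_pwms(d / _FILES["pwm"])[0],
        truth=json.loads((d / _FILES["truth"]).read_text()),
    )
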