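"""Two-arm regulatory network assembly.

The transcriptional arm collects significant genes whose promoters carry at
least one Myc/Max motif hit; the post-transcriptional arm collects the
unique genes of the anticorrelated (miRNA, gene) pair set. Their overlap
is the candidate set regulated through both mechanisms. Edges keep their
evidence (motif coordinates, seed-site positions) so the two-mechanism
topology can be reconstructed from the export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .pwm import MotifHit
from .targets import Pair, PairSet


@dataclass
class RegulatoryNetwork:
    motif_arm: dict[str, list[MotifHit]] = field(default_factory=dict)
    mirna_arm: dict[str, list[Pair]] = field(default_factory=dict)
    overlap: set[str] = field(default_factory=set)
    gene_directions: dict[str, str] = field(default_factory=dict)
    mirna_directions: dict[str, str] = field(default_factory=dict)

    @property
    def summary(self) -> dict:
        n_motif = len(self.motif_arm)
        n_mirna = len(self.mirna_arm)
        n_overlap = len(self.overlap)
        return {
            "motif_arm_size": n_motif,
            "mirna_arm_size": n_mirna,
            "overlap_size": n_overlap,
            "overlap_fraction_of_motif_arm":
                (n_overlap / n_motif) if n_motif else None,
            "overlap_fraction_of_mirna_arm":
                (n_overlap / n_mirna) if n_mirna else None,
        }


def assemble_network(sig_genes: dict[str, str], motif_hits: list[MotifHit],
                     pair_set: PairSet,
                     mirna_directions: dict[str, str] | None = None
                     ) -> RegulatoryNetwork:
    """Build the two-arm network from one study's upstream results.

    ``sig_genes`` maps significant genes to their direction. Genes in the
    motif-hit table or pair set that are not significant are ignored; if
    NO identifier from either evidence source is a significant gene, the
    inputs are presumed mismatched and assembly fails.
    """
    evidence_genes = {h.gene_id for h in motif_hits} | {
        p.gene_id for p in pair_set.pairs}
    if evidence_genes and not (evidence_genes & set(sig_genes)):
        raise ValueError(
            "no motif-hit or miRNA-target gene is a significant gene; "
            "input identifier namespaces do not intersect"
        )

    net = RegulatoryNetwork(gene_directions=dict(sig_genes))
    for h in motif_hits:
        if h.gene_id in sig_genes:
            net.motif_arm.setdefault(h.gene_id, []).append(h)
    for p in pair_set.pairs:
        if p.gene_id in sig_genes:
            net.mirna_arm.setdefault(p.gene_id, []).append(p)
            net.mirna_directions[p.mirna_id] = p.mirna_direction
    if mirna_directions:
        net.mirna_directions.update(mirna_directions)
    net.overlap = set(net.motif_arm) & set(net.mirna_arm)
    return net


def export_network(net: RegulatoryNetwork, directory,
                   basename: str = "network") -> dict[str, Path]:
    """Write a TSV edge list and a JSON summary; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    edge_path = directory / f"{basename}_edges.tsv"
    rows = ["regulator\ttype\ttarget\ttarget_direction\tevidence"]
    for gene in sorted(net.motif_arm):
        for h in net.motif_arm[gene]:
            ev = f"{h.pwm_id}@{h.start}{h.strand};mss={h.matrix_score:.4f}"
            rows.append(f"{h.pwm_id}\tmyc_motif\t{gene}\t"
                        f"{net.gene_directions.get(gene, 'NA')}\t{ev}")
    for gene in sorted(net.mirna_arm):
        for p in net.mirna_arm[gene]:
            ev = ",".join(f"{s.start}-{s.end}:{s.site_type}" for s in p.sites)
            rows.append(f"{p.mirna_id}\tmirna\t{gene}\t"
                        f"{p.gene_direction}\t{ev}")
    edge_path.write_text("\n".join(rows) + "\n")

    json_path = directory / f"{basename}.json"
    payload = {
        "summary": net.summary,
        "motif_arm": sorted(net.motif_arm),
        "mirna_arm": sorted(net.mirna_arm),
        "overlap": sorted(net.overlap),
        "gene_directions": dict(sorted(net.gene_directions.items())),
        "mirna_directions": dict(sorted(net.mirna_directions.items())),
    }
    json_path.write_text(json.dumps(payload, indent=2) + "\n")
    return {"edges": edge_path, "json": json_path}


def load_network_summary(path) -> dict:
    """Reload the JSON export (summary, arms, overlap)."""
    return json.loads(Path(path).read_text())
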