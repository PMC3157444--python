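"""Two-group differential filtering of expression matrices.

Implements the microarray-style analysis used on both the log2 mRNA matrix
and the miRNA ΔCT matrix: background elimination, per-feature two-group
ANOVA (equivalent, with two groups, to the equal-variance t-test with
F = t²), fold-change/p-value thresholding, and probe→gene collapsing.

For ΔCT input the fold-change sign is inverted, because a greater ΔCT
means lower expression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Feature × sample matrix: log2 intensities for mRNA probes, ΔCT for miRNAs."""

    values: pd.DataFrame
    feature_kind: str = "mrna_probe"  # {"mrna_probe", "mirna"}

    def __post_init__(self) -> None:
        if self.feature_kind not in {"mrna_probe", "mirna"}:
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("expression matrix contains non-finite values")


@dataclass
class GroupDesign:
    """Sample → group labeling with exactly two groups.

    ``reference`` is the baseline (wild type); ``test`` is the perturbed
    group (c-Myc knockdown). Directions are reported for test vs reference.
    """

    groups: dict[str, str]
    reference: str
    test: str

    def __post_init__(self) -> None:
        labels = set(self.groups.values())
        if labels != {self.reference, self.test}:
            raise ValueError(
                f"design labels {sorted(labels)} must be exactly "
                f"{{{self.reference!r}, {self.test!r}}}"
            )

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]


@dataclass
class DifferentialResult:
    feature: str
    log2fc: float          # signed, on the expression scale (test vs reference)
    fold_change: float     # linear-scale magnitude, ≥ 1
    direction: str         # {"up", "down", "none"}, for the test group
    p_value: float
    passes: bool = False


@dataclass
class SignificantSet:
    """Direction-partitioned significant features plus their full records."""

    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)
    results: list[DifferentialResult] = field(default_factory=list)

    @property
    def features(self) -> set[str]:
        return self.up | self.down


def background_filter(matrix: ExpressionMatrix,
                      threshold: float | None = None) -> ExpressionMatrix:
    """Drop features at or below background.

    A feature survives when its maximum value over samples strictly exceeds
    ``threshold`` (default: the 20th percentile of all matrix values).
    """
    if threshold is None:
        threshold = float(np.percentile(matrix.values.to_numpy(), 20))
    keep = matrix.values.max(axis=1) > threshold
    out = matrix.values.loc[keep]
    log.info("background filter (> %.3g): kept %d of %d features",
             threshold, len(out), len(matrix.values))
    return ExpressionMatrix(out, feature_kind=matrix.feature_kind)


def differential_test(matrix: ExpressionMatrix,
                      design: GroupDesign) -> list[DifferentialResult]:
    """Per-feature two-group ANOVA with geometric fold change.

    p comes from the equal-variance two-sample t-test (identical to the
    one-way two-group ANOVA; F = t²). For mRNA, log2FC = mean(test) −
    mean(reference); for miRNA ΔCT the sign is inverted. Degenerate
    features with zero variance in both groups get p = 1 when the means
    are equal and p = 0 otherwise.
    """
    ref_cols = design.samples(design.reference)
    test_cols = design.samples(design.test)
    if len(ref_cols) < 2 or len(test_cols) < 2:
        raise ValueError("each group needs at least 2 samples")
    missing = (set(ref_cols) | set(test_cols)) - set(matrix.values.columns)
    if missing:
        raise ValueError(f"design samples absent from matrix: {sorted(missing)}")

    ref = matrix.values[ref_cols].to_numpy(dtype=float)
    test = matrix.values[test_cols].to_numpy(dtype=float)
    with warnings.catch_warnings():
        # constant features trigger a precision warning; resolved below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(test, ref, axis=1, equal_var=True)

    diff = test.mean(axis=1) - ref.mean(axis=1)
    # zero pooled variance: ttest_ind yields nan; resolve by the means
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)

    if matrix.feature_kind == "mirna":
        log2fc = -diff  # greater ΔCT = lower expression
    else:
        log2fc = diff

    out = []
    for feat, lfc, pv in zip(matrix.values.index, log2fc, p):
        direction = "none" if lfc == 0 else ("up" if lfc > 0 else "down")
        out.append(DifferentialResult(
            feature=str(feat),
            log2fc=float(lfc),
            fold_change=float(2.0 ** abs(lfc)),
            direction=direction,
            p_value=float(pv),
        ))
    return out


def apply_thresholds(results: list[DifferentialResult],
                     fc_cutoff: float = 2.0,
                     p_cutoff: float = 0.05) -> SignificantSet:
    """Keep features with fold-change magnitude > fc_cutoff AND p < p_cutoff.

    Both inequalities are strict; a fold change of exactly the cutoff fails.
    """
    sig = SignificantSet()
    for r in results:
        r.passes = r.fold_change > fc_cutoff and r.p_value < p_cutoff
        if r.passes:
            sig.results.append(r)
            (sig.up if r.direction == "up" else sig.down).add(r.feature)
    return sig


@dataclass
class GeneCall:
    gene: str
    direction: str
    probes: tuple[str, ...]


@dataclass
class CollapsedGenes:
    """Unique significant genes after probe→gene collapsing.

    Genes whose significant probes disagree in direction are excluded from
    ``up``/``down`` and listed in ``discordant``; probes with no gene
    mapping are listed in ``unmapped``.
    """

    calls: list[GeneCall] = field(default_factory=list)
    discordant: list[str] = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)

    @property
    def up(self) -> set[str]:
        return {c.gene for c in self.calls if c.direction == "up"}

    @property
    def down(self) -> set[str]:
        return {c.gene for c in self.calls if c.direction == "down"}

    @property
    def genes(self) -> set[str]:
        return {c.gene for c in self.calls}

    def directions(self) -> dict[str, str]:
        return {c.gene: c.direction for c in self.calls}


def collapse_probes_to_genes(sig: SignificantSet,
                             probe2gene: dict[str, str]) -> CollapsedGenes:
    """Collapse significant probes to unique genes with a common direction."""
    by_gene: dict[str, list[DifferentialResult]] = {}
    out = CollapsedGenes()
    for r in sig.results:
        gene = probe2gene.get(r.feature)
        if gene is None:
            out.unmapped.append(r.feature)
            continue
        by_gene.setdefault(gene, []).append(r)

    for gene in sorted(by_gene):
        records = by_gene[gene]
        directions = {r.direction for r in records}
        if len(directions) > 1:
            out.discordant.append(gene)
            log.warning("gene %s has discordant probe directions; excluded", gene)
            continue
        out.calls.append(GeneCall(
            gene=gene,
            direction=directions.pop(),
            probes=tuple(sorted(r.feature for r in records)),
        ))
    return out


def results_to_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"feature": r.feature, "log2fc": r.log2fc,
             "fold_change": r.fold_change, "direction": r.direction,
             "p_value": r.p_value, "passes": r.passes}
            for r in results
        ]
    )
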