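"""miRNA seed-site prediction in 3′UTRs and anticorrelation pairing.

Two stringencies of canonical seed matching are provided. The stringent
mode reports exact Watson–Crick 8mer, 7mer-m8 and 7mer-A1 sites (the
TargetScan-style site types); the moderate mode additionally tolerates a
single G:U wobble pair inside the 7-nt seed match (miRBase/miRanda-style
sensitivity). Predicted targets are then intersected with the significant,
oppositely-regulated miRNA/gene sets: an upregulated miRNA is paired with
its downregulated predicted targets and vice versa.

Coordinates are 0-based half-open positions on the UTR (5′→3′, DNA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

RNA_ALPHABET = set("ACGU")
DNA_ALPHABET = set("ACGTN")

_RNA_TO_DNA_COMPLEMENT = {"A": "T", "U": "A", "G": "C", "C": "G"}
# Watson–Crick pairs, miRNA (RNA) base vs target (DNA) base
_WC = {("A", "T"), ("U", "A"), ("G", "C"), ("C", "G")}
# G:U wobble pairs on the same orientation
_WOBBLE = {("G", "T"), ("U", "G")}


@dataclass
class MiRNARecord:
    """A mature miRNA, 5′→3′ in the RNA alphabet. Seed = nucleotides 2–8."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("T", "U")
        if len(self.seq) < 8:
            raise ValueError(f"{self.id}: mature sequence shorter than 8 nt")
        if not set(self.seq) <= RNA_ALPHABET:
            raise ValueError(f"{self.id}: non-RNA characters in sequence")

    @property
    def seed(self) -> str:
        """Nucleotides 2–8 of the mature sequence (7 nt, 5′→3′)."""
        return self.seq[1:8]


@dataclass
class UTRRecord:
    """A 3′UTR, 5′→3′ in the DNA alphabet (N allowed, never matches)."""

    gene_id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not set(self.seq) <= DNA_ALPHABET:
            raise ValueError(f"{self.gene_id}: non-DNA characters in UTR")


@dataclass(frozen=True)
class TargetPrediction:
    mirna_id: str
    gene_id: str
    start: int
    end: int
    site_type: str  # {"8mer", "7mer-m8", "7mer-A1", "wobble-7mer"}
    mode: str       # {"stringent", "moderate"}


def reverse_complement_rna_to_dna(seq: str) -> str:
    """DNA reverse complement of an RNA sequence (the target-site pattern)."""
    return "".join(_RNA_TO_DNA_COMPLEMENT[b] for b in reversed(seq))


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def seed_site_patterns(seed: str) -> dict[str, str]:
    """Exact-match target patterns for a 7-nt seed (positions 2–8).

    8mer = reverse complement of the seed followed by A; 7mer-m8 = reverse
    complement of the seed; 7mer-A1 = reverse complement of seed positions
    2–7 followed by A.
    """
    rc = reverse_complement_rna_to_dna(seed)
    return {"8mer": rc + "A", "7mer-m8": rc, "7mer-A1": rc[1:] + "A"}


def wobble_site_patterns(seed: str) -> list[str]:
    """All 7-nt target patterns pairing the seed with exactly one G:U wobble.

    A miRNA G may face target T (instead of C) and a miRNA U may face
    target G (instead of A); one such substitution per site.
    """
    rc = reverse_complement_rna_to_dna(seed)
    patterns = []
    for i, mir_base in enumerate(seed):
        # seed position i pairs with pattern position 6 - i
        j = 6 - i
        if mir_base == "G":
            wob = "T"
        elif mir_base == "U":
            wob = "G"
        else:
            continue
        patterns.append(rc[:j] + wob + rc[j + 1:])
    return patterns


def predict_targets_stringent(mirna: MiRNARecord,
                              utr: UTRRecord) -> list[TargetPrediction]:
    """Exact Watson–Crick seed sites: 8mer, 7mer-m8 and 7mer-A1.

    Where an 8mer spans the same locus as its constituent 7mers, only the
    8mer is reported.
    """
    pats = seed_site_patterns(mirna.seed)
    sites8 = _find_all(utr.seq, pats["8mer"])
    occupied8 = set(sites8)

    out = [TargetPrediction(mirna.id, utr.gene_id, p, p + 8, "8mer", "stringent")
           for p in sites8]
    for p in _find_all(utr.seq, pats["7mer-m8"]):
        if p not in occupied8:
            out.append(TargetPrediction(mirna.id, utr.gene_id, p, p + 7,
                                        "7mer-m8", "stringent"))
    for p in _find_all(utr.seq, pats["7mer-A1"]):
        if p - 1 not in occupied8:  # same locus as an 8mer starting one base left
            out.append(TargetPrediction(mirna.id, utr.gene_id, p, p + 7,
                                        "7mer-A1", "stringent"))
    return sorted(out, key=lambda t: (t.start, t.site_type))


def _pairing_profile(seed: str, window: str) -> tuple[int, int]:
    """(#Watson–Crick, #wobble) pairs of a 7-nt window against the seed.

    The window is read 5′→3′ on the target; seed position i faces window
    position 6 − i. N never pairs.
    """
    wc = wob = 0
    for i, mir_base in enumerate(seed):
        pair = (mir_base, window[6 - i])
        if pair in _WC:
            wc += 1
        elif pair in _WOBBLE:
            wob += 1
    return wc, wob


def predict_targets_moderate(mirna: MiRNARecord,
                             utr: UTRRecord) -> list[TargetPrediction]:
    """Stringent sites plus 7-nt seed matches with exactly one G:U wobble."""
    strict = predict_targets_stringent(mirna, utr)
    out = [TargetPrediction(t.mirna_id, t.gene_id, t.start, t.end,
                            t.site_type, "moderate") for t in strict]
    seed = mirna.seed
    for p in range(len(utr.seq) - 6):
        wc, wob = _pairing_profile(seed, utr.seq[p:p + 7])
        if wob == 1 and wc == 6:
            out.append(TargetPrediction(mirna.id, utr.gene_id, p, p + 7,
                                        "wobble-7mer", "moderate"))
    return sorted(out, key=lambda t: (t.start, t.site_type))


def predict_all(mirnas: list[MiRNARecord], utrs: list[UTRRecord],
                mode: str = "stringent") -> list[TargetPrediction]:
    """Predictions for every (miRNA, UTR) combination at one stringency."""
    predict = {"stringent": predict_targets_stringent,
               "moderate": predict_targets_moderate}[mode]
    out: list[TargetPrediction] = []
    for m in mirnas:
        for u in utrs:
            out.extend(predict(m, u))
    return out


@dataclass(frozen=True)
class Pair:
    mirna_id: str
    gene_id: str
    mirna_direction: str
    gene_direction: str
    sites: tuple[TargetPrediction, ...]


@dataclass
class PairSet:
    """Anticorrelated significant (miRNA, gene) pairs with site evidence."""

    pairs: list[Pair] = field(default_factory=list)

    @property
    def unique_genes(self) -> set[str]:
        return {p.gene_id for p in self.pairs}

    def per_mirna_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.pairs:
            counts[p.mirna_id] = counts.get(p.mirna_id, 0) + 1
        return counts


def anticorrelated_pairs(mirnas_up: set[str], mirnas_down: set[str],
                         genes_up: set[str], genes_down: set[str],
                         predictions: list[TargetPrediction]) -> PairSet:
    """Intersect seed-site predictions with oppositely-directed DE sets.

    Keeps (m, g) when m is up and g is down, or m is down and g is up,
    and g is a predicted target of m. One pair per (miRNA, gene); all
    supporting sites are retained as evidence.
    """
    by_pair: dict[tuple[str, str], list[TargetPrediction]] = {}
    for t in predictions:
        by_pair.setdefault((t.mirna_id, t.gene_id), []).append(t)

    ps = PairSet()
    for (m, g) in sorted(by_pair):
        if m in mirnas_up and g in genes_down:
            mdir, gdir = "up", "down"
        elif m in mirnas_down and g in genes_up:
            mdir, gdir = "down", "up"
        else:
            continue
        sites = tuple(sorted(by_pair[(m, g)], key=lambda t: (t.start, t.site_type)))
        ps.pairs.append(Pair(m, g, mdir, gdir, sites))
    return ps
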