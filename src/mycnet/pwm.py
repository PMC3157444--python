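"""MATCH-style position-weight-matrix scanning of promoter regions.

A PWM here is a pseudocount-adjusted per-position base-frequency model with
an information vector I(i) = Σ_b f(i,b)·ln(4·f(i,b)) and a 5-position
"core" (the consecutive window of maximal summed information). Windows are
scored with the information-weighted matrix similarity score

    MSS = (Current − Min) / (Max − Min),
    Current = Σ_i I(i)·f(i, w_i),
    Min/Max = Σ_i I(i)·min_b/max_b f(i,b),

and the core similarity score (CSS), the same ratio restricted to the core
positions. Both lie in [0, 1]; the consensus word scores exactly 1. The
MSS cutoff is calibrated to an exceedance probability (p-value) under an
i.i.d. background model: exact enumeration of all 4^L words for short
matrices, seeded Monte-Carlo otherwise.

Promoter regions span up to 2 kb upstream of the TSS through the first
exon; hits are reported on both strands with 0-based half-open starts
relative to the TSS (negative = upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

BASES = "ACGT"
CORE_LEN = 5


@dataclass
class PWM:
    """Frequency matrix over ACGT with MATCH-style derived quantities."""

    id: str
    freqs: np.ndarray               # (L, 4), rows sum to 1
    counts: np.ndarray | None = None
    info: np.ndarray = field(init=False)        # (L,)
    core_start: int = field(default=-1)         # -1 → compute from info
    min_contrib: np.ndarray = field(init=False)
    max_contrib: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4:
            raise ValueError("frequency matrix must be (L, 4)")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("frequency columns must sum to 1")
        self.freqs = f
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(f > 0, f * np.log(4.0 * f), 0.0)
        self.info = terms.sum(axis=1)
        self.min_contrib = self.info * f.min(axis=1)
        self.max_contrib = self.info * f.max(axis=1)
        if self.core_start < 0:
            self.core_start = self._best_core_start()

    def _best_core_start(self) -> int:
        k = min(CORE_LEN, len(self))
        sums = [self.info[i:i + k].sum() for i in range(len(self) - k + 1)]
        return int(np.argmax(sums))  # leftmost on ties

    def __len__(self) -> int:
        return self.freqs.shape[0]

    @property
    def core_positions(self) -> np.ndarray:
        k = min(CORE_LEN, len(self))
        return np.arange(self.core_start, self.core_start + k)

    @property
    def consensus(self) -> str:
        return "".join(BASES[b] for b in self.freqs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        """Mirror-image PWM scoring the opposite strand; core mirrored."""
        k = min(CORE_LEN, len(self))
        return PWM(
            id=self.id,
            freqs=self.freqs[::-1, ::-1].copy(),
            counts=None if self.counts is None else self.counts[::-1, ::-1].copy(),
            core_start=len(self) - self.core_start - k,
        )


def build_pwm(count_matrix, id: str = "pwm",
              pseudocount: float = 0.25) -> PWM:
    """PWM from a (L, 4) nonnegative count matrix.

    ``pseudocount`` is added per base before normalizing. With a zero
    pseudocount every position must carry at least one observation.
    """
    counts = np.asarray(count_matrix, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("count matrix must be (L, 4)")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=1) + 4 * pseudocount
    if np.any(totals == 0):
        raise ValueError("all-zero count column requires a pseudocount")
    freqs = (counts + pseudocount) / totals[:, None]
    return PWM(id=id, freqs=freqs, counts=counts)


def _encode(seq: str) -> np.ndarray:
    """ACGT → 0..3; anything else (N) → 4."""
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(BASES):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _similarity(pwm: PWM, codes: np.ndarray, positions: np.ndarray) -> float:
    contrib = pwm.info[:, None] * pwm.freqs  # (L, 4)
    cur = 0.0
    for i in positions:
        c = codes[i]
        cur += pwm.min_contrib[i] if c == 4 else contrib[i, c]
    lo = pwm.min_contrib[positions].sum()
    hi = pwm.max_contrib[positions].sum()
    if hi == lo:  # fully uninformative over these positions
        return 1.0
    return float((cur - lo) / (hi - lo))


def matrix_similarity(pwm: PWM, word: str) -> float:
    """Information-weighted similarity of a length-L word, in [0, 1]."""
    if len(word) != len(pwm):
        raise ValueError(f"word length {len(word)} != matrix length {len(pwm)}")
    return _similarity(pwm, _encode(word), np.arange(len(pwm)))


def core_similarity(pwm: PWM, word: str) -> float:
    """Matrix similarity restricted to the 5 core positions."""
    if len(word) != len(pwm):
        raise ValueError(f"word length {len(word)} != matrix length {len(pwm)}")
    return _similarity(pwm, _encode(word), pwm.core_positions)


def background_probs(gc: float | None = None,
                     composition=None) -> np.ndarray:
    """i.i.d. background base probabilities (A, C, G, T)."""
    if composition is not None:
        p = np.asarray(composition, dtype=float)
        if p.shape != (4,) or not np.isclose(p.sum(), 1.0):
            raise ValueError("composition must be 4 probabilities summing to 1")
        return p
    gc = 0.5 if gc is None else float(gc)
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


EXACT_ENUMERATION_MAX_LEN = 8


def _score_distribution_exact(pwm: PWM, probs: np.ndarray):
    """MSS value and probability of every word, by full 4^L enumeration."""
    L = len(pwm)
    words = (np.arange(4 ** L)[:, None] // (4 ** np.arange(L - 1, -1, -1))) % 4
    contrib = pwm.info[:, None] * pwm.freqs
    cur = contrib[np.arange(L), words].sum(axis=1)
    lo, hi = pwm.min_contrib.sum(), pwm.max_contrib.sum()
    scores = (cur - lo) / (hi - lo) if hi > lo else np.ones(len(words))
    weights = probs[words].prod(axis=1)
    return scores, weights


def calibrate_threshold(pwm: PWM, probs=None, alpha: float = 0.01,
                        n_samples: int = 100_000, seed: int | None = None,
                        method: str = "auto") -> float:
    """MSS cutoff with exceedance probability ≤ alpha under i.i.d. background.

    Exact enumeration over all 4^L words when L ≤ 8 (or ``method="exact"``),
    otherwise seeded Monte-Carlo over ``n_samples`` background words.
    alpha = 1 degenerately admits every word (cutoff 0).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if alpha == 1.0:
        return 0.0
    probs = background_probs() if probs is None else np.asarray(probs, float)

    if method == "auto":
        method = "exact" if len(pwm) <= EXACT_ENUMERATION_MAX_LEN else "monte_carlo"
    if method == "exact":
        scores, weights = _score_distribution_exact(pwm, probs)
        uniq, inv = np.unique(scores, return_inverse=True)
        mass = np.bincount(inv, weights=weights)
        exceed = np.cumsum(mass[::-1])[::-1]  # P(MSS ≥ uniq[k])
        ok = exceed <= alpha + 1e-12
        if not ok.any():
            return float(uniq[-1])
        # smallest distinct score whose exceedance stays within alpha
        return float(uniq[np.flatnonzero(ok)[0]])
    if method == "monte_carlo":
        if n_samples * alpha < 10:
            raise ValueError(
                f"n_samples={n_samples} too small for alpha={alpha}; "
                f"need at least {int(np.ceil(10 / alpha))} samples"
            )
        rng = np.random.default_rng(seed)
        words = rng.choice(4, size=(n_samples, len(pwm)), p=probs)
        contrib = pwm.info[:, None] * pwm.freqs
        cur = contrib[np.arange(len(pwm)), words].sum(axis=1)
        lo, hi = pwm.min_contrib.sum(), pwm.max_contrib.sum()
        scores = (cur - lo) / (hi - lo) if hi > lo else np.ones(n_samples)
        return float(np.quantile(scores, 1 - alpha, method="higher"))
    raise ValueError(f"unknown method {method!r}")


def score_pvalue(pwm: PWM, score: float, probs=None) -> float:
    """Exceedance probability P(MSS ≥ score) for an L ≤ 8 matrix (exact)."""
    if len(pwm) > EXACT_ENUMERATION_MAX_LEN:
        raise ValueError("exact p-values limited to matrices of length ≤ 8")
    probs = background_probs() if probs is None else np.asarray(probs, float)
    scores, weights = _score_distribution_exact(pwm, probs)
    return float(weights[scores >= score - 1e-12].sum())


@dataclass
class PromoterRegion:
    """Sense-strand promoter sequence with TSS and first-exon-end offsets.

    ``tss_offset`` indexes the TSS within ``seq`` (≤ 2000, the upstream
    span); ``exon_end`` is one past the first exon. Scanning covers the
    whole [0, exon_end) span on both strands.
    """

    gene_id: str
    seq: str
    tss_offset: int
    exon_end: int

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not 0 <= self.tss_offset < self.exon_end <= len(self.seq):
            raise ValueError(
                f"{self.gene_id}: need 0 ≤ tss_offset < exon_end ≤ length"
            )
        if self.tss_offset > 2000:
            raise ValueError(f"{self.gene_id}: upstream span exceeds 2000 bases")


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    pwm_id: str
    start: int           # relative to TSS, 0-based half-open; negative = upstream
    strand: str          # {"+", "-"}
    core_score: float
    matrix_score: float
    p_value: float | None = None


def _window_scores(pwm: PWM, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(MSS, CSS) for every window start of an encoded sequence."""
    L = len(codes)
    W = len(pwm)
    n = L - W + 1
    if n <= 0:
        return np.empty(0), np.empty(0)
    contrib = pwm.info[:, None] * pwm.freqs           # (W, 4)
    table = np.column_stack([contrib, pwm.min_contrib])  # N scores as min
    windows = np.lib.stride_tricks.sliding_window_view(codes, W)[:n]
    per_pos = table[np.arange(W)[None, :], windows]   # (n, W)

    def norm(positions):
        lo = pwm.min_contrib[positions].sum()
        hi = pwm.max_contrib[positions].sum()
        cur = per_pos[:, positions].sum(axis=1)
        return (cur - lo) / (hi - lo) if hi > lo else np.ones(n)

    return norm(np.arange(W)), norm(pwm.core_positions)


def scan_region(pwm: PWM, region: PromoterRegion, mss_cutoff: float,
                css_cutoff: float = 0.75,
                pvalue_probs=None) -> list[MotifHit]:
    """All windows on both strands scoring ≥ both cutoffs.

    Hit starts are the leftmost sense-strand coordinate relative to the
    TSS. A region shorter than the matrix yields no hits.
    """
    if not (0 <= mss_cutoff <= 1 and 0 <= css_cutoff <= 1):
        raise ValueError("cutoffs must lie in [0, 1]")
    codes = _encode(region.seq[: region.exon_end])
    hits: list[MotifHit] = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        mss, css = _window_scores(mat, codes)
        for i in np.flatnonzero((mss >= mss_cutoff) & (css >= css_cutoff)):
            p = (score_pvalue(pwm, float(mss[i]), pvalue_probs)
                 if pvalue_probs is not None and len(pwm) <= EXACT_ENUMERATION_MAX_LEN
                 else None)
            hits.append(MotifHit(
                gene_id=region.gene_id, pwm_id=pwm.id,
                start=int(i) - region.tss_offset, strand=strand,
                core_score=float(css[i]), matrix_score=float(mss[i]),
                p_value=p,
            ))
    return sorted(hits, key=lambda h: (h.start, h.strand))


@dataclass
class ScanSummary:
    n_sites: int
    n_genes_with_site: int
    genes_with_site: list[str]


def scan_promoters(pwm: PWM, regions: list[PromoterRegion], mss_cutoff: float,
                   css_cutoff: float = 0.75,
                   pvalue_probs=None) -> tuple[list[MotifHit], ScanSummary]:
    """Scan a promoter set; returns concatenated hits plus count summary."""
    ids = [r.gene_id for r in regions]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate promoter gene ids: {dupes}")
    hits: list[MotifHit] = []
    for r in regions:
        hits.extend(scan_region(pwm, r, mss_cutoff, css_cutoff, pvalue_probs))
    genes = sorted({h.gene_id for h in hits})
    return hits, ScanSummary(len(hits), len(genes), genes)


def read_pwms(path, fmt: str | None = None,
              pseudocount: float = 0.25) -> list[PWM]:
    """Read PWMs from TRANSFAC flat or JASPAR text files (via Bio.motifs)."""
    from Bio import motifs as bio_motifs

    if fmt is None:
        with open(path) as fh:
            head = fh.read(2048)
        fmt = "jaspar" if head.lstrip().startswith(">") else "transfac"
    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, fmt):
            counts = np.column_stack([np.asarray(m.counts[b], float)
                                      for b in BASES])
            name = (getattr(m, "matrix_id", None)
                    or (m.get("ID") if hasattr(m, "get") else None)
                    or m.name or "pwm")
            out.append(build_pwm(counts, id=str(name), pseudocount=pseudocount))
    return out


def write_jaspar(pwms: list[PWM], path) -> None:
    """Write count matrices in JASPAR text format (integer-rounded counts)."""
    with open(path, "w") as fh:
        for p in pwms:
            counts = p.counts if p.counts is not None else p.freqs * 100
            fh.write(f">{p.id}\n")
            for b, row in zip(BASES, counts.T):
                cells = " ".join(str(int(round(v))) for v in row)
                fh.write(f"{b} [ {cells} ]\n")


def hits_to_bed(hits: list[MotifHit], pwm_len: int) -> str:
    """BED6 text: chrom = gene id, TSS-relative starts, scores scaled 0–1000."""
    lines = []
    for h in hits:
        lines.append("\t".join([
            h.gene_id, str(h.start), str(h.start + pwm_len), h.pwm_id,
            str(int(round(h.matrix_score * 1000))), h.strand,
        ]))
    return "\n".join(lines) + ("\n" if lines else "")
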