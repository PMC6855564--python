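"""PWM motif scanning with exact p-values and per-LM enrichment z-scores.

Scanning follows the FIMO recipe: a position probability matrix is turned
into a log2-odds score matrix against a genome-wide mononucleotide
background, scores are discretized, and the exact null distribution of the
site score under the background model is computed by positional convolution
(dynamic programming), giving an exact p-value for every attainable score.
Both strands of every region in a linked metacluster (LM) are scanned; the
candidate-site p-values are Benjamini-Hochberg corrected within that
(motif, LM) pair and sites passing the q-value threshold become hits.

Enrichment per transcription-factor motif: the fraction of regions in each
LM carrying at least one passing hit is compared across LMs with a
one-tailed z-score against the baseline (the mean fraction across all LMs
for that motif); LMs with p < alpha are reported as enriched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .io_formats import PWM, GenomicInterval
from .linker import LinkedMetaclusters

logger = logging.getLogger(__name__)

__all__ = [
    "MotifHit",
    "EnrichmentResult",
    "ScorePValueTable",
    "genome_background",
    "fetch_sequence",
    "pwm_logodds",
    "score_pvalue_distribution",
    "scan_sequences",
    "scan_regions",
    "scan_lms",
    "bh_qvalues",
    "enrichment_zscores",
]

DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_GRANULARITY = 1000
DEFAULT_Q_THRESHOLD = 0.05

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_NEG = -(2 ** 40)  # sentinel for unscorable (N) positions; safe from overflow


@dataclass
class MotifHit:
    motif_id: str
    region_id: str
    offset: int          # 0-based forward-strand start within the region
    strand: str          # "+" or "-"
    score: float         # log2-odds
    p: float
    q: float = np.nan
    lm: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p out of [0,1]")


@dataclass
class EnrichmentResult:
    motif_id: str
    lm_id: tuple[int, int]
    fraction: float      # regions with >=1 passing hit / regions in LM
    baseline: float      # mean fraction across analyzed LMs
    z: float
    p: float
    enriched: bool


# ---------------------------------------------------------------------------
# genome access and background
# ---------------------------------------------------------------------------

def _contig(genome, chrom: str) -> str:
    """Uppercase sequence of one contig from a dict or pyfaidx.Fasta."""
    seq = genome[chrom]
    return str(seq if isinstance(seq, str) else seq[:]).upper()


def genome_background(genome, chroms: list[str] | None = None) -> np.ndarray:
    """Genome-wide mononucleotide frequencies over (A,C,G,T); N excluded."""
    counts = np.zeros(4)
    keys = chroms if chroms is not None else list(genome.keys())
    for chrom in keys:
        seq = np.frombuffer(_contig(genome, chrom).encode(), dtype=np.uint8)
        for b, code in zip(b"ACGT", range(4)):
            counts[code] += int((seq == b).sum())
    if counts.sum() == 0:
        raise ValueError("genome contains no A/C/G/T bases")
    return counts / counts.sum()


def fetch_sequence(genome, region: GenomicInterval) -> str:
    seq = _contig(genome, region.chrom)
    if region.end > len(seq):
        raise ValueError(
            f"region {region.id} extends past end of {region.chrom} "
            f"({region.end} > {len(seq)})"
        )
    return seq[region.start:region.end]


def encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N) -> 4."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.int64)
    for b, code in zip(b"ACGT", range(4)):
        out[arr == b] = code
    return out


# ---------------------------------------------------------------------------
# log-odds and exact p-values
# ---------------------------------------------------------------------------

def pwm_logodds(pwm: PWM, background: np.ndarray,
                pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """s[i][b] = log2((p[i][b] + pseudocount*bg[b]) / bg[b]).

    With pseudocount 0 a zero probability gives -inf.
    """
    bg = np.asarray(background, dtype=np.float64)
    if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1) > 1e-6:
        raise ValueError("background must be 4 positive frequencies summing to 1")
    with np.errstate(divide="ignore"):
        return np.log2((pwm.matrix + pseudocount * bg[None, :]) / bg[None, :])


@dataclass
class ScorePValueTable:
    """Exact discretized null distribution of the site score.

    ``int_scores[i][b]`` is the quantized per-position score (offset so the
    per-position minimum is 0); ``sf[s]`` is P(total quantized score >= s)
    under the background model.  Unscorable entries (-inf with zero
    pseudocount) carry the sentinel bin 0.
    """

    int_scores: np.ndarray  # (L, 4) int64
    sf: np.ndarray          # survival function over total quantized score
    bin_width: float
    offsets: np.ndarray     # per-position real offset subtracted before binning

    def site_pvalue(self, total_int_score: int) -> float:
        s = min(int(total_int_score), len(self.sf) - 1)
        return float(self.sf[max(s, 0)])


def _quantize(score_matrix: np.ndarray, granularity: int) -> tuple[np.ndarray, float, np.ndarray]:
    finite = np.where(np.isfinite(score_matrix), score_matrix, np.nan)
    mins = np.nanmin(finite, axis=1)
    maxs = np.nanmax(finite, axis=1)
    span = float(np.max(maxs - mins))
    width = span / (granularity - 1) if span > 0 else 1.0
    q = np.zeros_like(score_matrix, dtype=np.int64)
    for i in range(score_matrix.shape[0]):
        row = score_matrix[i]
        # -inf entries (zero probability, zero pseudocount) get a bin strictly
        # below every finite score at this position
        bump = 1 if np.any(~np.isfinite(row)) else 0
        qi = np.where(np.isfinite(row),
                      np.rint((row - mins[i]) / width) + bump, 0).astype(np.int64)
        q[i] = qi
    return q, width, mins


def score_pvalue_distribution(score_matrix: np.ndarray, background: np.ndarray,
                              granularity: int = DEFAULT_GRANULARITY) -> ScorePValueTable:
    """Exact score -> p-value table by positional convolution.

    Scores are discretized to at most ``granularity`` bins per position on a
    common bin width; the probability mass function of the total quantized
    score of a background-distributed L-mer is built by convolving one
    position at a time, and p(s) = P(score >= s) is its survival function.
    """
    score_matrix = np.asarray(score_matrix, dtype=np.float64)
    if score_matrix.ndim != 2 or score_matrix.shape[1] != 4 or score_matrix.shape[0] < 1:
        raise ValueError("score matrix must be (L>=1, 4)")
    bg = np.asarray(background, dtype=np.float64)
    q, width, offsets = _quantize(score_matrix, granularity)
    max_total = int(q.max(axis=1).sum())
    pmf = np.zeros(max_total + 1)
    pmf[0] = 1.0
    top = 0
    for i in range(q.shape[0]):
        new = np.zeros(max_total + 1)
        for b in range(4):
            s = int(q[i, b])
            new[s:top + s + 1] += bg[b] * pmf[:top + 1]
        pmf = new
        top += int(q[i].max())
    sf = np.cumsum(pmf[::-1])[::-1]
    sf = np.minimum(sf, 1.0)
    return ScorePValueTable(q, sf, width, offsets)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _site_scores(codes: np.ndarray, int_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quantized total score at each start position, and a validity mask
    (False where the window contains an unscorable base)."""
    L = int_scores.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    padded = np.hstack([int_scores, np.full((L, 1), _NEG, dtype=np.int64)])
    total = np.zeros(n, dtype=np.int64)
    for i in range(L):
        total += padded[i, codes[i:i + n]]
    return total, total > -(2 ** 39)


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=np.float64)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def scan_sequences(sequences: dict[str, str], pwm: PWM, background: np.ndarray,
                   q_threshold: float = DEFAULT_Q_THRESHOLD,
                   pseudocount: float = DEFAULT_PSEUDOCOUNT,
                   granularity: int = DEFAULT_GRANULARITY) -> list[MotifHit]:
    """Scan both strands of a set of sequences (one LM's regions) for one
    motif; BH-correct the candidate-site p-values over all scanned positions
    in the set and keep hits with q < q_threshold.

    Hits on opposite strands at the same forward offset deduplicate to the
    better-scoring one (ties to "+").  Lowercase (repeat-masked) sequence is
    scanned as uppercase; windows containing N are skipped.
    """
    fwd = pwm_logodds(pwm, background, pseudocount)
    rev = pwm.reverse_complement()
    revs = pwm_logodds(rev, background, pseudocount)
    table = score_pvalue_distribution(fwd, background, granularity)
    table_rev = score_pvalue_distribution(revs, background, granularity)

    candidates: list[tuple[str, int, str, float, float]] = []
    for region_id, seq in sequences.items():
        codes = encode(seq)
        for strand, mat, tab in (("+", fwd, table), ("-", revs, table_rev)):
            totals, valid = _site_scores(codes, tab.int_scores)
            for pos in np.where(valid)[0]:
                ti = int(totals[pos])
                p = tab.site_pvalue(ti)
                real = ti * tab.bin_width + tab.offsets.sum()
                candidates.append((region_id, int(pos), strand, real, p))
    if not candidates:
        return []
    q = bh_qvalues(np.array([c[4] for c in candidates]))
    hits: dict[tuple[str, int], MotifHit] = {}
    for (region_id, pos, strand, score, p), qv in zip(candidates, q):
        if qv >= q_threshold:
            continue
        key = (region_id, pos)
        prev = hits.get(key)
        if prev is None or p < prev.p or (p == prev.p and strand == "+" and prev.strand == "-"):
            hits[key] = MotifHit(pwm.motif_id, region_id, pos, strand,
                                 float(score), float(p), float(qv))
    return sorted(hits.values(), key=lambda h: (h.region_id, h.offset))


def scan_regions(regions: list[GenomicInterval], genome, pwms: list[PWM],
                 q_threshold: float = DEFAULT_Q_THRESHOLD,
                 background: np.ndarray | None = None,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT,
                 granularity: int = DEFAULT_GRANULARITY) -> list[MotifHit]:
    """Scan one LM's regions (by genomic coordinates) for every motif."""
    if background is None:
        background = genome_background(genome)
    sequences = {r.id: fetch_sequence(genome, r) for r in regions}
    hits: list[MotifHit] = []
    for pwm in pwms:
        hits.extend(scan_sequences(sequences, pwm, background,
                                   q_threshold, pseudocount, granularity))
    return hits


def scan_lms(lms: LinkedMetaclusters, regions_by_id: dict[str, GenomicInterval],
             genome, pwms: list[PWM],
             lm_ids: list[tuple[int, int]] | None = None,
             min_regions: int = 5,
             q_threshold: float = DEFAULT_Q_THRESHOLD,
             background: np.ndarray | None = None,
             pseudocount: float = DEFAULT_PSEUDOCOUNT,
             granularity: int = DEFAULT_GRANULARITY) -> list[MotifHit]:
    """Scan every LM (or a given subset) holding >= min_regions regions;
    each hit is tagged with its LM.  BH correction is per (motif, LM)."""
    if background is None:
        background = genome_background(genome)
    out: list[MotifHit] = []
    ids = lm_ids if lm_ids is not None else sorted(lms.cells)
    for lm in ids:
        region_ids = sorted(set(lms.regions_in(lm)))
        if len(region_ids) < min_regions:
            continue
        regs = [regions_by_id[r] for r in region_ids]
        for h in scan_regions(regs, genome, pwms, q_threshold,
                              background, pseudocount, granularity):
            h.lm = lm
            out.append(h)
    logger.info("scanned %d LMs, %d passing hits", len(ids), len(out))
    return out


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def enrichment_zscores(hits: list[MotifHit], lms: LinkedMetaclusters,
                       alpha: float = 0.05, min_regions: int = 5,
                       motif_ids: list[str] | None = None,
                       lm_ids: list[tuple[int, int]] | None = None) -> list[EnrichmentResult]:
    """One-tailed z-test of per-LM motif occupancy against the cross-LM mean.

    For each motif, f_i is the fraction of regions in LM i with at least one
    passing hit, over LMs holding >= min_regions regions (all such LMs by
    default; pass lm_ids to restrict the baseline population).  The baseline
    is the mean of f_i, z_i = (f_i - mean) / sample SD, p from the standard
    normal upper tail; an SD of zero leaves every LM non-enriched.
    """
    analyzed = [lm for lm in (lm_ids if lm_ids is not None else sorted(lms.cells))
                if len(set(lms.regions_in(lm))) >= min_regions]
    if motif_ids is None:
        motif_ids = sorted({h.motif_id for h in hits})
    hit_regions: dict[tuple[str, tuple[int, int]], set[str]] = {}
    for h in hits:
        if h.lm is not None:
            hit_regions.setdefault((h.motif_id, h.lm), set()).add(h.region_id)

    results: list[EnrichmentResult] = []
    for motif_id in motif_ids:
        fractions = np.array([
            len(hit_regions.get((motif_id, lm), set()))
            / len(set(lms.regions_in(lm)))
            for lm in analyzed
        ])
        if len(fractions) == 0:
            continue
        mu = float(fractions.mean())
        sd = float(fractions.std(ddof=1)) if len(fractions) > 1 else 0.0
        if sd <= 1e-12:  # degenerate spread, incl. float noise on equal f_i
            sd = 0.0
        for lm, f in zip(analyzed, fractions):
            if sd == 0.0:
                z, p, enr = np.nan, 1.0, False
            else:
                z = (f - mu) / sd
                p = float(norm.sf(z))
                enr = p < alpha
            results.append(EnrichmentResult(motif_id, lm, float(f), mu,
                                            float(z), float(p), bool(enr)))
    return results
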