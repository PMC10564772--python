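"""Promoter extraction, k-mer over-representation, motif assembly, null clusters.

The discovery chain is an oligo-analysis-style procedure: promoter windows
are extracted strand-aware around the TSS (offset 0 = first transcribed
base, negative = upstream, sequences always promoter-sense); fixed-length
words are counted (optionally collapsing a word with its reverse complement
onto the lexicographically smaller key); each word is scored against an
order-0 background with an upper-tail binomial p-value and BH q-values; and
the significant words are greedily assembled around the most significant
seed into a count matrix with a cased consensus (uppercase where the
plurality base reaches 75% of sites).

Significance of the best motif is empirical: the identical chain is re-run
on random promoter clusters of the same size drawn from the promoter
universe, and ``empirical_p = (1 + #null >= observed) / (1 + n_null)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta
from scipy.stats import binom

from .diffexpr import P_FLOOR, bh_adjust
from .expression_qc import ValidationError
from .synthetic_data import reverse_complement

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class SamplingError(ValueError):
    pass


class LookupError_(KeyError):
    pass


@dataclass(frozen=True)
class PromoterWindow:
    """TSS-relative window [start_offset, end_offset); 0 = first transcribed base."""

    start_offset: int
    end_offset: int

    def __post_init__(self) -> None:
        if self.start_offset >= self.end_offset:
            raise ValidationError("window start_offset must be < end_offset")

    @property
    def length(self) -> int:
        return self.end_offset - self.start_offset

    @property
    def label(self) -> str:
        def fmt(x: int) -> str:
            return f"+{x}" if x > 0 else str(x)

        return f"[{fmt(self.start_offset)},{fmt(self.end_offset)}]"

    @classmethod
    def parse(cls, text: str) -> "PromoterWindow":
        """Parse "-500,+200" or "[-500,+200]" style strings."""
        clean = text.strip().strip("[]")
        start, end = (int(x) for x in clean.split(","))
        return cls(start, end)


@dataclass
class PromoterSeq:
    gene_id: str
    seq: str
    clipped: bool = False


@dataclass
class MotifModel:
    """Position count matrix with cased consensus and located sites."""

    counts: np.ndarray  # 4 x width, rows A/C/G/T
    consensus: str
    n_sites: int
    sites: list[tuple[str, int, str]]  # (sequence id, 0-based offset, strand)
    seed_word: str
    score: float  # -log10 of the seed word's q-value
    empirical_p: float | None = None

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=0, keepdims=True)
        return self.counts / np.where(totals == 0, 1, totals)


# ---------------------------------------------------------------------------
# promoter extraction


class PromoterExtractor:
    """Strand-aware promoter window extraction from a GFF3 + FASTA pair."""

    def __init__(self, gff_path, fasta_path):
        import gffutils

        self.db = gffutils.create_db(
            str(gff_path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        self.fasta = Fasta(str(fasta_path))

    def gene_anchor(self, gene_id: str) -> tuple[str, int, str]:
        """(contig, 1-based TSS, strand) for a gene."""
        try:
            feat = self.db[gene_id]
        except Exception as exc:  # gffutils raises its own FeatureNotFound
            raise LookupError_(f"gene {gene_id!r} absent from gene models") from exc
        tss = feat.start if feat.strand == "+" else feat.end
        return feat.seqid, tss, feat.strand

    def extract(
        self, window: PromoterWindow, genes: Iterable[str]
    ) -> dict[str, PromoterSeq]:
        """Promoter-sense window sequences for each gene, clipped at contig edges.

        For a "+" gene with TSS at 1-based position t the window covers
        forward positions [t + start_offset, t + end_offset - 1]; for a "-"
        gene offset o maps to forward position t - o and the extracted slice
        is reverse-complemented, so the output always reads 5'->3' toward the
        gene.
        """
        out: dict[str, PromoterSeq] = {}
        for gene in genes:
            contig, tss, strand = self.gene_anchor(gene)
            contig_len = len(self.fasta[contig])
            if strand == "+":
                lo = tss + window.start_offset  # 1-based inclusive
                hi = tss + window.end_offset - 1
            else:
                lo = tss - window.end_offset + 1
                hi = tss - window.start_offset
            clipped_lo, clipped_hi = max(lo, 1), min(hi, contig_len)
            if clipped_lo > clipped_hi:
                logger.warning("window %s entirely off-contig for gene %s", window.label, gene)
                out[gene] = PromoterSeq(gene, "", clipped=True)
                continue
            seq = self.fasta[contig][clipped_lo - 1 : clipped_hi].seq.upper()
            if strand == "-":
                seq = reverse_complement(seq)
            out[gene] = PromoterSeq(gene, seq, clipped=(clipped_lo != lo or clipped_hi != hi))
        return out


def extract_promoters(gff_path, fasta_path, window: PromoterWindow, genes) -> dict[str, PromoterSeq]:
    return PromoterExtractor(gff_path, fasta_path).extract(window, genes)


# ---------------------------------------------------------------------------
# k-mer counting


def _seq_strings(sequences) -> list[tuple[str, str]]:
    """Normalise input to (id, sequence) pairs."""
    if isinstance(sequences, Mapping):
        return [(k, v.seq if isinstance(v, PromoterSeq) else v) for k, v in sequences.items()]
    out = []
    for i, s in enumerate(sequences):
        if isinstance(s, PromoterSeq):
            out.append((s.gene_id, s.seq))
        else:
            out.append((str(i), s))
    return out


def canonical_word(word: str) -> str:
    rc = reverse_complement(word)
    return min(word, rc)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def _word_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all valid (ACGT-only) k-windows of an encoded sequence."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = codes[j : j + n]
        valid &= col < 4
        vals = vals * 4 + col
    return vals[valid]


def _decode(code: int, k: int) -> str:
    chars = []
    for _ in range(k):
        chars.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(chars))


from functools import lru_cache


@lru_cache(maxsize=8)
def _rc_code_table(k: int) -> np.ndarray:
    """code -> code of the reverse complement, for all 4**k words."""
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - tmp % 4)
        tmp //= 4
    return rc


def _decode_many(codes: np.ndarray, k: int) -> list[str]:
    lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    digits = np.empty((codes.size, k), dtype=np.int64)
    tmp = codes.copy()
    for j in range(k - 1, -1, -1):
        digits[:, j] = tmp % 4
        tmp //= 4
    raw = lookup[digits].tobytes()
    return [raw[i * k : (i + 1) * k].decode() for i in range(codes.size)]


def count_kmers(sequences, k: int, both_strands: bool = False) -> dict[str, int]:
    """Overlapping k-mer counts summed over sequences.

    With ``both_strands`` the reverse strand of every sequence is scanned as
    well and a word and its reverse complement are collapsed onto the
    lexicographically smaller key. Windows containing non-ACGT symbols are
    skipped.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    total = np.zeros(4**k, dtype=np.int64)
    for _, seq in _seq_strings(sequences):
        codes = _encode(seq.upper())
        wc = _word_codes(codes, k)
        if wc.size:
            total += np.bincount(wc, minlength=4**k)
    if both_strands:
        # scanning every reverse strand is equivalent to adding each forward
        # word's reverse-complement count, then collapsing onto the
        # lexicographically smaller (= numerically smaller) code
        rc = _rc_code_table(k)
        # per-code count over both scanned strands, then fold each pair onto
        # its numerically (= lexicographically) smaller member
        paired = total + total[rc]
        canon = np.minimum(np.arange(4**k, dtype=np.int64), rc)
        collapsed = np.zeros(4**k, dtype=np.int64)
        nz = paired > 0
        np.add.at(collapsed, canon[nz], paired[nz])
        total = collapsed
    nz = np.nonzero(total)[0]
    words = _decode_many(nz, k)
    return {w: int(total[c]) for w, c in zip(words, nz)}


def n_scanned_positions(sequences, k: int, both_strands: bool = False) -> int:
    """Number of word slots scanned by :func:`count_kmers` (valid or not)."""
    per = [max(len(s) - k + 1, 0) for _, s in _seq_strings(sequences)]
    return sum(per) * (2 if both_strands else 1)


def background_frequencies(sequences, k: int, both_strands: bool = False) -> dict[str, float]:
    """Order-0 background: word frequencies over a promoter universe."""
    counts = count_kmers(sequences, k, both_strands)
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("cannot build a background from empty sequences")
    return {w: c / total for w, c in counts.items()}


# ---------------------------------------------------------------------------
# word scoring


def score_words(
    observed: Mapping[str, int],
    background: Mapping[str, float],
    n_positions: int,
) -> pd.DataFrame:
    """Upper-tail binomial enrichment of observed word counts vs background.

    ``expected = background_freq * n_positions``; ``p = P(X >= observed)``
    for X ~ Binomial(n_positions, background_freq). Words with zero
    background but nonzero observed count get the machine-floor p with a
    warning. BH q-values over all scored words.
    """
    words = sorted(observed)
    obs = np.array([int(observed[w]) for w in words], dtype=np.int64)
    freq = np.array([float(background.get(w, 0.0)) for w in words])
    zero_bg = (freq == 0.0) & (obs > 0)
    if zero_bg.any():
        logger.warning(
            "%d words observed but absent from background (p set to machine floor)",
            int(zero_bg.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        p = binom.sf(obs - 1, n_positions, np.where(freq > 0, freq, 0.5))
    p = np.where(zero_bg, P_FLOOR, p)
    p = np.where(obs == 0, 1.0, p)
    p = np.clip(p, P_FLOOR, 1.0)
    df = pd.DataFrame(
        {"word": words, "observed": obs, "expected": freq * n_positions, "p_value": p},
        columns=["word", "observed", "expected", "p_value"],
    )
    if len(df):
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
        df = df.sort_values(["p_value", "word"], kind="stable").reset_index(drop=True)
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df


# ---------------------------------------------------------------------------
# motif assembly


def _best_alignment(seed: str, word: str, both_strands: bool, max_shift: int = 2):
    """Best (offset, oriented_word) alignment of ``word`` against ``seed``.

    Candidates overlap the seed by >= len(seed) - max_shift positions; at
    most one mismatch is allowed in the overlap. Returns None if no
    candidate qualifies.
    """
    k = len(seed)
    forms = [word] + ([reverse_complement(word)] if both_strands else [])
    best = None
    for form in forms:
        for off in range(-max_shift, max_shift + 1):
            lo, hi = max(0, off), min(k, off + len(form))
            overlap = hi - lo
            if overlap < k - max_shift:
                continue
            matches = sum(1 for i in range(lo, hi) if seed[i] == form[i - off])
            mismatches = overlap - matches
            if mismatches > 1:
                continue
            key = (matches, -abs(off))
            if best is None or key > best[0]:
                best = (key, off, form)
    if best is None:
        return None
    return best[1], best[2]


def assemble_motif(
    significant: pd.DataFrame,
    sequences,
    both_strands: bool = False,
) -> MotifModel | None:
    """Greedy assembly of significant words around the top seed.

    The most significant word seeds the motif; remaining words are aligned
    to it (either strand, shift <= 2, <= 1 mismatch in the overlap) in
    significance order. Every occurrence of an aligned word in the scanned
    sequences contributes a full-width site to the count matrix (sites
    truncated by sequence ends are dropped), so column sums equal
    ``n_sites``. Returns None when no significant word is supplied.
    """
    if significant is None or len(significant) == 0:
        return None
    words = list(significant["word"])
    seed = words[0]
    k = len(seed)
    aligned: list[tuple[str, int]] = [(seed, 0)]
    for word in words[1:]:
        hit = _best_alignment(seed, word, both_strands)
        if hit is not None:
            off, form = hit
            aligned.append((form, off))
    min_off = min(off for _, off in aligned)
    max_end = max(off + len(form) for form, off in aligned)
    width = max_end - min_off

    pairs = _seq_strings(sequences)
    scan: list[tuple[str, str, str]] = [(sid, "+", s.upper()) for sid, s in pairs]
    if both_strands:
        scan += [(sid, "-", reverse_complement(s.upper())) for sid, s in pairs]

    windows: dict[tuple[str, str, int], str] = {}
    for form, off in aligned:
        for sid, strand, seq in scan:
            start = seq.find(form)
            while start != -1:
                wstart = start - (off - min_off)
                if 0 <= wstart and wstart + width <= len(seq):
                    site = seq[wstart : wstart + width]
                    if all(c in _BASE_INDEX for c in site):
                        windows.setdefault((sid, strand, wstart), site)
                start = seq.find(form, start + 1)

    if not windows:
        return None
    counts = np.zeros((4, width), dtype=int)
    sites = []
    for (sid, strand, wstart), site in sorted(windows.items()):
        for j, base in enumerate(site):
            counts[_BASE_INDEX[base], j] += 1
        sites.append((sid, wstart, strand))

    n_sites = len(sites)
    consensus = []
    for j in range(width):
        col = counts[:, j]
        idx = int(np.argmax(col))
        base = BASES[idx]
        consensus.append(base if col[idx] / n_sites >= 0.75 else base.lower())
    q_seed = float(significant.iloc[0]["q_value"]) if "q_value" in significant else float(
        significant.iloc[0]["p_value"]
    )
    score = float(-np.log10(max(q_seed, P_FLOOR)))
    return MotifModel(
        counts=counts,
        consensus="".join(consensus),
        n_sites=n_sites,
        sites=sites,
        seed_word=seed,
        score=score,
    )


def discover_motif(
    cluster,
    background: Mapping[str, float],
    k: int,
    alpha: float = 0.05,
    both_strands: bool = False,
) -> MotifModel | None:
    """count -> score -> assemble on one promoter cluster; None if no signal."""
    counts = count_kmers(cluster, k, both_strands)
    n_pos = n_scanned_positions(cluster, k, both_strands)
    if n_pos == 0:
        return None
    scores = score_words(counts, background, n_pos)
    significant = scores[scores["q_value"] < alpha]
    return assemble_motif(significant, cluster, both_strands)


def null_cluster_significance(
    observed_score: float,
    universe: Mapping[str, "PromoterSeq | str"],
    cluster_size: int,
    k: int,
    n_null: int = 50,
    seed: int = 0,
    background: Mapping[str, float] | None = None,
    alpha: float = 0.05,
    both_strands: bool = False,
) -> tuple[float, list[float]]:
    """Empirical motif significance against random same-size promoter clusters.

    Draws ``n_null`` clusters of ``cluster_size`` promoters (without
    replacement within a cluster) from the universe, runs the identical
    count -> score -> assemble chain on each, and returns

        empirical_p = (1 + #null clusters with best score >= observed)
                      / (1 + n_null)

    together with the null score list.
    """
    if n_null < 1:
        raise SamplingError("n_null must be >= 1")
    names = sorted(universe)
    if len(names) <= cluster_size:
        raise SamplingError("promoter universe must be larger than cluster_size")
    if background is None:
        background = background_frequencies(universe, k, both_strands)
    rng = np.random.default_rng(seed)
    null_scores: list[float] = []
    for _ in range(n_null):
        chosen = rng.choice(names, size=cluster_size, replace=False)
        cluster = {str(g): universe[str(g)] for g in chosen}
        motif = discover_motif(cluster, background, k, alpha, both_strands)
        null_scores.append(motif.score if motif is not None else 0.0)
    n_ge = sum(1 for s in null_scores if s >= observed_score)
    return (1 + n_ge) / (1 + n_null), null_scores


# ---------------------------------------------------------------------------
# comparison helpers and output formats


def _column_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def matrix_revcomp(freq: np.ndarray) -> np.ndarray:
    return freq[::-1, ::-1]


def motif_matrix_correlation(
    recovered: np.ndarray, reference: np.ndarray, min_overlap: int | None = None
) -> float:
    """Best mean per-column Pearson correlation over shifts and strands.

    Both inputs are 4 x width frequency (or count) matrices; the shorter one
    slides along the longer, requiring at least ``min_overlap`` overlapping
    columns (default: shorter width minus 2).
    """
    a = np.asarray(recovered, dtype=float)
    b = np.asarray(reference, dtype=float)
    if min_overlap is None:
        min_overlap = max(min(a.shape[1], b.shape[1]) - 2, 1)
    best = -1.0
    for bb in (b, matrix_revcomp(b)):
        for shift in range(-bb.shape[1] + 1, a.shape[1]):
            lo_a, hi_a = max(0, shift), min(a.shape[1], shift + bb.shape[1])
            if hi_a - lo_a < min_overlap:
                continue
            cols = [
                _column_pearson(a[:, j], bb[:, j - shift]) for j in range(lo_a, hi_a)
            ]
            best = max(best, float(np.mean(cols)))
    return best


def consensus_matrix(consensus: str) -> np.ndarray:
    """One-hot 4 x width frequency matrix for a consensus string."""
    m = np.zeros((4, len(consensus)))
    for j, base in enumerate(consensus.upper()):
        m[_BASE_INDEX[base], j] = 1.0
    return m


def write_meme(motif: MotifModel, path, name: str = "motif_1") -> None:
    """Minimal MEME text format for one motif."""
    freq = motif.frequencies
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        fh.write(f"MOTIF {name} {motif.consensus}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {motif.width} nsites= {motif.n_sites}\n"
        )
        for j in range(motif.width):
            fh.write(" ".join(f"{freq[i, j]:.6f}" for i in range(4)) + "\n")


def sites_frame(motif: MotifModel) -> pd.DataFrame:
    return pd.DataFrame(motif.sites, columns=["sequence_id", "offset", "strand"])
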