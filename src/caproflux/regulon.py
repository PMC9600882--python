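"""Consensus-seeded binding-site prediction for redox/lactate regulators.

An IUPAC degenerate consensus (e.g. the Clostridiaceae Rex operator
``TTGTTAANNNNTTAACAA`` or the LldR operator ``TGGTNNNACCA``) is expanded
into a position weight matrix: at each position the allowed bases share the
probability mass ``1 - (4 - k) * epsilon`` equally (k = number of allowed
bases) and each disallowed base receives ``epsilon``.  Scores are summed
base-2 log-odds against the background.

Candidate windows are accepted when their *relative* score — the raw score
min-max normalized over the matrix's achievable range — reaches the
threshold fraction.  Sites are reported with their offset relative to the
downstream gene's translation start (negative = upstream, the usual 5'-UTR
sign convention).  Palindromic consensi (both operators above are their own
reverse complements) are scanned on the plus strand only, so each physical
site is reported once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import Feature, MalformedAnnotationError, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "IUPAC",
    "MotifModel",
    "GenomicInterval",
    "SiteHit",
    "consensus_to_pwm",
    "hamming_to_consensus",
    "extract_intergenic",
    "scan_string",
    "scan_sequences",
    "site_report",
]

IUPAC: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_CODE_COMPLEMENT: Dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def _revcomp_consensus(consensus: str) -> str:
    return "".join(_CODE_COMPLEMENT[c] for c in reversed(consensus))


@dataclass
class MotifModel:
    """A consensus with its derived probability and log-odds matrices."""

    consensus: str
    epsilon: float
    background: np.ndarray  # shape (4,), order ACGT
    probs: np.ndarray  # shape (L, 4)
    pwm: np.ndarray  # shape (L, 4), base-2 log-odds

    @property
    def length(self) -> int:
        return len(self.consensus)

    @property
    def max_score(self) -> float:
        return float(self.pwm.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.pwm.min(axis=1).sum())

    @property
    def is_palindromic(self) -> bool:
        return _revcomp_consensus(self.consensus) == self.consensus

    def score(self, site: str) -> float:
        """Raw log-odds score (bits) of a motif-length ACGT string."""
        if len(site) != self.length:
            raise ValueError("site length does not match motif length")
        idx = [_BASE_INDEX[b] for b in site.upper()]
        return float(self.pwm[np.arange(self.length), idx].sum())

    def relative_score(self, score: float) -> float:
        rng = self.max_score - self.min_score
        if rng == 0:  # fully degenerate motif: every window is maximal
            return 1.0
        return (score - self.min_score) / rng

    def counts_matrix(self, scale: int = 100) -> np.ndarray:
        """Integer count matrix (L x 4) for external logo rendering."""
        return np.rint(self.probs * scale).astype(int)


def consensus_to_pwm(
    consensus: str,
    epsilon: float = 1e-4,
    background: Optional[Sequence[float]] = None,
) -> MotifModel:
    """Expand an IUPAC consensus into probability and log-odds matrices."""
    if not consensus:
        raise ValueError("empty consensus")
    consensus = consensus.upper()
    bad = [c for c in consensus if c not in IUPAC]
    if bad:
        raise ValueError(f"invalid IUPAC character(s) {bad} in consensus")
    if not (0 < epsilon < 0.25):
        raise ValueError("epsilon must lie in (0, 0.25)")
    bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
        raise ValueError("background must be 4 positive probabilities summing to 1")

    probs = np.empty((len(consensus), 4))
    for i, code in enumerate(consensus):
        allowed = IUPAC[code]
        k = len(allowed)
        p_allowed = (1.0 - (4 - k) * epsilon) / k
        for b in _BASES:
            probs[i, _BASE_INDEX[b]] = p_allowed if b in allowed else epsilon
    pwm = np.log2(probs / bg)
    return MotifModel(consensus, epsilon, bg, probs, pwm)


def hamming_to_consensus(site: str, consensus: str) -> int:
    """Mismatches between a site and an IUPAC consensus (N matches everything)."""
    if len(site) != len(consensus):
        raise ValueError("site and consensus lengths differ")
    return sum(
        1 for b, c in zip(site.upper(), consensus.upper()) if b not in IUPAC[c]
    )


@dataclass
class GenomicInterval:
    """An intergenic region with the gene(s) whose 5' region it forms."""

    seqid: str
    start: int
    end: int
    seq: str
    downstream_plus: Optional[str] = None  # gene starting at/after end, + strand
    downstream_plus_start: Optional[int] = None
    downstream_minus: Optional[str] = None  # gene ending at/before start, - strand
    downstream_minus_end: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SiteHit:
    seqid: str
    start: int  # absolute, 0-based
    end: int
    strand: str
    site: str  # oriented along the hit strand
    score: float  # raw log-odds, bits
    rel_score: float
    downstream_gene: Optional[str]
    offset: Optional[int]  # site start relative to translation start; negative = upstream


def extract_intergenic(
    features: Iterable[Feature],
    sequences: Mapping[str, str],
    min_length: int = 1,
) -> List[GenomicInterval]:
    """Maximal regions of each sequence not covered by any CDS.

    Each interval carries the identity of its downstream gene on each
    strand: the nearest following gene on + (whose 5' region the interval
    is) and the nearest preceding gene on - (idem, since - genes read
    leftward).  A genome without genes yields one interval per sequence.
    """
    feats = [f for f in features if f.type == "CDS"] or list(features)
    by_seq: Dict[str, List[Feature]] = {}
    for f in feats:
        if f.seqid not in sequences:
            raise MalformedAnnotationError(
                f"feature {f.gene_id!r} references unknown sequence {f.seqid!r}"
            )
        if f.end > len(sequences[f.seqid]) or f.start < 0:
            raise MalformedAnnotationError(
                f"feature {f.gene_id!r} out of range on {f.seqid!r}"
            )
        by_seq.setdefault(f.seqid, []).append(f)

    intervals: List[GenomicInterval] = []
    for seqid, seq in sequences.items():
        genes = sorted(by_seq.get(seqid, []), key=lambda f: (f.start, f.end))
        # merge covered spans
        merged: List[Tuple[int, int]] = []
        for f in genes:
            if merged and f.start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], f.end))
            else:
                merged.append((f.start, f.end))
        gaps: List[Tuple[int, int]] = []
        prev = 0
        for a, b in merged:
            if a > prev:
                gaps.append((prev, a))
            prev = max(prev, b)
        if prev < len(seq):
            gaps.append((prev, len(seq)))
        for a, b in gaps:
            if b - a < min_length:
                continue
            nxt = next((f for f in genes if f.start >= b and f.strand == "+"), None)
            prv = next(
                (f for f in reversed(genes) if f.end <= a and f.strand == "-"), None
            )
            intervals.append(
                GenomicInterval(
                    seqid=seqid,
                    start=a,
                    end=b,
                    seq=seq[a:b],
                    downstream_plus=nxt.gene_id if nxt else None,
                    downstream_plus_start=nxt.start if nxt else None,
                    downstream_minus=prv.gene_id if prv else None,
                    downstream_minus_end=prv.end if prv else None,
                )
            )
    return intervals


def _window_scores(motif: MotifModel, seq: str) -> np.ndarray:
    """Raw scores of all plus-strand windows; non-ACGT bases poison a window."""
    L = motif.length
    enc = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    idx = np.full(enc.shape, 4, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        idx[enc == ord(b)] = i
    pwm_ext = np.hstack([motif.pwm, np.full((L, 1), -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    return pwm_ext[np.arange(L), windows].sum(axis=1)


def scan_string(
    motif: MotifModel, seq: str, threshold: float = 0.7, both_strands: bool = True
) -> List[Tuple[int, str, float]]:
    """Scan one raw sequence; returns (start, strand, raw score) tuples.

    ``threshold`` is the fraction of the motif's achievable score range
    (min-max relative score).  For palindromic motifs only the plus strand
    is scanned, which deduplicates each physical site to one report.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold fraction must lie in (0, 1]")
    L = motif.length
    if len(seq) < L:
        return []
    # tiny slack keeps windows whose score ties the cutoff included no matter
    # the float summation order (scores are direction-dependent at the ULP level)
    cutoff = motif.min_score + threshold * (motif.max_score - motif.min_score) - 1e-9
    out: List[Tuple[int, str, float]] = []
    fwd = _window_scores(motif, seq)
    for pos in np.flatnonzero(fwd >= cutoff):
        out.append((int(pos), "+", float(fwd[pos])))
    if both_strands and not motif.is_palindromic:
        rev = _window_scores(motif, reverse_complement(seq))
        n = len(seq)
        for pos in np.flatnonzero(rev >= cutoff):
            out.append((n - L - int(pos), "-", float(rev[pos])))
    return sorted(out)


def scan_sequences(
    motif: MotifModel,
    intervals: Iterable[GenomicInterval],
    threshold: float = 0.7,
    both_strands: bool = True,
) -> List[SiteHit]:
    """Scan intergenic intervals on both strands for motif matches.

    Hits carry the downstream gene matching the hit strand and the signed
    offset of the site start relative to that gene's translation start
    (negative upstream).  For a palindromic motif the strand is not
    physically meaningful; such hits are reported on + and annotated with
    whichever downstream gene exists (preferring the + gene).
    Intervals shorter than the motif are skipped with a log entry.
    """
    hits: List[SiteHit] = []
    for iv in intervals:
        if iv.length < motif.length:
            logger.info(
                "skipping interval %s:%d-%d shorter than motif", iv.seqid, iv.start, iv.end
            )
            continue
        for pos, strand, score in scan_string(motif, iv.seq, threshold, both_strands):
            abs_start = iv.start + pos
            abs_end = abs_start + motif.length
            window = iv.seq[pos : pos + motif.length]
            if strand == "-":
                gene, offset = iv.downstream_minus, None
                if iv.downstream_minus_end is not None:
                    offset = iv.downstream_minus_end - abs_end
                site = reverse_complement(window)
            else:
                site = window
                if motif.is_palindromic and iv.downstream_plus is None:
                    gene = iv.downstream_minus
                    offset = (
                        iv.downstream_minus_end - abs_end
                        if iv.downstream_minus_end is not None
                        else None
                    )
                else:
                    gene = iv.downstream_plus
                    offset = (
                        abs_start - iv.downstream_plus_start
                        if iv.downstream_plus_start is not None
                        else None
                    )
            hits.append(
                SiteHit(
                    seqid=iv.seqid,
                    start=abs_start,
                    end=abs_end,
                    strand=strand,
                    site=site,
                    score=score,
                    rel_score=motif.relative_score(score),
                    downstream_gene=gene,
                    offset=offset,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.seqid, h.start))
    return hits


def site_report(hits: Iterable[SiteHit]) -> pd.DataFrame:
    """Tabulate hits: downstream gene, offset, site, score.

    Sorted by score descending, ties broken by leftmost coordinate.
    """
    rows = [
        {
            "operon_first_gene": h.downstream_gene or "",
            "position": h.offset,
            "site": h.site,
            "score": round(h.score, 2),
            "strand": h.strand,
            "seqid": h.seqid,
            "start": h.start,
        }
        for h in hits
    ]
    df = pd.DataFrame(
        rows,
        columns=["operon_first_gene", "position", "site", "score", "strand", "seqid", "start"],
    )
    if len(df):
        df = df.sort_values(
            ["score", "seqid", "start"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return df
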