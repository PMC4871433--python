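"""Greedy consensus motif discovery by information-content maximization.

The search builds alignment matrices one sequence at a time: every
word of the first sequence seeds a single-site matrix; each subsequent
cycle extends every retained matrix with each word of the next sequence
(both strands when enabled), scores the extended matrices by total
information content, and keeps the top ``beam`` of them.  The final
model is the highest-IC matrix containing one site per input sequence.
The procedure is fully deterministic given the input order.

Information content follows the standard per-column relative-entropy
form, sum over columns of sum_b f_b * log2(f_b / p_b), with frequencies
formed from counts plus a pseudocount (default 0.25 per cell; 0 yields
the unsmoothed value).

Per-sequence match p-values are exact under the i.i.d. background
model: the best log-likelihood-ratio window score is compared against
the null score distribution obtained by dynamic-programming convolution
of the discretized per-column score distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from yy2scan.io_genomics import reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
UNIFORM_BACKGROUND = np.full(4, 0.25)


@dataclass
class MotifModel:
    """A position count/frequency matrix with its member sites.

    Matrices are 4 x width, rows ordered A, C, G, T.  ``member_sites``
    holds one ``(sequence_index, offset, strand)`` triple per input
    sequence; offsets are 0-based on the forward sequence.
    """

    width: int
    count_matrix: np.ndarray
    freq_matrix: np.ndarray
    background: np.ndarray
    consensus: str
    information_content: float
    member_sites: list[tuple[int, int, str]]


def _encode(seq: str) -> np.ndarray:
    """Map ACGT -> 0..3; N and other letters -> -1 (excluded from seeding words)."""
    return np.array([_BASE_INDEX.get(c, -1) for c in seq], dtype=np.int8)


def _counts_from_word(word_idx: np.ndarray) -> np.ndarray:
    counts = np.zeros((4, len(word_idx)), dtype=np.int64)
    counts[word_idx, np.arange(len(word_idx))] = 1
    return counts


def information_content(
    count_matrix: np.ndarray,
    background: np.ndarray | None = None,
    pseudocount: float = 0.25,
) -> float:
    """Total bits across columns of a 4 x width count matrix."""
    counts = np.asarray(count_matrix, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("count matrix must be 4 x width")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    if (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must be strictly positive and sum to 1")
    totals = counts.sum(axis=0) + 4 * pseudocount
    if (totals <= 0).any():
        raise ValueError("zero-total column with zero pseudocount")
    freq = (counts + pseudocount) / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freq > 0, freq * np.log2(freq / bg[:, None]), 0.0)
    return float(terms.sum())


def frequencies(count_matrix: np.ndarray, pseudocount: float = 0.25) -> np.ndarray:
    counts = np.asarray(count_matrix, dtype=float)
    return (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)


def consensus_string(freq_matrix: np.ndarray, majority_threshold: float = 0.5) -> str:
    """Per column, the majority base if its frequency >= threshold, else 'N'."""
    freq = np.asarray(freq_matrix, dtype=float)
    out = []
    for col in freq.T:
        b = int(np.argmax(col))
        out.append(BASES[b] if col[b] >= majority_threshold else "N")
    return "".join(out)


def _ic_batch(
    counts: np.ndarray, word_idx: np.ndarray, background: np.ndarray, pseudocount: float
) -> np.ndarray:
    """IC of ``counts`` extended by each word in ``word_idx`` (n_words x width)."""
    n, width = word_idx.shape
    ext = np.broadcast_to(counts, (n, 4, width)).copy()
    rows = np.arange(n)[:, None]
    cols = np.arange(width)[None, :]
    ext[rows, word_idx, cols] += 1
    totals = ext.sum(axis=1, keepdims=True) + 4 * pseudocount
    freq = (ext + pseudocount) / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freq > 0, freq * np.log2(freq / background[None, :, None]), 0.0)
    return terms.sum(axis=(1, 2))


def _words(seq_idx: np.ndarray, width: int) -> list[tuple[int, np.ndarray]]:
    """All fully-ACGT words of the given width, as (offset, index array)."""
    out = []
    for off in range(len(seq_idx) - width + 1):
        w = seq_idx[off : off + width]
        if (w >= 0).all():
            out.append((off, w))
    return out


def discover_motif(
    sequences: Sequence[str],
    width: int = 10,
    both_strands: bool = True,
    beam: int = 50,
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
    seed: int | None = None,
) -> MotifModel:
    """Greedy matrix-building consensus search over a set of DNA sequences.

    ``seed`` is accepted for interface symmetry; the search itself is
    deterministic (ties break by discovery order).
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    upper = [s.upper() for s in sequences]
    for i, s in enumerate(upper):
        if len(s) < width:
            raise ValueError(f"sequence {i} is shorter than the motif width {width}")
        if any(c not in "ACGTN" for c in s):
            raise ValueError(f"sequence {i} contains non-ACGTN characters")

    # per sequence: candidate words on requested strands
    seq_words: list[list[tuple[int, str, np.ndarray]]] = []
    for s in upper:
        fwd = [(off, "+", w) for off, w in _words(_encode(s), width)]
        cand = fwd
        if both_strands:
            rc = _encode(reverse_complement(s))
            # offset reported on the forward strand
            cand = fwd + [
                (len(s) - width - off, "-", w) for off, w in _words(rc, width)
            ]
        if not cand:
            raise ValueError("sequence has no ACGT-only word of the requested width")
        seq_words.append(cand)

    # beam state: (counts matrix, sites list).  Every word of the first
    # sequence seeds a matrix; single-word matrices all share the same IC,
    # so the beam is only applied after the first extension cycle.
    states = [
        (_counts_from_word(w), [(0, off, strand)]) for off, strand, w in seq_words[0]
    ]

    for si in range(1, len(upper)):
        words = seq_words[si]
        word_idx = np.stack([w for _off, _strand, w in words])  # (n_words, width)
        extended: list[tuple[float, np.ndarray, list]] = []
        for counts, sites in states:
            ics = _ic_batch(counts, word_idx, bg, pseudocount)
            for k in np.argsort(-ics, kind="stable")[: min(beam, len(ics))]:
                off, strand, w = words[k]
                extended.append(
                    (float(ics[k]), counts + _counts_from_word(w), sites + [(si, off, strand)])
                )
        extended.sort(key=lambda t: -t[0])
        states = [(c, s) for _ic, c, s in extended[:beam]]

    counts, sites = states[0]
    freq = frequencies(counts, pseudocount)
    return MotifModel(
        width=width,
        count_matrix=counts,
        freq_matrix=freq,
        background=bg,
        consensus=consensus_string(freq),
        information_content=information_content(counts, bg, pseudocount),
        member_sites=sites,
    )


# ---------------------------------------------------------------------------
# Exact match p-values
# ---------------------------------------------------------------------------

def _log_odds(motif: MotifModel) -> np.ndarray:
    """4 x width log2(f/p) matrix; zero-frequency cells become -inf."""
    with np.errstate(divide="ignore"):
        return np.log2(motif.freq_matrix / motif.background[:, None])


def score_window(motif: MotifModel, window: str) -> float:
    lo = _log_odds(motif)
    total = 0.0
    for j, c in enumerate(window.upper()):
        i = _BASE_INDEX.get(c)
        if i is None:
            return float("-inf")
        total += lo[i, j]
    return total


def _null_score_distribution(motif: MotifModel, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact pmf of the window score under i.i.d. background, discretized.

    Returns (support in bins, probabilities); -inf-scoring paths are
    dropped (they can never reach any finite threshold).
    """
    lo = _log_odds(motif)
    pmf: dict[int, float] = {0: 1.0}
    for j in range(motif.width):
        nxt: dict[int, float] = {}
        for b in range(4):
            s = lo[b, j]
            if not np.isfinite(s):
                continue  # mass on -inf paths never exceeds a finite score
            sb = int(round(s / bin_width))
            p = motif.background[b]
            for acc, q in pmf.items():
                nxt[acc + sb] = nxt.get(acc + sb, 0.0) + q * p
        pmf = nxt
    support = np.array(sorted(pmf), dtype=np.int64)
    probs = np.array([pmf[k] for k in support])
    return support, probs


def best_match_pvalue(
    motif: MotifModel,
    sequence: str,
    both_strands: bool = False,
    bin_width: float = 0.01,
) -> float:
    """P(one background window scores >= the best observed window score).

    Scores are discretized to ``bin_width`` in log2-likelihood units for
    both the observation and the null, so the comparison is consistent.
    """
    seq = sequence.upper()
    if len(seq) < motif.width:
        raise ValueError("sequence shorter than motif width")
    lo = _log_odds(motif)
    enc = _encode(seq)
    strands = [enc]
    if both_strands:
        strands.append(_encode(reverse_complement(seq)))
    binned = np.round(lo / bin_width).astype(float)  # keeps -inf
    best = float("-inf")
    for e in strands:
        for off in range(len(e) - motif.width + 1):
            w = e[off : off + motif.width]
            if (w < 0).any():
                continue
            s = binned[w, np.arange(motif.width)].sum()
            best = max(best, s)
    if best == float("-inf"):
        return 1.0
    support, probs = _null_score_distribution(motif, bin_width)
    return float(probs[support >= int(best)].sum())
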