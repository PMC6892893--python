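"""PAM-depletion screen analysis.

A randomized 4-nt PAM library sits between two fixed anchor sequences in a
reporter amplicon.  Cells whose PAM supports cleavage are killed under the
targeting guide, so functional PAMs are depleted from the targeting sample
relative to the non-targeting control.  This module extracts PAMs from
reads by anchor matching, tabulates them over the complete 4^k PAM space,
converts counts to pseudocounted frequencies, and scores each PAM by
comparing the targeting (X) and non-targeting (Y) frequencies.

Two score conventions are provided.  ``log2_ratio`` (default) is the log2
frequency change ``E_i = log2(Y_i / X_i)``: a functional, depleted PAM gets
a positive score.  ``ratio_of_logs`` is ``E_i = log2(Y_i) / log2(X_i)``, an
alternative convention in which the score is a ratio of log frequencies;
it is undefined where a frequency is 0 or 1 and such PAMs are flagged
rather than scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "PamExtractionSpec",
    "PamCountTable",
    "PamFrequencies",
    "EnrichmentTable",
    "extract_pam",
    "count_pams",
    "to_frequencies",
    "enrichment",
    "logo_matrix",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def all_pams(pam_len: int) -> list[str]:
    return ["".join(p) for p in product(_BASES, repeat=pam_len)]


@dataclass(frozen=True)
class PamExtractionSpec:
    """How to locate the randomized PAM within each read."""

    upstream_anchor: str
    downstream_anchor: str
    pam_len: int = 4
    max_anchor_mismatches: int = 1
    search_both_strands: bool = False

    def __post_init__(self):
        if not self.upstream_anchor or not self.downstream_anchor:
            raise ValueError("anchors must be non-empty")
        if self.pam_len < 1:
            raise ValueError("pam_len must be >= 1")
        object.__setattr__(self, "upstream_anchor", self.upstream_anchor.upper())
        object.__setattr__(
            self, "downstream_anchor", self.downstream_anchor.upper()
        )


@dataclass(frozen=True)
class PamCountTable:
    """Counts over the complete PAM space (zeros included)."""

    counts: dict[str, int]
    total_kept: int
    total_rejected: int
    rejections: dict[str, int] = field(default_factory=dict)
    pam_len: int = 4

    def __post_init__(self):
        if sum(self.counts.values()) != self.total_kept:
            raise ValueError("counts do not sum to total_kept")
        if len(self.counts) != 4 ** self.pam_len:
            raise ValueError("count table must cover the full PAM space")


@dataclass(frozen=True)
class PamFrequencies:
    freqs: dict[str, float]
    role: str  # "X" (targeting) or "Y" (non-targeting)
    pseudocount: float

    def __post_init__(self):
        if self.role not in ("X", "Y"):
            raise ValueError("role must be 'X' or 'Y'")
        total = sum(self.freqs.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"frequencies sum to {total}, expected 1")


@dataclass(frozen=True)
class EnrichmentTable:
    """Per-PAM scores; ``rank`` orders the PAM space best-first."""

    scores: dict[str, float]
    mode: str
    rank: tuple[str, ...]
    flagged: frozenset[str] = frozenset()

    def top(self, k: int) -> list[str]:
        return list(self.rank[:k])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pam": list(self.rank),
                "score": [self.scores[p] for p in self.rank],
                "rank": range(1, len(self.rank) + 1),
                "flagged": [p in self.flagged for p in self.rank],
            }
        )


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _placements(read: str, spec: PamExtractionSpec) -> list[str]:
    """All PAM strings at anchor placements within the mismatch budget."""
    u, d, k = spec.upstream_anchor, spec.downstream_anchor, spec.pam_len
    m = spec.max_anchor_mismatches
    pams = []
    for s in range(len(read) - len(u) - k - len(d) + 1):
        if _hamming(read[s : s + len(u)], u) <= m and _hamming(
            read[s + len(u) + k : s + len(u) + k + len(d)], d
        ) <= m:
            pams.append(read[s + len(u) : s + len(u) + k])
    return pams


def extract_pam(read: str, spec: PamExtractionSpec) -> tuple[str | None, str]:
    """Extract the PAM from one read.

    Returns (pam, "ok") on success, else (None, reason) with reason one of
    ``too-short``, ``anchor-not-found``, ``ambiguous-placement``,
    ``ambiguous-base``.
    """
    read = read.upper()
    need = len(spec.upstream_anchor) + spec.pam_len + len(spec.downstream_anchor)
    if len(read) < need:
        return None, "too-short"
    pams = _placements(read, spec)
    if spec.search_both_strands:
        pams += _placements(_revcomp(read), spec)
    if not pams:
        return None, "anchor-not-found"
    if len(pams) > 1:
        return None, "ambiguous-placement"
    pam = pams[0]
    if any(b not in _BASES for b in pam):
        return None, "ambiguous-base"
    return pam, "ok"


def _mean_phred(qual: str) -> float:
    return sum(ord(q) - 33 for q in qual) / len(qual)


def _count_batch(
    seqs: list[str], spec: PamExtractionSpec
) -> tuple[np.ndarray, dict[str, int]]:
    """Vectorized extraction for same-length reads (single strand).

    Returns per-PAM counts (indexed over the 4^k PAM space in lexicographic
    order) and a rejection tally.
    """
    k = spec.pam_len
    u, d = spec.upstream_anchor, spec.downstream_anchor
    m = spec.max_anchor_mismatches
    L = len(seqs[0])
    reads = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    reads = reads.reshape(len(seqs), L)
    ua = np.frombuffer(u.encode(), dtype=np.uint8)
    da = np.frombuffer(d.encode(), dtype=np.uint8)
    n_off = L - len(u) - k - len(d) + 1
    valid = np.zeros((len(seqs), n_off), dtype=bool)
    for s in range(n_off):
        mu = (reads[:, s : s + len(u)] != ua).sum(axis=1)
        md = (
            reads[:, s + len(u) + k : s + len(u) + k + len(d)] != da
        ).sum(axis=1)
        valid[:, s] = (mu <= m) & (md <= m)
    n_valid = valid.sum(axis=1)
    rejections = {
        "anchor-not-found": int((n_valid == 0).sum()),
        "ambiguous-placement": int((n_valid > 1).sum()),
    }
    keep = n_valid == 1
    offsets = valid[keep].argmax(axis=1) + len(u)
    kept = reads[keep]
    pam_mat = kept[np.arange(kept.shape[0])[:, None], offsets[:, None] + np.arange(k)]
    # encode A,C,G,T -> 0..3; anything else marks an ambiguous base
    code = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        code[ord(b)] = i
    digits = code[pam_mat]
    clean = (digits >= 0).all(axis=1)
    rejections["ambiguous-base"] = int((~clean).sum())
    idx = (digits[clean] * (4 ** np.arange(k - 1, -1, -1))).sum(axis=1)
    counts = np.bincount(idx, minlength=4**k)
    return counts, rejections


def count_pams(
    reads: Iterable[str | tuple[str, str, str]],
    spec: PamExtractionSpec,
    min_mean_quality: float | None = None,
) -> PamCountTable:
    """Tabulate PAMs over every read; kept + rejected == total reads.

    ``reads`` may be plain sequences or (id, sequence, quality) triples as
    yielded by :func:`casforge.io.read_fastq`.  When all reads share one
    length and a single-strand search suffices, counting is vectorized.
    """
    seqs: list[str] = []
    rejections: dict[str, int] = {}
    for r in reads:
        if isinstance(r, str):
            seq, qual = r, None
        else:
            _, seq, qual = r
        if (
            min_mean_quality is not None
            and qual is not None
            and _mean_phred(qual) < min_mean_quality
        ):
            rejections["low-quality"] = rejections.get("low-quality", 0) + 1
            continue
        seqs.append(seq.upper())

    space = all_pams(spec.pam_len)
    counts = dict.fromkeys(space, 0)
    need = len(spec.upstream_anchor) + spec.pam_len + len(spec.downstream_anchor)
    uniform = seqs and not spec.search_both_strands and len(set(map(len, seqs))) == 1
    if uniform and len(seqs[0]) >= need:
        vec, rej = _count_batch(seqs, spec)
        for reason, n in rej.items():
            rejections[reason] = rejections.get(reason, 0) + n
        for p, n in zip(space, vec):
            counts[p] = int(n)
    else:
        for seq in seqs:
            pam, reason = extract_pam(seq, spec)
            if pam is None:
                rejections[reason] = rejections.get(reason, 0) + 1
            else:
                counts[pam] += 1
    kept = sum(counts.values())
    return PamCountTable(
        counts=counts,
        total_kept=kept,
        total_rejected=sum(rejections.values()),
        rejections=rejections,
        pam_len=spec.pam_len,
    )


def to_frequencies(
    table: PamCountTable, pseudocount: float = 1.0, role: str = "X"
) -> PamFrequencies:
    """Pseudocounted frequencies ``(n_i + c) / sum_j (n_j + c)``."""
    denom = table.total_kept + pseudocount * len(table.counts)
    if denom <= 0:
        raise ValueError("no reads and no pseudocount; frequencies undefined")
    freqs = {p: (n + pseudocount) / denom for p, n in table.counts.items()}
    return PamFrequencies(freqs=freqs, role=role, pseudocount=pseudocount)


def enrichment(
    x: PamFrequencies, y: PamFrequencies, mode: str = "log2_ratio"
) -> EnrichmentTable:
    """Score every PAM by targeting-vs-control frequency comparison.

    ``x`` is the targeting sample (X_i), ``y`` the non-targeting control
    (Y_i).  Ranking is descending by score with lexicographic tie-break;
    PAMs with undefined scores (ratio_of_logs at frequency 0 or 1) are
    flagged and ranked last.
    """
    if set(x.freqs) != set(y.freqs):
        raise ValueError("X and Y cover different PAM spaces")
    scores: dict[str, float] = {}
    flagged = set()
    for pam in x.freqs:
        xi, yi = x.freqs[pam], y.freqs[pam]
        if mode == "log2_ratio":
            if xi <= 0 or yi <= 0:
                flagged.add(pam)
                scores[pam] = math.nan
            else:
                scores[pam] = math.log2(yi / xi)
        elif mode == "ratio_of_logs":
            if not (0 < xi < 1 and 0 < yi < 1):
                flagged.add(pam)
                scores[pam] = math.nan
            else:
                scores[pam] = math.log2(yi) / math.log2(xi)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    rank = tuple(
        sorted(
            scores,
            key=lambda p: (math.isnan(scores[p]), -scores[p] if not math.isnan(scores[p]) else 0.0, p),
        )
    )
    return EnrichmentTable(
        scores=scores, mode=mode, rank=rank, flagged=frozenset(flagged)
    )


def logo_matrix(table: EnrichmentTable, top_k: int) -> pd.DataFrame:
    """Position x base frequency matrix over the top-k PAMs.

    Each of the top-k ranked PAMs contributes weight ``max(score, 0)``;
    rows (positions) sum to 1.  Raises when no positive-score PAM is in
    the top k (nothing to display).
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    top = table.top(top_k)
    weights = {
        p: max(table.scores[p], 0.0)
        for p in top
        if not math.isnan(table.scores[p])
    }
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("no PAM with positive score among the top k")
    k = len(top[0])
    mat = np.zeros((k, 4))
    for pam, w in weights.items():
        for pos, base in enumerate(pam):
            mat[pos, _BASES.index(base)] += w / total
    return pd.DataFrame(
        mat, index=range(1, k + 1), columns=list(_BASES)
    )
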