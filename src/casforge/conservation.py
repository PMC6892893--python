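"""Conservation profiling and crossover-junction selection.

Chimeragenesis swaps protein segments between orthologs at junctions that
are locally conserved across the family, so that the exchanged segments
splice onto structurally equivalent residues.  The profile here is the
mean pairwise identity per alignment column (a gap against anything counts
as a mismatch), smoothed by a centred moving average; junctions are picked
greedily from the highest-scoring gap-free columns subject to a minimum
nucleotide spacing on every parent's CDS — the segments being exchanged
must each span a substantial stretch (default at least 500 bp).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .io import Msa

__all__ = [
    "ConservationProfile",
    "Junction",
    "JunctionSet",
    "conservation_profile",
    "select_junctions",
    "label_segments",
    "pairwise_identity",
]


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation scores in [0, 1] plus the smoothing width."""

    scores: np.ndarray
    window: int
    raw_scores: np.ndarray | None = None

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 1:
            raise ValueError("scores must be 1-D")
        if s.size and (s.min() < -1e-9 or s.max() > 1 + 1e-9):
            raise ValueError("scores must lie in [0, 1]")
        object.__setattr__(self, "scores", s)


@dataclass(frozen=True)
class Junction:
    """A crossover point: one alignment column projected onto every parent.

    ``residue_pos[p]`` is the 0-based index of the residue that starts the
    downstream segment in parent ``p``; ``nt_pos[p] == 3 * residue_pos[p]``.
    """

    index: int
    aln_column: int
    residue_pos: dict[str, int]
    nt_pos: dict[str, int]
    score: float


@dataclass(frozen=True)
class JunctionSet:
    junctions: tuple[Junction, ...]
    min_segment_nt: int
    domain_labels: tuple[str, ...] | None = None

    def __len__(self) -> int:
        return len(self.junctions)

    def __iter__(self):
        return iter(self.junctions)


def _seq_matrix(msa: Msa) -> np.ndarray:
    """Alignment as an (n_rows, n_cols) uint8 matrix; '-' encodes gaps."""
    return np.frombuffer(
        "".join(seq for _, seq in msa.rows).encode("ascii"), dtype=np.uint8
    ).reshape(len(msa.rows), msa.n_columns)


def _column_identity(mat: np.ndarray) -> np.ndarray:
    """Mean pairwise identity per column; gap-vs-anything is a mismatch."""
    n = mat.shape[0]
    gap = ord("-")
    matches = np.zeros(mat.shape[1], dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            matches += (mat[i] == mat[j]) & (mat[i] != gap)
    return matches / (n * (n - 1) / 2)


def _smooth(scores: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; the window is truncated at the edges."""
    if window == 1 or scores.size == 0:
        return scores.copy()
    half = window // 2
    padded = np.concatenate([np.zeros(half), scores, np.zeros(half)])
    csum = np.concatenate([[0.0], np.cumsum(padded)])
    sums = csum[window:] - csum[:-window]
    idx = np.arange(scores.size)
    counts = np.minimum(idx + half, scores.size - 1) - np.maximum(idx - half, 0) + 1
    return sums / counts


def conservation_profile(msa: Msa, window: int = 11) -> ConservationProfile:
    """Score each alignment column by mean pairwise identity, then smooth.

    Parameters
    ----------
    msa : Msa
        Protein alignment of the parental family (>= 2 rows).
    window : int
        Odd width of the centred moving-average smoother; 1 disables
        smoothing.  The default of 11 columns is roughly the width of the
        conserved sequence motifs flanking usable junctions.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if len(msa.rows) < 2:
        raise ValueError("alignment needs at least 2 rows")
    raw = _column_identity(_seq_matrix(msa))
    return ConservationProfile(
        scores=_smooth(raw, window), window=window, raw_scores=raw
    )


def pairwise_identity(msa: Msa) -> "pd.DataFrame":  # noqa: F821
    """Percent identity for every row pair, computed over alignment columns.

    Identity = matching non-gap columns / columns where at least one row is
    non-gap, as alignment viewers report it.  Returns a symmetric DataFrame
    in percent.
    """
    import pandas as pd

    mat = _seq_matrix(msa)
    gap = ord("-")
    n = mat.shape[0]
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            both_gap = (mat[i] == gap) & (mat[j] == gap)
            match = (mat[i] == mat[j]) & ~both_gap
            denom = (~both_gap).sum()
            out[i, j] = out[j, i] = 100.0 * match.sum() / denom if denom else 0.0
    ids = list(msa.ids)
    return pd.DataFrame(out, index=ids, columns=ids)


def _eligible_columns(msa: Msa) -> tuple[np.ndarray, np.ndarray]:
    """Gap-free columns and the residue index of each column in each row."""
    mat = _seq_matrix(msa)
    gap = ord("-")
    nongap = mat != gap
    # residue index at each column per row (value only meaningful where nongap)
    resindex = np.cumsum(nongap, axis=1) - 1
    return nongap.all(axis=0), resindex


def select_junctions(
    profile: ConservationProfile,
    msa: Msa,
    min_segment_nt: int = 500,
    max_junctions: int = 6,
) -> JunctionSet:
    """Greedily pick crossover columns by descending smoothed conservation.

    A column is accepted only if it is gap-free in every row and, for every
    parent, its nucleotide position (3 x residue index) is at least
    ``min_segment_nt`` from both CDS ends and from every already-accepted
    junction.  Ties in score fall to the smaller column.  Returns the
    junctions ordered by column; an empty set (with a warning) when nothing
    is eligible.
    """
    if min_segment_nt <= 0:
        raise ValueError("min_segment_nt must be positive")
    if len(profile.scores) != msa.n_columns:
        raise ValueError("profile length does not match alignment width")
    eligible, resindex = _eligible_columns(msa)
    ids = list(msa.ids)
    cds_len = {rid: 3 * len(msa.ungapped(rid)) for rid in ids}

    order = sorted(
        np.flatnonzero(eligible), key=lambda c: (-profile.scores[c], c)
    )
    accepted: list[int] = []  # 0-based columns
    accepted_nt: dict[str, list[int]] = {rid: [] for rid in ids}
    for c in order:
        if len(accepted) >= max_junctions:
            break
        ok = True
        for k, rid in enumerate(ids):
            nt = 3 * int(resindex[k, c])
            if nt < min_segment_nt or cds_len[rid] - nt < min_segment_nt:
                ok = False
                break
            if any(abs(nt - p) < min_segment_nt for p in accepted_nt[rid]):
                ok = False
                break
        if ok:
            accepted.append(c)
            for k, rid in enumerate(ids):
                accepted_nt[rid].append(3 * int(resindex[k, c]))
    if not accepted:
        warnings.warn("no eligible junction column under the given constraints")
    junctions = []
    for idx, c in enumerate(sorted(accepted), start=1):
        respos = {rid: int(resindex[k, c]) for k, rid in enumerate(ids)}
        junctions.append(
            Junction(
                index=idx,
                aln_column=c + 1,
                residue_pos=respos,
                nt_pos={rid: 3 * r for rid, r in respos.items()},
                score=float(profile.scores[c]),
            )
        )
    return JunctionSet(junctions=tuple(junctions), min_segment_nt=min_segment_nt)


def label_segments(junction_set: JunctionSet, labels: list[str]) -> JunctionSet:
    """Attach domain labels to the segments between junctions.

    ``labels`` must have exactly one more entry than there are junctions
    (segments include both sequence ends).
    """
    if len(labels) != len(junction_set.junctions) + 1:
        raise ValueError(
            f"need {len(junction_set.junctions) + 1} labels, got {len(labels)}"
        )
    return replace(junction_set, domain_labels=tuple(labels))
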