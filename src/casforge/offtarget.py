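"""Off-target cassette design and on/off-target read-count summaries.

The designed specificity panel places nine near-cognate spacers against a
guide: one substitution, one single-base deletion and one single-base
insertion at each of three positions (by default one per PAM-proximal,
middle and PAM-distal third of the guide).  Every cassette is exactly one
edit away from the guide.

Genome-wide cleavage data (e.g. CIRCLE-seq) arrive as finished site/read
count tables; ``offtarget_fraction`` filters low-support sites (strictly
more than ``min_reads`` reads survive) and reports the off-target read
share, and ``annotate_mismatches`` aligns each site to the target to
highlight substituted/inserted/deleted positions.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CassetteSpec",
    "OffTargetCassette",
    "SiteCountTable",
    "OffTargetSummary",
    "MismatchAnnotation",
    "generate_cassettes",
    "annotate_mismatches",
    "offtarget_fraction",
]

_TRANSVERSION = {"A": "T", "T": "A", "G": "C", "C": "G"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _default_positions(guide_len: int) -> tuple[int, int, int]:
    """One position per third of the guide: proximal, middle, distal."""
    return (
        -(-guide_len // 6),  # ceil(L/6)
        -(-guide_len // 2),
        -(-5 * guide_len // 6),
    )


@dataclass(frozen=True)
class CassetteSpec:
    """Which positions to perturb and how to choose substituted bases."""

    guide: str
    positions: tuple[int, int, int] | None = None
    substitution_policy: str = "transversion"

    def __post_init__(self):
        guide = self.guide.upper()
        if len(guide) < 6:
            raise ValueError("guide must be at least 6 nt")
        if any(b not in "ACGT" for b in guide):
            raise ValueError("guide must be A/C/G/T only")
        object.__setattr__(self, "guide", guide)
        pos = self.positions or _default_positions(len(guide))
        if len(set(pos)) != len(pos):
            raise ValueError(f"positions must be distinct, got {pos}")
        if any(not 1 <= p <= len(guide) for p in pos):
            raise ValueError(f"positions out of range 1..{len(guide)}: {pos}")
        object.__setattr__(self, "positions", tuple(pos))


@dataclass(frozen=True)
class OffTargetCassette:
    cassette_id: str
    edit_type: str  # substitution | deletion | insertion
    position: int  # 1-based guide position
    sequence: str


@dataclass(frozen=True)
class SiteCountTable:
    """On-target and off-target site sequences with their read counts."""

    target_sequence: str
    on_target_reads: int
    off_target_sites: tuple[tuple[str, int], ...]

    def __post_init__(self):
        if self.on_target_reads < 0 or any(
            n < 0 for _, n in self.off_target_sites
        ):
            raise ValueError("read counts must be nonnegative")


@dataclass(frozen=True)
class OffTargetSummary:
    percent_off_target: float
    sites_passing_filter: tuple[tuple[str, int], ...]
    min_reads: int
    on_target_reads: int


def _substituted_base(base: str, policy: str) -> str:
    if policy == "transversion":
        return _TRANSVERSION[base]
    if policy == "transition":
        return _TRANSITION[base]
    if policy in "ACGT" and len(policy) == 1:
        if policy == base:
            raise ValueError(
                f"fixed base {policy} equals the guide base; no edit"
            )
        return policy
    raise ValueError(f"unknown substitution policy {policy!r}")


def generate_cassettes(spec: CassetteSpec) -> list[OffTargetCassette]:
    """The nine-cassette panel: sub/del/ins at each configured position."""
    guide = spec.guide
    cassettes = []
    for edit_type in ("substitution", "deletion", "insertion"):
        for pos in spec.positions:
            i = pos - 1
            if edit_type == "substitution":
                seq = (
                    guide[:i]
                    + _substituted_base(guide[i], spec.substitution_policy)
                    + guide[i + 1 :]
                )
                cid = f"sub_p{pos}"
            elif edit_type == "deletion":
                seq = guide[:i] + guide[i + 1 :]
                cid = f"del_p{pos}"
            else:
                seq = (
                    guide[:i]
                    + _substituted_base(guide[i], spec.substitution_policy)
                    + guide[i:]
                )
                cid = f"ins_p{pos}"
            cassettes.append(OffTargetCassette(cid, edit_type, pos, seq))
    return cassettes


# ---------------------------------------------------------------------------
# mismatch annotation by global alignment


@dataclass(frozen=True)
class MismatchAnnotation:
    """Highlighted differences between a site and the target.

    Positions are 1-based on the target; an insertion is reported at the
    number of target bases consumed before the inserted site base.
    """

    aligned_target: str
    aligned_site: str
    substitutions: tuple[int, ...]
    deletions: tuple[int, ...]
    insertions: tuple[int, ...]
    score: int

    @property
    def n_edits(self) -> int:
        return (
            len(self.substitutions) + len(self.deletions) + len(self.insertions)
        )


MATCH, MISMATCH, GAP = 1, -1, -2


def annotate_mismatches(target: str, site_sequence: str) -> MismatchAnnotation:
    """Globally align a site to the target and highlight its edits.

    Needleman-Wunsch with match +1, mismatch -1, gap -2.  Among equal-score
    alignments the one with the leftmost gaps is returned (traceback
    prefers a target gap, then a site gap, then a diagonal step).
    """
    t, s = target.upper(), site_sequence.upper()
    if abs(len(t) - len(s)) > 2:
        raise ValueError(
            f"length difference {abs(len(t) - len(s))} exceeds 2"
        )
    n, m = len(t), len(s)
    # suffix scores: best[i][j] = optimal score aligning t[i:] vs s[j:]
    best = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n, -1, -1):
        for j in range(m, -1, -1):
            if i == n and j == m:
                continue
            cands = []
            if i < n:
                cands.append(GAP + best[i + 1][j])  # delete t[i]
            if j < m:
                cands.append(GAP + best[i][j + 1])  # insert s[j]
            if i < n and j < m:
                cands.append(
                    (MATCH if t[i] == s[j] else MISMATCH) + best[i + 1][j + 1]
                )
            best[i][j] = max(cands)
    at, asit = [], []
    subs, dels, ins = [], [], []
    i = j = 0
    while i < n or j < m:
        score = best[i][j]
        if i < n and score == GAP + best[i + 1][j]:
            at.append(t[i])
            asit.append("-")
            dels.append(i + 1)
            i += 1
        elif j < m and score == GAP + best[i][j + 1]:
            at.append("-")
            asit.append(s[j])
            ins.append(i)
            j += 1
        else:
            at.append(t[i])
            asit.append(s[j])
            if t[i] != s[j]:
                subs.append(i + 1)
            i += 1
            j += 1
    return MismatchAnnotation(
        aligned_target="".join(at),
        aligned_site="".join(asit),
        substitutions=tuple(subs),
        deletions=tuple(dels),
        insertions=tuple(ins),
        score=best[0][0],
    )


def offtarget_fraction(
    table: SiteCountTable, min_reads: int = 10
) -> OffTargetSummary:
    """Off-target read share after dropping weakly supported sites.

    Sites with reads <= ``min_reads`` are excluded (the filter is strict:
    a site needs more than ``min_reads`` reads to count).  The percentage
    is 100 x off / (on + off) over the surviving reads.
    """
    passing = tuple(
        (seq, n) for seq, n in table.off_target_sites if n > min_reads
    )
    off = sum(n for _, n in passing)
    denom = table.on_target_reads + off
    if denom == 0:
        raise ValueError("no reads survive the filter")
    return OffTargetSummary(
        percent_off_target=100.0 * off / denom,
        sites_passing_filter=passing,
        min_reads=min_reads,
        on_target_reads=table.on_target_reads,
    )
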