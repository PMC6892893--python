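"""Chimera enumeration, sequence realization and Gibson fragment layout.

Two enumeration schemes are provided.  "sequential" single-crossover designs
take parent A up to a junction and parent B after it (J x P x (P-1) designs
over J junctions and P parents).  "backbone-swap" double-crossover designs
replace the contiguous region between two junctions of a backbone parent
with the corresponding region of a donor (C(J,2) x P x (P-1) designs, or
C(J,2) x (P-1) with a fixed backbone).  A crossover sits immediately before
the junction residue: the junction residue belongs to the downstream
segment.

Realized CDSs are concatenations of donor CDS slices between projected
junction coordinates, so every segment is a verbatim substring of its
donor.  ``design_gblocks`` lays a CDS out as synthesis fragments with
shared homology overlaps for Gibson-style assembly into a vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

from .conservation import JunctionSet
from .io import ParentRecord, translate_cds

__all__ = [
    "ChimeraDesign",
    "ChimeraSequence",
    "AssemblyFragment",
    "enumerate_single_crossover",
    "enumerate_two_crossover",
    "build_sequence",
    "design_gblocks",
    "deduplicate",
]


@dataclass(frozen=True)
class ChimeraDesign:
    """A segment-to-donor assignment over the elementary junction segments.

    ``donors`` has one entry per elementary segment (J junctions define
    J+1 segments); ``n_crossovers`` equals the number of adjacent donor
    changes.
    """

    design_id: str
    n_crossovers: int
    donors: tuple[str, ...]

    def __post_init__(self):
        changes = sum(
            1 for a, b in zip(self.donors, self.donors[1:]) if a != b
        )
        if changes != self.n_crossovers:
            raise ValueError(
                f"{self.design_id}: donors imply {changes} crossovers, "
                f"declared {self.n_crossovers}"
            )


@dataclass(frozen=True)
class ChimeraSequence:
    design_id: str
    protein_seq: str
    cds_seq: str


@dataclass(frozen=True)
class AssemblyFragment:
    """One synthesis fragment; overlaps are shared verbatim with neighbours."""

    fragment_id: str
    sequence: str
    left_overlap: str
    right_overlap: str
    role: str  # "insert" (vector arms live on the terminal inserts)


def _check_parents(parents: list[ParentRecord]) -> dict[str, ParentRecord]:
    by_id = {p.id: p for p in parents}
    if len(by_id) != len(parents):
        raise ValueError("duplicate parent ids")
    return by_id


def enumerate_single_crossover(
    parents: list[ParentRecord], junction_set: JunctionSet
) -> list[ChimeraDesign]:
    """All A-then-B designs over each junction; J x P x (P-1) in total.

    Order is deterministic: junction index, then A, then B (lexicographic).
    """
    _check_parents(parents)
    ids = sorted(p.id for p in parents)
    nj = len(junction_set)
    if len(ids) < 2 or nj == 0:
        warnings.warn("need >=2 parents and >=1 junction; returning no designs")
        return []
    designs = []
    for j in range(1, nj + 1):
        for a in ids:
            for b in ids:
                if a == b:
                    continue
                donors = (a,) * j + (b,) * (nj + 1 - j)
                designs.append(
                    ChimeraDesign(f"S{j}_{a}-{b}", 1, donors)
                )
    return designs


def enumerate_two_crossover(
    parents: list[ParentRecord],
    junction_set: JunctionSet,
    backbone_policy: str = "all-backbones",
    backbone: str | None = None,
) -> list[ChimeraDesign]:
    """Backbone-swap designs: donor replaces the [i, j) region of a backbone.

    ``backbone_policy`` is "all-backbones" (C(J,2) x P x (P-1) designs) or
    "fixed-backbone" (C(J,2) x (P-1) designs for the named ``backbone``).
    """
    by_id = _check_parents(parents)
    ids = sorted(p.id for p in parents)
    nj = len(junction_set)
    if len(ids) < 2 or nj < 2:
        warnings.warn("need >=2 parents and >=2 junctions; returning no designs")
        return []
    if backbone_policy == "fixed-backbone":
        if backbone is None or backbone not in by_id:
            raise ValueError(f"unknown backbone id {backbone!r}")
        backbones = [backbone]
    elif backbone_policy == "all-backbones":
        backbones = ids
    else:
        raise ValueError(f"unknown backbone policy {backbone_policy!r}")
    designs = []
    for i, j in combinations(range(1, nj + 1), 2):
        for bb in backbones:
            for donor in ids:
                if donor == bb:
                    continue
                donors = (
                    (bb,) * i + (donor,) * (j - i) + (bb,) * (nj + 1 - j)
                )
                designs.append(
                    ChimeraDesign(f"D{i}.{j}_{bb}+{donor}", 2, donors)
                )
    return designs


def build_sequence(
    design: ChimeraDesign,
    parents: list[ParentRecord],
    junction_set: JunctionSet,
) -> ChimeraSequence:
    """Realize a design as a CDS (donor slices between junctions) + protein."""
    by_id = _check_parents(parents)
    nj = len(junction_set)
    if len(design.donors) != nj + 1:
        raise ValueError(
            f"{design.design_id}: {len(design.donors)} donors for "
            f"{nj + 1} segments"
        )
    parts = []
    for seg, donor in enumerate(design.donors):
        if donor not in by_id:
            raise KeyError(f"unknown donor {donor!r}")
        p = by_id[donor]
        start = 0 if seg == 0 else junction_set.junctions[seg - 1].nt_pos[donor]
        stop = p.cds_len if seg == nj else junction_set.junctions[seg].nt_pos[donor]
        if start > stop:
            raise ValueError(
                f"{design.design_id}: junction order inverted on {donor}"
            )
        parts.append(p.cds_seq[start:stop])
    cds = "".join(parts)
    protein = translate_cds(cds)
    if "*" in protein:
        raise ValueError(f"{design.design_id}: internal stop in chimera")
    return ChimeraSequence(design.design_id, protein, cds)


def design_gblocks(
    chimera: ChimeraSequence,
    vector_left: str,
    vector_right: str,
    homology_len: int = 40,
    max_fragment_len: int = 3000,
) -> list[AssemblyFragment]:
    """Split a CDS into synthesis fragments with Gibson homology overlaps.

    Adjacent fragments share exactly ``homology_len`` nt; the first/last
    fragments carry ``homology_len`` nt of the flanking vector sequence as
    assembly arms.  Overlap sequences are checked for uniqueness within the
    construct (collisions would allow mis-assembly) and reported as a
    warning.
    """
    cds = chimera.cds_seq
    if homology_len < 15:
        raise ValueError("homology_len must be >= 15")
    if max_fragment_len <= 2 * homology_len:
        raise ValueError("max_fragment_len must exceed 2 x homology_len")
    if len(cds) < homology_len:
        raise ValueError("CDS shorter than the homology length")
    if len(vector_left) < homology_len or len(vector_right) < homology_len:
        raise ValueError("vector sequences shorter than the homology length")

    core_max = max_fragment_len - 2 * homology_len
    n_pieces = -(-len(cds) // core_max)  # ceil
    bounds = [round(k * len(cds) / n_pieces) for k in range(n_pieces + 1)]
    cores = [cds[bounds[k] : bounds[k + 1]] for k in range(n_pieces)]
    if n_pieces > 1 and min(len(c) for c in cores) < homology_len:
        raise ValueError("fragment cores shorter than the homology length")

    left_arm = vector_left[-homology_len:]
    right_arm = vector_right[:homology_len]
    # fragment k = [left vector arm if first] + core_k + right extension,
    # where the right extension is the head of the next core (the shared
    # overlap) or the right vector arm on the last fragment.
    fragments: list[AssemblyFragment] = []
    for k, core in enumerate(cores):
        first, last = k == 0, k == n_pieces - 1
        right = right_arm if last else cores[k + 1][:homology_len]
        seq = (left_arm if first else "") + core + right
        left = left_arm if first else core[:homology_len]
        fragments.append(
            AssemblyFragment(
                fragment_id=f"{chimera.design_id}_frag{k + 1}",
                sequence=seq,
                left_overlap=left,
                right_overlap=right,
                role="insert",
            )
        )
    overlaps = [f.right_overlap for f in fragments[:-1]] + [left_arm, right_arm]
    collisions = [o for o in set(overlaps) if overlaps.count(o) > 1]
    if collisions:
        warnings.warn(
            f"{chimera.design_id}: non-unique assembly overlaps: {collisions}"
        )
    return fragments


def reassemble(fragments: list[AssemblyFragment], homology_len: int = 40) -> str:
    """Merge fragments on their shared overlaps (each counted once)."""
    if not fragments:
        return ""
    seq = fragments[0].sequence
    for frag in fragments[1:]:
        if seq[-homology_len:] != frag.sequence[:homology_len]:
            raise ValueError(
                f"{frag.fragment_id}: overlap does not match previous fragment"
            )
        seq += frag.sequence[homology_len:]
    return seq


def deduplicate(
    designs: list[ChimeraDesign], sequences: list[ChimeraSequence]
) -> tuple[list[ChimeraDesign], list[list[str]]]:
    """Collapse designs that realize the same protein sequence.

    Keeps the first design (input order) per distinct protein; returns the
    kept designs and the groups of colliding design ids.
    """
    if len(designs) != len(sequences):
        raise ValueError("designs and sequences must align")
    by_protein: dict[str, list[int]] = {}
    for k, seq in enumerate(sequences):
        by_protein.setdefault(seq.protein_seq, []).append(k)
    kept = [
        designs[idxs[0]]
        for idxs in sorted(by_protein.values(), key=lambda v: v[0])
    ]
    groups = [
        [designs[i].design_id for i in idxs]
        for idxs in sorted(by_protein.values(), key=lambda v: v[0])
        if len(idxs) > 1
    ]
    return kept, groups
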