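"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generators stand in for the study's raw inputs so that every stage is
testable without downloads:

* an orthologous nuclease family whose pairwise identity falls in a low
  band (default 33.8-42.99%) around fully conserved junction blocks;
* paired targeting / non-targeting PAM-library read sets in which
  functional PAMs are depleted from the targeting sample;
* binomially sampled colony counts for killing and colour screens;
* on/off-target site read-count tables with mismatch-dependent cleavage.

All generators are pure functions of their config: one global seed fans
out to fixed per-generator substreams, so adding one simulation never
perturbs another.  Ground truth (block positions, functional PAM set,
true efficiency, true off-target share) is returned alongside the data
for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .io import Msa, ParentRecord
from .offtarget import SiteCountTable
from .pam import all_pams
from .screens import ColonyCounts, ColorScreenCounts

__all__ = [
    "SimFamilyConfig",
    "SimPamConfig",
    "SimColonyConfig",
    "SimOffTargetConfig",
    "FamilySim",
    "PamScreenSim",
    "OffTargetSim",
    "simulate_parent_family",
    "simulate_pam_screen",
    "simulate_colony_counts",
    "simulate_offtarget_table",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"

# fixed substream tags so generators draw from independent streams
_STREAMS = {"family": 1, "pam": 2, "colony": 3, "offtarget": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


def _codon_map() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[1]
    out: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        out.setdefault(aa, []).append(codon)
    return out


# ---------------------------------------------------------------------------
# orthologous family


@dataclass(frozen=True)
class SimFamilyConfig:
    """Geometry and divergence of the synthetic nuclease family.

    ``identity_band`` is the target range of overall pairwise percent
    identity (as a fraction); the default matches the low-identity regime
    of a diverse Cas12a-type ortholog set.
    """

    n_parents: int = 9
    protein_length: int = 1300
    n_conserved_blocks: int = 6
    block_length: int = 15
    identity_band: tuple[float, float] = (0.338, 0.4299)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.identity_band
        if not 0 < lo <= hi < 1:
            raise ValueError("identity band must lie inside (0, 1)")
        if self.n_parents < 2 or self.protein_length < 10:
            raise ValueError("need >=2 parents and a nontrivial length")


@dataclass(frozen=True)
class FamilySim:
    parents: tuple[ParentRecord, ...]
    msa: Msa
    block_spans: tuple[tuple[int, int], ...]  # 1-based inclusive columns
    block_centers: tuple[int, ...]
    config: SimFamilyConfig


def _copy_prob_for_identity(t: float) -> float:
    """Per-column ancestor-copy probability giving pairwise identity ``t``.

    Two rows agree at a background column when both copied the ancestor
    (q^2) or independently mutated to the same of 19 alternatives
    ((1-q)^2 / 19); solve q^2 + (1-q)^2/19 = t for q in (0, 1).
    """
    # (20/19) q^2 - (2/19) q + (1/19 - t) = 0
    a, b, c = 20 / 19, -2 / 19, 1 / 19 - t
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError(f"identity {t} unreachable by this mechanism")
    q = (-b + math.sqrt(disc)) / (2 * a)
    if not 0 <= q <= 1:
        raise ValueError(f"identity {t} unreachable by this mechanism")
    return q


def _block_layout(cfg: SimFamilyConfig) -> list[tuple[int, int]]:
    """Evenly spaced block spans (0-based half-open residue intervals)."""
    L, B, w = cfg.protein_length, cfg.n_conserved_blocks, cfg.block_length
    spans = []
    for k in range(B):
        center = round((k + 1) * L / (B + 1))
        start = center - w // 2
        spans.append((start, start + w))
    if spans and (spans[0][0] < 0 or spans[-1][1] > L):
        raise ValueError("conserved blocks do not fit in the protein")
    if any(s2 < e1 for (_, e1), (s2, _) in zip(spans, spans[1:])):
        raise ValueError("conserved blocks overlap")
    return spans


def simulate_parent_family(cfg: SimFamilyConfig) -> FamilySim:
    """Draw an ungapped ortholog family with planted conserved blocks.

    Inside blocks every parent copies a common ancestor; outside, parent i
    copies the ancestor with probability q_i (and otherwise mutates
    uniformly), with the q_i spaced so that realized overall pairwise
    identities span the configured band.  CDSs are back-generated with
    uniform synonymous codons.
    """
    rng = _rng(cfg.seed, "family")
    L = cfg.protein_length
    spans = _block_layout(cfg)
    in_block = np.zeros(L, dtype=bool)
    for s, e in spans:
        in_block[s:e] = True
    frac_block = in_block.mean()

    lo, hi = cfg.identity_band
    t_lo = (lo - frac_block) / (1 - frac_block)
    t_hi = (hi - frac_block) / (1 - frac_block)
    if t_lo <= 0:
        raise ValueError(
            "identity band lower edge is below the conserved-block floor"
        )
    q = np.linspace(
        _copy_prob_for_identity(t_lo), _copy_prob_for_identity(t_hi), cfg.n_parents
    )

    ancestor = rng.choice(list(_AA), size=L)
    codons = _codon_map()
    parents = []
    rows = []
    for i in range(cfg.n_parents):
        copy = rng.random(L) < q[i]
        seq = ancestor.copy()
        mutate = ~copy & ~in_block
        for pos in np.flatnonzero(mutate):
            alternatives = [a for a in _AA if a != ancestor[pos]]
            seq[pos] = alternatives[rng.integers(len(alternatives))]
        protein = "".join(seq)
        cds = "".join(
            codons[aa][rng.integers(len(codons[aa]))] for aa in protein
        )
        pid = f"P{i + 1:02d}"
        parents.append(
            ParentRecord(id=pid, protein_seq=protein, cds_seq=cds)
        )
        rows.append((pid, protein))
    msa = Msa(rows=tuple(rows))
    return FamilySim(
        parents=tuple(parents),
        msa=msa,
        block_spans=tuple((s + 1, e) for s, e in spans),
        block_centers=tuple((s + e + 1) // 2 for s, e in spans),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# PAM screen


@dataclass(frozen=True)
class SimPamConfig:
    """Paired PAM-library samples with planted functional-PAM depletion."""

    functional_pam_set: tuple[str, ...] = ("TTTA", "TTTC", "TTTG")  # TTTV
    depletion_factor: float = 0.01
    n_reads: int = 100_000
    upstream_anchor: str = "TGGCACGT"
    downstream_anchor: str = "GATCCTGA"
    error_rate: float = 0.001
    pam_len: int = 4
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.depletion_factor <= 1:
            raise ValueError("depletion_factor must be in (0, 1]")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if any(len(p) != self.pam_len for p in self.functional_pam_set):
            raise ValueError("functional PAMs must match pam_len")


@dataclass(frozen=True)
class PamScreenSim:
    targeting_reads: list[str]
    nontargeting_reads: list[str]
    truth: dict[str, object] = field(default_factory=dict)
    config: SimPamConfig | None = None


def _reads_from_pams(
    pam_idx: np.ndarray,
    space: list[str],
    cfg: SimPamConfig,
    rng: np.random.Generator,
) -> list[str]:
    """Assemble anchor+PAM+anchor reads and apply uniform base errors."""
    up = np.frombuffer(cfg.upstream_anchor.encode(), dtype=np.uint8)
    down = np.frombuffer(cfg.downstream_anchor.encode(), dtype=np.uint8)
    pam_bytes = np.frombuffer(
        "".join(space).encode(), dtype=np.uint8
    ).reshape(len(space), cfg.pam_len)
    n = len(pam_idx)
    reads = np.empty((n, len(up) + cfg.pam_len + len(down)), dtype=np.uint8)
    reads[:, : len(up)] = up
    reads[:, len(up) : len(up) + cfg.pam_len] = pam_bytes[pam_idx]
    reads[:, len(up) + cfg.pam_len :] = down
    if cfg.error_rate > 0:
        nt = np.frombuffer(_NT.encode(), dtype=np.uint8)
        code = np.zeros(256, dtype=np.int64)
        for i, b in enumerate(_NT):
            code[ord(b)] = i
        err = rng.random(reads.shape) < cfg.error_rate
        shift = rng.integers(1, 4, size=int(err.sum()))
        reads[err] = nt[(code[reads[err]] + shift) % 4]
    flat = reads.tobytes().decode("ascii")
    w = reads.shape[1]
    return [flat[i * w : (i + 1) * w] for i in range(n)]


def simulate_pam_screen(cfg: SimPamConfig) -> PamScreenSim:
    """Draw paired read sets; functional PAMs depleted in the targeting one.

    The non-targeting sample is multinomial-uniform over the 4^k PAM space;
    the targeting sample down-weights each functional PAM by
    ``depletion_factor`` before renormalizing.  Reads are
    anchor + PAM + anchor with independent uniform substitution errors.
    """
    rng = _rng(cfg.seed, "pam")
    space = all_pams(cfg.pam_len)
    k = len(space)
    functional = set(cfg.functional_pam_set)
    unknown = functional - set(space)
    if unknown:
        raise ValueError(f"functional PAMs outside the PAM space: {unknown}")
    w_target = np.array(
        [cfg.depletion_factor if p in functional else 1.0 for p in space]
    )
    w_target /= w_target.sum()
    w_control = np.full(k, 1.0 / k)
    idx_t = rng.choice(k, size=cfg.n_reads, p=w_target)
    idx_n = rng.choice(k, size=cfg.n_reads, p=w_control)
    return PamScreenSim(
        targeting_reads=_reads_from_pams(idx_t, space, cfg, rng),
        nontargeting_reads=_reads_from_pams(idx_n, space, cfg, rng),
        truth={
            "functional_pams": tuple(sorted(functional)),
            "targeting_weights": dict(zip(space, w_target)),
        },
        config=cfg,
    )


# ---------------------------------------------------------------------------
# colony counts


@dataclass(frozen=True)
class SimColonyConfig:
    true_efficiency: float = 0.5
    n_plated: int = 100
    kind: str = "killing"  # or "color"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.true_efficiency <= 1:
            raise ValueError("true_efficiency must be in [0, 1]")
        if self.n_plated <= 0:
            raise ValueError("n_plated must be positive")
        if self.kind not in ("killing", "color"):
            raise ValueError("kind must be 'killing' or 'color'")


def simulate_colony_counts(
    cfg: SimColonyConfig,
) -> ColonyCounts | ColorScreenCounts:
    """Binomial colony counts at the configured true efficiency.

    ``killing``: survivors under the targeting guide are
    Binomial(n_plated, 1 - efficiency) against a full control plate.
    ``color``: white (edited) colonies are Binomial(n_plated, efficiency).
    """
    rng = _rng(cfg.seed, "colony")
    if cfg.kind == "killing":
        a = int(rng.binomial(cfg.n_plated, 1 - cfg.true_efficiency))
        return ColonyCounts(a=a, b=cfg.n_plated)
    white = int(rng.binomial(cfg.n_plated, cfg.true_efficiency))
    return ColorScreenCounts(edited=white, unedited=cfg.n_plated - white)


# ---------------------------------------------------------------------------
# off-target site tables


@dataclass(frozen=True)
class SimOffTargetConfig:
    """Read allocation over an on-target site and mismatched decoys.

    ``propensity[k]`` is the relative cleavage propensity of a site with k
    mismatches; it must be nonincreasing in k.
    """

    guide: str = "GATTACAGATTACAGATTAC"
    propensity: tuple[float, ...] = (1.0, 0.05, 0.01, 0.002, 0.0005)
    n_total_reads: int = 10_000
    n_decoy_sites: int = 8
    seed: int = 0

    def __post_init__(self):
        if any(
            a < b for a, b in zip(self.propensity, self.propensity[1:])
        ):
            raise ValueError("propensity must be nonincreasing in mismatches")
        if self.n_total_reads <= 0 or self.n_decoy_sites < 0:
            raise ValueError("need positive reads and nonnegative decoys")


@dataclass(frozen=True)
class OffTargetSim:
    table: SiteCountTable
    true_off_fraction: float
    decoy_mismatches: tuple[int, ...]
    config: SimOffTargetConfig


def simulate_offtarget_table(cfg: SimOffTargetConfig) -> OffTargetSim:
    """Allocate reads multinomially by mismatch-dependent propensity.

    Decoy sites carry 1..4 substitutions relative to the guide (cycling);
    the true off-target share recorded in the truth is the propensity-mass
    fraction, i.e. the expectation of the measured share at min_reads=0.
    """
    rng = _rng(cfg.seed, "offtarget")
    guide = cfg.guide.upper()
    max_mm = len(cfg.propensity) - 1
    decoys = []
    mismatches = []
    for s in range(cfg.n_decoy_sites):
        k = 1 + s % max_mm
        pos = rng.choice(len(guide), size=k, replace=False)
        site = list(guide)
        for p in pos:
            site[p] = _NT[(_NT.index(site[p]) + int(rng.integers(1, 4))) % 4]
        decoys.append("".join(site))
        mismatches.append(k)
    weights = np.array(
        [cfg.propensity[0]] + [cfg.propensity[k] for k in mismatches]
    )
    if weights.sum() == 0:
        raise ValueError("all propensities are zero")
    reads = rng.multinomial(cfg.n_total_reads, weights / weights.sum())
    table = SiteCountTable(
        target_sequence=guide,
        on_target_reads=int(reads[0]),
        off_target_sites=tuple(
            (site, int(n)) for site, n in zip(decoys, reads[1:])
        ),
    )
    true_off = float(weights[1:].sum() / weights.sum())
    return OffTargetSim(
        table=table,
        true_off_fraction=true_off,
        decoy_mismatches=tuple(mismatches),
        config=cfg,
    )
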