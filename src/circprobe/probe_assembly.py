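"""Junction validation, even-site selection, and circular-probe assembly.

Joining two 20-mer arms head-to-tail creates up to 15 new 16-mers that
span the boundary and exist in neither arm alone; these must also be
absent from the host index or the joint itself could hybridize to host
RNA. The default junction mode checks all 15 spanning 16-mers
(conservative superset); "center" mode checks only the single 16-mer
centred on the boundary (8 bases either side).

Four arms are chosen so their positions are spread evenly across the
target: ideal anchor centres sit at the four quartile midpoints
((i + 0.5)/4 * L for i = 0..3), each anchor greedily prefers the valid
site whose centre is nearest (leftmost start breaking ties), and a
deterministic backtracking search over these preference orders returns
the first quartet whose four junctions — three internal plus the
wrap-around from the last arm back to the first, since the ligated
probe is circular — are all clean. The probe is the 80-nt concatenation
of the four arms in genomic order; the reverse complement is the strand
actually synthesized and ligated (it is the strand complementary to the
target RNA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .candidate_filter import ARM_LENGTH, CandidateSite
from .errors import DesignFailure, InputError
from .kmer_index import K, HostIndex, encode_kmer
from .sequences import reverse_complement

N_ARMS = 4
PROBE_LENGTH = N_ARMS * ARM_LENGTH  # 80 nt, at the bottom of the
# 80-100 nt window the single-stranded circularization chemistry accepts

# starts (within the 40-nt pairwise concatenation) of 16-mers that
# cross the arm boundary at offset 20
_ALL_SPANNING_STARTS = tuple(range(ARM_LENGTH - K + 1, ARM_LENGTH))  # 5..19
_CENTER_START = ARM_LENGTH - K // 2  # 12: 8 bases either side of the joint


@dataclass(frozen=True)
class JunctionCheck:
    """Outcome of screening one head-to-tail joint against the host index."""

    left_start: int
    right_start: int
    checked_codes: tuple[int, ...]
    clean: bool


@dataclass(frozen=True)
class ProbeDesign:
    """A complete four-arm circular probe design."""

    target_id: str
    sites: tuple[CandidateSite, ...]  # 4 sites, ascending start
    probe_sequence: str  # 80-nt target-sense concatenation
    probe_revcomp: str  # the synthesis/ligation strand
    arm_revcomps: tuple[str, ...]
    junctions: tuple[JunctionCheck, ...]  # 3 internal + 1 wrap-around


def junction_spanning_starts(mode: str) -> tuple[int, ...]:
    if mode == "all":
        return _ALL_SPANNING_STARTS
    if mode == "center":
        return (_CENTER_START,)
    raise InputError(f"unknown junction mode {mode!r}")


def junction_clean(
    index: HostIndex,
    left: CandidateSite,
    right: CandidateSite,
    mode: str = "all",
) -> JunctionCheck:
    """Screen the 16-mers spanning the joint of left+right against the host."""
    joined = left.sequence + right.sequence
    codes = tuple(
        encode_kmer(joined[s : s + K]) for s in junction_spanning_starts(mode)
    )
    clean = not index.contains_any(codes)
    return JunctionCheck(
        left_start=left.start,
        right_start=right.start,
        checked_codes=codes,
        clean=clean,
    )


def _overlaps(a: CandidateSite, b: CandidateSite) -> bool:
    return abs(a.start - b.start) < ARM_LENGTH


def _quartet_junctions(
    index: HostIndex, ordered: Sequence[CandidateSite], mode: str
) -> tuple[JunctionCheck, ...]:
    """Three internal joints in genomic order plus the wrap-around joint."""
    pairs = [(ordered[i], ordered[i + 1]) for i in range(N_ARMS - 1)]
    pairs.append((ordered[-1], ordered[0]))
    return tuple(junction_clean(index, a, b, mode) for a, b in pairs)


def assemble_probe(
    sites: Sequence[CandidateSite], junctions: Sequence[JunctionCheck]
) -> ProbeDesign:
    """Concatenate four clean-junction arms into the 80-nt circular probe."""
    if len(sites) != N_ARMS:
        raise DesignFailure(f"need exactly {N_ARMS} sites, got {len(sites)}")
    starts = [s.start for s in sites]
    if starts != sorted(starts):
        raise DesignFailure("sites must be in ascending start order")
    for a, b in zip(sites, sites[1:]):
        if _overlaps(a, b):
            raise DesignFailure(
                f"sites at {a.start} and {b.start} overlap (need >= {ARM_LENGTH} apart)"
            )
    if len(junctions) != N_ARMS:
        raise DesignFailure(f"need {N_ARMS} junction checks, got {len(junctions)}")
    dirty = [j for j in junctions if not j.clean]
    if dirty:
        raise DesignFailure(
            f"assembly refused: junction {dirty[0].left_start}->{dirty[0].right_start} "
            "shares a 16-mer with the host"
        )
    probe = "".join(s.sequence for s in sites)
    assert len(probe) == PROBE_LENGTH
    return ProbeDesign(
        target_id=sites[0].target_id,
        sites=tuple(sites),
        probe_sequence=probe,
        probe_revcomp=reverse_complement(probe),
        arm_revcomps=tuple(reverse_complement(s.sequence) for s in sites),
        junctions=tuple(junctions),
    )


def select_even_sites(
    valid_sites: Sequence[CandidateSite],
    target_length: int,
    index: HostIndex,
    mode: str = "all",
) -> ProbeDesign:
    """Pick 4 evenly spread, junction-clean sites; deterministic.

    Preference orders are fixed by (distance to anchor, start); the
    backtracking search returns the lexicographically best feasible
    assignment under that key, so identical inputs always give the
    identical design. Raises :class:`DesignFailure`, naming the
    limiting constraint, when no quartet works.
    """
    sites = sorted(valid_sites, key=lambda s: s.start)
    if len(sites) < N_ARMS:
        raise DesignFailure(
            f"only {len(sites)} valid candidate sites; {N_ARMS} non-overlapping "
            "sites are required"
        )
    anchors = [((i + 0.5) / N_ARMS) * target_length for i in range(N_ARMS)]
    ranked = [
        sorted(sites, key=lambda s, a=a: (abs(s.center - a), s.start))
        for a in anchors
    ]

    saw_complete_quartet = False
    chosen: list[CandidateSite] = []

    def search(anchor_i: int) -> ProbeDesign | None:
        nonlocal saw_complete_quartet
        if anchor_i == N_ARMS:
            saw_complete_quartet = True
            ordered = sorted(chosen, key=lambda s: s.start)
            junctions = _quartet_junctions(index, ordered, mode)
            if all(j.clean for j in junctions):
                return assemble_probe(ordered, junctions)
            return None
        for site in ranked[anchor_i]:
            if any(_overlaps(site, c) for c in chosen):
                continue
            chosen.append(site)
            design = search(anchor_i + 1)
            if design is not None:
                return design
            chosen.pop()
        return None

    design = search(0)
    if design is not None:
        return design
    if saw_complete_quartet:
        raise DesignFailure(
            "every non-overlapping quartet of valid sites failed junction "
            "screening against the host index"
        )
    raise DesignFailure(
        f"fewer than {N_ARMS} mutually non-overlapping valid sites"
    )


AVG_NT_MW_PG_PER_PMOL = 330.0


@dataclass(frozen=True)
class QuantInput:
    """Inputs for converting a mass concentration to molarity."""

    conc_ug_per_ml: float
    n_nt: int
    avg_nt_mw: float = AVG_NT_MW_PG_PER_PMOL

    def moles_per_microliter(self) -> float:
        return moles_per_microliter(self.conc_ug_per_ml, self.n_nt, self.avg_nt_mw)


def moles_per_microliter(
    conc_ug_per_ml: float, n_nt: int, avg_nt_mw: float = AVG_NT_MW_PG_PER_PMOL
) -> float:
    """pmol/uL of an N-nucleotide oligo from its ug/mL concentration.

    (ug/mL) x (mL / 1000 uL) x (pmol / 330 pg) x (1e6 pg / ug) x (1/N),
    where 330 pg/pmol is the average molecular weight of one nucleotide.
    """
    if n_nt < 1:
        raise InputError(f"nucleotide count must be >= 1, got {n_nt}")
    if conc_ug_per_ml < 0:
        raise InputError("concentration must be non-negative")
    return (conc_ug_per_ml / 1000.0) * (1.0 / avg_nt_mw) * 1e6 / n_nt
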