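"""Seeded host/target sequence pairs with planted shared 16-mers.

The generator emulates the inputs of the probe-design workflow: a host
transcriptome sequence and a target (viral) mRNA. Both are i.i.d.
random bases at a configurable GC fraction; additionally, a requested
number of 16-mers are copied verbatim from random host positions into
recorded target positions. Plants are spaced at least 20 nt apart so
the 20-mer starts each plant invalidates — ``[p-4, p]`` clipped to the
target — are disjoint and exactly predictable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .candidate_filter import ARM_LENGTH, CandidateSite
from .errors import FixtureSpecError, InputError
from .kmer_index import K
from .sequences import NucSequence, write_fasta

MIN_PLANT_GAP = ARM_LENGTH  # >= 20 nt between plants: disjoint rejection windows


@dataclass(frozen=True)
class FixtureSpec:
    host_length: int = 10_000
    target_length: int = 1_000
    n_planted_shared: int = 0
    gc_bias: float = 0.5
    seed: int = 0
    planted_positions: tuple[int, ...] = ()  # filled in by generate_pair


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def _plant_positions(
    rng: np.random.Generator, n: int, target_length: int
) -> list[int]:
    # place n plants with >= MIN_PLANT_GAP between consecutive plant ends
    span = n * K + (n - 1) * MIN_PLANT_GAP if n else 0
    slack = target_length - span
    if n and slack < 0:
        raise FixtureSpecError(
            f"cannot place {n} non-overlapping 16-mer plants (>= {MIN_PLANT_GAP} nt "
            f"apart) in a {target_length}-nt target"
        )
    if not n:
        return []
    gaps = rng.multinomial(slack, [1.0 / (n + 1)] * (n + 1))
    positions = []
    cursor = 0
    for i in range(n):
        cursor += int(gaps[i])
        positions.append(cursor)
        cursor += K + MIN_PLANT_GAP
    return positions


def generate_pair(
    spec: FixtureSpec,
) -> tuple[NucSequence, NucSequence, FixtureSpec]:
    """Deterministic (host, target, truth) triple for a given seed."""
    if spec.host_length < ARM_LENGTH or spec.target_length < ARM_LENGTH:
        raise FixtureSpecError(f"lengths must be >= {ARM_LENGTH}")
    if not 0.0 < spec.gc_bias < 1.0:
        raise FixtureSpecError("gc_bias must be in (0, 1)")
    rng = np.random.default_rng(spec.seed)
    host_residues = _random_bases(rng, spec.host_length, spec.gc_bias)
    target = list(_random_bases(rng, spec.target_length, spec.gc_bias))
    positions = _plant_positions(rng, spec.n_planted_shared, spec.target_length)
    sources = rng.integers(0, spec.host_length - K + 1, size=len(positions))
    for pos, src in zip(positions, sources):
        target[pos : pos + K] = host_residues[src : src + K]
    host = NucSequence(id="host", residues=host_residues)
    target_seq = NucSequence(id="target", residues="".join(target))
    truth = replace(spec, planted_positions=tuple(positions))
    return host, target_seq, truth


def rejection_window(plant_pos: int, target_length: int) -> range:
    """20-mer starts whose window fully contains the plant at ``plant_pos``."""
    lo = max(0, plant_pos - (ARM_LENGTH - K))
    hi = min(plant_pos, target_length - ARM_LENGTH)
    return range(lo, hi + 1)


def truth_eval(
    truth: FixtureSpec, candidates: Sequence[CandidateSite]
) -> dict[str, int]:
    """Confusion counts of host-exclusion decisions vs planted ground truth.

    A candidate "should" be rejected iff its window fully contains a
    planted 16-mer. ``falsely_retained`` must always be 0 (soundness);
    ``falsely_rejected`` can only arise from chance 16-mer collisions
    between the random parts of the two sequences.
    """
    should_reject = set()
    for pos in truth.planted_positions:
        should_reject.update(rejection_window(pos, truth.target_length))
    counts = {
        "correctly_rejected": 0,
        "falsely_rejected": 0,
        "correctly_retained": 0,
        "falsely_retained": 0,
    }
    for site in candidates:
        if site.host_clean is None:
            raise InputError(
                "candidates must have host_clean evaluated before truth_eval"
            )
        planted = site.start in should_reject
        if not site.host_clean:
            counts["correctly_rejected" if planted else "falsely_rejected"] += 1
        else:
            counts["falsely_retained" if planted else "correctly_retained"] += 1
    return counts


def write_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Emit host.fa, target.fa and truth.json into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    host, target, truth = generate_pair(spec)
    paths = {
        "host": out_dir / "host.fa",
        "target": out_dir / "target.fa",
        "truth": out_dir / "truth.json",
    }
    write_fasta([(host.id, host.residues)], paths["host"])
    write_fasta([(target.id, target.residues)], paths["target"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "host_length": truth.host_length,
                "target_length": truth.target_length,
                "n_planted_shared": truth.n_planted_shared,
                "gc_bias": truth.gc_bias,
                "seed": truth.seed,
                "planted_positions": list(truth.planted_positions),
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    return paths
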