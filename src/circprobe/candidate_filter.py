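"""Enumeration and screening of candidate 20-mer probe-arm sites.

The target mRNA is cut into overlapping 20-mers (step 1, i.e. 19-base
overlap). Each 20-mer is screened in two independent stages:

* **host exclusion** — the 20-mer is decomposed into its five
  constituent 16-mers (starts 0..4); the candidate survives only if
  none of the five occurs anywhere in the host index. This guarantees
  that no 16-mer of a selected arm can hybridize exactly to host RNA.
* **composition** — GC fraction, annealing temperature, a 3'-terminal
  G/C clamp, and the longest homopolymer run are checked against
  configurable thresholds.

Failed checks are recorded per site by name so reports can explain
every rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from pathlib import Path
from typing import Iterable

import yaml

from .errors import ConfigError, InputError
from .kmer_index import K, HostIndex, encode_kmer
from .sequences import DNA_ALPHABET, NucSequence

ARM_LENGTH = 20
SUBKMERS_PER_ARM = ARM_LENGTH - K + 1  # five 16-mers per 20-mer

TM_METHODS = ("gc_adjusted", "wallace")
JUNCTION_MODES = ("all", "center")


@dataclass(frozen=True)
class FilterConfig:
    """Tunable thresholds for composition screening and junction mode.

    Defaults reflect common short-oligo design practice: GC in
    [0.40, 0.60], Tm by the GC-adjusted formula in [50, 65] degC
    (bracketing the 57-60 degC working temperature of the isothermal
    assay), homopolymer runs capped at 4, and a G/C clamp required at
    the 3' terminus.
    """

    gc_min: float = 0.40
    gc_max: float = 0.60
    tm_method: str = "gc_adjusted"
    tm_min: float = 50.0
    tm_max: float = 65.0
    max_homopolymer_run: int = 4
    require_strong_3prime: bool = True
    junction_mode: str = "all"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_min <= self.gc_max <= 1.0:
            raise ConfigError(
                f"need 0 <= gc_min <= gc_max <= 1, got {self.gc_min}, {self.gc_max}"
            )
        if self.tm_min > self.tm_max:
            raise ConfigError(f"tm_min {self.tm_min} > tm_max {self.tm_max}")
        if self.max_homopolymer_run < 1:
            raise ConfigError("max_homopolymer_run must be >= 1")
        if self.tm_method not in TM_METHODS:
            raise ConfigError(f"unknown tm_method {self.tm_method!r}")
        if self.junction_mode not in JUNCTION_MODES:
            raise ConfigError(f"unknown junction_mode {self.junction_mode!r}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "FilterConfig":
        """Build from flat keys; unknown keys are rejected."""
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_mapping(data)


@dataclass
class CandidateSite:
    """One 20-nt window of the target with metrics and screening flags."""

    target_id: str
    start: int  # 0-based offset into the target
    sequence: str
    gc_fraction: float
    tm_celsius: float
    max_homopolymer: int
    host_clean: bool | None = None
    composition_pass: bool | None = None
    fail_reasons: list[str] = field(default_factory=list)

    @property
    def end(self) -> int:
        """Half-open end coordinate."""
        return self.start + ARM_LENGTH

    @property
    def center(self) -> float:
        return self.start + ARM_LENGTH / 2


def gc_fraction(seq: str) -> float:
    """(#G + #C) / length."""
    if not seq:
        raise InputError("cannot compute GC fraction of an empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(seq: str, method: str = "gc_adjusted") -> float:
    """Oligo annealing temperature in degC.

    gc_adjusted: 64.9 + 41*(nG + nC - 16.4)/N (length-corrected GC rule);
    wallace: 2*(nA + nT) + 4*(nG + nC) (rule of thumb for short oligos).
    """
    if not seq:
        raise InputError("cannot compute Tm of an empty sequence")
    n_gc = seq.count("G") + seq.count("C")
    n = len(seq)
    if method == "gc_adjusted":
        return 64.9 + 41.0 * (n_gc - 16.4) / n
    if method == "wallace":
        return 2.0 * (n - n_gc) + 4.0 * n_gc
    raise ConfigError(f"unknown tm_method {method!r}")


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of a single repeated base."""
    if not seq:
        raise InputError("empty sequence has no homopolymer run")
    return max(len(list(group)) for _, group in groupby(seq))


def subkmer_codes(seq: str) -> list[int]:
    """Codes of the five constituent 16-mers of a 20-mer (starts 0..4)."""
    if len(seq) != ARM_LENGTH:
        raise InputError(f"expected a {ARM_LENGTH}-mer, got length {len(seq)}")
    return [encode_kmer(seq[i : i + K]) for i in range(SUBKMERS_PER_ARM)]


def _make_site(target_id: str, start: int, seq: str, cfg: FilterConfig) -> CandidateSite:
    return CandidateSite(
        target_id=target_id,
        start=start,
        sequence=seq,
        gc_fraction=gc_fraction(seq),
        tm_celsius=melting_temperature(seq, cfg.tm_method),
        max_homopolymer=max_homopolymer_run(seq),
    )


def enumerate_candidates(
    target: NucSequence, cfg: FilterConfig | None = None
) -> list[CandidateSite]:
    """One candidate per start in [0, L-20]; non-ACGT windows skipped."""
    cfg = cfg or FilterConfig()
    residues = target.residues
    if len(residues) < ARM_LENGTH:
        raise InputError(
            f"target {target.id!r} is {len(residues)} nt; need >= {ARM_LENGTH}"
        )
    sites = []
    for start in range(len(residues) - ARM_LENGTH + 1):
        window = residues[start : start + ARM_LENGTH]
        if set(window) <= DNA_ALPHABET:
            sites.append(_make_site(target.id, start, window, cfg))
    return sites


def is_host_clean(index: HostIndex, site: CandidateSite) -> bool:
    """True iff none of the site's five 16-mers occurs in the host index."""
    clean = not index.contains_any(subkmer_codes(site.sequence))
    site.host_clean = clean
    if not clean and "host" not in site.fail_reasons:
        site.fail_reasons.append("host")
    return clean


def passes_composition(site: CandidateSite, cfg: FilterConfig) -> bool:
    """Apply GC / Tm / homopolymer / 3'-clamp checks; record failures."""
    reasons = []
    if not cfg.gc_min <= site.gc_fraction <= cfg.gc_max:
        reasons.append("gc")
    if not cfg.tm_min <= site.tm_celsius <= cfg.tm_max:
        reasons.append("tm")
    if site.max_homopolymer > cfg.max_homopolymer_run:
        reasons.append("homopolymer")
    if cfg.require_strong_3prime and site.sequence[-1] not in "GC":
        reasons.append("3prime_clamp")
    site.composition_pass = not reasons
    for reason in reasons:
        if reason not in site.fail_reasons:
            site.fail_reasons.append(reason)
    return site.composition_pass


def evaluate_candidates(
    index: HostIndex, target: NucSequence, cfg: FilterConfig | None = None
) -> list[CandidateSite]:
    """All candidate windows with host and composition flags populated."""
    cfg = cfg or FilterConfig()
    sites = enumerate_candidates(target, cfg)
    for site in sites:
        is_host_clean(index, site)
        passes_composition(site, cfg)
    return sites


def filter_candidates(
    index: HostIndex, target: NucSequence, cfg: FilterConfig | None = None
) -> list[CandidateSite]:
    """Host-clean, composition-passing sites in ascending start order."""
    return [
        s
        for s in evaluate_candidates(index, target, cfg)
        if s.host_clean and s.composition_pass
    ]


def write_candidate_report(sites: Iterable[CandidateSite], path: str | Path) -> None:
    """TSV report of every evaluated window with metrics and fail reasons."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "target_id",
                "start",
                "end",
                "sequence",
                "gc",
                "tm",
                "max_run",
                "host_clean",
                "composition_pass",
                "fail_reasons",
            ]
        )
        for s in sites:
            writer.writerow(
                [
                    s.target_id,
                    s.start,
                    s.end,
                    s.sequence,
                    f"{s.gc_fraction:.2f}",
                    f"{s.tm_celsius:.2f}",
                    s.max_homopolymer,
                    s.host_clean,
                    s.composition_pass,
                    ",".join(s.fail_reasons),
                ]
            )
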