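"""Writers for probe-design outputs (FASTA records, TSV design report)."""

from __future__ import annotations

import csv
from pathlib import Path

from .probe_assembly import ProbeDesign
from .sequences import write_fasta


def write_design(
    design: ProbeDesign, fasta_path: str | Path, tsv_path: str | Path
) -> None:
    """Write the design as FASTA + TSV; repeated writes are byte-identical.

    FASTA records: probe, probe_revcomp, arm_1..4, arm_revcomp_1..4.
    TSV: one row per arm with coordinates, metrics, and the result of
    the junction check from that arm to the next (arm 4 wraps to arm 1).
    """
    records = [
        ("probe", design.probe_sequence),
        ("probe_revcomp", design.probe_revcomp),
    ]
    for i, site in enumerate(design.sites, start=1):
        records.append((f"arm_{i}", site.sequence))
    for i, rc in enumerate(design.arm_revcomps, start=1):
        records.append((f"arm_revcomp_{i}", rc))
    write_fasta(records, fasta_path)

    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "arm",
                "target_id",
                "start",
                "end",
                "sequence",
                "gc",
                "tm",
                "max_run",
                "junction_to_next_clean",
                "junction_kmers_checked",
            ]
        )
        for i, (site, junction) in enumerate(
            zip(design.sites, design.junctions), start=1
        ):
            writer.writerow(
                [
                    i,
                    site.target_id,
                    site.start,
                    site.end,
                    site.sequence,
                    f"{site.gc_fraction:.2f}",
                    f"{site.tm_celsius:.2f}",
                    site.max_homopolymer,
                    junction.clean,
                    len(junction.checked_codes),
                ]
            )
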