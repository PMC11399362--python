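# Methods

## Model of probe specificity

The unit of cross-hybridization risk is the exact 16-mer: a probe whose
every 16-mer is absent from the host transcriptome cannot form a
perfect 16-bp duplex with host RNA anywhere. `circprobe` therefore
reduces specificity to exact set membership over the 4¹⁶ = 2³² possible
16-mers, which is decidable with one bit per code: a 512 MiB bitmap,
independent of host size. This is an exact index — no false positives
or negatives, unlike Bloom-filter or minimizer sketches — and the
deliberate trade is memory for certainty. Only exact 16-mer sharing is
modelled: near-matches with mismatches, thermodynamic duplex energies
and secondary structure (hairpins, probe dimers) are out of scope.

Probe arms are 20-mers, so each candidate arm contains exactly
20 − 16 + 1 = 5 constituent 16-mers, and an arm is host-clean iff all
five are absent. A shared 16-mer at target position *p* therefore
invalidates exactly the 20-mer starts in [*p*−4, *p*] (clipped to
[0, L−20]) — the property the synthetic fixtures are built to test.

Only the sense strand of the host is indexed and only the sense strand
of the target is tiled, matching an RNA-vs-RNA exclusion model; the
probe's reverse complement (the synthesized strand) is derived at the
end rather than screened separately, since its 16-mer content is
determined by the sense design.

## Encoding and persistence

Bases pack 2 bits each (A=00, C=01, G=10, T=11), first base in the most
significant pair, so numeric order of codes coincides with
lexicographic order of 16-mers. Windows containing any non-ACGT letter
(N and other IUPAC codes survive ingest) are skipped while the window
position still advances, so real transcriptome FASTA files are usable
without preprocessing; `U` is mapped to `T` at ingest so one DNA
alphabet serves RNA input and DNA probe chemistry.

The on-disk index is a 24-byte header (magic `ROAIDX`, format version,
k, sequence count, distinct-code count) followed by the raw bitmap,
bit *j* of byte *i* holding code *i*·8+*j*. The layout is fixed so a
saved index round-trips bit-exactly across machines. A hash-set backend
(`backend="set"`) gives identical answers with memory proportional to
content; it exists for small jobs and fast tests, and the 512 MiB size
statement applies to the default bitmap backend.

## Filter parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `gc_min`–`gc_max` | 0.40–0.60 | fraction | standard short-oligo design window |
| `tm_method` | `gc_adjusted` | — | 64.9 + 41·(n_GC − 16.4)/N; `wallace` (2·AT + 4·GC) available |
| `tm_min`–`tm_max` | 50–65 | °C | brackets the 57–60 °C working temperature of the isothermal reaction |
| `max_homopolymer_run` | 4 | nt | common primer-design cap; long runs cause synthesis/slippage artifacts |
| `require_strong_3prime` | on | — | G/C clamp at the 3′ terminus of each arm |
| `junction_mode` | `all` | — | screen all 15 boundary-spanning 16-mers; `center` screens only the 8+8 16-mer |

None of the numeric thresholds is a claim about the assay; they are
configurable design choices (YAML config or keyword arguments), and
widening any interval can only add candidates (monotonicity is a tested
property). "3′-end specific base" is interpreted as a G/C clamp, the
common reading; it can be switched off. The junction default `all` is
the conservative superset of the single-16-mer check: any 16-mer
created by the joint and present in the host would make the assembled
circle locally host-like, so screening all fifteen spanning 16-mers is
strictly safer than screening one.

## Site selection

"Evenly distributed" is made precise as: ideal anchor centres at
((i + 0.5)/4)·L for i = 0..3; each anchor ranks valid sites by
(|site centre − anchor|, start); a depth-first backtracking search over
these preference orders accepts the first quartet that is pairwise
non-overlapping (start difference ≥ 20 — no larger minimum gap is
imposed) and whose four junctions are clean. Because preference orders
are total (the start tie-break) and the search order is fixed, the
result is the lexicographic minimum of the per-anchor
(distance, start) vector over all feasible quartets — reproducible, and
verified against exhaustive search in the tests. The four junctions are
the three internal joints in genomic order plus the wrap-around joint
from the last arm back to the first: the ligated probe is a circle, so
that boundary exists chemically even though pairwise joining alone
would not create it. Arms are concatenated with no spacer bases; the
4 × 20 = 80-nt result sits at the bottom of the 80–100 nt substrate
window of the single-stranded ligation chemistry.

Degenerate inputs: fewer than four valid sites, no pairwise
non-overlapping quartet, and "every quartet has a dirty junction" are
distinct `DesignFailure` messages (CLI exit code 3) so the limiting
constraint is visible.

## Quantity conversion

pmol/µL = (µg/mL) × (mL/1000 µL) × (pmol/330 pg) × (10⁶ pg/µg) / N for
an N-nucleotide oligo, with 330 pg/pmol the average single-nucleotide
molecular weight. The conversion is a product of exact factors, so it
inverts to floating-point precision; the tests require 1 × 10⁻¹²
relative round-trip error.

## Synthetic fixtures

`FixtureSpec` generates a host/target pair: i.i.d. random bases at a
configurable GC fraction (default 0.5, host 10 kb, target 1 kb —
transcript-scale sequences that keep every test oracle-checkable by
brute force), plus a requested number of 16-mers copied verbatim from
random host positions into recorded target positions. Plants are spaced
≥ 20 nt apart so their rejection windows are disjoint and exactly
predictable. The test suite itself runs on a 3 kb host / 600 nt target
pair with three plants.

Two stochastic effects are expected and handled rather than suppressed:
a chance 16-mer collision between the random parts of host and target
(probability ≈ n_host·n_target/2³² per pair, negligible at these
sizes), and plant-boundary extension — the random base flanking a plant
matches the host base flanking its source with probability 1/4 per
side, creating one extra genuine shared 16-mer. `truth_eval` reports
such rejections as outside the planted window, and the tests verify
each one is explained by a real shared 16-mer via substring search.
What the generator does **not** emulate: real transcriptome k-mer
composition (repeats, low-complexity tracts, codon bias), splicing, or
expression levels. Passing tests demonstrate the algorithm's
correctness guarantees (exactness of membership, soundness of
exclusion, determinism of selection), not that four valid arms exist
for any particular real host/target combination — on real data the
composition filters or junction screening can legitimately leave no
feasible quartet, which the tool reports as a design failure.

## Problem sizes

The default test suite builds one 512 MiB bitmap in memory, writes one
index file through the CLI, and checks oracle equivalence on the
3 kb/600 nt pair with 1,000 random membership probes; the exhaustive
selection oracle runs on 10–12 sites (≤ 11,880 ordered quartets). The
acceptance script measures the bitmap built from a 10 kb host. All
brute-force oracles are kept at scales where they finish in seconds.
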