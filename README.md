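# circprobe

Design of four-arm circular (padlock-style) DNA probes for
rolling-circle amplification (RCA) assays, with exact host-transcriptome
exclusion.

## The problem

Isothermal RCA-based detection of a short RNA (a miRNA or a viral mRNA
fragment) hinges on one reagent: a single-stranded DNA circle whose
sequence is complementary to the target. If any stretch of the circle
can hybridize to abundant host RNA instead, the assay amplifies the
wrong template. `circprobe` designs that circle so that **no 16-mer of
the probe — including the new 16-mers created where two arms join —
occurs anywhere in the host transcriptome**, while each of its four
20-nt arms also satisfies standard oligo composition rules.

It is a library for people building RCA/padlock assays: the importable
API does the work, `examples/` shows each capability, and a thin
`circprobe` CLI wraps the common batch steps.

## The method

1. **Host index.** Every overlapping 16-mer of the host transcriptome
   (window step 1, i.e. 15-base overlap) is packed into a 32-bit code
   at 2 bits/base (A=00, C=01, G=10, T=11, first base most
   significant). Presence over the whole 2³² code space is stored in a
   bitmap of 2³² bits = **536,870,912 bytes (512 MB)** — constant no
   matter how many sequences are indexed — giving exact, O(1)
   membership. The index persists to disk for reuse.
2. **Candidate screening.** The target mRNA is cut into overlapping
   20-mers (19-base overlap). Each 20-mer is decomposed into its five
   constituent 16-mers; it survives only if none of the five is in the
   host index. Survivors are then filtered on GC fraction (default
   0.40–0.60), annealing temperature (default GC-adjusted
   Tm = 64.9 + 41·(n_GC − 16.4)/N in 50–65 °C; Wallace rule available),
   longest homopolymer run (≤ 4), and a 3′-terminal G/C clamp.
3. **Junction screening and assembly.** Joining arms head-to-tail
   creates up to 15 new boundary-spanning 16-mers; these are screened
   against the host index too (all 15 by default, or just the central
   8+8 16-mer in `center` mode). Four sites are selected near the
   quartile midpoints of the target — nearest valid site per anchor,
   deterministic backtracking until all four junctions (three internal
   plus the wrap-around of the circle) are clean — and concatenated in
   genomic order into the 80-nt probe. The reverse complement, the
   strand actually synthesized and ligated, is emitted alongside
   per-arm reverse complements.
4. **Quantity conversion.** For bench work,
   (µg/mL) × 10⁶ / (1000 × 330 × N) = pmol/µL, with 330 pg/pmol the
   average nucleotide weight of an N-nt oligo.

## Worked example

```sh
python examples/02_design_circular_probe.py
```

```
host 10000 nt, target 1000 nt, planted shared 16-mers at (231, 499, 755)
20-mer windows: 981  host-clean: 966  composition-pass: 240

arm start positions : [104, 362, 615, 864]
  arm_1 [ 104, 124)  GGTCACTCCTGACTATCGAG  GC=0.55  Tm=53.8C
  arm_2 [ 362, 382)  AATGGCGTCACTCTAGCGCG  GC=0.60  Tm=55.9C
  arm_3 [ 615, 635)  TGTCGCTCTCTGTATCAGAG  GC=0.50  Tm=51.8C
  arm_4 [ 864, 884)  CTCTCCATCGGCATCAAGGC  GC=0.60  Tm=55.9C

probe   (target sense, 80 nt):
  GGTCACTCCTGACTATCGAGAATGGCGTCACTCTAGCGCGTGTCGCTCTCTGTATCAGAGCTCTCCATCGGCATCAAGGC
probe reverse complement (synthesis/ligation strand):
  GCCTTGATGCCGATGGAGAGCTCTGATACAGAGAGCGACACGCGCTAGAGTGACGCCATTCTCGATAGTCAGGAGTGACC
all junctions host-clean: True
```

Of the 981 target windows, 15 are rejected because they contain one of
the three 16-mers deliberately shared with the synthetic host (each
shared 16-mer at position *p* kills exactly the window starts
*p−4 … p*), and 240 also pass composition. The four chosen arms sit
near the quartile midpoints (125, 375, 625, 875) of the 1,000-nt
target; the 80-nt probe is at the bottom of the 80–100 nt window the
single-stranded circularization chemistry accepts.

The same pipeline from a shell:

```sh
circprobe fixtures --host-length 10000 --target-length 1000 --plants 3 \
    --seed 7 --out-dir fx
circprobe build-index --host fx/host.fa --out host.roaidx
circprobe design --index host.roaidx --target fx/target.fa \
    --out probe.fa --report probe.tsv
circprobe quant --conc 3.3 --length 100    # -> 0.1 (pmol/uL)
```

Exit codes: 0 success, 2 input/config error, 3 design failure.

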