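"""Build the 512 MiB host 16-mer bitmap index and query it.

Generates a synthetic 10 kb host transcriptome, indexes every 16-mer
(2-bit packed into a 32-bit code), and shows that the index answers
exact membership while its size never depends on how much was indexed.
"""

import circprobe as cp

host, target, _ = cp.generate_pair(cp.FixtureSpec(seed=1))

index = cp.build_host_index([host], backend="bitmap")
print(f"host length          : {len(host)} nt")
print(f"distinct 16-mers set : {index.n_kmers_set}")
print(f"bitmap size          : {index.capacity_bytes} bytes "
      f"({index.capacity_bytes / 2**20:.0f} MiB)")

index.add_sequence(target)
print(f"after 2nd sequence   : {index._bits.nbytes} bytes (unchanged), "
      f"{index.n_kmers_set} 16-mers set")

probe_kmer = host.residues[100:116]
code = cp.encode_kmer(probe_kmer)
print(f"\n16-mer {probe_kmer} -> code {code}")
print(f"present in host index: {index.contains(code)}")
print(f"random 16-mer present: {index.contains(cp.encode_kmer('ACGTGGTACCAGTTCA'))}")

# The size line is the point: one bit per possible 16-mer code (2^32 of
# them) is 512 MiB whether one transcript or a whole transcriptome is
# indexed; membership answers are exact, never approximate.
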