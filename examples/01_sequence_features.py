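"""Encode one mRNA sequence as k-mer and gapped-pair profiles.

The 7-nt toy sequence ACGCCGC is small enough to check by hand: it has
exactly three 5-mer windows, and among all ordered position pairs the
pattern A..G occurs twice and C..C six times.
"""

import numpy as np

from rnaloc import (
    MrnaRecord,
    aggregate_pair_counts,
    distance_profile,
    kmer_profile,
    multi_kmer_profile,
)
from rnaloc.distance import PAIR_NAMES, pair_index
from rnaloc.kmer import enumerate_kmers

rec = MrnaRecord("demo", "ACGCCGC")

prof = kmer_profile(rec, k=5)
kmers = enumerate_kmers(5)
present = {kmers[i]: int(v) for i, v in enumerate(prof.values) if v}
print(f"5-mer windows of {rec.sequence}: {present}")
# -> {'ACGCC': 1, 'CGCCG': 1, 'GCCGC': 1}; each window of width 5 counted once

dist = distance_profile(rec, k_max=8)
print(f"distance profile length: {len(dist.values)} (16 pair cells x 9 gap sizes)")
gap1 = {PAIR_NAMES[i]: int(v) for i, v in enumerate(dist.block(1)) if v}
print(f"gap-1 pairs (one intervening base): {gap1}")
# -> AxG:1, CxC:2, CxG:1, GxC:1 — e.g. CxC counts CGC at two positions

agg = aggregate_pair_counts(rec)
print(f"aggregate A..G count: {int(agg[pair_index('A', 'G')])} (expected 2)")
print(f"aggregate C..C count: {int(agg[pair_index('C', 'C')])} (expected 6)")
print(f"total ordered pairs:  {int(agg.sum())} = 7*6/2")

multi = multi_kmer_profile(rec, 1, 5)
print(f"concatenated 1..5-mer profile length: {len(multi.values)} "
      "(4+16+64+256+1024, the k-mer-baseline input width)")
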