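"""How likely is a sex-linked pattern to arise by chance?

For n sexed individuals a sex-independent locus mimics perfect sex
linkage with probability 0.5**n; multiplying by the panel size gives the
expected number of false perfect hits.
"""

from sexlink import expected_spurious, required_sample_size, round_sig, spurious_probability

n_individuals = 30
n_loci = 50_348 + 51_294  # SNP + PA panels

p = spurious_probability(n_individuals)
print(f"P(single locus spuriously perfect | n={n_individuals}) = "
      f"{round_sig(p, 3):.3g}")
print(f"expected spurious perfect loci over {n_loci:,} markers = "
      f"{expected_spurious(n_loci, round_sig(p, 3)):.4g}")
for budget in (1.0, 0.01):
    n_req = required_sample_size(n_loci, budget)
    print(f"smallest cohort keeping expected spurious hits < {budget}: {n_req}")
# With 30 sexed individuals the expected count is ~1e-4: any perfect
# candidate in a panel of this size is almost surely genuinely sex-linked.
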