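"""Design an orthogonal three-letter-code domain library and export FASTA.

Domains use only A/T/C (no G on designed strands), limited base runs and
30-70 % C content; the screen bounds the longest shared or complementary
stretch between any two accepted domains.
"""

import itertools

from cryodsd import longest_common_substring, screen_library, write_fasta

library = screen_library(n_domains=12, length=15, orthogonality_limit=6, seed=0)
worst = max(
    longest_common_substring(a.bases, b.bases)
    for a, b in itertools.combinations(library, 2)
)
for d in library:
    print(f"{d.domain_id}: {d.bases}  (C fraction {d.bases.count('C') / d.length:.2f})")
print(f"worst pairwise shared stretch: {worst} nt (limit 6)")

write_fasta(library, "scratch_domains.fasta")
print("wrote scratch_domains.fasta (domains + reverse complements)")
# No designed strand contains G, so G and C never co-occur in one strand.
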