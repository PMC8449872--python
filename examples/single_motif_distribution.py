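"""Occurrence-count distribution of one motif in a 20 kb background.

Computes the full distribution of the number of times AACGTT occurs in
a random 20,000-base equiprobable genome, plus the expected count and
an enrichment p-value for an observed count of 12.
"""

from motifdist import build_background, count_distribution, tail_pvalue

model = build_background({s: 0.25 for s in "ACGT"})
dist = count_distribution(model, "AACGTT", 20_000)

print(f"expected count : {dist.expected_count:.4f}")
print(f"mode           : {max(dist.probs, key=dist.probs.get)}")
for j in range(11):
    print(f"  P({j:2d}) = {dist.probs[j]:.6f}")
p_ge, p_le = tail_pvalue(dist, 12)
print(f"P(count >= 12) = {p_ge:.6f}   (enrichment p-value)")
print(f"P(count <= 12) = {p_le:.6f}   (depletion p-value)")

# Under the equiprobable model a length-6 motif has window probability
# 0.25^6, so ~4.88 occurrences are expected in 19,995 windows; the
# distribution peaks near that value and observing 12 or more would be
# surprising at about the 0.3% level.
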