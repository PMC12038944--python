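"""Hardy-Weinberg arithmetic: from recessive-disease prevalence to the
expected heterozygous-carrier frequency.

For a recessive disease with prevalence q^2, the carrier frequency is
2q(1-q), commonly approximated as 2q for small q.
"""

import founderdel as fd

for prevalence in (1e-6, 1 / 500_000):
    approx = fd.hwe_carrier_frequency(prevalence, approximate=True)
    exact = fd.hwe_carrier_frequency(prevalence, approximate=False)
    print(f"prevalence 1:{1 / prevalence:,.0f}  q = {exact.q:.6f}")
    print(f"  2q approximation : {approx.het_freq:.6f}  (1:{approx.reciprocal:.0f})")
    print(f"  exact 2q(1-q)    : {exact.het_freq:.6f}  (1:{exact.reciprocal:.0f})")
# a prevalence range of 1:1,000,000 .. 1:500,000 implies carriers at about
# 1:500 .. 1:354; an external lower bound of 1:300 is not derivable from
# Hardy-Weinberg alone.
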