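"""Independent brute-force oracles for the gamete-frequency recursions.

Deliberately structured differently from the package implementation: the
next-generation gamete pool is built by looping over every ordered pair of
gametes, working out the diploid genotype's viability and meiotic output
from first principles, and accumulating probability mass gamete by gamete.
"""

import numpy as np


def two_locus_oracle(x, tr, k, c_sup, suppressor_mode="facultative"):
    """Next-generation 4-class gamete frequencies by mating-table enumeration.

    Gamete order: D0/S0, D0/S1, D1/S0, D1/S1.
    """
    t, c = tr.t(k), tr.c(k)
    out = np.zeros(4)
    for g1 in range(4):
        d1, s1 = g1 // 2, g1 % 2
        for g2 in range(4):
            d2, s2 = g2 // 2, g2 % 2
            freq = x[g1] * x[g2]
            if freq == 0.0:
                continue
            has_d = d1 + d2 > 0
            has_s = s1 + s2 > 0
            if suppressor_mode == "facultative":
                expressed_sup = has_s and has_d
            else:  # obligate: constitutively expressed whenever present
                expressed_sup = has_s
            # Viability: the suppression cost applies when the suppressor is
            # expressed; the distortion cost when a distorter is present and
            # no suppressor silences it (a present suppressor always
            # silences, in both modes).
            w = 1.0
            if expressed_sup:
                w *= 1.0 - c_sup
            if has_d and not has_s:
                w *= 1.0 - c
            # Meiosis: distorter locus may drive in unsuppressed heterozygotes.
            if d1 != d2 and not has_s:
                p_d1_allele = (1.0 + t) / 2.0
            else:
                p_d1_allele = (d1 + d2) / 2.0
            p_s1_allele = (s1 + s2) / 2.0
            for d_out, pd in ((1, p_d1_allele), (0, 1.0 - p_d1_allele)):
                for s_out, ps in ((1, p_s1_allele), (0, 1.0 - p_s1_allele)):
                    out[2 * d_out + s_out] += freq * w * pd * ps
    return out / out.sum()


def three_allele_oracle(x, tr, k, k_hat, c_sup):
    """Next-generation 6-class gamete frequencies (resident D1, mutant D2,
    suppressor S1) by mating-table enumeration, stronger distorter dominant.

    Gamete order: D0/S0, D0/S1, D1/S0, D1/S1, D2/S0, D2/S1.
    """
    strengths = {0: 0.0, 1: k, 2: k_hat}
    out = np.zeros(6)
    for g1 in range(6):
        d1, s1 = g1 // 2, g1 % 2
        for g2 in range(6):
            d2, s2 = g2 // 2, g2 % 2
            freq = x[g1] * x[g2]
            if freq == 0.0:
                continue
            ka, kb = strengths[d1], strengths[d2]
            has_d = max(ka, kb) > 0.0
            has_s = s1 + s2 > 0
            w = 1.0
            if has_s and has_d:
                w *= 1.0 - c_sup  # suppressor expressed; drive + cost cancelled
            elif has_d:
                w *= 1.0 - tr.c(max(ka, kb))
            # Distorter-locus transmission.
            if d1 == d2 or has_s:
                p_allele1 = 0.5
            else:
                p_allele1 = (1.0 + tr.t(ka) - tr.t(kb)) / 2.0
            p_s1_allele = (s1 + s2) / 2.0
            for d_out, pd in ((d1, p_allele1), (d2, 1.0 - p_allele1)):
                for s_out, ps in ((1, p_s1_allele), (0, 1.0 - p_s1_allele)):
                    out[2 * d_out + s_out] += freq * w * pd * ps
    return out / out.sum()
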