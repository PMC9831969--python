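"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately written with plain Python loops and
elementary math, sharing no code with the package's vectorised
implementations, so it can serve as an oracle.
"""

from __future__ import annotations

import itertools
import math


def oracle_neg_log_likelihood(enc, space_xy, traps_xy, mu_fn, p0_fn, sigma_fn,
                              psi_female):
    """Brute-force SCR marginal negative log-likelihood.

    Parameters
    ----------
    enc : EncounterArray
    space_xy : list of (x, y) pixel centers
    traps_xy : list of (x, y) trap coordinates
    mu_fn(session, pixel_index) -> expected count in that pixel
    p0_fn(session, sex, trap_index, occasion_index0) -> baseline detection
    sigma_fn(session, sex) -> half-normal scale (m)
    psi_female : mixture probability of being female
    """
    psi = {"F": psi_female, "M": 1.0 - psi_female}
    total = 0.0
    for g, session in enc.sessions.items():
        K = session.n_occasions
        n_traps = len(traps_xy)

        def p_det(s, sex, j, k):
            dx = space_xy[s][0] - traps_xy[j][0]
            dy = space_xy[s][1] - traps_xy[j][1]
            d2 = dx * dx + dy * dy
            sig = sigma_fn(g, sex)
            return p0_fn(g, sex, j, k) * math.exp(-d2 / (2.0 * sig * sig))

        # Poisson correction: expected detected individuals
        for s in range(len(space_xy)):
            for sex in ("F", "M"):
                prod = 1.0
                for j in range(n_traps):
                    for k in range(K):
                        prod *= 1.0 - p_det(s, sex, j, k)
                total -= psi[sex] * mu_fn(g, s) * (1.0 - prod)

        for i, ind in enumerate(session.individuals):
            sex_i = str(session.sex[i])
            sexes = ("F", "M") if sex_i not in ("F", "M") else (sex_i,)
            lik = 0.0
            for sex in sexes:
                marg = 0.0
                for s in range(len(space_xy)):
                    prob = 1.0
                    for j in range(n_traps):
                        for k in range(K):
                            p = p_det(s, sex, j, k)
                            y = session.y[i, j, k]
                            prob *= p if y else (1.0 - p)
                    marg += mu_fn(g, s) * prob
                lik += psi[sex] * marg
            total += math.log(lik)
    return -total


def oracle_pi(freqs):
    """PI by enumerating genotype probabilities under Hardy-Weinberg and
    summing squared genotype probabilities."""
    alleles = list(freqs)
    total = 0.0
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            pg = freqs[a] ** 2 if a == b else 2.0 * freqs[a] * freqs[b]
            total += pg * pg
    return total


def oracle_pisib(freqs):
    """Sibling probability of identity by enumerating parental genotypes and
    transmissions for two full siblings."""
    alleles = list(freqs)
    total = 0.0
    for m1, m2, f1, f2 in itertools.product(alleles, repeat=4):
        p_parents = freqs[m1] * freqs[m2] * freqs[f1] * freqs[f2]
        # each child inherits one maternal and one paternal allele, each
        # with probability 1/2; count transmission pairs giving identical
        # unordered genotypes
        n_same = 0
        for cm1, cf1 in itertools.product((m1, m2), (f1, f2)):
            g1 = tuple(sorted((cm1, cf1)))
            for cm2, cf2 in itertools.product((m1, m2), (f1, f2)):
                if tuple(sorted((cm2, cf2))) == g1:
                    n_same += 1
        total += p_parents * n_same / 16.0
    return total
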