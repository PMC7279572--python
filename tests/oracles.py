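"""Independent slow reference implementations used only by the tests.

Deliberately written with explicit nested loops and scalar math so they
share no code path with the vectorised package implementations.
"""

import math


def brute_force_negloglik(theta, counts, T, trap_xy, mask_pts, cell_area):
    """Negative log of the Poisson-n SCR likelihood (log n! dropped)."""
    log_d, logit_g0, log_sigma = float(theta[0]), float(theta[1]), float(theta[2])
    dens = math.exp(log_d)
    g0 = 1.0 / (1.0 + math.exp(-logit_g0))
    sigma = math.exp(log_sigma)

    def p_det(s, k):
        d2 = (s[0] - k[0]) ** 2 + (s[1] - k[1]) ** 2
        return g0 * math.exp(-d2 / (2.0 * sigma * sigma))

    # expected number of detected individuals
    total_pdot = 0.0
    for s in mask_pts:
        surv = 1.0
        for k in trap_xy:
            surv *= (1.0 - p_det(s, k)) ** T
        total_pdot += 1.0 - surv
    loglik = -dens * cell_area * total_pdot

    for row in counts:
        mask_sum = 0.0
        for s in mask_pts:
            pr = 1.0
            for kk, k in enumerate(trap_xy):
                p = p_det(s, k)
                pr *= p ** row[kk] * (1.0 - p) ** (T - row[kk])
            mask_sum += pr
        loglik += math.log(dens * cell_area * mask_sum)
    return -loglik


def shoelace_area(vertices):
    """Polygon area by the shoelace formula (vertices in order)."""
    a = 0.0
    m = len(vertices)
    for i in range(m):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % m]
        a += x1 * y2 - x2 * y1
    return abs(a) / 2.0
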