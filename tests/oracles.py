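"""Independent oracle implementations shared by the test modules.

These deliberately re-derive quantities with straightforward (slow) code so
the package implementations are checked against a second, independent path.
"""

import math

import numpy as np


def brute_force_score(model, xls, psi_value, d0, alpha=0.3, k_ev=1.0, k_c=1.0,
                      connect_dmax=4.0):
    """Independent single-pass re-implementation of the posterior score."""
    xl = 0.0
    for rec in xls:
        pa = model.coords[model.bead(rec.protein1, rec.residue1)]
        pb = model.coords[model.bead(rec.protein2, rec.residue2)]
        d = math.dist(pa, pb)
        f = 1.0 / (1.0 + math.exp(alpha * (d - d0)))
        xl -= math.log(psi_value + (1.0 - 2.0 * psi_value) * f)
    owner = model.bead_of_body()
    rev = {v: k for k, v in model.residue_index.items()}
    ev = 0.0
    n = model.n_beads
    for i in range(n):
        for j in range(i + 1, n):
            if owner[i] >= 0 and owner[i] == owner[j]:
                continue
            (ca, ra), (cb, rb) = rev[i], rev[j]
            if ca == cb and abs(ra - rb) == 1:
                continue
            d = math.dist(model.coords[i], model.coords[j])
            ov = model.bead_radii[i] + model.bead_radii[j] - d
            if ov > 0:
                ev += k_ev * ov * ov
    conn = 0.0
    for (comp, res), i in model.residue_index.items():
        j = model.residue_index.get((comp, res + 1))
        if j is None or (owner[i] >= 0 and owner[i] == owner[j]):
            continue
        d = math.dist(model.coords[i], model.coords[j])
        if d > connect_dmax:
            conn += k_c * (d - connect_dmax) ** 2
    return xl, ev, conn



def _conformer_groups(seed=0, n_per=10, spread=0.3):
    """Three well-separated conformer groups of a 30-bead chain."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(30, 3)) * 5
    centers = [np.zeros(3), np.array([60.0, 0, 0]), np.array([0, 60.0, 0])]
    models, labels = [], []
    for g, c in enumerate(centers):
        jitter_dir = rng.normal(size=(30, 3))
        for k in range(n_per):
            m = base.copy()
            m[10:] += c  # move the non-reference part only
            m += rng.normal(scale=spread / math.sqrt(3), size=(30, 3))
            models.append(m)
            labels.append(g)
    return models, np.array(labels)

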