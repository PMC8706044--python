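"""Independent brute-force oracles used to cross-check the pipeline.

These re-derive expected results by exhaustive enumeration rather than
calling the implementation's grouping/filter code paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def consensus_oracle(tables, ppm_tol=5.0, rt_tol=0.3, noise_threshold=50.0):
    """Exhaustive replicate-consensus grouping.

    Pools all features above the noise threshold, visits seeds in
    descending intensity (ties: ascending m/z, then pool order), and for
    each seed enumerates every cross-injection tuple of unused features
    within the tolerances, keeping the tuple that minimizes the
    concatenated (|dmz|, |drt|, index) keys.  Returns a set of
    frozensets of member feature ids.
    """
    n_inj = len(tables)
    pool = []
    for slot, t in enumerate(tables):
        for row in t.itertuples(index=False):
            if row.intensity >= noise_threshold:
                pool.append((float(row.intensity), float(row.mz), float(row.rt_min),
                             slot, str(row.feature_id)))
    order = sorted(range(len(pool)), key=lambda i: (-pool[i][0], pool[i][1], i))
    used = set()
    groups = set()
    for i in order:
        if i in used:
            continue
        _, mz0, rt0, _, _ = pool[i]
        per_slot = []
        for slot in range(n_inj):
            cands = [j for j in range(len(pool))
                     if j not in used and pool[j][3] == slot
                     and abs(pool[j][1] - mz0) / mz0 * 1e6 <= ppm_tol
                     and abs(pool[j][2] - rt0) <= rt_tol]
            per_slot.append(cands)
        if all(per_slot):
            def tuple_key(tup):
                key = []
                for j in tup:
                    key.append((abs(pool[j][1] - mz0), abs(pool[j][2] - rt0), j))
                return tuple(key)
            best = min(itertools.product(*per_slot), key=tuple_key)
            used.update(best)
            groups.add(frozenset(pool[j][4] for j in best))
        else:
            used.add(i)
    return groups


def blank_subtract_oracle(features, blank, ppm_tol=5.0, rt_tol=0.3):
    """Direct double-loop blank subtraction (coordinate mode)."""
    survivors = []
    for f in features:
        removed = False
        for row in blank.itertuples(index=False):
            if (abs(row.mz - f.mz) / f.mz * 1e6 <= ppm_tol
                    and abs(row.rt_min - f.rt) <= rt_tol):
                removed = True
                break
        if not removed:
            survivors.append(f.feature_id)
    return set(survivors)


def mass_screen_oracle(feature_mz, db, ppm_window=5.0):
    """Brute-force candidate scan over the database."""
    out = set()
    for c in db:
        ppm = (c.adduct_mass - feature_mz) / c.adduct_mass * 1e6
        if abs(ppm) <= ppm_window:
            out.add(c.compound_id)
    return out


def splot_oracle(Z, t1):
    """Direct covariance/correlation S-plot coordinates on scaled data."""
    n = len(t1)
    t1c = t1 - t1.mean()
    sd_t = t1.std(ddof=1)
    p1, pcorr1 = [], []
    for j in range(Z.shape[1]):
        xc = Z[:, j] - Z[:, j].mean()
        cov = float(t1c @ xc) / (n - 1)
        sd_x = Z[:, j].std(ddof=1)
        p1.append(cov / sd_t)
        pcorr1.append(0.0 if sd_x == 0 else cov / (sd_t * sd_x))
    return np.array(p1), np.array(pcorr1)
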