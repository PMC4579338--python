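"""Independent brute-force oracles used to cross-check the fast paths.

These deliberately avoid the package's optimised implementations: the
segmentation oracle recomputes every candidate split with fresh per-slice
arithmetic at every recursion level, and the recurrence oracle counts
subjects per base over explicit arrays.
"""

import math

import numpy as np


def oracle_segment(values, settings):
    """Exhaustive recursive splitting under the same acceptance rule.

    At each level every admissible split is evaluated from scratch
    (two-sample z with pooled within-child variance); the leftmost maximal
    split is accepted when its two-sided normal p-value is below alpha and
    both children keep min_probes probes.
    """
    values = np.asarray(values, dtype=float)
    found: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        best_i, best_z = None, -1.0
        for i in range(lo + settings.min_probes, hi - settings.min_probes + 1):
            left, right = values[lo:i], values[i:hi]
            m_l, m_r = left.mean(), right.mean()
            ss = ((left - m_l) ** 2).sum() + ((right - m_r) ** 2).sum()
            var = ss / (n - 2)
            if abs(m_l - m_r) <= 1e-9:  # same tolerance as the fast path
                z = 0.0
            elif var <= 0.0:
                z = math.inf
            else:
                z = abs(m_l - m_r) / math.sqrt(
                    var * (1.0 / len(left) + 1.0 / len(right))
                )
            if z > best_z:
                best_i, best_z = i, z
        if best_i is None:
            return
        p = math.erfc(best_z / math.sqrt(2.0)) if math.isfinite(best_z) else 0.0
        if p < settings.alpha:
            found.append(best_i)
            recurse(lo, best_i)
            recurse(best_i, hi)

    recurse(0, len(values))
    return sorted(found)


def oracle_peaks(unit_intervals: dict, length: int):
    """Per-base peak finding on one chromosome.

    ``unit_intervals``: unit id -> list of 1-based inclusive (start, end).
    Returns a list of (start, end, count, frozenset_of_units) for every
    local-maximum plateau, split at contributing-set changes.
    """
    units = sorted(unit_intervals)
    mask = np.zeros(length + 2, dtype=np.int64)
    for ui, unit in enumerate(units):
        for s, e in unit_intervals[unit]:
            mask[s : e + 1] |= 1 << ui

    # constant-mask atoms over covered bases
    atoms = []  # (start, end, mask)
    b = 1
    while b <= length:
        if mask[b] == 0:
            b += 1
            continue
        s = b
        while b + 1 <= length and mask[b + 1] == mask[s]:
            b += 1
        atoms.append((s, b, int(mask[s])))
        b += 1

    def count(m):
        return bin(m).count("1")

    # contiguous equal-count plateaus
    plateaus: list[list[tuple]] = []
    for atom in atoms:
        prev = plateaus[-1] if plateaus else None
        if (
            prev is not None
            and prev[-1][1] + 1 == atom[0]
            and count(prev[-1][2]) == count(atom[2])
        ):
            prev.append(atom)
        else:
            plateaus.append([atom])

    peaks = []
    for i, plat in enumerate(plateaus):
        c = count(plat[0][2])
        left = (
            count(plateaus[i - 1][-1][2])
            if i > 0 and plateaus[i - 1][-1][1] + 1 == plat[0][0]
            else 0
        )
        right = (
            count(plateaus[i + 1][0][2])
            if i + 1 < len(plateaus) and plat[-1][1] + 1 == plateaus[i + 1][0][0]
            else 0
        )
        if c > left and c > right:
            for s, e, m in plat:
                members = frozenset(
                    units[ui] for ui in range(len(units)) if m >> ui & 1
                )
                peaks.append((s, e, c, members))
    return peaks
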