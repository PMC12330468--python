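"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's data structures and algorithms:
plain loops and exhaustive scans, kept simple enough to audit by eye.
"""

from __future__ import annotations


def greedy_match_oracle(case_units, comparator_units, k=1, caliper=None, replacement=False):
    """Replay greedy nearest-neighbor matching with explicit O(n^2) scans.

    ``case_units`` / ``comparator_units``: list of (unit_id, logit).
    Cases in descending logit (ties by id); per case, k nearest unused
    comparators by |logit diff|, distance ties to the smaller id.
    Returns (pairs, unmatched_case_ids).
    """
    cases = sorted(case_units, key=lambda t: (-t[1], t[0]))
    available = {uid: lg for uid, lg in comparator_units}
    pairs = []
    unmatched = []
    for cid, clog in cases:
        taken = 0
        for _ in range(k):
            best = None
            for uid, lg in sorted(available.items()):
                d = abs(lg - clog)
                if best is None or d < best[1]:
                    best = (uid, d)
            if best is None:
                break
            if caliper is not None and best[1] > caliper:
                break
            pairs.append((cid, best[0], best[1]))
            taken += 1
            if not replacement:
                del available[best[0]]
        if taken == 0:
            unmatched.append(cid)
    return pairs, unmatched


def cooccurrence_tally_oracle(profiles, case_ids):
    """Per-code patient tallies by direct enumeration.

    Returns {code: (n_B, n_AB)} over every code in any profile.
    """
    out = {}
    for code in sorted({c for codes in profiles.values() for c in codes}):
        n_b = sum(1 for codes in profiles.values() if code in codes)
        n_ab = sum(
            1 for pid, codes in profiles.items() if code in codes and pid in case_ids
        )
        out[code] = (n_b, n_ab)
    return out
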