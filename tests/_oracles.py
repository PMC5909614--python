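"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written against the *definitions* (day-by-day
accounting, exhaustive scans, numerical elevation sweeps), deliberately
not sharing code paths with the package internals it checks.
"""

import math

import numpy as np

from phenoscan import ANTHESIS_FAILED


def daylength_by_elevation_sweep(latitude, doy, depression, step_minutes=0.25):
    """Day length (h) by sweeping solar elevation over the day.

    Counts the minutes for which the sun is above ``-depression``
    degrees, using the same declination convention as the package but a
    completely different computation (elevation sampling instead of the
    closed-form hour-angle solution).
    """
    phi = math.radians(latitude)
    decl = math.radians(-23.45) * math.cos(2 * math.pi * (doy + 10) / 365.0)
    minutes = np.arange(0.0, 24 * 60.0, step_minutes)
    hour_angle = np.radians((minutes / 60.0 - 12.0) * 15.0)
    sin_elev = math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(
        decl
    ) * np.cos(hour_angle)
    above = sin_elev > math.sin(math.radians(-depression))
    return above.sum() * step_minutes / 60.0


def simulate_anthesis_dayloop(
    tmax_by_dap,
    tmin_by_dap,
    daylength_by_dap,
    p1,
    p2,
    p2o,
    phint,
    tbase=8.0,
    topt=34.0,
    emergence_gdd=45.0,
):
    """Spreadsheet-style day-by-day trace of the three-stage model.

    Inputs are per-day-after-sowing sequences (index 0 = day 1).
    Returns (emergence, end_juvenile, tassel_initiation, anthesis) days
    after sowing, with ANTHESIS_FAILED for anthesis if the sequence
    runs out, mirroring the contract of the fast implementation.
    """
    horizon = len(tmax_by_dap)

    def gdd(i):
        mean = 0.5 * (tmax_by_dap[i] + tmin_by_dap[i])
        return max(0.0, min(mean, topt) - tbase)

    stage = "pre_emergence"
    acc = 0.0
    cum_from_emergence = 0.0
    s2 = 0.0
    emergence = end_juv = ti = None
    sumdtt = None
    threshold3 = None
    for i in range(horizon):
        day = i + 1
        g = gdd(i)
        if stage == "pre_emergence":
            acc += g
            if acc >= emergence_gdd:
                emergence = day
                stage = "juvenile"
                acc = 0.0
            continue
        cum_from_emergence += g
        if stage == "juvenile":
            acc += g
            if acc >= p1:
                end_juv = day
                stage = "photoperiod"
            continue
        if stage == "photoperiod":
            s2 += 1.0 / (4.0 + p2 * max(0.0, daylength_by_dap[i] - p2o))
            if s2 >= 1.0 - 1e-9:
                ti = day
                sumdtt = cum_from_emergence
                toln = sumdtt / (0.5 * phint) + 5.0
                threshold3 = (toln + 0.5) * phint - sumdtt
                stage = "leaf_expansion"
                acc = 0.0
            continue
        if stage == "leaf_expansion":
            acc += g
            if acc >= threshold3:
                return emergence, end_juv, ti, day
    return emergence, end_juv, ti, ANTHESIS_FAILED


def exhaustive_best_and_ties(anthesis_rows, observed):
    """Argmin + tie count by a plain loop over database rows.

    ``anthesis_rows``: (n_rows, k) simulated days; ``observed``: length-k
    ints.  Rows containing the failure sentinel are skipped.  Returns
    (best_index, best_sse, tie_count, tied_indices).
    """
    best_idx = None
    best_sse = None
    tied = []
    for i, row in enumerate(anthesis_rows):
        if any(v == ANTHESIS_FAILED for v in row):
            continue
        sse = sum((int(a) - int(b)) ** 2 for a, b in zip(row, observed))
        if best_sse is None or sse < best_sse:
            best_idx, best_sse, tied = i, sse, [i]
        elif sse == best_sse:
            tied.append(i)
    if best_idx is None:
        return None
    return best_idx, best_sse, len(tied) - 1, tied


def exhaustive_achievable(anthesis_rows):
    """Distinct tuples and first witnesses by a plain dict pass."""
    seen = {}
    for i, row in enumerate(anthesis_rows):
        if any(v == ANTHESIS_FAILED for v in row):
            continue
        key = tuple(int(v) for v in row)
        if key not in seen:
            seen[key] = i
    return seen
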