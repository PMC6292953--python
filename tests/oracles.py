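"""Independent oracles used by the test suite.

These deliberately re-derive results through the most transparent route
available — naive full-rescan merging for movement units, textbook
sums-of-squares for the mixed ANOVA — and stay independent of the package
implementations they are used to check.
"""

from __future__ import annotations

import numpy as np


def oracle_movement_units(speed, accel, dv_min=20.0, da_min=5.0) -> int:
    """Brute-force movement-unit count of a speed series.

    Semantics: alternating extrema (both endpoints included, plateaus
    collapsed to their last frame, index 0 always kept), then repeated
    removal of the globally smallest adjacent interior pair below ``dv_min``
    (earliest pair on ties), then candidate maxima with rise and fall >=
    ``dv_min`` and an acceleration excursion to ``+da_min`` and ``-da_min``
    inside the unit.  Every pass rescans the whole list from scratch.
    """
    speed = np.asarray(speed, dtype=float)
    accel = np.asarray(accel, dtype=float)
    n = len(speed)
    if n == 0:
        return 0

    # --- alternating extrema -------------------------------------------------
    d = np.diff(speed)
    sgn = np.sign(d)
    nz = np.flatnonzero(sgn)
    pts = [0]
    for a, b in zip(nz, nz[1:]):
        if sgn[a] != sgn[b]:
            pts.append(int(b))  # last frame of the run ending before the flip
    if pts[-1] != n - 1:
        pts.append(n - 1)
    if len(nz) == 0:
        first_rising = True  # constant series: convention irrelevant
    else:
        first_rising = sgn[nz[0]] > 0
    kinds = []
    k = -1 if first_rising else 1  # -1 min, +1 max
    for _ in pts:
        kinds.append(k)
        k = -k

    # --- merge smallest interior pair, full rescan each pass -----------------
    while True:
        candidates = [
            (abs(speed[pts[j + 1]] - speed[pts[j]]), j)
            for j in range(1, len(pts) - 2)
            if abs(speed[pts[j + 1]] - speed[pts[j]]) < dv_min
        ]
        if not candidates:
            break
        _, j = min(candidates)
        pts = pts[:j] + pts[j + 2 :]
        kinds = kinds[:j] + kinds[j + 2 :]

    # --- candidate maxima with thresholds and acceleration gate --------------
    count = 0
    for j in range(1, len(pts) - 1):
        if kinds[j] != 1:
            continue
        rise = speed[pts[j]] - speed[pts[j - 1]]
        fall = speed[pts[j]] - speed[pts[j + 1]]
        if rise < dv_min or fall < dv_min:
            continue
        seg = accel[pts[j - 1] : pts[j + 1] + 1]
        if len(seg) and seg.max() >= da_min and seg.min() <= -da_min:
            count += 1
    return count


def oracle_mixed_anova(y_g1: np.ndarray, y_g2: np.ndarray) -> dict:
    """Textbook balanced 2x2 mixed-design ANOVA from raw sums of squares.

    ``y_gk`` has shape (n_subjects, 2) with columns (level 1, level 2).
    Returns F statistics for the group, test and interaction effects.
    """
    a, b = 2, 2
    n = len(y_g1)
    assert len(y_g2) == n, "oracle requires balanced groups"
    y = np.stack([y_g1, y_g2])  # (a, n, b)
    grand = y.mean()
    subj_means = y.mean(axis=2)  # (a, n)
    group_means = y.mean(axis=(1, 2))  # (a,)
    test_means = y.mean(axis=(0, 1))  # (b,)
    cell_means = y.mean(axis=1)  # (a, b)

    ss_between_subj = b * ((subj_means - grand) ** 2).sum()
    ss_group = n * b * ((group_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    df_subj = a * (n - 1)

    ss_test = a * n * ((test_means - grand) ** 2).sum()
    ss_int = n * (
        (cell_means - group_means[:, None] - test_means[None, :] + grand) ** 2
    ).sum()
    ss_within = ((y - subj_means[:, :, None]) ** 2).sum()
    ss_err = ss_within - ss_test - ss_int
    df_err = a * (n - 1) * (b - 1)

    return {
        "group": (ss_group / 1) / (ss_subj_within / df_subj),
        "test": (ss_test / 1) / (ss_err / df_err),
        "group x test": (ss_int / 1) / (ss_err / df_err),
        "df_error": df_subj,
    }
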