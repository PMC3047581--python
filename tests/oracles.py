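"""Independent brute-force oracles.

Straight-line transcriptions of the documented analysis rules, written
against raw numpy arrays with hand-coded normal-equations least squares —
deliberately sharing no code with the package — so the package's window
selection and regression can be checked against a second, independent
implementation of the same rules.
"""

from __future__ import annotations

import math

import numpy as np


def ols_normal_equations(x, y):
    """(intercept, slope, r2) by the textbook normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    yhat = intercept + slope * x
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(intercept), float(slope), r2


def _f0(fc, cycle, emax, fmax):
    if not (0 < fc < fmax) or emax <= 0 or fmax <= 0:
        return math.nan
    return fmax / (1.0 + ((fmax - fc) / fc) * (1.0 + emax) ** cycle)


def _fit(fc, ec, cycles):
    """Window fit on 1-based `cycles`; returns dict or None if invalid."""
    x = np.array([fc[c - 1] for c in cycles])
    y = np.array([ec[c - 2] for c in cycles])
    if not np.all(np.isfinite(y)):
        return None
    emax, delta_e, r2 = ols_normal_equations(x, y)
    if not (delta_e < 0 and emax > 0):
        return None
    fmax = -emax / delta_e
    f0s = [_f0(v, c, emax, fmax) for v, c in zip(x, cycles)]
    f0s = [v for v in f0s if math.isfinite(v)]
    if not f0s:
        return None
    avg_f0 = sum(f0s) / len(f0s)
    if not avg_f0 > 0:
        return None
    return {"emax": emax, "delta_e": delta_e, "fmax": fmax, "avg_f0": avg_f0}


def oracle_half_max(fc):
    """Transcription of the provisional half-max rule; None if the
    profile does not amplify."""
    fc = np.asarray(fc, dtype=float)
    n = len(fc)
    if fc.max() <= 0:
        return None
    df = np.diff(fc)
    ipeak = int(np.argmax(df))
    peak = df[ipeak]
    if peak <= 0:
        return None
    level = None
    for i in range(ipeak + 1, n - 1):
        if df[i] <= 0.05 * peak:
            level = i + 1
            break
        if df[i] >= df[i - 1] and df[i - 1] < 0.8 * peak:
            level = i + 1
            break
    if level is None:
        return None
    plateau = float(np.mean(fc[level : min(level + 3, n)]))
    if plateau <= 0:
        return None
    scale = float(np.median(np.abs(df)))
    if scale > 0 and plateau < 8.0 * scale:
        return None
    half = plateau / 2.0
    idx = None
    for i in range(n):
        if fc[i] >= half:
            idx = i
            break
    if idx is None:
        return None
    if idx == 0:
        return 1.0
    if fc[idx] <= fc[idx - 1]:
        return float(idx + 1)
    return idx + (half - fc[idx - 1]) / (fc[idx] - fc[idx - 1])


def oracle_analyze(
    raw,
    baseline_cycles=(4, 9),
    min_fc=None,
    f0_threshold=0.06,
    initial_window_size=3,
):
    """Rule-by-rule re-derivation of start cycle and final LRE window.

    Returns a dict with ``start``, ``window`` (start, size) and ``flag``
    (None when the analysis succeeds).
    """
    raw = np.asarray(raw, dtype=float)
    n = len(raw)
    if baseline_cycles is None:
        baseline = 0.0
    else:
        lo, hi = baseline_cycles
        baseline = float(np.mean(raw[lo - 1 : hi]))
    fc = raw - baseline
    ec = np.full(n - 1, np.nan)
    for c in range(2, n + 1):
        if fc[c - 2] > 0:
            ec[c - 2] = fc[c - 1] / fc[c - 2] - 1.0

    if min_fc is not None:
        first = None
        for c in range(1, n + 1):
            if fc[c - 1] > min_fc:
                first = c
                break
        if first is None or first >= n:
            return {"start": None, "window": None, "flag": "no_window"}
        start = max(first + 1, 2)
    else:
        half = oracle_half_max(fc)
        if half is None:
            return {"start": None, "window": None, "flag": "non_amplifying"}
        start = math.floor(half)
        if start == half:
            start -= 1
        start = max(start, 2)

    if start + initial_window_size - 1 > n:
        return {"start": start, "window": None, "flag": "window_too_short"}
    # initial fit, retrying with a larger window while the slope is junk
    fit = None
    size = None
    for trial in range(initial_window_size, min(initial_window_size + 4, n - start + 2)):
        cycles = list(range(start, start + trial))
        if cycles[-1] > n:
            break
        try:
            cand = _fit(fc, ec, cycles)
        except Exception:
            return {"start": start, "window": None, "flag": "window_too_short"}
        if cand is not None:
            fit, size = cand, trial
            break
    if fit is None:
        return {"start": start, "window": None, "flag": "aberrant_fit"}
    end = start + size - 1
    while end < n:
        cand_cycle = end + 1
        fcc = fc[cand_cycle - 1]
        if fcc >= 0.999 * fit["fmax"]:
            break
        f0c = _f0(fcc, cand_cycle, fit["emax"], fit["fmax"])
        pct = abs(f0c - fit["avg_f0"]) / fit["avg_f0"]
        if pct > f0_threshold:
            break
        new_fit = _fit(fc, ec, list(range(start, cand_cycle + 1)))
        if new_fit is None:
            break
        end = cand_cycle
        fit = new_fit
    return {"start": start, "window": (start, end - start + 1), "flag": None}
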