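"""Independent brute-force oracles used to cross-check the detectors.

These are deliberately naive sample-by-sample / interval-by-interval scans,
kept free of numpy vectorisation and of any code shared with the package.
"""

import statistics


def brute_threshold_runs(values, valid, rate, threshold, min_dur):
    """Maximal runs of valid samples strictly below threshold, >= min_dur s.

    Returns a list of (onset_s, duration_s).
    """
    events = []
    i, n = 0, len(values)
    while i < n:
        if valid[i] and values[i] < threshold:
            j = i
            while j < n and valid[j] and values[j] < threshold:
                j += 1
            dur = (j - i) / rate
            if dur >= min_dur:
                events.append((i / rate, dur))
            i = j
        else:
            i += 1
    return events


def brute_pauses(onsets, short_lo=3.0, short_hi=5.0):
    """Pauses from a breath-onset list: silent time beyond one median cycle.

    Returns a list of (onset_s, duration_s, kind) with kind 'short'/'long'.
    """
    onsets = list(onsets)
    if len(onsets) < 2:
        return []
    intervals = [b - a for a, b in zip(onsets, onsets[1:])]
    period = statistics.median(intervals)
    out = []
    for a, iv in zip(onsets, intervals):
        d = iv - period
        if d > short_lo:
            kind = "short" if d <= short_hi else "long"
            out.append((a + period, d, kind))
    return out


def assert_runs_equal(got, want, tol=1e-9):
    """Exact (to float tolerance) equality of two (onset, duration) run lists."""
    assert len(got) == len(want), f"{len(got)} events != oracle's {len(want)}"
    for (a, b), (c, d) in zip(got, want):
        assert abs(a - c) <= tol and abs(b - d) <= tol, f"{(a, b)} != {(c, d)}"


def brute_paired_t(off, on, transform=None):
    """Textbook paired t from first principles: t = mean(d) / (sd(d)/sqrt(n))."""
    import math

    if transform is not None:
        off = [transform(v) for v in off]
        on = [transform(v) for v in on]
    d = [a - b for a, b in zip(off, on)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    return mean / math.sqrt(var / n)
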