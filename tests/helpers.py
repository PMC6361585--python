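"""Independent oracles used to cross-check the implementation."""

import re

import numpy as np

OPEN_S = 0.080
CONTINUE_S = 0.160


def burst_oracle(times, open_isi=OPEN_S, continue_isi=CONTINUE_S):
    """Brute-force burst enumeration by symbolic ISI runs.

    Each ISI is classified as 'o' (< open threshold), 'c' (in [open,
    continue]) or 'x' (> continue). A burst corresponds to a maximal run
    of non-'x' ISIs that contains at least one 'o': it starts at the
    first spike of the run's first 'o' interval and extends to the end of
    the run (every later interval in the run is <= the continuation
    bound, so every spike joins). This is a different formulation from
    the scanning implementation and serves as its oracle.

    Returns a list of (first_spike_index, last_spike_index) pairs.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        return []
    isi = np.diff(times)
    symbols = "".join("o" if d < open_isi else ("c" if d <= continue_isi else "x")
                      for d in isi)
    bursts = []
    for match in re.finditer(r"[oc]+", symbols):
        run = match.group()
        first_open = run.find("o")
        if first_open == -1:
            continue
        start_isi = match.start() + first_open
        end_isi = match.end() - 1
        bursts.append((start_isi, end_isi + 1))
    return bursts


def burst_oracle_pct(times, **kwargs):
    bursts = burst_oracle(times, **kwargs)
    n = len(np.atleast_1d(times))
    if n == 0:
        return 0.0
    in_burst = sum(j - i + 1 for i, j in bursts)
    return 100.0 * in_burst / n


def _chi2_statistic(counts):
    counts = np.asarray(counts, dtype=float)
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row @ col / counts.sum()
    if np.any(expected == 0):
        return 0.0
    return float(((counts - expected) ** 2 / expected).sum())


def binomial_resampling_p(counts, n_resamples=20000, seed=0):
    """Resampling oracle for a 2x2 proportion contrast.

    Redraws both groups' success counts from the pooled null proportion
    and uses the chi-square statistic itself as the discrepancy measure;
    two-sided p as the exceedance fraction.
    """
    counts = np.asarray(counts, dtype=int)
    assert counts.shape == (2, 2)
    n1, n2 = counts.sum(axis=1)
    pooled = counts[:, 0].sum() / (n1 + n2)
    observed = _chi2_statistic(counts)
    rng = np.random.default_rng(seed)
    a = rng.binomial(n1, pooled, n_resamples)
    b = rng.binomial(n2, pooled, n_resamples)
    sims = np.array([_chi2_statistic([[x, n1 - x], [y, n2 - y]])
                     for x, y in zip(a, b)])
    return float(np.mean(sims >= observed - 1e-9))
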