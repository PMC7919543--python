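"""Estimation of the per-cycle substitution error rate from mapped reads.

Sequencing error is estimated directly from the data using reads that map
unambiguously: species with wide conspecific/heterospecific score
separation, multiple reference accessions (to absorb genuine biological
variation) and deep read counts.  Per-cycle mismatch proportions from those
reads are pooled and a polynomial in cycle number is fitted, with the order
chosen by the Akaike information criterion in its Gaussian least-squares
form, ``AIC = n ln(RSS/n) + 2 (k + 1)``.

Rates are modeled in read-cycle coordinates; edge-skipped cycles contribute
no observations, and the fitted curve is extrapolated over the full read for
simulation use.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .align import OP_MATCH, OP_INS, OP_SKIP
from .synth import ErrorModel


def select_unambiguous(
    db,
    score_gaps,
    counts: dict[str, int] | pd.Series,
    min_gap_bits: float = 28.0,
    min_accessions: int = 2,
    min_reads: int = 1000,
) -> list[str]:
    """Species suitable for error-rate estimation.

    Keeps species that (1) are separated from all heterospecific references
    by at least ``min_gap_bits`` bits, (2) have at least ``min_accessions``
    distinct references, and (3) have at least ``min_reads`` mapped reads.
    Sorted by mapped-read count, descending.
    """
    counts = pd.Series(counts, dtype=float)
    chosen = []
    for sg in score_gaps:
        n_mapped = float(counts.get(sg.species, 0))
        if (sg.n_accessions >= min_accessions
                and sg.eligible(min_gap_bits)
                and n_mapped >= min_reads):
            chosen.append((sg.species, n_mapped))
    if not chosen:
        warnings.warn("no species satisfy the unambiguous-mapping criteria",
                      stacklevel=2)
    return [sp for sp, _ in sorted(chosen, key=lambda x: (-x[1], x[0]))]


def _cycle_observations(rec) -> tuple[np.ndarray, np.ndarray]:
    """Covered cycles and mismatch flags for one alignment record."""
    covered = []
    pos = 0
    for op, n in rec.ops:
        if op == OP_MATCH:
            covered.extend(range(pos + 1, pos + n + 1))
            pos += n
        elif op in (OP_INS, OP_SKIP):
            pos += n
    covered = np.asarray(covered, dtype=int)
    mm = np.zeros(covered.size, dtype=bool)
    mmset = set(rec.mismatch_positions)
    for i, c in enumerate(covered):
        if c in mmset:
            mm[i] = True
    return covered, mm


def tabulate_rates(
    records,
    read_length: int = 98,
    min_reads_per_ref: int = 5,
    max_site_rate: float = 0.10,
) -> pd.DataFrame:
    """Per-cycle mismatch proportions pooled over references.

    ``records`` are filtered alignment records of unique reads from the
    selected species.  References with fewer than ``min_reads_per_ref``
    mapped reads, or with any site exceeding ``max_site_rate`` (likely true
    polymorphism rather than sequencing error), are excluded from pooling.
    Returns a table with columns ``position``, ``n_reads``,
    ``mismatch_rate``.
    """
    by_acc: dict[str, list] = {}
    for rec in records:
        by_acc.setdefault(rec.accession, []).append(rec)

    cov_total = np.zeros(read_length, dtype=float)
    mm_total = np.zeros(read_length, dtype=float)
    excluded: list[str] = []
    for acc, recs in sorted(by_acc.items()):
        if len(recs) < min_reads_per_ref:
            excluded.append(acc)
            continue
        cov = np.zeros(read_length, dtype=float)
        mm = np.zeros(read_length, dtype=float)
        for rec in recs:
            cycles, flags = _cycle_observations(rec)
            keep = cycles <= read_length
            cov[cycles[keep] - 1] += 1
            mm[cycles[keep] - 1] += flags[keep]
        with np.errstate(invalid="ignore", divide="ignore"):
            site_rate = np.where(cov > 0, mm / np.maximum(cov, 1), 0.0)
        if (site_rate > max_site_rate).any():
            excluded.append(acc)
            continue
        cov_total += cov
        mm_total += mm
    if cov_total.sum() == 0:
        raise ValueError("no usable references: pool is empty")
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(cov_total > 0, mm_total / np.maximum(cov_total, 1), np.nan)
    table = pd.DataFrame({
        "position": np.arange(1, read_length + 1),
        "n_reads": cov_total.astype(int),
        "mismatch_rate": rate,
    })
    table.attrs["excluded_accessions"] = excluded
    return table


def fit_polynomial(
    table: pd.DataFrame,
    window: tuple[int, int] = (10, 90),
    max_order: int = 5,
    indel_fraction: float = 0.0,
) -> ErrorModel:
    """Fit polynomial error-rate curves and select the order by AIC.

    Ordinary least squares is fitted for each order 0..``max_order`` on
    (position, mismatch_rate) within ``window``; the minimum-AIC order wins.
    The returned model extrapolates over all cycles for simulation use (its
    ``rate`` is clipped to [0, 1]).
    """
    sel = table[(table["position"] >= window[0])
                & (table["position"] <= window[1])
                & table["mismatch_rate"].notna()
                & (table["n_reads"] > 0)]
    x = sel["position"].to_numpy(dtype=float)
    y = sel["mismatch_rate"].to_numpy(dtype=float)
    n = x.size
    if n < max_order + 2:
        raise ValueError(
            f"need at least {max_order + 2} positions in window, got {n}")
    if np.ptp(y) < 1e-15:
        model = ErrorModel([float(y.mean())], indel_fraction=indel_fraction,
                           window=window)
        model.note = "degenerate design: all rates equal; order 0 returned"
        return model

    aics: dict[int, float] = {}
    coefs: dict[int, np.ndarray] = {}
    rss_prev = np.inf
    for k in range(max_order + 1):
        c = np.polynomial.polynomial.polyfit(x, y, k)
        resid = y - np.polynomial.polynomial.polyval(x, c)
        rss = float(resid @ resid)
        rss = min(rss, rss_prev)  # guard against numerical non-monotonicity
        rss_prev = rss
        aics[k] = n * np.log(max(rss, 1e-300) / n) + 2 * (k + 1)
        coefs[k] = c
    best = min(aics, key=lambda k: (aics[k], k))
    model = ErrorModel([float(c) for c in coefs[best]],
                       indel_fraction=indel_fraction, window=window)
    model.aic_by_order = aics
    return model
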