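"""Bin-level counts tables, contamination screening and data censoring.

Accession counts are summed into bin x sample tables.  Negative-control
(field blank) samples are used to estimate the index-crosstalk rate under a
pooled binomial model and to flag taxa whose control counts exceed what
crosstalk can explain (point contamination).  Quantitative analyses then
work on a censored table: contaminant taxa dropped, small libraries
excluded, and cells below a proportion threshold masked to zero -- with the
mask recorded, never silently applied.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .binning import BinMap


@dataclass
class CountsTable:
    """Bins x samples integer counts with sample types and censoring state."""

    counts: pd.DataFrame                  # bins x samples, int
    sample_types: dict[str, str]          # sample -> biological/negative
    censored_cells: pd.DataFrame | None = None   # boolean mask, True = masked
    excluded_samples: list[str] = field(default_factory=list)
    dropped_taxa: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def library_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def bins(self) -> list[str]:
        return list(self.counts.index)

    def of_type(self, sample_type: str) -> list[str]:
        return [s for s in self.samples
                if self.sample_types.get(s, "biological") == sample_type]

    @property
    def analyzed(self) -> pd.DataFrame:
        """Counts over samples retained for quantitative analysis."""
        keep = [s for s in self.samples if s not in self.excluded_samples]
        return self.counts[keep]


def aggregate(accession_counts: pd.DataFrame,
              bin_map: BinMap,
              accession_species: dict[str, str],
              sample_types: dict[str, str] | None = None) -> CountsTable:
    """Sum accession x sample counts into bin x sample counts.

    Every accession must resolve to a species with a bin; an orphan is an
    error, not a silent drop.  Column totals are conserved.
    """
    lookup = bin_map.species_to_bin
    bins = []
    for acc in accession_counts.index:
        sp = accession_species.get(acc)
        if sp is None or sp not in lookup:
            raise KeyError(f"accession {acc} has no taxon bin")
        bins.append(lookup[sp])
    summed = accession_counts.groupby(pd.Index(bins, name="bin")).sum()
    return CountsTable(counts=summed.astype(int),
                       sample_types=dict(sample_types or {}))


def estimate_crosstalk(
    table: CountsTable,
    quantile: float = 0.999,
    exposure: str = "uniform",
) -> dict:
    """Estimate the index-crosstalk rate from negative controls.

    Model: each read of a taxon independently hops to another library with
    probability ``rate``; with ``exposure='uniform'`` the destination is
    uniform over the other samples, so a taxon with total count ``T`` is
    expected to place ``rate * T * n_controls / (n_samples - 1)`` reads in
    the controls.  With ``exposure='library-share'`` the destination is
    proportional to library size.  The pooled maximum-likelihood rate under
    the binomial model is observed control counts over total exposure.
    Taxa whose control counts exceed the binomial ``quantile`` quantile
    (Bonferroni-corrected over taxa) are flagged as contaminants, with the
    dominant control sample identified.
    """
    controls = table.of_type("negative")
    if not controls:
        warnings.warn("no negative-control samples; crosstalk not estimated",
                      stacklevel=2)
        return {"rate": None, "flags": []}
    counts = table.counts
    n_samples = len(table.samples)
    if exposure == "uniform":
        share = len(controls) / max(n_samples - 1, 1)
    elif exposure == "library-share":
        totals = table.library_totals
        share = float(totals[controls].sum() / max(totals.sum(), 1))
    else:
        raise ValueError(f"unknown exposure model {exposure!r}")

    taxon_totals = counts.sum(axis=1)
    control_counts = counts[controls].sum(axis=1)
    exposure_n = taxon_totals * share
    rate = float(control_counts.sum() / exposure_n.sum()) if exposure_n.sum() else 0.0

    n_taxa = max((taxon_totals > 0).sum(), 1)
    alpha = (1 - quantile) / n_taxa
    flags = []
    for taxon in counts.index:
        n_exp = int(taxon_totals[taxon])
        if n_exp == 0:
            continue
        p = min(rate * share, 1.0) if rate else 0.0
        crit = stats.binom.ppf(1 - alpha, n_exp, p) if p > 0 else 0
        if control_counts[taxon] > crit:
            dominant = counts.loc[taxon, controls].idxmax()
            flags.append({"taxon": taxon,
                          "control_count": int(control_counts[taxon]),
                          "expected": float(n_exp * p),
                          "dominant_control": dominant})
    return {"rate": rate, "flags": flags, "share": share,
            "n_controls": len(controls)}


def censor(
    table: CountsTable,
    min_prop: float = 0.001,
    min_library: int = 1500,
    drop_taxa: list[str] | None = None,
) -> CountsTable:
    """Censor the counts table for quantitative analysis.

    Taxa in ``drop_taxa`` (flagged contaminants) are removed entirely.
    Samples whose library total is below ``min_library`` are excluded from
    quantitative analyses but kept in the table.  Cells whose proportion of
    the library is strictly below ``min_prop`` are masked to zero ("at
    least 0.1%" detections are retained).  The censoring mask is recorded;
    no cell ever increases.
    """
    # library size is judged on the full mapped totals; contaminant taxa
    # are removed from the analysis, not from the sequencing depth
    full_totals = table.counts.sum(axis=0)
    excluded = [s for s in table.counts.columns if full_totals[s] < min_library]
    counts = table.counts.drop(index=list(drop_taxa or []), errors="ignore")
    totals = counts.sum(axis=0)
    props = counts.div(totals.replace(0, np.nan), axis=1)
    mask = (counts > 0) & (props < min_prop)
    censored = counts.mask(mask, 0)
    return CountsTable(
        counts=censored.astype(int),
        sample_types=dict(table.sample_types),
        censored_cells=mask,
        excluded_samples=excluded,
        dropped_taxa=sorted(set(table.dropped_taxa) | set(drop_taxa or [])),
    )


@dataclass
class MismatchHistogram:
    """Distribution of per-read mismatch counts for one reference."""

    accession: str
    counts: list[int]          # reads with 0..max_mismatch mismatches
    multimodal: bool

    @property
    def n_reads(self) -> int:
        return sum(self.counts)


def mismatch_histograms(records, min_reads: int = 100,
                        max_mismatch: int = 3,
                        minor_mode_fraction: float = 0.10
                        ) -> list[MismatchHistogram]:
    """Audit per-reference mismatch distributions for hidden haplotypes.

    With a single underlying haplotype, mismatch counts of mapped reads
    decay from zero (errors only).  A second haplotype k substitutions from
    the reference adds a mode at k.  A histogram is flagged multimodal when
    some interior bin is a strict local minimum and a later bin still holds
    at least ``minor_mode_fraction`` of the reads.
    """
    by_acc: dict[str, list[int]] = {}
    for rec in records:
        m = len(rec.mismatch_positions)
        if m > max_mismatch:
            continue
        by_acc.setdefault(rec.accession, []).append(m)
    out = []
    for acc, ms in sorted(by_acc.items()):
        if len(ms) < min_reads:
            continue
        hist = [0] * (max_mismatch + 1)
        for m in ms:
            hist[m] += 1
        total = sum(hist)
        flag = False
        for k in range(1, max_mismatch):
            if hist[k] < hist[k - 1] and hist[k] < max(hist[k + 1:]):
                if sum(hist[k + 1:]) >= minor_mode_fraction * total:
                    flag = True
        out.append(MismatchHistogram(accession=acc, counts=hist,
                                     multimodal=flag))
    return out


def _pairwise_identity(a: str, b: str) -> float:
    res = edlib.align(a, b, mode="NW", task="path")
    d = res["editDistance"]
    aln_len = sum(int(n) for n, _ in re.findall(r"(\d+)([=XIDM])", res["cigar"]))
    return 1.0 - d / aln_len if aln_len else 0.0


def greedy_cluster(reads, identity: float = 0.98,
                   keep_singletons: bool = False) -> list[dict]:
    """Greedy centroid clustering of dereplicated reads.

    ``reads`` is a list of ``(sequence, abundance)`` pairs; clustering runs
    in abundance-descending order (ties by input order) and each read joins
    the first centroid whose pairwise identity (matching columns over
    alignment length, from a global alignment) meets the threshold, else it
    founds a new centroid.  Singleton clusters are discarded by default.
    """
    ordered = sorted(enumerate(reads), key=lambda t: (-t[1][1], t[0]))
    clusters: list[dict] = []
    for _, (seq, abundance) in ordered:
        placed = False
        for cl in clusters:
            if _pairwise_identity(seq, cl["centroid"]) >= identity:
                cl["members"] += 1
                cl["abundance"] += abundance
                placed = True
                break
        if not placed:
            clusters.append({"centroid": seq, "members": 1,
                             "abundance": abundance})
    if not keep_singletons:
        clusters = [c for c in clusters if c["members"] > 1]
    return clusters


def correlated_bins(
    composition: pd.DataFrame,
    detected: pd.DataFrame,
    min_samples: int = 4,
    r_flag: float = 0.9,
    method: str = "pearson",
) -> list[dict]:
    """Flag bin pairs whose compositions track each other suspiciously.

    ``composition`` is the scaled CLR table (bins x samples) and
    ``detected`` the boolean detection mask from censoring.  Bins detected
    in fewer than ``min_samples`` samples are ignored.  For each remaining
    pair, correlation is computed over samples where both are detected;
    pairs at or above ``r_flag`` are returned for manual bin-merge review
    (merging is a logged user action, never automatic -- the decision needs
    outside evidence such as range data or pileup inspection).
    """
    eligible = [b for b in composition.index
                if int(detected.loc[b].sum()) >= min_samples]
    flags = []
    for i, a in enumerate(eligible):
        for b in eligible[i + 1:]:
            both = detected.loc[a] & detected.loc[b]
            if int(both.sum()) < 3:
                continue
            x = composition.loc[a, both].astype(float)
            y = composition.loc[b, both].astype(float)
            if x.std() == 0 or y.std() == 0:
                r = 1.0 if (x.std() == 0 and y.std() == 0) else 0.0
            elif method == "pearson":
                r = float(stats.pearsonr(x, y)[0])
            else:
                r = float(stats.spearmanr(x, y)[0])
            if r >= r_flag:
                flags.append({"bin_a": a, "bin_b": b, "r": r,
                              "n_samples": int(both.sum())})
    return flags
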