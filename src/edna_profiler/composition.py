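"""Compositional analysis of censored counts and comparison to capture data.

Read counts are compositional: library sizes are arbitrary, so per-sample
proportions are placed in an unconstrained space with the centered log-ratio
(CLR) transform, ``clr(p_i) = ln p_i - mean_j ln p_j``, computed over the
bins detected in that sample (censored zeros carry no information about the
log-ratio geometry and are excluded rather than imputed).  A single global
scalar, ``-min(CLR) + eps``, is then added to every detected cell so that
all detections are positive and per-bin sums across samples are meaningful;
the scalar is recorded on the table because summed compositions shift by
``n_positive * scalar`` under any other choice.

On top of the transform: per-bin summed/average compositions and ranks,
correlation of summed composition with log(CPUE), technical-replicate
concordance and dropout, site contrasts, a sample correlation matrix with
Ward clustering, and the eDNA-versus-capture concordance classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .countsqc import CountsTable


@dataclass
class CompositionTable:
    """Scaled CLR values (bins x samples) with the applied offset."""

    values: pd.DataFrame            # 0 where undetected
    detected: pd.DataFrame          # boolean mask of detected cells
    scalar_offset: float
    dropped_samples: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def bins(self) -> list[str]:
        return list(self.values.index)

    def unscaled(self) -> pd.DataFrame:
        """CLR values before the positivity offset (0 where undetected)."""
        return self.values.where(~self.detected, self.values - self.scalar_offset)


def clr_transform(table: CountsTable, eps: float = 0.01,
                  sample_types: tuple[str, ...] = ("biological",)
                  ) -> CompositionTable:
    """Scaled CLR of censored per-sample proportions.

    Proportions are renormalized over the detected bins of each analyzed
    sample, CLR-transformed (so they sum to zero per sample), then shifted
    by a single dataset-wide scalar making every detected value positive.
    Samples with fewer than two detected bins have no defined log-ratio and
    are dropped with a warning.  Undetected cells remain exactly zero.
    """
    use = [s for s in table.analyzed.columns
           if table.sample_types.get(s, "biological") in sample_types]
    counts = table.counts[use]
    clr = pd.DataFrame(0.0, index=counts.index, columns=use)
    detected = counts > 0
    dropped = []
    for s in use:
        det = detected[s]
        if int(det.sum()) < 2:
            dropped.append(s)
            continue
        p = counts.loc[det, s].astype(float)
        p = p / p.sum()
        logp = np.log(p)
        clr.loc[det, s] = logp - logp.mean()
    keep = [s for s in use if s not in dropped]
    if dropped:
        warnings.warn(f"samples with <2 detected bins dropped: {dropped}",
                      stacklevel=2)
    clr = clr[keep]
    detected = detected[keep].astype(bool)
    det_values = clr.to_numpy()[detected.to_numpy()] if keep else np.array([])
    offset = float(-det_values.min() + eps) if det_values.size else eps
    scaled = clr.where(~detected, clr + offset)
    return CompositionTable(values=scaled, detected=detected,
                            scalar_offset=offset, dropped_samples=dropped)


def summarize_bins(comp: CompositionTable) -> pd.DataFrame:
    """Per-bin summed and average compositions over positive samples.

    Positivity is detection after censoring (at least the proportion
    threshold, pre-transform).  Average = sum / n_positive; ranks are by
    summed composition, descending; bins never detected are unranked.
    """
    summed = comp.values.where(comp.detected, 0.0).sum(axis=1)
    n_pos = comp.detected.sum(axis=1).astype(int)
    avg = summed.divide(n_pos.replace(0, np.nan))
    out = pd.DataFrame({
        "summed_composition": summed,
        "average_composition": avg.fillna(0.0),
        "n_positive": n_pos,
    })
    ranked = out[out["n_positive"] > 0].sort_values(
        "summed_composition", ascending=False)
    out["edna_rank"] = pd.Series(
        range(1, len(ranked) + 1), index=ranked.index, dtype="float")
    return out


def cpue_correlation(
    summed: pd.Series,
    cpue: pd.Series,
    exclusions: list[str] | None = None,
) -> dict:
    """Correlate summed eDNA composition with log CPUE across bins.

    CPUE is scaled to percentages of its total before the log -- a constant
    multiplier that provably cannot change the correlation (asserted).
    Pearson (with t-distribution p, n-2 df) and Spearman are both reported.
    """
    drop = set(exclusions or [])
    common = [b for b in summed.index
              if b in cpue.index and b not in drop
              and np.isfinite(cpue[b]) and cpue[b] > 0]
    if len(common) < 3:
        raise ValueError(f"need >=3 bins with CPUE, got {len(common)}")
    y = summed[common].astype(float)
    scaled = 100.0 * cpue[common] / cpue[common].sum()
    x = np.log(scaled.astype(float))
    r, p = stats.pearsonr(x, y)
    r_unscaled = stats.pearsonr(np.log(cpue[common].astype(float)), y)[0]
    assert abs(r - r_unscaled) < 1e-12, "CPUE rescaling changed Pearson R"
    rho, p_s = stats.spearmanr(x, y)
    return {"pearson_r": float(r), "pearson_p": float(p),
            "spearman_rho": float(rho), "spearman_p": float(p_s),
            "n": len(common)}


def replicate_concordance(comp: CompositionTable,
                          replicate_pairs: list[tuple[str, str]]) -> dict:
    """Concordance and dropout between technical replicate pairs.

    Pools (replicate 1, replicate 2) scaled compositions across pairs for
    taxa detected in both members (Pearson R over the pooled points), and
    tallies taxa detected in exactly one member with the detected member's
    composition -- the dropout pattern.
    """
    pairs = [(a, b) for a, b in replicate_pairs
             if a in comp.values.columns and b in comp.values.columns]
    if not pairs:
        warnings.warn("no replicate pairs with both members analyzable",
                      stacklevel=2)
        return {"pearson_r": None, "pearson_p": None, "n_pairs": 0,
                "nonzero_points": pd.DataFrame(), "dropout": pd.DataFrame()}
    both_x, both_y = [], []
    dropout_rows = []
    both_rows = []
    for a, b in pairs:
        det_a, det_b = comp.detected[a], comp.detected[b]
        for taxon in comp.bins:
            va, vb = comp.values.loc[taxon, a], comp.values.loc[taxon, b]
            if det_a[taxon] and det_b[taxon]:
                both_x.append(va)
                both_y.append(vb)
                both_rows.append({"pair": f"{a}|{b}", "taxon": taxon,
                                  "mean_composition": (va + vb) / 2})
            elif det_a[taxon] != det_b[taxon]:
                dropout_rows.append({
                    "pair": f"{a}|{b}", "taxon": taxon,
                    "detected_in": a if det_a[taxon] else b,
                    "composition": va if det_a[taxon] else vb})
    if len(both_x) >= 3:
        r, p = stats.pearsonr(both_x, both_y)
    else:
        r = p = float("nan")
    n_obs = len(both_rows) + len(dropout_rows)
    return {
        "pearson_r": float(r), "pearson_p": float(p), "n_pairs": len(pairs),
        "nonzero_points": pd.DataFrame({"rep1": both_x, "rep2": both_y}),
        "both_detected": pd.DataFrame(both_rows),
        "dropout": pd.DataFrame(dropout_rows),
        "dropout_fraction": len(dropout_rows) / n_obs if n_obs else 0.0,
    }


def site_contrast(comp: CompositionTable, manifest: pd.DataFrame,
                  site_a: str, site_b: str,
                  min_detections: int = 2) -> pd.DataFrame:
    """Per-bin mean compositions at two sites and their difference.

    Only bins detected in at least ``min_detections`` samples at one of the
    two sites are reported; a side with zero detections is annotated (the
    analog of the asterisks in a barrier-contrast plot).
    """
    site_of = dict(zip(manifest["sample"], manifest["site"]))
    cols_a = [s for s in comp.samples if site_of.get(s) == site_a]
    cols_b = [s for s in comp.samples if site_of.get(s) == site_b]
    if not cols_a or not cols_b:
        raise KeyError(f"no analyzable samples at {site_a!r} or {site_b!r}")
    rows = []
    for taxon in comp.bins:
        det_a = int(comp.detected.loc[taxon, cols_a].sum())
        det_b = int(comp.detected.loc[taxon, cols_b].sum())
        if max(det_a, det_b) < min_detections:
            continue
        mean_a = float(comp.values.loc[taxon, cols_a].mean())
        mean_b = float(comp.values.loc[taxon, cols_b].mean())
        rows.append({"bin": taxon, "mean_a": mean_a, "mean_b": mean_b,
                     "difference": mean_a - mean_b,
                     "zero_side": (site_a if det_a == 0 else
                                   site_b if det_b == 0 else "")})
    return pd.DataFrame(rows).set_index("bin") if rows else pd.DataFrame(
        columns=["mean_a", "mean_b", "difference", "zero_side"])


def sample_correlation_matrix(comp: CompositionTable,
                              min_prevalence: int = 4
                              ) -> tuple[pd.DataFrame, list[str]]:
    """Samples x samples Spearman matrix with a Ward clustering order.

    Taxa detected in fewer than ``min_prevalence`` samples are removed
    first.  Ward linkage is computed on ``1 - r`` and the dendrogram leaf
    order returned alongside the symmetric, unit-diagonal matrix.
    """
    if len(comp.samples) < 3:
        raise ValueError("need at least 3 samples")
    keep = comp.detected.sum(axis=1) >= min_prevalence
    values = comp.values.loc[keep]
    rho = values.corr(method="spearman")
    np.fill_diagonal(rho.values, 1.0)
    dist = squareform((1 - rho).to_numpy(), checks=False)
    link = hierarchy.linkage(dist, method="ward")
    order = [comp.samples[i] for i in hierarchy.leaves_list(link)]
    return rho, order


CONCORDANCE_CLASSES = ("both", "eDNA-only", "capture-only", "no-reference",
                       "flagged-contaminant")


def concordance_classify(
    bin_totals: pd.Series,
    capture: pd.Series,
    no_reference: list[str] | None = None,
    contaminant_flags: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Classify taxa by eDNA-versus-capture concordance and tally support.

    ``bin_totals`` are total eDNA reads per bin (zero/absent = undetected);
    ``capture`` is CPUE per taxon observed by active capture;
    ``no_reference`` lists capture taxa with no reference sequence;
    ``contaminant_flags`` lists bins disqualified by control enrichment.
    Classes are mutually exclusive in the order: flagged-contaminant,
    no-reference, both, eDNA-only, capture-only.  The tallies summarize read
    support: concordant bins with >50 reads and with exactly 1 read, and
    eDNA-only bins with <10 and with 10-49 reads.
    """
    noref = set(no_reference or [])
    flagged = set(contaminant_flags or [])
    taxa = sorted(set(bin_totals.index) | set(capture.index) | noref)
    rows = []
    for t in taxa:
        reads = int(bin_totals.get(t, 0))
        cp = capture.get(t, np.nan)
        caught = t in capture.index  # CPUE may be unavailable yet observed
        if t in flagged:
            cls = "flagged-contaminant"
        elif t in noref:
            cls = "no-reference"
        elif reads > 0 and caught:
            cls = "both"
        elif reads > 0:
            cls = "eDNA-only"
        else:
            cls = "capture-only"
        rows.append({"taxon": t, "total_reads": reads,
                     "cpue": cp, "class": cls})
    report = pd.DataFrame(rows).set_index("taxon")
    both = report[report["class"] == "both"]
    only = report[report["class"] == "eDNA-only"]
    tallies = {
        "concordant_over_50_reads": int((both["total_reads"] > 50).sum()),
        "concordant_single_read": int((both["total_reads"] == 1).sum()),
        "edna_only_under_10_reads": int((only["total_reads"] < 10).sum()),
        "edna_only_10_to_49_reads": int(
            ((only["total_reads"] >= 10) & (only["total_reads"] < 50)).sum()),
    }
    return report, tallies
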