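"""Published watershed-survey summary tables and desk statistics over them.

The package ships the per-bin summary tables of a 12S eDNA metabarcoding
survey of the St. Regis River (NY) fish community, alongside active-capture
CPUE from the same watershed: one table of taxonomic bins detected by both
eDNA and capture surveys, and one of discordant detections (contaminant-
flagged bins, capture-only taxa, taxa lacking any 12S reference, and
eDNA-only detections graded by range plausibility).  These serve as a real
reference dataset for the compositional statistics: the CPUE correlation
and the read-support tallies are recomputed from the printed columns.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .composition import concordance_classify, cpue_correlation

# Whole-run aggregates reported for the survey: total reads mapped at the
# chosen stringency, and the number of libraries above the 1,500-read
# threshold used for compositional analysis.
TOTAL_MAPPED_READS = 2_890_000
N_ANALYZED_SAMPLES = 45


def _load(name: str) -> pd.DataFrame:
    with resources.files("edna_profiler.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_concordant_bins() -> pd.DataFrame:
    """Bins detected by both eDNA and capture (ranked + below-threshold)."""
    return _load("survey_concordant_bins.tsv")


def load_discordant_bins() -> pd.DataFrame:
    """Taxa detected by only one method, plus contaminant-flagged bins."""
    return _load("survey_discordant_bins.tsv")


def survey_cpue_correlation() -> dict:
    """Correlation of summed eDNA composition with log CPUE.

    Uses the ranked concordant bins, excluding the CYPRINID3 bin (a shadow
    of CYPRINID2 via low-rate misassignment) and bins without CPUE.
    """
    t1 = load_concordant_bins()
    ranked = t1[t1["summed_composition"].notna()]
    summed = pd.Series(ranked["summed_composition"].to_numpy(),
                       index=ranked["taxon"])
    cpue = pd.Series(ranked["cpue"].to_numpy(), index=ranked["taxon"])
    return cpue_correlation(summed, cpue, exclusions=["CYPRINID3"])


def survey_concordance_report() -> tuple[pd.DataFrame, dict]:
    """Rebuild the concordance classification from the printed tables."""
    t1 = load_concordant_bins()
    t2 = load_discordant_bins()
    totals = pd.concat([
        pd.Series(t1["total_reads"].to_numpy(), index=t1["taxon"]),
        pd.Series(t2["total_reads"].fillna(0).to_numpy(), index=t2["taxon"]),
    ])
    observed = pd.concat([
        pd.Series(t1["cpue"].to_numpy(), index=t1["taxon"]),
        pd.Series(t2.loc[t2["observed"] == 1, "cpue"].to_numpy(),
                  index=t2.loc[t2["observed"] == 1, "taxon"]),
    ])
    no_ref = t2.loc[t2["category"] == "no-reference", "taxon"].tolist()
    flagged = t2.loc[t2["category"] == "contaminant-flagged", "taxon"].tolist()
    return concordance_classify(totals, observed, no_reference=no_ref,
                                contaminant_flags=flagged)


def survey_read_support_tallies() -> dict:
    """Read-support tallies of the concordance classification."""
    _, tallies = survey_concordance_report()
    return tallies


def survey_library_summary() -> dict:
    """Per-sample depth and taxon skew from the run aggregates.

    Mean mapped reads per compositionally analyzed sample, and the share of
    all mapped reads held by the four most abundant bins.
    """
    t1 = load_concordant_bins()
    top4 = t1["total_reads"].astype(float).nlargest(4).sum()
    return {
        "mean_mapped_reads_per_sample": TOTAL_MAPPED_READS / N_ANALYZED_SAMPLES,
        "top4_bin_read_share_pct": 100.0 * top4 / TOTAL_MAPPED_READS,
    }
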