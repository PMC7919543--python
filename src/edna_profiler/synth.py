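"""Synthetic data generation for the 12S profiling pipeline.

Everything here is deterministic under a fixed seed.  One global seed is
expanded into per-operation child seeds through numpy's ``SeedSequence``
spawn-key mechanism, keyed by a stable CRC32 of an operation label, so that
components draw from independent streams but remain reproducible.

The module provides

* reference sets with controlled pairwise divergence structure, including
  identical cross-species sequences (the seeds of a-priori taxon bins);
* amplicon reads with a position-dependent substitution error rate and a
  small fraction of 1-bp indels;
* multi-sample communities with log-skewed abundances, index crosstalk,
  point contamination of negative controls and technical-replicate dropout;
* a catch-per-unit-effort (CPUE) table lognormally perturbed around the true
  community totals;
* the "watershed" scenario: a fixed 20-species reference structure and
  sampling design emulating the study conditions of a riverine fish eDNA
  survey (see docs/methods.md for the rationale of every default).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .refdb import ReferenceDB, ReferenceSequence

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"


def child_seed(seed: int, label: str, index: int = 0) -> np.random.SeedSequence:
    """Derive an independent child seed from ``seed`` for operation ``label``."""
    return np.random.SeedSequence(seed, spawn_key=(zlib.crc32(label.encode()), index))


def child_rng(seed: int, label: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, label, index))


# ---------------------------------------------------------------------------
# Error model
# ---------------------------------------------------------------------------

@dataclass
class ErrorModel:
    """Per-position substitution error probability as a polynomial in cycle.

    ``coefficients[k]`` multiplies ``position**k`` with 1-based positions
    (sequencing cycles).  ``indel_fraction`` is the fraction of error events
    realized as 1-bp indels instead of substitutions (insertion or deletion
    with equal odds).
    """

    coefficients: list[float]
    indel_fraction: float = 0.0
    window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.coefficients) == 0:
            raise ValueError("at least one coefficient required")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ValueError("indel_fraction must be in [0, 1]")

    @property
    def order(self) -> int:
        return len(self.coefficients) - 1

    def rate(self, positions) -> np.ndarray:
        """Error probability at 1-based positions, clipped to [0, 1]."""
        pos = np.asarray(positions, dtype=float)
        out = np.zeros_like(pos)
        for k, c in enumerate(self.coefficients):
            out += c * pos**k
        return np.clip(out, 0.0, 1.0)

    @classmethod
    def linear(cls, rate_first: float, rate_last: float, read_length: int = 98,
               indel_fraction: float = 0.0) -> "ErrorModel":
        """Line through (1, rate_first) and (read_length, rate_last)."""
        slope = (rate_last - rate_first) / (read_length - 1)
        return cls([rate_first - slope, slope], indel_fraction=indel_fraction)

    @classmethod
    def study_default(cls, indel_fraction: float = 0.2) -> "ErrorModel":
        """Linear 0.66% at cycle 1 rising to 2.96% at cycle 98.

        These endpoints are the package's default MiSeq-like amplicon error
        profile; 20% of errors are realized as 1-bp indels, mirroring the
        substitution:indel convention of common read simulators.
        """
        return cls.linear(0.0066, 0.0296, 98, indel_fraction=indel_fraction)

    def to_dict(self) -> dict:
        return {"order": self.order, "coefficients": list(self.coefficients),
                "indel_fraction": self.indel_fraction,
                "window": list(self.window) if self.window else None}

    @classmethod
    def from_dict(cls, d: dict) -> "ErrorModel":
        return cls(list(d["coefficients"]),
                   indel_fraction=d.get("indel_fraction", 0.0),
                   window=tuple(d["window"]) if d.get("window") else None)


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------

class InfeasibleDivergence(ValueError):
    """Target pairwise divergences cannot be realized on sequence space."""


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(seq: np.ndarray, sites, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for s in sites:
        choices = _BASES[_BASES != out[s]]
        out[s] = rng.choice(choices)
    return out


def generate_references(
    divergence_matrix: pd.DataFrame,
    length: int = 98,
    identical_groups: list[set[str]] | None = None,
    accession_counts: dict[str, int] | None = None,
    intra_divergence_subs: int = 1,
    seed: int = 0,
) -> ReferenceDB:
    """Generate reference sequences realizing target pairwise divergences.

    ``divergence_matrix`` is a symmetric species-by-species table of target
    divergences (fractions of ``length``).  Targets are converted to
    substitution counts and must be additive along a tree (checked on the
    minimum spanning tree to within +-2 substitutions); mutated sites are
    globally disjoint so realized Hamming divergences match targets exactly.
    Species in an ``identical_groups`` set share one sequence.  Species
    listed in ``accession_counts`` with count > 1 receive extra accessions
    at ``intra_divergence_subs`` substitutions from the primary sequence.
    """
    dm = divergence_matrix
    species = list(dm.index)
    if list(dm.columns) != species:
        raise ValueError("divergence matrix must be square with matching labels")
    if (dm.values < 0).any() or (dm.values > 0.75).any():
        raise InfeasibleDivergence("divergences must lie in [0, 0.75]")
    groups = [set(g) for g in (identical_groups or [])]
    flat = [s for g in groups for s in g]
    if len(flat) != len(set(flat)):
        raise ValueError("identical_groups must be disjoint")
    rep_of: dict[str, str] = {}
    for g in groups:
        rep = min(g)
        for s in g:
            rep_of[s] = rep
            for t in g:
                if s != t and round(dm.loc[s, t] * length) != 0:
                    raise InfeasibleDivergence(
                        f"{s} and {t} are in an identical group but target "
                        f"divergence is nonzero")
    reps = sorted({rep_of.get(s, s) for s in species})

    k = (dm * length).round().astype(int)
    tree = nx.Graph()
    tree.add_nodes_from(reps)
    complete = nx.Graph()
    for i, a in enumerate(reps):
        for b in reps[i + 1:]:
            complete.add_edge(a, b, weight=int(k.loc[a, b]))
    mst = nx.minimum_spanning_tree(complete) if len(reps) > 1 else tree
    # Tree-path distances must reproduce the requested matrix.
    for i, a in enumerate(reps):
        lengths = nx.single_source_dijkstra_path_length(mst, a) if len(reps) > 1 else {a: 0}
        for b in reps[i + 1:]:
            if abs(lengths[b] - int(k.loc[a, b])) > 2:
                raise InfeasibleDivergence(
                    f"target divergences are not tree-additive: pair "
                    f"({a}, {b}) realizable only at {lengths[b]} of "
                    f"{int(k.loc[a, b])} substitutions")

    counts = dict(accession_counts or {})
    n_extra_sites = sum(
        (counts.get(s, 1) - 1) * intra_divergence_subs for s in species)
    total_subs = sum(d["weight"] for _, _, d in mst.edges(data=True))
    if total_subs + n_extra_sites > length:
        raise InfeasibleDivergence(
            f"{total_subs + n_extra_sites} substitution sites needed but "
            f"sequences are only {length} bp")

    rng = np.random.default_rng(child_seed(seed, "generate_references"))
    site_pool = list(rng.permutation(length))
    root = reps[0]
    seqs: dict[str, np.ndarray] = {root: _random_seq(rng, length)}
    for parent, child in nx.bfs_edges(mst, root) if len(reps) > 1 else []:
        w = mst.edges[parent, child]["weight"]
        sites = [site_pool.pop() for _ in range(w)]
        seqs[child] = _mutate(seqs[parent], sites, rng)

    db_seqs: list[ReferenceSequence] = []
    counter = 1
    for sp in species:
        primary = seqs[rep_of.get(sp, sp)]
        n_acc = counts.get(sp, 1)
        for a in range(n_acc):
            if a == 0:
                seq = primary
            else:
                sites = [site_pool.pop() for _ in range(intra_divergence_subs)]
                seq = _mutate(primary, sites, rng)
            db_seqs.append(ReferenceSequence(
                f"SYN{counter:04d}", sp, seq.tobytes().decode()))
            counter += 1
    return ReferenceDB(db_seqs, checklist=species)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    ref,
    n: int = 10000,
    model: ErrorModel | None = None,
    seed: int = 0,
    id_prefix: str | None = None,
) -> list[tuple[str, str]]:
    """Simulate ``n`` error-bearing reads from one reference sequence.

    Each position of the template fails independently with the model's
    position-specific probability; an error is a substitution to one of the
    three other bases (uniformly) with probability ``1 - indel_fraction``,
    otherwise a 1-bp insertion (random base after the position) or deletion
    with equal odds.  Homopolymer-specific error is not modeled.  Read ids
    record provenance as ``<prefix>_r<k>``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    model = model or ErrorModel.study_default()
    if isinstance(ref, ReferenceSequence):
        template, prefix = ref.sequence, id_prefix or ref.accession
    else:
        template, prefix = str(ref).upper(), id_prefix or "ref"
    L = len(template)
    p = model.rate(np.arange(1, L + 1))
    rng = np.random.default_rng(child_seed(seed, "simulate_reads"))
    tarr = np.frombuffer(template.encode(), dtype=np.uint8)

    err_mask = rng.random((n, L)) < p
    is_indel = err_mask & (rng.random((n, L)) < model.indel_fraction)
    reads: list[tuple[str, str]] = []
    for i in range(n):
        errs = np.flatnonzero(err_mask[i])
        rid = f"{prefix}_r{i}"
        if errs.size == 0:
            reads.append((rid, template))
            continue
        chars: list[str] = list(template)
        # Apply right-to-left so indels do not shift pending positions.
        for j in errs[::-1]:
            if is_indel[i, j]:
                if rng.random() < 0.5:
                    chars.insert(j + 1, _BASE_STR[rng.integers(0, 4)])
                else:
                    del chars[j]
            else:
                alt = _BASE_STR.replace(chr(tarr[j]), "")
                chars[j] = alt[rng.integers(0, 3)]
        reads.append((rid, "".join(chars)))
    return reads


def write_reads_fasta(reads, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f">{rid}\n{seq}\n")


def write_reads_fastq(reads, path, quality: int = 30) -> None:
    q = chr(quality + 33)
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{q * len(seq)}\n")


# ---------------------------------------------------------------------------
# Community simulation
# ---------------------------------------------------------------------------

@dataclass
class CommunitySpec:
    """Sampling design for a multi-sample synthetic community."""

    species_abundances: dict[str, dict[str, float]]
    n_reads: dict[str, int]
    sample_types: dict[str, str] = field(default_factory=dict)
    sites: dict[str, str] = field(default_factory=dict)
    crosstalk_rate: float = 0.0
    contamination_spikes: list[tuple[str, str, int]] = field(default_factory=list)
    replicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    dropout_prob: float = 0.0
    seed: int = 0

    @property
    def samples(self) -> list[str]:
        return list(self.n_reads)

    def sample_type(self, sample: str) -> str:
        if sample in self.sample_types:
            return self.sample_types[sample]
        return "negative" if not self.species_abundances.get(sample) else "biological"

    def validate(self) -> None:
        for rate in (self.crosstalk_rate, self.dropout_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        spiked = {s for s, _, _ in self.contamination_spikes}
        for sample in self.samples:
            ab = self.species_abundances.get(sample, {})
            if ab:
                total = sum(ab.values())
                if abs(total - 1.0) > 1e-6:
                    raise ValueError(
                        f"abundances of {sample} sum to {total}, expected 1")
            if self.sample_type(sample) == "negative" and ab and sample not in spiked:
                raise ValueError(
                    f"negative control {sample} has nonzero abundances")
        for a, b in self.replicate_pairs:
            if a not in self.n_reads or b not in self.n_reads:
                raise ValueError(f"replicate pair ({a}, {b}) not in samples")

    def manifest(self) -> pd.DataFrame:
        pair_of = {}
        for i, (a, b) in enumerate(self.replicate_pairs, start=1):
            pair_of[a] = pair_of[b] = f"pair{i}"
        return pd.DataFrame({
            "sample": self.samples,
            "type": [self.sample_type(s) for s in self.samples],
            "site": [self.sites.get(s, "") for s in self.samples],
            "replicate_pair": [pair_of.get(s, "") for s in self.samples],
        })


def simulate_counts(spec: CommunitySpec, species: list[str] | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count-level community simulation (no read sequences).

    Returns ``(truth, observed)`` species-by-sample tables: ``truth`` holds
    per-sample source counts after replicate dropout and contamination
    spikes but before crosstalk; ``observed`` additionally relocates reads
    between samples at the crosstalk rate.  This is the fast path used for
    Monte-Carlo calibration of downstream statistics; ``generate_community``
    builds actual reads on top of the same logic.
    """
    spec.validate()
    rng = np.random.default_rng(child_seed(spec.seed, "community_counts"))
    all_species = species or sorted(
        {sp for ab in spec.species_abundances.values() for sp in ab}
        | {sp for _, sp, _ in spec.contamination_spikes})
    samples = spec.samples
    truth = pd.DataFrame(0, index=all_species, columns=samples, dtype=int)
    abundances = {s: dict(spec.species_abundances.get(s, {})) for s in samples}

    # Technical-replicate dropout: each taxon independently vanishes from one
    # randomly chosen member of a pair (amplification failure).
    for a, b in spec.replicate_pairs:
        taxa = sorted(set(abundances[a]) | set(abundances[b]))
        for t in taxa:
            if rng.random() < spec.dropout_prob:
                victim = a if rng.random() < 0.5 else b
                abundances[victim].pop(t, None)

    for s in samples:
        ab = abundances[s]
        n = spec.n_reads[s]
        if not ab or n == 0:
            continue
        taxa = sorted(ab)
        probs = np.array([ab[t] for t in taxa], dtype=float)
        probs /= probs.sum()
        counts = rng.multinomial(n, probs)
        for t, c in zip(taxa, counts):
            truth.loc[t, s] += int(c)
    for sample, sp, count in spec.contamination_spikes:
        truth.loc[sp, sample] += int(count)

    observed = truth.copy()
    if spec.crosstalk_rate > 0 and len(samples) > 1:
        for s in samples:
            for sp in all_species:
                c = int(truth.loc[sp, s])
                if c == 0:
                    continue
                hops = rng.binomial(c, spec.crosstalk_rate)
                if hops == 0:
                    continue
                observed.loc[sp, s] -= hops
                others = [x for x in samples if x != s]
                dest = rng.integers(0, len(others), size=hops)
                for d in dest:
                    observed.loc[sp, others[d]] += 1
    return truth, observed


@dataclass
class CommunityData:
    """Realized synthetic community: reads plus ground truth."""

    reads: dict[str, list[tuple[str, str]]]  # sample -> [(read_id, seq)]
    truth: pd.DataFrame                      # species x samples, pre-crosstalk
    manifest: pd.DataFrame
    source: dict[str, tuple[str, str]]       # read_id -> (species, accession)
    n_relocated: int = 0

    def sample_labels(self) -> dict[str, str]:
        return {rid: s for s, rs in self.reads.items() for rid, _ in rs}

    def all_reads(self) -> list[tuple[str, str]]:
        return [r for s in self.reads for r in self.reads[s]]


def generate_community(db: ReferenceDB, spec: CommunitySpec,
                       model: ErrorModel | None = None) -> CommunityData:
    """Generate per-sample reads for a community specification.

    Reads are drawn multinomially from per-sample species abundances (after
    replicate dropout), split uniformly among the species' reference
    accessions, passed through the error model, then relocated read-wise at
    the crosstalk rate; contamination spikes are appended before crosstalk.
    """
    spec.validate()
    model = model or ErrorModel.study_default()
    for s in spec.species_abundances.values():
        missing = set(s) - set(db.species_index)
        if missing:
            raise ValueError(f"species not in reference DB: {sorted(missing)}")
    truth, _ = simulate_counts(spec, species=sorted(db.species_index))
    rng = np.random.default_rng(child_seed(spec.seed, "community_reads"))
    idx = db.species_index

    reads: dict[str, list[tuple[str, str]]] = {s: [] for s in spec.samples}
    source: dict[str, tuple[str, str]] = {}
    for s in spec.samples:
        for sp in truth.index:
            c = int(truth.loc[sp, s])
            if c == 0:
                continue
            accs = sorted(idx[sp])
            split = rng.multinomial(c, np.full(len(accs), 1 / len(accs)))
            for acc, m in zip(accs, split):
                if m == 0:
                    continue
                sub = simulate_reads(
                    db.get(acc), n=int(m), model=model,
                    seed=int(rng.integers(0, 2**31)),
                    id_prefix=f"{s}.{acc}")
                for rid, seq in sub:
                    reads[s].append((rid, seq))
                    source[rid] = (sp, acc)

    n_relocated = 0
    if spec.crosstalk_rate > 0 and len(spec.samples) > 1:
        samples = spec.samples
        for s in samples:
            kept = []
            for rid, seq in reads[s]:
                if rng.random() < spec.crosstalk_rate:
                    others = [x for x in samples if x != s]
                    dest = others[rng.integers(0, len(others))]
                    reads[dest].append((rid, seq))
                    n_relocated += 1
                else:
                    kept.append((rid, seq))
            reads[s] = kept
    return CommunityData(reads=reads, truth=truth, manifest=spec.manifest(),
                         source=source, n_relocated=n_relocated)


def generate_cpue(totals, noise_sd: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Lognormal CPUE around true totals: ``CPUE = total * exp(N(0, sd^2))``."""
    totals = pd.Series(totals, dtype=float)
    if (totals <= 0).any():
        raise ValueError("totals must be positive for included taxa")
    rng = np.random.default_rng(child_seed(seed, "generate_cpue"))
    eps = rng.normal(0.0, noise_sd, size=len(totals))
    return pd.DataFrame({"taxon": totals.index,
                         "cpue": totals.values * np.exp(eps)})


# ---------------------------------------------------------------------------
# The watershed scenario (fixed study conditions)
# ---------------------------------------------------------------------------

# 30 species whose reference structure mirrors the confusability classes of
# a regional 12S database: well-separated taxa, two identical-sequence
# groups, a star-shaped haplotype complex dense enough to force an
# error-based bin, and six congener pairs one substitution apart (close
# enough to leak reads, too separated to be binned).  Names are synthetic.
_ISOLATED = [
    "Esox_simulans", "Perca_ficta", "Salmo_fictus", "Ictalurus_simulatus",
    "Catostomus_fictus", "Anguilla_simulans", "Lota_ficta",
    "Ambloplites_fictus", "Micropterus_simulatus",
]
_IDENTICAL_GROUPS = [
    {"Coregonus_parvus", "Coregonus_minor"},
    {"Lampetra_sima", "Lampetra_simillima"},
]
# (early accession species, late accession species, 0-based differing site)
_CLOSE_PAIRS = [
    ("Etheostoma_unum", "Etheostoma_duo", 39),
    ("Lepomis_primus", "Lepomis_secundus", 59),
    ("Moxostoma_majus", "Moxostoma_minus", 74),
    ("Ameiurus_altus", "Ameiurus_imus", 81),
    ("Noturus_castus", "Noturus_cautus", 87),
    ("Percina_soror", "Percina_sororcula", 92),
]
_COMPLEX_CENTER = "Notropis_medius"
_COMPLEX_STAR = ("Notropis_radians", (19, 59, 79, 91))  # accessions 1 sub each
_COMPLEX_SATELLITES = [
    ("Notropis_alpha", (24, 64)),
    ("Notropis_beta", (34, 77)),
    ("Notropis_gamma", (44, 84)),
]

WATERSHED_LENGTH = 98


def watershed_species() -> list[str]:
    sats = [s for s, _ in _COMPLEX_SATELLITES]
    return (_ISOLATED + sorted(set().union(*_IDENTICAL_GROUPS))
            + [s for pair in _CLOSE_PAIRS for s in pair[:2]]
            + [_COMPLEX_CENTER, _COMPLEX_STAR[0]] + sats)


def watershed_reference_db(seed: int = 0) -> ReferenceDB:
    """Build the fixed 30-species watershed reference database.

    Each species group is seeded by mutating ~8 random sites of a common
    ancestral sequence, keeping between-group divergences near 14-16%;
    within-group structure (identical sequences, single-substitution
    congeners, the star complex) is imposed exactly at fixed sites.  Two
    isolated species carry a second conspecific accession one substitution
    away, giving the accession redundancy needed for error-rate estimation.
    """
    L = WATERSHED_LENGTH
    rng = np.random.default_rng(child_seed(seed, "watershed_refs"))
    base = _random_seq(rng, L)
    reserved = sorted(set(_COMPLEX_STAR[1])
                      | {s for _, sites in _COMPLEX_SATELLITES for s in sites}
                      | {s for _, _, s in _CLOSE_PAIRS})
    free_sites = [s for s in range(L) if s not in reserved]

    def founder() -> np.ndarray:
        sites = rng.choice(len(free_sites), size=8, replace=False)
        return _mutate(base, [free_sites[i] for i in sites], rng)

    seqs: list[ReferenceSequence] = []
    counter = 0

    def add(species: str, seq: np.ndarray) -> None:
        nonlocal counter
        counter += 1
        seqs.append(ReferenceSequence(
            f"SYN{counter:04d}", species, seq.tobytes().decode()))

    for i, sp in enumerate(_ISOLATED):
        f = founder()
        add(sp, f)
        if i < 2:  # two species get a second, slightly divergent accession
            site = free_sites[int(rng.integers(0, len(free_sites)))]
            add(sp, _mutate(f, [site], rng))
    for group in _IDENTICAL_GROUPS:
        f = founder()
        for sp in sorted(group):
            add(sp, f)
    for early, late, site in _CLOSE_PAIRS:
        f = founder()
        add(early, f)
        add(late, _mutate(f, [site], rng))
    center = founder()
    star_sp, star_sites = _COMPLEX_STAR
    # Star accessions are assigned before the central haplotype so that
    # tied best hits resolve away from the center: the center species then
    # leaks enough reads to the star species to force an error-based bin,
    # emulating a radiating haplotype complex with unsettled taxonomy.
    for site in star_sites:
        add(star_sp, _mutate(center, [site], rng))
    add(_COMPLEX_CENTER, center)
    for sp, sites in _COMPLEX_SATELLITES:
        add(sp, _mutate(center, list(sites), rng))
    return ReferenceDB(seqs, checklist=watershed_species())


def watershed_community_spec(
    db: ReferenceDB,
    seed: int = 0,
    n_biological: int = 10,
    n_negative: int = 3,
    n_replicate_pairs: int = 2,
    reads_per_sample: int = 8000,
    abundance_sigma: float = 1.3,
    crosstalk_rate: float = 1e-4,
    spike_reads: int = 500,
    dropout_prob: float = 0.2,
) -> CommunitySpec:
    """Sampling design emulating the survey: log-skewed communities at two
    sites separated by a barrier, field blanks with one point-contamination
    spike, index crosstalk at 1e-4 and technical-replicate dropout."""
    rng = np.random.default_rng(child_seed(seed, "watershed_community"))
    species = sorted(db.species_index)
    below_only = set(rng.choice(species, size=4, replace=False))
    weights = {sp: float(np.exp(rng.normal(0.0, abundance_sigma)))
               for sp in species}

    def site_abundance(site: str) -> dict[str, float]:
        present = [sp for sp in species
                   if site == "below_dam" or sp not in below_only]
        jitter = {sp: weights[sp] * float(np.exp(rng.normal(0.0, 0.4)))
                  for sp in present}
        total = sum(jitter.values())
        return {sp: w / total for sp, w in jitter.items()}

    abundances: dict[str, dict[str, float]] = {}
    n_reads: dict[str, int] = {}
    sites: dict[str, str] = {}
    types: dict[str, str] = {}
    for i in range(n_biological):
        s = f"BIO{i + 1:02d}"
        site = "below_dam" if i < n_biological // 2 else "above_dam"
        abundances[s] = site_abundance(site)
        n_reads[s] = reads_per_sample
        sites[s], types[s] = site, "biological"
    pairs: list[tuple[str, str]] = []
    for i in range(n_replicate_pairs):
        a = f"BIO{i + 1:02d}"
        b = f"{a}dup"
        abundances[b] = dict(abundances[a])
        n_reads[b] = reads_per_sample
        sites[b], types[b] = sites[a], "biological"
        pairs.append((a, b))
    spikes = []
    for i in range(n_negative):
        s = f"NEG{i + 1:02d}"
        abundances[s] = {}
        n_reads[s] = 0
        sites[s], types[s] = "", "negative"
    if spike_reads > 0 and n_negative > 0:
        spikes.append(("NEG01", "Salmo_fictus", spike_reads))
    return CommunitySpec(
        species_abundances=abundances, n_reads=n_reads, sample_types=types,
        sites=sites, crosstalk_rate=crosstalk_rate,
        contamination_spikes=spikes, replicate_pairs=pairs,
        dropout_prob=dropout_prob,
        seed=int(child_seed(seed, "community_spec").generate_state(1)[0] % 2**31))
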