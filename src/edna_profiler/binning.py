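"""Taxon binning from simulated misassignment plus identical-sequence groups.

Reads are simulated in equal numbers from every reference accession, mapped
back to the full database, and the rate at which each query species' reads
are assigned to heterospecific references is recorded as a directed,
weighted adjacency ("misassignment graph").  Query species whose total
misassignment exceeds a threshold (default 5%) are retained, individually
negligible edges (default <1% of that query's total error) are dropped, and
the connected components of the surviving undirected graph become taxon
bins.  Species whose references are identical across species boundaries are
additionally grouped a priori, since no simulation can separate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import align as _align
from .refdb import ReferenceDB
from .synth import ErrorModel, child_seed, simulate_reads


@dataclass
class MisassignmentGraph:
    """Species-level directed misassignment rates from simulated reads."""

    graph: nx.DiGraph                 # edge weight = misassigned fraction
    n_simulated: dict[str, int]       # reads simulated per query species
    unmapped: dict[str, int]          # simulated reads with no passing hit

    def weight(self, query: str, ref: str) -> float:
        if self.graph.has_edge(query, ref):
            return self.graph.edges[query, ref]["weight"]
        return 0.0

    def total_misassignment(self, query: str) -> float:
        return sum(d["weight"] for _, _, d in
                   self.graph.out_edges(query, data=True))

    def unmapped_rate(self, query: str) -> float:
        n = self.n_simulated.get(query, 0)
        return self.unmapped.get(query, 0) / n if n else 0.0

    def edge_table(self) -> pd.DataFrame:
        rows = [{"query": q, "reference": r, "weight": d["weight"]}
                for q, r, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["query", "reference", "weight"])


@dataclass
class BinMap:
    """A partition of species into taxon bins with provenance labels."""

    bins: dict[str, set[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for members in self.bins.values():
            overlap = seen & members
            if overlap:
                raise ValueError(f"bins overlap on {sorted(overlap)}")
            seen |= members

    @property
    def species_to_bin(self) -> dict[str, str]:
        return {sp: b for b, members in self.bins.items() for sp in members}

    def bin_of(self, species: str) -> str:
        return self.species_to_bin[species]

    def multispecies_bins(self, provenance: str | None = None) -> list[str]:
        out = []
        for b, members in self.bins.items():
            if len(members) < 2:
                continue
            if provenance is None or self.provenance.get(b) == provenance:
                out.append(b)
        return sorted(out)

    def assert_partition(self, species: list[str]) -> None:
        covered = set().union(*self.bins.values()) if self.bins else set()
        if covered != set(species):
            raise ValueError(
                f"bins do not partition the species set; difference: "
                f"{sorted(set(species) ^ covered)}")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"species": sp, "bin": b,
                 "provenance": self.provenance.get(b, "")}
                for b, members in sorted(self.bins.items())
                for sp in sorted(members)]
        return pd.DataFrame(rows, columns=["species", "bin", "provenance"])


def _bin_name(members: set[str]) -> str:
    if len(members) == 1:
        return next(iter(members))
    return "BIN_" + "+".join(sorted(members))


def bin_identical(db: ReferenceDB) -> list[set[str]]:
    """A-priori groups: species sharing an identical reference sequence.

    Grouping is transitive: if A shares a sequence with B and B (through a
    different sequence) with C, then {A, B, C} form one group.  Only groups
    of two or more species are returned.
    """
    g = nx.Graph()
    by_seq: dict[str, set[str]] = {}
    for s in db.sequences:
        by_seq.setdefault(s.sequence, set()).add(s.species)
    for species in by_seq.values():
        members = sorted(species)
        g.add_nodes_from(members)
        for a, b in zip(members, members[1:]):
            g.add_edge(a, b)
    return [set(c) for c in nx.connected_components(g) if len(c) > 1]


def build_graph(assignments: dict[str, str | None],
                truth: dict[str, str]) -> MisassignmentGraph:
    """Tabulate directed misassignment rates from simulated assignments.

    ``truth`` maps read id to source species; ``assignments`` maps read id
    to assigned species, or ``None`` for reads that failed mapping or
    filtering.  Unassigned reads feed a per-species unmapped tally, not
    edges.
    """
    unknown = set(assignments) - set(truth)
    if unknown:
        raise KeyError(f"assignments for unknown read ids: {sorted(unknown)[:5]}")
    n_sim: dict[str, int] = {}
    unmapped: dict[str, int] = {}
    mis: dict[tuple[str, str], int] = {}
    for rid, src in truth.items():
        n_sim[src] = n_sim.get(src, 0) + 1
        assigned = assignments.get(rid)
        if assigned is None:
            unmapped[src] = unmapped.get(src, 0) + 1
        elif assigned != src:
            mis[(src, assigned)] = mis.get((src, assigned), 0) + 1
    g = nx.DiGraph()
    g.add_nodes_from(n_sim)
    for (q, r), c in mis.items():
        g.add_edge(q, r, weight=c / n_sim[q])
    return MisassignmentGraph(graph=g, n_simulated=n_sim, unmapped=unmapped)


def prune_and_bin(
    graph: MisassignmentGraph,
    a_priori: list[set[str]] | None = None,
    query_threshold: float = 0.05,
    pair_fraction: float = 0.01,
    species: list[str] | None = None,
) -> BinMap:
    """Derive taxon bins from the misassignment graph.

    Query species with total misassignment strictly greater than
    ``query_threshold`` are retained; for each retained query, edges
    contributing strictly less than ``pair_fraction`` of that query's total
    error are dropped.  Surviving directed edges are read as undirected
    connections and each connected component becomes an error-based bin.
    A-priori identical-sequence groups are merged in afterwards; everything
    else is a singleton bin.
    """
    all_species = sorted(set(species or [])
                         | set(graph.n_simulated)
                         | set().union(*(a_priori or [set()])))
    und = nx.Graph()
    und.add_nodes_from(all_species)
    for q in graph.graph.nodes:
        total = graph.total_misassignment(q)
        if total <= query_threshold:
            continue
        for _, r, d in graph.graph.out_edges(q, data=True):
            if d["weight"] < pair_fraction * total:
                continue
            und.add_edge(q, r)
    error_components = [set(c) for c in nx.connected_components(und)]

    merged = nx.Graph()
    merged.add_nodes_from(all_species)
    for comp in error_components + [set(g) for g in (a_priori or [])]:
        members = sorted(comp)
        for a, b in zip(members, members[1:]):
            merged.add_edge(a, b)
    error_multi = {frozenset(c) for c in error_components if len(c) > 1}
    apriori_sets = {frozenset(g) for g in (a_priori or [])}

    bins: dict[str, set[str]] = {}
    provenance: dict[str, str] = {}
    for comp in nx.connected_components(merged):
        comp = set(comp)
        name = _bin_name(comp)
        bins[name] = comp
        if len(comp) == 1:
            provenance[name] = "singleton"
        elif frozenset(comp) in apriori_sets:
            # identical references: imposed regardless of simulated error
            provenance[name] = "a-priori"
        elif frozenset(comp) in error_multi:
            provenance[name] = "error-based"
        else:
            provenance[name] = "merged"
    bm = BinMap(bins=bins, provenance=provenance)
    bm.assert_partition(all_species)
    return bm


def overall_error(assignments: dict[str, str | None],
                  truth: dict[str, str],
                  bins: BinMap) -> dict[str, float]:
    """Fraction of mapped simulated reads assigned outside their source bin.

    Unmapped reads are excluded from the denominator and reported
    separately, since assignment error is a property of reads that mapped.
    """
    lookup = bins.species_to_bin
    mapped = wrong = unmapped = 0
    for rid, src in truth.items():
        assigned = assignments.get(rid)
        if assigned is None:
            unmapped += 1
            continue
        mapped += 1
        if lookup[assigned] != lookup[src]:
            wrong += 1
    return {
        "overall_error": wrong / mapped if mapped else 0.0,
        "unmapped_rate": unmapped / len(truth) if truth else 0.0,
        "n_mapped": mapped,
        "n_reads": len(truth),
    }


def simulate_assignment_error(
    db: ReferenceDB,
    model: ErrorModel | None = None,
    n_per_accession: int = 10000,
    seed: int = 0,
    scoring: dict | None = None,
    thresholds: tuple[int, int, int] = (3, 3, 3),
) -> tuple[dict[str, str | None], dict[str, str]]:
    """Simulate reads from every accession and map them back to the database.

    Equal read numbers per accession (the equal-abundance assumption of the
    error simulation).  Returns ``(assignments, truth)`` at species level;
    reads rejected by the G/M/L filter, or rejected outright, map to
    ``None``.
    """
    model = model or ErrorModel.study_default()
    acc_species = db.accession_species()
    ref_lengths = db.ref_lengths()
    g, m, l = thresholds
    truth: dict[str, str] = {}
    assignments: dict[str, str | None] = {}
    for k, ref in enumerate(sorted(db.sequences, key=lambda s: s.accession)):
        sub_seed = int(child_seed(seed, "assignment_sim", k).generate_state(1)[0]
                       % 2**31)
        reads = simulate_reads(ref, n=n_per_accession, model=model,
                               seed=sub_seed, id_prefix=ref.accession)
        for rid, _ in reads:
            truth[rid] = ref.species
        records, rejects = _align.map_reads(reads, db, scoring=scoring)
        passing, _tally = _align.filter_alignments(
            records.values(), ref_lengths, g=g, m=m, l=l)
        passing_ids = {rec.read_id: rec for rec in passing}
        for rid, _ in reads:
            rec = passing_ids.get(rid)
            assignments[rid] = acc_species[rec.accession] if rec else None
    return assignments, truth
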