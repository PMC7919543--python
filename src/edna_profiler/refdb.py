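"""Reference database construction and curation for 12S metabarcoding.

A reference database maps accessions to species and carries the ~98-bp
amplicon sequence for each accession, optionally with a gapped version from
a multiple alignment.  Curation steps implemented here:

* dereplication at 100% identity within species (identical sequences shared
  across species are all retained -- they seed a-priori taxon bins);
* removal of entries with long terminal alignment gaps (incomplete
  sequences), with a taxon exemption list for genuinely short sequences;
* an advisory divergence screen that flags accessions suspiciously far from
  their conspecifics under the Kimura two-parameter distance;
* per-species conspecific/heterospecific alignment-score separation, used
  downstream to pick species suitable for error-rate estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import align as _align

# Ungapped-equivalent Karlin-Altschul constants for match +2 / mismatch -3
# nucleotide scoring; overridable wherever bit scores are computed.
DEFAULT_LAMBDA = 1.28
DEFAULT_K = 0.46

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_GAPS = {"-", "."}


@dataclass
class ReferenceSequence:
    accession: str
    species: str
    sequence: str
    aligned_sequence: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("-", "")
        if self.aligned_sequence is not None:
            self.aligned_sequence = self.aligned_sequence.upper()
            ungapped = "".join(
                c for c in self.aligned_sequence if c not in _GAPS)
            if ungapped != self.sequence:
                raise ValueError(
                    f"{self.accession}: aligned_sequence does not match sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceDB:
    sequences: list[ReferenceSequence]
    checklist: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for s in self.sequences:
            seen[s.accession] = seen.get(s.accession, 0) + 1
        dups = sorted(a for a, n in seen.items() if n > 1)
        if dups:
            raise ValueError(f"duplicate accession IDs: {', '.join(dups)}")

    @property
    def species_index(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {}
        for s in self.sequences:
            idx.setdefault(s.species, []).append(s.accession)
        return idx

    @property
    def species(self) -> list[str]:
        return sorted(self.species_index)

    def __len__(self) -> int:
        return len(self.sequences)

    def get(self, accession: str) -> ReferenceSequence:
        for s in self.sequences:
            if s.accession == accession:
                return s
        raise KeyError(accession)

    def species_of(self, accession: str) -> str:
        return self.get(accession).species

    def accession_species(self) -> dict[str, str]:
        return {s.accession: s.species for s in self.sequences}

    def ref_lengths(self) -> dict[str, int]:
        return {s.accession: s.length for s in self.sequences}


# -- FASTA I/O ---------------------------------------------------------------
# Header dialect: >ACCESSION|Genus_species

def _parse_header(header: str) -> tuple[str, str]:
    if "|" not in header:
        raise ValueError(
            f"header {header!r} not in ACCESSION|Genus_species form")
    acc, species = header.split("|", 1)
    return acc.strip(), species.strip()


def read_fasta(path, checklist: list[str] | None = None,
               aligned: bool = False) -> ReferenceDB:
    """Load references from FASTA with ``>ACCESSION|Genus_species`` headers."""
    from Bio import SeqIO

    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        acc, species = _parse_header(rec.id)
        raw = str(rec.seq).upper()
        if aligned:
            seqs.append(ReferenceSequence(
                acc, species, raw.replace("-", ""), aligned_sequence=raw))
        else:
            seqs.append(ReferenceSequence(acc, species, raw))
    return ReferenceDB(seqs, checklist=checklist or [])


def write_fasta(db: ReferenceDB, path, aligned: bool = False) -> None:
    with open(path, "w") as fh:
        for s in db.sequences:
            seq = s.aligned_sequence if aligned else s.sequence
            fh.write(f">{s.accession}|{s.species}\n{seq}\n")


def attach_alignment(db: ReferenceDB, aligned_fasta) -> ReferenceDB:
    """Attach gapped sequences from a pre-aligned FASTA to matching accessions."""
    aln = read_fasta(aligned_fasta, aligned=True)
    gapped = {s.accession: s.aligned_sequence for s in aln.sequences}
    out = []
    for s in db.sequences:
        out.append(ReferenceSequence(
            s.accession, s.species, s.sequence,
            aligned_sequence=gapped.get(s.accession, s.aligned_sequence)))
    return ReferenceDB(out, checklist=db.checklist)


# -- Curation operations -----------------------------------------------------

def dereplicate(db: ReferenceDB) -> ReferenceDB:
    """Collapse identical conspecific sequences to one representative.

    Within each species exactly one accession per distinct sequence string is
    kept (the lexicographically smallest, for reproducibility).  Identical
    sequences shared across species are all retained: they are the basis of
    the a-priori taxon bins.
    """
    if not db.sequences:
        raise ValueError("empty reference database")
    keep: dict[tuple[str, str], ReferenceSequence] = {}
    for s in sorted(db.sequences, key=lambda s: s.accession):
        key = (s.species, s.sequence)
        if key not in keep:
            keep[key] = s
    kept = sorted(keep.values(), key=lambda s: s.accession)
    return ReferenceDB(kept, checklist=db.checklist)


def _terminal_gap_runs(aligned: str) -> tuple[int, int]:
    lead = len(aligned) - len(aligned.lstrip("".join(_GAPS)))
    trail = len(aligned) - len(aligned.rstrip("".join(_GAPS)))
    return lead, trail


def filter_terminal_gaps(
    db: ReferenceDB,
    max_terminal_gap: int = 9,
    exempt_taxa: list[str] | None = None,
) -> tuple[ReferenceDB, list[dict]]:
    """Drop incomplete entries with terminal alignment gaps beyond threshold.

    Species in ``exempt_taxa`` (e.g. lampreys, whose 12S region is genuinely
    shorter) are never removed.  Returns the filtered DB and a removal
    report.
    """
    exempt = set(exempt_taxa or [])
    kept, removed = [], []
    for s in db.sequences:
        if s.aligned_sequence is None:
            raise ValueError(f"{s.accession}: aligned_sequence required")
        lead, trail = _terminal_gap_runs(s.aligned_sequence)
        if max(lead, trail) > max_terminal_gap and s.species not in exempt:
            removed.append({"accession": s.accession, "species": s.species,
                            "leading_gap": lead, "trailing_gap": trail})
        else:
            kept.append(s)
    return ReferenceDB(kept, checklist=db.checklist), removed


def k2p_distance(seq1: str, seq2: str) -> float:
    """Kimura two-parameter distance between two aligned sequences.

    ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`` with P, Q the transition
    and transversion proportions over comparable (non-gap, ACGT) sites.
    Returns ``inf`` when divergence exceeds the model's valid range.
    """
    if len(seq1) != len(seq2):
        raise ValueError(
            "sequences have unequal length; align them first (provide "
            "aligned_sequence or equal-length sequences)")
    sites = transitions = transversions = 0
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a in _GAPS or b in _GAPS or a == "N" or b == "N":
            continue
        sites += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValueError("no comparable sites")
    P, Q = transitions / sites, transversions / sites
    x, y = 1 - 2 * P - Q, 1 - 2 * Q
    if x <= 0 or y <= 0:
        return math.inf
    return -0.5 * math.log(x) - 0.25 * math.log(y)


def _comparable(s: ReferenceSequence) -> str:
    return s.aligned_sequence if s.aligned_sequence is not None else s.sequence


def divergence_screen(
    db: ReferenceDB,
    max_conspecific_divergence: float = 0.13,
) -> list[dict]:
    """Advisory flags for taxonomically suspect accessions.

    An accession is flagged when its minimum K2P distance to any conspecific
    exceeds the threshold, or when its overall nearest neighbour is
    heterospecific while conspecifics exist.  Nothing is removed; the report
    is meant to prompt manual review (range data, tree inspection).
    """
    seqs = db.sequences
    lens = {len(_comparable(s)) for s in seqs}
    if len(lens) > 1 and any(s.aligned_sequence is None for s in seqs):
        raise ValueError(
            "sequences have unequal lengths and no alignment; "
            "attach a multiple alignment before divergence screening")
    flags = []
    for s in seqs:
        others = [t for t in seqs if t.accession != s.accession]
        cons = [t for t in others if t.species == s.species]
        if not cons:
            continue
        dist = {t.accession: k2p_distance(_comparable(s), _comparable(t))
                for t in others}
        min_con = min(dist[t.accession] for t in cons)
        nearest = min(others, key=lambda t: (dist[t.accession], t.accession))
        reasons = []
        if min_con > max_conspecific_divergence:
            reasons.append(
                f"min conspecific K2P {min_con:.3f} > {max_conspecific_divergence}")
        if nearest.species != s.species and dist[nearest.accession] < min_con:
            reasons.append(
                f"nearest neighbour {nearest.accession} is heterospecific "
                f"({nearest.species})")
        if reasons:
            flags.append({"accession": s.accession, "species": s.species,
                          "min_conspecific_k2p": min_con,
                          "nearest_accession": nearest.accession,
                          "nearest_species": nearest.species,
                          "reasons": reasons})
    return flags


@dataclass
class SpeciesScoreGap:
    """Conspecific/heterospecific bit-score separation for one species."""

    species: str
    min_conspecific: float | None
    max_heterospecific: float
    n_accessions: int

    @property
    def gap(self) -> float | None:
        if self.min_conspecific is None:
            return None
        return self.min_conspecific - self.max_heterospecific

    def eligible(self, min_gap_bits: float = 28.0) -> bool:
        return (self.n_accessions >= 2 and self.gap is not None
                and self.gap >= min_gap_bits)


def bit_score(raw_score: float, lam: float = DEFAULT_LAMBDA,
              k: float = DEFAULT_K) -> float:
    """Convert a raw alignment score to bits: (lambda*S - ln K) / ln 2."""
    return (lam * raw_score - math.log(k)) / math.log(2)


def score_gaps(
    db: ReferenceDB,
    scoring: dict | None = None,
    lam: float = DEFAULT_LAMBDA,
    k: float = DEFAULT_K,
) -> list[SpeciesScoreGap]:
    """All-vs-all local alignment bit-score separation per species.

    For every species with at least two accessions, reports the lowest
    conspecific and highest heterospecific bit score.  Species with a single
    accession have an undefined conspecific minimum and are ineligible for
    error-rate estimation.
    """
    scoring = dict(_align.DEFAULT_SCORING, **(scoring or {}))
    aligner = _align._make_aligner(scoring)
    seqs = db.sequences
    n = len(seqs)
    raw = {}
    for i in range(n):
        for j in range(i + 1, n):
            raw[(i, j)] = aligner.score(seqs[i].sequence, seqs[j].sequence)
    out = []
    for species, accs in sorted(db.species_index.items()):
        con: list[float] = []
        het: list[float] = []
        for i in range(n):
            for j in range(i + 1, n):
                a, b = seqs[i], seqs[j]
                if species not in (a.species, b.species):
                    continue
                s = bit_score(raw[(i, j)], lam, k)
                if a.species == b.species == species:
                    con.append(s)
                elif species in (a.species, b.species):
                    het.append(s)
        out.append(SpeciesScoreGap(
            species=species,
            min_conspecific=min(con) if con else None,
            max_heterospecific=max(het) if het else -math.inf,
            n_accessions=len(accs)))
    return out
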