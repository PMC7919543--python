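"""Local alignment of reads to references and the G/M/L stringency statistics.

Reads are assigned to the single best-scoring reference by Smith-Waterman
local alignment, and each alignment is summarized by three integers used as
mapping-stringency thresholds:

* ``G`` -- number of distinct gap positions: one per insertion run, one per
  deletion run, and one per edge skip (soft clip), regardless of run length;
* ``M`` -- number of mismatch positions inside match columns;
* ``L`` -- reference-length shortfall: reference length minus the number of
  read bases placed in match columns, floored at zero.

A multi-base internal indel counts as a single gap position (one event), the
same convention applied to edge skips.  Externally produced alignments are
ingested from SAM text (CIGAR plus MD field) and reduced to the same record.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field

import edlib
from Bio import Align

# Alignment operation codes: match column, insertion to reference (read base
# not in reference), deletion from reference, edge skip (unaligned read end).
OP_MATCH = "M"
OP_INS = "I"
OP_DEL = "D"
OP_SKIP = "S"

_READ_CONSUMING = {OP_MATCH, OP_INS, OP_SKIP}

DEFAULT_SCORING = {
    "match": 2,
    "mismatch": -3,
    "gap_open": -5,
    "gap_extend": -2,
}


@dataclass
class GMLStats:
    """Gap-position, mismatch-position and length-shortfall counts."""

    G: int
    M: int
    L: int

    def __post_init__(self) -> None:
        if self.G < 0 or self.M < 0 or self.L < 0:
            raise ValueError("G, M and L must be non-negative")

    def passes(self, g: int = 3, m: int = 3, l: int = 3) -> bool:
        return self.G <= g and self.M <= m and self.L <= l


@dataclass
class AlignmentRecord:
    """One read-to-reference local alignment.

    ``ops`` is the ordered run-length encoding of the alignment using the
    operation codes above.  ``mismatch_positions`` are 1-based read positions
    (sequencing cycles) at which an aligned base differs from the reference.
    """

    read_id: str
    accession: str
    ops: list[tuple[str, int]]
    mismatch_positions: list[int] = field(default_factory=list)
    score: float = 0.0
    tie_flag: bool = False

    @property
    def read_length(self) -> int:
        return sum(n for op, n in self.ops if op in _READ_CONSUMING)

    @property
    def aligned_read_bases(self) -> int:
        """Read bases placed in match columns (CIGAR M/=/X)."""
        return sum(n for op, n in self.ops if op == OP_MATCH)

    def validate(self) -> None:
        spans: list[tuple[int, int]] = []
        pos = 0
        for op, n in self.ops:
            if n <= 0:
                raise ValueError(f"non-positive run length in ops: {(op, n)}")
            if op == OP_MATCH:
                spans.append((pos + 1, pos + n))
            if op in _READ_CONSUMING:
                pos += n
        for p in self.mismatch_positions:
            if not any(lo <= p <= hi for lo, hi in spans):
                raise ValueError(f"mismatch position {p} outside match columns")


class ReadRejected(ValueError):
    """Raised when a read is unsuitable for alignment."""


def compute_gml(rec: AlignmentRecord, ref_length: int) -> GMLStats:
    """Reduce an alignment record to its G/M/L statistics.

    Gap runs are counted as events: a 5-base internal deletion and a 5-base
    edge skip each contribute one gap position.  ``L`` penalizes incomplete
    reference coverage; insertions do not count toward aligned bases.
    """
    g = sum(1 for op, _ in rec.ops if op in (OP_INS, OP_DEL, OP_SKIP))
    m = len(rec.mismatch_positions)
    l = max(0, ref_length - rec.aligned_read_bases)
    return GMLStats(G=g, M=m, L=l)


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_MD_RE = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    if not cigar or cigar == "*":
        raise ValueError("missing CIGAR string")
    parsed = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in parsed) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return [(op, int(n)) for n, op in parsed]


def parse_sam(record: str, ref_lengths: dict[str, int] | None = None) -> AlignmentRecord:
    """Reconstruct an :class:`AlignmentRecord` from one SAM alignment line.

    Requires the CIGAR field and an ``MD:Z:`` auxiliary tag so that mismatch
    positions can be recovered without the reference sequence.  Soft clips
    become edge skips; hard clips are treated as edge skips with a warning
    (the clipped length is taken from the CIGAR).  ``ref_lengths`` is
    accepted for interface symmetry with downstream G/M/L computation but is
    not needed to reconstruct the alignment itself.
    """
    fields = record.rstrip("\n").split("\t")
    if len(fields) < 11:
        raise ValueError("SAM line has fewer than 11 fields")
    qname, flag, rname, _pos, _mapq, cigar = (
        fields[0], int(fields[1]), fields[2], fields[3], fields[4], fields[5])
    if flag & 0x4:
        raise ValueError(f"read {qname} is unmapped")
    md = None
    score = 0.0
    for tag in fields[11:]:
        if tag.startswith("MD:Z:"):
            md = tag[5:]
        elif tag.startswith("AS:i:"):
            score = float(tag[5:])
    if md is None:
        raise ValueError(f"read {qname}: MD field required to locate mismatches")

    ops: list[tuple[str, int]] = []
    # Read positions (1-based cycles) of successive match columns, in order.
    match_read_pos: list[int] = []
    read_pos = 0
    for op, n in _parse_cigar(cigar):
        if op in ("S", "H"):
            if op == "H":
                warnings.warn(
                    f"read {qname}: hard clip treated as edge skip", stacklevel=2)
            ops.append((OP_SKIP, n))
            read_pos += n
        elif op in ("M", "=", "X"):
            if ops and ops[-1][0] == OP_MATCH:
                ops[-1] = (OP_MATCH, ops[-1][1] + n)
            else:
                ops.append((OP_MATCH, n))
            match_read_pos.extend(range(read_pos + 1, read_pos + n + 1))
            read_pos += n
        elif op == "I":
            ops.append((OP_INS, n))
            read_pos += n
        elif op in ("D", "N"):
            ops.append((OP_DEL, n))
        elif op == "P":
            continue
        else:  # pragma: no cover - regex restricts codes
            raise ValueError(f"unsupported CIGAR op {op!r}")

    mismatch_positions: list[int] = []
    col = 0  # index into match_read_pos
    for num, deletion, sub in _MD_RE.findall(md):
        if num:
            col += int(num)
        elif deletion:
            continue  # deleted reference bases consume no read positions
        else:
            if col >= len(match_read_pos):
                raise ValueError(f"read {qname}: MD string exceeds aligned length")
            mismatch_positions.append(match_read_pos[col])
            col += 1

    rec = AlignmentRecord(
        read_id=qname, accession=rname, ops=ops,
        mismatch_positions=mismatch_positions, score=score)
    rec.validate()
    return rec


def read_sam(path, ref_lengths: dict[str, int] | None = None):
    """Yield :class:`AlignmentRecord` for each mapped line of a SAM text file."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("@") or not line.strip():
                continue
            flag = int(line.split("\t", 3)[1])
            if flag & 0x4:
                continue
            yield parse_sam(line, ref_lengths)


def _make_aligner(scoring: dict) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring["match"]
    aligner.mismatch_score = scoring["mismatch"]
    aligner.open_gap_score = scoring["gap_open"]
    aligner.extend_gap_score = scoring["gap_extend"]
    return aligner


def _alignment_to_ops(alignment, ref: str, read: str):
    """Convert a Biopython local alignment to run-length ops and mismatches."""
    tblocks, qblocks = alignment.aligned
    ops: list[tuple[str, int]] = []
    mismatches: list[int] = []
    if len(qblocks) == 0:
        raise ValueError("empty alignment")
    lead = qblocks[0][0]
    if lead > 0:
        ops.append((OP_SKIP, int(lead)))
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(tblocks, qblocks):
        if prev_t is not None:
            if t0 > prev_t:
                ops.append((OP_DEL, int(t0 - prev_t)))
            if q0 > prev_q:
                ops.append((OP_INS, int(q0 - prev_q)))
        if ops and ops[-1][0] == OP_MATCH:
            ops[-1] = (OP_MATCH, ops[-1][1] + int(t1 - t0))
        else:
            ops.append((OP_MATCH, int(t1 - t0)))
        for k in range(t1 - t0):
            if ref[t0 + k] != read[q0 + k]:
                mismatches.append(q0 + k + 1)
        prev_t, prev_q = t1, q1
    trail = len(read) - qblocks[-1][1]
    if trail > 0:
        ops.append((OP_SKIP, int(trail)))
    return ops, mismatches


def local_align(
    read: str,
    db,
    scoring: dict | None = None,
    read_id: str = "read",
    min_length: int = 20,
) -> AlignmentRecord:
    """Best-hit Smith-Waterman alignment of one read against every reference.

    The single best-scoring reference is reported; ties are broken by the
    lexicographically smallest accession with ``tie_flag`` set.  The search
    is exact but avoids scoring hopeless references using the bound
    ``SW score <= len(read) + len(ref) - editdistance(read, ref)``, which
    follows from each edit operation removing at least one potential match
    column (match = +2 here).  Edit distances come from edlib.

    ``db`` is anything with a ``.sequences`` attribute of objects carrying
    ``accession`` and ``sequence`` (e.g. a ReferenceDB).
    """
    scoring = dict(DEFAULT_SCORING, **(scoring or {}))
    read = read.upper()
    if len(read) < min_length:
        raise ReadRejected(f"read {read_id}: shorter than {min_length} bp after trimming")
    if read.count("N") > len(read) / 2:
        raise ReadRejected(f"read {read_id}: low complexity/ambiguity (>50% N)")
    refs = sorted(
        ((s.accession, s.sequence) for s in db.sequences), key=lambda x: x[0])
    if not refs:
        raise ValueError("empty reference database")

    aligner = _make_aligner(scoring)
    bounds = []
    for acc, seq in refs:
        d = edlib.align(read, seq, mode="NW", task="distance")["editDistance"]
        bounds.append((len(read) + len(seq) - d, acc, seq))
    # Score candidates in decreasing bound order; stop once no remaining
    # bound can reach the best observed score (ties must still be examined,
    # hence the non-strict comparison).
    bounds.sort(key=lambda x: (-x[0], x[1]))
    best_score = -1.0
    best: list[tuple[str, str]] = []
    for bound, acc, seq in bounds:
        if bound < best_score:
            break
        s = aligner.score(seq, read)
        if s > best_score:
            best_score = s
            best = [(acc, seq)]
        elif s == best_score:
            best.append((acc, seq))
    best.sort(key=lambda x: x[0])
    acc, refseq = best[0]
    alignment = aligner.align(refseq, read)[0]
    ops, mismatches = _alignment_to_ops(alignment, refseq, read)
    rec = AlignmentRecord(
        read_id=read_id, accession=acc, ops=ops,
        mismatch_positions=mismatches, score=float(best_score),
        tie_flag=len(best) > 1)
    rec.validate()
    return rec


def map_reads(
    reads,
    db,
    scoring: dict | None = None,
    min_length: int = 20,
) -> tuple[dict[str, AlignmentRecord], dict[str, str]]:
    """Align many reads, dereplicating at 100% identity first.

    ``reads`` is an iterable of ``(read_id, sequence)``.  Each distinct
    sequence is aligned once and the record re-expanded to every read
    carrying it.  Returns ``(records_by_read_id, rejects_by_read_id)`` where
    rejects map read id to a reason string.
    """
    by_seq: dict[str, list[str]] = {}
    for rid, seq in reads:
        by_seq.setdefault(seq.upper(), []).append(rid)
    records: dict[str, AlignmentRecord] = {}
    rejects: dict[str, str] = {}
    for seq, rids in by_seq.items():
        try:
            proto = local_align(seq, db, scoring=scoring, read_id=rids[0],
                                min_length=min_length)
        except ReadRejected as exc:
            for rid in rids:
                rejects[rid] = str(exc)
            continue
        for rid in rids:
            records[rid] = AlignmentRecord(
                read_id=rid, accession=proto.accession, ops=proto.ops,
                mismatch_positions=proto.mismatch_positions,
                score=proto.score, tie_flag=proto.tie_flag)
    return records, rejects


def filter_alignments(
    records,
    ref_lengths: dict[str, int],
    g: int = 3,
    m: int = 3,
    l: int = 3,
):
    """Apply the G/M/L stringency thresholds (all boundary-inclusive).

    Returns ``(passing_records, tally)`` where ``tally`` counts rejections by
    the first violated criterion, checked in the order G, M, L.
    """
    if min(g, m, l) < 0:
        raise ValueError("thresholds must be non-negative")
    passing = []
    tally: Counter[str] = Counter()
    for rec in records:
        stats = compute_gml(rec, ref_lengths[rec.accession])
        if stats.G > g:
            tally["G"] += 1
        elif stats.M > m:
            tally["M"] += 1
        elif stats.L > l:
            tally["L"] += 1
        else:
            passing.append(rec)
    return passing, dict(tally)


def count_by_accession(records, sample_labels: dict[str, str], samples=None):
    """Tabulate passing reads into an accession x sample integer table.

    ``sample_labels`` maps read id to sample name.  ``samples`` optionally
    fixes the column set (so empty samples appear with zero counts).
    """
    import pandas as pd

    cells: Counter[tuple[str, str]] = Counter()
    accs = set()
    for rec in records:
        if rec.read_id not in sample_labels:
            raise KeyError(f"read {rec.read_id} has no sample label")
        cells[(rec.accession, sample_labels[rec.read_id])] += 1
        accs.add(rec.accession)
    cols = list(samples) if samples is not None else sorted(
        {s for _, s in cells})
    table = pd.DataFrame(0, index=sorted(accs), columns=cols, dtype=int)
    for (acc, sample), n in cells.items():
        table.loc[acc, sample] = n
    return table
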