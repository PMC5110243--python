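"""Two-species consensus-sequence construction with discordance masking.

Reads mapped to one species' genome are biased against the other species at
divergent sites. A remedy is to map to a consensus built from a pairwise
genome alignment in which every discordant site, and every indel together
with a flanking window, is replaced by 'N' so that no read can be rewarded
or penalised there. This module implements the masking rule at
single-alignment scale: SNV columns are masked at their reference position,
and each maximal gap run is masked over the reference positions it touches
plus ``flank`` bases on either side (for an insertion into the non-reference
sequence the window extends from the insertion point both ways).

Coordinates are 0-based, half-open, in the frame of ``seq_a`` (the
reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ALPHABET = set("ACGTN-")
_BASES = set("ACGT")


class AlignmentError(ValueError):
    """Malformed pairwise alignment; the message names the offending column."""


@dataclass
class PairwiseAlignment:
    """Gapped two-sequence alignment over {A,C,G,T,N,-}.

    ``seq_a`` is the reference. Both strings must have equal length and no
    column may be a gap in both sequences.
    """

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise AlignmentError(
                f"length mismatch: {len(self.seq_a)} vs {len(self.seq_b)}"
            )
        for i, (a, b) in enumerate(zip(self.seq_a, self.seq_b)):
            if a not in _ALPHABET or b not in _ALPHABET:
                raise AlignmentError(f"invalid character at column {i}: {a!r}/{b!r}")
            if a == "-" and b == "-":
                raise AlignmentError(f"all-gap column at {i}")

    @property
    def n_columns(self) -> int:
        return len(self.seq_a)

    @property
    def ref_length(self) -> int:
        return sum(1 for c in self.seq_a if c != "-")


@dataclass
class MaskedConsensus:
    """Masked consensus in reference coordinates.

    ``mask_intervals`` are sorted, merged, 0-based half-open intervals; every
    position inside one carries 'N' in ``sequence``.
    """

    sequence: str
    mask_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        prev_end = -1
        for start, end in self.mask_intervals:
            if not (0 <= start < end <= n):
                raise ValueError(f"interval ({start}, {end}) out of bounds for {n}")
            if start <= prev_end:
                raise ValueError("intervals not sorted/merged")
            prev_end = end
            if set(self.sequence[start:end]) != {"N"}:
                raise ValueError(f"unmasked base inside interval ({start}, {end})")

    @property
    def masked_positions(self) -> set[int]:
        return {p for s, e in self.mask_intervals for p in range(s, e)}


def _merge_intervals(
    intervals: list[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    clipped = [
        (max(0, s), min(length, e)) for s, e in intervals if max(0, s) < min(length, e)
    ]
    clipped.sort()
    merged: list[tuple[int, int]] = []
    for s, e in clipped:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' as half-open column intervals."""
    runs = []
    start = None
    for i, c in enumerate(seq):
        if c == "-" and start is None:
            start = i
        elif c != "-" and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def mask_consensus(aln: PairwiseAlignment, flank: int = 6) -> MaskedConsensus:
    """Build the N-masked consensus of a pairwise alignment.

    Masking rules, in reference (seq_a) coordinates:

    * a column where both sequences carry a base but the bases differ, or
      where either base is 'N', masks that reference position;
    * a maximal gap run in ``seq_b`` (deletion) masks the reference positions
      it spans plus ``flank`` bases on each side;
    * a maximal gap run in ``seq_a`` (insertion into seq_b) has zero
      reference width; ``flank`` bases on each side of the insertion point
      are masked.

    All intervals are clipped to the sequence and merged. Unmasked positions
    carry the agreed base.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    ref_len = aln.ref_length
    # reference position of each column (position of the seq_a base, or for
    # gap-in-a columns the index of the next seq_a base = insertion point)
    ref_pos = []
    p = 0
    for a in aln.seq_a:
        ref_pos.append(p)
        if a != "-":
            p += 1

    intervals: list[tuple[int, int]] = []
    consensus = ["?"] * ref_len
    for i, (a, b) in enumerate(zip(aln.seq_a, aln.seq_b)):
        if a == "-":
            continue
        rp = ref_pos[i]
        if b == "-":
            consensus[rp] = a  # covered by the gap-run interval below
        elif a != b or a == "N" or b == "N":
            intervals.append((rp, rp + 1))
            consensus[rp] = a
        else:
            consensus[rp] = a

    for start, end in _gap_runs(aln.seq_b):  # deletions: ref width end-start
        lo = ref_pos[start]
        hi = ref_pos[end - 1] + 1
        intervals.append((lo - flank, hi + flank))
    for start, end in _gap_runs(aln.seq_a):  # insertions: zero ref width
        point = ref_pos[start]
        intervals.append((point - flank, point + flank))

    merged = _merge_intervals(intervals, ref_len)
    for s, e in merged:
        for q in range(s, e):
            consensus[q] = "N"
    return MaskedConsensus("".join(consensus), merged)


# ---------------------------------------------------------------------------
# I/O


def read_alignment_fasta(path: str | Path) -> PairwiseAlignment:
    """Read a two-record aligned FASTA ('-' gaps, equal lengths)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise AlignmentError(f"expected 2 records in {path}, found {len(records)}")
    return PairwiseAlignment(str(records[0].seq), str(records[1].seq))


def write_alignment_fasta(
    aln: PairwiseAlignment, path: str | Path, ids: tuple[str, str] = ("ref", "alt")
) -> None:
    recs = [
        SeqRecord(Seq(aln.seq_a), id=ids[0], description=""),
        SeqRecord(Seq(aln.seq_b), id=ids[1], description=""),
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_masked_consensus(
    cons: MaskedConsensus,
    fasta_path: str | Path,
    bed_path: str | Path | None = None,
    seq_id: str = "consensus",
) -> None:
    """Write the consensus FASTA and, optionally, the mask intervals as BED."""
    rec = SeqRecord(Seq(cons.sequence), id=seq_id, description="masked consensus")
    SeqIO.write([rec], str(fasta_path), "fasta")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for s, e in cons.mask_intervals:
                fh.write(f"{seq_id}\t{s}\t{e}\n")
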