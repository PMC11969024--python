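"""Paired-end amplicon parsing and variant counting for phage-display libraries.

The sequencing construct places a 48-nt peptide-encoding insert between two
constant regions, flanked by demultiplexing motifs::

    fwd_demux .. fwd_const | insert | rev_const .. revcomp(rev_demux)

Both mates must independently yield an identical, unambiguous insert of the
expected length for a read pair to be accepted; every failure is recorded as
a status, never an exception.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

# Printed construct motifs used for demultiplexing and insert location.
DEFAULT_FWD_DEMUX = "CTAGCGCT"
DEFAULT_REV_DEMUX = "CGCAGACG"
DEFAULT_FWD_CONST = "ATGCCTATGCAGCCTCTTCATCTGGC"
DEFAULT_REV_CONST = (
    "GGTGGAGGATCCGGAGGAGGCGCCGAGGGTGACGATCCCGCAAAAGCGGCCTTTAACTCC"
    "CTGCAAGCCTCAGCGACCGAATATATCGGTTATGCGTGGGCGATGGTTGTTGTCAT"
)

REJECT_REASONS = (
    "reject_missing_motif",
    "reject_discordant",
    "reject_size",
    "reject_ambiguous",
)


class FastqParseError(ValueError):
    """Raised for a malformed FASTQ record; names the record index."""


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: str = ""
    rev_qual: str = ""

    def __post_init__(self) -> None:
        if self.fwd_qual and len(self.fwd_qual) != len(self.fwd_seq):
            raise ValueError(f"{self.read_id}: fwd qual/seq length mismatch")
        if self.rev_qual and len(self.rev_qual) != len(self.rev_seq):
            raise ValueError(f"{self.read_id}: rev qual/seq length mismatch")


@dataclass(frozen=True)
class AmpliconScaffold:
    """Motifs delimiting the variable insert; defaults are the printed construct."""

    fwd_demux: str = DEFAULT_FWD_DEMUX
    rev_demux: str = DEFAULT_REV_DEMUX
    fwd_const: str = DEFAULT_FWD_CONST
    rev_const: str = DEFAULT_REV_CONST
    insert_length_nt: int = 48

    def __post_init__(self) -> None:
        for name in ("fwd_demux", "rev_demux", "fwd_const", "rev_const"):
            if not getattr(self, name):
                raise ValueError(f"scaffold motif {name} must be non-empty")
        if self.insert_length_nt <= 0 or self.insert_length_nt % 3:
            raise ValueError("insert_length_nt must be a positive multiple of 3")

    @property
    def peptide_length(self) -> int:
        return self.insert_length_nt // 3


@dataclass(frozen=True)
class InsertCall:
    read_id: str
    status: str
    insert_nt: str | None = None
    peptide: str | None = None


@dataclass
class VariantCounts:
    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)
    n_reads_total: int = 0
    n_rejected_by_reason: dict[str, int] = field(default_factory=dict)
    designed_only: bool = False

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("variant counts must be non-negative")
        if sum(self.counts.values()) > self.n_reads_total and self.n_reads_total:
            raise ValueError("counted reads exceed n_reads_total")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a FASTQ file, gzip-transparent.

    Raises :class:`FastqParseError` naming the 1-based record index on a
    truncated or malformed record.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        record_idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            record_idx += 1
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise FastqParseError(f"malformed FASTQ record {record_idx} in {path}")
            if not seq or not qual or len(seq) != len(qual):
                raise FastqParseError(f"truncated FASTQ record {record_idx} in {path}")
            yield header[1:].split()[0], seq.upper(), qual


@dataclass
class JoinedReads:
    pairs: list[ReadPair]
    n_only_fwd: int = 0
    n_only_rev: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_only_fwd + self.n_only_rev


def join_pairs(
    fwd_stream: Iterable[tuple[str, str, str]],
    rev_stream: Iterable[tuple[str, str, str]],
) -> JoinedReads:
    """Join mates on read id; ids present in only one stream are dropped and tallied."""
    fwd = {rid: (seq, qual) for rid, seq, qual in fwd_stream}
    rev = {rid: (seq, qual) for rid, seq, qual in rev_stream}
    shared = fwd.keys() & rev.keys()
    pairs = [
        ReadPair(rid, fwd[rid][0], rev[rid][0], fwd[rid][1], rev[rid][1])
        for rid in fwd
        if rid in shared
    ]
    return JoinedReads(
        pairs=pairs,
        n_only_fwd=len(fwd.keys() - shared),
        n_only_rev=len(rev.keys() - shared),
    )


def _insert_from_canonical(seq: str, scaffold: AmpliconScaffold) -> str | None:
    """Insert between fwd_const and rev_const if all four motifs occur, else None.

    ``seq`` must already be in canonical (forward) orientation. First exact
    occurrence of each motif is used; no mismatches are tolerated.
    """
    i_demux = seq.find(scaffold.fwd_demux)
    i_const = seq.find(scaffold.fwd_const)
    i_rev_const = seq.find(scaffold.rev_const)
    i_rev_demux = seq.find(_revcomp(scaffold.rev_demux))
    if min(i_demux, i_const, i_rev_const, i_rev_demux) < 0:
        return None
    return seq[i_const + len(scaffold.fwd_const): i_rev_const]


def extract_insert(pair: ReadPair, scaffold: AmpliconScaffold) -> InsertCall:
    """Recover the insert independently from each mate and cross-validate.

    The reverse mate is reverse-complemented before motif search. Statuses:
    ``reject_missing_motif`` (any motif absent from either mate),
    ``reject_discordant`` (mates disagree), ``reject_size`` (wrong length),
    ``reject_ambiguous`` (N in insert), else ``accepted``.
    """
    fwd_insert = _insert_from_canonical(pair.fwd_seq, scaffold)
    rev_insert = _insert_from_canonical(_revcomp(pair.rev_seq), scaffold)
    if fwd_insert is None or rev_insert is None:
        return InsertCall(pair.read_id, "reject_missing_motif")
    if fwd_insert != rev_insert:
        return InsertCall(pair.read_id, "reject_discordant")
    if len(fwd_insert) != scaffold.insert_length_nt:
        return InsertCall(pair.read_id, "reject_size", insert_nt=fwd_insert)
    if "N" in fwd_insert:
        return InsertCall(pair.read_id, "reject_ambiguous", insert_nt=fwd_insert)
    peptide = str(Seq(fwd_insert).translate())
    return InsertCall(pair.read_id, "accepted", insert_nt=fwd_insert, peptide=peptide)


def count_variants(
    calls: Iterable[InsertCall],
    designed: set[str],
    sample_id: str = "sample",
) -> VariantCounts:
    """Count accepted peptides that belong to the designed library.

    Accepted peptides outside the designed library are tallied under
    ``off_library``; rejection tallies are carried through.
    """
    if not designed:
        raise ValueError("designed library must be non-empty")
    counts: Counter[str] = Counter()
    tallies: Counter[str] = Counter()
    n_total = 0
    for call in calls:
        n_total += 1
        if call.status != "accepted":
            tallies[call.status] += 1
        elif call.peptide in designed:
            counts[call.peptide] += 1
        else:
            tallies["off_library"] += 1
    if n_total == 0:
        warnings.warn(f"{sample_id}: empty call stream; returning empty counts")
    return VariantCounts(
        sample_id=sample_id,
        counts=dict(counts),
        n_reads_total=n_total,
        n_rejected_by_reason=dict(tallies),
        designed_only=True,
    )


def count_fastq_pair(
    fwd_path: str | Path,
    rev_path: str | Path,
    designed: set[str],
    scaffold: AmpliconScaffold | None = None,
    sample_id: str = "sample",
) -> VariantCounts:
    """End-to-end: FASTQ pair -> joined reads -> insert calls -> variant counts."""
    scaffold = scaffold or AmpliconScaffold()
    joined = join_pairs(read_fastq(fwd_path), read_fastq(rev_path))
    calls = (extract_insert(p, scaffold) for p in joined.pairs)
    vc = count_variants(calls, designed, sample_id=sample_id)
    if joined.n_dropped:
        vc.n_rejected_by_reason["unpaired"] = joined.n_dropped
        vc.n_reads_total += joined.n_dropped
    return vc
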