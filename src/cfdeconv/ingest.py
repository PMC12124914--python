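"""Turn Bismark-style read intervals and per-CpG calls into fragment records.

The pipeline has three steps, each usable on its own:

1. :func:`merge_pe_reads` — union the intervals of paired-end mates into one
   fragment interval per read id.
2. :func:`merge_cpgs` — collect per-CpG methylation calls onto fragments,
   resolving mate-overlap duplicates (agreeing duplicates collapse, conflicting
   duplicates are dropped and counted).
3. :func:`generate_frag_meth` — join the two outputs into :class:`Fragment`
   records carrying the ordered joint methylation state string.

Coordinate conventions
----------------------
Read and fragment intervals are 0-based half-open (BED). Methylation-extractor
call positions are 1-based; calls from the original-bottom (OB) strand are
shifted by one so that both strands index the cytosine of the CpG on the
forward strand. The methylation state alphabet is ``"1"`` (methylated) /
``"0"`` (unmethylated).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, NamedTuple, Sequence, Union

logger = logging.getLogger(__name__)

METHYLATED = "1"
UNMETHYLATED = "0"

PathLike = Union[str, Path]


class GenomicInterval(NamedTuple):
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read (mate) as a BED-style interval."""

    read_id: str
    chrom: str
    start: int
    end: int
    mate: int = 1
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"read {self.read_id!r}: start must be < end, got [{self.start}, {self.end})"
            )
        if self.mate not in (1, 2):
            raise ValueError(f"read {self.read_id!r}: mate must be 1 or 2, got {self.mate}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id!r}: strand must be '+' or '-'")


@dataclass(frozen=True)
class MethCall:
    """One per-CpG methylation call from a methylation-extractor file.

    ``pos`` is the 1-based position as reported by the extractor;
    :attr:`forward_pos0` gives the normalized 0-based position of the CpG
    cytosine on the forward strand.
    """

    read_id: str
    call_strand: str  # "OT" or "OB"
    chrom: str
    pos: int
    methylated: bool

    def __post_init__(self) -> None:
        if self.call_strand not in ("OT", "OB"):
            raise ValueError(f"call_strand must be 'OT' or 'OB', got {self.call_strand!r}")
        if self.pos < 1:
            raise ValueError(f"call position must be >= 1, got {self.pos}")

    @property
    def forward_pos0(self) -> int:
        # OB calls index the G of the CpG; shift -1 to the C, then 1->0 based.
        return self.pos - 1 - (1 if self.call_strand == "OB" else 0)


@dataclass(frozen=True)
class Fragment:
    """One cfDNA fragment with its joint methylation state.

    ``cpg_positions`` are 0-based forward-strand CpG positions, strictly
    increasing and contained in ``[start, end)``. ``meth_state`` is a string
    over the ``"0"``/``"1"`` alphabet with one symbol per CpG.
    """

    fragment_id: str
    chrom: str
    start: int
    end: int
    cpg_positions: tuple[int, ...] = ()
    meth_state: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"fragment {self.fragment_id!r}: start must be < end, "
                f"got [{self.start}, {self.end})"
            )
        if len(self.cpg_positions) != len(self.meth_state):
            raise ValueError(
                f"fragment {self.fragment_id!r}: {len(self.cpg_positions)} CpG positions "
                f"but {len(self.meth_state)} state symbols"
            )
        if any(s not in (METHYLATED, UNMETHYLATED) for s in self.meth_state):
            raise ValueError(
                f"fragment {self.fragment_id!r}: meth_state must use the "
                f"'{METHYLATED}'/'{UNMETHYLATED}' alphabet, got {self.meth_state!r}"
            )
        pos = self.cpg_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(
                f"fragment {self.fragment_id!r}: CpG positions must be strictly increasing"
            )
        if pos and (pos[0] < self.start or pos[-1] >= self.end):
            raise ValueError(
                f"fragment {self.fragment_id!r}: CpG positions must lie in "
                f"[{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_cpg(self) -> int:
        return len(self.meth_state)

    @property
    def k_meth(self) -> int:
        return self.meth_state.count(METHYLATED)


@dataclass
class MergeStats:
    """Tallies from :func:`merge_pe_reads`."""

    n_read_ids: int = 0
    n_fragments: int = 0
    n_rejected: int = 0


@dataclass
class CpGMergeStats:
    """Tallies from :func:`merge_cpgs`."""

    n_calls: int = 0
    n_conflicts: int = 0
    n_duplicates_agreeing: int = 0
    n_unmatched: int = 0


def merge_pe_reads(
    reads: Iterable[ReadRecord],
) -> tuple[dict[str, GenomicInterval], MergeStats]:
    """Union paired-end mate intervals into one fragment interval per read id.

    Singleton mates pass through as their own interval. Mate pairs on
    different chromosomes are rejected and counted in ``stats.n_rejected``.
    More than two records sharing a read id is an error.
    """
    grouped: dict[str, list[ReadRecord]] = {}
    for read in reads:
        mates = grouped.setdefault(read.read_id, [])
        if len(mates) >= 2:
            raise ValueError(f"more than two records share read id {read.read_id!r}")
        mates.append(read)

    intervals: dict[str, GenomicInterval] = {}
    stats = MergeStats(n_read_ids=len(grouped))
    for read_id, mates in grouped.items():
        if len(mates) == 2 and mates[0].chrom != mates[1].chrom:
            stats.n_rejected += 1
            logger.debug("rejecting %r: mates on %s and %s", read_id, mates[0].chrom, mates[1].chrom)
            continue
        intervals[read_id] = GenomicInterval(
            mates[0].chrom,
            min(m.start for m in mates),
            max(m.end for m in mates),
        )
    stats.n_fragments = len(intervals)
    return intervals, stats


def merge_cpgs(
    calls: Iterable[MethCall],
    intervals: Mapping[str, GenomicInterval],
) -> tuple[dict[str, dict[int, str]], CpGMergeStats]:
    """Collect normalized CpG states per fragment.

    A CpG reported by both mates with the same state appears once; conflicting
    duplicate calls remove the CpG from the fragment and increment
    ``stats.n_conflicts`` (one count per conflicted position). Calls whose
    read id has no fragment interval (e.g. rejected cross-chromosome pairs)
    are skipped and counted in ``stats.n_unmatched``.
    """
    states: dict[str, dict[int, str]] = {}
    conflicted: dict[str, set[int]] = {}
    stats = CpGMergeStats()
    for call in calls:
        stats.n_calls += 1
        if call.read_id not in intervals:
            stats.n_unmatched += 1
            continue
        pos = call.forward_pos0
        frag_states = states.setdefault(call.read_id, {})
        bad = conflicted.setdefault(call.read_id, set())
        if pos in bad:
            continue
        symbol = METHYLATED if call.methylated else UNMETHYLATED
        prior = frag_states.get(pos)
        if prior is None:
            frag_states[pos] = symbol
        elif prior == symbol:
            stats.n_duplicates_agreeing += 1
        else:
            del frag_states[pos]
            bad.add(pos)
            stats.n_conflicts += 1
    if stats.n_conflicts:
        logger.warning("dropped %d CpGs with conflicting mate-overlap calls", stats.n_conflicts)
    return states, stats


def generate_frag_meth(
    intervals: Mapping[str, GenomicInterval],
    states: Mapping[str, Mapping[int, str]],
) -> list[Fragment]:
    """Join fragment intervals with CpG states into :class:`Fragment` records.

    Every interval yields one fragment; intervals without any calls get an
    empty ``meth_state`` (with a warning). CpG states outside the fragment
    interval, or states for unknown fragment ids, are dropped with a warning.
    Output order follows the interval mapping's iteration order.
    """
    orphans = set(states) - set(intervals)
    if orphans:
        logger.warning(
            "%d fragment ids have CpG states but no interval; skipped (e.g. %r)",
            len(orphans),
            next(iter(sorted(orphans))),
        )
    n_missing = 0
    fragments: list[Fragment] = []
    for read_id, interval in intervals.items():
        frag_states = states.get(read_id)
        if frag_states is None:
            n_missing += 1
            frag_states = {}
        in_range = {p: s for p, s in frag_states.items() if interval.start <= p < interval.end}
        if len(in_range) != len(frag_states):
            logger.warning(
                "fragment %r: dropped %d CpG calls outside [%d, %d)",
                read_id,
                len(frag_states) - len(in_range),
                interval.start,
                interval.end,
            )
        positions = tuple(sorted(in_range))
        fragments.append(
            Fragment(
                fragment_id=read_id,
                chrom=interval.chrom,
                start=interval.start,
                end=interval.end,
                cpg_positions=positions,
                meth_state="".join(in_range[p] for p in positions),
            )
        )
    if n_missing:
        logger.warning("%d fragments had no methylation calls; emitted with empty methState", n_missing)
    return fragments


# ---------------------------------------------------------------------------
# file readers / writers
# ---------------------------------------------------------------------------


def _open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_bed_reads(path: PathLike) -> Iterator[ReadRecord]:
    """Read BED6-compatible read intervals (plain or gzip).

    Columns: chrom, start, end, name (read id), score (ignored), strand.
    A ``/1`` or ``/2`` suffix on the name is stripped and used as the mate
    number. ``track``/``browser``/``#`` lines are skipped.
    """
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns, got {len(fields)}")
            name = fields[3]
            mate = 1
            if name.endswith(("/1", "/2")):
                mate = int(name[-1])
                name = name[:-2]
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "+"
            yield ReadRecord(
                read_id=name,
                chrom=fields[0],
                start=int(fields[1]),
                end=int(fields[2]),
                mate=mate,
                strand=strand,
            )


_CPG_SYMBOLS = {"Z": True, "z": False}


def read_bismark_calls(path: PathLike, call_strand: str) -> Iterator[MethCall]:
    """Read a Bismark methylation-extractor call file (CpG_OT* or CpG_OB*).

    Tab-delimited columns: read id, call strandness (+/-), chromosome,
    1-based position, call symbol. Only CpG-context symbols (``Z``
    methylated / ``z`` unmethylated) are yielded; other contexts are skipped.
    A leading ``Bismark ...`` header line is tolerated.
    """
    if call_strand not in ("OT", "OB"):
        raise ValueError(f"call_strand must be 'OT' or 'OB', got {call_strand!r}")
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().startswith("bismark"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            symbol = fields[4]
            if symbol not in _CPG_SYMBOLS:
                continue  # non-CpG context (X/x, H/h, U/u)
            name = fields[0]
            if name.endswith(("/1", "/2")):
                name = name[:-2]
            yield MethCall(
                read_id=name,
                call_strand=call_strand,
                chrom=fields[2],
                pos=int(fields[3]),
                methylated=_CPG_SYMBOLS[symbol],
            )


FRAGMENT_TABLE_COLUMNS = ("chrom", "start", "end", "length", "n_cpg", "methState", "cpgPositions", "fragmentId")


def write_fragment_table(fragments: Iterable[Fragment], path: PathLike) -> None:
    """Write the fragment-level methylation table (TSV, gzip by suffix).

    Columns: chrom, start, end, length, n_cpg, methState, cpgPositions
    (comma-separated 0-based), fragmentId. The last two columns make the
    table a lossless serialization of :class:`Fragment`.
    """
    with _open_text(path, "wt") as handle:
        handle.write("#" + "\t".join(FRAGMENT_TABLE_COLUMNS) + "\n")
        for frag in fragments:
            handle.write(
                "\t".join(
                    (
                        frag.chrom,
                        str(frag.start),
                        str(frag.end),
                        str(frag.length),
                        str(frag.n_cpg),
                        frag.meth_state,
                        ",".join(map(str, frag.cpg_positions)),
                        frag.fragment_id,
                    )
                )
                + "\n"
            )


def read_fragment_table(path: PathLike) -> list[Fragment]:
    """Read a fragment table written by :func:`write_fragment_table`.

    Missing ``cpgPositions``/``fragmentId`` columns are tolerated for
    foreign 6-column tables: positions are then synthesized as consecutive
    coordinates from ``start`` (adequate for likelihood work, which only
    uses counts) and ids from the row number.
    """
    fragments: list[Fragment] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 columns, got {len(fields)}")
            chrom, start, end, _length, n_cpg, meth_state = fields[:6]
            n = int(n_cpg)
            if len(meth_state) != n:
                raise ValueError(
                    f"{path}:{lineno}: n_cpg={n} but methState has {len(meth_state)} symbols"
                )
            if len(fields) > 6 and fields[6]:
                positions = tuple(int(p) for p in fields[6].split(","))
            else:
                positions = tuple(range(int(start), int(start) + n))
            frag_id = fields[7] if len(fields) > 7 else f"row{lineno}"
            fragments.append(
                Fragment(
                    fragment_id=frag_id,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    cpg_positions=positions,
                    meth_state=meth_state,
                )
            )
    return fragments


def ingest_bismark(
    bed_path: PathLike,
    calls_ot_path: PathLike,
    calls_ob_path: PathLike,
) -> tuple[list[Fragment], MergeStats, CpGMergeStats]:
    """Full ingestion: read BED + call files, run all three merge steps."""
    intervals, merge_stats = merge_pe_reads(read_bed_reads(bed_path))

    def _all_calls() -> Iterator[MethCall]:
        yield from read_bismark_calls(calls_ot_path, "OT")
        yield from read_bismark_calls(calls_ob_path, "OB")

    states, cpg_stats = merge_cpgs(_all_calls(), intervals)
    return generate_frag_meth(intervals, states), merge_stats, cpg_stats
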