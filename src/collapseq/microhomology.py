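"""Deletion and junctional-microhomology calling from amplicon reads.

The repair of resected double-strand breaks by end joining leaves
deletions whose junctions often fall inside short identical sequences
present on both sides of the break (microhomology).  This module calls
such deletions under a single-deletion model: a read is explained as the
reference minus one contiguous segment, or it is left unclassified.
Richer indel grammars (insertions, substitution clusters, multi-segment
events) belong to dedicated editing-outcome tools.

Ambiguous junction placement inside a repeat is resolved by left
alignment (the VCF convention), which makes the reported coordinates
stable and the microhomology length well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

INTACT = "intact"
DELETION = "deletion"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class DeletionCall:
    """A left-aligned deletion junction on the reference."""

    del_start: int
    del_end: int
    mh_length: int
    support: int = 1

    def __post_init__(self) -> None:
        if not self.del_start < self.del_end:
            raise ValueError("del_start must be < del_end")
        if self.mh_length < 0:
            raise ValueError("microhomology length must be >= 0")

    @property
    def length(self) -> int:
        return self.del_end - self.del_start


@dataclass(frozen=True)
class ReadOutcome:
    """Classification of one read: intact, one deletion, or unclassified."""

    status: str
    call: Optional[DeletionCall] = None


def microhomology_length(ref: str, del_start: int, del_end: int) -> int:
    """Junctional microhomology of a deletion [del_start, del_end) on ref.

    The largest m with ref[del_start : del_start + m) ==
    ref[del_end : del_end + m), bounded by the remaining reference length.
    """
    if not 0 <= del_start < del_end <= len(ref):
        raise ValueError(f"invalid deletion [{del_start}, {del_end}) on ref of length {len(ref)}")
    m = 0
    while del_end + m < len(ref) and ref[del_start + m] == ref[del_end + m]:
        m += 1
    return m


def call_deletion(read: str, ref: str, tolerance: int = 0) -> ReadOutcome:
    """Explain a read as the reference minus one contiguous segment.

    The junction split k partitions the read into a prefix aligned to
    ref[:k] and a suffix aligned to ref[k + d:], with d = len(ref) -
    len(read) the deletion length.  The smallest k with at most
    ``tolerance`` total mismatches wins (left alignment).  A read equal
    to the reference is intact; a read not explicable this way is
    unclassified.
    """
    if len(read) == 0:
        raise ValueError("empty read")
    if len(read) > len(ref):
        return ReadOutcome(UNCLASSIFIED)
    d = len(ref) - len(read)
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    f = np.frombuffer(ref.encode(), dtype=np.uint8)
    if d == 0:
        return ReadOutcome(INTACT) if read == ref else ReadOutcome(UNCLASSIFIED)
    # prefix_mm[k]: mismatches of read[:k] vs ref[:k]
    prefix_mm = np.concatenate(([0], np.cumsum(r != f[: len(r)])))
    # suffix_mm[k]: mismatches of read[k:] vs ref[k + d:]
    tail = np.cumsum((r != f[d:])[::-1])[::-1]
    suffix_mm = np.concatenate((tail, [0]))
    total = prefix_mm + suffix_mm
    ks = np.flatnonzero(total <= tolerance)
    if ks.size == 0:
        return ReadOutcome(UNCLASSIFIED)
    k = int(ks[0])
    call = DeletionCall(
        del_start=k, del_end=k + d, mh_length=microhomology_length(ref, k, k + d)
    )
    return ReadOutcome(DELETION, call)


@dataclass
class JunctionSummary:
    """Aggregate view of deletion junctions across reads."""

    table: pd.DataFrame  # deletion-length bin x microhomology length counts
    n_reads: int
    n_deleted: int
    n_unclassified: int
    fraction_with_deletion: float
    fraction_mh_ge2: float
    calls: pd.DataFrame  # aggregated by exact (del_start, del_end)


_LENGTH_BINS = [0, 5, 10, 20, 50, 100, np.inf]
_LENGTH_LABELS = ["1-5", "6-10", "11-20", "21-50", "51-100", ">100"]


def summarize_junctions(outcomes: Iterable[ReadOutcome]) -> JunctionSummary:
    """Tabulate deletion length x microhomology and headline fractions.

    ``fraction_mh_ge2`` is the share of deletion-bearing reads whose
    junction carries at least 2 bp of microhomology, the usual signature
    of microhomology-mediated end joining.
    """
    outcomes = list(outcomes)
    n_reads = len(outcomes)
    dels = [o.call for o in outcomes if o.status == DELETION]
    n_unclassified = sum(o.status == UNCLASSIFIED for o in outcomes)
    if dels:
        df = pd.DataFrame(
            {
                "del_start": [c.del_start for c in dels],
                "del_end": [c.del_end for c in dels],
                "del_length": [c.length for c in dels],
                "mh_length": [c.mh_length for c in dels],
            }
        )
        df["length_bin"] = pd.cut(
            df["del_length"], bins=_LENGTH_BINS, labels=_LENGTH_LABELS, right=True
        )
        table = (
            df.groupby(["length_bin", "mh_length"], observed=False)
            .size()
            .unstack(fill_value=0)
        )
        frac_mh2 = float((df["mh_length"] >= 2).mean())
        calls = (
            df.groupby(["del_start", "del_end", "del_length", "mh_length"])
            .size()
            .rename("support")
            .reset_index()
            .sort_values("support", ascending=False, ignore_index=True)
        )
    else:
        table = pd.DataFrame(index=pd.CategoricalIndex([], name="length_bin"))
        frac_mh2 = 0.0
        calls = pd.DataFrame(
            columns=["del_start", "del_end", "del_length", "mh_length", "support"]
        )
    return JunctionSummary(
        table=table,
        n_reads=n_reads,
        n_deleted=len(dels),
        n_unclassified=n_unclassified,
        fraction_with_deletion=(len(dels) / n_reads) if n_reads else 0.0,
        fraction_mh_ge2=frac_mh2,
        calls=calls,
    )
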