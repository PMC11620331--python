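"""Replication fork directionality (RFD) and leading/lagging nick designation.

RFD is a per-bin statistic in [-1, 1] derived from stranded replication
fragment counts (OK-seq / TrAEL-seq style).  We fix the polarity at the
API: positive RFD means predominantly rightward-moving forks, computed as
(C - W) / (C + W) with C the Crick-strand and W the Watson-strand fragment
count per bin.  TrAEL-derived inputs, whose chemistry labels strands the
other way round, may need a sign flip before entering this module.

A nick's collision orientation follows from its target strand and the net
fork direction at its locus: a Crick-strand nick in a region of rightward
forks (RFD > 0) sits on the lagging-strand template, so the replisome
bypasses it (double-ended break); with leftward forks (RFD < 0) it sits on
the leading-strand template and the fork runs off (single-ended break).
Watson-strand nicks mirror this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .tracks_io import NickSite

LEADING = "leading"
LAGGING = "lagging"
UNCLASSIFIED = "unclassified"


@dataclass
class RFDProfile:
    """Binned stranded replication fragment counts and derived RFD values.

    ``crick[i]`` and ``watson[i]`` count fragments in the bin covering
    ``[i * bin_size, (i + 1) * bin_size)``.  RFD is undefined (NaN) where
    a bin holds no fragments at all.
    """

    chrom: str
    bin_size: int
    crick: np.ndarray
    watson: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        self.crick = np.asarray(self.crick, dtype=float)
        self.watson = np.asarray(self.watson, dtype=float)
        if self.crick.shape != self.watson.shape:
            raise ValueError("crick and watson count arrays must have equal length")
        if (self.crick < 0).any() or (self.watson < 0).any():
            raise ValueError("fragment counts must be >= 0")

    @property
    def rfd(self) -> np.ndarray:
        total = self.crick + self.watson
        with np.errstate(invalid="ignore", divide="ignore"):
            values = (self.crick - self.watson) / total
        values[total == 0] = np.nan
        return values

    def value_at(self, position: int) -> float:
        """RFD of the bin containing ``position`` (NaN if undefined/outside)."""
        i = position // self.bin_size
        if not 0 <= i < len(self.crick):
            return math.nan
        return float(self.rfd[i])

    def to_frame(self) -> pd.DataFrame:
        starts = np.arange(len(self.crick)) * self.bin_size
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": starts,
                "end": starts + self.bin_size,
                "crick": self.crick,
                "watson": self.watson,
                "rfd": self.rfd,
            }
        )


def compute_rfd(
    crick: np.ndarray,
    watson: np.ndarray,
    bin_size: int,
    chrom: str = "chr1",
    already_binned: bool = False,
) -> RFDProfile:
    """Bin stranded fragment counts and form RFD = (C - W) / (C + W).

    Parameters
    ----------
    crick, watson
        Per-base count arrays (summed into ``bin_size`` bins), or per-bin
        counts if ``already_binned``.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    crick = np.asarray(crick, dtype=float)
    watson = np.asarray(watson, dtype=float)
    if already_binned:
        return RFDProfile(chrom=chrom, bin_size=bin_size, crick=crick, watson=watson)
    n_bins = -(-len(crick) // bin_size)
    c = np.zeros(n_bins)
    w = np.zeros(n_bins)
    for i in range(n_bins):
        lo, hi = i * bin_size, (i + 1) * bin_size
        c[i] = crick[lo:hi].sum()
        w[i] = watson[lo:hi].sum()
    return RFDProfile(chrom=chrom, bin_size=bin_size, crick=c, watson=w)


def classify_nick(nick: NickSite, rfd_value: float) -> str:
    """Designate a nick as a leading- or lagging-strand collision.

    Crick-strand (-) nick: RFD > 0 -> lagging, RFD < 0 -> leading.
    Watson-strand (+) nick: mirrored.  RFD of exactly 0, or undefined,
    leaves the nick unclassified.
    """
    if rfd_value is None or math.isnan(rfd_value) or rfd_value == 0.0:
        return UNCLASSIFIED
    if nick.target_strand == "-":
        return LAGGING if rfd_value > 0 else LEADING
    return LEADING if rfd_value > 0 else LAGGING


def correlate_asymmetry_rfd(
    records: pd.DataFrame, orientation_class: str
) -> tuple[float, int]:
    """Spearman correlation between break asymmetry and RFD within a class.

    ``records`` needs columns ``class``, ``asymmetry``, ``rfd``.  Rows with
    non-finite asymmetry or RFD are dropped.  For leading-strand sites
    |RFD| is paired with |asymmetry| (both fold with the fork direction,
    so magnitudes carry the relationship regardless of which side of the
    origin a site sits on); lagging-strand sites are correlated on the raw
    signed values.  Returns (r, n); r is NaN when either vector is
    constant.
    """
    sub = records[records["class"] == orientation_class]
    sub = sub[np.isfinite(sub["asymmetry"]) & np.isfinite(sub["rfd"])]
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 finite records in class {orientation_class!r}, got {n}")
    a = sub["asymmetry"].to_numpy()
    r_ = sub["rfd"].to_numpy()
    if orientation_class == LEADING:
        a, r_ = np.abs(a), np.abs(r_)
    if np.all(a == a[0]) or np.all(r_ == r_[0]):
        return math.nan, n
    rho = stats.spearmanr(a, r_).statistic
    return float(rho), n


def write_rfd_tsv(profile: RFDProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def read_binned_counts_tsv(path) -> RFDProfile:
    """Read a TSV of binned stranded counts (chrom, start, end, crick, watson)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "start", "end", "crick", "watson"}
    if not required.issubset(df.columns):
        raise ValueError(f"binned counts TSV needs columns {sorted(required)}")
    bin_size = int(df["end"].iloc[0] - df["start"].iloc[0])
    return RFDProfile(
        chrom=str(df["chrom"].iloc[0]),
        bin_size=bin_size,
        crick=df["crick"].to_numpy(float),
        watson=df["watson"].to_numpy(float),
    )
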