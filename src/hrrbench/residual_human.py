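"""Identifiability risk from residual host reads.

Quantifies what is left after removal: per-chromosome read counts normalized
for chromosome length and library size, mean depths, a pseudo-log transform
for display of depths spanning zero and large magnitudes, and a genetic-sex
score from the ratio of Y-chromosome to autosomal mean depth.

Normalization (a documented package choice): reads per megabase of
chromosome per million evaluated reads. The sex call thresholds are
score-scale configuration, chosen to separate zero-signal from male-like
Y:autosome depth ratios by orders of magnitude; they are configuration, not
biological claims.

The module consumes per-chromosome count/depth tables — re-alignment of
post-removal reads to a host reference is the caller's step. For synthetic
fixtures the tables can be built directly from provenance labels via
:func:`summary_from_reads`, since each residual host read records its source
contig and fragment coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

from hrrbench.sequence_io import LabelledRead, ReadPair, SourceClass

__all__ = [
    "ChromDepthSummary",
    "SexCall",
    "SexCallResult",
    "chrom_summary",
    "pseudo_log",
    "sex_score",
    "summary_from_reads",
]

LN10 = math.log(10.0)

_SEX_CHROMS_X = frozenset({"X"})
_SEX_CHROMS_Y = frozenset({"Y"})


def canonical_chrom(name: str) -> str:
    """Map chr1/1, chrX/X ... onto a canonical bare name."""
    n = name.strip()
    if n.lower().startswith("chr"):
        n = n[3:]
    return n.upper() if n.upper() in ("X", "Y", "M", "MT") else n


@dataclass
class ChromDepthSummary:
    """Per-chromosome residual-read summary.

    ``per_chrom`` is indexed by canonical chromosome name with columns
    read_count, length, mean_depth, normalized_count (reads per Mb per
    million evaluated reads).
    """

    per_chrom: pd.DataFrame
    total_reads: int

    @property
    def total_residual_reads(self) -> int:
        return int(self.per_chrom["read_count"].sum())

    def depth_of(self, chroms: Iterable[str]) -> float:
        """Length-weighted mean depth over a chromosome subset (0 if absent)."""
        sub = self.per_chrom.loc[self.per_chrom.index.isin(set(chroms))]
        if sub.empty or sub["length"].sum() == 0:
            return 0.0
        return float((sub["mean_depth"] * sub["length"]).sum() / sub["length"].sum())


class SexCall(Enum):
    MALE_CONSISTENT = "MALE_CONSISTENT"
    FEMALE_CONSISTENT = "FEMALE_CONSISTENT"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class SexCallResult:
    y_mean_depth: float
    x_mean_depth: float
    autosomal_mean_depth: float
    y_score: float
    call: SexCall
    threshold_used: float
    reason: str = ""


def chrom_summary(
    alignment_counts: Union[Mapping[str, Tuple[int, float]], pd.DataFrame],
    chrom_lengths: Mapping[str, int],
    total_reads: int,
) -> ChromDepthSummary:
    """Summarize per-chromosome residual reads.

    ``alignment_counts`` maps chromosome → (read_count, summed_depth) where
    summed_depth is the total of per-position depths (equivalently, total
    aligned bases); a DataFrame with columns (chrom, read_count,
    summed_depth) is also accepted. Chromosome names are alias-tolerant
    (chr1 == 1). mean_depth = summed_depth / length; normalized_count =
    read_count / (length_Mb · total_reads_millions).
    """
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    if isinstance(alignment_counts, pd.DataFrame):
        counts = {
            str(r["chrom"]): (int(r["read_count"]), float(r["summed_depth"]))
            for _, r in alignment_counts.iterrows()
        }
    else:
        counts = {k: (int(v[0]), float(v[1])) for k, v in alignment_counts.items()}

    lengths = {}
    for name, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        lengths[canonical_chrom(name)] = int(length)

    rows = {}
    for name, (rc, sd) in counts.items():
        canon = canonical_chrom(name)
        if canon not in lengths:
            raise KeyError(f"unknown chromosome {name!r} (no declared length)")
        if rc < 0 or sd < 0:
            raise ValueError(f"chromosome {name!r}: negative counts")
        prev = rows.get(canon, (0, 0.0))
        rows[canon] = (prev[0] + rc, prev[1] + sd)

    records = []
    for canon in lengths:
        rc, sd = rows.get(canon, (0, 0.0))
        length = lengths[canon]
        mean_depth = sd / length
        if total_reads > 0:
            norm = rc / ((length / 1e6) * (total_reads / 1e6))
        else:
            norm = 0.0
        records.append(
            {
                "chrom": canon,
                "read_count": rc,
                "length": length,
                "mean_depth": mean_depth,
                "normalized_count": norm,
            }
        )
    df = pd.DataFrame(records).set_index("chrom")
    return ChromDepthSummary(df, total_reads)


def pseudo_log(x, sigma: float = 1.0):
    """Signed log-like transform finite at zero: asinh(x / 2σ) / ln 10.

    Odd, strictly monotone, ≈ log10(x) for x ≫ σ.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return np.arcsinh(np.asarray(x, dtype=float) / (2.0 * sigma)) / LN10


def sex_score(
    summary: ChromDepthSummary,
    tau_hi: float = 0.1,
    tau_lo: float = 0.01,
    depth_floor: float = 1e-9,
) -> SexCallResult:
    """Genetic-sex consistency call from residual chromosome depths.

    y_score = Y mean depth / max(autosomal mean depth, ``depth_floor``);
    call is MALE_CONSISTENT at y_score ≥ tau_hi, FEMALE_CONSISTENT at
    ≤ tau_lo (with non-zero autosomal signal), else INDETERMINATE.
    Missing sex chromosomes or all-zero depths → INDETERMINATE with reason.
    """
    if not tau_lo <= tau_hi:
        raise ValueError("need tau_lo <= tau_hi")
    idx = set(summary.per_chrom.index)
    missing = [c for c in ("X", "Y") if c not in idx]
    y_depth = summary.depth_of(_SEX_CHROMS_Y)
    x_depth = summary.depth_of(_SEX_CHROMS_X)
    autosomes = [c for c in summary.per_chrom.index if c not in ("X", "Y", "M", "MT")]
    auto_depth = summary.depth_of(autosomes)
    score = y_depth / max(auto_depth, depth_floor)

    if missing:
        return SexCallResult(
            y_depth, x_depth, auto_depth, score, SexCall.INDETERMINATE, tau_hi,
            reason=f"missing sex chromosome(s): {missing}",
        )
    if auto_depth <= 0 and y_depth <= 0 and x_depth <= 0:
        return SexCallResult(
            y_depth, x_depth, auto_depth, score, SexCall.INDETERMINATE, tau_hi,
            reason="no residual signal on any chromosome",
        )
    if score >= tau_hi:
        return SexCallResult(y_depth, x_depth, auto_depth, score, SexCall.MALE_CONSISTENT, tau_hi)
    if score <= tau_lo and auto_depth > 0:
        return SexCallResult(
            y_depth, x_depth, auto_depth, score, SexCall.FEMALE_CONSISTENT, tau_lo
        )
    return SexCallResult(
        y_depth, x_depth, auto_depth, score, SexCall.INDETERMINATE, tau_hi,
        reason="y_score between thresholds",
    )


def summary_from_reads(
    reads: Iterable[LabelledRead],
    chrom_lengths: Mapping[str, int],
    total_reads: int,
    host_only: bool = True,
) -> ChromDepthSummary:
    """Build a per-chromosome summary directly from labelled residual reads.

    Each read's source contig is parsed from its provenance
    ``origin_read_id`` (``contig:start-end``); summed depth contributes the
    read length. With ``host_only`` (default) only HOST-class reads count —
    the truth-based analogue of re-aligning residual reads to the host
    reference.
    """
    counts: Dict[str, Tuple[int, float]] = {}
    n_seen = 0
    for read in reads:
        n_seen += 1
        if read.label is None:
            continue
        if host_only and read.label.source_class is not SourceClass.HOST:
            continue
        origin = read.label.origin_read_id
        contig = origin.rsplit(":", 1)[0]
        rc, sd = counts.get(contig, (0, 0.0))
        counts[contig] = (rc + 1, sd + len(read.sequence))
    return chrom_summary(counts, chrom_lengths, total_reads)
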