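"""Synthetic titration mixture construction.

Builds mixtures of target (viral/microbial) and host reads at host:target
proportions spanning 1:9 … 9:1 ("human titer" t means host fraction t/10),
sampling host reads with identical frequency from every donor pool, in
replicate, with a full manifest. Sampling is without replacement everywhere
(pools are finite read sets) and every output read retains its provenance
label, so read fate stays exactly recoverable downstream.

Two sizing modes are provided: FIXED_TOTAL holds the total pair count per
mixture constant across titers (the default, giving deterministic totals);
FIXED_VIRAL holds the target pair count constant and scales the host count
to reach the requested proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from hrrbench.sequence_io import ReadPair, SourceClass, write_pairs
from hrrbench.synthetic_fixtures import child_seed, round_half_away

__all__ = [
    "SizingMode",
    "MixtureSpec",
    "TitrationDesign",
    "allocate_donor_counts",
    "mixture_counts",
    "build_mixture",
    "run_design",
    "MANIFEST_COLUMNS",
]


class SizingMode(Enum):
    FIXED_TOTAL = "FIXED_TOTAL"
    FIXED_VIRAL = "FIXED_VIRAL"


@dataclass(frozen=True)
class MixtureSpec:
    """One titration cell: sample × human titer × iteration, with its seed."""

    sample_id: str
    human_titer: int
    iteration: int
    donor_ids: Tuple[str, ...]
    seed: int
    total_pairs: Optional[int] = None
    viral_pairs: Optional[int] = None

    def __post_init__(self) -> None:
        if not 1 <= self.human_titer <= 9:
            raise ValueError(f"human_titer must be in 1..9, got {self.human_titer}")
        if self.iteration < 1:
            raise ValueError("iteration must be >= 1")
        if (self.total_pairs is None) == (self.viral_pairs is None):
            raise ValueError("exactly one of total_pairs / viral_pairs must be set")
        if not self.donor_ids:
            raise ValueError("donor_ids must be non-empty")
        if len(set(self.donor_ids)) != len(self.donor_ids):
            raise ValueError("donor_ids must be unique")

    @property
    def mode(self) -> SizingMode:
        return SizingMode.FIXED_TOTAL if self.total_pairs is not None else SizingMode.FIXED_VIRAL


@dataclass(frozen=True)
class TitrationDesign:
    """The full factorial design: samples × titers × iterations."""

    sample_ids: Tuple[str, ...]
    titers: Tuple[int, ...] = tuple(range(1, 10))
    iterations: int = 3
    base_seed: int = 0
    mode: SizingMode = SizingMode.FIXED_TOTAL
    pairs_per_mixture: int = 1000

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise ValueError("at least one sample_id required")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if not self.titers or not set(self.titers) <= set(range(1, 10)):
            raise ValueError("titers must be a non-empty subset of 1..9")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @property
    def n_mixtures(self) -> int:
        return len(self.sample_ids) * len(self.titers) * self.iterations


MANIFEST_COLUMNS = [
    "sample_id",
    "human_titer",
    "iteration",
    "seed",
    "n_viral_pairs",
    "n_host_pairs",
    "donor_counts",
    "fastq1",
    "fastq2",
]


def allocate_donor_counts(n_host_pairs: int, donor_ids: Sequence[str]) -> Dict[str, int]:
    """Split ``n_host_pairs`` equally across donors.

    Each donor gets floor(n/D); the remainder r = n mod D goes one extra pair
    to the first r donors in lexicographic donor_id order. Counts therefore
    sum to n and differ by at most 1.
    """
    if n_host_pairs < 0:
        raise ValueError("n_host_pairs must be >= 0")
    if len(set(donor_ids)) != len(donor_ids):
        raise ValueError("donor ids must be unique")
    if not donor_ids:
        if n_host_pairs > 0:
            raise ValueError("cannot allocate host pairs to an empty donor list")
        return {}
    d = len(donor_ids)
    base, rem = divmod(n_host_pairs, d)
    extras = set(sorted(donor_ids)[:rem])
    return {did: base + (1 if did in extras else 0) for did in donor_ids}


def mixture_counts(spec: MixtureSpec) -> Tuple[int, int]:
    """Return (n_viral_pairs, n_host_pairs) for a titration cell.

    FIXED_TOTAL: host = round(t/10 · total), viral = total − host.
    FIXED_VIRAL: host = round(viral · t/(10−t)), viral as given.
    """
    t = spec.human_titer
    if spec.mode is SizingMode.FIXED_TOTAL:
        assert spec.total_pairs is not None
        n_host = round_half_away(t / 10 * spec.total_pairs)
        return spec.total_pairs - n_host, n_host
    assert spec.viral_pairs is not None
    n_host = round_half_away(spec.viral_pairs * t / (10 - t))
    return spec.viral_pairs, n_host


def _sample_without_replacement(
    pool: Sequence[ReadPair], k: int, rng: np.random.Generator, pool_name: str
) -> List[ReadPair]:
    if k > len(pool):
        raise ValueError(
            f"pool {pool_name!r} too shallow: need {k} pairs, have {len(pool)} "
            f"(shortfall {k - len(pool)})"
        )
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in idx]


def build_mixture(
    spec: MixtureSpec,
    viral_pool: Sequence[ReadPair],
    donor_pools: Mapping[str, Sequence[ReadPair]],
    outdir: Optional[Path] = None,
    gzip_output: bool = True,
) -> Tuple[List[ReadPair], Dict[str, object]]:
    """Sample one titration mixture and (optionally) write its paired FASTQ.

    Samples n_viral pairs without replacement from the viral pool and the
    equal-frequency allocation from each donor pool, concatenates and shuffles
    deterministically by the cell seed. Donor pools may contain
    CONTAMINANT-labelled pairs; they count within that donor's quota.

    Returns the sampled pairs and a manifest row.
    """
    n_viral, n_host = mixture_counts(spec)
    alloc = allocate_donor_counts(n_host, spec.donor_ids)
    rng = np.random.default_rng(spec.seed)

    sampled = _sample_without_replacement(viral_pool, n_viral, rng, "viral")
    for did in spec.donor_ids:
        if did not in donor_pools:
            raise KeyError(f"no pool supplied for donor {did!r}")
        sampled.extend(
            _sample_without_replacement(donor_pools[did], alloc[did], rng, f"donor:{did}")
        )
    order = rng.permutation(len(sampled))
    mixture = [sampled[i] for i in order]

    fq1 = fq2 = ""
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ext = ".fastq.gz" if gzip_output else ".fastq"
        stem = f"{spec.sample_id}_t{spec.human_titer}_i{spec.iteration}"
        p1 = outdir / f"{stem}_1{ext}"
        p2 = outdir / f"{stem}_2{ext}"
        n_written = write_pairs(mixture, p1, p2, gzip_output=gzip_output)
        assert n_written == n_viral + n_host
        fq1, fq2 = str(p1), str(p2)

    row: Dict[str, object] = {
        "sample_id": spec.sample_id,
        "human_titer": spec.human_titer,
        "iteration": spec.iteration,
        "seed": spec.seed,
        "n_viral_pairs": n_viral,
        "n_host_pairs": n_host,
        "donor_counts": ";".join(f"{d}={alloc[d]}" for d in sorted(alloc)),
        "fastq1": fq1,
        "fastq2": fq2,
    }
    return mixture, row


def run_design(
    design: TitrationDesign,
    viral_pools: Mapping[str, Sequence[ReadPair]],
    donor_pools: Mapping[str, Sequence[ReadPair]],
    outdir: Optional[Path] = None,
    gzip_output: bool = True,
    manifest_path: Optional[Path] = None,
) -> pd.DataFrame:
    """Build every mixture of the design; returns the manifest.

    Per-cell seeds are derived deterministically from
    (base_seed, sample_id, titer, iteration), so the whole design is
    reproducible and stable under reordering. With the default design shape
    (9 titers × 3 iterations) 13 sample pools yield 351 mixtures.
    """
    donor_ids = tuple(sorted(donor_pools))
    rows = []
    for sample_id in design.sample_ids:
        if sample_id not in viral_pools:
            raise KeyError(f"no viral pool supplied for sample {sample_id!r}")
        for titer in design.titers:
            for it in range(1, design.iterations + 1):
                seed = child_seed("cell", design.base_seed, sample_id, titer, it)
                kwargs = (
                    {"total_pairs": design.pairs_per_mixture}
                    if design.mode is SizingMode.FIXED_TOTAL
                    else {"viral_pairs": design.pairs_per_mixture}
                )
                spec = MixtureSpec(
                    sample_id=sample_id,
                    human_titer=titer,
                    iteration=it,
                    donor_ids=donor_ids,
                    seed=seed,
                    **kwargs,
                )
                try:
                    _, row = build_mixture(
                        spec, viral_pools[sample_id], donor_pools, outdir, gzip_output
                    )
                except ValueError as exc:
                    raise ValueError(
                        f"cell (sample={sample_id}, titer={titer}, iteration={it}): {exc}"
                    ) from exc
                rows.append(row)
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if manifest_path is not None:
        manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest
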