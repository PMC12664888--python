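"""Desk-scale synthetic stand-ins for the benchmark inputs.

Generates mock host and target genomes, per-donor host genome variants,
contaminant-bearing donor read pools, and simulated paired-end reads, so
every downstream stage (mixing, removal, fate scoring, composition and
identifiability analyses) is testable with no external data.

The error model is substitution-only: fragments are drawn uniformly from the
genome with a Gaussian insert length truncated to [read_length, genome
length]; mate 1 is the forward start of the fragment, mate 2 the reverse
complement of its end. All operations are fully deterministic under their
seeds, and the class/donor composition of every generated pool matches its
specification exactly (counts, not approximations).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np

from hrrbench.sequence_io import LabelledRead, ProvenanceLabel, ReadPair, SourceClass

__all__ = [
    "MockGenome",
    "DonorModel",
    "ReadSimParams",
    "make_genome",
    "derive_donor",
    "simulate_pairs",
    "build_donor_pool",
    "child_seed",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = str.maketrans("ACGTN", "TGCAN")

MIN_GENOME_LENGTH = 200


def child_seed(*parts: object) -> int:
    """Derive a stable 31-bit seed from arbitrary coordinates.

    Hash-based so that per-cell / per-pool seeds are independent of iteration
    order and stable under design reordering.
    """
    key = "\x1f".join(str(p) for p in parts).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") & 0x7FFFFFFF


@dataclass(frozen=True)
class MockGenome:
    """A synthetic reference contig."""

    name: str
    sequence: str
    kind: SourceClass

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DonorModel:
    """One synthetic host donor: a SNP-bearing copy of the base host genome
    whose read pool may include a fixed fraction of contaminant reads,
    emulating the microbial contaminants observed inside real human-sample
    read sets."""

    donor_id: str
    base_genome: MockGenome
    snp_rate: float = 0.001
    contamination_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.snp_rate <= 0.05:
            raise ValueError(f"snp_rate must be in [0, 0.05], got {self.snp_rate}")
        if not 0.0 <= self.contamination_fraction < 1.0:
            raise ValueError(
                f"contamination_fraction must be in [0, 1), got {self.contamination_fraction}"
            )


@dataclass(frozen=True)
class ReadSimParams:
    """Paired-end read simulation parameters (substitution errors only)."""

    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 20:
            raise ValueError(f"read_length must be >= 20, got {self.read_length}")
        if self.insert_mean < self.read_length:
            raise ValueError("insert_mean must be >= read_length")
        if not 0.0 <= self.error_rate < 0.1:
            raise ValueError(f"error_rate must be in [0, 0.1), got {self.error_rate}")


def make_genome(
    name: str,
    length: int,
    kind: SourceClass = SourceClass.HOST,
    seed: int = 0,
    gc: Optional[float] = None,
) -> MockGenome:
    """Generate a random genome; uniform base composition unless ``gc`` given."""
    if length < MIN_GENOME_LENGTH:
        raise ValueError(f"genome length must be >= {MIN_GENOME_LENGTH}, got {length}")
    rng = np.random.default_rng(child_seed("genome", name, length, seed))
    if gc is None:
        probs = None
    else:
        if not 0.0 < gc < 1.0:
            raise ValueError(f"gc must be in (0, 1), got {gc}")
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = rng.choice(_BASES, size=length, p=probs).tobytes().decode("ascii")
    return MockGenome(name=name, sequence=seq, kind=kind)


def derive_donor(
    base: MockGenome, donor_id: str, snp_rate: float, seed: int = 0
) -> MockGenome:
    """Derive a donor genome from the base host genome by i.i.d. substitutions.

    Substitutions always change the base (drawn from the three alternatives),
    so the realized Hamming distance is Binomial(L, snp_rate)/L. Donor genomes
    are derived rather than independent so "host-like" reads remain mutually
    similar across donors.
    """
    if base.kind is not SourceClass.HOST:
        raise ValueError(f"donor genomes derive from HOST genomes, got {base.kind}")
    if not 0.0 <= snp_rate <= 0.05:
        raise ValueError(f"snp_rate must be in [0, 0.05], got {snp_rate}")
    if snp_rate == 0.0:
        return MockGenome(name=f"{base.name}.{donor_id}", sequence=base.sequence, kind=base.kind)
    rng = np.random.default_rng(child_seed("donor", donor_id, seed))
    arr = np.frombuffer(base.sequence.encode("ascii"), dtype="S1").copy()
    hit = rng.random(len(arr)) < snp_rate
    idx = np.flatnonzero(hit)
    if idx.size:
        # shift by 1..3 in base space => never substitute a base for itself
        codes = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
        cur = np.array([codes[bytes(b)] for b in arr[idx]])
        arr[idx] = _BASES[(cur + rng.integers(1, 4, size=idx.size)) % 4]
    return MockGenome(
        name=f"{base.name}.{donor_id}", sequence=arr.tobytes().decode("ascii"), kind=base.kind
    )


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_pairs(
    genome: MockGenome,
    n_pairs: int,
    params: ReadSimParams,
    label_class: SourceClass,
    donor_id: str,
    name_prefix: Optional[str] = None,
) -> List[ReadPair]:
    """Simulate labelled paired-end reads from ``genome``.

    Fragment starts are uniform; inserts ~ Normal(insert_mean, insert_sd)
    truncated to [read_length, len(genome)]. Each read gets i.i.d. per-base
    substitution errors at ``params.error_rate``. The provenance label records
    (label_class, donor_id, fragment coordinates) and is identical for both
    mates. Deterministic for fixed (params.seed, genome, donor_id, class).
    """
    if n_pairs <= 0:
        raise ValueError(f"n_pairs must be positive, got {n_pairs}")
    L = len(genome)
    rl = params.read_length
    if L < 2 * rl or L < params.insert_mean:
        raise ValueError(
            f"genome {genome.name!r} (length {L}) too short for the insert model"
        )
    rng = np.random.default_rng(
        child_seed("reads", params.seed, genome.name, donor_id, label_class.value)
    )
    prefix = name_prefix if name_prefix is not None else f"{donor_id}.{label_class.value}"

    inserts = np.rint(rng.normal(params.insert_mean, params.insert_sd, size=n_pairs))
    inserts = np.clip(inserts, rl, L).astype(np.int64)
    starts = rng.integers(0, L - inserts + 1)
    ends = starts + inserts

    # substitution errors, vectorized over reads that actually have any
    n_err = rng.binomial(rl, params.error_rate, size=2 * n_pairs)
    qual = "I" * rl
    seq = genome.sequence
    gname = genome.name
    pairs: List[ReadPair] = []
    for i in range(n_pairs):
        s, e = int(starts[i]), int(ends[i])
        fwd = seq[s : s + rl]
        rev = _revcomp(seq[e - rl : e])
        k1, k2 = int(n_err[2 * i]), int(n_err[2 * i + 1])
        if k1:
            fwd = _mutate(fwd, k1, rng)
        if k2:
            rev = _mutate(rev, k2, rng)
        origin = f"{gname}:{s + 1}-{e}"
        label = ProvenanceLabel(label_class, donor_id, origin)
        name = f"{prefix}.{i:07d}"
        pairs.append(
            ReadPair(
                LabelledRead(name, 1, fwd, qual, label),
                LabelledRead(name, 2, rev, qual, label),
            )
        )
    return pairs


def _mutate(read: str, k: int, rng: np.random.Generator) -> str:
    pos = rng.choice(len(read), size=k, replace=False)
    chars = list(read)
    alts = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG", "N": "ACGT"}
    for p in pos:
        chars[p] = alts[chars[p]][rng.integers(0, 3)]
    return "".join(chars)


def round_half_away(x: float) -> int:
    """Round half away from zero (so pool compositions are exact and testable)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def build_donor_pool(
    donor: DonorModel,
    contaminant_genomes: Sequence[MockGenome],
    n_pairs: int,
    params: ReadSimParams,
) -> List[ReadPair]:
    """Build one donor's read pool: HOST reads from the donor genome plus
    ``round(contamination_fraction * n_pairs)`` CONTAMINANT pairs drawn evenly
    from the contaminant genomes, all labelled with this donor's id, shuffled
    deterministically."""
    if n_pairs <= 0:
        raise ValueError(f"n_pairs must be positive, got {n_pairs}")
    n_cont = round_half_away(donor.contamination_fraction * n_pairs)
    if n_cont > 0 and not contaminant_genomes:
        raise ValueError(
            f"donor {donor.donor_id!r}: contamination_fraction > 0 but no contaminant genomes"
        )
    n_host = n_pairs - n_cont

    pool: List[ReadPair] = []
    if n_host > 0:
        genome = derive_donor(donor.base_genome, donor.donor_id, donor.snp_rate, donor.seed)
        host_params = ReadSimParams(
            params.read_length,
            params.insert_mean,
            params.insert_sd,
            params.error_rate,
            seed=child_seed("pool-host", params.seed, donor.donor_id, donor.seed),
        )
        pool.extend(
            simulate_pairs(genome, n_host, host_params, SourceClass.HOST, donor.donor_id)
        )
    if n_cont > 0:
        k = len(contaminant_genomes)
        base, rem = divmod(n_cont, k)
        for j, cg in enumerate(contaminant_genomes):
            nj = base + (1 if j < rem else 0)
            if nj == 0:
                continue
            cont_params = ReadSimParams(
                params.read_length,
                params.insert_mean,
                params.insert_sd,
                params.error_rate,
                seed=child_seed("pool-cont", params.seed, donor.donor_id, donor.seed, cg.name),
            )
            pool.extend(
                simulate_pairs(
                    cg,
                    nj,
                    cont_params,
                    SourceClass.CONTAMINANT,
                    donor.donor_id,
                    name_prefix=f"{donor.donor_id}.C.{cg.name}",
                )
            )
    rng = np.random.default_rng(child_seed("pool-shuffle", params.seed, donor.donor_id, donor.seed))
    order = rng.permutation(len(pool))
    return [pool[i] for i in order]


def write_genome_fasta(genomes: Iterable[MockGenome], path, width: int = 80) -> None:
    """Write genomes as FASTA (plain text)."""
    with open(path, "wt") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")
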