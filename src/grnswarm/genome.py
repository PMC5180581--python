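"""Artificial genome: multi-chromosome digit strings encoding promoter-tagged genes.

The genome is the heritable, mutable layer of the robot controller.  Each
chromosome is a string over a small digit alphabet (default ``0123``) in the
artificial-genome tradition: genes are located by a fixed promoter motif and
consist of a 2-character type field (signalling / regulatory / structural by
residue mod 3), a binding site, and a payload that encodes the gene product's
signature and — for structural genes — its actuator wiring.

Binding between a product signature and a binding site is *complementary*
(0<->3, 1<->2, i.e. ``c -> A-1-c``) with a configurable mismatch tolerance, so
point mutations tune regulatory connectivity gradually rather than all-or-none.

Replication applies per-character point mutations (always to a different
character) and chromosome segment duplications; with all rates zero the child
is bit-identical to the parent.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SIGNALLING", "REGULATORY", "STRUCTURAL", "GENE_TYPES",
    "GenomeError", "GeneLayout", "GeneLocus", "MutationRates",
    "ArtificialGenome", "init_genome", "scan_genes", "scan_arrays", "binds",
    "complement_mismatches", "replicate_genome", "save_genome", "load_genome",
]

SIGNALLING = "signalling"
REGULATORY = "regulatory"
STRUCTURAL = "structural"
GENE_TYPES = (SIGNALLING, REGULATORY, STRUCTURAL)


class GenomeError(ValueError):
    """Invalid genome construction or operation arguments."""


@dataclass(frozen=True)
class GeneLayout:
    """Positional anatomy of a gene: promoter | type | binding site | payload.

    The payload's first ``binding_len`` characters are the product signature;
    the next two characters are wiring (actuator index for structural genes,
    activator/repressor flag for regulatory genes) and the final two encode a
    structural output value on [-1, 1].
    """

    promoter: str = "0101"
    type_len: int = 2
    binding_len: int = 4
    payload_len: int = 8

    @property
    def gene_len(self) -> int:
        return len(self.promoter) + self.type_len + self.binding_len + self.payload_len


@dataclass(frozen=True)
class GeneLocus:
    """A gene found on a chromosome; offsets are 0-based and half-open."""

    chromosome: int
    start: int
    end: int
    gene_type: str
    binding_site: str
    payload: str
    promoter_offset: int


@dataclass(frozen=True)
class MutationRates:
    point_rate: float
    duplication_rate: float
    duplication_mean_length: int = 50

    def __post_init__(self) -> None:
        if not (0.0 <= self.point_rate <= 1.0 and 0.0 <= self.duplication_rate <= 1.0):
            raise GenomeError("mutation probabilities must lie in [0, 1]")
        if self.duplication_mean_length < 1:
            raise GenomeError("duplication_mean_length must be >= 1")


class ArtificialGenome:
    """Ordered chromosomes over a fixed alphabet, stored as uint8 index arrays."""

    __slots__ = ("chromosomes", "alphabet", "seed", "mutation_count", "_cache")

    def __init__(
        self,
        chromosomes: Sequence[np.ndarray | Sequence[int]],
        alphabet: str,
        seed: int | None = None,
        mutation_count: int = 0,
    ):
        if len(set(alphabet)) != len(alphabet) or len(alphabet) < 2:
            raise GenomeError("alphabet must have >= 2 distinct characters")
        if len(chromosomes) < 1:
            raise GenomeError("genome needs at least one chromosome")
        chroms = []
        A = len(alphabet)
        for arr in chromosomes:
            a = np.asarray(arr, dtype=np.uint8)
            if a.ndim != 1 or a.size == 0:
                raise GenomeError("every chromosome must be a non-empty 1-D sequence")
            if a.max(initial=0) >= A:
                raise GenomeError("chromosome character outside alphabet")
            a.setflags(write=False)
            chroms.append(a)
        self.chromosomes: tuple[np.ndarray, ...] = tuple(chroms)
        self.alphabet = alphabet
        self.seed = seed
        self.mutation_count = mutation_count
        self._cache: dict = {}  # per-genome derived data (scan results, networks)

    # -- basic introspection ------------------------------------------------
    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(self.lengths)

    def chromosome_str(self, i: int) -> str:
        return decode(self.chromosomes[i], self.alphabet)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ArtificialGenome):
            return NotImplemented
        return (
            self.alphabet == other.alphabet
            and self.lengths == other.lengths
            and all(np.array_equal(a, b) for a, b in zip(self.chromosomes, other.chromosomes))
        )

    def __hash__(self) -> int:  # identity-hash: genomes are de-facto immutable
        return id(self)

    @classmethod
    def from_strings(cls, seqs: Iterable[str], alphabet: str, **kw) -> "ArtificialGenome":
        return cls([encode(s, alphabet) for s in seqs], alphabet, **kw)


def encode(seq: str, alphabet: str) -> np.ndarray:
    """Map a character string to a uint8 index array over ``alphabet``."""
    try:
        return np.fromiter((alphabet.index(ch) for ch in seq), dtype=np.uint8, count=len(seq))
    except ValueError as exc:
        raise GenomeError(f"character outside alphabet: {exc}") from None


def decode(arr: np.ndarray, alphabet: str) -> str:
    return "".join(alphabet[int(i)] for i in arr)


def init_genome(
    seed: int,
    n_chromosomes: int = 10,
    chrom_length: int = 10_000,
    alphabet: str = "0123",
) -> ArtificialGenome:
    """Generate a uniform-random genome; the same seed yields a bit-identical genome."""
    if n_chromosomes < 1 or chrom_length < 1:
        raise GenomeError("genome dimensions must be positive")
    if len(set(alphabet)) < 2:
        raise GenomeError("alphabet must have >= 2 distinct characters")
    rng = np.random.default_rng(seed)
    A = len(alphabet)
    chroms = [rng.integers(0, A, size=chrom_length, dtype=np.uint8) for _ in range(n_chromosomes)]
    return ArtificialGenome(chroms, alphabet, seed=seed)


# -- gene scanning ----------------------------------------------------------

def scan_arrays(genome: ArtificialGenome, layout: GeneLayout = GeneLayout()) -> dict:
    """Array-level gene scan (the fast path behind :func:`scan_genes`).

    Returns a dict of equal-length arrays: ``chromosome``, ``start``
    (absolute promoter offsets of the accepted, non-overlapping genes, in
    (chromosome, start) order), ``type_value`` (raw type-field value),
    ``sites`` (n x binding_len) and ``payloads`` (n x payload_len) character
    index matrices.  Cached per (genome, layout).
    """
    key = ("scan", layout)
    cached = genome._cache.get(key)
    if cached is not None:
        return cached
    prom = encode(layout.promoter, genome.alphabet)
    A = len(genome.alphabet)
    glen = layout.gene_len
    chrom_ids: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    tvals: list[np.ndarray] = []
    sites: list[np.ndarray] = []
    payloads: list[np.ndarray] = []
    for ci, chrom in enumerate(genome.chromosomes):
        n = len(chrom)
        if n < glen:
            continue
        hits = _promoter_hits(chrom, prom)
        acc: list[int] = []
        pos = 0
        for h in hits:
            if h < pos or h + glen > n:
                continue
            acc.append(int(h))
            pos = int(h) + glen
        if not acc:
            continue
        st = np.asarray(acc, dtype=np.int64)
        t0 = st + len(prom)
        tv = np.zeros(len(st), dtype=np.int64)
        for k in range(layout.type_len):
            tv = tv * A + chrom[t0 + k]
        b0 = t0 + layout.type_len
        site = chrom[b0[:, None] + np.arange(layout.binding_len)]
        pay = chrom[(b0 + layout.binding_len)[:, None] + np.arange(layout.payload_len)]
        chrom_ids.append(np.full(len(st), ci, dtype=np.int64))
        starts.append(st)
        tvals.append(tv)
        sites.append(site)
        payloads.append(pay)
    if starts:
        out = {
            "chromosome": np.concatenate(chrom_ids),
            "start": np.concatenate(starts),
            "type_value": np.concatenate(tvals),
            "sites": np.concatenate(sites),
            "payloads": np.concatenate(payloads),
        }
    else:
        out = {
            "chromosome": np.empty(0, dtype=np.int64),
            "start": np.empty(0, dtype=np.int64),
            "type_value": np.empty(0, dtype=np.int64),
            "sites": np.empty((0, layout.binding_len), dtype=np.uint8),
            "payloads": np.empty((0, layout.payload_len), dtype=np.uint8),
        }
    genome._cache[key] = out
    return out


def scan_genes(genome: ArtificialGenome, layout: GeneLayout = GeneLayout()) -> list[GeneLocus]:
    """Locate all complete genes, left-to-right, non-overlapping.

    Promoter hits are resolved first-come: after a gene is read, scanning
    resumes at its end, so overlapping promoter occurrences inside a gene body
    are ignored.  A promoter too close to the chromosome end to carry a full
    gene yields nothing.  Scanning is pure (the genome is never modified) and
    cached per (genome, layout).
    """
    key = ("loci", layout)
    cached = genome._cache.get(key)
    if cached is not None:
        return cached
    arrs = scan_arrays(genome, layout)
    glen = layout.gene_len
    loci = [
        GeneLocus(
            chromosome=int(arrs["chromosome"][i]),
            start=int(arrs["start"][i]),
            end=int(arrs["start"][i]) + glen,
            gene_type=GENE_TYPES[int(arrs["type_value"][i]) % 3],
            binding_site=decode(arrs["sites"][i], genome.alphabet),
            payload=decode(arrs["payloads"][i], genome.alphabet),
            promoter_offset=int(arrs["start"][i]),
        )
        for i in range(len(arrs["start"]))
    ]
    genome._cache[key] = loci
    return loci


def _promoter_hits(chrom: np.ndarray, prom: np.ndarray) -> np.ndarray:
    """Offsets of all (possibly overlapping) promoter occurrences."""
    L, n = len(prom), len(chrom)
    if n < L:
        return np.empty(0, dtype=np.int64)
    m = chrom[: n - L + 1] == prom[0]
    for k in range(1, L):
        m = m & (chrom[k : n - L + 1 + k] == prom[k])
    return np.flatnonzero(m)


# -- binding ----------------------------------------------------------------

def complement_mismatches(signature: str, site: str, alphabet: str) -> int:
    """Count positions where the signature is NOT the complement of the site."""
    if len(signature) != len(site):
        raise GenomeError("signature and binding site lengths differ")
    A = len(alphabet)
    sig = encode(signature, alphabet)
    st = encode(site, alphabet)
    return int(np.count_nonzero(sig != (A - 1 - st)))


def binds(signature: str, site: str, alphabet: str = "0123", tolerance: int = 1) -> bool:
    """True when the complement distance between signature and site is <= tolerance."""
    return complement_mismatches(signature, site, alphabet) <= tolerance


# -- replication ------------------------------------------------------------

def replicate_genome(
    parent: ArtificialGenome,
    rates: MutationRates,
    rng: np.random.Generator,
) -> ArtificialGenome:
    """Copy the genome through the mutational operators.

    Point mutations replace single characters with a *different* uniformly
    chosen character (a hit always changes the sequence); duplications insert
    a copy of a contiguous segment (geometric length, mean
    ``duplication_mean_length``) at a uniform insertion point of the same
    chromosome.  Duplication grows the chromosome by exactly the segment
    length; point mutation preserves length.
    """
    A = len(parent.alphabet)
    children: list[np.ndarray] = []
    n_mutations = 0
    for chrom in parent.chromosomes:
        arr = chrom.copy()
        n = len(arr)
        # point mutations
        if rates.point_rate > 0:
            k = int(rng.binomial(n, rates.point_rate))
            if k:
                pos = rng.choice(n, size=k, replace=False)
                shift = rng.integers(1, A, size=k, dtype=np.uint8)
                arr[pos] = (arr[pos] + shift) % A
                n_mutations += k
        # segment duplication
        if rates.duplication_rate > 0 and rng.random() < rates.duplication_rate:
            seg_len = min(int(rng.geometric(1.0 / rates.duplication_mean_length)), n)
            src = int(rng.integers(0, n - seg_len + 1))
            ins = int(rng.integers(0, n + 1))
            arr = np.concatenate([arr[:ins], arr[src : src + seg_len], arr[ins:]])
            n_mutations += 1
        children.append(arr)
    return ArtificialGenome(
        children,
        parent.alphabet,
        seed=parent.seed,
        mutation_count=parent.mutation_count + n_mutations,
    )


# -- persistence ------------------------------------------------------------

def save_genome(genome: ArtificialGenome, path: str) -> None:
    """Plain-text genome file: a header line, then one chromosome per line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"#grnswarm-genome alphabet={genome.alphabet} "
            f"seed={genome.seed} mutations={genome.mutation_count}\n"
        )
        for i in range(genome.n_chromosomes):
            fh.write(genome.chromosome_str(i) + "\n")


def load_genome(path: str) -> ArtificialGenome:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("#grnswarm-genome"):
            raise GenomeError(f"{path}: not a genome file")
        meta = dict(tok.split("=", 1) for tok in header.split()[1:])
        seqs = [line.strip() for line in fh if line.strip()]
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    return ArtificialGenome.from_strings(
        seqs, meta["alphabet"], seed=seed, mutation_count=int(meta.get("mutations", 0))
    )
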