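"""Paired-read quality filtering, fixed-length trimming, and organelle removal.

Genome-skimming repeat quantification works on raw read pairs: pairs with too
many low-quality calls are dropped, survivors are cut to a common length so
every read carries equal weight in clustering, and pairs matching the plastid
genome are removed so cluster proportions refer to the nuclear genome only.
Organelle matching here is alignment-free: a pair is discarded when either
mate shares a high fraction of canonical k-mers with the organelle reference.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, TextIO

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._kmers import kmer_set

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read: sequences plus Phred+33 quality strings."""

    id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")
        bad = (set(self.seq1) | set(self.seq2)) - _VALID_BASES
        if bad:
            raise ValueError(f"read {self.id}: invalid bases {sorted(bad)}")


def phred_scores(qual: str) -> np.ndarray:
    """Phred+33 quality string to integer scores."""
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33


@dataclass(frozen=True)
class OrganelleIndex:
    """Canonical k-mer set of an organelle reference, for alignment-free matching."""

    k: int
    kmer_set: np.ndarray  # sorted unique canonical k-mer codes

    @classmethod
    def from_sequence(cls, seq: str, k: int = 31) -> "OrganelleIndex":
        return cls(k=k, kmer_set=kmer_set(seq, k))

    def hit_fraction(self, seq: str) -> float:
        """Fraction of the read's canonical k-mers present in the index."""
        kmers = kmer_set(seq, self.k)
        if kmers.size == 0:
            return 0.0
        pos = np.searchsorted(self.kmer_set, kmers)
        pos = np.clip(pos, 0, self.kmer_set.size - 1)
        hits = int((self.kmer_set[pos] == kmers).sum()) if self.kmer_set.size else 0
        return hits / kmers.size


def quality_filter_pair(pair: ReadPair, q_min: int = 20, max_frac: float = 0.05) -> bool:
    """Keep a pair iff its low-quality share is within ``max_frac`` and it has no N.

    The share is counted across both mates jointly (one decision per pair) and
    the boundary is inclusive: exactly ``max_frac`` low-quality bases is kept.
    """
    if "N" in pair.seq1 or "N" in pair.seq2:
        return False
    scores = np.concatenate([phred_scores(pair.qual1), phred_scores(pair.qual2)])
    low = int((scores < q_min).sum())
    return low / scores.size <= max_frac


def trim_pair(pair: ReadPair, length: int = 125) -> ReadPair | None:
    """Truncate both mates to their first ``length`` bases; drop short pairs.

    Returns None when either mate is shorter than ``length`` (short pairs are
    discarded rather than padded, so every retained read has equal weight).
    """
    if len(pair.seq1) < length or len(pair.seq2) < length:
        return None
    return replace(
        pair,
        seq1=pair.seq1[:length],
        seq2=pair.seq2[:length],
        qual1=pair.qual1[:length],
        qual2=pair.qual2[:length],
    )


def organelle_filter(
    pairs: Iterable[ReadPair],
    index: OrganelleIndex,
    hit_frac: float = 0.8,
    stats: dict | None = None,
) -> Iterator[ReadPair]:
    """Drop pairs where either mate matches the organelle index at >= ``hit_frac``.

    Survivors pass through unchanged and in input order. Mates shorter than k
    are treated as non-matching (retained), since no k-mer evidence exists.
    """
    discarded = 0
    for pair in pairs:
        if (
            index.hit_fraction(pair.seq1) >= hit_frac
            or index.hit_fraction(pair.seq2) >= hit_frac
        ):
            discarded += 1
            continue
        yield pair
    if stats is not None:
        stats["discarded_organelle"] = stats.get("discarded_organelle", 0) + discarded


def preprocess_pairs(
    pairs: Iterable[ReadPair],
    organelle: OrganelleIndex | None = None,
    trim_length: int = 125,
    q_min: int = 20,
    max_lowq_frac: float = 0.05,
    hit_frac: float = 0.8,
) -> tuple[list[ReadPair], dict]:
    """Full preparation: quality/N filter, fixed-length trim, organelle removal.

    Returns the surviving pairs (input order preserved) and a summary-count log.
    """
    log = {
        "input_pairs": 0,
        "discarded_quality_or_n": 0,
        "discarded_short": 0,
        "discarded_organelle": 0,
        "output_pairs": 0,
    }
    kept: list[ReadPair] = []
    for pair in pairs:
        log["input_pairs"] += 1
        if not quality_filter_pair(pair, q_min=q_min, max_frac=max_lowq_frac):
            log["discarded_quality_or_n"] += 1
            continue
        trimmed = trim_pair(pair, length=trim_length)
        if trimmed is None:
            log["discarded_short"] += 1
            continue
        kept.append(trimmed)
    if organelle is not None:
        kept = list(organelle_filter(kept, organelle, hit_frac=hit_frac, stats=log))
    log["output_pairs"] = len(kept)
    return kept, log


# ---------------------------------------------------------------------------
# FASTQ input/output (4-line records, Phred+33; .gz handled transparently)

def _open_text(path, mode: str = "rt") -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(path1, path2) -> Iterator[ReadPair]:
    """Iterate read pairs from two synchronized FASTQ files."""
    with _open_text(path1) as h1, _open_text(path2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        for (id1, seq1, q1), (id2, seq2, q2) in zip(it1, it2, strict=True):
            yield ReadPair(
                id=id1.split()[0].removesuffix("/1"),
                seq1=seq1.upper(), seq2=seq2.upper(), qual1=q1, qual2=q2,
            )


def write_fastq_pairs(pairs: Iterable[ReadPair], path1, path2) -> int:
    """Write pairs to two FASTQ files; returns the number of pairs written."""
    n = 0
    with _open_text(path1, "wt") as h1, _open_text(path2, "wt") as h2:
        for p in pairs:
            h1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            h2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")
            n += 1
    return n


def write_log(log: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
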