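"""Triplex-forming-oligonucleotide (TFO) target-site search and design.

TFOs bind purine-rich duplex DNA in the major groove, causing DNA damage in
proportion to target copy number — which makes amplified sequences
selectively targetable.  A usable target is a long run of purines (A/G) on
one strand.  The scanner reports *maximal* purine tracts: runs that start
and end with a purine, tolerate isolated single-pyrimidine interruptions
(which lengthen and strengthen a target), and are terminated on both ends
by two consecutive pyrimidines (or the sequence boundary, or an ``N``).

Coordinates are 0-based half-open on the plus (input) strand; minus-strand
hits are mapped back to plus coordinates with ``strand='-'`` and their
``site_seq`` given 5'->3' on the purine-carrying strand.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "TfoTargetSite",
    "TfoCandidate",
    "find_purine_runs",
    "scan_fasta",
    "rank_sites",
    "design_oligo",
    "make_combo",
    "write_bed",
    "write_oligo_fasta",
    "write_manifest",
]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
ALPHABET = frozenset("ACGTN")
DEFAULT_MIN_LENGTH = 15

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceAlphabetError(ValueError):
    """Input sequence contains a character outside {A,C,G,T,N}."""

    def __init__(self, char: str, position: int):
        super().__init__(f"invalid character {char!r} at position {position}")
        self.char = char
        self.position = position


@dataclass(frozen=True)
class TfoTargetSite:
    """A maximal purine tract usable as a TFO target.

    ``start``/``end`` are 0-based half-open plus-strand coordinates;
    ``site_seq`` is the purine-strand sequence 5'->3' (the reverse
    complement of the plus-strand slice when ``strand == '-'``).
    """

    seq_id: str
    start: int
    end: int
    strand: str
    site_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start != len(self.site_seq):
            raise ValueError("site_seq length must equal end - start")
        if not self.site_seq or self.site_seq[0] not in PURINES or self.site_seq[-1] not in PURINES:
            raise ValueError("site_seq must begin and end with a purine")
        for a, b in zip(self.site_seq, self.site_seq[1:]):
            if a not in PURINES and b not in PURINES:
                raise ValueError("site_seq must not contain two consecutive pyrimidines")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def purine_count(self) -> int:
        return sum(1 for b in self.site_seq if b in PURINES)

    @property
    def gap_count(self) -> int:
        """Number of tolerated isolated-pyrimidine interruptions."""
        return self.length - self.purine_count

    @property
    def purine_fraction(self) -> float:
        return self.purine_count / self.length


@dataclass(frozen=True)
class TfoCandidate:
    """A candidate oligo derived from a target site."""

    target: TfoTargetSite
    oligo_seq: str
    orientation_convention: str
    rank: int | None = None

    def __post_init__(self) -> None:
        if len(self.oligo_seq) != self.target.length:
            raise ValueError("oligo length must equal target length")


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in ALPHABET:
            raise SequenceAlphabetError(ch, i)
    return seq


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _scan_strand(seq: str) -> list[tuple[int, int]]:
    """Maximal qualifying runs on one strand as (start, end) pairs.

    Linear greedy scan: a run starts at a purine and extends through purines
    and isolated pyrimidines followed by a purine; two consecutive
    non-purines (pyrimidine or N) or an N terminate it.  ``N`` never sits
    inside a run.  Greedy extension makes every emitted run maximal.
    """
    runs: list[tuple[int, int]] = []
    L = len(seq)
    i = 0
    while i < L:
        if seq[i] not in PURINES:
            i += 1
            continue
        start = i
        last_purine = i
        i += 1
        while i < L:
            ch = seq[i]
            if ch in PURINES:
                last_purine = i
                i += 1
            elif ch in PYRIMIDINES and i + 1 < L and seq[i + 1] in PURINES:
                last_purine = i + 1  # tolerated single-pyrimidine gap
                i += 2
            else:
                break
        runs.append((start, last_purine + 1))
        i = last_purine + 2  # position after the terminating pyrimidine
    return runs


def find_purine_runs(
    sequence: str,
    min_length: int = DEFAULT_MIN_LENGTH,
    scan_both_strands: bool = False,
    seq_id: str = "seq",
) -> list[TfoTargetSite]:
    """All maximal purine tracts of length >= ``min_length``.

    With ``scan_both_strands`` the reverse complement is scanned identically
    and hits are reported on the minus strand in plus-strand coordinates.
    Sites are returned sorted by (start, strand).
    """
    if min_length < 1:
        raise ValueError(f"min_length must be >= 1, got {min_length}")
    seq = _validate_sequence(sequence)
    L = len(seq)
    sites = [
        TfoTargetSite(seq_id, a, b, "+", seq[a:b])
        for a, b in _scan_strand(seq)
        if b - a >= min_length
    ]
    if scan_both_strands:
        rc = reverse_complement(seq)
        for a, b in _scan_strand(rc):
            if b - a < min_length:
                continue
            start, end = L - b, L - a
            sites.append(TfoTargetSite(seq_id, start, end, "-", rc[a:b]))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def scan_fasta(
    path: str | Path,
    min_length: int = DEFAULT_MIN_LENGTH,
    scan_both_strands: bool = False,
) -> list[TfoTargetSite]:
    """Scan every record of a (multi-)FASTA file."""
    sites: list[TfoTargetSite] = []
    for record in SeqIO.parse(str(path), "fasta"):
        sites.extend(
            find_purine_runs(
                str(record.seq), min_length, scan_both_strands, seq_id=record.id
            )
        )
    return sites


def rank_sites(
    sites: Sequence[TfoTargetSite], top_k: int | None = None
) -> list[TfoTargetSite]:
    """Deterministic total ordering of candidate sites.

    Longer first, then higher purine fraction, then leftmost start, then
    sequence id and strand as final tie-breaks.
    """
    ordered = sorted(
        sites,
        key=lambda s: (-s.length, -s.purine_fraction, s.start, s.seq_id, s.strand),
    )
    return ordered if top_k is None else ordered[:top_k]


def design_oligo(
    site: TfoTargetSite,
    convention: str = "antiparallel-GA",
    gap_base: str = "T",
) -> TfoCandidate:
    """Derive a candidate TFO from a target site.

    Conventions:

    * ``antiparallel-GA`` (default): purine-motif oligo antiparallel to the
      purine strand — G opposite G.C, A opposite A.T — i.e. the reverse of
      the purine-strand sequence, with tolerated-gap positions carrying the
      placeholder ``gap_base``.
    * ``parallel-CT``: pyrimidine-motif oligo parallel to the purine strand
      (C opposite G.C, T opposite A.T; the C requires protonation to bind).
    * ``purine-strand``: the raw purine-strand sequence itself (no
      placeholder substitution).
    """
    s = site.site_seq
    if convention == "antiparallel-GA":
        oligo = "".join(b if b in PURINES else gap_base for b in s)[::-1]
    elif convention == "parallel-CT":
        table = {"G": "C", "A": "T"}
        oligo = "".join(table.get(b, gap_base) for b in s)
    elif convention == "purine-strand":
        oligo = s
    else:
        raise ValueError(f"unknown oligo convention {convention!r}")
    return TfoCandidate(target=site, oligo_seq=oligo, orientation_convention=convention)


def make_combo(
    candidates: Sequence[TfoCandidate], k: int
) -> pd.DataFrame:
    """Equal-ratio cocktail manifest of the top-``k`` candidates.

    Mirrors the pooled-TFO treatment design (e.g. three oligos at 1:1:1, or
    four at 1:1:1:1).  Returns a manifest with oligo names, sequences,
    target coordinates and mixing ratios summing to 1.  The 3'-amino
    modification used for synthesized TFOs is recorded as metadata.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(candidates):
        raise ValueError(f"requested k={k} but only {len(candidates)} candidates")
    chosen = list(candidates[:k])
    rows = []
    for i, cand in enumerate(chosen, start=1):
        t = cand.target
        rows.append(
            {
                "name": f"{t.seq_id}_TFO{i}",
                "oligo_seq": cand.oligo_seq,
                "convention": cand.orientation_convention,
                "seq_id": t.seq_id,
                "start": t.start,
                "end": t.end,
                "strand": t.strand,
                "site_seq": t.site_seq,
                "length": t.length,
                "purine_count": t.purine_count,
                "ratio": 1.0 / k,
                "modification": "3'-amino",
            }
        )
    manifest = pd.DataFrame(rows)
    assert abs(manifest["ratio"].sum() - 1.0) < 1e-12
    return manifest


# ---------------------------------------------------------------------------
# writers

def write_bed(sites: Sequence[TfoTargetSite], path: str | Path) -> None:
    """BED6: name = site id, score = purine count."""
    with open(path, "w") as fh:
        for i, s in enumerate(sites, start=1):
            fh.write(
                f"{s.seq_id}\t{s.start}\t{s.end}\t{s.seq_id}_site{i}\t{s.purine_count}\t{s.strand}\n"
            )


def write_oligo_fasta(candidates: Sequence[TfoCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, cand in enumerate(candidates, start=1):
            t = cand.target
            fh.write(
                f">{t.seq_id}_TFO{i} {t.seq_id}:{t.start}-{t.end}({t.strand}) {cand.orientation_convention}\n"
            )
            fh.write(cand.oligo_seq + "\n")


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)
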