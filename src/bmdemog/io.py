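"""Readers and writers: GENEPOP genotype tables, FASTA alignments, CSV export.

GENEPOP dialect handled: a title line, one locus name per line (or a single
comma-separated line), ``Pop`` markers, then per-individual lines of the form
``id , 010012 008008``.  Both 2- and 3-digit allele codes are accepted and
auto-detected from token length; an allele code of zero marks a missing call.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import MISSING, GenotypeMatrix, LocusSummary, SequenceAlignment

__all__ = [
    "read_genepop",
    "write_genepop",
    "read_fasta",
    "write_fasta",
    "locus_summaries_to_csv",
]


class GenepopParseError(ValueError):
    """Raised when a GENEPOP file violates the format."""


def _decode_token(token: str, path: str, lineno: int) -> tuple[int, int]:
    if len(token) == 6 or len(token) == 4:
        half = len(token) // 2
    else:
        raise GenepopParseError(
            f"{path}:{lineno}: genotype token {token!r} is not 4 or 6 digits"
        )
    if not token.isdigit():
        raise GenepopParseError(f"{path}:{lineno}: non-numeric genotype token {token!r}")
    a, b = int(token[:half]), int(token[half:])
    if a == 0 or b == 0:
        return (MISSING, MISSING)
    return (a, b)


def read_genepop(path: str | os.PathLike) -> GenotypeMatrix:
    """Parse a GENEPOP file into a :class:`GenotypeMatrix`.

    Populations are concatenated (the BCB stock is managed as a single
    population, and every statistic here is population-agnostic).
    """
    path = os.fspath(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise GenepopParseError(f"{path}: truncated file")
    # line 0 is the title; locus names follow until the first Pop marker
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        row = lines[i].strip()
        if row:
            loci.extend(name.strip() for name in row.split(",") if name.strip())
        i += 1
    if i == len(lines):
        raise GenepopParseError(f"{path}: no 'Pop' marker found")
    if len(set(loci)) != len(loci):
        dup = sorted({x for x in loci if loci.count(x) > 1})
        raise GenepopParseError(f"{path}: duplicate locus names {dup}")
    if not loci:
        raise GenepopParseError(f"{path}: no locus names before first 'Pop'")

    individuals: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    for lineno, raw in enumerate(lines[i:], start=i + 1):
        row = raw.strip()
        if not row:
            continue
        if row.lower() == "pop":
            continue
        if "," not in row:
            raise GenepopParseError(f"{path}:{lineno}: expected 'id , genotypes'")
        ind_id, _, geno = row.partition(",")
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenepopParseError(
                f"{path}:{lineno}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        individuals.append(ind_id.strip())
        calls.append([_decode_token(t, path, lineno) for t in tokens])
    if not individuals:
        raise GenepopParseError(f"{path}: no individuals")
    return GenotypeMatrix(individuals, loci, np.array(calls, dtype=np.int64))


def write_genepop(matrix: GenotypeMatrix, path: str | os.PathLike, title: str = "bmdemog export") -> None:
    """Write a :class:`GenotypeMatrix` as a single-population GENEPOP file."""
    width = 3 if matrix.alleles.max(initial=0) > 99 else 2
    if matrix.alleles.max(initial=0) > 999:
        raise ValueError("allele sizes exceed the 3-digit GENEPOP code range")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in matrix.loci:
            fh.write(locus + "\n")
        fh.write("Pop\n")
        for i, ind in enumerate(matrix.individuals):
            tokens = [
                f"{a:0{width}d}{b:0{width}d}" for a, b in matrix.alleles[i]
            ]
            fh.write(f"{ind} , " + " ".join(tokens) + "\n")


def read_fasta(
    path: str | os.PathLike,
    partitions: dict[str, tuple[int, int]] | None = None,
) -> SequenceAlignment:
    """Read an aligned FASTA file; lowercase is normalized to uppercase."""
    records = list(SeqIO.parse(os.fspath(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        offender = next(r.id for r in records if len(r.seq) != len(records[0].seq))
        raise ValueError(
            f"{path}: ragged alignment (record {offender!r} differs in length)"
        )
    return SequenceAlignment(
        ids=[r.id for r in records],
        sequences=[str(r.seq).upper() for r in records],
        partitions=partitions or {},
    )


def write_fasta(alignment: SequenceAlignment, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(alignment.ids, alignment.sequences)
    ]
    SeqIO.write(records, os.fspath(path), "fasta")


def locus_summaries_to_csv(summaries: list[LocusSummary], path: str | os.PathLike) -> pd.DataFrame:
    """Export per-locus summaries in the layout of the study's Table-2-style report."""
    df = pd.DataFrame(
        {
            "locus": [s.name for s in summaries],
            "n_alleles": [s.k for s in summaries],
            "Ho": [s.Ho for s in summaries],
            "He": [s.He for s in summaries],
            "hwe_p": [s.hwe_p for s in summaries],
            "null_allele_freq": [s.null_freq for s in summaries],
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df
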