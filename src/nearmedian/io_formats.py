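"""Reading and writing genomes.

Two plain-text formats are supported:

* GRIMM-style signed permutations: a ``>label`` header line followed by
  whitespace-separated signed integers; each circular chromosome is
  terminated by ``@``.  The linear terminator ``$`` is rejected, since the
  model is circular-only.
* A flat adjacency TSV with columns ``genome_label``, ``end1``, ``end2``
  and end tokens like ``12h`` (gene id followed by ``h``/``t``).  Partial
  adjacency sets are allowed, so diagnostics and intermediate
  constructions can be exported as well as full genomes.

Files are UTF-8 with Unix newlines.
"""

from __future__ import annotations

import csv
import sys
from contextlib import contextmanager
from typing import IO, Iterable, Sequence

from .genome_model import (
    AdjacencySet,
    Adjacency,
    GenomeError,
    Genome,
    chromosomes,
    genome_from_chromosomes,
    parse_end,
)


class FormatError(GenomeError):
    """Raised for malformed genome files."""


@contextmanager
def _open_read(path_or_file):
    if hasattr(path_or_file, "read"):
        yield path_or_file
    else:
        with open(path_or_file, "r", encoding="utf-8") as fh:
            yield fh


@contextmanager
def _open_write(path_or_file):
    if path_or_file == "-":
        yield sys.stdout
    elif hasattr(path_or_file, "write"):
        yield path_or_file
    else:
        with open(path_or_file, "w", encoding="utf-8", newline="\n") as fh:
            yield fh


def _finish_record(label, chroms, pending, genomes):
    if pending:
        raise FormatError(f"genome {label!r}: chromosome not terminated by '@'")
    if not chroms:
        raise FormatError(f"genome {label!r}: no chromosomes")
    try:
        genomes.append(genome_from_chromosomes(chroms, label=label))
    except GenomeError as exc:
        raise FormatError(f"genome {label!r}: {exc}") from exc


def read_grimm(path_or_file) -> list[Genome]:
    """Read one or more circular genomes from a GRIMM-style file."""
    genomes: list[Genome] = []
    label = None
    chroms: list[list[int]] = []
    pending: list[int] = []
    with _open_read(path_or_file) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                if label is not None:
                    _finish_record(label, chroms, pending, genomes)
                label = line[1:].strip()
                chroms, pending = [], []
                continue
            if label is None:
                raise FormatError(f"line {lineno}: data before any '>' header")
            for tok in line.split():
                if tok == "@":
                    if not pending:
                        raise FormatError(f"line {lineno}: empty chromosome before '@'")
                    chroms.append(pending)
                    pending = []
                elif tok == "$":
                    raise FormatError(
                        f"line {lineno}: linear terminator '$' not supported "
                        "(circular-only model; use '@')"
                    )
                else:
                    try:
                        pending.append(int(tok))
                    except ValueError:
                        raise FormatError(f"line {lineno}: malformed integer {tok!r}") from None
    if label is not None:
        _finish_record(label, chroms, pending, genomes)
    ns = {g.n for g in genomes}
    if len(ns) > 1:
        raise FormatError(f"genomes in one file must share a gene universe, got n in {sorted(ns)}")
    return genomes


def write_grimm(genomes: Iterable[Genome], path_or_file) -> None:
    """Write genomes as canonical '@'-terminated signed circular permutations."""
    with _open_write(path_or_file) as fh:
        for i, g in enumerate(genomes):
            fh.write(f">{g.label or f'genome{i + 1}'}\n")
            for chrom in chromosomes(g):
                fh.write(" ".join(str(x) for x in chrom) + " @\n")


def read_adjacency_tsv(path_or_file, n: int | None = None) -> list[tuple[str, AdjacencySet]]:
    """Read labelled (possibly partial) adjacency sets from a TSV.

    The gene universe size is taken as the largest gene id seen unless
    ``n`` is given.  Compatibility is validated per label on read.
    """
    rows: list[tuple[int, str, str, str]] = []
    with _open_read(path_or_file) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise FormatError(f"row {lineno}: expected 3 columns, got {len(row)}")
            rows.append((lineno, row[0], row[1], row[2]))
    try:
        parsed = [(lineno, label, parse_end(e1), parse_end(e2)) for lineno, label, e1, e2 in rows]
    except GenomeError as exc:
        raise FormatError(str(exc)) from exc
    if n is None:
        n = max((max(e1.gene, e2.gene) for _, _, e1, e2 in parsed), default=0)
        if n == 0:
            return []
    out: dict[str, AdjacencySet] = {}
    for lineno, label, e1, e2 in parsed:
        aset = out.setdefault(label, AdjacencySet(n))
        try:
            aset.add(Adjacency(e1, e2))
        except GenomeError as exc:
            raise FormatError(f"row {lineno} ({label!r}): {exc}") from exc
    return list(out.items())


def write_adjacency_tsv(records, path_or_file) -> None:
    """Write labelled adjacency sets (or genomes) as a 3-column TSV.

    ``records`` is an iterable of ``(label, AdjacencySet)`` pairs or of
    :class:`Genome` objects (whose ``label`` attribute is used).
    """
    with _open_write(path_or_file) as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for i, rec in enumerate(records):
            if isinstance(rec, AdjacencySet):
                label = getattr(rec, "label", "") or f"set{i + 1}"
                aset = rec
            else:
                label, aset = rec
            for adj in aset:
                writer.writerow([label, str(adj.first), str(adj.second)])
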