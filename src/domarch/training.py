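"""Training pipeline: annotation parsing, architecture assembly, n-gram counting.

Covers the two offline stages that precede simulation: pre-processing (turn
per-genome domain annotation tables into domain architectures) and
pre-calculation (deduplicate, count monograms/bigrams/trigrams, and build the
smoothed first-order model).  Architectures are deduplicated before counting
so that gene duplication does not over-represent the bigrams of a family of
paralogs; the model is trained on the set of *unique* architectures.

File formats
------------
* Annotation input: tab-separated text, one domain assignment per line, in
  the style of SUPERFAMILY per-genome self-assignment files.  The default
  :class:`Dialect` expects columns ``genome_id, protein_id, region,
  superfamily_id`` with region ``start-end`` (multi-segment regions
  ``a-b,c-d`` are collapsed to their outer span for ordering).
* Plain DA format: one architecture per line, whitespace-separated tokens,
  ``#`` comments, UTF-8.
* Model artifact: JSON with alphabet, k, and sparse bigram counts (counts
  rather than probabilities, so k can be changed without re-parsing).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .model import (
    NULL,
    Alphabet,
    Architecture,
    CountTables,
    FirstOrderModel,
    as_architecture,
)

logger = logging.getLogger(__name__)


class AnnotationFormatError(ValueError):
    """Raised in strict mode for malformed annotation lines, and always for
    structurally unusable files (e.g. too few columns for the dialect)."""


@dataclass(frozen=True)
class Dialect:
    """Column mapping for tab-separated annotation files (0-based indices)."""

    genome_col: int = 0
    protein_col: int = 1
    region_col: int = 2
    superfamily_col: int = 3
    family_col: int | None = None

    @property
    def min_columns(self) -> int:
        cols = [self.genome_col, self.protein_col, self.region_col, self.superfamily_col]
        if self.family_col is not None:
            cols.append(self.family_col)
        return max(cols) + 1


@dataclass(frozen=True)
class AnnotationRecord:
    """One domain assignment: a superfamily hit on a region of one protein."""

    genome_id: str
    protein_id: str
    region_start: int  # 1-based amino-acid positions
    region_end: int
    superfamily_id: str
    family_id: str | None = None

    def __post_init__(self) -> None:
        if self.region_start > self.region_end:
            raise ValueError(f"region start {self.region_start} > end {self.region_end}")
        if not self.superfamily_id:
            raise ValueError("superfamily id must be non-empty")


@dataclass
class TrainingCorpus:
    """A deduplicated architecture set with its alphabet and n-gram counts."""

    unique_architectures: tuple[Architecture, ...]
    alphabet: Alphabet
    counts: CountTables
    provenance: tuple[str, ...] = ()


def _parse_region(text: str) -> tuple[int, int]:
    """Outer span of a region like ``10-85`` or multi-segment ``10-85,90-120``."""
    starts, ends = [], []
    for segment in text.split(","):
        lo, _, hi = segment.partition("-")
        starts.append(int(lo))
        ends.append(int(hi))
    return min(starts), max(ends)


def parse_annotations(
    path: str | Path,
    dialect: Dialect = Dialect(),
    strict: bool = False,
) -> list[AnnotationRecord]:
    """Parse a tab-separated annotation file into :class:`AnnotationRecord` s.

    Malformed lines are collected and logged with their line numbers; in
    ``strict`` mode the first malformed line aborts the parse instead.
    """
    path = Path(path)
    records: list[AnnotationRecord] = []
    bad: list[tuple[int, str]] = []
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < dialect.min_columns:
                msg = f"{path.name}:{lineno}: expected >= {dialect.min_columns} tab-separated columns, got {len(fields)}"
                if strict:
                    raise AnnotationFormatError(msg)
                bad.append((lineno, msg))
                continue
            try:
                start, end = _parse_region(fields[dialect.region_col])
                records.append(
                    AnnotationRecord(
                        genome_id=fields[dialect.genome_col],
                        protein_id=fields[dialect.protein_col],
                        region_start=start,
                        region_end=end,
                        superfamily_id=fields[dialect.superfamily_col],
                        family_id=fields[dialect.family_col] if dialect.family_col is not None else None,
                    )
                )
            except (ValueError, IndexError) as exc:
                msg = f"{path.name}:{lineno}: {exc}"
                if strict:
                    raise AnnotationFormatError(msg) from exc
                bad.append((lineno, msg))
    for _, msg in bad:
        logger.warning("skipped malformed annotation line: %s", msg)
    if not records and not bad:
        logger.warning("annotation file %s contained no assignments", path)
    return records


def assemble_architectures(
    records: Iterable[AnnotationRecord],
) -> dict[str, Architecture]:
    """Group assignments by protein and order domains N->C by region start.

    Ties on ``region_start`` break by ascending ``region_end`` then by
    superfamily id (deterministic).  Overlapping regions are both kept,
    ordered by start; overlaps are counted and logged.
    """
    by_protein: dict[str, list[AnnotationRecord]] = defaultdict(list)
    for rec in records:
        by_protein[(rec.genome_id, rec.protein_id)].append(rec)

    overlaps = 0
    out: dict[str, Architecture] = {}
    for (genome, protein), recs in by_protein.items():
        recs.sort(key=lambda r: (r.region_start, r.region_end, r.superfamily_id))
        for a, b in zip(recs, recs[1:]):
            if b.region_start <= a.region_end:
                overlaps += 1
        key = protein if protein not in out else f"{genome}:{protein}"
        out[key] = as_architecture(r.superfamily_id for r in recs)
    if overlaps:
        logger.warning("%d overlapping domain region pairs kept as-is", overlaps)
    return out


def unique_architectures(archs: Iterable[Sequence[str]]) -> tuple[Architecture, ...]:
    """Exact-sequence deduplication, returned in lexicographic order."""
    return tuple(sorted({as_architecture(a) for a in archs}))


def count_ngrams(corpus: Iterable[Sequence[str]], per_da_monograms: bool = False) -> CountTables:
    """Monogram/bigram/trigram counts over a set of unique architectures.

    Bigrams include the boundary pairs ``(NULL, d1)`` and ``(dn, NULL)``;
    trigrams include the boundary-padded triples ``(NULL, d1, d2)`` and
    ``(dn-1, dn, NULL)``, with a single-domain DA contributing
    ``(NULL, d1, NULL)``.  Monograms count occurrences with multiplicity by
    default; ``per_da_monograms`` counts per-DA presence instead.
    """
    tables = CountTables()
    n = 0
    for arch in corpus:
        arch = as_architecture(arch)
        n += 1
        if per_da_monograms:
            tables.monogram.update(set(arch))
        else:
            tables.monogram.update(arch)
        padded = (NULL, *arch, NULL)
        for a, b in zip(padded, padded[1:]):
            tables.bigram[(a, b)] += 1
        for a, b, c in zip(padded, padded[1:], padded[2:]):
            tables.trigram[(a, b, c)] += 1
    if n == 0:
        raise ValueError("cannot count n-grams of an empty corpus")
    tables.n_unique_das = n
    return tables


def build_model(
    counts: CountTables,
    alphabet: Alphabet,
    k: float | str = "default",
) -> FirstOrderModel:
    """Smoothed first-order model; ``k="default"`` resolves to ``1 / N_D``."""
    model = FirstOrderModel.from_counts(counts, alphabet, k)
    if not model.is_irreducible:
        logger.warning(
            "model has zero conditionals (k=%g): the simulator's chain is not irreducible", model.k
        )
    return model


def build_corpus(
    archs: Iterable[Sequence[str]],
    provenance: Iterable[str] = (),
) -> TrainingCorpus:
    """Deduplicate, derive the alphabet, and count n-grams in one step."""
    uniq = unique_architectures(archs)
    if not uniq:
        raise ValueError("no architectures to train on")
    alphabet = Alphabet(tuple(t for arch in uniq for t in arch))
    return TrainingCorpus(
        unique_architectures=uniq,
        alphabet=alphabet,
        counts=count_ngrams(uniq),
        provenance=tuple(provenance),
    )


# -- plain DA format ---------------------------------------------------------


def read_da_file(path: str | Path) -> list[Architecture]:
    """Read the one-architecture-per-line token format ('#' comments)."""
    out = []
    with Path(path).open(encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(as_architecture(line.split()))
    return out


def write_da_file(path: str | Path, archs: Iterable[Sequence[str]], header: str | None = None) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        if header:
            for line in header.splitlines():
                handle.write(f"# {line}\n")
        for arch in archs:
            handle.write(" ".join(arch) + "\n")


def save_model(model: FirstOrderModel, path: str | Path) -> None:
    Path(path).write_text(model.to_json(), encoding="utf-8")


def load_model(path: str | Path) -> FirstOrderModel:
    return FirstOrderModel.from_json(Path(path).read_text(encoding="utf-8"))
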