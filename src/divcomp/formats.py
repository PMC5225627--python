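"""Readers and writers for the standard file formats the pipeline touches.

Three formats are supported with strict validation:

* **sync** (PoPoolation2): one line per genomic site, tab-separated
  ``chrom  pos  ref  A:T:C:G:N:del  A:T:C:G:N:del ...`` with one
  colon-separated count block per population pool.
* **GenePop**: diploid microsatellite genotype tables with 2- or 3-digit
  allele coding (auto-detected per file), ``POP`` separators, and
  ``000``/``000000`` for missing data.  Marker-class metadata
  (cross-species vs. species-specific) lives in a sidecar TSV because the
  GenePop dialect has no slot for it.
* **GFF3** exon annotations, grouped by gene with overlapping exons merged.

All coordinates are 1-based inclusive end-to-end; no half-open conversion
is exposed.  The ``N`` and deletion columns of sync records are parsed and
round-tripped but excluded from every allele-frequency computation
downstream (they are not nucleotide alleles).
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

import numpy as np

SYNC_BASES = ("A", "T", "C", "G", "N", "del")
#: indices of the four nucleotide columns inside a sync count block
NUCLEOTIDES = ("A", "T", "C", "G")

CROSS_SPECIES = "cross-species"
SPECIES_SPECIFIC = "species-specific"
MARKER_CLASSES = (CROSS_SPECIES, SPECIES_SPECIFIC)


class FormatError(ValueError):
    """Malformed input file; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


# ---------------------------------------------------------------------------
# sync
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoolSiteCounts:
    """Per-site, per-population read counts of A/T/C/G/N/deletion."""

    chrom: str
    pos: int
    ref: str
    counts: np.ndarray  # shape (n_populations, 6), non-negative ints

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        if counts.ndim != 2 or counts.shape[1] != 6:
            raise FormatError(
                f"counts must have shape (n_populations, 6), got {counts.shape}"
            )
        if (counts < 0).any():
            raise FormatError("negative read count")

    @property
    def n_populations(self) -> int:
        return self.counts.shape[0]

    @property
    def nucleotide_counts(self) -> np.ndarray:
        """A/T/C/G counts only, shape (n_populations, 4)."""
        return self.counts[:, :4]

    def to_line(self) -> str:
        blocks = "\t".join(":".join(str(c) for c in row) for row in self.counts)
        return f"{self.chrom}\t{self.pos}\t{self.ref}\t{blocks}"


def _parse_count_block(block: str, line_no: int) -> list[int]:
    parts = block.split(":")
    if len(parts) != 6:
        raise FormatError(
            f"count block {block!r} has {len(parts)} fields, expected 6", line_no
        )
    try:
        values = [int(p) for p in parts]
    except ValueError:
        raise FormatError(f"non-integer count in block {block!r}", line_no) from None
    if any(v < 0 for v in values):
        raise FormatError(f"negative count in block {block!r}", line_no)
    return values


def read_sync(
    source: str | os.PathLike | TextIO, n_populations: int | None = None
) -> Iterator[PoolSiteCounts]:
    """Stream records from a sync file, validating each line.

    ``n_populations``, when given, is checked against every record; the
    block arity must in any case be constant across the file.  Reading is
    line-by-line (constant memory per record).
    """
    own = isinstance(source, (str, os.PathLike))
    handle = open(source) if own else source
    try:
        expected = n_populations
        for line_no, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"expected at least 4 tab-separated fields, got {len(fields)}",
                    line_no,
                )
            chrom, pos_str, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_str)
            except ValueError:
                raise FormatError(f"non-integer position {pos_str!r}", line_no) from None
            if pos < 1:
                raise FormatError(f"position must be >= 1, got {pos}", line_no)
            blocks = [_parse_count_block(b, line_no) for b in fields[3:]]
            if expected is None:
                expected = len(blocks)
            elif len(blocks) != expected:
                raise FormatError(
                    f"{len(blocks)} count blocks, expected {expected}", line_no
                )
            yield PoolSiteCounts(
                chrom=chrom, pos=pos, ref=ref, counts=np.array(blocks, dtype=np.int64)
            )
    finally:
        if own:
            handle.close()


def write_sync(
    records: Iterable[PoolSiteCounts], target: str | os.PathLike | TextIO
) -> int:
    """Write sync records; returns the number of records written."""
    own = isinstance(target, (str, os.PathLike))
    handle = open(target, "w") if own else target
    n = 0
    try:
        for rec in records:
            handle.write(rec.to_line() + "\n")
            n += 1
    finally:
        if own:
            handle.close()
    return n


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

@dataclass
class SSRGenotypeTable:
    """Diploid microsatellite genotypes for several populations.

    ``genotypes`` is an ``(n_individuals, n_loci, 2)`` integer array of
    allele labels (fragment lengths); ``0`` encodes a missing allele and a
    genotype is treated as missing when either allele is 0.
    """

    populations: list[str]
    pop_index: np.ndarray  # (n_individuals,) index into populations
    individuals: list[str]
    loci: list[str]
    genotypes: np.ndarray  # (n_individuals, n_loci, 2), 0 = missing
    locus_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.pop_index = np.asarray(self.pop_index, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        n, l = len(self.individuals), len(self.loci)
        if self.genotypes.shape != (n, l, 2):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} != ({n}, {l}, 2)"
            )
        if self.pop_index.shape != (n,):
            raise ValueError("pop_index length mismatch")
        if (self.genotypes < 0).any():
            raise ValueError("negative allele label")
        for locus, klass in self.locus_class.items():
            if klass not in MARKER_CLASSES:
                raise ValueError(f"unknown marker class {klass!r} for {locus}")

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def population_sizes(self) -> dict[str, int]:
        return {
            p: int((self.pop_index == i).sum())
            for i, p in enumerate(self.populations)
        }

    def individuals_of(self, population: str) -> np.ndarray:
        i = self.populations.index(population)
        return np.flatnonzero(self.pop_index == i)

    def locus_indices(self, marker_set: str = "all") -> list[int]:
        """Indices of loci in a marker set: ``all`` or one of the classes."""
        if marker_set == "all":
            return list(range(len(self.loci)))
        if marker_set not in MARKER_CLASSES:
            raise ValueError(f"unknown marker set {marker_set!r}")
        if not self.locus_class:
            raise ValueError("table has no marker-class metadata")
        return [
            i for i, l in enumerate(self.loci) if self.locus_class.get(l) == marker_set
        ]

    def missing_fraction(self) -> float:
        miss = (self.genotypes == 0).any(axis=2)
        return float(miss.mean())


def _genepop_digits(fields: list[str], line_no: int) -> int:
    widths = {len(f) for f in fields}
    if widths <= {4}:
        return 2
    if widths <= {6}:
        return 3
    raise FormatError(
        f"inconsistent genotype field widths {sorted(widths)} (expect 4 or 6 chars)",
        line_no,
    )


def read_genepop(
    source: str | os.PathLike | TextIO,
    class_sidecar: str | os.PathLike | None = None,
) -> SSRGenotypeTable:
    """Parse a GenePop file (2- or 3-digit coding auto-detected).

    Population labels are taken from the shared ``name_`` prefix of the
    individual identifiers in each POP block when one exists, else
    ``pop1 .. popK``.
    """
    own = isinstance(source, (str, os.PathLike))
    handle = open(source) if own else source
    try:
        lines = handle.read().splitlines()
    finally:
        if own:
            handle.close()
    if not lines:
        raise FormatError("empty GenePop file")

    loci: list[str] = []
    i = 1  # skip title line
    while i < len(lines) and lines[i].strip().lower() != "pop":
        part = lines[i].strip()
        if part:
            loci.extend(x.strip() for x in part.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise FormatError("no POP separator found")
    if not loci:
        raise FormatError("no locus names before first POP")

    blocks: list[list[tuple[str, list[str]]]] = []
    current: list[tuple[str, list[str]]] = []
    for line_no in range(i, len(lines)):
        line = lines[line_no]
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            blocks.append(current)
            current = []
            continue
        if "," not in line:
            raise FormatError("individual line lacks ',' separator", line_no + 1)
        ind_id, geno_part = line.split(",", 1)
        fields = geno_part.split()
        if len(fields) != len(loci):
            raise FormatError(
                f"individual {ind_id.strip()!r} has {len(fields)} genotypes, "
                f"expected {len(loci)}",
                line_no + 1,
            )
        current.append((ind_id.strip(), fields))
    blocks.append(current)
    # first append at the initial 'pop' keyword produced an empty leading block
    blocks = [b for b in blocks if b]
    if not blocks:
        raise FormatError("no individuals found")

    digits: int | None = None
    individuals: list[str] = []
    pop_index: list[int] = []
    pop_labels: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    for b, block in enumerate(blocks):
        ids = [ind for ind, _ in block]
        prefixes = {x.rsplit("_", 1)[0] for x in ids if "_" in x}
        label = prefixes.pop() if len(prefixes) == 1 else f"pop{b + 1}"
        if label in pop_labels:
            label = f"{label}.{b + 1}"
        pop_labels.append(label)
        for ind_id, fields in block:
            w = _genepop_digits(fields, 0)
            if digits is None:
                digits = w
            elif digits != w:
                raise FormatError(
                    f"allele code width changes within file for {ind_id!r}"
                )
            pairs = []
            for f in fields:
                a1, a2 = int(f[:digits]), int(f[digits:])
                if a1 == 0 or a2 == 0:
                    a1 = a2 = 0
                pairs.append((a1, a2))
            individuals.append(ind_id)
            pop_index.append(b)
            rows.append(pairs)

    genotypes = np.array(rows, dtype=np.int64)
    locus_class = read_marker_classes(class_sidecar) if class_sidecar else {}
    if locus_class:
        missing = [l for l in loci if l not in locus_class]
        if missing:
            raise FormatError(f"marker class missing for loci: {missing}")
    return SSRGenotypeTable(
        populations=pop_labels,
        pop_index=np.array(pop_index),
        individuals=individuals,
        loci=loci,
        genotypes=genotypes,
        locus_class=locus_class,
    )


def write_genepop(
    table: SSRGenotypeTable,
    target: str | os.PathLike | TextIO,
    title: str = "divcomp genotypes",
    digits: int = 3,
) -> None:
    own = isinstance(target, (str, os.PathLike))
    handle = open(target, "w") if own else target
    try:
        handle.write(title + "\n")
        for locus in table.loci:
            handle.write(locus + "\n")
        for p in range(table.n_populations):
            handle.write("pop\n")
            for i in np.flatnonzero(table.pop_index == p):
                codes = " ".join(
                    f"{a1:0{digits}d}{a2:0{digits}d}"
                    for a1, a2 in table.genotypes[i]
                )
                handle.write(f"{table.individuals[i]} , {codes}\n")
    finally:
        if own:
            handle.close()


def read_marker_classes(path: str | os.PathLike) -> dict[str, str]:
    """Sidecar TSV mapping locus name -> marker class."""
    classes: dict[str, str] = {}
    with open(path) as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError("expected 'locus<TAB>class'", line_no)
            locus, klass = (p.strip() for p in parts)
            if line_no == 1 and locus.lower() == "locus":
                continue  # header
            if klass not in MARKER_CLASSES:
                raise FormatError(f"unknown marker class {klass!r}", line_no)
            classes[locus] = klass
    return classes


def write_marker_classes(classes: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("locus\tclass\n")
        for locus, klass in classes.items():
            handle.write(f"{locus}\t{klass}\n")


# ---------------------------------------------------------------------------
# GFF3 exon annotation
# ---------------------------------------------------------------------------

@dataclass
class ExonAnnotation:
    """Merged exon intervals of one gene (1-based inclusive)."""

    gene_id: str
    chrom: str
    exons: list[tuple[int, int]]
    strand: str = "."

    def __post_init__(self):
        for start, end in self.exons:
            if start > end:
                raise FormatError(
                    f"exon start {start} > end {end} for gene {self.gene_id}"
                )
            if start < 1:
                raise FormatError(f"exon start {start} < 1 for gene {self.gene_id}")
        self.exons = merge_intervals(self.exons)

    @property
    def length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent 1-based inclusive intervals."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def read_gff3_exons(
    path: str | os.PathLike,
) -> tuple[dict[str, ExonAnnotation], dict[str, int]]:
    """Collect exons per gene from a GFF3 file.

    Exons are resolved to a gene through their Parent/ID attribute chain
    (exon -> mRNA -> gene, or exon -> gene directly).  Exons without a
    resolvable gene parent are skipped with a warning and counted in the
    returned report.  An empty file yields an empty collection.
    """
    import gffutils

    with open(path) as handle:
        content = handle.read()
    report = {"genes": 0, "exons": 0, "skipped_exons": 0}
    if not any(line.strip() and not line.startswith("#") for line in content.splitlines()):
        return {}, report

    db = gffutils.create_db(
        content, dbfn=":memory:", from_string=True,
        merge_strategy="create_unique", keep_order=True,
    )
    per_gene: dict[str, ExonAnnotation] = {}
    raw: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for exon in db.features_of_type("exon"):
        if exon.start > exon.end:
            raise FormatError(
                f"exon start {exon.start} > end {exon.end} at {exon.seqid}"
            )
        genes = list(db.parents(exon, featuretype="gene"))
        if not genes:
            # exon may point at a gene directly through Parent
            parent_ids = exon.attributes.get("Parent", [])
            genes = []
            for pid in parent_ids:
                try:
                    feat = db[pid]
                except gffutils.FeatureNotFoundError:
                    continue
                if feat.featuretype == "gene":
                    genes = [feat]
                    break
        if not genes:
            report["skipped_exons"] += 1
            warnings.warn(
                f"exon at {exon.seqid}:{exon.start}-{exon.end} has no resolvable "
                "gene parent; skipped",
                stacklevel=2,
            )
            continue
        gene = genes[0]
        raw.setdefault(gene.id, []).append((exon.start, exon.end))
        meta[gene.id] = (exon.seqid, gene.strand or ".")
        report["exons"] += 1
    for gene_id, exons in raw.items():
        chrom, strand = meta[gene_id]
        per_gene[gene_id] = ExonAnnotation(
            gene_id=gene_id, chrom=chrom, exons=exons, strand=strand
        )
    report["genes"] = len(per_gene)
    return per_gene, report


def write_gff3(
    annotations: Mapping[str, ExonAnnotation], path: str | os.PathLike
) -> None:
    """Emit a minimal GFF3 with gene + exon features."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for ann in annotations.values():
            start = min(s for s, _ in ann.exons)
            end = max(e for _, e in ann.exons)
            handle.write(
                f"{ann.chrom}\tdivcomp\tgene\t{start}\t{end}\t.\t{ann.strand}\t.\t"
                f"ID={ann.gene_id}\n"
            )
            for k, (s, e) in enumerate(ann.exons, start=1):
                handle.write(
                    f"{ann.chrom}\tdivcomp\texon\t{s}\t{e}\t.\t{ann.strand}\t.\t"
                    f"ID={ann.gene_id}.exon{k};Parent={ann.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_table(df, path: str | os.PathLike, metadata: Mapping[str, object] | None = None) -> None:
    """Write a result table as TSV with a '#' metadata preamble."""
    buf = io.StringIO()
    from . import __version__

    buf.write(f"# divcomp {__version__}\n")
    for key, value in (metadata or {}).items():
        buf.write(f"# {key}: {value}\n")
    df.to_csv(buf, sep="\t", index=False)
    with open(path, "w") as handle:
        handle.write(buf.getvalue())


def read_table(path: str | os.PathLike):
    """Read a TSV written by :func:`write_table`, skipping the preamble."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")
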