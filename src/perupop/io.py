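"""Readers, writers and coordinate-aware masking for the pipeline's external formats.

All genomic coordinates are 1-based inclusive in the rCRS frame (the
standard 16,569-site human mitochondrial coordinate system).  Tables are
tab-delimited UTF-8 with a header row and LF line endings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceAlignment",
    "PopulationMap",
    "StrHaplotypeTable",
    "GenotypeTable",
    "QMatrix",
    "AlignmentError",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "apply_site_mask",
    "parse_accession_range",
    "read_population_map",
    "write_population_map",
    "read_str_table",
    "write_str_table",
    "read_genotype_table",
    "write_genotype_table",
    "read_qmatrix",
    "write_qmatrix",
]

MISSING_CHARS = ("N", "-")


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged records, duplicate ids)."""


@dataclass(frozen=True)
class SequenceAlignment:
    """Aligned haploid sequences with a site mask in rCRS coordinates.

    ``coordinate_origin`` is the 1-based rCRS position of the first
    alignment column; ``active_sites`` holds the rCRS positions currently
    retained for analysis (initially every covered position).
    """

    sample_ids: tuple[str, ...]
    sequences: tuple[str, ...]
    coordinate_origin: int = 1
    active_sites: frozenset[int] = field(default=frozenset())

    def __post_init__(self):
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError("sample_ids and sequences length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise AlignmentError(f"duplicate sample ids: {dupes}")
        if self.sequences:
            L = len(self.sequences[0])
            for idx, seq in enumerate(self.sequences):
                if len(seq) != L:
                    raise AlignmentError(
                        f"record {idx + 1} ({self.sample_ids[idx]!r}) has length "
                        f"{len(seq)}, expected {L}"
                    )
        if not self.active_sites:
            object.__setattr__(self, "active_sites", frozenset(self.covered_sites()))
        else:
            extra = self.active_sites - set(self.covered_sites())
            if extra:
                raise AlignmentError(f"active sites outside covered range: {sorted(extra)[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def covered_sites(self) -> range:
        return range(self.coordinate_origin, self.coordinate_origin + self.length)

    def active_columns(self) -> np.ndarray:
        """0-based column indices of active sites, ascending."""
        return np.array(sorted(p - self.coordinate_origin for p in self.active_sites), dtype=int)

    def matrix(self) -> np.ndarray:
        """(n_samples, length) array of single-byte characters."""
        if not self.sequences:
            return np.empty((0, 0), dtype="S1")
        return np.frombuffer("".join(self.sequences).encode("ascii"), dtype="S1").reshape(
            self.n_samples, self.length
        )

    def subset(self, sample_ids) -> "SequenceAlignment":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not in alignment: {missing}")
        return replace(
            self,
            sample_ids=tuple(sample_ids),
            sequences=tuple(self.sequences[index[s]] for s in sample_ids),
        )


@dataclass(frozen=True)
class PopulationMap:
    """sample_id -> (subgroup, region, macro_region) hierarchy.

    A subgroup belongs to exactly one region and a region to exactly one
    macro-region; this is validated at construction.
    """

    assignments: dict[str, tuple[str, str, str]]

    LEVELS = ("subgroup", "region", "macro_region")

    def __post_init__(self):
        sub_to_region: dict[str, str] = {}
        region_to_macro: dict[str, str] = {}
        for sid, (sub, region, macro) in self.assignments.items():
            if not sid or not sub or not region or not macro:
                raise ValueError(f"empty label in population map entry {sid!r}")
            if sub_to_region.setdefault(sub, region) != region:
                raise ValueError(f"subgroup {sub!r} maps to multiple regions")
            if region_to_macro.setdefault(region, macro) != macro:
                raise ValueError(f"region {region!r} maps to multiple macro-regions")

    def label(self, sample_id: str, level: str = "subgroup") -> str:
        return self.assignments[sample_id][self.LEVELS.index(level)]

    def populations(self, level: str = "subgroup") -> dict[str, list[str]]:
        """Population label -> member sample ids, insertion-ordered."""
        i = self.LEVELS.index(level)
        out: dict[str, list[str]] = {}
        for sid, labels in self.assignments.items():
            out.setdefault(labels[i], []).append(sid)
        return out

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.assignments


@dataclass(frozen=True)
class StrHaplotypeTable:
    """Per-sample repeat counts across named Y-STR loci (-1 encodes missing)."""

    sample_ids: tuple[str, ...]
    locus_names: tuple[str, ...]
    repeat_counts: np.ndarray  # (n_samples, n_loci) int, -1 = missing

    def __post_init__(self):
        rc = np.asarray(self.repeat_counts, dtype=int)
        if rc.shape != (len(self.sample_ids), len(self.locus_names)):
            raise ValueError("repeat_counts shape mismatch")
        if ((rc <= 0) & (rc != -1)).any():
            raise ValueError("repeat counts must be positive integers or -1 (missing)")
        object.__setattr__(self, "repeat_counts", rc)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids) -> "StrHaplotypeTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return StrHaplotypeTable(tuple(sample_ids), self.locus_names, self.repeat_counts[rows])


@dataclass(frozen=True)
class GenotypeTable:
    """Diploid genotypes: two alleles per sample x locus, or both missing.

    Alleles are stored as strings (repeat counts or SNP bases); ``None``
    marks a missing allele, and missingness is all-or-nothing per call.
    """

    sample_ids: tuple[str, ...]
    locus_names: tuple[str, ...]
    alleles: np.ndarray  # (n_samples, n_loci, 2) object array of str | None

    def __post_init__(self):
        a = np.asarray(self.alleles, dtype=object)
        if a.shape != (len(self.sample_ids), len(self.locus_names), 2):
            raise ValueError("alleles shape mismatch")
        half = (a[:, :, 0] == None) ^ (a[:, :, 1] == None)  # noqa: E711
        if half.any():
            i, j = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing genotype for sample {self.sample_ids[i]!r} "
                f"locus {self.locus_names[j]!r}: exactly 0 or 2 alleles required"
            )
        object.__setattr__(self, "alleles", a)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def genotype(self, i: int, j: int):
        a = self.alleles[i, j]
        return None if a[0] is None else (a[0], a[1])

    def subset(self, sample_ids) -> "GenotypeTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return GenotypeTable(tuple(sample_ids), self.locus_names, self.alleles[rows])


@dataclass(frozen=True)
class QMatrix:
    """Individuals x K ancestry proportions; each row lies on the simplex."""

    sample_ids: tuple[str, ...]
    proportions: np.ndarray  # (n, K)

    def __post_init__(self):
        q = np.asarray(self.proportions, dtype=float)
        if q.ndim != 2 or q.shape[0] != len(self.sample_ids):
            raise ValueError("proportions shape mismatch")
        if q.shape[1] < 2:
            raise ValueError("K must be >= 2")
        if (q < 0).any():
            raise ValueError("negative ancestry proportion")
        if not np.allclose(q.sum(axis=1), 1.0, atol=1e-6):
            bad = np.argmax(np.abs(q.sum(axis=1) - 1.0))
            raise ValueError(f"row for {self.sample_ids[bad]!r} does not sum to 1")
        object.__setattr__(self, "proportions", q)

    @property
    def K(self) -> int:
        return self.proportions.shape[1]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta_alignment(path, coordinate_origin: int = 1) -> SequenceAlignment:
    """Read an aligned FASTA; record ids are the header up to first whitespace."""
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if seqs:
        L = len(seqs[0])
        for k, s in enumerate(seqs):
            if len(s) != L:
                raise AlignmentError(
                    f"record {k + 1} ({ids[k]!r}) has length {len(s)}, expected {L}"
                )
    return SequenceAlignment(tuple(ids), tuple(seqs), coordinate_origin)


def write_fasta_alignment(aln: SequenceAlignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(aln.sample_ids, aln.sequences)
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# Site masking

def apply_site_mask(
    aln: SequenceAlignment,
    exclude: list[tuple[int, int]] | None = None,
    restrict: tuple[int, int] | None = None,
) -> SequenceAlignment:
    """Restrict then exclude 1-based inclusive rCRS ranges from the active set.

    Sequence content is untouched; downstream statistics consult
    ``active_sites`` only.  Applying the same mask twice is a no-op.
    """
    active = set(aln.active_sites)
    if restrict is not None:
        lo, hi = restrict
        if lo > hi:
            raise ValueError(f"inverted range {restrict}")
        active &= set(range(lo, hi + 1))
    for lo, hi in exclude or []:
        if lo > hi:
            raise ValueError(f"inverted range ({lo}, {hi})")
        active -= set(range(lo, hi + 1))
    return replace(aln, active_sites=frozenset(active))


# ---------------------------------------------------------------------------
# Accession ranges

_ACC_RE = re.compile(r"^([A-Za-z]+)(\d+)\s*[–-]\s*([A-Za-z]+)(\d+)$")


def parse_accession_range(text: str) -> list[str]:
    """Expand e.g. ``"MN857248–MN857411"`` to the inclusive accession list."""
    m = _ACC_RE.match(text.strip())
    if not m:
        raise ValueError(f"unparseable accession range: {text!r}")
    p1, d1, p2, d2 = m.groups()
    if p1 != p2:
        raise ValueError(f"mismatched accession prefixes {p1!r} vs {p2!r}")
    if len(d1) != len(d2):
        raise ValueError("accession digit widths differ")
    first, last = int(d1), int(d2)
    if last < first:
        raise ValueError(f"descending accession range {text!r}")
    width = len(d1)
    return [f"{p1}{i:0{width}d}" for i in range(first, last + 1)]


# ---------------------------------------------------------------------------
# TSV tables

def _read_tsv(path) -> tuple[list[str], list[list[str]]]:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    return header, [ln.split("\t") for ln in lines[1:]]


def _write_tsv(path, header: list[str], rows, comments: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_population_map(path) -> PopulationMap:
    """TSV with columns sample_id, subgroup, region, macro_region."""
    _, rows = _read_tsv(path)
    return PopulationMap({r[0]: (r[1], r[2], r[3]) for r in rows})


def write_population_map(popmap: PopulationMap, path) -> None:
    _write_tsv(
        path,
        ["sample_id", "subgroup", "region", "macro_region"],
        [[sid, *labels] for sid, labels in popmap.assignments.items()],
    )


def read_str_table(path) -> StrHaplotypeTable:
    """TSV: sample_id column then one integer column per locus; blank = missing."""
    header, rows = _read_tsv(path)
    counts = np.array(
        [[int(c) if c.strip() else -1 for c in r[1:]] for r in rows], dtype=int
    ).reshape(len(rows), len(header) - 1)
    return StrHaplotypeTable(tuple(r[0] for r in rows), tuple(header[1:]), counts)


def write_str_table(table: StrHaplotypeTable, path) -> None:
    rows = [
        [sid, *("" if c == -1 else str(c) for c in table.repeat_counts[i])]
        for i, sid in enumerate(table.sample_ids)
    ]
    _write_tsv(path, ["sample_id", *table.locus_names], rows)


def read_genotype_table(path) -> GenotypeTable:
    """TSV: sample_id then per-locus 'a/b' genotype calls; blank = missing."""
    header, rows = _read_tsv(path)
    n, L = len(rows), len(header) - 1
    alleles = np.full((n, L, 2), None, dtype=object)
    for i, r in enumerate(rows):
        for j, cell in enumerate(r[1:]):
            if cell.strip():
                a, b = cell.split("/")
                alleles[i, j] = (a, b)
    return GenotypeTable(tuple(r[0] for r in rows), tuple(header[1:]), alleles)


def write_genotype_table(table: GenotypeTable, path) -> None:
    rows = []
    for i, sid in enumerate(table.sample_ids):
        cells = []
        for j in range(len(table.locus_names)):
            g = table.genotype(i, j)
            cells.append("" if g is None else f"{g[0]}/{g[1]}")
        rows.append([sid, *cells])
    _write_tsv(path, ["sample_id", *table.locus_names], rows)


def read_qmatrix(path, column_offset: int = 0) -> QMatrix:
    """Whitespace-delimited Q matrix: sample id then K proportions per row.

    ``column_offset`` skips anchor columns that some clustering programs
    insert between the id and the proportions.  Rows whose sum is within
    1e-3 of 1 are renormalized to sum exactly 1; anything further off is an
    error, as is any negative proportion.
    """
    ids, rows = [], []
    first_data_line = True
    with open(path, encoding="utf-8") as fh:
        for ln in fh:
            parts = ln.split()
            if not parts or parts[0].startswith("#"):
                continue
            if first_data_line:
                first_data_line = False
                try:
                    [float(x) for x in parts[1 + column_offset:]]
                except ValueError:  # header row
                    continue
            ids.append(parts[0])
            vals = np.array([float(x) for x in parts[1 + column_offset:]])
            if (vals < 0).any():
                raise ValueError(f"negative proportion for {parts[0]!r}")
            s = vals.sum()
            if not (0.999 <= s <= 1.001):
                raise ValueError(f"row for {parts[0]!r} sums to {s:.4f}, not 1")
            rows.append(vals / s)
    return QMatrix(tuple(ids), np.array(rows))


def write_qmatrix(q: QMatrix, path) -> None:
    rows = [
        [sid, *(f"{v:.6f}" for v in q.proportions[i])] for i, sid in enumerate(q.sample_ids)
    ]
    _write_tsv(path, ["sample_id", *(f"Q{k + 1}" for k in range(q.K))], rows)
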