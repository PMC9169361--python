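"""MAF-format mutation I/O, reference-context attachment, and pyrimidine normalization.

Somatic single-nucleotide variants are represented on the pyrimidine strand:
a substitution whose reference base is a purine (A or G) is reverse-complemented
together with its flanking bases, so that every SNV maps to one of the 96
canonical trinucleotide substitution channels (6 substitution types with a C or
T reference, times 16 flanking-base combinations).

Channel ordering is substitution-major (C>A, C>G, C>T, T>A, T>C, T>G), with the
16 upstream x downstream contexts in A/C/G/T lexicographic order inside each
substitution block.  This is the de-facto ordering of published SBS catalogs,
so user-supplied 96-row signature tables align row-wise without re-sorting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: The six pyrimidine-reference substitution types, in catalog order.
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 channel labels, e.g. ``"T[C>T]A"``, in the fixed catalog ordering.
CHANNEL_LABELS: tuple[str, ...] = tuple(
    f"{up}[{sub}]{down}"
    for sub in SUBSTITUTION_TYPES
    for up in BASES
    for down in BASES
)

_SUB_OFFSET = {sub: 16 * i for i, sub in enumerate(SUBSTITUTION_TYPES)}
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class MafFormatError(ValueError):
    """A MAF file is missing a required column or is otherwise malformed."""


class ContigNotFoundError(KeyError):
    """A record's chromosome is absent from the reference sequence."""


class AmbiguousContextError(ValueError):
    """A record cannot be normalized (N or non-ACGT base at the triplet positions)."""


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def channel_index(upstream: str, ref: str, alt: str, downstream: str) -> int:
    """Index of a canonical (pyrimidine-reference) substitution in [0, 96).

    Raises
    ------
    AmbiguousContextError
        If any base is outside {A, C, G, T} or ref is not C/T.
    """
    sub = f"{ref}>{alt}"
    if sub not in _SUB_OFFSET:
        raise AmbiguousContextError(f"not a canonical substitution: {sub!r}")
    try:
        return _SUB_OFFSET[sub] + 4 * _BASE_INDEX[upstream] + _BASE_INDEX[downstream]
    except KeyError:
        raise AmbiguousContextError(
            f"ambiguous flanking base in {upstream!r}/{downstream!r}"
        ) from None


@dataclass(frozen=True)
class CanonicalSubstitution:
    """A pyrimidine-normalized SNV with its immediate trinucleotide context."""

    ref_pyrimidine: str
    alt: str
    upstream: str
    downstream: str
    channel_index: int

    @property
    def label(self) -> str:
        return CHANNEL_LABELS[self.channel_index]


@dataclass
class MutationRecord:
    """One somatic mutation call (MAF conventions: 1-based inclusive coordinates)."""

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_classification: str = ""
    gene_symbol: str | None = None
    context: str | None = None
    ref_mismatch: bool = False

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in BASES
            and self.alt_allele in BASES
            and self.ref_allele != self.alt_allele
        )


class MutationTable:
    """An ordered collection of :class:`MutationRecord` grouped by sample."""

    def __init__(self, records: list[MutationRecord] | None = None):
        self.records: list[MutationRecord] = list(records or [])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MutationRecord]:
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, MutationTable) and self.records == other.records

    @property
    def sample_ids(self) -> list[str]:
        """Distinct sample identifiers in first-appearance order."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.sample_id, None)
        return list(seen)

    @property
    def n_reference_mismatch(self) -> int:
        """Records whose claimed reference allele disagreed with the reference."""
        return sum(rec.ref_mismatch for rec in self.records)

    def by_sample(self) -> dict[str, list[MutationRecord]]:
        out: dict[str, list[MutationRecord]] = {s: [] for s in self.sample_ids}
        for rec in self.records:
            out[rec.sample_id].append(rec)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        cols = {name: [] for name in DEFAULT_MAF_COLUMNS.values()}
        has_gene = any(r.gene_symbol is not None for r in self.records)
        has_ctx = any(r.context is not None for r in self.records)
        rows = []
        for r in self.records:
            row = {
                "Tumor_Sample_Barcode": r.sample_id,
                "Chromosome": r.chrom,
                "Start_Position": r.pos,
                "Reference_Allele": r.ref_allele,
                "Tumor_Seq_Allele2": r.alt_allele,
                "Variant_Classification": r.variant_classification,
            }
            if has_gene:
                row["Hugo_Symbol"] = r.gene_symbol if r.gene_symbol is not None else ""
            if has_ctx:
                row["Context"] = r.context if r.context is not None else ""
            rows.append(row)
        if not rows:
            return pd.DataFrame(columns=list(cols))
        return pd.DataFrame(rows)


#: Default MAF header names for each :class:`MutationRecord` field.
DEFAULT_MAF_COLUMNS: dict[str, str] = {
    "sample_id": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref_allele": "Reference_Allele",
    "alt_allele": "Tumor_Seq_Allele2",
    "variant_classification": "Variant_Classification",
}

_OPTIONAL_MAF_COLUMNS: dict[str, str] = {
    "gene_symbol": "Hugo_Symbol",
    "context": "Context",
}


def read_maf(path, columns: Mapping[str, str] | None = None) -> MutationTable:
    """Read tab-separated MAF-format mutation calls.

    Parameters
    ----------
    path
        Tab-separated text file with a header row; lines starting with ``#``
        are skipped.
    columns
        Optional field-name -> column-name overrides (keys as in
        :data:`DEFAULT_MAF_COLUMNS`).

    Rows whose position does not parse as a positive integer are rejected with
    a warning naming the data row.  An empty file yields an empty table.
    """
    colmap = dict(DEFAULT_MAF_COLUMNS)
    optmap = dict(_OPTIONAL_MAF_COLUMNS)
    for key, name in (columns or {}).items():
        if key in colmap:
            colmap[key] = name
        elif key in optmap:
            optmap[key] = name
        else:
            raise MafFormatError(f"unknown MAF field {key!r}")
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype=str, keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        return MutationTable([])
    for field_name, col in colmap.items():
        if col not in df.columns:
            raise MafFormatError(f"missing required MAF column {col!r}")
    records = []
    bad_rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        try:
            pos = int(row[colmap["pos"]])
            if pos < 1:
                raise ValueError
        except (ValueError, TypeError):
            bad_rows.append(i + 2)  # 1-based data row, after the header
            continue
        gene = row.get(optmap["gene_symbol"])
        ctx = row.get(optmap["context"])
        records.append(
            MutationRecord(
                sample_id=row[colmap["sample_id"]],
                chrom=row[colmap["chrom"]],
                pos=pos,
                ref_allele=row[colmap["ref_allele"]].upper(),
                alt_allele=row[colmap["alt_allele"]].upper(),
                variant_classification=row[colmap["variant_classification"]],
                gene_symbol=gene if gene else None,
                context=ctx.upper() if ctx else None,
            )
        )
    if bad_rows:
        warnings.warn(
            f"rejected {len(bad_rows)} row(s) with unparseable coordinates "
            f"(file rows {bad_rows[:10]}{'...' if len(bad_rows) > 10 else ''})",
            stacklevel=2,
        )
    return MutationTable(records)


def write_maf(table: MutationTable, path) -> None:
    """Write a table back to MAF-format text (round-trips with :func:`read_maf`)."""
    table.to_dataframe().to_csv(path, sep="\t", index=False)


def _contig_sequence(reference, chrom: str, chr_tolerant: bool = False) -> str:
    """Fetch a full contig as an uppercase string from a mapping, pyfaidx Fasta, or path."""
    if isinstance(reference, (str, Path)):
        import pyfaidx

        reference = pyfaidx.Fasta(str(reference))
    names = None
    if isinstance(reference, Mapping):
        names = reference.keys()
    else:  # pyfaidx.Fasta exposes keys()
        names = reference.keys()
    candidates = [chrom]
    if chr_tolerant:
        candidates.append(chrom[3:] if chrom.startswith("chr") else "chr" + chrom)
    for name in candidates:
        if name in names:
            seq = reference[name]
            return str(seq[:]).upper() if not isinstance(seq, str) else seq.upper()
    raise ContigNotFoundError(f"contig {chrom!r} not found in reference")


def attach_context(
    muts: MutationTable,
    reference,
    flank: int = 20,
    chr_tolerant: bool = False,
) -> MutationTable:
    """Attach a +/-``flank`` bp reference context string to every SNV record.

    The context has length ``2*flank + 1`` and is centered on the mutated base
    (reference positions ``pos-flank .. pos+flank``, 1-based inclusive); windows
    running off a contig end are padded with ``N``.  Records whose stated
    reference allele disagrees with the reference sequence are flagged
    (``ref_mismatch=True``) and thereby excluded from downstream motif and
    channel counting; the exclusion count is reported with a warning.

    ``reference`` may be a ``{contig: sequence}`` mapping, an open
    ``pyfaidx.Fasta``, or a FASTA path.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    seqs: dict[str, str] = {}
    out = []
    n_mismatch = 0
    for rec in muts:
        if not rec.is_snv:
            out.append(replace(rec))
            continue
        if rec.chrom not in seqs:
            seqs[rec.chrom] = _contig_sequence(reference, rec.chrom, chr_tolerant)
        seq = seqs[rec.chrom]
        if not 1 <= rec.pos <= len(seq):
            raise ValueError(
                f"position {rec.pos} outside contig {rec.chrom!r} (length {len(seq)})"
            )
        lo = rec.pos - 1 - flank
        hi = rec.pos + flank  # exclusive, 0-based
        window = seq[max(lo, 0) : min(hi, len(seq))]
        window = "N" * max(0, -lo) + window + "N" * max(0, hi - len(seq))
        mismatch = window[flank] != rec.ref_allele
        n_mismatch += mismatch
        out.append(replace(rec, context=window, ref_mismatch=mismatch))
    if n_mismatch:
        warnings.warn(
            f"{n_mismatch} record(s) disagree with the reference allele and are "
            "excluded from motif counting",
            stacklevel=2,
        )
    return MutationTable(out)


def normalize_to_pyrimidine(record: MutationRecord) -> CanonicalSubstitution:
    """Map an SNV with context to its canonical pyrimidine-strand substitution.

    Purine-reference records (ref A/G) are reverse-complemented together with
    their flanking bases, so e.g. a G>A at a forward-strand ``TGA`` reads as a
    C>T at ``TCA`` on the opposite strand.

    Raises
    ------
    AmbiguousContextError
        If the reference, alternate, or either immediate neighbor is not a
        plain A/C/G/T base.
    ValueError
        If the record is not an SNV or carries no odd-length context.
    """
    if not record.is_snv:
        raise ValueError("pyrimidine normalization applies to SNVs only")
    ctx = record.context
    if ctx is None or len(ctx) < 3 or len(ctx) % 2 == 0:
        raise ValueError("record has no odd-length context of length >= 3")
    mid = len(ctx) // 2
    if ctx[mid] != record.ref_allele:
        raise ValueError(
            f"context middle base {ctx[mid]!r} != ref allele {record.ref_allele!r}"
        )
    up, down = ctx[mid - 1], ctx[mid + 1]
    ref, alt = record.ref_allele, record.alt_allele
    if ref in "GA":
        ref = reverse_complement(ref)
        alt = reverse_complement(alt)
        up, down = reverse_complement(down), reverse_complement(up)
    idx = channel_index(up, ref, alt, down)
    return CanonicalSubstitution(
        ref_pyrimidine=ref, alt=alt, upstream=up, downstream=down, channel_index=idx
    )


def try_normalize(record: MutationRecord) -> CanonicalSubstitution | None:
    """Like :func:`normalize_to_pyrimidine`, but returns None for records that
    cannot enter channel counting (non-SNV, missing context, N bases, flagged
    reference mismatch)."""
    if record.ref_mismatch or not record.is_snv or record.context is None:
        return None
    try:
        return normalize_to_pyrimidine(record)
    except (AmbiguousContextError, ValueError):
        return None
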