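"""Per-sample APOBEC mutagenesis enrichment score (AMES).

APOBEC cytidine deaminases mutate cytosines preferentially in a TCW motif
(W = A or T; the reverse-strand mirror is WGA), producing C>T transitions and
C>G transversions.  The enrichment score contrasts the fraction of a sample's
C>T/C>G mutations that fall in TCW against the background TCW density around
the mutated sites:

    AMES = [ n(TCW mutated) / n(C mutated) ] * [ nC_background / nTCW_background ]

where the background counts tally cytosines (C or G on the forward strand) and
TCW/WGA motifs within +/-20 bp of each counted mutation, summed per mutation
(overlapping windows are counted once per mutation, not unioned).  A score of
1 means the mutated-motif fraction matches the local background fraction, i.e.
no APOBEC enrichment.  Samples are stratified into categorical levels at
configurable cutoffs (1 and 2 by default, giving low / moderate / high).

C>A mutations do not enter either tally; indels and multi-nucleotide variants
never participate.  Undefined scores (no C mutations, or no background motif)
propagate as missing values, never as 0.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variant_io import (
    CanonicalSubstitution,
    MutationRecord,
    MutationTable,
    _contig_sequence,
    try_normalize,
)

#: Forward-strand motifs whose central pyrimidine is an APOBEC target.
TCW_MOTIFS = ("TCA", "TCT")
#: Reverse-strand mirrors (central G on the forward strand).
WGA_MOTIFS = ("AGA", "TGA")

DEFAULT_CUTOFFS = (1.0, 2.0)
DEFAULT_LABELS = ("L", "M", "H")


@dataclass(frozen=True)
class TcwCounts:
    """Mutation-side counts of the AMES numerator fraction."""

    n_tcw_mut: int
    n_c_mut: int


@dataclass(frozen=True)
class BackgroundCounts:
    """Background cytosine and TCW-motif counts within the mutation windows."""

    n_background_c: int
    n_background_tcw: int


@dataclass(frozen=True)
class AmesResult:
    sample_id: str
    counts: TcwCounts
    background: BackgroundCounts
    score: float  # NaN when undefined
    level: str | None


def eligible_substitutions(
    records: Iterable[MutationRecord],
) -> list[tuple[MutationRecord, CanonicalSubstitution]]:
    """Records that enter the AMES tallies: SNVs with usable context whose
    canonical form is C>T or C>G (reference-mismatch and N-context records are
    silently excluded, as are all other substitution types)."""
    out = []
    for rec in records:
        canon = try_normalize(rec)
        if canon is None:
            continue
        if canon.ref_pyrimidine == "C" and canon.alt in "TG":
            out.append((rec, canon))
    return out


def count_tcw_mutations(records: Iterable[MutationRecord]) -> TcwCounts:
    """Count C>T/C>G mutations (pyrimidine-normalized) and the TCW subset."""
    n_c = n_tcw = 0
    for _, canon in eligible_substitutions(records):
        n_c += 1
        if canon.upstream == "T" and canon.downstream in "AT":
            n_tcw += 1
    return TcwCounts(n_tcw_mut=n_tcw, n_c_mut=n_c)


def count_background(
    records: Iterable[MutationRecord],
    reference,
    window: int = 20,
    chr_tolerant: bool = False,
) -> BackgroundCounts:
    """Background cytosine and TCW counts within +/-``window`` bp of each
    counted mutation.

    For every eligible mutation (same filter as :func:`count_tcw_mutations`),
    reference positions ``pos-window .. pos+window`` (truncated at contig
    ends) contribute their C and G bases to ``n_background_c``, and every
    TCW or WGA motif whose start lies in the window (motif fully on the
    contig) contributes to ``n_background_tcw``.  Windows of distinct
    mutations are summed independently.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    seqs: dict[str, str] = {}
    n_c = n_tcw = 0
    for rec, _ in eligible_substitutions(records):
        if rec.chrom not in seqs:
            seqs[rec.chrom] = _contig_sequence(reference, rec.chrom, chr_tolerant)
        seq = seqs[rec.chrom]
        lo = max(rec.pos - 1 - window, 0)  # 0-based inclusive
        hi = min(rec.pos - 1 + window, len(seq) - 1)
        span = seq[lo : hi + 1]
        n_c += span.count("C") + span.count("G")
        for start in range(lo, hi + 1):
            triplet = seq[start : start + 3]
            if len(triplet) == 3 and (triplet in TCW_MOTIFS or triplet in WGA_MOTIFS):
                n_tcw += 1
    return BackgroundCounts(n_background_c=n_c, n_background_tcw=n_tcw)


def compute_ames(counts: TcwCounts, background: BackgroundCounts) -> float:
    """The enrichment score; NaN (undefined, distinct from 0) when either
    denominator is zero."""
    if counts.n_c_mut == 0 or background.n_background_tcw == 0:
        return math.nan
    return (counts.n_tcw_mut / counts.n_c_mut) * (
        background.n_background_c / background.n_background_tcw
    )


def stratify_ames(
    scores: Mapping[str, float] | pd.Series,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    labels: Sequence[str] = DEFAULT_LABELS,
) -> dict[str, str | None]:
    """Assign each score to a categorical level with left-closed cutoffs.

    ``score < cutoffs[0]`` maps to ``labels[0]``; ``cutoffs[i] <= score <
    cutoffs[i+1]`` to ``labels[i+1]``; a score equal to a cutoff joins the
    upper interval.  NaN scores map to None.
    """
    cutoffs = list(cutoffs)
    if sorted(cutoffs) != cutoffs or len(set(cutoffs)) != len(cutoffs):
        raise ValueError("cutoffs must be strictly ascending")
    if len(labels) != len(cutoffs) + 1:
        raise ValueError("need exactly one more label than cutoffs")
    items = scores.items() if hasattr(scores, "items") else scores
    out: dict[str, str | None] = {}
    for sample, score in items:
        if score is None or (isinstance(score, float) and math.isnan(score)):
            out[sample] = None
        else:
            out[sample] = labels[bisect_right(cutoffs, score)]
    return out


def score_sample(
    records: Iterable[MutationRecord],
    reference,
    sample_id: str,
    window: int = 20,
    chr_tolerant: bool = False,
) -> AmesResult:
    """Counts and score for one sample's records (level left unset)."""
    records = list(records)
    counts = count_tcw_mutations(records)
    background = count_background(records, reference, window, chr_tolerant)
    return AmesResult(
        sample_id=sample_id,
        counts=counts,
        background=background,
        score=compute_ames(counts, background),
        level=None,
    )


def score_samples(
    muts: MutationTable,
    reference,
    window: int = 20,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    labels: Sequence[str] = DEFAULT_LABELS,
    min_c_mut: int = 0,
    chr_tolerant: bool = False,
) -> pd.DataFrame:
    """AMES table for every sample in a context-attached mutation table.

    Returns a DataFrame indexed by sample with columns ``n_tcw_mut``,
    ``n_c_mut``, ``n_background_c``, ``n_background_tcw``, ``ames`` and
    ``level``.  Samples with fewer than ``min_c_mut`` counted C mutations get
    a missing score and level (no filtering by default).
    """
    rows = []
    for sample, records in muts.by_sample().items():
        res = score_sample(records, reference, sample, window, chr_tolerant)
        score = res.score
        if res.counts.n_c_mut < min_c_mut:
            score = math.nan
        rows.append(
            {
                "sample_id": sample,
                "n_tcw_mut": res.counts.n_tcw_mut,
                "n_c_mut": res.counts.n_c_mut,
                "n_background_c": res.background.n_background_c,
                "n_background_tcw": res.background.n_background_tcw,
                "ames": score,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "n_tcw_mut",
            "n_c_mut",
            "n_background_c",
            "n_background_tcw",
            "ames",
        ],
    ).set_index("sample_id")
    levels = stratify_ames(df["ames"], cutoffs, labels)
    df["level"] = [levels[s] for s in df.index]
    return df
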