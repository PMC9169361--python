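"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: plain string scans,
exhaustive enumeration, and a bounded-variable least-squares solver from a
different scipy entry point.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import lsq_linear
from scipy.stats import hypergeom

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(COMP[b] for b in reversed(s))


def naive_ames_counts(records, reference, window=20):
    """Four AMES counts by direct per-record rescanning of the reference.

    ``records`` are (sample-agnostic) mutation records with chrom/pos/ref/alt;
    mismatching or edge-ambiguous records are skipped exactly as the package
    contract states.
    """
    n_tcw = n_c = bg_c = bg_tcw = 0
    for rec in records:
        seq = reference[rec.chrom]
        if len(rec.ref_allele) != 1 or len(rec.alt_allele) != 1:
            continue
        if rec.ref_allele not in "ACGT" or rec.alt_allele not in "ACGT":
            continue
        if seq[rec.pos - 1] != rec.ref_allele:
            continue
        ref, alt = rec.ref_allele, rec.alt_allele
        # pyrimidine-normalize by hand
        if ref == "C":
            up = seq[rec.pos - 2] if rec.pos >= 2 else "N"
            down = seq[rec.pos] if rec.pos <= len(seq) - 1 else "N"
            pyr_alt = alt
        elif ref == "G":
            up = revcomp(seq[rec.pos]) if rec.pos <= len(seq) - 1 else "N"
            down = revcomp(seq[rec.pos - 2]) if rec.pos >= 2 else "N"
            pyr_alt = revcomp(alt)
        else:
            continue
        if up == "N" or down == "N" or pyr_alt not in ("T", "G"):
            continue
        n_c += 1
        if up == "T" and down in ("A", "T"):
            n_tcw += 1
        lo = max(rec.pos - 1 - window, 0)
        hi = min(rec.pos - 1 + window, len(seq) - 1)
        for i in range(lo, hi + 1):
            if seq[i] in "CG":
                bg_c += 1
            tri = seq[i : i + 3]
            if len(tri) == 3 and (
                (tri[0] == "T" and tri[1] == "C" and tri[2] in "AT")
                or (tri[0] in "AT" and tri[1] == "G" and tri[2] == "A")
            ):
                bg_tcw += 1
    return n_tcw, n_c, bg_c, bg_tcw


def naive_channel_counts(records):
    """96-channel tallies via independent label construction per record."""
    subs = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
    labels = [
        f"{u}[{s}]{d}" for s in subs for u in "ACGT" for d in "ACGT"
    ]
    counts = {lab: 0 for lab in labels}
    skipped = 0
    for rec in records:
        ctx, ref, alt = rec.context, rec.ref_allele, rec.alt_allele
        if (
            rec.ref_mismatch
            or ctx is None
            or len(ref) != 1
            or len(alt) != 1
            or ref == alt
            or ref not in "ACGT"
            or alt not in "ACGT"
        ):
            skipped += 1
            continue
        mid = len(ctx) // 2
        tri = ctx[mid - 1 : mid + 2]
        if ref in "GA":
            tri = revcomp(tri)
            ref, alt = COMP[ref], COMP[alt]
        if "N" in tri or ref not in "CT":
            skipped += 1
            continue
        counts[f"{tri[0]}[{ref}>{alt}]{tri[2]}"] += 1
    return counts, skipped


def nnls_oracle(P, v, tol=1e-14):
    """Non-negative least squares via scipy's BVLS bounded solver."""
    res = lsq_linear(P, v, bounds=(0.0, np.inf), method="bvls", tol=tol)
    return res.x


def fisher_two_sided(a, b, c, d):
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums P(X = k) over all tables with the observed margins whose probability
    does not exceed the observed one (with the customary 1 + 1e-7 relative
    slack for floating-point ties).
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if row1 in (0, n) or col1 in (0, n):
        return 1.0  # degenerate margin: only one table is possible
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    pmf = hypergeom.pmf(np.arange(kmin, kmax + 1), n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def ssgsea_oracle(values, gene_names, members, alpha=0.25):
    """Single-sample enrichment score by direct definition (one sample)."""
    order = sorted(range(len(values)), key=lambda i: (-values[i], i))
    n = len(values)
    member_set = set(members)
    weights = []
    in_flags = []
    for pos, idx in enumerate(order):
        in_set = gene_names[idx] in member_set
        in_flags.append(in_set)
        weights.append((n - pos) ** alpha if in_set else 0.0)
    total_w = sum(weights)
    n_out = n - sum(in_flags)
    es = 0.0
    cum_w = 0.0
    cum_out = 0
    for pos in range(n):
        cum_w += weights[pos]
        cum_out += 0 if in_flags[pos] else 1
        p_in = cum_w / total_w
        p_out = cum_out / n_out if n_out else 0.0
        es += p_in - p_out
    return es
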