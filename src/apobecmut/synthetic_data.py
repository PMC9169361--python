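"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of its arguments (seed included), so the
same configuration reproduces identical bytes.  The simulated objects carry a
truth record sufficient to compute the expected value of every recovery check
without re-deriving it from the outputs.

The mutation generator plants an APOBEC-like process on a random reference: a
mutation is, with probability ``apobec_weight``, a C>T or C>G change (equal
odds) at a uniformly chosen TCW-context cytosine (either strand), and
otherwise the same change at a uniformly chosen cytosine.  At weight 0 the
motif fraction of mutations matches the genomic background by construction,
so the expected enrichment score is ~1; at weight 1 every C mutation sits in
a TCW motif.  The background process draws cytosines only (not all bases):
the enrichment statistic concerns C>T/C>G fractions, and an all-base
background would only dilute counts without moving the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_scores import ExpressionMatrix, GeneSetCollection
from .signature_decomposition import ContextMatrix96, ReferenceCatalog
from .variant_io import CHANNEL_LABELS, MutationRecord, MutationTable, channel_index

_MIN_REFERENCE_LENGTH = 200


@dataclass
class SimulationConfig:
    """Bundle of generator settings (defaults are the package's study conditions)."""

    seed: int = 0
    genome_length: int = 10_000
    gc_fraction: float = 0.5
    n_samples: int = 50
    muts_per_sample: int = 200
    apobec_weight: float = 0.0
    # expression side
    n_genes: int = 1_000
    group_sizes: tuple[tuple[str, int], ...] = (("A", 20), ("B", 20))
    set_size: int = 25
    effect_size: float = 2.0
    noise_sd: float = 1.0


@dataclass
class MutationTruth:
    """Planted parameters of :func:`plant_mutations`."""

    apobec_weight: float
    n_apobec: dict[str, int]  # per-sample count of motif-targeted draws
    n_tcw_sites: int  # TCW-context cytosines in the reference (both strands)
    n_c_sites: int  # cytosines in the reference (both strands)


@dataclass
class ExpressionTruth:
    """Planted parameters of :func:`sim_expression`."""

    groups: dict[str, str]  # sample -> group label
    shifted_sets: dict[str, tuple[str, ...]]
    shifted_group: str
    effect_size: float


def gen_reference(
    length: int,
    gc_fraction: float = 0.5,
    seed: int = 0,
    name: str = "chr1",
) -> dict[str, str]:
    """I.i.d. random contig with P(C) = P(G) = gc/2, as a {name: sequence} dict."""
    if length < _MIN_REFERENCE_LENGTH:
        raise ValueError(f"reference length must be >= {_MIN_REFERENCE_LENGTH}")
    if not 0 <= gc_fraction < 1:
        raise ValueError("gc_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    bases = rng.choice(list("ACGT"), size=length, p=[at, gc, gc, at])
    return {name: "".join(bases)}


def write_fasta(reference: Mapping[str, str], path) -> None:
    """Write a reference mapping as FASTA (wrapped at 80 columns)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def cytosine_sites(seq: str) -> list[int]:
    """1-based positions of cytosines on either strand (C or G forward),
    excluding the first and last base so the immediate triplet is defined."""
    return [i + 1 for i in range(1, len(seq) - 1) if seq[i] in "CG"]


def tcw_sites(seq: str) -> list[int]:
    """1-based positions of TCW-context cytosines on either strand
    (forward TCW with the C in the middle, or forward WGA with the G in the
    middle)."""
    out = []
    for i in range(1, len(seq) - 1):
        tri = seq[i - 1 : i + 2]
        if (tri[1] == "C" and tri[0] == "T" and tri[2] in "AT") or (
            tri[1] == "G" and tri[2] == "A" and tri[0] in "AT"
        ):
            out.append(i + 1)
    return out


def plant_mutations(
    reference: Mapping[str, str],
    n_samples: int = 50,
    muts_per_sample: int = 200,
    apobec_weight: float = 0.0,
    seed: int = 0,
    poisson: bool = False,
    classification: str = "Missense_Mutation",
    classification_weights: Mapping[str, float] | None = None,
    gene_pool: Sequence[str] | None = None,
    sample_prefix: str = "S",
) -> tuple[MutationTable, MutationTruth]:
    """Plant per-sample C>T/C>G SNVs with a controllable APOBEC motif bias.

    Per mutation, with probability ``apobec_weight`` a TCW-context cytosine
    (either strand) is chosen uniformly, otherwise a uniform cytosine; the
    base change is C>T or C>G with equal odds (mirrored to G>A / G>C on the
    forward strand for reverse-strand cytosines).  Positions are sampled
    without replacement within each sample.  Records default to a Missense
    classification so burden and DDR bookkeeping stay orthogonal to motif
    analyses; ``classification_weights`` mixes several classes, and
    ``gene_pool`` assigns uniform random gene symbols.
    """
    if not 0 <= apobec_weight <= 1:
        raise ValueError("apobec_weight must be in [0, 1]")
    if len(reference) != 1:
        raise ValueError("plant_mutations expects a single-contig reference")
    (chrom, seq), = reference.items()
    c_pool = np.array(cytosine_sites(seq))
    t_pool = np.array(tcw_sites(seq))
    if c_pool.size == 0 or t_pool.size == 0:
        raise ValueError("reference has no TCW-context cytosine to mutate")
    t_set = set(t_pool.tolist())
    rng = np.random.default_rng(seed)
    classes, class_p = None, None
    if classification_weights:
        classes = list(classification_weights)
        weights = np.array([classification_weights[c] for c in classes], float)
        class_p = weights / weights.sum()
    records: list[MutationRecord] = []
    n_apobec_per_sample: dict[str, int] = {}
    width = len(str(n_samples))
    for s in range(n_samples):
        sample = f"{sample_prefix}{s + 1:0{width}d}"
        n = int(rng.poisson(muts_per_sample)) if poisson else muts_per_sample
        n_apo = int(rng.binomial(n, apobec_weight))
        if n_apo > t_pool.size or n > c_pool.size:
            raise ValueError(
                f"sample {sample}: {n} mutations requested but only "
                f"{c_pool.size} cytosine sites ({t_pool.size} in TCW) available"
            )
        apo_pos = rng.choice(t_pool, size=n_apo, replace=False)
        taken = set(apo_pos.tolist())
        remaining = np.array([p for p in c_pool if p not in taken])
        bg_pos = rng.choice(remaining, size=n - n_apo, replace=False)
        n_apobec_per_sample[sample] = n_apo
        positions = np.concatenate([apo_pos, bg_pos]).astype(int)
        rng.shuffle(positions)
        for pos in positions:
            ref = seq[pos - 1]
            to_t = rng.random() < 0.5  # C>T on the pyrimidine strand, else C>G
            if ref == "C":
                alt = "T" if to_t else "G"
            else:  # reverse-strand cytosine (forward G)
                alt = "A" if to_t else "C"
            if classes is not None:
                vclass = classes[int(rng.choice(len(classes), p=class_p))]
            else:
                vclass = classification
            gene = (
                str(rng.choice(gene_pool)) if gene_pool is not None else None
            )
            records.append(
                MutationRecord(
                    sample_id=sample,
                    chrom=chrom,
                    pos=int(pos),
                    ref_allele=ref,
                    alt_allele=alt,
                    variant_classification=vclass,
                    gene_symbol=gene,
                )
            )
    truth = MutationTruth(
        apobec_weight=apobec_weight,
        n_apobec=n_apobec_per_sample,
        n_tcw_sites=int(t_pool.size),
        n_c_sites=int(c_pool.size),
    )
    return MutationTable(records), truth


def sim_signature_counts(
    signature_matrix: np.ndarray,
    exposure_matrix: np.ndarray,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> ContextMatrix96:
    """Multinomial 96-channel counts from known signatures x exposures.

    Sample ``s`` draws ``N_s = sum_k H[s, k]`` mutations from the channel
    distribution ``P @ H[s] / N_s`` (``P`` column-stochastic 96 x k, ``H``
    nonnegative integer samples x k).
    """
    P = np.asarray(signature_matrix, dtype=float)
    H = np.asarray(exposure_matrix)
    if P.ndim != 2 or P.shape[0] != 96:
        raise ValueError("signature_matrix must be 96 x k")
    if H.ndim != 2 or H.shape[1] != P.shape[1]:
        raise ValueError("exposure_matrix must be samples x k matching signatures")
    if (H < 0).any() or not np.allclose(H, np.round(H)):
        raise ValueError("exposures must be nonnegative integers")
    if not np.allclose(P.sum(axis=0), 1.0, atol=1e-8):
        raise ValueError("signature columns must sum to 1")
    rng = np.random.default_rng(seed)
    n_samples = H.shape[0]
    counts = np.zeros((n_samples, 96), dtype=np.int64)
    for s in range(n_samples):
        total = int(H[s].sum())
        if total == 0:
            continue
        probs = P @ (H[s] / total)
        counts[s] = rng.multinomial(total, probs)
    ids = list(sample_ids) if sample_ids is not None else [
        f"S{s + 1:03d}" for s in range(n_samples)
    ]
    return ContextMatrix96(counts, ids)


def planted_exposures(
    n_samples: int,
    k: int,
    total_mutations: int,
    dominant_weight: float = 0.7,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Integer exposures where each sample is dominated by one signature.

    The dominant signature cycles over samples; its weight is
    ``dominant_weight`` and the remainder splits evenly.  Returns (H, dominant
    labels).
    """
    if not 0 < dominant_weight <= 1:
        raise ValueError("dominant_weight must be in (0, 1]")
    rng = np.random.default_rng(seed)
    H = np.zeros((n_samples, k), dtype=np.int64)
    dominant = np.arange(n_samples) % k
    rng.shuffle(dominant)
    for s in range(n_samples):
        w = np.full(k, (1.0 - dominant_weight) / max(k - 1, 1))
        w[dominant[s]] = dominant_weight
        H[s] = rng.multinomial(total_mutations, w / w.sum())
    return H, dominant


def synthetic_sbs_catalog() -> ReferenceCatalog:
    """A small synthetic signature catalog for tests and demonstrations.

    The profiles are constructed, not measured: an APOBEC-like pair
    concentrated on TCW-context C>T and C>G channels, a CpG-deamination-like
    C>T profile, a T>G-enriched profile, and a flat background.  They mimic
    the shape of curated SBS catalogs (column-stochastic 96-vectors in the
    fixed channel ordering) without reproducing any published values.
    """
    labels = list(CHANNEL_LABELS)

    def profile(channel_weights: dict[str, float], floor: float = 0.05) -> np.ndarray:
        p = np.full(96, floor / 96)
        total = sum(channel_weights.values())
        for label, w in channel_weights.items():
            p[labels.index(label)] += (1.0 - floor) * w / total
        return p / p.sum()

    cols = {
        "SBS_APOBEC_CT": profile({"T[C>T]A": 1.0, "T[C>T]T": 1.0}),
        "SBS_APOBEC_CG": profile({"T[C>G]A": 1.0, "T[C>G]T": 1.0}),
        "SBS_CPG_CT": profile(
            {f"{u}[C>T]G": 1.0 for u in "ACGT"}
        ),
        "SBS_TG": profile(
            {f"{u}[T>G]{d}": 1.0 for u in "ACGT" for d in "ACGT"}, floor=0.02
        ),
        "SBS_FLAT": np.full(96, 1.0 / 96),
    }
    df = pd.DataFrame(cols, index=labels)
    return ReferenceCatalog(df, provenance="synthetic in-package catalog")


def sim_expression(
    n_genes: int = 1_000,
    group_sizes: Sequence[tuple[str, int]] = (("A", 20), ("B", 20)),
    set_size: int = 25,
    effect_size: float = 2.0,
    noise_sd: float = 1.0,
    baseline_mean: float = 5.0,
    baseline_sd: float = 2.0,
    seed: int = 0,
    shifted_sets: Mapping[str, Sequence[str]] | None = None,
    shifted_group: str | None = None,
) -> tuple[ExpressionMatrix, GeneSetCollection, ExpressionTruth]:
    """Log2-scale expression with a planted group shift in chosen gene sets.

    Per-gene baselines are Normal(baseline_mean, baseline_sd); cells add
    i.i.d. Normal(0, noise_sd) noise; genes of every shifted set gain
    ``effect_size`` log2 units in the designated group (the first group by
    default).  If no sets are supplied, one random set of ``set_size`` genes
    named ``"PLANTED"`` is created.
    """
    group_sizes = list(group_sizes)
    labels = [g for g, _ in group_sizes]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be distinct")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    samples, groups = [], {}
    for label, size in group_sizes:
        for i in range(size):
            name = f"{label}{i + 1:03d}"
            samples.append(name)
            groups[name] = label
    if shifted_sets is None:
        chosen = rng.choice(n_genes, size=set_size, replace=False)
        shifted_sets = {"PLANTED": [genes[i] for i in sorted(chosen)]}
    shifted_sets = {k: tuple(g.upper() for g in v) for k, v in shifted_sets.items()}
    universe = set(genes)
    for name, members in shifted_sets.items():
        if not set(members) <= universe:
            raise ValueError(f"shifted set {name!r} is not a subset of the genes")
    shifted_group = shifted_group or labels[0]
    if shifted_group not in labels:
        raise ValueError(f"unknown shifted group {shifted_group!r}")
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    values = baseline[:, None] + rng.normal(
        0.0, noise_sd, size=(n_genes, len(samples))
    )
    shifted_genes = sorted({g for members in shifted_sets.values() for g in members})
    gene_idx = {g: i for i, g in enumerate(genes)}
    shift_rows = [gene_idx[g] for g in shifted_genes]
    shift_cols = [j for j, s in enumerate(samples) if groups[s] == shifted_group]
    values[np.ix_(shift_rows, shift_cols)] += effect_size
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale="log2"
    )
    truth = ExpressionTruth(
        groups=groups,
        shifted_sets=dict(shifted_sets),
        shifted_group=shifted_group,
        effect_size=effect_size,
    )
    return expr, GeneSetCollection(shifted_sets), truth
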