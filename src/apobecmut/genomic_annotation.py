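"""Variant-class bookkeeping: mutation burden, DDR pathway status, co-occurrence.

Tumor mutational burden (TMB) is the count of non-synonymous somatic
mutations per megabase of captured exome, with 38 Mb as the whole-exome size
estimate.  The non-synonymous classes are the usual MAF terms
(frame-shift and in-frame indels, missense, nonsense, nonstop, splice site,
translation start site); everything else counts as synonymous.

DNA damage response (DDR) status is a binary call: a sample is DDR-Mut if any
gene of any DDR pathway (BER, NER, MMR, HRR, NHEJ, FA, TLS) carries a
non-silent mutation, with per-pathway flags by the same rule.  "Non-silent"
is equated with the non-synonymous class list.

Pairwise somatic co-occurrence / mutual exclusivity between genes is tested
with a two-sided Fisher exact test on per-sample binary mutation presence
(multiple hits in one gene count once), with Benjamini-Hochberg adjustment
across all tested pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .variant_io import MutationTable

#: MAF variant classes counted as non-synonymous (with spelling aliases).
DEFAULT_NONSYNONYMOUS = frozenset(
    {
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Missense",
        "Missense_Mutation",
        "Nonsense",
        "Nonsense_Mutation",
        "Nonstop",
        "Nonstop_Mutation",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

#: Classes known to be synonymous/non-coding; anything else triggers a warning.
KNOWN_SYNONYMOUS = frozenset(
    {
        "Silent",
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "IGR",
        "RNA",
        "lincRNA",
        "Splice_Region",
        "Targeted_Region",
        "De_novo_Start_InFrame",
        "De_novo_Start_OutOfFrame",
    }
)

DEFAULT_EXOME_SIZE_MB = 38.0


@dataclass(frozen=True)
class VariantClassPolicy:
    """Which MAF classification terms count as non-synonymous."""

    nonsynonymous_classes: frozenset = DEFAULT_NONSYNONYMOUS

    def is_nonsynonymous(self, term: str) -> bool:
        return term in self.nonsynonymous_classes


def classify_variants(
    muts: MutationTable, policy: VariantClassPolicy | None = None
) -> pd.Series:
    """Per-record non-synonymous flag (True = non-synonymous).

    Terms outside both the policy set and the known synonymous vocabulary are
    treated as synonymous with a warning.
    """
    policy = policy or VariantClassPolicy()
    flags = []
    unknown = set()
    for rec in muts:
        term = rec.variant_classification
        if policy.is_nonsynonymous(term):
            flags.append(True)
        else:
            if term not in KNOWN_SYNONYMOUS:
                unknown.add(term)
            flags.append(False)
    if unknown:
        warnings.warn(
            f"unknown variant classes treated as synonymous: {sorted(unknown)}",
            stacklevel=2,
        )
    return pd.Series(flags, name="nonsynonymous")


def compute_tmb(
    muts: MutationTable,
    policy: VariantClassPolicy | None = None,
    exome_size_mb: float = DEFAULT_EXOME_SIZE_MB,
) -> pd.DataFrame:
    """Per-sample mutation burden: non-synonymous mutations per megabase.

    Returns a DataFrame indexed by sample with columns ``n_nonsyn``,
    ``n_syn`` and ``tmb`` (= n_nonsyn / exome_size_mb).  Only samples present
    in the table appear.
    """
    if exome_size_mb <= 0:
        raise ValueError("exome_size_mb must be positive")
    flags = classify_variants(muts, policy)
    rows: dict[str, list[int]] = {s: [0, 0] for s in muts.sample_ids}
    for rec, nonsyn in zip(muts, flags):
        rows[rec.sample_id][0 if nonsyn else 1] += 1
    df = pd.DataFrame(
        [(s, ns, syn) for s, (ns, syn) in rows.items()],
        columns=["sample_id", "n_nonsyn", "n_syn"],
    ).set_index("sample_id")
    df["tmb"] = df["n_nonsyn"] / exome_size_mb
    return df


@dataclass
class PathwayGeneMap:
    """Pathway name -> gene symbol set (a gene may belong to several pathways)."""

    mapping: dict[str, frozenset]

    def __post_init__(self):
        if not self.mapping:
            raise ValueError("pathway map is empty")
        self.mapping = {
            p: frozenset(g.upper() for g in genes) for p, genes in self.mapping.items()
        }
        for pathway, genes in self.mapping.items():
            if not genes:
                raise ValueError(f"pathway {pathway!r} has an empty gene set")

    @property
    def pathways(self) -> list[str]:
        return list(self.mapping)

    def pathways_of(self, gene: str) -> list[str]:
        gene = gene.upper()
        return [p for p, genes in self.mapping.items() if gene in genes]

    @classmethod
    def from_tsv(cls, path) -> "PathwayGeneMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("pathway", "gene"):
            if col not in df.columns:
                raise ValueError(f"pathway map TSV needs a {col!r} column")
        mapping: dict[str, set] = {}
        for _, row in df.iterrows():
            mapping.setdefault(row["pathway"], set()).add(row["gene"])
        return cls({p: frozenset(g) for p, g in mapping.items()})

    @classmethod
    def ddr_starter(cls) -> "PathwayGeneMap":
        """The bundled starter DDR map (ten frequently mutated DDR genes).

        Deliberately partial: full pathway memberships are study-specific and
        should be supplied by the user for real analyses.
        """
        ref = resources.files("apobecmut").joinpath("data/ddr_pathways.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def ddr_status(
    muts: MutationTable,
    pathway_map: PathwayGeneMap | None = None,
    policy: VariantClassPolicy | None = None,
) -> pd.DataFrame:
    """Per-sample DDR pathway mutation flags and the overall DDR-Mut/WT call.

    A pathway is flagged mutated if the sample has at least one
    non-synonymous record in any of its genes; the overall status is DDR-Mut
    iff any pathway flag is set.
    """
    pathway_map = pathway_map or PathwayGeneMap.ddr_starter()
    flags = classify_variants(muts, policy)
    pathways = pathway_map.pathways
    status = {s: {p: False for p in pathways} for s in muts.sample_ids}
    for rec, nonsyn in zip(muts, flags):
        if not nonsyn or not rec.gene_symbol:
            continue
        for pathway in pathway_map.pathways_of(rec.gene_symbol):
            status[rec.sample_id][pathway] = True
    df = pd.DataFrame.from_dict(status, orient="index").reindex(
        muts.sample_ids
    )
    df.index.name = "sample_id"
    df["ddr_status"] = np.where(df[pathways].any(axis=1), "DDR-Mut", "DDR-WT")
    return df


def mutation_matrix(
    muts: MutationTable,
    policy: VariantClassPolicy | None = None,
    nonsynonymous_only: bool = True,
) -> pd.DataFrame:
    """Binary gene x sample mutation-presence matrix (multiple hits collapse to 1)."""
    flags = classify_variants(muts, policy)
    samples = muts.sample_ids
    genes: dict[str, None] = {}
    hits = set()
    for rec, nonsyn in zip(muts, flags):
        if rec.gene_symbol is None:
            continue
        if nonsynonymous_only and not nonsyn:
            continue
        genes.setdefault(rec.gene_symbol, None)
        hits.add((rec.gene_symbol, rec.sample_id))
    mat = pd.DataFrame(0, index=list(genes), columns=samples, dtype=np.int8)
    for gene, sample in hits:
        mat.at[gene, sample] = 1
    return mat


def pairwise_cooccurrence(
    gene_by_sample: pd.DataFrame, min_mutated: int = 3
) -> pd.DataFrame:
    """Fisher-exact co-occurrence / mutual-exclusivity screen over gene pairs.

    Genes mutated in fewer than ``min_mutated`` samples are skipped.  For each
    retained pair a 2x2 table (both, A only, B only, neither) is tested
    two-sided; q-values are Benjamini-Hochberg across all tested pairs, and
    the direction is co-occurrence when the odds ratio is >= 1, exclusivity
    otherwise.
    """
    mat = (gene_by_sample.to_numpy() > 0).astype(np.int64)
    genes = list(gene_by_sample.index)
    keep = [i for i, g in enumerate(genes) if mat[i].sum() >= min_mutated]
    rows = []
    for i, j in itertools.combinations(keep, 2):
        a, b = mat[i], mat[j]
        both = int(np.sum(a & b))
        a_only = int(np.sum(a & ~b & 1))
        b_only = int(np.sum(~a & 1 & b))
        neither = int(np.sum((1 - a) & (1 - b)))
        table = [[both, a_only], [b_only, neither]]
        odds, p = fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "gene_a": genes[i],
                "gene_b": genes[j],
                "both": both,
                "a_only": a_only,
                "b_only": b_only,
                "neither": neither,
                "odds_ratio": odds,
                "p_value": p,
                "direction": "co-occurrence" if odds >= 1 else "exclusivity",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_a",
            "gene_b",
            "both",
            "a_only",
            "b_only",
            "neither",
            "odds_ratio",
            "p_value",
            "direction",
        ],
    )
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df[
        [
            "gene_a",
            "gene_b",
            "both",
            "a_only",
            "b_only",
            "neither",
            "odds_ratio",
            "p_value",
            "q_value",
            "direction",
        ]
    ]
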