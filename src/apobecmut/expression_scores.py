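"""Bulk-expression scoring: ssGSEA, cytolytic activity, linear risk signatures.

ssGSEA (single-sample gene set enrichment) scores one sample at a time: genes
are ranked by expression (descending; ties broken by stable input order), and
the enrichment score is the sum over the ranked list of the difference between
the weighted in-set empirical CDF (weights rank^alpha, alpha = 0.25 by
default) and the uniform out-of-set ECDF.  Being rank-based, the score is
invariant to any monotone per-sample transform of expression.

The cytolytic activity (CYT) score is the geometric mean of PRF1 and GZMA on
the linear TPM scale with a small offset (0.01), sqrt((PRF1+e)(GZMA+e)).

Linear risk signatures (e.g. a LASSO-Cox gene panel such as the 21-gene
APOBEC-mutagenesis-related risk score) are applied as a plain dot product of
per-gene coefficients with log2 expression, optionally split into high/low
groups at the cohort median or a fixed threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_SSGSEA_ALPHA = 0.25
CYT_EPSILON = 0.01


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a scale tag (log2 or linear)."""

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self):
        if self.scale not in ("log2", "linear"):
            raise ValueError("scale must be 'log2' or 'linear'")
        df = self.values.copy()
        df.index = df.index.astype(str).str.upper()
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids after uppercasing: {dupes[:5]}")
        all_missing = df.isna().all(axis=1)
        if all_missing.any():
            warnings.warn(
                f"dropping {int(all_missing.sum())} all-missing gene row(s)",
                stacklevel=2,
            )
            df = df.loc[~all_missing]
        self.values = df

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path, scale: str = "log2") -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0), scale=scale)

    def to_linear(self) -> pd.DataFrame:
        """Values on the linear scale (log2 input back-transformed as 2^x - 1)."""
        if self.scale == "linear":
            return self.values.copy()
        return (2.0 ** self.values - 1.0).clip(lower=0.0)


class GeneSetCollection:
    """Named gene-symbol sets (GMT-style)."""

    def __init__(self, sets: Mapping[str, Sequence[str]]):
        self.sets: dict[str, tuple[str, ...]] = {
            name: tuple(dict.fromkeys(g.upper() for g in genes))
            for name, genes in sets.items()
        }
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
        sets: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                sets[parts[0]] = [g for g in parts[2:] if g]
        return cls(sets)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, genes in self.sets.items():
                fh.write("\t".join([name, name] + list(genes)) + "\n")


def _ssgsea_sample(
    values: np.ndarray, member_masks: dict[str, np.ndarray], alpha: float
) -> dict[str, float]:
    n = values.size
    order = np.argsort(-values, kind="stable")  # descending; stable tie rule
    weights = (n - np.arange(n, dtype=float)) ** alpha  # top gene weighted n^alpha
    scores = {}
    for name, mask in member_masks.items():
        member = mask[order]
        m = int(member.sum())
        w = np.where(member, weights, 0.0)
        p_in = np.cumsum(w) / w.sum()
        if m == n:
            p_out = np.zeros(n)
        else:
            p_out = np.cumsum(~member) / (n - m)
        scores[name] = float(np.sum(p_in - p_out))
    return scores


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = DEFAULT_SSGSEA_ALPHA,
    normalize: bool = False,
) -> pd.DataFrame:
    """Per-sample ssGSEA enrichment for every gene set.

    Returns a sets x samples DataFrame.  Sets with fewer than two genes in
    the matrix are skipped with a warning.  With ``normalize=True`` each
    set's scores are divided by their (max - min) across samples.
    """
    genes = pd.Index(expr.gene_ids)
    masks = {}
    for name, members in sets.items():
        mask = genes.isin(members)
        if mask.sum() < 2:
            warnings.warn(
                f"gene set {name!r} has <2 genes in the matrix; skipped",
                stacklevel=2,
            )
            continue
        masks[name] = mask
    if not masks:
        raise ValueError("no gene set overlaps the expression matrix")
    mat = expr.values.to_numpy(dtype=float)
    out = {
        sample: _ssgsea_sample(mat[:, j], masks, alpha)
        for j, sample in enumerate(expr.sample_ids)
    }
    df = pd.DataFrame(out)  # sets x samples
    df = df.reindex([n for n in masks])
    if normalize:
        rng = df.max(axis=1) - df.min(axis=1)
        rng = rng.replace(0, 1.0)
        df = df.div(rng, axis=0)
    return df


def cyt_score(expr: ExpressionMatrix, epsilon: float = CYT_EPSILON) -> pd.Series:
    """Cytolytic activity: geometric mean of PRF1 and GZMA on the linear scale."""
    linear = expr.to_linear()
    for gene in ("PRF1", "GZMA"):
        if gene not in linear.index:
            raise KeyError(f"gene {gene!r} missing from the expression matrix")
    score = np.sqrt(
        (linear.loc["PRF1"] + epsilon) * (linear.loc["GZMA"] + epsilon)
    )
    score.name = "cyt"
    return score


@dataclass
class LinearSignature:
    """A named gene -> Cox-coefficient mapping applied as a dot product."""

    coefficients: dict[str, float]
    name: str = "risk_score"

    def __post_init__(self):
        self.coefficients = {
            g.upper(): float(c) for g, c in self.coefficients.items()
        }
        for gene, coef in self.coefficients.items():
            if not np.isfinite(coef) or coef == 0:
                raise ValueError(f"coefficient for {gene} must be finite and nonzero")

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "LinearSignature":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str})
        for col in ("gene", "coefficient"):
            if col not in df.columns:
                raise ValueError(f"signature TSV needs a {col!r} column")
        return cls(
            dict(zip(df["gene"], df["coefficient"].astype(float))),
            name=name or str(path),
        )


def apply_linear_signature(
    expr: ExpressionMatrix,
    signature: LinearSignature,
    split: str | float | None = "median",
) -> pd.DataFrame:
    """Per-sample risk score = sum of coefficient x log2 expression.

    Genes absent from the matrix contribute 0 with a warning; if none are
    present an error is raised.  ``split`` dichotomizes scores into
    high/low at the cohort median (default), at a numeric threshold, or not
    at all (None).  Scores above the threshold are "high".
    """
    values = expr.values if expr.scale == "log2" else np.log2(expr.to_linear() + 1.0)
    present = [g for g in signature.coefficients if g in values.index]
    missing = [g for g in signature.coefficients if g not in values.index]
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    if missing:
        warnings.warn(
            f"{len(missing)} signature gene(s) missing; contributing 0: "
            f"{missing[:5]}",
            stacklevel=2,
        )
    coeffs = pd.Series({g: signature.coefficients[g] for g in present})
    scores = values.loc[present].mul(coeffs, axis=0).sum(axis=0)
    df = pd.DataFrame({"score": scores})
    if split is not None:
        threshold = float(scores.median()) if split == "median" else float(split)
        df["group"] = np.where(df["score"] > threshold, "high", "low")
    return df
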