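"""Mutational-signature extraction from 96-context count matrices.

The pipeline is the standard de novo signature workflow: build a samples x 96
trinucleotide-substitution count matrix, factorize it with non-negative matrix
factorization (multiplicative updates, generalized Kullback-Leibler objective)
over a range of ranks with several random restarts, pick the rank with the
cophenetic-correlation criterion (the rank just before consensus stability
first drops sharply), annotate each de novo profile against a reference SBS
catalog by cosine similarity, and refit per-sample exposures with non-negative
least squares.

Consensus stability is measured Brunet-style: each restart assigns every
sample to its dominant signature (largest exposure); the consensus matrix is
the fraction of restarts in which two samples share a dominant signature, and
the cophenetic coefficient correlates the consensus distances with the
average-linkage dendrogram distances derived from them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF

from .variant_io import CHANNEL_LABELS, MutationTable, try_normalize


@dataclass
class ContextMatrix96:
    """Samples x 96 matrix of pyrimidine-normalized trinucleotide substitution counts."""

    counts: np.ndarray  # (n_samples, 96) nonnegative integers
    sample_ids: list[str]
    n_excluded: int = 0  # records dropped (non-SNV, N context, reference mismatch)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 96:
            raise ValueError("counts must be a samples x 96 matrix")
        if len(self.sample_ids) != self.counts.shape[0]:
            raise ValueError("sample_ids length must match the matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=list(CHANNEL_LABELS)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_excluded: int = 0) -> "ContextMatrix96":
        df = df.reindex(columns=list(CHANNEL_LABELS))
        if df.isna().any().any():
            raise ValueError("frame does not cover the 96 channel labels")
        return cls(df.to_numpy(), list(df.index), n_excluded)


@dataclass(frozen=True)
class SignatureAnnotation:
    name: str  # best catalog match, or "unassigned"
    cosine: float  # reported to 3 decimals


@dataclass
class SignatureSet:
    """Column-stochastic 96 x k de novo signature profiles."""

    profiles: np.ndarray  # (96, k), columns sum to 1
    names: list[str] = field(default_factory=list)
    cophenetic: float | None = None
    annotations: list[SignatureAnnotation] | None = None

    def __post_init__(self):
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape[0] != 96:
            raise ValueError("profiles must be 96 x k")
        if (self.profiles < 0).any():
            raise ValueError("profiles must be nonnegative")
        sums = self.profiles.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("profile columns must sum to 1")
        if not self.names:
            self.names = [f"Sig{i + 1}" for i in range(self.k)]

    @property
    def k(self) -> int:
        return self.profiles.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.profiles, index=list(CHANNEL_LABELS), columns=self.names
        )


@dataclass
class ExposureMatrix:
    """Per-sample signature activities in mutation-count units."""

    exposures: np.ndarray  # (n_samples, k) nonnegative
    residual: np.ndarray  # per-sample reconstruction residual norm
    sample_ids: list[str]
    signature_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.exposures, index=self.sample_ids, columns=self.signature_names
        )
        df["residual"] = self.residual
        return df


@dataclass
class ReferenceCatalog:
    """Named 96-channel signature profiles, each summing to 1."""

    profiles: pd.DataFrame  # index = channel labels, one column per signature
    provenance: str = ""

    def __post_init__(self):
        df = self.profiles.reindex(list(CHANNEL_LABELS))
        if df.isna().any().any():
            raise ValueError("catalog rows must cover the 96 channel labels")
        sums = df.sum(axis=0)
        if not np.allclose(sums.to_numpy(), 1.0, atol=1e-6):
            bad = sums[(sums - 1.0).abs() > 1e-6].index.tolist()
            raise ValueError(f"catalog profiles must sum to 1: {bad}")
        self.profiles = df

    @property
    def names(self) -> list[str]:
        return list(self.profiles.columns)

    @classmethod
    def from_tsv(cls, path, provenance: str = "") -> "ReferenceCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, provenance=provenance or str(path))

    def to_tsv(self, path) -> None:
        self.profiles.to_csv(path, sep="\t", index_label="channel")


def build_context_matrix(muts: MutationTable) -> ContextMatrix96:
    """Tally every usable SNV into its (sample, channel) cell.

    Records that cannot be normalized (non-SNV, missing/ambiguous context,
    flagged reference mismatch) are excluded and reported in ``n_excluded``.
    Samples with no usable SNVs keep an all-zero row.
    """
    samples = muts.sample_ids
    row = {s: i for i, s in enumerate(samples)}
    counts = np.zeros((len(samples), 96), dtype=np.int64)
    excluded = 0
    for rec in muts:
        canon = try_normalize(rec)
        if canon is None:
            excluded += 1
            continue
        counts[row[rec.sample_id], canon.channel_index] += 1
    return ContextMatrix96(counts, samples, n_excluded=excluded)


def _restart_seed(seed: int, k: int, restart: int) -> int:
    """Deterministic 31-bit stream per (master seed, rank, restart)."""
    return int(np.random.SeedSequence((seed, k, restart)).generate_state(1)[0] >> 1)


def _cophenetic_coefficient(labels: np.ndarray) -> float:
    """Cophenetic correlation of the dominant-signature consensus matrix.

    ``labels`` is (restarts, n_samples).  Perfect consensus (all pairwise
    distances 0) is defined as 1; a flat, structureless consensus (constant
    nonzero distances) as 0.
    """
    n = labels.shape[1]
    if n < 3:
        return 1.0
    consensus = np.zeros((n, n))
    for run in labels:
        consensus += run[:, None] == run[None, :]
    consensus /= labels.shape[0]
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, 0.0):
        return 1.0
    if np.isclose(condensed.std(), 0.0):
        return 0.0
    tree = linkage(condensed, method="average")
    coeff, _ = cophenet(tree, condensed)
    return float(coeff)


def extract_signatures(
    matrix: ContextMatrix96,
    k_range: Iterable[int],
    restarts: int = 10,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> dict[int, SignatureSet]:
    """De novo NMF factorizations for each rank in ``k_range``.

    For each rank, ``restarts`` randomly initialized factorizations are run
    (multiplicative updates, generalized KL objective); the best-objective one
    is kept and its profiles are column-normalized to sum 1 (the scale is
    recovered later by the NNLS exposure fit).  The per-rank cophenetic
    coefficient summarizes how stably samples co-assign to dominant signatures
    across restarts.  Identical inputs and seed give identical outputs.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1:
        raise ValueError("k_range must contain positive ranks")
    if restarts < 2:
        raise ValueError("need at least 2 restarts for a consensus")
    X = np.asarray(matrix.counts, dtype=float)
    nonzero = X.sum(axis=1) > 0
    if ks[-1] >= min(96, int(nonzero.sum()) + 1):
        raise ValueError(
            f"k_max={ks[-1]} too large for {int(nonzero.sum())} nonzero samples"
        )
    Xnz = X[nonzero]
    out: dict[int, SignatureSet] = {}
    for k in ks:
        best_err = np.inf
        best_H = None
        labels = np.empty((restarts, Xnz.shape[0]), dtype=np.int64)
        for r in range(restarts):
            model = NMF(
                n_components=k,
                init="random",
                solver="mu",
                beta_loss="kullback-leibler",
                max_iter=max_iter,
                tol=tol,
                random_state=_restart_seed(seed, k, r),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                W = model.fit_transform(Xnz)
            labels[r] = W.argmax(axis=1)
            if model.reconstruction_err_ < best_err:
                best_err = model.reconstruction_err_
                best_H = model.components_
        profiles = best_H.T.copy()
        sums = profiles.sum(axis=0)
        sums[sums == 0] = 1.0
        profiles /= sums
        coph = 1.0 if k == 1 else _cophenetic_coefficient(labels)
        out[k] = SignatureSet(profiles=profiles, cophenetic=coph)
    return out


def select_rank(
    cophenetics: Mapping[int, float], drop_threshold: float = 0.05
) -> int:
    """Rank selection by the first significant cophenetic drop.

    Returns the rank immediately before the first successive drop larger than
    ``drop_threshold``; if no drop exceeds the threshold, falls back to the
    rank with the maximal coefficient (ties broken toward smaller rank).
    """
    ks = sorted(cophenetics)
    if not ks:
        raise ValueError("no ranks supplied")
    if len(ks) == 1:
        warnings.warn("only one rank supplied; returning it", stacklevel=2)
        return ks[0]
    for k, k_next in zip(ks, ks[1:]):
        if cophenetics[k] - cophenetics[k_next] > drop_threshold:
            return k
    return max(ks, key=lambda k: (cophenetics[k], -k))


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two nonnegative profiles (0 if either is zero)."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def annotate_signatures(
    signatures: SignatureSet,
    catalog: ReferenceCatalog,
    min_cosine: float = 0.8,
) -> SignatureSet:
    """Label each de novo signature with its best-cosine catalog match.

    Matches below ``min_cosine`` are labeled ``"unassigned"``; similarities
    are reported to 3 decimals.  Ties go to the earlier catalog column.
    """
    cat = catalog.profiles.to_numpy()
    annotations = []
    for j in range(signatures.k):
        sims = [cosine_similarity(signatures.profiles[:, j], cat[:, m])
                for m in range(cat.shape[1])]
        best = int(np.argmax(sims))
        name = catalog.names[best] if sims[best] >= min_cosine else "unassigned"
        annotations.append(SignatureAnnotation(name=name, cosine=round(sims[best], 3)))
    return replace(signatures, annotations=annotations)


def fit_exposures_nnls(
    matrix: ContextMatrix96, signatures: SignatureSet
) -> ExposureMatrix:
    """Per-sample non-negative least-squares exposures against fixed profiles.

    Solves ``min ||v - P h||_2, h >= 0`` for each sample's 96-vector ``v``.
    Because profiles are column-stochastic, exposures come out in
    mutation-count units (their sum approximates the sample's SNV count when
    the fit is good).  All-zero samples get zero exposures and zero residual.
    """
    P = signatures.profiles
    n = matrix.n_samples
    exposures = np.zeros((n, signatures.k))
    residual = np.zeros(n)
    for i in range(n):
        v = matrix.counts[i].astype(float)
        if v.sum() == 0:
            continue
        h, rnorm = nnls(P, v)
        exposures[i] = h
        residual[i] = rnorm
    return ExposureMatrix(
        exposures=exposures,
        residual=residual,
        sample_ids=list(matrix.sample_ids),
        signature_names=list(signatures.names),
    )
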