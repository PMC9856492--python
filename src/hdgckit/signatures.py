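"""SBS-96 mutation catalogs, signature refitting, and exposure clustering.

Somatic single-base substitutions are binned into the standard 96
pyrimidine-centric categories: six substitution classes (C>A, C>G, C>T,
T>A, T>C, T>G) by sixteen flanking-base contexts, the 5' flank varying
slowest. Substitutions at purine reference bases are reverse-complemented
together with their flanks.

Refitting (attribution of a sample's catalog to a fixed set of known
signatures by non-negative least squares) is implemented rather than
de-novo extraction: the analysis asks how well known processes explain the
cohort, not what new processes exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.cluster import KMeans

from .io_formats import ReferenceGenome, VariantKey
from .stats import ContingencyTable2x2, fisher_exact, percent

__all__ = [
    "SUBSTITUTION_CLASSES",
    "CATEGORY_LABELS",
    "context_category",
    "category_label",
    "MutationCatalog",
    "SignatureMatrix",
    "ExposureVector",
    "fit_exposures",
    "assign_dominant",
    "dominance_table",
    "cluster_exposures",
    "enrichment_2x2",
]

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

CATEGORY_LABELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in _BASES
    for three in _BASES
)


def category_label(index: int) -> str:
    return CATEGORY_LABELS[index]


def category_index(ref: str, alt: str, five: str, three: str) -> int:
    """Category index for a pyrimidine-or-purine-centred substitution."""
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five, three = _COMPLEMENT[three], _COMPLEMENT[five]
    sub = SUBSTITUTION_CLASSES.index(f"{ref}>{alt}")
    return sub * 16 + _BASES.index(five) * 4 + _BASES.index(three)


def context_category(key: VariantKey, reference: ReferenceGenome) -> int | None:
    """SBS-96 category of an SNV, or None when the context contains N."""
    if not key.is_snv:
        raise ValueError(f"{key}: context categories are defined for SNVs only")
    pos0 = key.pos - 1
    if pos0 == 0 or pos0 + 1 >= reference.contig_length(key.chrom):
        return None
    ctx = reference.fetch(key.chrom, pos0 - 1, pos0 + 2)
    if ctx[1] != key.ref:
        raise ValueError(f"{key}: reference base mismatch ({ctx[1]} in FASTA)")
    if any(b not in _BASES for b in ctx) or key.alt not in _BASES:
        return None
    return category_index(ctx[1], key.alt, ctx[0], ctx[2])


@dataclass
class MutationCatalog:
    """Per-sample SBS-96 mutation counts (samples x 96)."""

    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), 96):
            raise ValueError("catalog must be samples x 96")
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @classmethod
    def from_variants(
        cls,
        per_sample_snvs: dict[str, list[VariantKey]],
        reference: ReferenceGenome,
    ) -> "MutationCatalog":
        """Bin each sample's somatic SNVs; variants with N context are dropped."""
        sample_ids = sorted(per_sample_snvs)
        counts = np.zeros((len(sample_ids), 96), dtype=int)
        for i, sid in enumerate(sample_ids):
            for key in per_sample_snvs[sid]:
                cat = context_category(key, reference)
                if cat is not None:
                    counts[i, cat] += 1
        return cls(sample_ids, counts)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.counts.T, index=list(CATEGORY_LABELS), columns=self.sample_ids)
        df.index.name = "category"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(CATEGORY_LABELS):
            raise ValueError("catalog TSV must have the 96 categories in canonical order")
        return cls(list(df.columns), df.to_numpy().T)


@dataclass
class SignatureMatrix:
    """96 x K matrix of signature probability profiles."""

    signature_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.signature_ids)):
            raise ValueError("signature matrix must be 96 x K")
        if (self.matrix < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("each signature column must sum to 1")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(CATEGORY_LABELS):
            raise ValueError("signature TSV must list the 96 categories in canonical order")
        return cls(list(df.columns), df.to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, index=list(CATEGORY_LABELS), columns=self.signature_ids)
        df.index.name = "category"
        df.to_csv(path, sep="\t")


@dataclass
class ExposureVector:
    """Non-negative signature weights for one sample, summing to 1."""

    sample_id: str
    signature_ids: list[str]
    weights: np.ndarray
    reconstruction_cosine: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("exposure weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("exposure weights must sum to 1")

    @property
    def dominant(self) -> str:
        """Signature with the largest weight; ties go to the smallest id."""
        order = sorted(
            range(len(self.signature_ids)),
            key=lambda i: (-self.weights[i], self.signature_ids[i]),
        )
        return self.signature_ids[order[0]]


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def fit_exposures(
    catalog: MutationCatalog, signatures: SignatureMatrix
) -> tuple[list[ExposureVector], list[str]]:
    """Refit each sample's catalog against the signature matrix by NNLS.

    Each catalog row is normalized to a frequency vector and decomposed as
    a non-negative combination of signature columns; the weights are then
    renormalized to sum to 1. Returns the fitted exposures and the ids of
    samples skipped for having an empty catalog.
    """
    exposures: list[ExposureVector] = []
    skipped: list[str] = []
    S = signatures.matrix
    for sid, row in zip(catalog.sample_ids, catalog.counts):
        total = row.sum()
        if total == 0:
            skipped.append(sid)
            continue
        target = row / total
        w, _ = nnls(S, target)
        if w.sum() == 0:
            skipped.append(sid)
            continue
        recon = S @ w
        exposures.append(
            ExposureVector(
                sample_id=sid,
                signature_ids=list(signatures.signature_ids),
                weights=w / w.sum(),
                reconstruction_cosine=_cosine(row.astype(float), recon),
            )
        )
    return exposures, skipped


def assign_dominant(exposures: list[ExposureVector]) -> pd.DataFrame:
    """Per-sample dominant signature assignments."""
    return pd.DataFrame(
        [(e.sample_id, e.dominant, float(e.weights.max())) for e in exposures],
        columns=["sample_id", "dominant", "weight"],
    )


def dominance_table(exposures: list[ExposureVector]) -> pd.DataFrame:
    """Cohort dominance counts with one-decimal percentages."""
    dom = assign_dominant(exposures)
    n = len(dom)
    rows = [
        (sig, int(cnt), percent(int(cnt), n))
        for sig, cnt in dom["dominant"].value_counts().sort_index().items()
    ]
    return pd.DataFrame(rows, columns=["signature", "n_dominant", "percent"])


def cluster_exposures(
    exposures: list[ExposureVector], k: int, seed: int = 0
) -> pd.DataFrame:
    """K-means clustering of exposure vectors; deterministic given the seed."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(exposures):
        raise ValueError(f"k={k} exceeds the number of samples ({len(exposures)})")
    X = np.vstack([e.weights for e in exposures])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    return pd.DataFrame(
        {"sample_id": [e.sample_id for e in exposures], "cluster": labels.astype(int)}
    )


def enrichment_2x2(
    flag_a: dict[str, bool | None], flag_b: dict[str, bool | None]
) -> tuple[ContingencyTable2x2, float, int]:
    """Association of two per-sample booleans by two-sided Fisher exact test.

    Samples with an unknown (None) status in either flag are excluded; the
    number excluded is returned. Table rows are flag_a (True/False), the
    columns flag_b.
    """
    shared = sorted(set(flag_a) & set(flag_b))
    excluded = 0
    a = b = c = d = 0
    for sid in shared:
        fa, fb = flag_a[sid], flag_b[sid]
        if fa is None or fb is None:
            excluded += 1
            continue
        if fa and fb:
            a += 1
        elif fa and not fb:
            b += 1
        elif fb:
            c += 1
        else:
            d += 1
    table = ContingencyTable2x2(a, b, c, d)
    return table, fisher_exact(table), excluded
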