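"""External clustering validation indices: AMI, ARI and FMI.

All three compare a predicted partition C against a reference partition R
through the |R|×|C| contingency table and its pair statistics:

    a — pairs together in both R and C
    b — pairs separated in both
    c — pairs together in R, separated in C
    d — pairs separated in R, together in C

FMI = a / sqrt((a+c)(a+d)) is the geometric mean of pair precision and
recall. ARI is the Rand index adjusted for chance under the permutation
model. AMI is mutual information (natural log) adjusted by its
hypergeometric expectation and normalized by the arithmetic mean of the
two entropies — the adjusted form, so independent labelings score ≈ 0 and
can go slightly negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "MetricReport",
    "contingency",
    "fmi",
    "ari",
    "ami",
    "evaluate",
]


@dataclass
class ContingencyTable:
    counts: np.ndarray  # |R| x |C| integer matrix
    N: int
    a: int
    b: int
    c: int
    d: int


@dataclass
class MetricReport:
    ami: float
    ari: float
    fmi: float

    def as_dict(self) -> dict[str, float]:
        return {"ami": self.ami, "ari": self.ari, "fmi": self.fmi}


def _comb2(x: np.ndarray | int) -> np.ndarray | int:
    return x * (x - 1) // 2


def contingency(y_true, y_pred) -> ContingencyTable:
    """Contingency counts and the four pair statistics a, b, c, d."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D of equal length")
    N = len(y_true)
    if N < 2:
        raise ValueError("need at least two points")
    _, ri = np.unique(y_true, return_inverse=True)
    _, ci = np.unique(y_pred, return_inverse=True)
    counts = np.zeros((ri.max() + 1, ci.max() + 1), dtype=np.int64)
    np.add.at(counts, (ri, ci), 1)
    a = int(_comb2(counts).sum())
    same_r = int(_comb2(counts.sum(axis=1)).sum())
    same_c = int(_comb2(counts.sum(axis=0)).sum())
    total = int(_comb2(N))
    c = same_r - a
    d = same_c - a
    b = total - a - c - d
    return ContingencyTable(counts=counts, N=N, a=a, b=b, c=c, d=d)


def fmi(ct: ContingencyTable) -> float:
    """Fowlkes–Mallows index a / sqrt((a+c)(a+d)) ∈ [0, 1]."""
    if ct.a + ct.c == 0 or ct.a + ct.d == 0:
        # both partitions all-singletons on the degenerate side: identical
        # partitions score 1, anything else 0
        return 1.0 if ct.c == 0 and ct.d == 0 else 0.0
    return ct.a / np.sqrt(float(ct.a + ct.c) * float(ct.a + ct.d))


def ari(ct: ContingencyTable) -> float:
    """Adjusted Rand index (1 for identical partitions, ≈0 under independence)."""
    sum_comb = float(ct.a)
    sum_r = float(ct.a + ct.c)
    sum_c = float(ct.a + ct.d)
    total = float(_comb2(ct.N))
    expected = sum_r * sum_c / total
    max_index = 0.5 * (sum_r + sum_c)
    if max_index == expected:
        return 1.0  # both partitions trivial (all-in-one or all-singletons)
    return (sum_comb - expected) / (max_index - expected)


def _entropy(sizes: np.ndarray, N: int) -> float:
    p = sizes[sizes > 0] / N
    return float(-(p * np.log(p)).sum())


def _mutual_information(ct: ContingencyTable) -> float:
    N = ct.N
    nz = ct.counts > 0
    nij = ct.counts[nz].astype(float)
    ai = ct.counts.sum(axis=1, keepdims=True)
    bj = ct.counts.sum(axis=0, keepdims=True)
    outer = np.broadcast_to(ai * bj, ct.counts.shape)[nz].astype(float)
    return float((nij / N * np.log(N * nij / outer)).sum())


def _expected_mutual_information(ct: ContingencyTable) -> float:
    """E[MI] over the hypergeometric model of random tables with fixed margins."""
    N = ct.N
    ai = ct.counts.sum(axis=1).astype(np.int64)
    bj = ct.counts.sum(axis=0).astype(np.int64)
    emi = 0.0
    lgN = gammaln(N + 1)
    for a_i in ai:
        for b_j in bj:
            lo = max(1, a_i + b_j - N)
            hi = min(a_i, b_j)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1, dtype=np.int64)
            term1 = nij / N * np.log(N * nij / (a_i * b_j))
            log_p = (
                gammaln(a_i + 1)
                + gammaln(b_j + 1)
                + gammaln(N - a_i + 1)
                + gammaln(N - b_j + 1)
                - lgN
                - gammaln(nij + 1)
                - gammaln(a_i - nij + 1)
                - gammaln(b_j - nij + 1)
                - gammaln(N - a_i - b_j + nij + 1)
            )
            emi += float((term1 * np.exp(log_p)).sum())
    return emi


def ami(ct: ContingencyTable) -> float:
    """Adjusted mutual information, arithmetic-mean normalization.

    AMI = (MI − E[MI]) / (mean(H(R), H(C)) − E[MI]); 1 when the partitions
    are identical relabelings, defined as 1 when both partitions are a
    single cluster (no information to adjust).
    """
    h_r = _entropy(ct.counts.sum(axis=1), ct.N)
    h_c = _entropy(ct.counts.sum(axis=0), ct.N)
    if h_r == 0.0 and h_c == 0.0:
        return 1.0
    mi = _mutual_information(ct)
    emi = _expected_mutual_information(ct)
    denom = 0.5 * (h_r + h_c) - emi
    if denom == 0.0:
        return 1.0 if mi == emi else 0.0
    return (mi - emi) / denom


def evaluate(y_true, y_pred) -> MetricReport:
    """AMI / ARI / FMI of a predicted labeling against ground truth."""
    ct = contingency(y_true, y_pred)
    return MetricReport(ami=ami(ct), ari=ari(ct), fmi=fmi(ct))
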