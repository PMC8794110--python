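"""Protein-complex prediction quality metrics.

Predicted communities P are scored against a benchmark complex set B with
the standard battery used for complex prediction on PPI networks:

* neighbour affinity score  AS(p, b) = |p ∩ b|² / (|p|·|b|);
* match counts Ncp / Ncb at an affinity threshold θ (default 0.1, with the
  inclusive comparison AS ≥ θ);
* Precision = Ncp/|P|, Recall = Ncb/|B|, and their harmonic mean F;
* Sn (coverage of benchmark proteins by best-matching predictions),
  PPV (purity of predictions), Acc = sqrt(Sn·PPV);
* the Composite Score = Precision + Sn + Acc.

Note the θ footgun: because the comparison is inclusive, θ = 0 matches even
zero-overlap pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .netio import ComplexSet

#: Default affinity-score threshold for counting a prediction as matched.
DEFAULT_THETA = 0.1

_TSV_COLUMNS = (
    "Precision", "Recall", "F-measure", "Sn", "PPV", "Acc", "Composite Score",
)


def _as_sets(complexes: ComplexSet | Iterable[Iterable[str]]) -> list[frozenset[str]]:
    if isinstance(complexes, ComplexSet):
        return complexes.member_sets()
    return [frozenset(c) for c in complexes]


def round2(x: float) -> float:
    """Round half-up to 2 decimals (table rendering convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# pairwise matching
# ---------------------------------------------------------------------------

def affinity_score(p: Iterable[str], b: Iterable[str]) -> float:
    """Neighbour affinity score AS(p, b) = |p ∩ b|² / (|p|·|b|) ∈ [0, 1].

    Symmetric; 1 exactly when the two sets are equal, 0 when disjoint.
    """
    p, b = frozenset(p), frozenset(b)
    if not p or not b:
        raise ValueError("affinity score is undefined for empty sets")
    return len(p & b) ** 2 / (len(p) * len(b))


def match_counts(
    predicted: ComplexSet | Iterable[Iterable[str]],
    benchmark: ComplexSet | Iterable[Iterable[str]],
    theta: float = DEFAULT_THETA,
) -> tuple[int, int]:
    """(Ncp, Ncb): predictions matching some benchmark complex at AS ≥ θ,
    and benchmark complexes matched by some prediction."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    P = _as_sets(predicted)
    B = _as_sets(benchmark)
    matched_p = [False] * len(P)
    matched_b = [False] * len(B)
    for i, p in enumerate(P):
        for j, b in enumerate(B):
            if matched_p[i] and matched_b[j]:
                continue
            if affinity_score(p, b) >= theta:
                matched_p[i] = True
                matched_b[j] = True
    return sum(matched_p), sum(matched_b)


def precision_recall_f(
    ncp: int, ncb: int, size_p: int, size_b: int
) -> tuple[float, float, float]:
    """Precision = Ncp/|P|, Recall = Ncb/|B|, F = 2PR/(P+R).

    Empty P or B yields 0 for the corresponding score; F is 0 when both
    Precision and Recall vanish.
    """
    if ncp > size_p or ncb > size_b:
        raise ValueError("matched counts exceed set sizes")
    precision = ncp / size_p if size_p else 0.0
    recall = ncb / size_b if size_b else 0.0
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f


# ---------------------------------------------------------------------------
# overlap-matrix metrics
# ---------------------------------------------------------------------------

@dataclass
class OverlapMatrix:
    """T[i, j] = |benchmark_i ∩ predicted_j| with benchmark sizes N_i."""

    T: np.ndarray
    N: np.ndarray

    @classmethod
    def build(
        cls,
        predicted: ComplexSet | Iterable[Iterable[str]],
        benchmark: ComplexSet | Iterable[Iterable[str]],
    ) -> "OverlapMatrix":
        P = _as_sets(predicted)
        B = _as_sets(benchmark)
        T = np.array(
            [[len(b & p) for p in P] for b in B], dtype=int
        ).reshape(len(B), len(P))
        N = np.array([len(b) for b in B], dtype=int)
        return cls(T=T, N=N)


def sn_ppv_acc(overlap: OverlapMatrix) -> tuple[float, float, float]:
    """Sn = Σ_i max_j T_ij / Σ_i N_i, PPV = Σ_j max_i T_ij / ΣΣ T_ij,
    Acc = sqrt(Sn·PPV).

    PPV is defined as 0 when no prediction overlaps any benchmark complex.
    """
    T, N = overlap.T, overlap.N
    if T.shape[0] < 1 or N.size < 1:
        raise ValueError("need at least one benchmark complex")
    if np.any(N == 0):
        raise ValueError("benchmark complexes must be non-empty")
    sn = float(T.max(axis=1).sum() / N.sum()) if T.size else 0.0
    total = T.sum()
    ppv = float(T.max(axis=0).sum() / total) if T.size and total > 0 else 0.0
    acc = float(np.sqrt(sn * ppv))
    return sn, ppv, acc


def composite_score(precision: float, sn: float, acc: float) -> float:
    """Composite Score = Precision + Sn + Acc (a single summary in [0, 3])."""
    return precision + sn + acc


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """All scores for one prediction/benchmark pair at a given θ.

    Full-precision values are retained; :meth:`rounded` applies the 2-decimal
    half-up rendering used in result tables.
    """

    theta: float
    n_predicted: int
    n_benchmark: int
    ncp: int
    ncb: int
    precision: float
    recall: float
    fmeasure: float
    sn: float
    ppv: float
    acc: float
    composite: float

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "n_predicted": self.n_predicted,
            "n_benchmark": self.n_benchmark,
            "Ncp": self.ncp,
            "Ncb": self.ncb,
            "Precision": self.precision,
            "Recall": self.recall,
            "F-measure": self.fmeasure,
            "Sn": self.sn,
            "PPV": self.ppv,
            "Acc": self.acc,
            "Composite Score": self.composite,
        }

    def rounded(self) -> dict:
        out = self.to_dict()
        for key in _TSV_COLUMNS:
            out[key] = round2(out[key])
        return out

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.to_dict(), handle, indent=2)
            handle.write("\n")

    def write_tsv(self, path: str | Path) -> None:
        rounded = self.rounded()
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("\t".join(_TSV_COLUMNS) + "\n")
            handle.write(
                "\t".join(f"{rounded[c]:.2f}" for c in _TSV_COLUMNS) + "\n"
            )


def evaluate(
    predicted: ComplexSet | Iterable[Iterable[str]],
    benchmark: ComplexSet | Iterable[Iterable[str]],
    theta: float = DEFAULT_THETA,
    min_complex_size: int = 1,
    restrict_to_nodes: Sequence[str] | None = None,
) -> EvaluationReport:
    """Compute the full metric battery for P against B.

    ``min_complex_size`` drops small predicted communities before scoring
    (the default keeps everything, size-1 and size-2 communities included).
    ``restrict_to_nodes`` optionally restricts each benchmark complex to the
    proteins present in the evaluated network (off by default: the full
    benchmark is scored, so Recall and Sn are penalised by unreachable
    proteins).
    """
    P = [p for p in _as_sets(predicted) if len(p) >= min_complex_size]
    B = _as_sets(benchmark)
    if restrict_to_nodes is not None:
        nodes = frozenset(restrict_to_nodes)
        B = [b & nodes for b in B]
        B = [b for b in B if b]
    if not B:
        raise ValueError("benchmark is empty (after restriction)")
    if not P:
        return EvaluationReport(
            theta=theta, n_predicted=0, n_benchmark=len(B),
            ncp=0, ncb=0, precision=0.0, recall=0.0, fmeasure=0.0,
            sn=0.0, ppv=0.0, acc=0.0, composite=0.0,
        )
    ncp, ncb = match_counts(P, B, theta)
    precision, recall, f = precision_recall_f(ncp, ncb, len(P), len(B))
    sn, ppv, acc = sn_ppv_acc(OverlapMatrix.build(P, B))
    return EvaluationReport(
        theta=theta,
        n_predicted=len(P),
        n_benchmark=len(B),
        ncp=ncp,
        ncb=ncb,
        precision=precision,
        recall=recall,
        fmeasure=f,
        sn=sn,
        ppv=ppv,
        acc=acc,
        composite=composite_score(precision, sn, acc),
    )
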