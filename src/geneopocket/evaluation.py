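"""Ranking and distance metrics for pocket predictions.

A predicted pocket *matches* the truth when it has the largest (positive)
overlap with the ground-truth mask; if no pocket intersects the truth the
method *failed* on that protein.  With n the protein-dependent number of
true pockets, H_n is the fraction of proteins matched within the first n
ranks and H_{n+j} (j >= 1) the fraction matched exactly at rank n+j; the
cumulative T_{n+j} sums H up to n+j.  DCA is the minimal distance from any
ligand heavy atom to the predicted centroid, DCC the distance between truth
and prediction centroids; both are conventionally called successful below
4 Å and reported as the best value among the top n+2 ranked pockets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .channels import TruthMask
from .errors import DegenerateTruthError
from .model import Pocket

FAILURE = "FAILURE"
DEFAULT_TOP_EXTRA = 2           # report best-of top n+2 pockets
DEFAULT_THRESHOLDS = tuple(np.arange(4.0, 20.5, 0.5))


# ---------------------------------------------------------------------------
# Per-protein quantities
# ---------------------------------------------------------------------------

def overlap(pocket_voxels: np.ndarray, truth: TruthMask | np.ndarray) -> float:
    """|pocket & truth| / |truth| — volumetric recall of one pocket."""
    tau = truth.values if isinstance(truth, TruthMask) else np.asarray(truth)
    n_tau = int(tau.sum())
    if n_tau == 0:
        raise DegenerateTruthError("ground-truth mask is empty")
    idx = np.asarray(pocket_voxels, dtype=int).reshape(-1, 3)
    if idx.size == 0:
        return 0.0
    hits = tau[tuple(idx.T)].sum()
    return float(hits) / n_tau


def match_rank(pockets: Sequence[Pocket], truth: TruthMask | np.ndarray):
    """Rank of the largest-overlap pocket, or FAILURE when every overlap is
    zero.  Ties go to the best (lowest) rank."""
    best_rank = None
    best_ov = 0.0
    for p in sorted(pockets, key=lambda p: p.rank):
        ov = overlap(p.voxel_indices, truth)
        if ov > best_ov:
            best_ov = ov
            best_rank = p.rank
    return FAILURE if best_rank is None else best_rank


def dca(pocket_centroid: np.ndarray, ligand_coords: np.ndarray) -> float:
    """Minimal distance from any ligand heavy atom to the centroid."""
    lig = np.asarray(ligand_coords, dtype=float).reshape(-1, 3)
    if lig.size == 0:
        raise ValueError("ligand coordinates are empty")
    return float(np.linalg.norm(lig - np.asarray(pocket_centroid), axis=1).min())


def dcc(truth_centroid: np.ndarray, pocket_centroid: np.ndarray) -> float:
    """Distance between truth and prediction centroids."""
    return float(np.linalg.norm(np.asarray(truth_centroid, dtype=float)
                                - np.asarray(pocket_centroid, dtype=float)))


# ---------------------------------------------------------------------------
# Aggregates
# ---------------------------------------------------------------------------

def h_t_coefficients(outcomes: Sequence[tuple[int, int | str]]
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Aggregate (n, match_rank-or-FAILURE) outcomes into H and T sequences.

    Returns ``(H, T, failure_fraction)`` where ``H[j]`` is H_{n+j}: the
    fraction of proteins matched within the top n for j = 0, or exactly at
    rank n+j for j >= 1.  ``T`` is the running sum.  Failures are excluded
    from every bucket and reported separately.
    """
    if not outcomes:
        raise ValueError("no outcomes supplied")
    total = len(outcomes)
    buckets: dict[int, int] = {}
    failures = 0
    for n, rank in outcomes:
        if n < 1:
            raise ValueError("n must be >= 1")
        if rank == FAILURE:
            failures += 1
            continue
        j = 0 if rank <= n else rank - n
        buckets[j] = buckets.get(j, 0) + 1
    j_max = max(buckets) if buckets else 0
    h = np.zeros(j_max + 1)
    for j, count in buckets.items():
        h[j] = count / total
    t = np.cumsum(h)
    return h, t, failures / total


def success_curve(values: Sequence[float | str],
                  thresholds: Sequence[float] = DEFAULT_THRESHOLDS
                  ) -> np.ndarray:
    """Fraction of proteins with value strictly below each threshold;
    failures (non-numeric entries) never count as successes."""
    thresholds = np.asarray(list(thresholds), dtype=float)
    if thresholds.size == 0:
        return np.zeros(0)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    numeric = np.array([v for v in values if not isinstance(v, str)],
                       dtype=float)
    total = len(values)
    if total == 0:
        raise ValueError("no values supplied")
    return np.array([(numeric < t).sum() / total for t in thresholds])


# ---------------------------------------------------------------------------
# Record-level evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationRecord:
    protein_id: str
    pockets: list[Pocket]
    truth: TruthMask
    ligand_coords: np.ndarray | None = None   # heavy atoms, (L, 3)
    n_true_pockets: int = 1


@dataclass
class MetricsReport:
    per_protein: list[dict] = field(default_factory=list)
    h: np.ndarray = field(default_factory=lambda: np.zeros(1))
    t: np.ndarray = field(default_factory=lambda: np.zeros(1))
    failure_fraction: float = 0.0
    dca_curve: np.ndarray | None = None
    dcc_curve: np.ndarray | None = None
    thresholds: np.ndarray = field(
        default_factory=lambda: np.asarray(DEFAULT_THRESHOLDS))

    @property
    def h1(self) -> float:
        return float(self.h[0])

    def to_dict(self) -> dict:
        return {"H": self.h.tolist(), "T": self.t.tolist(),
                "failure_fraction": self.failure_fraction,
                "thresholds": np.asarray(self.thresholds).tolist(),
                "dca_curve": None if self.dca_curve is None else self.dca_curve.tolist(),
                "dcc_curve": None if self.dcc_curve is None else self.dcc_curve.tolist(),
                "per_protein": self.per_protein}


def evaluate_records(records: Sequence[EvaluationRecord],
                     thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                     top_extra: int = DEFAULT_TOP_EXTRA) -> MetricsReport:
    """Full metric suite over per-protein records.

    Overlap/DCA/DCC are reported as the best value among the top
    ``n + top_extra`` ranked pockets; match rank uses all pockets.
    """
    outcomes = []
    dca_vals: list[float | str] = []
    dcc_vals: list[float | str] = []
    per_protein = []
    for rec in records:
        rank = match_rank(rec.pockets, rec.truth)
        outcomes.append((rec.n_true_pockets, rank))
        top = sorted(rec.pockets, key=lambda p: p.rank)[:rec.n_true_pockets + top_extra]
        best_overlap = max((overlap(p.voxel_indices, rec.truth) for p in top),
                           default=0.0)
        row = {"protein_id": rec.protein_id, "match_rank": rank,
               "best_overlap": best_overlap, "dca": None, "dcc": None}
        if top:
            tau_centroid = rec.truth.centroid()
            d_cc = min(dcc(tau_centroid, p.centroid) for p in top)
            dcc_vals.append(d_cc)
            row["dcc"] = d_cc
            if rec.ligand_coords is not None and len(rec.ligand_coords):
                d_ca = min(dca(p.centroid, rec.ligand_coords) for p in top)
                dca_vals.append(d_ca)
                row["dca"] = d_ca
        else:
            dcc_vals.append(FAILURE)
            dca_vals.append(FAILURE)
        per_protein.append(row)

    h, t, failure = h_t_coefficients(outcomes)
    report = MetricsReport(per_protein=per_protein, h=h, t=t,
                           failure_fraction=failure,
                           thresholds=np.asarray(list(thresholds), dtype=float))
    if dcc_vals:
        report.dcc_curve = success_curve(dcc_vals, thresholds)
    if dca_vals:
        report.dca_curve = success_curve(dca_vals, thresholds)
    return report


def h1_on_examples(params, examples, **model_kwargs) -> float:
    """Run the model on channel/truth examples and return H1 (n = 1)."""
    from .model import run_model

    outcomes = []
    for ex in examples:
        out = run_model(ex.stack, params, **model_kwargs)
        outcomes.append((1, match_rank(out.pockets, ex.truth)))
    h, _, _ = h_t_coefficients(outcomes)
    return float(h[0])
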