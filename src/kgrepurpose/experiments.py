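"""Downstream studies: candidate ranking, connectivity correlation,
leave-out retraining, and class-balance analysis.

``rank_candidates`` applies a trained classifier to a list of candidate
drugs for one disease, reporting each connected candidate's prediction
score together with two connectivity statistics: the number of
intermediate concepts between drug and disease, and the drug's
whole-graph degree.  ``correlate_connectivity`` then measures, with
Kendall's tau-b, whether the classifier systematically favours weakly or
strongly connected drugs.  ``leave_out_retrain`` probes the influence of
specific training pairs on the ranking, and ``class_balance_experiment``
contrasts cross-validation performance between disease classes at
matched class ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from kgrepurpose.features import FeatureMatrix, featurize_pair
from kgrepurpose.graph import (
    KnowledgeGraph,
    degree,
    direct_path_exists,
    intermediate_concepts,
)
from kgrepurpose.modeling import (
    CVReport,
    ModelSpec,
    RepurposingClassifier,
    RepurposingResults,
    kendall_tau_b,
)
from kgrepurpose.reference import DrugDiseasePair

logger = logging.getLogger(__name__)


@dataclass
class CandidateSet:
    """Candidate drugs to prioritize for one disease."""

    disease_id: str
    drugs: list[tuple[str, str]]  # (drug concept id, display name)

    def map_active_ingredients(self, mapping: dict[str, str]) -> "CandidateSet":
        """Normalize candidate ids to active-ingredient concepts, merging
        entries that collapse to the same ingredient (first name kept)."""
        seen: dict[str, str] = {}
        for drug_id, name in self.drugs:
            ingredient = mapping.get(drug_id, drug_id)
            seen.setdefault(ingredient, name)
        return CandidateSet(self.disease_id, list(seen.items()))


def load_candidates(path: str | Path, disease_id: str) -> CandidateSet:
    """Read a ``drug_id<TAB>name`` candidate list."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["drug_id", "name"]:
        raise ValueError(f"{path}: expected columns drug_id, name")
    return CandidateSet(disease_id, list(zip(df["drug_id"], df["name"])))


@dataclass
class RankingReport:
    """Per-candidate score and connectivity, sorted by score descending
    (ties broken alphabetically by name)."""

    rows: list[dict] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rows = sorted(self.rows, key=lambda r: (-r["prediction_score"], r["name"]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["name", "prediction_score", "n_intermediates", "drug_degree"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.1f")

    def scores(self) -> list[float]:
        return [r["prediction_score"] for r in self.rows]

    def n_above_cutoff(self, cutoff: float = 50.0) -> int:
        return sum(1 for r in self.rows if r["prediction_score"] > cutoff)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RankingReport":
        df = pd.read_csv(path, sep="\t")
        required = ["name", "prediction_score", "n_intermediates", "drug_degree"]
        if list(df.columns[:4]) != required:
            raise ValueError(f"{path}: expected columns {required}")
        return cls(rows=df[required].to_dict("records"))


def load_adpkd_table() -> RankingReport:
    """The shipped ADPKD prioritization table: 21 candidate drugs with
    their prediction scores and connectivity statistics."""
    ref = resources.files("kgrepurpose.data").joinpath("table4_adpkd.tsv")
    with resources.as_file(ref) as path:
        return RankingReport.from_tsv(path)


def rank_candidates(
    results: RepurposingResults, g: KnowledgeGraph, cs: CandidateSet
) -> RankingReport:
    """Score every candidate drug against the disease and rank.

    Candidates with neither a direct nor a one-intermediate path to the
    disease cannot be featurized meaningfully and are excluded (logged);
    candidates absent from the graph likewise.
    """
    if cs.disease_id not in g:
        raise KeyError(f"disease {cs.disease_id!r} absent from graph")
    rows, excluded = [], []
    for drug_id, name in cs.drugs:
        if drug_id not in g:
            excluded.append(name)
            continue
        inter = intermediate_concepts(g, drug_id, cs.disease_id)
        if not inter and not direct_path_exists(g, drug_id, cs.disease_id):
            excluded.append(name)
            continue
        pair = DrugDiseasePair(
            drug_id=drug_id, disease_id=cs.disease_id, status="approved", drug_name=name
        )
        row = featurize_pair(g, pair, results.schema).reshape(1, -1)
        m = FeatureMatrix(schema=results.schema, values=row, pair_ids=[pair.pair_id])
        score = float(results.predict_scores(m)[0])
        rows.append(
            {
                "name": name,
                "prediction_score": round(score, 1),
                "n_intermediates": len(inter),
                "drug_degree": degree(g, drug_id),
            }
        )
    if excluded:
        logger.info("candidates without direct or indirect path, excluded: %s", excluded)
    return RankingReport(rows=rows, excluded=excluded)


def correlate_connectivity(report: RankingReport) -> dict[str, tuple[float, float]]:
    """Kendall tau-b of (score, intermediate count) and (score, degree)."""
    if len(report.rows) < 3:
        raise ValueError("need at least three ranked candidates")
    scores = report.scores()
    return {
        "intermediates": kendall_tau_b(scores, [r["n_intermediates"] for r in report.rows]),
        "degree": kendall_tau_b(scores, [r["drug_degree"] for r in report.rows]),
    }


@dataclass
class LeaveOutResult:
    """Candidate scores before/after excluding training pairs."""

    excluded_pair_ids: list[str]
    baseline: RankingReport
    retrained: RankingReport
    excluded_pair_scores: dict[str, float]  # scored by the retrained model
    rank_changes: dict[str, int]


def leave_out_retrain(
    m: FeatureMatrix,
    excluded: list[str],
    spec: ModelSpec,
    g: KnowledgeGraph,
    cs: CandidateSet,
) -> LeaveOutResult:
    """Retrain without the excluded pairs and re-rank the candidates.

    The excluded pairs themselves are also scored by the retrained model
    (they are no longer training instances, so the score is out-of-bag in
    spirit).  An empty exclusion list reproduces the baseline exactly.
    """
    missing = [pid for pid in excluded if pid not in m.pair_ids]
    if missing:
        raise KeyError(f"excluded ids not in matrix: {missing}")
    baseline_model = RepurposingClassifier(m, spec).fit()
    baseline = rank_candidates(baseline_model, g, cs)

    keep = np.array([pid not in set(excluded) for pid in m.pair_ids])
    reduced = m.subset(keep)
    if len(set(reduced.labels)) < 2:
        raise ValueError("exclusion removed an entire class")
    retrained_model = RepurposingClassifier(reduced, spec).fit()
    retrained = rank_candidates(retrained_model, g, cs)

    excl_scores: dict[str, float] = {}
    if excluded:
        excl_mask = np.array([pid in set(excluded) for pid in m.pair_ids])
        excl_matrix = m.subset(excl_mask)
        scores = retrained_model.predict_scores(excl_matrix)
        excl_scores = {pid: round(float(s), 1)
                       for pid, s in zip(excl_matrix.pair_ids, scores)}

    def ranks(rep: RankingReport) -> dict[str, int]:
        return {r["name"]: i for i, r in enumerate(rep.rows)}

    rb, rr = ranks(baseline), ranks(retrained)
    changes = {name: rr[name] - rb[name] for name in rb if name in rr}
    return LeaveOutResult(
        excluded_pair_ids=list(excluded),
        baseline=baseline,
        retrained=retrained,
        excluded_pair_scores=excl_scores,
        rank_changes=changes,
    )


def _subsample_matrix_to_ratio(
    m: FeatureMatrix, positive_to_negative: float, seed: int
) -> FeatureMatrix:
    """Downsample one class of a labelled matrix to a target ratio
    (same scheme as reference-set subsampling, on rows)."""
    labels = np.asarray(m.labels)
    pos_idx = np.flatnonzero(labels == "approved")
    neg_idx = np.flatnonzero(labels == "terminated")
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("both classes required")
    rng = np.random.default_rng(seed)
    if len(pos_idx) / len(neg_idx) > positive_to_negative:
        target = int(round(positive_to_negative * len(neg_idx)))
        keep = set(rng.choice(pos_idx, size=target, replace=False).tolist()) | set(
            neg_idx.tolist()
        )
    else:
        target = int(round(len(pos_idx) / positive_to_negative))
        keep = set(pos_idx.tolist()) | set(
            rng.choice(neg_idx, size=target, replace=False).tolist()
        )
    mask = np.array([i in keep for i in range(m.n_rows)])
    return m.subset(mask)


def class_balance_experiment(
    m: FeatureMatrix,
    disease_classes: list[str],
    spec: ModelSpec,
    seed: int,
    repeats: int = 10,
    folds: int = 10,
    ratio: float | None = None,
) -> dict[str, CVReport]:
    """Separate CV for cancer and non-cancer subsets, plus the cancer
    subset rebalanced to the non-cancer approved:terminated ratio.

    ``disease_classes`` aligns with the matrix rows.  When ``ratio`` is
    None the non-cancer subset's own ratio is used as the target.
    """
    if len(disease_classes) != m.n_rows:
        raise ValueError("disease_classes must align with matrix rows")
    classes = np.asarray(disease_classes)
    cancer = m.subset(classes == "cancer")
    non_cancer = m.subset(classes == "non-cancer")
    if cancer.n_rows == 0 or non_cancer.n_rows == 0:
        raise ValueError("both disease classes must be represented")
    if ratio is None:
        labels = np.asarray(non_cancer.labels)
        n_pos = int((labels == "approved").sum())
        n_neg = int((labels == "terminated").sum())
        if n_neg == 0:
            raise ValueError("non-cancer subset has no terminated pairs")
        ratio = n_pos / n_neg
    rebalanced = _subsample_matrix_to_ratio(cancer, ratio, seed)
    out = {}
    for label, subset in (
        ("cancer", cancer),
        ("non-cancer", non_cancer),
        ("cancer-rebalanced", rebalanced),
    ):
        out[label] = RepurposingClassifier(subset, spec).cross_validate(
            repeats=repeats, folds=folds, seed=seed, label=label
        )
    return out
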