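"""The Psoriasis-Microbiome Index: a per-sample log-ratio dysbiosis score.

PMI = log10( Σ abundance of genera increased in psoriasis
             / Σ abundance of genera decreased in psoriasis ),
computed on genus-level relative abundances so the score is sequencing-depth
independent and transfers across cohorts.  The module builds the index from
discriminant features, scores samples, calibrates a cutoff where the ROC
sensitivity and specificity curves intersect, runs stratified tenfold
cross-validation (optionally re-selecting genera inside each training fold
to avoid selection leakage), and applies a frozen index + cutoff to an
independent cohort.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .core_io import AbundanceTable, SampleMetadata
from .diff_abundance import DifferentialFeature, lefse
from .synthetic import derive_seed

__all__ = [
    "IndexDefinition", "RocCurve", "CutoffResult", "IndexEvaluation",
    "CrossValidationResult", "define_index", "compute_pmi", "roc_curve",
    "select_cutoff", "cross_validate", "apply_index",
]


@dataclass(frozen=True)
class IndexDefinition:
    """Frozen numerator/denominator genus sets of the log-ratio index."""

    increased_genera: frozenset[str]
    decreased_genera: frozenset[str]
    log_base: float = 10.0
    pseudocount_policy: str | float = "half_min_nonzero"

    def __post_init__(self) -> None:
        inc = frozenset(self.increased_genera)
        dec = frozenset(self.decreased_genera)
        object.__setattr__(self, "increased_genera", inc)
        object.__setattr__(self, "decreased_genera", dec)
        if not inc or not dec:
            raise ValueError("both genus sets must be non-empty")
        overlap = inc & dec
        if overlap:
            raise ValueError(f"genera in both sets: {sorted(overlap)}")
        if self.log_base <= 0 or self.log_base == 1:
            raise ValueError("log_base must be positive and != 1")

    def to_json(self) -> str:
        return json.dumps({
            "increased": sorted(self.increased_genera),
            "decreased": sorted(self.decreased_genera),
            "log_base": self.log_base,
            "pseudocount": self.pseudocount_policy,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "IndexDefinition":
        obj = json.loads(text)
        return cls(frozenset(obj["increased"]), frozenset(obj["decreased"]),
                   float(obj.get("log_base", 10.0)),
                   obj.get("pseudocount", "half_min_nonzero"))


def define_index(features: list[DifferentialFeature],
                 log_base: float = 10.0,
                 pseudocount_policy: str | float = "half_min_nonzero"
                 ) -> IndexDefinition:
    """Numerator = case-enriched genera, denominator = control-enriched."""
    inc = frozenset(f.genus for f in features if f.direction == "case_enriched")
    dec = frozenset(f.genus for f in features
                    if f.direction == "control_enriched")
    if not inc or not dec:
        raise ValueError(
            "need at least one feature in each direction to define an index")
    return IndexDefinition(inc, dec, log_base, pseudocount_policy)


def compute_pmi(table: AbundanceTable, idx: IndexDefinition) -> pd.Series:
    """Per-sample index scores on a genus-level proportion table.

    Genera named by the index but absent from the table contribute zero (a
    warning is emitted); a pseudocount — half the table's smallest nonzero
    proportion, or the fixed value of the policy — is added to both sums
    only for samples where either sum is zero.
    """
    if not table.is_relative:
        raise ValueError("compute_pmi expects a relative-abundance table")
    present_inc = [g for g in sorted(idx.increased_genera)
                   if g in table.data.index]
    present_dec = [g for g in sorted(idx.decreased_genera)
                   if g in table.data.index]
    missing = (idx.increased_genera | idx.decreased_genera) \
        - set(table.data.index)
    if missing:
        warnings.warn(f"index genera absent from table (contribute 0): "
                      f"{sorted(missing)}", stacklevel=2)
    if not present_inc and not present_dec:
        raise ValueError("none of the index genera are present in the table")
    num = table.data.loc[present_inc].sum(axis=0) if present_inc \
        else pd.Series(0.0, index=table.data.columns)
    den = table.data.loc[present_dec].sum(axis=0) if present_dec \
        else pd.Series(0.0, index=table.data.columns)
    if idx.pseudocount_policy == "half_min_nonzero":
        vals = table.data.to_numpy()
        nonzero = vals[vals > 0]
        pseudo = float(nonzero.min()) / 2.0 if nonzero.size else 1e-9
    else:
        pseudo = float(idx.pseudocount_policy)
    zero = (num == 0) | (den == 0)
    num = num + zero * pseudo
    den = den + zero * pseudo
    scores = np.log(num / den) / np.log(idx.log_base)
    return pd.Series(scores, index=table.data.columns, name="pmi")


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocCurve:
    """Thresholds (descending, ±inf sentinels) with sens/spec and AUC.

    A sample is called a case when its score ≥ threshold, so sensitivity is
    non-decreasing as the threshold falls.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, float)
    lab = np.asarray(labels)
    if s.shape != lab.shape:
        raise ValueError("scores and labels must align")
    unknown = set(np.unique(lab)) - {"case", "control"}
    if unknown:
        raise ValueError(f"labels must be case/control, got {sorted(unknown)}")
    cases = s[lab == "case"]
    controls = s[lab == "control"]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present")
    return cases, controls


def roc_curve(scores, labels) -> RocCurve:
    """ROC over thresholds at midpoints between consecutive distinct scores.

    AUC is the pairwise concordance probability
    P(score_case > score_control) + ½·P(tie), computed by ranking (the
    Mann–Whitney identity), which coincides with the trapezoid area.
    """
    cases, controls = _split_scores(scores, labels)
    s = np.concatenate([cases, controls])
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[np.inf], mids[::-1], [-np.inf]])
    sens = np.array([(cases >= t).mean() for t in thresholds])
    spec = np.array([(controls < t).mean() for t in thresholds])

    ranks = rankdata(s)
    u = ranks[:len(cases)].sum() - len(cases) * (len(cases) + 1) / 2.0
    auc = u / (len(cases) * len(controls))
    return RocCurve(thresholds, sens, spec, float(auc))


@dataclass
class CutoffResult:
    threshold: float
    sensitivity: float
    specificity: float


def select_cutoff(rc: RocCurve, score_range: tuple[float, float] | None = None
                  ) -> CutoffResult:
    """Threshold where sensitivity and specificity intersect.

    Minimizes |sens − spec|; ties broken by larger sens + spec, then by the
    smaller threshold.  ``score_range`` clamps a sentinel threshold back
    into the observed score range for degenerate curves.
    """
    gap = np.abs(rc.sensitivity - rc.specificity)
    youden = rc.sensitivity + rc.specificity
    best = None
    for i in range(len(rc.thresholds)):
        key = (gap[i], -youden[i], rc.thresholds[i])
        if best is None or key < best[0]:
            best = (key, i)
    i = best[1]
    threshold = float(rc.thresholds[i])
    if not np.isfinite(threshold) and score_range is not None:
        lo, hi = score_range
        threshold = hi if threshold > 0 else lo
    return CutoffResult(threshold, float(rc.sensitivity[i]),
                        float(rc.specificity[i]))


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class IndexEvaluation:
    """An index + cutoff measured on one cohort."""

    scores: pd.Series
    cutoff: float
    sensitivity: float
    specificity: float
    auc: float
    provenance: str                   # training | cross_validation | external


def evaluate_at_cutoff(scores: pd.Series, md: SampleMetadata, cutoff: float,
                       provenance: str) -> IndexEvaluation:
    labels = md.groups.reindex(scores.index).to_numpy()
    cases, controls = _split_scores(scores.to_numpy(), labels)
    rc = roc_curve(scores.to_numpy(), labels)
    return IndexEvaluation(
        scores=scores, cutoff=float(cutoff),
        sensitivity=float((cases >= cutoff).mean()),
        specificity=float((controls < cutoff).mean()),
        auc=rc.auc, provenance=provenance)


@dataclass
class CrossValidationResult:
    """Stratified k-fold CV with pooled held-out scores."""

    fold_assignments: pd.Series       # sample_id -> fold number
    scores: pd.Series                 # pooled held-out scores
    labels: pd.Series
    roc: RocCurve
    fold_indices: list[IndexDefinition] = field(default_factory=list)


def cross_validate(table: AbundanceTable, md: SampleMetadata, k: int = 10,
                   seed: int = 0, reselect: bool = True,
                   index: IndexDefinition | None = None,
                   lefse_params: dict | None = None) -> CrossValidationResult:
    """Stratified k-fold CV of the index on a relative genus table.

    With ``reselect`` (default) the discriminant genera are re-chosen by
    LEfSe inside each training fold, so held-out performance is free of
    selection leakage; otherwise a frozen ``index`` scores every fold.
    """
    if not table.is_relative:
        raise ValueError("cross_validate expects a relative-abundance table")
    if not reselect and index is None:
        raise ValueError("reselect=False requires a frozen index")
    labels = md.groups.reindex(table.sample_ids)
    if labels.isna().any():
        raise ValueError("metadata missing for some table samples")
    counts = labels.value_counts()
    if (counts < k).any():
        small = int(counts.min())
        raise ValueError(
            f"smallest class has {small} samples; use k <= {small}")
    sample_ids = np.array(table.sample_ids)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = pd.Series(-1, index=table.sample_ids, dtype=int, name="fold")
    scores_parts, fold_defs = [], []
    params = dict(lefse_params or {})
    for fold, (train, test) in enumerate(
            skf.split(sample_ids, labels.to_numpy())):
        folds.iloc[test] = fold
        if reselect:
            sub = table.subset_samples(sample_ids[train])
            feats = lefse(sub, md.subset(sample_ids[train]),
                          seed=derive_seed(seed, f"lefse_fold_{fold}"),
                          **params)
            idx = define_index(feats)
        else:
            idx = index
        fold_defs.append(idx)
        held = table.subset_samples(sample_ids[test])
        scores_parts.append(compute_pmi(held, idx))
    pooled = pd.concat(scores_parts).reindex(table.sample_ids)
    rc = roc_curve(pooled.to_numpy(), labels.to_numpy())
    return CrossValidationResult(folds, pooled, labels, rc, fold_defs)


def apply_index(test_table: AbundanceTable, idx: IndexDefinition,
                cutoff: float, test_md: SampleMetadata) -> IndexEvaluation:
    """Score an independent cohort with a frozen index and cutoff."""
    scores = compute_pmi(test_table, idx)
    return evaluate_at_cutoff(scores, test_md, cutoff, provenance="external")
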