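"""Group-discriminant genera: KW screen, LEfSe-style LDA effect sizes,
Bonferroni adjustment, and the Firmicutes:Bacteroidetes ratio.

The LEfSe procedure here follows the original design for the plain
two-class case: a per-genus Kruskal–Wallis screen at alpha, then, for the
survivors, bootstrap rounds of a one-component linear discriminant on
per-million-scaled abundances.  Each round's per-genus effect averages the
genus's share of the discriminant-axis class separation with the raw
class-mean difference; the reported score is log10(1 + mean effect), and
genera at or above the LDA-score threshold (conventionally 2.0) are
returned with their direction of enrichment.  Numeric parity with any
particular LEfSe release is not promised — recovery of injected signatures
and false-positive calibration are the contract.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .core_io import AbundanceTable, SampleMetadata, collapse_to_rank

__all__ = [
    "KruskalResult", "DifferentialFeature", "FbRatioResult",
    "kruskal_wallis", "bonferroni", "lefse", "fb_ratio",
]


@dataclass
class KruskalResult:
    h: float
    p_value: float
    degenerate: bool = False


def kruskal_wallis(*groups) -> KruskalResult:
    """Tie-corrected Kruskal–Wallis H with a chi-square p on k−1 df.

    All observations identical across groups is degenerate by convention:
    H = 0, p = 1, flagged.
    """
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs at least 2 observations")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return KruskalResult(0.0, 1.0, degenerate=True)
    h, p = stats.kruskal(*arrays)
    return KruskalResult(float(h), float(p))


def bonferroni(p_values) -> np.ndarray:
    """min(1, m·p) elementwise over a family of m tests."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


@dataclass
class DifferentialFeature:
    """A genus that discriminates the two groups."""

    genus: str
    direction: str          # "case_enriched" | "control_enriched"
    kw_p: float
    lda_score: float


def _per_million(data: pd.DataFrame) -> pd.DataFrame:
    sums = data.sum(axis=0)
    if (sums == 0).any():
        bad = sums.index[int(np.argmax((sums == 0).to_numpy()))]
        raise ValueError(f"sample {bad!r} has zero total abundance")
    return data.astype(float) / sums * 1e6


def lefse(table: AbundanceTable, md: SampleMetadata, alpha: float = 0.05,
          lda_threshold: float = 2.0, n_boot: int = 30, seed: int = 0,
          bootstrap_fraction: float = 2.0 / 3.0
          ) -> list[DifferentialFeature]:
    """Two-class LEfSe: KW screen then bootstrapped LDA effect sizes.

    ``table`` holds genus-level abundances (counts or proportions; samples
    are rescaled to per-million internally, so the result is invariant to
    per-sample scaling).  Returns features with KW p < ``alpha`` and
    lda_score ≥ ``lda_threshold``, sorted by descending score.  With two
    plain classes the subclass (Wilcoxon) stage of the original procedure
    has nothing to compare and is a no-op.
    """
    labels = md.groups.reindex(table.sample_ids)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])
        raise ValueError(f"metadata missing for samples: {missing}")
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"lefse needs exactly 2 classes, got {classes}")
    counts = labels.value_counts()
    if (counts < 3).any():
        raise ValueError(f"each class needs >= 3 samples, got {dict(counts)}")

    x = _per_million(table.data)          # taxa × samples, per-million
    is_case = (labels == "case").to_numpy() if "case" in classes \
        else (labels == classes[1]).to_numpy()
    case_label = "case" if "case" in classes else classes[1]

    survivors: list[str] = []
    kw_ps: dict[str, float] = {}
    for genus in x.index:
        row = x.loc[genus].to_numpy()
        res = kruskal_wallis(row[is_case], row[~is_case])
        if not res.degenerate and res.p_value < alpha:
            survivors.append(genus)
            kw_ps[genus] = res.p_value
    if not survivors:
        return []

    xs = x.loc[survivors].to_numpy().T    # samples × survivors
    y = is_case.astype(int)
    rng = np.random.default_rng(seed)
    idx_case = np.flatnonzero(y == 1)
    idx_ctrl = np.flatnonzero(y == 0)
    n_case = max(3, int(round(bootstrap_fraction * len(idx_case))))
    n_ctrl = max(3, int(round(bootstrap_fraction * len(idx_ctrl))))

    effects = np.zeros(len(survivors))
    rounds = 0
    for _ in range(n_boot):
        take = np.concatenate([
            rng.choice(idx_case, size=min(n_case, len(idx_case)),
                       replace=False),
            rng.choice(idx_ctrl, size=min(n_ctrl, len(idx_ctrl)),
                       replace=False)])
        xb, yb = xs[take].copy(), y[take]
        raw_diff = xb[yb == 1].mean(axis=0) - xb[yb == 0].mean(axis=0)
        # jitter zero-variance columns so the within-class scatter stays
        # invertible (as the original tool does)
        within_var = (xb[yb == 1].var(axis=0) + xb[yb == 0].var(axis=0))
        flat = within_var == 0
        if flat.any():
            scale = np.maximum(1.0, np.abs(xb[:, flat]).max(axis=0)) * 1e-6
            xb[:, flat] += rng.normal(0.0, scale, size=(len(xb), flat.sum()))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lda = LinearDiscriminantAnalysis(solver="svd")
                lda.fit(xb, yb)
                w = lda.scalings_[:, 0]
        except (np.linalg.LinAlgError, ValueError, IndexError):
            continue
        norm = np.linalg.norm(w)
        if norm == 0 or not np.isfinite(norm):
            continue
        w_unit = w / norm
        proj = xb @ w_unit
        gap = abs(proj[yb == 1].mean() - proj[yb == 0].mean())
        effects += (np.abs(w_unit) * gap + np.abs(raw_diff)) / 2.0
        rounds += 1
    if rounds == 0:
        return []
    effects /= rounds
    scores = np.log10(1.0 + effects)

    overall_diff = xs[y == 1].mean(axis=0) - xs[y == 0].mean(axis=0)
    features = []
    for genus, score, diff in zip(survivors, scores, overall_diff):
        if score >= lda_threshold:
            direction = ("case_enriched" if diff > 0 else "control_enriched")
            features.append(DifferentialFeature(genus, direction,
                                                kw_ps[genus], float(score)))
    features.sort(key=lambda f: -f.lda_score)
    return features


@dataclass
class FbRatioResult:
    """Per-sample Firmicutes:Bacteroidetes ratios and the group contrast."""

    ratios: pd.Series
    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float
    p_value: float
    test: str


def fb_ratio(table: AbundanceTable, md: SampleMetadata,
             test: str = "mannwhitney") -> FbRatioResult:
    """Per-sample Firmicutes / Bacteroidetes abundance ratio by group.

    A raised ratio is the aggregate dysbiosis signal expected in psoriasis
    stool.  Zero denominators get a pseudocount of half the smallest nonzero
    phylum sum so ratios stay positive and finite.  The group contrast is a
    two-sided Mann–Whitney U by default (``test="ttest"`` → Welch).
    """
    phyla = collapse_to_rank(table, "phylum")
    index_lower = {t.lower(): t for t in phyla.taxon_ids}
    try:
        firm = phyla.data.loc[index_lower["firmicutes"]].to_numpy(float)
        bact = phyla.data.loc[index_lower["bacteroidetes"]].to_numpy(float)
    except KeyError as exc:
        raise ValueError(f"phylum {exc.args[0]!r} absent from table") from None
    pool = np.concatenate([firm, bact])
    nonzero = pool[pool > 0]
    if nonzero.size == 0:
        raise ValueError("Firmicutes and Bacteroidetes are zero everywhere")
    pseudo = nonzero.min() / 2.0
    num = np.where((firm == 0) | (bact == 0), firm + pseudo, firm)
    den = np.where((firm == 0) | (bact == 0), bact + pseudo, bact)
    ratios = pd.Series(num / den, index=phyla.sample_ids, name="fb_ratio")

    groups = md.groups.reindex(ratios.index)
    case = ratios[groups == "case"]
    ctrl = ratios[groups == "control"]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("need >= 2 samples per group for the F:B contrast")
    if test == "mannwhitney":
        p = float(stats.mannwhitneyu(case, ctrl, alternative="two-sided").pvalue)
    elif test == "ttest":
        p = float(stats.ttest_ind(case, ctrl, equal_var=False).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return FbRatioResult(
        ratios=ratios,
        case_mean=float(case.mean()), case_sd=float(case.std(ddof=1)),
        control_mean=float(ctrl.mean()), control_sd=float(ctrl.std(ddof=1)),
        p_value=p, test=test)
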