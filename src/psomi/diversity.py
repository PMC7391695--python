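"""Alpha and beta diversity: Chao1, rarefaction, UniFrac, PCoA, PERMANOVA.

UniFrac is computed by explicit branch accumulation: every branch of the
rooted phylogeny contributes its length weighted by how the two communities'
descendants differ through it (presence/absence for unweighted, proportion
difference for weighted).  PERMANOVA follows the pseudo-F sum-of-squares
partition of Anderson (2001) with label-permutation p-values, the test behind
the `adonis` convention in community ecology.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, ttest_ind
from skbio import TreeNode

from .core_io import AbundanceTable, SampleMetadata

__all__ = [
    "DistanceMatrix", "PermanovaResult", "OrdinationResult",
    "chao1", "rarefy", "unweighted_unifrac", "weighted_unifrac",
    "distance_matrix", "pcoa", "permanova", "compare_alpha", "METRICS",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample distances with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match "
                             f"{n} sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (np.diag(v) != 0).any():
            raise ValueError("distance matrix diagonal must be exactly zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class OrdinationResult:
    """Classical-scaling embedding: axes ordered by decreasing eigenvalue."""

    sample_ids: list[str]
    coordinates: np.ndarray        # samples × positive axes
    eigenvalues: np.ndarray        # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues only


# ---------------------------------------------------------------------------
# alpha diversity


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1−1) / (2(F2+1))."""
    c = np.asarray(counts)
    if c.size == 0 or (c < 0).any():
        raise ValueError("counts must be a non-empty non-negative vector")
    if not np.allclose(c, np.round(c)):
        raise ValueError("Chao1 requires integer counts")
    c = np.round(c).astype(np.int64)
    s_obs = int((c > 0).sum())
    if s_obs == 0:
        raise ValueError("Chao1 undefined for an all-zero sample")
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def rarefy(counts, depth: int, seed: int) -> np.ndarray:
    """Subsample reads without replacement to a fixed depth (seeded)."""
    c = np.asarray(counts)
    if (c < 0).any() or not np.allclose(c, np.round(c)):
        raise ValueError("rarefy requires non-negative integer counts")
    c = np.round(c).astype(np.int64)
    total = int(c.sum())
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth > total:
        raise ValueError(f"depth {depth} exceeds sample total {total}")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(c, depth).astype(np.int64)


# ---------------------------------------------------------------------------
# UniFrac


def _edge_structure(tree: TreeNode, taxon_ids: list[str]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and branch × taxon descendant incidence.

    Row e of the boolean matrix marks the taxa descending through branch e
    (the branch above each non-root node; a missing root-adjacent length is
    treated as 0 and still contributes its incidence row).
    """
    tip_index = {}
    for tip in tree.tips():
        if tip.name in tip_index:
            raise ValueError(f"duplicate tip label {tip.name!r}")
        tip_index[tip.name] = len(tip_index)
    missing = [t for t in taxon_ids if t not in tip_index]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    col = {t: j for j, t in enumerate(taxon_ids)}

    lengths: list[float] = []
    rows: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            mask = np.zeros(len(taxon_ids), dtype=bool)
            if node.name in col:
                mask[col[node.name]] = True
        else:
            mask = np.zeros(len(taxon_ids), dtype=bool)
            for child in node.children:
                mask |= below[id(child)]
        below[id(node)] = mask
        if node is not tree:
            lengths.append(float(node.length or 0.0))
            rows.append(mask)
    return np.array(lengths), np.array(rows)


def _as_vector(x, n: int, what: str) -> np.ndarray:
    v = np.asarray(x, float)
    if v.shape != (n,):
        raise ValueError(f"{what} must be a length-{n} vector")
    if (v < 0).any():
        raise ValueError(f"{what} contains negative abundances")
    return v


def unweighted_unifrac(tree: TreeNode, taxon_ids, a, b) -> float:
    """Fraction of branch length unique to either community's taxa.

    Presence-only: branch length leading exclusively to taxa of one sample,
    over branch length leading to taxa of either.  Lies in [0, 1].
    """
    taxon_ids = list(taxon_ids)
    lengths, inc = _edge_structure(tree, taxon_ids)
    av = _as_vector(a, len(taxon_ids), "sample a") > 0
    bv = _as_vector(b, len(taxon_ids), "sample b") > 0
    in_a = inc @ av > 0
    in_b = inc @ bv > 0
    union = float(lengths[in_a | in_b].sum())
    if union == 0.0:
        return 0.0
    shared = float(lengths[in_a & in_b].sum())
    return (union - shared) / union


def weighted_unifrac(tree: TreeNode, taxon_ids, a, b,
                     normalized: bool = False) -> float:
    """Σ_branches len · |A_e − B_e| over descendant proportion flows.

    Samples are converted to proportions internally.  With ``normalized``
    the raw distance is divided by its maximum attainable value on the tree,
    Σ len · (A_e + B_e), bounding it by 1.
    """
    taxon_ids = list(taxon_ids)
    lengths, inc = _edge_structure(tree, taxon_ids)
    av = _as_vector(a, len(taxon_ids), "sample a")
    bv = _as_vector(b, len(taxon_ids), "sample b")
    if av.sum() == 0 or bv.sum() == 0:
        raise ValueError("weighted UniFrac needs samples with nonzero totals")
    ap = av / av.sum()
    bp = bv / bv.sum()
    flow_a = inc @ ap
    flow_b = inc @ bp
    raw = float(lengths @ np.abs(flow_a - flow_b))
    if not normalized:
        return raw
    denom = float(lengths @ (flow_a + flow_b))
    return raw / denom if denom > 0 else 0.0


METRICS = ("unweighted_unifrac", "weighted_unifrac",
           "weighted_unifrac_normalized")


def distance_matrix(table: AbundanceTable, tree: TreeNode,
                    metric: str) -> DistanceMatrix:
    """All-pairs UniFrac over a table's samples (vectorized over branches)."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    taxon_ids = table.taxon_ids
    lengths, inc = _edge_structure(tree, taxon_ids)
    x = table.data.to_numpy(dtype=float)
    n = x.shape[1]
    if metric == "unweighted_unifrac":
        present = (inc.astype(float) @ (x > 0)) > 0      # branches × samples
        wl = present.T * lengths                          # samples × branches
        pb = present.astype(float)
        both = wl @ pb                                    # len of shared branches
        totals = wl.sum(axis=1)
        union = totals[:, None] + totals[None, :] - both
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(union > 0, (union - both) / union, 0.0)
    else:
        sums = x.sum(axis=0)
        if (sums == 0).any():
            bad = table.sample_ids[int(np.argmax(sums == 0))]
            raise ValueError(f"sample {bad!r} has zero total abundance")
        flows = inc.astype(float) @ (x / sums)            # branches × samples
        diffs = np.abs(flows[:, :, None] - flows[:, None, :])
        d = np.einsum("e,eij->ij", lengths, diffs)
        if metric == "weighted_unifrac_normalized":
            mass = lengths @ flows
            denom = mass[:, None] + mass[None, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                d = np.where(denom > 0, d / denom, 0.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(table.sample_ids, d)


# ---------------------------------------------------------------------------
# ordination


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Eigendecomposition of the Gower-centred −½D² matrix; axes with positive
    eigenvalue carry coordinates; negative eigenvalues (non-Euclidean
    distances) are reported but excluded from the proportion-explained
    denominator.
    """
    d = dm.values
    n = d.shape[0]
    if n < 2:
        raise ValueError("PCoA needs at least 2 samples")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    proportion = (eigvals[pos] / pos_sum) if pos_sum > 0 else eigvals[pos]
    return OrdinationResult(list(dm.sample_ids), coords, eigvals, proportion)


# ---------------------------------------------------------------------------
# PERMANOVA


def _ss_within(d2: np.ndarray, group_indices: list[np.ndarray]) -> float:
    ss = 0.0
    for idx in group_indices:
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss


def permanova(dm: DistanceMatrix, groups, n_permutations: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Permutational MANOVA pseudo-F with an add-one permutation p-value.

    ``groups`` maps each sample id to its group label (dict or Series).
    p = (1 + #{permuted F ≥ observed F}) / (1 + n_permutations).
    """
    labels = pd.Series(groups).reindex(dm.sample_ids)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])
        raise ValueError(f"groups missing for samples: {missing}")
    codes, uniques = pd.factorize(labels.to_numpy())
    k = len(uniques)
    if k < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [str(uniques[g]) for g in np.flatnonzero(sizes < 2)]
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    n = len(codes)
    d2 = dm.values ** 2
    ss_total = d2.sum() / (2.0 * n)

    def pseudo_f(assignment: np.ndarray) -> float:
        idx = [np.flatnonzero(assignment == g) for g in range(k)]
        ss_w = _ss_within(d2, idx)
        ss_a = ss_total - ss_w
        with np.errstate(divide="ignore"):   # ss_w = 0 -> F = inf
            return (ss_a / (k - 1)) / (ss_w / (n - k))

    f_obs = pseudo_f(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if pseudo_f(rng.permutation(codes)) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(p), n_permutations, seed)


# ---------------------------------------------------------------------------
# group comparison of alpha diversity


def compare_alpha(table: AbundanceTable, md: SampleMetadata,
                  groups: tuple[str, str] = ("case", "control"),
                  rarefaction_depth: int | None = None,
                  test: str = "mannwhitney", seed: int = 0,
                  column: str = "group") -> dict:
    """Per-sample Chao1 at a common rarefaction depth, compared across groups.

    Depth defaults to the cohort's minimum per-sample total.  The comparison
    test is two-sided Mann–Whitney U (``test="ttest"`` switches to Welch).
    Returns the per-sample richness values, the depth used and the p-value.
    """
    if table.is_relative:
        raise ValueError("alpha diversity requires a counts table")
    totals = table.data.sum(axis=0)
    depth = int(totals.min()) if rarefaction_depth is None else rarefaction_depth
    rich = {}
    for i, s in enumerate(table.sample_ids):
        sub = rarefy(table.data[s].to_numpy(), depth,
                     seed=(seed + i) % (2 ** 31))
        rich[s] = chao1(sub) if sub.sum() > 0 else 0.0
    rich = pd.Series(rich, name="chao1")
    col = md.frame[column]
    a = rich[col[col == groups[0]].index.intersection(rich.index)]
    b = rich[col[col == groups[1]].index.intersection(rich.index)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"need >= 2 samples per group {groups}")
    if test == "mannwhitney":
        p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
    elif test == "ttest":
        p = float(ttest_ind(a, b, equal_var=False).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {"chao1": rich, "depth": depth, "p_value": p,
            "groups": groups, "test": test}
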