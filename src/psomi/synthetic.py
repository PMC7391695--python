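"""Synthetic two-group stool 16S cohorts for pipeline testing and benchmarks.

Real psoriasis cohort data lives in sequence archives and cannot travel with a
test suite, so this module simulates genus-level count tables with the
statistical structure the downstream analysis assumes: per-sample genus
proportions drawn from a Dirichlet around group-specific means (case effects
applied as fold-changes on the control baseline), sequencing depth drawn
lognormally, and reads drawn multinomially.  A random bifurcating phylogeny
over the genera provides the UniFrac substrate.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_io import AbundanceTable, SampleMetadata, TaxonLineage

__all__ = [
    "SyntheticCohortConfig", "GroundTruth", "generate_cohort",
    "default_psoriasis_config", "generate_tree", "derive_seed",
]


def derive_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from one global seed (< 2**31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class GroundTruth:
    """Genera injected with a true group effect (the recoverable signature)."""

    increased_genera: frozenset[str] = frozenset()
    decreased_genera: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = self.increased_genera & self.decreased_genera
        if overlap:
            raise ValueError(f"genera in both directions: {sorted(overlap)}")


@dataclass
class SyntheticCohortConfig:
    """Dirichlet-multinomial cohort model.

    ``baseline_proportions`` are the control-group Dirichlet means per genus
    (must sum to 1); case means are ``baseline × effect_multipliers``
    renormalized.  ``concentration`` is the Dirichlet precision (larger →
    less sample-to-sample compositional scatter).  ``depth_mean``/``depth_sd``
    are the natural-scale mean and SD of the lognormal per-sample read depth.
    """

    n_cases: int
    n_controls: int
    baseline_proportions: dict[str, float]
    lineages: dict[str, TaxonLineage]
    effect_multipliers: dict[str, float] = field(default_factory=dict)
    concentration: float = 200.0
    depth_mean: float = 29873.0
    depth_sd: float = 6453.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 2:
            raise ValueError("n_cases must be >= 2")
        if self.n_controls < 2:
            raise ValueError("n_controls must be >= 2")
        if not self.baseline_proportions:
            raise ValueError("baseline_proportions is empty")
        props = np.array(list(self.baseline_proportions.values()), float)
        if (props <= 0).any():
            raise ValueError("baseline_proportions must be positive")
        if abs(props.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"baseline_proportions sum to {props.sum():.6f}, expected 1")
        unknown = set(self.effect_multipliers) - set(self.baseline_proportions)
        if unknown:
            raise ValueError(
                f"effect_multipliers name unknown genera: {sorted(unknown)}")
        if any(m <= 0 for m in self.effect_multipliers.values()):
            raise ValueError("effect_multipliers must be > 0")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.depth_mean <= 0 or self.depth_sd <= 0:
            raise ValueError("depth_mean and depth_sd must be > 0")
        missing = set(self.baseline_proportions) - set(self.lineages)
        if missing:
            raise ValueError(f"lineages missing for genera: {sorted(missing)}")

    def group_means(self) -> tuple[np.ndarray, np.ndarray]:
        """(control, case) Dirichlet mean vectors in baseline genus order."""
        genera = list(self.baseline_proportions)
        base = np.array([self.baseline_proportions[g] for g in genera])
        control = base / base.sum()
        mult = np.array([self.effect_multipliers.get(g, 1.0) for g in genera])
        case = base * mult
        case = case / case.sum()
        return control, case

    def ground_truth(self) -> GroundTruth:
        inc = frozenset(g for g, m in self.effect_multipliers.items() if m > 1)
        dec = frozenset(g for g, m in self.effect_multipliers.items() if m < 1)
        return GroundTruth(inc, dec)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_cohort(cfg: SyntheticCohortConfig
                    ) -> tuple[AbundanceTable, SampleMetadata, GroundTruth]:
    """Draw one cohort: counts table, metadata and the injected ground truth.

    Deterministic given ``cfg.seed``: per sample, genus proportions are
    Dirichlet(group mean × concentration), depth is a rounded lognormal
    draw (minimum 1 read), and counts are multinomial(depth, proportions).
    Cases are split roughly evenly into mild / moderate-to-severe strata.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genera = list(cfg.baseline_proportions)
    control_mean, case_mean = cfg.group_means()
    mu, sigma = _lognormal_params(cfg.depth_mean, cfg.depth_sd)

    sample_ids: list[str] = []
    groups: list[str] = []
    severities: list[str] = []
    columns = []
    specs = [("case", cfg.n_cases, case_mean),
             ("control", cfg.n_controls, control_mean)]
    for group, n, mean in specs:
        alpha = mean * cfg.concentration
        for i in range(n):
            p = rng.dirichlet(alpha)
            depth = max(1, int(round(rng.lognormal(mu, sigma))))
            counts = rng.multinomial(depth, p)
            sample_ids.append(f"{group}_{i + 1:03d}")
            groups.append(group)
            if group == "control":
                severities.append("not_applicable")
            else:
                severities.append("mild" if rng.random() < 0.5
                                  else "moderate_severe")
            columns.append(counts)

    data = pd.DataFrame(np.column_stack(columns).astype(np.int64),
                        index=pd.Index(genera, name="#taxon_id"),
                        columns=sample_ids)
    table = AbundanceTable(data, dict(cfg.lineages), is_relative=False)
    md = SampleMetadata(pd.DataFrame(
        {"group": groups, "severity": severities},
        index=pd.Index(sample_ids, name="sample_id")))
    return table, md, cfg.ground_truth()


# ---------------------------------------------------------------------------
# default psoriasis-like cohort

# Control-group genus baseline (sums to 1).  Phylum totals: Bacteroidetes
# 0.599, Firmicutes 0.330, Proteobacteria 0.042, Actinobacteria 0.008,
# Verrucomicrobia 0.014, Fusobacteria 0.007 — the composition reported for
# non-psoriasis stool communities this generator emulates.
_BASELINE: dict[str, tuple[str, float]] = {
    # genus: (phylum, control mean proportion)
    "Bacteroides": ("Bacteroidetes", 0.180),
    "Prevotella": ("Bacteroidetes", 0.200),
    "Paraprevotella": ("Bacteroidetes", 0.020),
    "Parabacteroides": ("Bacteroidetes", 0.090),
    "Alistipes": ("Bacteroidetes", 0.070),
    "Odoribacter": ("Bacteroidetes", 0.039),
    "Faecalibacterium": ("Firmicutes", 0.055),
    "Blautia": ("Firmicutes", 0.028),
    "Roseburia": ("Firmicutes", 0.040),
    "Ruminococcus": ("Firmicutes", 0.050),
    "Oscillospira": ("Firmicutes", 0.030),
    "Lachnospira": ("Firmicutes", 0.025),
    "Coprococcus": ("Firmicutes", 0.030),
    "Dialister": ("Firmicutes", 0.020),
    "Clostridium": ("Firmicutes", 0.022),
    "Streptococcus": ("Firmicutes", 0.030),
    "Sutterella": ("Proteobacteria", 0.020),
    "Escherichia": ("Proteobacteria", 0.012),
    "Desulfovibrio": ("Proteobacteria", 0.010),
    "Bifidobacterium": ("Actinobacteria", 0.006),
    "Collinsella": ("Actinobacteria", 0.002),
    "Akkermansia": ("Verrucomicrobia", 0.014),
    "Fusobacterium": ("Fusobacteria", 0.007),
}

# Case fold-changes on the Dirichlet mean: the four-genus dysbiosis
# signature (butyrate producers up, Bacteroidetes fermenters down).
_CASE_EFFECTS = {
    "Faecalibacterium": 2.5,
    "Blautia": 2.5,
    "Bacteroides": 0.4,
    "Paraprevotella": 0.4,
}


def default_psoriasis_config(seed: int, n_cases: int = 55,
                             n_controls: int = 27,
                             verrucomicrobia_case_multiplier: float = 1.0,
                             ) -> SyntheticCohortConfig:
    """Psoriasis-like cohort defaults.

    Controls carry ~59.9% Bacteroidetes / 33.0% Firmicutes across ~20 stool
    genera; cases double-and-a-half *Faecalibacterium* and *Blautia* and
    deplete *Bacteroides* and *Paraprevotella* to 0.4×, which shifts the
    case phylum balance to roughly 47/45 and raises the per-sample
    Firmicutes:Bacteroidetes ratio.  Depth matches ~29,873 ± 6,453 mapped
    reads per sample.  Set ``verrucomicrobia_case_multiplier`` below 1
    (e.g. 0.05) to additionally deplete *Akkermansia* in cases; it defaults
    to 1 so the injected signature is exactly the four-genus panel.
    """
    baseline = {g: p for g, (_, p) in _BASELINE.items()}
    lineages = {
        g: TaxonLineage(kingdom="Bacteria", phylum=ph, genus=g,
                        raw=f"k__Bacteria; p__{ph}; g__{g}")
        for g, (ph, _) in _BASELINE.items()
    }
    effects = dict(_CASE_EFFECTS)
    if verrucomicrobia_case_multiplier != 1.0:
        effects["Akkermansia"] = verrucomicrobia_case_multiplier
    return SyntheticCohortConfig(
        n_cases=n_cases, n_controls=n_controls,
        baseline_proportions=baseline, lineages=lineages,
        effect_multipliers=effects, concentration=200.0,
        depth_mean=29873.0, depth_sd=6453.0, seed=seed)


def generate_tree(taxon_ids, seed: int) -> TreeNode:
    """Random rooted bifurcating tree over ``taxon_ids``.

    Built by uniformly random pairwise joins with Exponential(1) branch
    lengths on every non-root branch; the root carries no branch.  For n
    taxa this yields n − 1 internal nodes and 2n − 2 branches.
    """
    taxon_ids = list(taxon_ids)
    if len(taxon_ids) < 2:
        raise ValueError("need at least 2 taxa to build a tree")
    if len(set(taxon_ids)) != len(taxon_ids):
        raise ValueError("duplicate taxon ids")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=t) for t in taxon_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = sorted((int(i), int(j)))
        right = nodes.pop(j)
        left = nodes.pop(i)
        left.length = float(rng.exponential(1.0))
        right.length = float(rng.exponential(1.0))
        parent = TreeNode(children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root
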