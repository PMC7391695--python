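"""Data model and flat-file formats for genus-level microbiome analysis.

The currency of the pipeline is the :class:`AbundanceTable` — a taxon-by-sample
matrix of read counts (or proportions) with a Greengenes-style lineage attached
to every taxon — plus :class:`SampleMetadata` for case/control status and
psoriasis severity, and a rooted phylogeny for UniFrac.  Tables and metadata
travel as TSV, trees as newick, so every artifact stays diff-able plain text.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
_PREFIX_RANK = {p[0]: i for i, p in enumerate(_PREFIXES)}
_PREFIX_RE = re.compile(r"^([kpcofgs])__(.*)$")

TAXON_COLUMN = "#taxon_id"
TAXONOMY_COLUMN = "taxonomy"


class FormatError(ValueError):
    """Malformed input file or table contents."""


@dataclass(frozen=True)
class TaxonLineage:
    """One taxon's rank-labelled classification, kingdom through species.

    Missing ranks are empty strings, never dropped, so the rank order is
    always explicit.  ``raw`` keeps the original lineage text verbatim so
    parsing round-trips.
    """

    kingdom: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""
    raw: str = ""

    def get(self, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return getattr(self, "class_" if rank == "class" else rank)

    def names(self) -> tuple[str, ...]:
        return (self.kingdom, self.phylum, self.class_, self.order,
                self.family, self.genus, self.species)

    def to_string(self) -> str:
        """Serialize in the prefixed Greengenes dialect (``k__X; p__Y; ...``).

        Emits ranks down to the deepest named one; fully empty lineages
        serialize as the bare kingdom prefix.
        """
        names = self.names()
        deepest = 0
        for i, name in enumerate(names):
            if name:
                deepest = i
        return "; ".join(_PREFIXES[i] + names[i] for i in range(deepest + 1))


def parse_taxonomy_string(s: str) -> TaxonLineage:
    """Parse a semicolon-separated lineage in prefixed or bare form.

    Both ``k__Bacteria; p__Firmicutes; ...`` (Greengenes 13_8) and
    ``Bacteria;Firmicutes;...`` are accepted; prefixed ranks out of the
    canonical kingdom→species order are rejected.
    """
    names = [""] * len(RANKS)
    last_rank = -1
    tokens = [tok.strip() for tok in s.split(";")]
    for tok in tokens:
        if tok == "" and last_rank == len(RANKS) - 1:
            continue  # tolerate a trailing separator
        m = _PREFIX_RE.match(tok)
        if m:
            rank = _PREFIX_RANK[m.group(1)]
            name = m.group(2).strip()
        else:
            rank = last_rank + 1
            name = tok
        if rank <= last_rank:
            raise FormatError(
                f"lineage ranks out of order in {s!r}: "
                f"{RANKS[rank]} after {RANKS[last_rank]}")
        if rank >= len(RANKS):
            raise FormatError(f"lineage {s!r} has more than {len(RANKS)} ranks")
        names[rank] = name
        last_rank = rank
    return TaxonLineage(kingdom=names[0], phylum=names[1], class_=names[2],
                        order=names[3], family=names[4], genus=names[5],
                        species=names[6], raw=s)


@dataclass
class AbundanceTable:
    """Taxon-by-sample abundance matrix with per-taxon lineages.

    ``data`` holds taxa as rows and samples as columns; values are
    non-negative read counts unless ``is_relative`` is set, in which case
    every sample column sums to one.
    """

    data: pd.DataFrame
    lineages: dict[str, TaxonLineage] = field(default_factory=dict)
    is_relative: bool = False

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon ids: {dupes}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise FormatError("abundance values must be numeric")
        if values.size and (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative abundance at taxon {idx[r]!r}, sample {cols[c]!r}")
        missing = [t for t in idx if t not in self.lineages]
        if missing:
            # tables may arrive without a taxonomy column; every taxon still
            # gets an explicit (empty) lineage entry
            for t in missing:
                self.lineages[t] = TaxonLineage(raw="")
        if self.is_relative and values.size:
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = cols[np.argmax(np.abs(sums - 1.0))]
                raise FormatError(
                    f"proportions for sample {bad!r} do not sum to 1")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return AbundanceTable(self.data.loc[:, list(sample_ids)].copy(),
                              dict(self.lineages), self.is_relative)


GROUPS = ("case", "control")
SEVERITIES = ("mild", "moderate_severe", "not_applicable")
METADATA_COLUMNS = ("sample_id", "group", "severity")


@dataclass
class SampleMetadata:
    """Per-sample case/control status, severity stratum and covariates.

    Severity is ``not_applicable`` exactly for controls; cases are ``mild``
    or ``moderate_severe`` (BSA/PASI/IGA-defined strata).
    """

    frame: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        f = self.frame
        if f.index.has_duplicates:
            dupes = f.index[f.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids in metadata: {dupes}")
        for col in ("group", "severity"):
            if col not in f.columns:
                raise FormatError(f"metadata missing required column {col!r}")
        bad = set(f["group"]) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")
        bad = set(f["severity"]) - set(SEVERITIES)
        if bad:
            raise FormatError(f"unknown severity labels: {sorted(bad)}")
        ctrl = f["group"] == "control"
        na = f["severity"] == "not_applicable"
        if (ctrl != na).any():
            offender = f.index[(ctrl != na)][0]
            raise FormatError(
                f"sample {offender!r}: severity must be not_applicable "
                "iff group is control")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def groups(self) -> pd.Series:
        return self.frame["group"]

    def ids_in_group(self, group: str) -> list[str]:
        return list(self.frame.index[self.frame["group"] == group])

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)].copy())


# ---------------------------------------------------------------------------
# readers / writers


def read_abundance_table(path) -> AbundanceTable:
    """Read a taxon × sample TSV (counts; optional trailing taxonomy column)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    # pandas de-duplicates repeated headers silently; check the raw line
    seen: set[str] = set()
    for h in header:
        if h in seen:
            raise FormatError(f"duplicated column header {h!r}")
        seen.add(h)
    raw = pd.read_csv(path, sep="\t", header=None, names=header, skiprows=1,
                      dtype=str, keep_default_na=False)
    if header[0] != TAXON_COLUMN:
        raise FormatError(
            f"first column must be {TAXON_COLUMN!r}, got {header[0]!r}")
    has_tax = header[-1] == TAXONOMY_COLUMN
    sample_cols = header[1:-1] if has_tax else header[1:]
    if not sample_cols:
        raise FormatError("table has no sample columns")
    taxa = raw[TAXON_COLUMN].tolist()
    values = np.empty((len(taxa), len(sample_cols)))
    for j, col in enumerate(sample_cols):
        for i, cell in enumerate(raw[col]):
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(
                    f"non-numeric value {cell!r} at taxon {taxa[i]!r}, "
                    f"sample {col!r}") from None
            if v < 0:
                raise FormatError(
                    f"negative value at taxon {taxa[i]!r}, sample {col!r}")
            values[i, j] = v
    if np.allclose(values, np.round(values)):
        values = np.round(values).astype(np.int64)
    data = pd.DataFrame(values, index=pd.Index(taxa, name=TAXON_COLUMN),
                        columns=sample_cols)
    lineages = {}
    if has_tax:
        lineages = {t: parse_taxonomy_string(s)
                    for t, s in zip(taxa, raw[TAXONOMY_COLUMN])}
    return AbundanceTable(data, lineages, is_relative=False)


def write_abundance_table(table: AbundanceTable, path) -> None:
    out = table.data.copy()
    out.index.name = TAXON_COLUMN
    out[TAXONOMY_COLUMN] = [table.lineages[t].to_string()
                            for t in table.taxon_ids]
    out.to_csv(path, sep="\t")


def read_sample_metadata(path) -> SampleMetadata:
    f = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in METADATA_COLUMNS:
        if col not in f.columns:
            raise FormatError(f"metadata missing required column {col!r}")
    return SampleMetadata(f.set_index("sample_id"))


def write_sample_metadata(md: SampleMetadata, path) -> None:
    md.frame.to_csv(path, sep="\t", index_label="sample_id")


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    validate_tree(tree)
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def validate_tree(tree: TreeNode) -> None:
    """Check UniFrac preconditions: unique tips, finite non-negative lengths."""
    names = [tip.name for tip in tree.tips()]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"duplicate tip labels: {dupes}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            continue
        if not np.isfinite(node.length) or node.length < 0:
            raise FormatError(
                f"invalid branch length {node.length!r} at {node.name!r}")


# ---------------------------------------------------------------------------
# table-level transforms


def filter_low_confidence(table: AbundanceTable, min_fraction: float = 0.001
                          ) -> tuple[AbundanceTable, list[str]]:
    """Drop low-confidence taxa carrying < ``min_fraction`` of all reads.

    A taxon is removed when its total count across the whole cohort is
    strictly below ``min_fraction`` times the grand total (default 0.1% —
    the usual low-confidence OTU cut); a taxon sitting exactly on the
    boundary is kept.  Returns the filtered table and the dropped ids.
    """
    if table.is_relative:
        raise ValueError("filter_low_confidence expects a counts table")
    if table.data.empty:
        raise ValueError("cannot filter an empty table")
    totals = table.data.sum(axis=1)
    grand = float(totals.sum())
    keep = totals >= min_fraction * grand
    dropped = list(table.data.index[~keep])
    if not keep.any():
        raise ValueError(
            "all taxa fall below the low-confidence threshold; empty result")
    kept = table.data.loc[keep].copy()
    lineages = {t: table.lineages[t] for t in kept.index}
    return AbundanceTable(kept, lineages, is_relative=False), dropped


def _collapse_key(lineage: TaxonLineage, rank: str) -> tuple[str, TaxonLineage]:
    """Name and lineage for the collapsed bin a taxon falls into at ``rank``."""
    rank_i = RANKS.index(rank)
    name = lineage.get(rank)
    names = list(lineage.names())
    if name:
        kept = names[:rank_i + 1] + [""] * (len(RANKS) - rank_i - 1)
        return name, TaxonLineage(*kept)
    # unclassified at this rank: pool under the nearest named ancestor so
    # bins stay unambiguous (no single global "unclassified" bucket)
    parent_i = None
    for i in range(rank_i - 1, -1, -1):
        if names[i]:
            parent_i = i
            break
    if parent_i is None:
        return "unclassified_root", TaxonLineage()
    kept = names[:parent_i + 1] + [""] * (len(RANKS) - parent_i - 1)
    key = f"unclassified_{RANKS[parent_i]}_{names[parent_i]}"
    return key, TaxonLineage(*kept)


def collapse_to_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum abundances over taxa sharing the named rank.

    Per-sample totals are conserved exactly (integer arithmetic on counts);
    taxa unnamed at ``rank`` are pooled per nearest named ancestor, e.g.
    ``unclassified_family_Ruminococcaceae``.  Idempotent at a fixed rank.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    keys: list[str] = []
    bin_lineages: dict[str, TaxonLineage] = {}
    for t in table.taxon_ids:
        key, lin = _collapse_key(table.lineages[t], rank)
        keys.append(key)
        bin_lineages.setdefault(key, lin)
    grouped = table.data.groupby(pd.Index(keys, name=TAXON_COLUMN),
                                 sort=False).sum()
    return AbundanceTable(grouped, bin_lineages, table.is_relative)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample column by its total; idempotent on proportions."""
    sums = table.data.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total abundance")
    rel = table.data.astype(float) / sums
    return AbundanceTable(rel, dict(table.lineages), is_relative=True)


__all__ = [
    "RANKS", "TaxonLineage", "AbundanceTable", "SampleMetadata", "FormatError",
    "parse_taxonomy_string", "read_abundance_table", "write_abundance_table",
    "read_sample_metadata", "write_sample_metadata", "read_tree", "write_tree",
    "validate_tree", "filter_low_confidence", "collapse_to_rank", "to_relative",
]
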