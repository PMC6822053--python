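"""Reading, writing and validation of the pipeline's external formats.

All species identifiers are normalized to canonical binomial form
("Genus epithet", single spaces) so that abundance tables, trait tables
and phylogenies from different sources can be aligned by name.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_species_name",
    "AbundanceMatrix",
    "TraitTable",
    "TreeSet",
    "read_abundance",
    "write_abundance",
    "read_traits",
    "write_traits",
    "read_trees",
    "write_trees",
    "write_results",
    "load_function_score_fixture",
]


def normalize_species_name(name: str) -> str:
    """Canonicalize a species label to "Genus epithet [subspecies]" form.

    Underscores become spaces, runs of whitespace collapse to one space,
    the genus is capitalized and all following tokens lower-cased.
    Idempotent; raises ValueError on an empty label.
    """
    if name is None:
        raise ValueError("species name is missing")
    tokens = str(name).replace("_", " ").split()
    if not tokens:
        raise ValueError(f"empty species name: {name!r}")
    tokens = [tokens[0].capitalize()] + [t.lower() for t in tokens[1:]]
    return " ".join(tokens)


def _normalize_index(index) -> list[str]:
    return [normalize_species_name(s) for s in index]


@dataclass
class AbundanceMatrix:
    """Species x year table of standardized log abundance indices.

    ``data`` holds one row per species (canonical name index) and one
    column per consecutive calendar year; missing species-year cells are
    NaN.  Validation enforces the contract the downstream stages assume:
    consecutive years, at least 2 species and 3 years, and at least two
    observations per species.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = _normalize_index(df.index)
        df.index.name = "species"
        df.columns = [int(c) for c in df.columns]
        dup = df.index[df.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate species rows: {dup}")
        years = list(df.columns)
        if len(years) < 3:
            raise ValueError(f"need at least 3 year columns, got {len(years)}")
        if any(b - a != 1 for a, b in zip(years, years[1:])):
            raise ValueError(f"year columns must be consecutive: {years}")
        if len(df) < 2:
            raise ValueError("need at least 2 species")
        df = df.astype(float)
        n_obs = df.notna().sum(axis=1)
        bad = n_obs[n_obs < 2].index.tolist()
        if bad:
            raise ValueError(f"species with fewer than 2 observations: {bad}")
        self.data = df

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def years(self) -> list[int]:
        return list(self.data.columns)

    @property
    def missing(self) -> pd.DataFrame:
        return self.data.isna()


@dataclass
class TraitTable:
    """Per-species trait inputs for the production functions.

    ``traits`` columns: O (occupied 10-km squares), A (mean survey count),
    L (larval length, mm), M (mobility index), Y (mean public-survey
    count; NaN means the species is outside the published top list and
    scores zero cultural function).  ``visits`` is a species x plant-family
    0/1 matrix of flower-visitation records.
    """

    traits: pd.DataFrame
    visits: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        t = self.traits.copy()
        t.index = _normalize_index(t.index)
        t.index.name = "species"
        for col in ("O", "A"):
            if col not in t.columns:
                raise ValueError(f"trait table is missing mandatory column {col!r}")
        for col in ("L", "M", "Y"):
            if col not in t.columns:
                t[col] = np.nan
        t = t[["O", "A", "L", "M", "Y"]].astype(float)
        for col in ("O", "A", "Y"):
            vals = t[col].dropna()
            if (vals < 0).any():
                raise ValueError(f"column {col!r} has negative entries")
        v = self.visits.copy() if len(self.visits) else pd.DataFrame(index=t.index)
        if len(v):
            v.index = _normalize_index(v.index)
            v = v.reindex(t.index)
            if any(not str(c).strip() for c in v.columns):
                raise ValueError("empty plant family name in visitation columns")
            v = v.fillna(0).astype(int)
            if not v.isin([0, 1]).all().all():
                raise ValueError("visitation flags must be 0 or 1")
        self.traits, self.visits = t, v

    @property
    def species(self) -> list[str]:
        return list(self.traits.index)

    @property
    def families(self) -> list[str]:
        return list(self.visits.columns)


@dataclass
class TreeSet:
    """A collection of rooted trees over one shared taxon set."""

    trees: dendropy.TreeList

    def __post_init__(self) -> None:
        if len(self.trees) == 0:
            raise ValueError("tree set is empty")
        ref = None
        for i, tree in enumerate(self.trees):
            taxa = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
            if len(taxa) < 3:
                raise ValueError(f"tree {i} has fewer than 3 taxa")
            for edge in tree.preorder_edge_iter():
                if edge.length is not None and edge.length < 0:
                    raise ValueError(f"tree {i} has a negative branch length")
            if ref is None:
                ref = taxa
            elif taxa != ref:
                extra = sorted(taxa - ref)
                missing = sorted(ref - taxa)
                raise ValueError(
                    f"tree {i} taxon set differs from tree 0: "
                    f"extra={extra}, missing={missing}"
                )

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def taxa(self) -> list[str]:
        return sorted(leaf.taxon.label for leaf in self.trees[0].leaf_node_iter())


# ---------------------------------------------------------------------------
# readers / writers


def read_abundance(path: str | Path) -> AbundanceMatrix:
    """Read a species x year abundance CSV (first column = species).

    Blank cells and "NA" are missing.  Year columns must be consecutive.
    """
    df = pd.read_csv(path, index_col=0, na_values=["NA", ""])
    raw_names = [normalize_species_name(s) for s in df.index]
    seen: dict[str, int] = {}
    for name in raw_names:
        seen[name] = seen.get(name, 0) + 1
    dups = [n for n, k in seen.items() if k > 1]
    if dups:
        raise ValueError(f"duplicate species rows in {path}: {dups}")
    try:
        df.columns = [int(c) for c in df.columns]
    except ValueError as exc:
        raise ValueError(f"non-integer year column in {path}: {exc}") from exc
    non_numeric = df.map(lambda v: isinstance(v, str))
    if non_numeric.any().any():
        rows = df.index[non_numeric.any(axis=1)].tolist()
        raise ValueError(f"non-numeric abundance cells for species {rows} in {path}")
    return AbundanceMatrix(df)


def write_abundance(abund: AbundanceMatrix, path: str | Path) -> None:
    abund.data.to_csv(path, na_rep="")


def read_traits(path: str | Path) -> TraitTable:
    """Read a trait CSV with columns O, A, [L, M, Y] and X_<family> flags."""
    df = pd.read_csv(path, index_col=0, na_values=["NA", ""])
    visit_cols = [c for c in df.columns if str(c).startswith("X_")]
    visits = df[visit_cols].rename(columns=lambda c: str(c)[2:])
    traits = df.drop(columns=visit_cols)
    return TraitTable(traits=traits, visits=visits)


def write_traits(table: TraitTable, path: str | Path) -> None:
    out = table.traits.copy()
    for fam in table.families:
        out[f"X_{fam}"] = table.visits[fam]
    out.to_csv(path, na_rep="")


def read_trees(path: str | Path) -> TreeSet:
    """Read a multi-tree Newick file (one tree per line).

    Unquoted underscores in labels are read as spaces (standard Newick
    convention) and labels are normalized to canonical binomials.
    """
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    if len(trees) == 0:
        raise ValueError(f"no trees parsed from {path}")
    for taxon in trees.taxon_namespace:
        taxon.label = normalize_species_name(taxon.label)
    return TreeSet(trees)


def write_trees(treeset: TreeSet, path: str | Path) -> None:
    treeset.trees.write(path=str(path), schema="newick", suppress_rooting=True)


def write_results(
    mantel_table: pd.DataFrame | None,
    guild_table: pd.DataFrame | None,
    out_dir: str | Path,
    prefix: str = "",
) -> dict[str, Path]:
    """Write results tables as TSV plus a JSON mirror.

    ``mantel_table`` is the matrix-association summary (matrix1, matrix2,
    mantel_r, p_value, ci_lower, ci_upper); ``guild_table`` the species x
    resolution guild labels.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    core_cols = [
        "matrix1", "matrix2", "mantel_r", "p_value", "ci_lower", "ci_upper"
    ]
    if mantel_table is not None:
        p = out_dir / f"{prefix}mantel_tests.tsv"
        cols = [c for c in core_cols if c in mantel_table.columns]
        mantel_table[cols].to_csv(p, sep="\t", index=False, na_rep="NA")
        written["mantel_tsv"] = p
        pj = out_dir / f"{prefix}mantel_tests.json"
        pj.write_text(json.dumps(mantel_table.to_dict(orient="records"), indent=1))
        written["mantel_json"] = pj
    if guild_table is not None:
        p = out_dir / f"{prefix}guilds.tsv"
        guild_table.to_csv(p, sep="\t", na_rep="NA")
        written["guilds_tsv"] = p
    return written


def load_function_score_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the published standardized UK butterfly function scores.

    Returns ``(scores, qualifiers)``: scores has columns biomass,
    cultural, pollination, p_brassicaceae, p_caryophyllaceae with NaN for
    unpublished cells; qualifiers holds "" (exact), "lt" (printed as
    below 0.001), "gt" (printed as above 0.001) or "na".  Cells flagged
    lt/gt carry the placeholder 0.0005 — only their sign is meaningful.
    """
    ref = importlib.resources.files("responseguilds.data").joinpath(
        "uk_butterfly_function_scores.csv"
    )
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, index_col=0, keep_default_na=False, na_values=[""])
    df.index = _normalize_index(df.index)
    score_cols = [c for c in df.columns if not c.endswith("_qual")]
    scores = df[score_cols].astype(float)
    quals = pd.DataFrame(index=df.index)
    quals["biomass"] = df["biomass_qual"]
    quals["pollination"] = df["pollination_qual"]
    quals["p_brassicaceae"] = df["p_brassicaceae_qual"]
    quals["p_caryophyllaceae"] = df["p_caryophyllaceae_qual"]
    quals = quals.fillna("")
    return scores, quals


def align_species(
    *objects: pd.DataFrame, min_overlap: int = 3
) -> list[pd.DataFrame]:
    """Trim index-aligned tables to their sorted common species set."""
    common: set[str] | None = None
    for obj in objects:
        names = set(obj.index)
        common = names if common is None else common & names
    assert common is not None
    shared = sorted(common)
    if len(shared) < min_overlap:
        raise ValueError(
            f"only {len(shared)} species shared across inputs "
            f"(need >= {min_overlap})"
        )
    for obj in objects:
        dropped = sorted(set(obj.index) - common)
        if dropped:
            warnings.warn(f"dropping {len(dropped)} unmatched species: {dropped}")
    return [obj.loc[shared] for obj in objects]
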