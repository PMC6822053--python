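"""Production functions: per-species proxies of ecosystem-function roles.

Each score combines trait data multiplicatively and is normalized by the
community-wide maximum, so every defined score lies in [0, 1] and the
top-contributing species scores exactly 1:

    D   = O*A / max(O*A)      relative national density
    B   = D*L / max(D*L)      larval biomass (food provision)
    P   = D*M / max(D*M)      general wildflower pollination
    P_x = D*M*X / max(D*M*X)  pollination of plant family x (X is 0/1)
    C   = Y / max(Y)          aesthetic cultural function (top-N survey
                              species; all others score 0)

Missing required inputs (L for B; M for P, P_x) make the score missing,
never zero: zero is reserved for true zeros such as X = 0 or a species
outside the public-survey top list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import TraitTable

__all__ = [
    "density_index",
    "biomass_index",
    "pollination_index",
    "family_pollination_index",
    "cultural_index",
    "compute_function_scores",
    "function_distance",
    "FunctionDistanceMatrix",
]


def _normalize_by_max(raw: pd.Series, what: str) -> pd.Series:
    defined = raw.dropna()
    if defined.empty or (m := defined.max()) <= 0:
        raise ValueError(f"cannot normalize {what}: no positive values")
    return raw / m


def density_index(traits: TraitTable) -> pd.Series:
    """Relative national density D = O*A / max(O*A)."""
    t = traits.traits
    if t["O"].isna().any() or t["A"].isna().any():
        missing = t.index[t["O"].isna() | t["A"].isna()].tolist()
        raise ValueError(f"O and A are mandatory; missing for {missing}")
    return _normalize_by_max(t["O"] * t["A"], "density (O*A)").rename("D")


def biomass_index(traits: TraitTable, D: pd.Series | None = None) -> pd.Series:
    """Larval biomass B = D*L / max(D*L); missing where L is unavailable."""
    if D is None:
        D = density_index(traits)
    raw = D * traits.traits["L"]
    return _normalize_by_max(raw, "biomass (D*L)").rename("B")


def pollination_index(traits: TraitTable, D: pd.Series | None = None) -> pd.Series:
    """General pollination P = D*M / max(D*M); missing where M is."""
    if D is None:
        D = density_index(traits)
    raw = D * traits.traits["M"]
    return _normalize_by_max(raw, "pollination (D*M)").rename("P")


def family_pollination_index(
    traits: TraitTable, family: str, D: pd.Series | None = None
) -> pd.Series:
    """Per-family pollination P_x = D*M*X / max(D*M*X) with X in {0,1}.

    Non-visitors (X = 0) score exactly 0; species with missing mobility
    are missing.  The denominator is the family-specific maximum over
    species with complete inputs.
    """
    if family not in traits.families:
        raise KeyError(f"no visitation column for family {family!r}")
    if D is None:
        D = density_index(traits)
    X = traits.visits[family].astype(float)
    raw = D * traits.traits["M"] * X
    defined = raw.dropna()
    if defined.empty or defined.max() <= 0:
        raise ValueError(
            f"family {family!r} has no visiting species with defined D*M; "
            "P_x is undefined for all species"
        )
    return (raw / defined.max()).rename(f"P_{family}")


def cultural_index(traits: TraitTable, top_n: int = 18) -> pd.Series:
    """Cultural function C = Y / max(Y) over the public-survey top-N.

    Species without a survey count Y (or outside the top N) have
    negligible public visibility and score exactly 0.
    """
    Y = traits.traits["Y"]
    scored = Y.dropna()
    if scored.empty:
        raise ValueError("no species has a public-survey count Y")
    if len(scored) > top_n:
        warnings.warn(
            f"{len(scored)} species have survey counts; keeping the top "
            f"{top_n} and zeroing the rest"
        )
        scored = scored.nlargest(top_n)
    C = pd.Series(0.0, index=Y.index, name="C")
    C[scored.index] = scored / scored.max()
    return C


def compute_function_scores(
    traits: TraitTable,
    families: list[str] | None = None,
    top_n: int = 18,
) -> pd.DataFrame:
    """All production-function scores as one species x score table.

    Columns: D, B, P, C and one ``P_<family>`` per requested plant
    family (default: every family in the visitation table).
    """
    D = density_index(traits)
    out = pd.DataFrame({"D": D})
    out["B"] = biomass_index(traits, D)
    out["P"] = pollination_index(traits, D)
    out["C"] = cultural_index(traits, top_n=top_n)
    for fam in families if families is not None else traits.families:
        out[f"P_{fam}"] = family_pollination_index(traits, fam, D)
    return out


@dataclass
class FunctionDistanceMatrix:
    """Absolute differences of z-scored function values.

    Built from one score vector: values are scaled to zero mean and unit
    variance over the species with a defined score, and f[i, j] =
    |z_i - z_j| (for a single score this is the Euclidean distance).
    Species with missing scores are excluded and listed.
    """

    f: pd.DataFrame
    excluded: list[str]

    @property
    def species(self) -> list[str]:
        return list(self.f.index)


def function_distance(scores: pd.Series) -> FunctionDistanceMatrix:
    """Pairwise |z_i - z_j| matrix for one function-score vector."""
    defined = scores.dropna()
    excluded = sorted(set(scores.index) - set(defined.index))
    if len(defined) < 3:
        raise ValueError(
            f"need >= 3 species with defined scores, have {len(defined)}"
        )
    sd = defined.std(ddof=1)
    if sd == 0:
        raise ValueError("scores have zero variance; distances undefined")
    z = (defined - defined.mean()) / sd
    vals = np.abs(z.to_numpy()[:, None] - z.to_numpy()[None, :])
    f = pd.DataFrame(vals, index=defined.index, columns=defined.index)
    return FunctionDistanceMatrix(f=f, excluded=excluded)
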