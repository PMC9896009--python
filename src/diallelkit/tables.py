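"""Long-format phenotype tables and stage-1 entry-mean containers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

PHENO_COLUMNS = ["environment", "replicate", "block", "entry", "trait", "value"]


@dataclass(frozen=True)
class TraitMeta:
    """Scale and selection direction of a trait.

    ``scale`` is ``'continuous'`` or ``'ordinal'``; ordinal traits (visual
    1-9 damage/disease ratings) carry integer ``bounds``.  ``direction`` says
    whether larger values are desirable (``'higher'``, e.g. grain yield) or
    smaller ones are (``'lower'``, e.g. foliar damage scores).
    """

    scale: str = "continuous"
    direction: str = "higher"
    bounds: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.scale not in ("continuous", "ordinal"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.direction not in ("higher", "lower"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.scale == "ordinal" and self.bounds is None:
            object.__setattr__(self, "bounds", (1.0, 9.0))

    @property
    def is_ordinal(self) -> bool:
        return self.scale == "ordinal"


@dataclass
class PhenotypeTable:
    """Long-format plot observations plus per-trait metadata.

    ``data`` holds one row per plot x trait with columns
    ``environment, replicate, block, entry, trait, value`` and an optional
    boolean ``outlier`` column set by the screening step.  The key
    ``(environment, replicate, entry, trait)`` must be unique.
    """

    data: pd.DataFrame
    trait_meta: dict[str, TraitMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in PHENO_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns: {missing}")
        key = ["environment", "replicate", "entry", "trait"]
        if self.data.duplicated(subset=key).any():
            dup = self.data[self.data.duplicated(subset=key, keep=False)]
            raise ValueError(
                f"duplicated (environment, replicate, entry, trait) keys:\n"
                f"{dup[key].head()}")
        for trait, meta in self.trait_meta.items():
            if meta.is_ordinal:
                vals = self.data.loc[self.data["trait"] == trait, "value"].dropna()
                lo, hi = meta.bounds
                if len(vals) and ((vals < lo) | (vals > hi)).any():
                    raise ValueError(
                        f"ordinal trait {trait!r} has values outside {meta.bounds}")

    @property
    def clean(self) -> pd.DataFrame:
        """Rows not flagged as outliers (all rows if screening never ran)."""
        if "outlier" in self.data.columns:
            return self.data[~self.data["outlier"].astype(bool)]
        return self.data

    def environments(self) -> list[str]:
        return sorted(self.data["environment"].unique())

    def entries(self) -> list[str]:
        return sorted(self.data["entry"].unique())

    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    def meta(self, trait: str) -> TraitMeta:
        return self.trait_meta.get(trait, TraitMeta())


@dataclass
class EntryMeans:
    """Stage-1 output: per-environment and across-environment entry means.

    ``per_env`` maps environment -> (entry x trait) matrix of BLUEs;
    ``across`` is the across-environment entry x trait matrix (BLUEs or
    BLUPs depending on how the stage was run).  ``pooled_error_ms`` is the
    replication-weighted plot-level residual mean square per trait; with
    ``n_reps`` and ``n_envs`` it supplies the entry-mean error used by the
    combining-ability F-tests and the heritability denominator.
    """

    per_env: dict[str, pd.DataFrame]
    across: pd.DataFrame
    pooled_error_ms: dict[str, float]
    pooled_error_df: dict[str, float]
    n_reps: int
    n_envs: int
    trait_meta: dict[str, TraitMeta] = field(default_factory=dict)
    across_varcomp: dict[str, dict[str, float]] = field(default_factory=dict)
    entry_effect: str = "fixed"

    def __post_init__(self) -> None:
        for trait, ms in self.pooled_error_ms.items():
            if ms < 0:
                raise ValueError(f"negative pooled error MS for {trait!r}")
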