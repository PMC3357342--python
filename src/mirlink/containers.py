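"""Core in-memory containers for paired mRNA/miRNA expression analysis.

All downstream stages (preprocessing, differential expression, enrichment,
integration, network overlay) consume and produce these types.  Identifier
namespaces are caller-supplied strings and matching is case-sensitive
throughout: silent case-folding creates false joins between probe, gene and
miRNA namespaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "FeatureKind",
    "ExpressionMatrix",
    "GroupDesign",
    "GeneSet",
    "GeneSetCollection",
    "TargetMap",
    "InteractionTable",
    "DERecord",
    "CollapseMap",
]


class FeatureKind(str, Enum):
    """What the rows of an :class:`ExpressionMatrix` represent."""

    MRNA_PROBE = "mrna_probe"
    GENE = "gene"
    MIRNA = "mirna"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID: {i!r}")
        seen.add(i)


class ExpressionMatrix:
    """Log2 background-subtracted intensities, features x samples.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are features, columns are samples, entries are log2 intensities.
        Entries may be NaN only where ``detected`` is False.
    feature_kind : FeatureKind or str
        Namespace of the row identifiers (mRNA probe, gene, or miRNA).
    detected : pandas.DataFrame, optional
        Boolean detection-call matrix with the same index/columns.  A probe
        called undetected on an array may carry a NaN intensity.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        feature_kind: FeatureKind | str,
        detected: Optional[pd.DataFrame] = None,
    ):
        if not isinstance(values, pd.DataFrame):
            values = pd.DataFrame(values)
        _check_unique(list(values.index), "feature")
        _check_unique(list(values.columns), "sample")
        values = values.astype(float)
        self.values = values
        self.feature_kind = FeatureKind(feature_kind)
        if detected is not None:
            if detected.shape != values.shape:
                raise ValueError(
                    f"detected shape {detected.shape} != values shape {values.shape}"
                )
            if list(detected.index) != list(values.index) or list(
                detected.columns
            ) != list(values.columns):
                raise ValueError("detected index/columns must match values")
            detected = detected.astype(bool)
            bad = values.isna().to_numpy() & detected.to_numpy()
            if bad.any():
                raise ValueError("values must be finite wherever detected is True")
        else:
            if values.isna().any().any():
                raise ValueError(
                    "NaN values require a detection matrix marking them undetected"
                )
        self.detected = detected

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, keep: Sequence[str]) -> "ExpressionMatrix":
        """Row subset preserving the given order."""
        det = self.detected.loc[list(keep)] if self.detected is not None else None
        return ExpressionMatrix(self.values.loc[list(keep)], self.feature_kind, det)

    def drop_samples(self, drop: Sequence[str]) -> "ExpressionMatrix":
        """Remove sample columns (e.g. an array failing hybridization QC)."""
        missing = [s for s in drop if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not present: {missing}")
        keep = [s for s in self.sample_ids if s not in set(drop)]
        det = self.detected[keep] if self.detected is not None else None
        return ExpressionMatrix(self.values[keep], self.feature_kind, det)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.feature_kind.value}, "
            f"{self.n_features} features x {self.n_samples} samples)"
        )


EXPOSURE = "exposure"
CONTROL = "control"


@dataclass(frozen=True)
class GroupDesign:
    """Two-group sample assignment (exposure vs control).

    Every sample belongs to exactly one group and both groups are non-empty.
    """

    assignment: Mapping[str, str]

    def __post_init__(self):
        groups = set(self.assignment.values())
        if not groups <= {EXPOSURE, CONTROL}:
            raise ValueError(f"groups must be {{'exposure','control'}}, got {groups}")
        if EXPOSURE not in groups or CONTROL not in groups:
            raise ValueError("both exposure and control groups must be non-empty")
        object.__setattr__(self, "assignment", dict(self.assignment))

    @classmethod
    def from_samples(
        cls, exposure: Sequence[str], control: Sequence[str]
    ) -> "GroupDesign":
        overlap = set(exposure) & set(control)
        if overlap:
            raise ValueError(f"samples in both groups: {sorted(overlap)}")
        d = {s: EXPOSURE for s in exposure}
        d.update({s: CONTROL for s in control})
        return cls(d)

    @property
    def exposure_samples(self) -> List[str]:
        return [s for s, g in self.assignment.items() if g == EXPOSURE]

    @property
    def control_samples(self) -> List[str]:
        return [s for s, g in self.assignment.items() if g == CONTROL]

    def restrict(self, samples: Sequence[str]) -> "GroupDesign":
        sub = {s: self.assignment[s] for s in samples if s in self.assignment}
        return GroupDesign(sub)

    def swap(self) -> "GroupDesign":
        flip = {EXPOSURE: CONTROL, CONTROL: EXPOSURE}
        return GroupDesign({s: flip[g] for s, g in self.assignment.items()})


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: FrozenSet[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))


class GeneSetCollection:
    """Named, non-empty gene sets (a GMT collection in memory)."""

    def __init__(self, sets: Sequence[GeneSet]):
        self._sets: Dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self._sets:
                raise ValueError(f"duplicate gene set name: {s.name!r}")
            self._sets[s.name] = s

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> List[str]:
        return list(self._sets)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneSetCollection({len(self)} sets)"


class TargetMap:
    """miRNA -> predicted target genes (miRanda/MicroCosm-style table as data).

    Empty target sets are not stored; gene IDs share the namespace of the
    gene-level expression matrix.
    """

    def __init__(self, targets: Mapping[str, Sequence[str]]):
        self.targets: Dict[str, FrozenSet[str]] = {}
        for mirna, genes in targets.items():
            fs = frozenset(genes)
            if not fs:
                raise ValueError(f"empty target set for {mirna!r}")
            self.targets[mirna] = fs

    def __contains__(self, mirna: str) -> bool:
        return mirna in self.targets

    def __getitem__(self, mirna: str) -> FrozenSet[str]:
        return self.targets[mirna]

    def get(self, mirna: str, default=frozenset()) -> FrozenSet[str]:
        return self.targets.get(mirna, default)

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def mirna_ids(self) -> List[str]:
        return list(self.targets)


def _canon_edge(a: str, b: str) -> Tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class InteractionTable:
    """Undirected gene-product interaction edges (Ingenuity/STRING-style export).

    Self-loops are dropped with a warning; duplicate pairs collapse to one
    edge (first source tag wins).
    """

    def __init__(self, edges: Sequence[Tuple[str, str, str]]):
        seen: Dict[Tuple[str, str], str] = {}
        n_loops = 0
        for a, b, src in edges:
            if a == b:
                n_loops += 1
                continue
            key = _canon_edge(a, b)
            if key not in seen:
                seen[key] = src
        if n_loops:
            warnings.warn(
                f"dropped {n_loops} self-loop interaction(s)", stacklevel=2
            )
        self.edges: List[Tuple[str, str, str]] = [
            (a, b, src) for (a, b), src in seen.items()
        ]

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[Tuple[str, str, str]]:
        return iter(self.edges)

    def pairs(self) -> List[Tuple[str, str]]:
        return [(a, b) for a, b, _ in self.edges]


UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class DERecord:
    """Per-feature differential expression result.

    ``fold`` is the signed ratio convention used in array studies: +2.0 is a
    two-fold increase under exposure, -2.0 a two-fold decrease; a ratio of 1
    is reported as +1.0.  ``direction`` is 'up' iff fold > 0.
    """

    feature_id: str
    fold: float
    t_stat: float
    p_value: float
    q_value: float
    direction: str = field(default="")

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0,1], got {self.p_value}")
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"q_value must be in [0,1], got {self.q_value}")
        expect = UP if self.fold > 0 else DOWN
        if self.direction == "":
            object.__setattr__(self, "direction", expect)
        elif self.direction != expect:
            raise ValueError(
                f"direction {self.direction!r} inconsistent with fold {self.fold}"
            )


class CollapseMap:
    """Many-to-one probe -> gene mapping used to collapse probe-level rows."""

    def __init__(self, mapping: Mapping[str, str]):
        self.mapping: Dict[str, str] = dict(mapping)
        for probe, gene in self.mapping.items():
            if not gene:
                raise ValueError(f"probe {probe!r} maps to empty gene ID")

    def __getitem__(self, probe: str) -> str:
        return self.mapping[probe]

    def __contains__(self, probe: str) -> bool:
        return probe in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)
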