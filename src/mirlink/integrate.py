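"""Anti-correlation linkage of differentially expressed miRNAs to modules.

A miRNA represses its targets, so its expression change is expected to be
anti-correlated with theirs.  A differentially expressed miRNA is linked to
an enriched functional module when the module's leading edge contains at
least one predicted target of the miRNA whose expression moved in the
opposite direction.  Direction is compared at the level of DE signs (miRNA
fold sign vs gene ranking-score sign); an optional stricter mode
additionally requires a negative sample-level Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .containers import DERecord, ExpressionMatrix, TargetMap
from .gsea import ModuleResult

__all__ = [
    "MiRNAModuleLink",
    "LinkageResult",
    "link_mirnas_to_modules",
    "bipartite_summary",
]


@dataclass(frozen=True)
class MiRNAModuleLink:
    """One (miRNA, module) regulatory link supported by anti-correlated targets.

    Every linking gene is a predicted target of the miRNA, lies in the
    module's leading edge, and moved opposite to the miRNA.
    """

    mirna_id: str
    mirna_direction: str  # 'up' | 'down'
    module_name: str
    linking_genes: Tuple[Tuple[str, str], ...]  # (gene, gene_direction), rank order

    def __post_init__(self):
        if not self.linking_genes:
            raise ValueError("link must carry at least one linking gene")
        for gene, gdir in self.linking_genes:
            if gdir == self.mirna_direction:
                raise ValueError(
                    f"linking gene {gene!r} is not anti-correlated with "
                    f"{self.mirna_id!r}"
                )


@dataclass(frozen=True)
class LinkageResult:
    links: Tuple[MiRNAModuleLink, ...]
    unlinked_mirnas: Tuple[str, ...]  # DE miRNAs with zero module links

    def for_module(self, module_name: str) -> List[MiRNAModuleLink]:
        return [l for l in self.links if l.module_name == module_name]


def _anticorrelated(
    mirna: str,
    gene: str,
    mrna: ExpressionMatrix,
    mirna_m: ExpressionMatrix,
    threshold: float,
) -> bool:
    if gene not in mrna.values.index or mirna not in mirna_m.values.index:
        return False
    common = [s for s in mrna.sample_ids if s in set(mirna_m.sample_ids)]
    if len(common) < 3:
        return False
    x = mrna.values.loc[gene, common].to_numpy()
    y = mirna_m.values.loc[mirna, common].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return False
    r = float(np.corrcoef(x, y)[0, 1])
    return r < threshold


def link_mirnas_to_modules(
    de_mirnas: Sequence[DERecord],
    tmap: TargetMap,
    modules: Sequence[ModuleResult],
    require_correlation: bool = False,
    correlation_threshold: float = -0.3,
    mrna_matrix: Optional[ExpressionMatrix] = None,
    mirna_matrix: Optional[ExpressionMatrix] = None,
) -> LinkageResult:
    """Link each DE miRNA to every module harboring anti-correlated targets.

    ``de_mirnas`` should already be filtered to the significance threshold.
    A miRNA absent from the target map yields a warning and no links.  When
    ``require_correlation`` is set, linking genes must additionally show a
    sample-level Pearson correlation below ``correlation_threshold`` with
    the miRNA (both expression matrices must then be supplied).

    Returns the sorted link list together with the DE miRNAs that linked to
    no module at all.
    """
    if require_correlation and (mrna_matrix is None or mirna_matrix is None):
        raise ValueError(
            "require_correlation needs both mRNA and miRNA expression matrices"
        )
    links: List[MiRNAModuleLink] = []
    linked: set = set()
    for rec in sorted(de_mirnas, key=lambda r: r.feature_id):
        if rec.feature_id not in tmap:
            warnings.warn(
                f"miRNA {rec.feature_id!r} absent from target map; no links",
                stacklevel=2,
            )
            continue
        targets = tmap[rec.feature_id]
        for module in sorted(modules, key=lambda m: m.module_name):
            qualifying: List[Tuple[str, str]] = []
            for gene in module.leading_edge:  # already rank-ordered
                if gene not in targets:
                    continue
                gdir = module.gene_directions[gene]
                if gdir == rec.direction:
                    continue
                if require_correlation and not _anticorrelated(
                    rec.feature_id,
                    gene,
                    mrna_matrix,
                    mirna_matrix,
                    correlation_threshold,
                ):
                    continue
                qualifying.append((gene, gdir))
            if qualifying:
                links.append(
                    MiRNAModuleLink(
                        mirna_id=rec.feature_id,
                        mirna_direction=rec.direction,
                        module_name=module.module_name,
                        linking_genes=tuple(qualifying),
                    )
                )
                linked.add(rec.feature_id)
    unlinked = tuple(
        sorted(r.feature_id for r in de_mirnas if r.feature_id not in linked)
    )
    return LinkageResult(tuple(links), unlinked)


def bipartite_summary(links: Sequence[MiRNAModuleLink]) -> Dict[str, dict]:
    """Per-miRNA module counts and per-module miRNA lists, deterministically ordered."""
    mirna_counts: Dict[str, int] = {}
    module_mirnas: Dict[str, List[str]] = {}
    for l in links:
        mirna_counts[l.mirna_id] = mirna_counts.get(l.mirna_id, 0) + 1
        module_mirnas.setdefault(l.module_name, []).append(l.mirna_id)
    return {
        "mirna_module_counts": dict(sorted(mirna_counts.items())),
        "module_mirnas": {
            k: sorted(v) for k, v in sorted(module_mirnas.items())
        },
    }
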