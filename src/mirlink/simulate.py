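"""Seeded generator of paired mRNA/miRNA study data with known ground truth.

The generator emulates a two-group one-color array experiment (exposure vs
control, 8 animals per group by default): log2 intensities are Gaussian
around a common baseline, a handful of gene sets are "planted" as enriched
by shifting a fraction of their members up or down in the exposure group
(directions alternate so both enrichment tails are exercised), and each
planted set is paired with one planted miRNA shifted in the opposite
direction whose predicted-target list is seeded with that set's shifted
genes.  The accompanying truth tables record every planted structure and
the module links they are expected to produce under the anti-correlation
rule, so each pipeline stage can be scored against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Tuple

import numpy as np
import pandas as pd

from .containers import (
    DERecord,
    ExpressionMatrix,
    FeatureKind,
    GeneSet,
    GeneSetCollection,
    GroupDesign,
    InteractionTable,
    TargetMap,
)
from .gsea import DOWN_IN_EXPOSURE, UP_IN_EXPOSURE, ModuleResult
from . import io as mio

__all__ = ["SimConfig", "TruthTables", "SimData", "generate"]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic paired-omics experiment.

    Defaults mirror the emulated design: 8 exposure vs 8 control arrays,
    ~2000 unique genes, a few hundred miRNA probes, 200 gene sets of size
    15-50 of which 10 are planted, a one-unit log2 shift (= two-fold) on 70%
    of each planted set's genes, and a 0.8 log2 shift on planted miRNAs.
    """

    n_genes: int = 2000
    n_mirnas: int = 300
    n_samples_per_group: int = 8
    n_gene_sets: int = 200
    set_size_min: int = 15
    set_size_max: int = 50
    n_planted_sets: int = 10
    gene_effect: float = 1.0       # log2 shift of planted-set genes
    mirna_effect: float = 0.8      # log2 shift of planted miRNAs
    noise_sd: float = 1.0          # array noise on the log2 scale
    shifted_fraction: float = 0.7  # fraction of a planted set's genes shifted
    targets_per_mirna: int = 30    # predicted targets per planted miRNA
    planted_target_fraction: float = 0.5  # >= this fraction from the paired set
    baseline: float = 8.0          # mean log2 intensity
    n_decoy_target_mirnas: int = 50
    n_decoy_edges: int = 200
    interaction_edge_prob: float = 0.1
    n_undetected_mirnas: int = 12
    seed: int = 0

    def __post_init__(self):
        if min(
            self.n_genes,
            self.n_mirnas,
            self.n_samples_per_group,
            self.n_gene_sets,
            self.n_planted_sets,
            self.targets_per_mirna,
        ) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_planted_sets > self.n_gene_sets:
            raise ValueError("planted sets cannot exceed total sets")
        if self.n_planted_sets > self.n_mirnas:
            raise ValueError("need one miRNA per planted set")
        if not (0 < self.shifted_fraction <= 1):
            raise ValueError("shifted_fraction must be in (0,1]")
        if not (0 < self.planted_target_fraction <= 1):
            raise ValueError("planted_target_fraction must be in (0,1]")
        if self.set_size_min < 2 or self.set_size_max < self.set_size_min:
            raise ValueError("invalid set size range")
        if self.set_size_max >= self.n_genes:
            raise ValueError("set sizes must be smaller than the gene count")
        if self.noise_sd < 0 or self.gene_effect < 0 or self.mirna_effect < 0:
            raise ValueError("effect sizes and noise sd must be non-negative")


@dataclass(frozen=True)
class TruthTables:
    """Planted ground truth: set/miRNA directions, targets, expected links.

    ``expected_links`` maps (mirna, set_name) to the genes that satisfy the
    anti-correlation linkage rule given the planted directions; it is
    derivable from the other fields by enumerating all (miRNA, set, gene)
    triples.
    """

    planted_set_directions: Mapping[str, int]          # set -> +1 / -1
    shifted_genes: Mapping[str, Tuple[str, ...]]       # set -> shifted members
    planted_mirna_directions: Mapping[str, int]        # mirna -> +1 / -1
    mirna_to_set: Mapping[str, str]                    # planted pairing
    planted_targets: FrozenSet[Tuple[str, str]]        # (mirna, gene)
    expected_links: Mapping[Tuple[str, str], FrozenSet[str]]

    def truth_modules(self) -> List[ModuleResult]:
        """One module per planted set, leading edge = its shifted genes."""
        out = []
        for name, direction in self.planted_set_directions.items():
            genes = tuple(sorted(self.shifted_genes[name]))
            gdir = "up" if direction > 0 else "down"
            out.append(
                ModuleResult(
                    module_name=name,
                    member_sets=(name,),
                    leading_edge=genes,
                    gene_directions={g: gdir for g in genes},
                    direction=UP_IN_EXPOSURE if direction > 0 else DOWN_IN_EXPOSURE,
                )
            )
        return out

    def truth_de_mirnas(self) -> List[DERecord]:
        """Synthetic DE records carrying the planted miRNA directions."""
        out = []
        for mirna, direction in self.planted_mirna_directions.items():
            fold = 2.0 if direction > 0 else -2.0
            out.append(
                DERecord(
                    feature_id=mirna,
                    fold=fold,
                    t_stat=5.0 * direction,
                    p_value=1e-4,
                    q_value=1e-4,
                )
            )
        return out


@dataclass(frozen=True)
class SimData:
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    design: GroupDesign
    sets: GeneSetCollection
    tmap: TargetMap
    interactions: InteractionTable
    truth: TruthTables

    def write(self, outdir) -> Dict[str, str]:
        """Write every input in its pipeline text format; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mrna": str(outdir / "mrna.tsv"),
            "mirna": str(outdir / "mirna.tsv"),
            "design": str(outdir / "design.tsv"),
            "gene_sets": str(outdir / "gene_sets.gmt"),
            "targets": str(outdir / "targets.tsv"),
            "interactions": str(outdir / "interactions.tsv"),
        }
        mio.write_expression_tsv(self.mrna, paths["mrna"])
        mio.write_expression_tsv(self.mirna, paths["mirna"])
        with open(paths["design"], "w") as fh:
            fh.write("sample\tgroup\n")
            for s in self.mrna.sample_ids:
                fh.write(f"{s}\t{self.design.assignment[s]}\n")
        mio.write_gmt(self.sets, paths["gene_sets"])
        mio.write_target_map(self.tmap, paths["targets"])
        mio.write_interactions(self.interactions, paths["interactions"])
        return paths


def _expected_links(
    planted_set_dir: Dict[str, int],
    shifted: Dict[str, Tuple[str, ...]],
    mirna_dir: Dict[str, int],
    targets: Dict[str, FrozenSet[str]],
) -> Dict[Tuple[str, str], FrozenSet[str]]:
    """Enumerate the anti-correlation linkage rule over planted structures."""
    links: Dict[Tuple[str, str], FrozenSet[str]] = {}
    for mirna, mdir in mirna_dir.items():
        for sname, sdir in planted_set_dir.items():
            if sdir == mdir:
                continue  # not anti-correlated
            genes = frozenset(shifted[sname]) & targets[mirna]
            if genes:
                links[(mirna, sname)] = genes
    return links


def generate(cfg: SimConfig = SimConfig()) -> SimData:
    """Generate one synthetic paired mRNA/miRNA study, reproducible from seed."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples_per_group
    genes = [f"G{i:05d}" for i in range(1, cfg.n_genes + 1)]
    mirnas = [f"sim-miR-{i:04d}" for i in range(1, cfg.n_mirnas + 1)]
    exp_samples = [f"SF{i:02d}" for i in range(1, n + 1)]
    ctl_samples = [f"C{i:02d}" for i in range(1, n + 1)]
    samples = exp_samples + ctl_samples
    design = GroupDesign.from_samples(exp_samples, ctl_samples)

    # --- gene sets with planted directions -----------------------------
    set_names = [f"SET{i:04d}" for i in range(1, cfg.n_gene_sets + 1)]
    members: Dict[str, np.ndarray] = {}
    for name in set_names:
        size = int(rng.integers(cfg.set_size_min, cfg.set_size_max + 1))
        members[name] = rng.choice(cfg.n_genes, size=size, replace=False)
    planted = set_names[: cfg.n_planted_sets]
    planted_set_dir = {name: (1 if i % 2 == 0 else -1) for i, name in enumerate(planted)}
    shifted: Dict[str, Tuple[str, ...]] = {}
    for name in planted:
        idx = members[name]
        n_shift = max(1, int(round(cfg.shifted_fraction * len(idx))))
        pick = rng.choice(idx, size=n_shift, replace=False)
        shifted[name] = tuple(sorted(genes[i] for i in pick))

    # --- mRNA matrix ----------------------------------------------------
    X = cfg.baseline + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, 2 * n))
    gene_index = {g: i for i, g in enumerate(genes)}
    for name in planted:
        d = planted_set_dir[name]
        for g in shifted[name]:
            X[gene_index[g], :n] += d * cfg.gene_effect
    mrna = ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=samples), FeatureKind.GENE
    )

    # --- planted miRNAs (opposite direction to their paired set) --------
    planted_mirnas = mirnas[: cfg.n_planted_sets]
    mirna_to_set = dict(zip(planted_mirnas, planted))
    mirna_dir = {m: -planted_set_dir[s] for m, s in mirna_to_set.items()}
    Y = cfg.baseline + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_mirnas, 2 * n))
    mirna_index = {m: i for i, m in enumerate(mirnas)}
    for m, d in mirna_dir.items():
        Y[mirna_index[m], :n] += d * cfg.mirna_effect
    # detection flags: a few null miRNA probes are undetected on all arrays
    det = np.ones((cfg.n_mirnas, 2 * n), dtype=bool)
    n_undet = min(cfg.n_undetected_mirnas, cfg.n_mirnas - cfg.n_planted_sets)
    if n_undet > 0:
        undet_pool = np.arange(cfg.n_planted_sets, cfg.n_mirnas)
        undet = rng.choice(undet_pool, size=n_undet, replace=False)
        det[undet, :] = False
    mirna_m = ExpressionMatrix(
        pd.DataFrame(Y, index=mirnas, columns=samples),
        FeatureKind.MIRNA,
        pd.DataFrame(det, index=mirnas, columns=samples),
    )

    # --- target map: planted pairs + decoys ------------------------------
    targets: Dict[str, FrozenSet[str]] = {}
    for m in planted_mirnas:
        sname = mirna_to_set[m]
        pool = list(shifted[sname])
        n_from_set = min(
            len(pool),
            max(1, int(round(cfg.planted_target_fraction * cfg.targets_per_mirna))),
        )
        from_set = list(rng.choice(pool, size=n_from_set, replace=False))
        outside = [g for g in genes if g not in set(pool)]
        n_decoy = cfg.targets_per_mirna - n_from_set
        decoys = list(
            np.asarray(outside)[rng.choice(len(outside), size=n_decoy, replace=False)]
        )
        targets[m] = frozenset(from_set + decoys)
    n_decoy_mirnas = min(cfg.n_decoy_target_mirnas, cfg.n_mirnas - len(planted_mirnas))
    for m in mirnas[cfg.n_planted_sets : cfg.n_planted_sets + n_decoy_mirnas]:
        pick = rng.choice(cfg.n_genes, size=cfg.targets_per_mirna, replace=False)
        targets[m] = frozenset(genes[i] for i in pick)
    tmap = TargetMap(targets)

    # --- interaction table: random graph over planted-set genes + decoys -
    edges: List[Tuple[str, str, str]] = []
    for name in planted:
        ids = sorted(genes[i] for i in members[name])
        for i in range(len(ids)):
            draws = rng.random(len(ids) - i - 1)
            for off, u in enumerate(draws):
                if u < cfg.interaction_edge_prob:
                    edges.append((ids[i], ids[i + 1 + off], "sim"))
    for _ in range(cfg.n_decoy_edges):
        i, j = rng.choice(cfg.n_genes, size=2, replace=False)
        edges.append((genes[i], genes[j], "decoy"))
    interactions = InteractionTable(edges)

    sets = GeneSetCollection(
        [
            GeneSet(name, "synthetic gene set", frozenset(genes[i] for i in members[name]))
            for name in set_names
        ]
    )
    truth = TruthTables(
        planted_set_directions=planted_set_dir,
        shifted_genes=shifted,
        planted_mirna_directions=mirna_dir,
        mirna_to_set=mirna_to_set,
        planted_targets=frozenset(
            (m, g) for m in planted_mirnas for g in targets[m]
        ),
        expected_links=_expected_links(planted_set_dir, shifted, mirna_dir, targets),
    )
    return SimData(mrna, mirna_m, design, sets, tmap, interactions, truth)
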