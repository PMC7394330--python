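"""Pathway-overlap validation of specific vs general modules.

Known pathway gene sets (GMT format) are intersected with the network; the
fraction of those genes falling in modules labelled *specific* versus
*general* estimates how well the specificity ranking concentrates pathway
genes.  Genes in sub-mesoscale (never-scored) modules count in neither
fraction, so the two fractions need not sum to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .detection import ModulePartition
from .network import ProteinNetwork
from .specificity import ModuleFunctionalProfile

logger = logging.getLogger(__name__)


class GmtParseError(ValueError):
    pass


@dataclass(frozen=True)
class PathwayGeneSet:
    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} has an empty gene set")


@dataclass(frozen=True)
class PathwayOverlap:
    pathway: str
    n_in_network: int
    specific_fraction: float | None
    general_fraction: float | None
    n_unlabeled: int


def read_gmt(path) -> list[PathwayGeneSet]:
    """Read pathway gene sets from GMT (name TAB description TAB gene...)."""
    out: list[PathwayGeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            name, desc, genes = fields[0], fields[1], fields[2:]
            out.append(PathwayGeneSet(name=name, genes=frozenset(g for g in genes if g), source=desc))
    return out


def write_gmt(pathways: list[PathwayGeneSet], path) -> None:
    with open(path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.name, p.source or "na", *sorted(p.genes)]) + "\n")


def pathway_network_overlap(pathway: PathwayGeneSet, net: ProteinNetwork) -> int:
    """Number of pathway genes present in the network."""
    return len(pathway.genes & net.nodes)


def pathway_module_overlap(
    pathway: PathwayGeneSet,
    profiles: list[ModuleFunctionalProfile],
    partition: ModulePartition,
    net: ProteinNetwork,
) -> PathwayOverlap:
    """Fractions of the pathway's in-network genes in specific/general modules.

    The denominator is |pathway ∩ network|; genes in modules without a
    functional profile (sub-mesoscale, never scored) are excluded from both
    fractions and reported as ``n_unlabeled``.  An empty denominator yields
    missing fractions and a warning.
    """
    label_by_module = {p.module_id: p.label for p in profiles}
    in_net = pathway.genes & net.nodes
    if not in_net:
        logger.warning("pathway %s shares no genes with network %s", pathway.name, net.name)
        return PathwayOverlap(pathway.name, 0, None, None, 0)
    n_spec = n_gen = n_unlabeled = 0
    for gene in in_net:
        label = label_by_module.get(partition.assignment.get(gene))
        if label == "specific":
            n_spec += 1
        elif label == "general":
            n_gen += 1
        else:
            n_unlabeled += 1
    denom = len(in_net)
    return PathwayOverlap(
        pathway=pathway.name,
        n_in_network=denom,
        specific_fraction=n_spec / denom,
        general_fraction=n_gen / denom,
        n_unlabeled=n_unlabeled,
    )


def overlap_table(
    pathways: list[PathwayGeneSet],
    profiles: list[ModuleFunctionalProfile],
    partition: ModulePartition,
    net: ProteinNetwork,
) -> pd.DataFrame:
    """Per-pathway overlap fractions as a DataFrame."""
    rows = [
        vars(pathway_module_overlap(p, profiles, partition, net)) for p in pathways
    ]
    return pd.DataFrame(
        rows,
        columns=["pathway", "n_in_network", "specific_fraction", "general_fraction", "n_unlabeled"],
    )


def plot_overlap(df: pd.DataFrame, path) -> None:
    """Grouped-bar chart of specific vs general overlap fractions per pathway."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    x = np.arange(len(df))
    width = 0.38
    fig, ax = plt.subplots(figsize=(1.6 * max(4, len(df)), 4))
    ax.bar(x - width / 2, df["specific_fraction"].fillna(0), width, label="specific modules")
    ax.bar(x + width / 2, df["general_fraction"].fillna(0), width, label="general modules")
    ax.set_xticks(x)
    ax.set_xticklabels(df["pathway"], rotation=30, ha="right")
    ax.set_ylabel("fraction of in-network pathway genes")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
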