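"""Disease-gene filtering and compound–disease–DEG intersection logic.

Disease gene tables from scored sources are filtered with strict
per-source score cut-offs (DisGeNET > 0.1, GeneCards > 5, PharmGKB kept
unfiltered) and unioned.  Differential-expression calls from up to three
methods are combined by a k-of-3 consensus vote per direction.  The
pipeline then intersects each compound's predicted targets with the disease
set and the DEGs, and the common core across all compounds is the centre of
the petal diagram.

Gene identity throughout is the uppercased symbol string; no alias
resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: strict (>) score cut-offs per source; ``None`` keeps every gene
DEFAULT_SOURCE_THRESHOLDS: dict[str, float | None] = {
    "disgenet": 0.1,
    "genecards": 5.0,
    "pharmgkb": None,
}

VALID_DIRECTIONS = ("up", "down")
VALID_METHODS = ("edger", "deseq2", "limma")


@dataclass(frozen=True)
class GeneSet:
    """A deduplicated set of uppercased gene symbols with a label."""

    genes: frozenset[str]
    label: str = ""

    @classmethod
    def from_iterable(cls, genes: Iterable[str], label: str = "") -> "GeneSet":
        return cls(genes=frozenset(str(g).upper() for g in genes), label=label)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes

    def __iter__(self):
        return iter(sorted(self.genes))


def filter_disease_genes(
    tables: pd.DataFrame | Sequence[pd.DataFrame],
    thresholds: Mapping[str, float | None] | None = None,
) -> GeneSet:
    """Union of per-source survivors of strict score filtering.

    ``tables`` holds columns ``gene``, ``score``, ``source``; a gene survives
    its source when ``score > threshold`` (strictly), or unconditionally for
    a source whose threshold is ``None``.  Duplicates across sources are
    collapsed in the union.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    thresholds = dict(DEFAULT_SOURCE_THRESHOLDS if thresholds is None else thresholds)
    survivors: set[str] = set()
    for df in tables:
        for col in ("gene", "score", "source"):
            if col not in df.columns:
                raise ValueError(f"scored gene table lacks column {col!r}")
        unknown = set(df["source"].str.lower()) - set(thresholds)
        if unknown:
            raise ValueError(f"unknown sources {sorted(unknown)}; expected {sorted(thresholds)}")
        for source, cutoff in thresholds.items():
            sub = df[df["source"].str.lower() == source]
            if cutoff is not None:
                sub = sub[sub["score"].astype(float) > cutoff]
            survivors.update(sub["gene"].astype(str).str.upper())
    return GeneSet(genes=frozenset(survivors), label="disease")


def consensus_deg(deg_table: pd.DataFrame, k: int = 3) -> dict[str, GeneSet]:
    """k-of-3 consensus differential-expression calls per direction.

    ``deg_table`` has columns ``gene``, ``log2fc``, ``pvalue``, ``direction``
    (``up``/``down``) and ``method``; a gene is kept in a direction when at
    least ``k`` methods call it in that direction.  A method calling one gene
    in both directions is an inconsistency and raises.
    """
    if k not in (1, 2, 3):
        raise ValueError("consensus k must be 1, 2 or 3")
    df = deg_table.copy()
    for col in ("gene", "direction", "method"):
        if col not in df.columns:
            raise ValueError(f"DEG table lacks column {col!r}")
    df["gene"] = df["gene"].astype(str).str.upper()
    df["direction"] = df["direction"].str.lower()
    df["method"] = df["method"].str.lower()
    bad_dir = set(df["direction"]) - set(VALID_DIRECTIONS)
    if bad_dir:
        raise ValueError(f"unknown DEG directions {sorted(bad_dir)}")
    if "log2fc" in df.columns:
        sign_ok = np.where(df["direction"] == "up", df["log2fc"] > 0, df["log2fc"] < 0)
        if not bool(np.all(sign_ok)):
            raise ValueError("DEG direction inconsistent with log2 fold-change sign")
    conflicts = (
        df.groupby(["gene", "method"])["direction"].nunique().pipe(lambda s: s[s > 1])
    )
    if len(conflicts):
        raise ValueError(
            f"conflicting directions within one method for genes {sorted({g for g, _ in conflicts.index})}"
        )
    out: dict[str, GeneSet] = {}
    for direction in VALID_DIRECTIONS:
        votes = (
            df[df["direction"] == direction]
            .drop_duplicates(["gene", "method"])
            .groupby("gene")
            .size()
        )
        out[direction] = GeneSet(
            genes=frozenset(votes[votes >= k].index), label=f"deg_{direction}_k{k}"
        )
    return out


def compound_disease_intersection(
    compound_targets: GeneSet, disease: GeneSet, degs: GeneSet
) -> GeneSet:
    """Three-way intersection: compound targets ∩ disease genes ∩ DEGs."""
    genes = compound_targets.genes & disease.genes & degs.genes
    return GeneSet(genes=genes, label=f"{compound_targets.label}_x_disease_x_deg")


def common_core(sets: Sequence[GeneSet]) -> GeneSet:
    """Intersection across all sets — the centre of the petal diagram."""
    if len(sets) < 2:
        raise ValueError("common core requires at least 2 gene sets")
    genes = frozenset.intersection(*(s.genes for s in sets))
    return GeneSet(genes=genes, label="core")


# ---------------------------------------------------------------------------
# file I/O


def read_gene_set(path: str | Path, label: str = "") -> GeneSet:
    """One symbol per line, or a headered table with a ``gene`` column."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.iloc[0, 0].strip().lower() == "gene":
        genes = df.iloc[1:, 0]
    else:
        genes = df.iloc[:, 0]
    return GeneSet.from_iterable(genes.dropna(), label=label or Path(path).stem)


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    Path(path).write_text("gene\n" + "".join(f"{g}\n" for g in sorted(gs.genes)), encoding="utf-8")


def read_compound_targets(path: str | Path) -> dict[str, GeneSet]:
    """Two-column TSV ``compound``, ``gene`` → per-compound gene sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        str(comp): GeneSet.from_iterable(sub["gene"], label=str(comp))
        for comp, sub in df.groupby("compound", sort=True)
    }


def intersection_report(
    per_compound: Mapping[str, GeneSet], intersections: Mapping[str, GeneSet]
) -> pd.DataFrame:
    rows = [
        {
            "compound": comp,
            "n_targets": len(per_compound[comp]),
            "n_intersection": len(intersections[comp]),
            "genes": ",".join(sorted(intersections[comp].genes)),
        }
        for comp in per_compound
    ]
    return pd.DataFrame(rows)
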