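"""Frontier-orbital descriptor tables: HOMO–LUMO gaps and reactivity ranking.

The package does not run quantum-chemistry calculations; it ingests tables
of externally computed HOMO and LUMO energies (eV), recomputes the gap
``E_LUMO − E_HOMO``, cross-checks any printed gap column against the
recomputed value, and ranks compounds by ascending gap — a smaller gap is
read as higher chemical reactivity.  A packaged table carries the published
B3LYP/6-31G* energies of the ten licorice flavonoids.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

#: flags discrepancies beyond exact-at-two-decimals agreement
DEFAULT_GAP_TOLERANCE = 0.005


def homo_lumo_gap(homo_ev: float, lumo_ev: float, ndigits: int | None = 2) -> float:
    """Gap ``E_LUMO − E_HOMO`` in eV, rounded to 2 decimals for reporting.

    Pass ``ndigits=None`` for the full-precision difference.  The HOMO must
    lie strictly below the LUMO.
    """
    if homo_ev >= lumo_ev:
        raise ValueError(f"E_HOMO ({homo_ev}) must be below E_LUMO ({lumo_ev})")
    gap = lumo_ev - homo_ev
    return gap if ndigits is None else round(gap, ndigits)


def load_descriptor_table(path: str | Path | None = None) -> pd.DataFrame:
    """Descriptor TSV (``compound``, ``homo_ev``, ``lumo_ev``[, ``gap_ev``]).

    Defaults to the packaged table of the ten licorice flavonoids.  Adds a
    full-precision ``gap_computed`` column and validates ``homo < lumo``.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "flavonoid_orbitals.tsv"
    df = pd.read_csv(path, sep="\t")
    for col in ("compound", "homo_ev", "lumo_ev"):
        if col not in df.columns:
            raise ValueError(f"descriptor table lacks column {col!r}")
    bad = df[df["homo_ev"] >= df["lumo_ev"]]
    if len(bad):
        raise ValueError(f"rows with E_HOMO >= E_LUMO: {bad['compound'].tolist()}")
    df = df.copy()
    df["gap_computed"] = df["lumo_ev"] - df["homo_ev"]
    return df


def validate_gaps(rows: pd.DataFrame, tol: float = DEFAULT_GAP_TOLERANCE) -> pd.DataFrame:
    """Rows whose printed gap disagrees with ``E_LUMO − E_HOMO`` beyond *tol*.

    Rows without a printed ``gap_ev`` are skipped.  The validator only
    reports discrepancies; it never alters the printed values.
    """
    if "gap_ev" not in rows.columns:
        return rows.iloc[0:0].assign(discrepancy=pd.Series(dtype=float))
    df = rows.dropna(subset=["gap_ev"]).copy()
    if "gap_computed" not in df.columns:
        df["gap_computed"] = df["lumo_ev"] - df["homo_ev"]
    df["discrepancy"] = (df["gap_ev"] - df["gap_computed"]).abs()
    return df[df["discrepancy"] > tol].reset_index(drop=True)


def reactivity_ranking(rows: pd.DataFrame) -> list[str]:
    """Compound ids ordered by ascending recomputed gap (ties lexicographic)."""
    if len(rows) < 1:
        raise ValueError("reactivity ranking requires at least one row")
    df = rows.copy()
    if "gap_computed" not in df.columns:
        df["gap_computed"] = df["lumo_ev"] - df["homo_ev"]
    df = df.sort_values(["gap_computed", "compound"], kind="mergesort")
    return df["compound"].tolist()
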